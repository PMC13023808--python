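"""Instrument QC: reading, selection, clumping, strength and direction filters,
allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrchain.sumstats import (
    GwasTable,
    LdMatrix,
    clump,
    f_statistic,
    filter_weak_instruments,
    harmonize,
    read_gwas_table,
    select_instruments,
    steiger_filter,
)

from conftest import make_hset, make_table


# ---------------------------------------------------------------- reading

CANON_TSV = (
    "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\tN_CASES\n"
    "rs1\t1\t100000\tA\tG\t0.3\t0.10\t0.01\t1e-9\t30000\t\n"
    "rs2\t1\t200000\tC\tT\t0.4\t-0.08\t0.01\t4e-6\t30000\t\n"
    "rs3\t2\t300000\tG\tA\t0.2\t0.05\t0.02\t6e-6\t30000\t\n"
)


def test_read_well_formed_table_passes_through(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text(CANON_TSV)
    t = read_gwas_table(p, trait_id="g")
    assert len(t) == 3
    assert t.snp_ids == ["rs1", "rs2", "rs3"]  # row order preserved
    assert t.drop_log == []


def test_read_drops_nonpositive_se_with_reason(tmp_path):
    bad = CANON_TSV + "rs4\t2\t400000\tA\tC\t0.1\t0.02\t0\t0.5\t30000\t\n"
    p = tmp_path / "g.tsv"
    p.write_text(bad)
    t = read_gwas_table(p)
    assert len(t) == 3
    assert [(d.snp_id, d.reason) for d in t.drop_log] == [("rs4", "nonpositive_se")]


def test_read_dialect_matches_canonical(tmp_path):
    """A renamed-column file parses to the same records as the canonical one."""
    alt = (
        "rsid\tchrom\tbp\ta1\ta2\tfreq\tb\tse\tp\tn\n"
        "rs1\t1\t100000\tA\tG\t0.3\t0.10\t0.01\t1e-9\t30000\n"
        "rs2\t1\t200000\tC\tT\t0.4\t-0.08\t0.01\t4e-6\t30000\n"
        "rs3\t2\t300000\tG\tA\t0.2\t0.05\t0.02\t6e-6\t30000\n"
    )
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    pa.write_text(CANON_TSV)
    pb.write_text(alt)
    dialect = {"rsid": "SNP", "chrom": "CHR", "bp": "POS", "a1": "EA",
               "a2": "OA", "freq": "EAF", "b": "BETA", "se": "SE",
               "p": "P", "n": "N"}
    ta = read_gwas_table(pa, trait_id="x")
    tb = read_gwas_table(pb, dialect=dialect, trait_id="x")
    pd.testing.assert_frame_equal(
        ta.df.drop(columns="N_CASES"), tb.df.drop(columns="N_CASES")
    )


def test_read_missing_mandatory_column_is_fatal(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text("SNP\tEA\tOA\tBETA\tSE\nrs1\tA\tG\t0.1\t0.01\n")
    with pytest.raises(ValueError, match="P"):
        read_gwas_table(p)


def test_read_empty_after_validation_is_fatal(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\tN_CASES\n"
                 "rs1\t1\t1\tA\tA\t0.3\t0.1\t0.01\t0.5\t100\t\n")
    with pytest.raises(ValueError, match="no valid rows"):
        read_gwas_table(p)


def test_duplicate_snp_keeps_smallest_p():
    t = make_table([
        {"SNP": "rs1", "BETA": 0.1, "SE": 0.01, "P": 1e-4},
        {"SNP": "rs1", "BETA": 0.2, "SE": 0.01, "P": 1e-8},
    ])
    from mrchain.sumstats import _validate_rows

    clean, drops = _validate_rows(t.df, "read")
    assert len(clean) == 1
    assert clean.iloc[0]["P"] == 1e-8
    assert drops[0].reason == "duplicate_snp"


# ---------------------------------------------------------------- selection

def test_select_instruments_strict_threshold():
    t = make_table([
        {"BETA": 0.1, "SE": 0.01, "P": 1e-9},
        {"BETA": 0.1, "SE": 0.01, "P": 4e-6},
        {"BETA": 0.1, "SE": 0.01, "P": 6e-6},
    ])
    kept = select_instruments(t, 5e-6)
    assert kept.snp_ids == ["rs1", "rs2"]
    # boundary value excluded under the strict inequality
    t2 = make_table([{"BETA": 0.1, "SE": 0.01, "P": 5e-6}])
    with pytest.warns(UserWarning):
        assert len(select_instruments(t2, 5e-6)) == 0
    # stricter genome-wide threshold retains all stronger hits
    t4 = make_table([
        {"SNP": f"s{i}", "BETA": 0.1, "SE": 0.01, "P": 1e-9} for i in range(3)
    ])
    assert len(select_instruments(t4, 5e-8)) == 3


@given(st.floats(min_value=1e-10, max_value=0.99))
@settings(max_examples=25, deadline=None)
def test_select_instruments_idempotent(threshold):
    t = make_table([
        {"SNP": f"s{i}", "BETA": 0.1, "SE": 0.01, "P": p}
        for i, p in enumerate([1e-9, 1e-7, 1e-5, 1e-3, 0.5])
    ])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        once = select_instruments(t, threshold)
        twice = select_instruments(once, threshold) if len(once) else once
    assert (twice.df["SNP"].tolist() if len(once) else []) == once.df["SNP"].tolist()


# ---------------------------------------------------------------- clumping

def _ld(ids, pairs):
    n = len(ids)
    m = np.eye(n)
    idx = {s: i for i, s in enumerate(ids)}
    for a, b, r in pairs:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
    return LdMatrix(ids, m)


def test_clump_keeps_smallest_p_index_snps():
    t = make_table([
        {"SNP": "s1", "POS": 1_000_000, "BETA": 0.1, "SE": 0.01, "P": 1e-10},
        {"SNP": "s2", "POS": 1_050_000, "BETA": 0.1, "SE": 0.01, "P": 1e-9},
        {"SNP": "s3", "POS": 1_100_000, "BETA": 0.1, "SE": 0.01, "P": 1e-8},
    ])
    ld = _ld(["s1", "s2", "s3"], [("s1", "s2", 0.5)])
    out = clump(t, ld, r2_max=0.001, window_kb=10_000)
    assert out.snp_ids == ["s1", "s3"]
    assert [(d.snp_id, d.reason) for d in out.drop_log] == [("s2", "clumped")]


def test_clump_unlinked_all_retained():
    t = make_table([
        {"SNP": f"s{i}", "POS": 1_000_000 + i * 1000, "BETA": 0.1, "SE": 0.01, "P": 1e-8}
        for i in range(4)
    ])
    ld = _ld([f"s{i}" for i in range(4)], [])
    assert len(clump(t, ld, 0.001, 10_000)) == 4


def test_clump_outside_window_retained_despite_ld():
    t = make_table([
        {"SNP": "s1", "POS": 1_000_000, "BETA": 0.1, "SE": 0.01, "P": 1e-10},
        {"SNP": "s2", "POS": 21_000_001, "BETA": 0.1, "SE": 0.01, "P": 1e-9},
    ])
    ld = _ld(["s1", "s2"], [("s1", "s2", 0.5)])
    assert len(clump(t, ld, 0.001, 10_000)) == 2


def test_clump_parameter_validation():
    t = make_table([{"BETA": 0.1, "SE": 0.01, "P": 1e-8}])
    ld = _ld(["rs1"], [])
    with pytest.raises(ValueError):
        clump(t, ld, 0.1, -5)
    with pytest.raises(ValueError):
        clump(t, ld, 0.0, 10_000)
    with pytest.raises(ValueError):
        clump(t, ld, 1.5, 10_000)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=20, deadline=None)
def test_clump_output_is_independent_set(seed):
    """No retained pair within the window has r2 >= threshold, and the result
    equals an independently coded greedy reference."""
    rng = np.random.default_rng(seed)
    n = 8
    ids = [f"s{i}" for i in range(n)]
    a = rng.uniform(0, 1, size=(n, n))
    r2 = (a + a.T) / 2
    np.fill_diagonal(r2, 1.0)
    pos = rng.integers(1, 30_000_000, size=n)
    pvals = rng.uniform(1e-12, 1e-4, size=n)
    t = make_table([
        {"SNP": ids[i], "POS": int(pos[i]), "BETA": 0.1, "SE": 0.01, "P": pvals[i]}
        for i in range(n)
    ])
    ld = LdMatrix(ids, r2)
    out = clump(t, ld, r2_max=0.3, window_kb=5_000)
    kept = out.snp_ids

    # brute-force reference: independent greedy walk over p-sorted SNPs
    order = sorted(range(n), key=lambda i: pvals[i])
    ref, removed = [], set()
    for i in order:
        if i in removed:
            continue
        ref.append(ids[i])
        for jj in order:
            if jj != i and jj not in removed and abs(pos[i] - pos[jj]) <= 5_000_000:
                if r2[i, jj] >= 0.3:
                    removed.add(jj)
    assert kept == ref
    idx = {s: i for i, s in enumerate(ids)}
    for x in kept:
        for y in kept:
            if x != y and abs(pos[idx[x]] - pos[idx[y]]) <= 5_000_000:
                assert r2[idx[x], idx[y]] < 0.3


# ---------------------------------------------------------------- F statistic

def test_f_statistic_values():
    assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
    assert f_statistic(0.1, 0.05) == pytest.approx(4.0)
    assert f_statistic(0.0, 0.01) == 0.0


@given(st.floats(min_value=-5, max_value=5, allow_nan=False),
       st.floats(min_value=1e-6, max_value=10))
@settings(max_examples=50, deadline=None)
def test_f_statistic_sign_invariant(beta, se):
    assert f_statistic(beta, se) == pytest.approx(f_statistic(-beta, se))


def test_weak_instrument_filter_strict_at_10():
    t = make_table([
        {"SNP": "strong", "BETA": 0.1, "SE": 0.02, "P": 1e-8},   # F = 25
        {"SNP": "weak", "BETA": 0.1, "SE": 0.05, "P": 1e-8},     # F = 4
        {"SNP": "boundary", "BETA": 0.1, "SE": 0.1 / np.sqrt(10), "P": 1e-8},  # F = 10
    ])
    out = filter_weak_instruments(t, f_min=10.0)
    assert set(out.snp_ids) == {"strong", "boundary"}  # F = 10 retained (strict <)
    assert [(d.snp_id, d.reason) for d in out.drop_log] == [("weak", "weak_instrument")]


# ---------------------------------------------------------------- harmonize

def _pair(exp_rows, out_rows):
    return (make_table(exp_rows, trait_id="e"),
            make_table(out_rows, trait_id="o"))


def test_harmonize_swapped_alleles_flips_sign():
    e, o = _pair(
        [{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.2, "SE": 0.01, "P": 1e-9, "EAF": 0.7}],
        [{"SNP": "rs1", "EA": "G", "OA": "A", "BETA": 0.1, "SE": 0.02, "P": 0.01, "EAF": 0.3}],
    )
    h = harmonize(e, o)
    assert h.beta_out[0] == pytest.approx(-0.1)


def test_harmonize_identical_orientation_unchanged():
    e, o = _pair(
        [{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.2, "SE": 0.01, "P": 1e-9}],
        [{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.1, "SE": 0.02, "P": 0.01}],
    )
    h = harmonize(e, o)
    assert h.beta_out[0] == pytest.approx(0.1)
    assert h.beta_exp[0] == pytest.approx(0.2)


def test_harmonize_ambiguous_palindrome_dropped():
    e, o = _pair(
        [{"SNP": "rs1", "EA": "A", "OA": "T", "BETA": 0.2, "SE": 0.01, "P": 1e-9, "EAF": 0.50},
         {"SNP": "rs2", "EA": "A", "OA": "G", "BETA": 0.2, "SE": 0.01, "P": 1e-9, "EAF": 0.3}],
        [{"SNP": "rs1", "EA": "A", "OA": "T", "BETA": 0.1, "SE": 0.02, "P": 0.01, "EAF": 0.52},
         {"SNP": "rs2", "EA": "A", "OA": "G", "BETA": 0.1, "SE": 0.02, "P": 0.01, "EAF": 0.3}],
    )
    h = harmonize(e, o, palindrome_eaf_band=0.08)
    assert list(h.snp_id) == ["rs2"]
    assert [(d.snp_id, d.reason) for d in h.drop_log] == [("rs1", "ambiguous_palindrome")]


def test_harmonize_unambiguous_palindrome_oriented_by_frequency():
    # both studies report the minor allele on the same side of 0.5: no flip
    e, o = _pair(
        [{"SNP": "rs1", "EA": "A", "OA": "T", "BETA": 0.2, "SE": 0.01, "P": 1e-9, "EAF": 0.2}],
        [{"SNP": "rs1", "EA": "A", "OA": "T", "BETA": 0.1, "SE": 0.02, "P": 0.01, "EAF": 0.22}],
    )
    assert harmonize(e, o).beta_out[0] == pytest.approx(0.1)
    # opposite sides: the outcome's label refers to the strand complement
    e, o = _pair(
        [{"SNP": "rs1", "EA": "A", "OA": "T", "BETA": 0.2, "SE": 0.01, "P": 1e-9, "EAF": 0.2}],
        [{"SNP": "rs1", "EA": "A", "OA": "T", "BETA": 0.1, "SE": 0.02, "P": 0.01, "EAF": 0.78}],
    )
    assert harmonize(e, o).beta_out[0] == pytest.approx(-0.1)


def test_harmonize_incompatible_alleles_dropped():
    e, o = _pair(
        [{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.2, "SE": 0.01, "P": 1e-9},
         {"SNP": "rs2", "EA": "A", "OA": "G", "BETA": 0.2, "SE": 0.01, "P": 1e-9}],
        [{"SNP": "rs1", "EA": "A", "OA": "C", "BETA": 0.1, "SE": 0.02, "P": 0.01},
         {"SNP": "rs2", "EA": "A", "OA": "G", "BETA": 0.1, "SE": 0.02, "P": 0.01}],
    )
    h = harmonize(e, o)
    assert list(h.snp_id) == ["rs2"]
    assert h.drop_log[0].reason == "incompatible_alleles"


def test_harmonize_strand_complement_resolved():
    # T/C reported in the outcome is the complement of the exposure's A/G
    e, o = _pair(
        [{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.2, "SE": 0.01, "P": 1e-9}],
        [{"SNP": "rs1", "EA": "T", "OA": "C", "BETA": 0.1, "SE": 0.02, "P": 0.01}],
    )
    assert harmonize(e, o).beta_out[0] == pytest.approx(0.1)
    e, o = _pair(
        [{"SNP": "rs1", "EA": "A", "OA": "G", "BETA": 0.2, "SE": 0.01, "P": 1e-9}],
        [{"SNP": "rs1", "EA": "C", "OA": "T", "BETA": 0.1, "SE": 0.02, "P": 0.01, "EAF": 0.7}],
    )
    assert harmonize(e, o).beta_out[0] == pytest.approx(-0.1)


def test_harmonize_empty_intersection_fatal():
    e, o = _pair(
        [{"SNP": "rs1", "BETA": 0.2, "SE": 0.01, "P": 1e-9}],
        [{"SNP": "rs2", "BETA": 0.1, "SE": 0.02, "P": 0.01}],
    )
    with pytest.raises(ValueError, match="no shared SNPs"):
        harmonize(e, o)


def test_harmonize_idempotent_and_flip_consistent(rng):
    """Re-harmonizing an aligned pair changes nothing; recoding every outcome
    record to the opposite allele pair gives an identical harmonized set."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    alleles = [("A", "G"), ("C", "T"), ("G", "T"), ("A", "C")]
    exp_rows, out_rows, flip_rows = [], [], []
    for i in range(8):
        ea, oa = alleles[i % 4]
        b_e, b_o = rng.normal(0, 0.1), rng.normal(0, 0.05)
        eaf = rng.uniform(0.1, 0.4)
        base = {"SNP": f"rs{i}", "EA": ea, "OA": oa, "SE": 0.01, "P": 1e-9, "EAF": eaf}
        exp_rows.append({**base, "BETA": b_e})
        out_rows.append({**base, "BETA": b_o, "SE": 0.02, "P": 0.5})
        flip_rows.append({**base, "EA": oa, "OA": ea, "BETA": -b_o,
                          "EAF": 1 - eaf, "SE": 0.02, "P": 0.5})
    e = make_table(exp_rows, trait_id="e")
    o = make_table(out_rows, trait_id="o")
    of = make_table(flip_rows, trait_id="o")
    h1 = harmonize(e, o)
    h2 = harmonize(e, of)
    np.testing.assert_allclose(h1.beta_out, h2.beta_out)
    np.testing.assert_allclose(h1.beta_exp, h2.beta_exp)
    # idempotence: rebuild an outcome table from the harmonized arrays
    re_rows = [
        {"SNP": str(s), "EA": exp_rows[i]["EA"], "OA": exp_rows[i]["OA"],
         "BETA": h1.beta_out[i], "SE": h1.se_out[i], "P": 0.5,
         "EAF": exp_rows[i]["EAF"]}
        for i, s in enumerate(h1.snp_id)
    ]
    h3 = harmonize(e, make_table(re_rows, trait_id="o"))
    np.testing.assert_allclose(h3.beta_out, h1.beta_out)


# ---------------------------------------------------------------- Steiger

def test_steiger_hand_arithmetic_retained():
    # Z_exp = 10 on n = 30,000 vs Z_out = 2 on n = 700,000
    h = make_hset([0.1], [0.01], [0.01], [0.005], n_exp=30_000, n_out=700_000)
    kept, report = steiger_filter(h)
    assert kept.n_snp == 1
    assert report["r2_exposure"][0] == pytest.approx(100 / 30_100, rel=1e-12)
    assert report["r2_outcome"][0] == pytest.approx(4 / 700_004, rel=1e-12)
    assert report["correct_direction"].all()


def test_steiger_reverse_direction_dropped():
    h = make_hset([0.01, 0.1], [0.01, 0.01], [0.5, 0.001], [0.005, 0.005])
    kept, report = steiger_filter(h)
    assert list(kept.snp_id) == ["rs2"]
    assert kept.drop_log[-1].reason == "steiger_reverse"


def test_steiger_noop_when_all_correct():
    h = make_hset([0.1, 0.2], [0.01, 0.01], [0.01, 0.02], [0.005, 0.005])
    kept, _ = steiger_filter(h)
    assert kept.n_snp == 2
    np.testing.assert_array_equal(kept.beta_exp, h.beta_exp)


def test_steiger_small_n_fatal():
    h = make_hset([0.1], [0.01], [0.01], [0.005], n_exp=2, n_out=700_000)
    with pytest.raises(ValueError):
        steiger_filter(h)
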