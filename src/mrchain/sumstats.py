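"""GWAS summary-statistics containers, readers, and instrument quality control.

This module turns raw per-SNP association tables into analysis-ready,
allele-harmonized instrument sets for two-sample Mendelian randomization:

* :class:`GwasTable` — a validated table of per-SNP marginal associations
  for one trait (quantitative or binary).
* :func:`select_instruments` — genome-wide / suggestive p-value selection.
* :func:`clump` — greedy LD clumping (index-SNP, window + r² rule).
* :func:`f_statistic` / :func:`filter_weak_instruments` — instrument-strength
  screen (drop F < 10 by convention).
* :func:`harmonize` — align exposure and outcome effect alleles, resolving
  strand flips and palindromic SNPs by allele frequency.
* :func:`steiger_filter` — directionality screen removing SNPs that explain
  more variance in the outcome than in the exposure.

Every exclusion is recorded as a :class:`DropRecord` so the provenance of the
final instrument set is auditable (drop logs serialize to TSV).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_COLUMNS",
    "DropRecord",
    "GwasTable",
    "LdMatrix",
    "HarmonizedInstrumentSet",
    "read_gwas_table",
    "select_instruments",
    "clump",
    "f_statistic",
    "filter_weak_instruments",
    "harmonize",
    "steiger_filter",
]

#: Canonical column names for a GWAS summary-statistics table.
CANONICAL_COLUMNS = (
    "SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "N_CASES",
)

_MANDATORY = ("SNP", "EA", "OA", "BETA", "SE", "P")
_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class DropRecord:
    """One excluded SNP: which QC stage removed it and why."""

    snp_id: str
    stage: str
    reason: str


def drop_log_frame(records: list[DropRecord]) -> pd.DataFrame:
    """Drop log as a 3-column DataFrame (snp_id, stage, reason)."""
    return pd.DataFrame(
        [(r.snp_id, r.stage, r.reason) for r in records],
        columns=["snp_id", "stage", "reason"],
    )


@dataclass
class GwasTable:
    """Validated per-SNP summary statistics for a single trait.

    ``df`` holds canonical columns (see :data:`CANONICAL_COLUMNS`); rows are
    unique on ``SNP``. ``trait_type`` is ``"quantitative"`` or ``"binary"``;
    binary traits carry case counts (``N_CASES`` column or ``n_cases``).
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    provenance: str = ""
    n_cases: float | None = None
    drop_log: list[DropRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            has_col = "N_CASES" in self.df.columns and self.df["N_CASES"].notna().any()
            if not has_col and self.n_cases is None:
                raise ValueError(
                    f"binary trait {self.trait_id!r} requires case counts "
                    "(N_CASES column or n_cases metadata)"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.df["SNP"])

    def with_df(self, df: pd.DataFrame, extra_drops: list[DropRecord] | None = None) -> "GwasTable":
        """Copy of this table with a new row set (drop log carried forward)."""
        log = list(self.drop_log) + list(extra_drops or [])
        return replace(self, df=df.reset_index(drop=True), drop_log=log)


def _validate_rows(df: pd.DataFrame, stage: str) -> tuple[pd.DataFrame, list[DropRecord]]:
    """Row-level invariant enforcement; returns clean rows + drop records."""
    drops: list[DropRecord] = []
    keep = pd.Series(True, index=df.index)

    def flag(bad: pd.Series, reason: str) -> None:
        nonlocal keep
        bad = bad & keep
        for sid in df.loc[bad, "SNP"]:
            drops.append(DropRecord(str(sid), stage, reason))
        keep &= ~bad

    ea = df["EA"].astype(str).str.upper()
    oa = df["OA"].astype(str).str.upper()
    flag(~(ea.isin(_VALID_ALLELES) & oa.isin(_VALID_ALLELES)), "invalid_allele")
    flag(ea == oa, "same_alleles")
    flag(~(pd.to_numeric(df["SE"], errors="coerce") > 0), "nonpositive_se")
    p = pd.to_numeric(df["P"], errors="coerce")
    flag(~((p > 0) & (p <= 1)), "invalid_pval")
    flag(~np.isfinite(pd.to_numeric(df["BETA"], errors="coerce")), "invalid_beta")
    if "EAF" in df.columns:
        eaf = pd.to_numeric(df["EAF"], errors="coerce")
        flag(eaf.notna() & ~((eaf >= 0) & (eaf <= 1)), "invalid_eaf")

    out = df.loc[keep].copy()
    out["EA"] = ea.loc[keep]
    out["OA"] = oa.loc[keep]

    # Duplicate SNP ids: keep the smallest p, log the rest.
    if out["SNP"].duplicated().any():
        order = out.assign(_p=pd.to_numeric(out["P"], errors="coerce")).sort_values(
            "_p", kind="stable"
        )
        dup = order.duplicated("SNP", keep="first")
        for sid in order.loc[dup, "SNP"]:
            drops.append(DropRecord(str(sid), stage, "duplicate_snp"))
        keep_ids = order.loc[~dup].index
        out = out.loc[out.index.isin(keep_ids)]
    return out.reset_index(drop=True), drops


def read_gwas_table(
    path,
    dialect: dict[str, str] | None = None,
    trait_id: str = "",
    trait_type: str = "quantitative",
    provenance: str = "",
    n_cases: float | None = None,
    sep: str | None = None,
) -> GwasTable:
    """Read a delimited summary-statistics file into a validated GwasTable.

    Parameters
    ----------
    path
        Delimited text file with a header row (TSV/CSV/whitespace sniffed
        when ``sep`` is None).
    dialect
        Mapping from source column names to canonical names, e.g.
        ``{"rsid": "SNP", "a1": "EA"}``. Canonical-named files need none.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(CANONICAL_COLUMNS)]
    df["SNP"] = df["SNP"].astype(str)
    clean, drops = _validate_rows(df, stage="read")
    if clean.empty:
        raise ValueError(f"no valid rows remain in {path!r} after validation")
    if not trait_id:
        trait_id = str(path)
    return GwasTable(
        trait_id=trait_id,
        trait_type=trait_type,
        df=clean,
        provenance=provenance or str(path),
        n_cases=n_cases,
        drop_log=drops,
    )


def write_gwas_table(table: GwasTable, path) -> None:
    """Write a GwasTable to canonical TSV."""
    table.df.to_csv(path, sep="\t", index=False)


def select_instruments(table: GwasTable, p_threshold: float) -> GwasTable:
    """Retain SNPs with p strictly below ``p_threshold``.

    Suggestive / genome-wide instrument selection; the inequality is strict
    ("p < threshold"), so a SNP at exactly the threshold is excluded.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    kept = table.df[pd.to_numeric(table.df["P"]) < p_threshold]
    if kept.empty:
        warnings.warn(
            f"no instruments for {table.trait_id!r} at p < {p_threshold:g}",
            stacklevel=2,
        )
    return table.with_df(kept)


@dataclass
class LdMatrix:
    """Squared-correlation (r²) matrix over a set of SNPs.

    Symmetric with unit diagonal; entries in [0, 1].
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 dimensions do not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def get(self, a: str, b: str) -> float | None:
        """r² between two SNPs, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_square_file(cls, path) -> "LdMatrix":
        """Square whitespace/tab-delimited matrix with a header of SNP ids."""
        df = pd.read_csv(path, sep=None, engine="python", index_col=None)
        ids = [str(c) for c in df.columns]
        return cls(ids, df.to_numpy(dtype=float))

    @classmethod
    def from_long_file(cls, path) -> "LdMatrix":
        """Long format: three columns snp_a, snp_b, r2 (unlisted pairs = 0)."""
        df = pd.read_csv(path, sep=None, engine="python")
        a, b, v = df.columns[:3]
        ids = sorted(set(df[a].astype(str)) | set(df[b].astype(str)))
        idx = {s: i for i, s in enumerate(ids)}
        m = np.zeros((len(ids), len(ids)))
        np.fill_diagonal(m, 1.0)
        for sa, sb, r in zip(df[a].astype(str), df[b].astype(str), df[v].astype(float)):
            m[idx[sa], idx[sb]] = r
            m[idx[sb], idx[sa]] = r
        return cls(ids, m)

    def to_square_file(self, path) -> None:
        pd.DataFrame(self.r2, columns=self.snp_ids).to_csv(path, sep="\t", index=False)


def clump(
    table: GwasTable,
    ld: LdMatrix | None,
    r2_max: float,
    window_kb: float,
) -> GwasTable:
    """Greedy LD clumping: keep index SNPs, drop correlated neighbours.

    Repeatedly keeps the smallest-p remaining SNP and removes remaining SNPs
    on the same chromosome within ``window_kb`` (center-to-center) having
    r² ≥ ``r2_max`` with it. SNPs absent from ``ld`` (or ``ld=None``) are
    treated as unlinked, with a logged warning. Output is ordered by p.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must lie in (0, 1]")
    df = table.df.copy()
    df["_p"] = pd.to_numeric(df["P"])
    df = df.sort_values("_p", kind="stable").drop(columns="_p")

    if ld is not None:
        missing = [s for s in df["SNP"] if s not in ld._index]
        if missing:
            warnings.warn(
                f"{len(missing)} SNP(s) absent from LD matrix treated as unlinked",
                stacklevel=2,
            )

    window_bp = window_kb * 1000.0
    kept_rows: list[int] = []
    drops: list[DropRecord] = []
    remaining = list(df.index)
    chrom = df["CHR"].astype(str)
    pos = pd.to_numeric(df["POS"], errors="coerce")
    while remaining:
        idx = remaining.pop(0)
        kept_rows.append(idx)
        survivors = []
        for j in remaining:
            linked = False
            if chrom[idx] == chrom[j] and np.isfinite(pos[idx]) and np.isfinite(pos[j]):
                if abs(pos[idx] - pos[j]) <= window_bp:
                    r2 = ld.get(df.at[idx, "SNP"], df.at[j, "SNP"]) if ld else None
                    linked = r2 is not None and r2 >= r2_max
            if linked:
                drops.append(DropRecord(str(df.at[j, "SNP"]), "clump", "clumped"))
            else:
                survivors.append(j)
        remaining = survivors
    return table.with_df(df.loc[kept_rows], extra_drops=drops)


def f_statistic(beta, se):
    """Per-SNP instrument-strength F statistic, (beta/se)².

    Sign-invariant in beta; equals the square of the Wald Z for the
    SNP-exposure association.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_weak_instruments(table: GwasTable, f_min: float = 10.0) -> GwasTable:
    """Drop SNPs with F strictly below ``f_min`` (weak-instrument screen)."""
    f = f_statistic(table.df["BETA"].to_numpy(), table.df["SE"].to_numpy())
    f = np.atleast_1d(f)
    weak = f < f_min
    drops = [
        DropRecord(str(s), "f_filter", "weak_instrument")
        for s in table.df.loc[weak, "SNP"]
    ]
    return table.with_df(table.df.loc[~weak], extra_drops=drops)


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned exposure/outcome effects for one MR analysis.

    All per-SNP arrays are aligned and equal length. Outcome effects have
    been re-signed so that both betas refer to the same effect allele.
    """

    exposure_id: str
    outcome_id: str
    snp_id: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf: np.ndarray
    n_exp: np.ndarray
    n_out: np.ndarray
    n_cases_out: float | None = None
    drop_log: list[DropRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        arrays = [self.beta_exp, self.se_exp, self.beta_out, self.se_out,
                  self.eaf, self.n_exp, self.n_out]
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        for name in ("beta_exp", "se_exp", "beta_out", "se_out", "eaf", "n_exp", "n_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.snp_id)
        if n < 1:
            raise ValueError("harmonized set must contain at least one SNP")
        for name, arr in zip(
            ("beta_exp", "se_exp", "beta_out", "se_out", "eaf", "n_exp", "n_out"),
            arrays,
        ):
            if len(np.asarray(arr)) != n:
                raise ValueError(f"array {name} length mismatch")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def n_snp(self) -> int:
        return len(self.snp_id)

    def ratios(self) -> np.ndarray:
        """Per-SNP Wald ratios beta_out / beta_exp."""
        return self.beta_out / self.beta_exp

    def ivw_weights(self) -> np.ndarray:
        """Ratio-scale inverse-variance weights beta_exp² / se_out²."""
        return self.beta_exp**2 / self.se_out**2

    def subset(self, mask) -> "HarmonizedInstrumentSet":
        mask = np.asarray(mask)
        return HarmonizedInstrumentSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            snp_id=self.snp_id[mask],
            beta_exp=self.beta_exp[mask],
            se_exp=self.se_exp[mask],
            beta_out=self.beta_out[mask],
            se_out=self.se_out[mask],
            eaf=self.eaf[mask],
            n_exp=self.n_exp[mask],
            n_out=self.n_out[mask],
            n_cases_out=self.n_cases_out,
            drop_log=list(self.drop_log),
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exp: GwasTable,
    out: GwasTable,
    palindrome_eaf_band: float = 0.08,
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    For each SNP shared between the two tables:

    * same allele pair, same orientation — copied unchanged;
    * swapped alleles — outcome beta negated, outcome EAF replaced by 1−EAF;
    * strand-complement matches are resolved the same way after complementing;
    * palindromic (A/T, G/C) SNPs — orientation inferred from allele
      frequency; dropped as ``ambiguous_palindrome`` when either study's EAF
      is missing or within ``palindrome_eaf_band`` of 0.5;
    * anything else — dropped as ``incompatible_alleles``.
    """
    merged = exp.df.merge(out.df, on="SNP", suffixes=("_e", "_o"))
    if merged.empty:
        raise ValueError(
            f"no shared SNPs between {exp.trait_id!r} and {out.trait_id!r}"
        )
    drops: list[DropRecord] = []
    rows = []
    for rec in merged.itertuples(index=False):
        ea_e, oa_e = rec.EA_e, rec.OA_e
        ea_o, oa_o = rec.EA_o, rec.OA_o
        beta_o, eaf_o = rec.BETA_o, rec.EAF_o
        if _is_palindromic(ea_e, oa_e):
            if {ea_o, oa_o} != {ea_e, oa_e}:
                drops.append(DropRecord(rec.SNP, "harmonize", "incompatible_alleles"))
                continue
            eaf_e = rec.EAF_e
            # frequency of the exposure effect allele in the outcome study,
            # under the orientation reported by the outcome file
            eaf_o_aligned = eaf_o if ea_o == ea_e else (
                1 - eaf_o if pd.notna(eaf_o) else np.nan
            )
            ambiguous = (
                pd.isna(eaf_e)
                or pd.isna(eaf_o_aligned)
                or abs(eaf_e - 0.5) <= palindrome_eaf_band
                or abs(eaf_o_aligned - 0.5) <= palindrome_eaf_band
            )
            if ambiguous:
                drops.append(DropRecord(rec.SNP, "harmonize", "ambiguous_palindrome"))
                continue
            # same strand assumed when minor/major orientation agrees
            if (eaf_e - 0.5) * (eaf_o_aligned - 0.5) > 0:
                flip = ea_o != ea_e
            else:
                flip = ea_o == ea_e  # opposite strand: labels refer to complements
            if flip:
                beta_o = -beta_o
                eaf_o = 1 - eaf_o if pd.notna(eaf_o) else np.nan
            rows.append((rec, beta_o, eaf_o))
            continue
        # non-palindromic: direct match, swap, or strand-complement match
        if (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_o = -beta_o
            eaf_o = 1 - eaf_o if pd.notna(eaf_o) else np.nan
        elif (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o]) == (ea_e, oa_e):
            pass
        elif (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o]) == (oa_e, ea_e):
            beta_o = -beta_o
            eaf_o = 1 - eaf_o if pd.notna(eaf_o) else np.nan
        else:
            drops.append(DropRecord(rec.SNP, "harmonize", "incompatible_alleles"))
            continue
        rows.append((rec, beta_o, eaf_o))

    if not rows:
        raise ValueError("no SNPs survive harmonization")

    recs = [r[0] for r in rows]
    n_cases = out.n_cases
    if n_cases is None and "N_CASES" in out.df.columns:
        vals = pd.to_numeric(out.df["N_CASES"], errors="coerce").dropna()
        n_cases = float(vals.median()) if len(vals) else None
    return HarmonizedInstrumentSet(
        exposure_id=exp.trait_id,
        outcome_id=out.trait_id,
        snp_id=np.array([r.SNP for r in recs], dtype=object),
        beta_exp=np.array([r.BETA_e for r in recs], dtype=float),
        se_exp=np.array([r.SE_e for r in recs], dtype=float),
        beta_out=np.array([b for _, b, _ in rows], dtype=float),
        se_out=np.array([r.SE_o for r in recs], dtype=float),
        eaf=np.array([r.EAF_e for r in recs], dtype=float),
        n_exp=np.array([r.N_e for r in recs], dtype=float),
        n_out=np.array([r.N_o for r in recs], dtype=float),
        n_cases_out=n_cases,
        drop_log=drops,
    )


def steiger_filter(
    hset: HarmonizedInstrumentSet,
) -> tuple[HarmonizedInstrumentSet, pd.DataFrame]:
    """Directionality screen: drop SNPs explaining more outcome than exposure
    variance.

    Variance explained is approximated per SNP as r² = Z²/(Z²+n) with
    Z = beta/se — monotone in |Z| and applicable to both quantitative and
    binary traits (for binary outcomes the r² is an observed-scale
    approximation, flagged in the report). The per-SNP p-value compares the
    two correlations by Fisher z-transformation.
    """
    if np.any(hset.n_exp <= 2) or np.any(hset.n_out <= 2):
        raise ValueError("sample sizes must exceed 2 for Steiger filtering")
    z_exp = hset.beta_exp / hset.se_exp
    z_out = hset.beta_out / hset.se_out
    r2_exp = z_exp**2 / (z_exp**2 + hset.n_exp)
    r2_out = z_out**2 / (z_out**2 + hset.n_out)
    keep = r2_out <= r2_exp
    # Fisher z two-correlation comparison (independent samples)
    with np.errstate(divide="ignore"):
        fz = np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))
        denom = np.sqrt(1 / np.maximum(hset.n_exp - 3, 1) + 1 / np.maximum(hset.n_out - 3, 1))
    zstat = fz / denom
    pval = 2 * stats.norm.sf(np.abs(zstat))
    report = pd.DataFrame(
        {
            "snp_id": hset.snp_id,
            "r2_exposure": r2_exp,
            "r2_outcome": r2_out,
            "steiger_z": zstat,
            "steiger_p": pval,
            "correct_direction": keep,
            "binary_outcome_approx": hset.n_cases_out is not None,
        }
    )
    if not keep.any():
        raise ValueError("Steiger filtering removed every instrument")
    kept = hset.subset(keep)
    kept.drop_log = list(hset.drop_log) + [
        DropRecord(str(s), "steiger", "steiger_reverse")
        for s in hset.snp_id[~keep]
    ]
    return kept, report
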