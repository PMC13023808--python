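"""Synthetic GWAS summary statistics with known causal truth.

Generates a three-layer study — a quantitative exposure (an expression trait
instrumented by a handful of cis SNPs), a quantitative mediator (a microbial
abundance trait), and a binary disease outcome — as three linked summary-
statistics tables plus a truth record of every generating parameter, so the
whole MR/mediation pipeline is testable offline.

Two engines:

* ``analytic`` — computes each SNP's expected marginal effect and nominal SE
  from sample size and allele frequency, then samples the observed effect
  from its sampling distribution. Fast enough for thousands of replicate
  studies.
* ``individual`` — simulates genotypes and phenotypes explicitly (liability
  threshold for the binary outcome) and fits per-SNP regressions; used to
  cross-validate the analytic engine at moderate sample sizes.

The causal chain is exposure →(β1) mediator →(β2) outcome, with a direct
exposure→outcome effect β_direct and optional per-SNP pleiotropy, so the true
total effect is β_direct + β1·β2 and the true mediated proportion is
β1·β2 / (β_direct + β1·β2).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import GwasTable, LdMatrix, HarmonizedInstrumentSet

__all__ = [
    "ChainSimConfig",
    "SyntheticStudy",
    "ViolationSpec",
    "simulate_chain",
    "plant_violations",
    "simulate_battery",
    "merge_studies",
    "simulate_instrument_set",
    "liability_logodds_scale",
    "write_study",
]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                         ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]


def liability_logodds_scale(prevalence: float) -> float:
    """First-order scaling constant from liability units to log odds.

    For a liability-threshold trait with prevalence K, a small liability
    effect b translates to a log-odds effect ≈ b·φ(z_K)/(K(1−K)) with
    z_K = Φ⁻¹(1−K).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    z = stats.norm.ppf(1 - prevalence)
    return float(stats.norm.pdf(z) / (prevalence * (1 - prevalence)))


@dataclass
class ChainSimConfig:
    """Generating parameters for one exposure→mediator→outcome study.

    Defaults mirror the scale of the emulated data sources: an eQTL-style
    exposure GWAS of ~30,000 individuals, a metagenomic abundance GWAS of
    5,959 individuals with suggestive-significance instruments, and a
    case-control disease GWAS of 8,434 cases / 770,180 controls.
    """

    j_exp: int = 10
    j_med: int = 15
    maf_range: tuple[float, float] = (0.05, 0.5)
    var_explained_exp: float = 0.03
    var_explained_med: float = 0.05
    beta1: float = 0.2
    beta2: float = 0.5
    beta_direct: float = 0.15
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    n_exp: int = 30_000
    n_med: int = 5_959
    n_out: int = 778_614
    n_cases_out: int = 8_434
    ld_block_r2: float = 0.0
    ld_block_size: int = 1
    engine: str = "analytic"
    seed: int = 0
    exposure_id: str = "gene_1"
    mediator_id: str = "taxon_1"
    outcome_id: str = "disease"
    snp_id_offset: int = 0

    def __post_init__(self) -> None:
        if self.j_exp < 1 or self.j_med < 1:
            raise ValueError("instrument counts must be >= 1")
        for v in (self.var_explained_exp, self.var_explained_med):
            if not 0 < v < 1:
                raise ValueError("variance-explained targets must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.engine not in ("analytic", "individual"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not 0 < self.n_cases_out < self.n_out:
            raise ValueError("n_cases_out must lie strictly between 0 and n_out")


@dataclass
class SyntheticStudy:
    """Three linked GWAS tables plus the generating truth."""

    exposure_gwas: GwasTable
    mediator_gwas: GwasTable
    outcome_gwas: GwasTable
    ld: LdMatrix | None
    truth: dict = field(default_factory=dict)


def _scaled_effects(rng, mafs, var_target):
    """Per-allele effects on a standardized trait with Σ 2p(1−p)β² = target."""
    raw = rng.normal(size=len(mafs))
    var_raw = np.sum(2 * mafs * (1 - mafs) * raw**2)
    return raw * np.sqrt(var_target / var_raw)


def _observed_table(rng, snp, chrom, pos, ea, oa, eaf, true_beta, se, n,
                    trait_id, trait_type, n_cases=None, provenance="synthetic"):
    beta = true_beta + rng.normal(0, se)
    z = beta / se
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    df = pd.DataFrame(
        {
            "SNP": snp,
            "CHR": chrom,
            "POS": pos,
            "EA": ea,
            "OA": oa,
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": float(n),
            "N_CASES": float(n_cases) if n_cases is not None else np.nan,
        }
    )
    return GwasTable(
        trait_id=trait_id,
        trait_type=trait_type,
        df=df,
        provenance=provenance,
        n_cases=float(n_cases) if n_cases is not None else None,
    )


def simulate_chain(config: ChainSimConfig) -> SyntheticStudy:
    """Simulate one three-layer study under ``config``.

    Every SNP appears in all three tables (as in genome-wide summary files):
    exposure instruments act on the mediator via β1 and on the outcome via
    β_direct + β1·β2 plus any per-SNP pleiotropy; mediator instruments act
    on the outcome via β2 and have no effect on the exposure. Identical
    seeds give bit-identical studies.
    """
    if config.engine == "individual":
        return _simulate_individual(config)
    return _simulate_analytic(config)


def _layout(config: ChainSimConfig, rng):
    """Shared SNP layout: ids, positions, alleles, frequencies, true effects."""
    j_e, j_m = config.j_exp, config.j_med
    j = j_e + j_m
    off = config.snp_id_offset
    snp = np.array([f"rs{off + i + 1}" for i in range(j)], dtype=object)
    mafs = rng.uniform(*config.maf_range, size=j)
    pairs = [_NONPALINDROMIC_PAIRS[i] for i in rng.integers(0, len(_NONPALINDROMIC_PAIRS), j)]
    ea = np.array([p[0] for p in pairs], dtype=object)
    oa = np.array([p[1] for p in pairs], dtype=object)

    # LD blocks only among exposure instruments; blocks far apart, members close
    block = config.ld_block_size if config.ld_block_size > 1 else 1
    pos = np.empty(j, dtype=float)
    chrom = np.array(["1"] * j_e + ["2"] * j_m, dtype=object)
    for i in range(j_e):
        pos[i] = 1e6 + (i // block) * 2e7 + (i % block) * 5e4
    for k in range(j_m):
        pos[j_e + k] = 1e6 + k * 2e7

    a = _scaled_effects(rng, mafs[:j_e], config.var_explained_exp)
    m = _scaled_effects(rng, mafs[j_e:], config.var_explained_med)
    pleio = (
        rng.normal(config.pleio_mean, config.pleio_sd, size=j_e)
        if (config.pleio_sd > 0 or config.pleio_mean != 0)
        else np.zeros(j_e)
    )

    ld = None
    if block > 1 and config.ld_block_r2 > 0:
        r2 = np.eye(j)
        for start in range(0, j_e, block):
            idx = np.arange(start, min(start + block, j_e))
            for x in idx:
                for y in idx:
                    if x != y:
                        r2[x, y] = config.ld_block_r2
        ld = LdMatrix(list(snp), r2)
    return snp, chrom, pos, ea, oa, mafs, a, m, pleio, ld


def _truth_record(config, snp, a, m, pleio) -> dict:
    total = config.beta_direct + config.beta1 * config.beta2
    prop = (config.beta1 * config.beta2) / total if total != 0 else float("nan")
    j_e = config.j_exp
    return {
        "config": asdict(config),
        "exposure_snps": list(snp[:j_e]),
        "mediator_snps": list(snp[j_e:]),
        "true_effect_exposure": {s: float(v) for s, v in zip(snp[:j_e], a)},
        "true_effect_mediator_snps": {s: float(v) for s, v in zip(snp[j_e:], m)},
        "pleiotropy": {s: float(v) for s, v in zip(snp[:j_e], pleio)},
        "beta1": config.beta1,
        "beta2": config.beta2,
        "beta_direct": config.beta_direct,
        "total": total,
        "indirect": config.beta1 * config.beta2,
        "proportion": prop,
        "prevalence": config.n_cases_out / config.n_out,
        "liability_logodds_scale": liability_logodds_scale(
            config.n_cases_out / config.n_out
        ),
        "engine": config.engine,
        "seed": config.seed,
        "violations": {},
    }


def _simulate_analytic(config: ChainSimConfig) -> SyntheticStudy:
    rng = np.random.default_rng(config.seed)
    snp, chrom, pos, ea, oa, mafs, a, m, pleio, ld = _layout(config, rng)
    j_e = config.j_exp
    hw = 2 * mafs * (1 - mafs)  # per-SNP genotype variance (HWE)

    total = config.beta_direct + config.beta1 * config.beta2
    true_exp = np.concatenate([a, np.zeros(config.j_med)])
    true_med = np.concatenate([config.beta1 * a, m])
    true_out = np.concatenate([total * a + pleio, config.beta2 * m])

    se_exp = 1.0 / np.sqrt(hw * config.n_exp)
    se_med = 1.0 / np.sqrt(hw * config.n_med)
    k = config.n_cases_out / config.n_out
    se_out = 1.0 / np.sqrt(hw * config.n_out * k * (1 - k))

    exposure = _observed_table(
        rng, snp, chrom, pos, ea, oa, mafs, true_exp, se_exp, config.n_exp,
        config.exposure_id, "quantitative",
    )
    mediator = _observed_table(
        rng, snp, chrom, pos, ea, oa, mafs, true_med, se_med, config.n_med,
        config.mediator_id, "quantitative",
    )
    outcome = _observed_table(
        rng, snp, chrom, pos, ea, oa, mafs, true_out, se_out, config.n_out,
        config.outcome_id, "binary", n_cases=config.n_cases_out,
    )
    return SyntheticStudy(
        exposure_gwas=exposure,
        mediator_gwas=mediator,
        outcome_gwas=outcome,
        ld=ld,
        truth=_truth_record(config, snp, a, m, pleio),
    )


def _ols_per_snp(g, y):
    """Per-column simple-regression beta and se (closed form)."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    beta = gc.T @ yc / sxx
    resid_var = (np.sum(yc**2) - beta**2 * sxx) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    return beta, se


def _logistic_per_snp(g, y, max_iter=30, tol=1e-10):
    """Per-column logistic regression (intercept + genotype) by IRLS."""
    n, j = g.shape
    betas = np.empty(j)
    ses = np.empty(j)
    for col in range(j):
        x = np.column_stack([np.ones(n), g[:, col]])
        b = np.zeros(2)
        for _ in range(max_iter):
            eta = x @ b
            mu = 1 / (1 + np.exp(-eta))
            wdiag = mu * (1 - mu)
            grad = x.T @ (y - mu)
            hess = (x.T * wdiag) @ x
            step = np.linalg.solve(hess, grad)
            b += step
            if np.max(np.abs(step)) < tol:
                break
        cov = np.linalg.inv((x.T * (1 / (1 + np.exp(-(x @ b))) * (1 - 1 / (1 + np.exp(-(x @ b)))))) @ x)
        betas[col] = b[1]
        ses[col] = np.sqrt(cov[1, 1])
    return betas, ses


def _simulate_individual(config: ChainSimConfig) -> SyntheticStudy:
    """Genotype-level simulation with a liability-threshold binary outcome.

    Intended for engine cross-validation; refuses cohort sizes above 50,000.
    """
    for n in (config.n_exp, config.n_med, config.n_out):
        if n > 50_000:
            raise ValueError(
                "individual engine supports cohorts up to 50,000; "
                "use the analytic engine for larger studies"
            )
    rng = np.random.default_rng(config.seed)
    snp, chrom, pos, ea, oa, mafs, a, m, pleio, ld = _layout(config, rng)
    j_e, j_m = config.j_exp, config.j_med
    k = config.n_cases_out / config.n_out
    c = liability_logodds_scale(k)

    def genotypes(n):
        return rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)

    def latent(g):
        x_g = g[:, :j_e] @ a
        var_x = config.var_explained_exp
        x = x_g + rng.normal(0, np.sqrt(max(1 - var_x, 1e-9)), size=len(g))
        m_g = g[:, j_e:] @ m
        var_em = max(1 - config.beta1**2 - config.var_explained_med, 1e-9)
        med = config.beta1 * x + m_g + rng.normal(0, np.sqrt(var_em), size=len(g))
        return x, med

    # exposure cohort
    g_e = genotypes(config.n_exp)
    x_e, _ = latent(g_e)
    b_exp, se_exp = _ols_per_snp(g_e, x_e)

    # mediator cohort
    g_m = genotypes(config.n_med)
    _, med_m = latent(g_m)
    b_med, se_med = _ols_per_snp(g_m, med_m)

    # outcome cohort: liability threshold at the configured prevalence
    g_o = genotypes(config.n_out)
    x_o, med_o = latent(g_o)
    liab = (
        (config.beta_direct / c) * x_o
        + (config.beta2 / c) * med_o
        + g_o[:, :j_e] @ (pleio / c)
        + rng.normal(0, 1, size=config.n_out)
    )
    thresh = np.quantile(liab, 1 - k)
    y = (liab > thresh).astype(float)
    b_out, se_out = _logistic_per_snp(g_o, y)

    def table(b, se, n, trait_id, trait_type, n_cases=None):
        z = b / se
        p = np.maximum(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
        df = pd.DataFrame(
            {
                "SNP": snp, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
                "EAF": mafs, "BETA": b, "SE": se, "P": p, "N": float(n),
                "N_CASES": float(n_cases) if n_cases is not None else np.nan,
            }
        )
        return GwasTable(trait_id=trait_id, trait_type=trait_type, df=df,
                         provenance="synthetic-individual",
                         n_cases=float(n_cases) if n_cases is not None else None)

    return SyntheticStudy(
        exposure_gwas=table(b_exp, se_exp, config.n_exp, config.exposure_id, "quantitative"),
        mediator_gwas=table(b_med, se_med, config.n_med, config.mediator_id, "quantitative"),
        outcome_gwas=table(b_out, se_out, config.n_out, config.outcome_id, "binary",
                           n_cases=config.n_cases_out),
        ld=ld,
        truth=_truth_record(config, snp, a, m, pleio),
    )


@dataclass
class ViolationSpec:
    """Named defects to inject into a clean synthetic study."""

    n_pleiotropic: int = 0
    pleio_shift: float = 0.02
    n_outliers: int = 0
    outlier_ratio_scale: float = 10.0
    outlier_se_factor: float = 0.3
    n_weak: int = 0
    n_reverse: int = 0
    reverse_z_exp: float = 6.0
    reverse_z_out: float = 50.0
    n_palindromic: int = 0
    palindrome_eaf: float = 0.5
    seed: int | None = None


def plant_violations(study: SyntheticStudy, spec: ViolationSpec) -> SyntheticStudy:
    """Return a copy of ``study`` with named defects injected.

    Defects are assigned to disjoint subsets of the exposure instruments
    (chosen with the spec's seed) and each injection is logged in
    ``truth["violations"]``:

    * directional pleiotropy — a constant shift added to the outcome beta;
    * gross outlier — outcome beta rewritten so the Wald ratio is
      ``outlier_ratio_scale`` times the true total effect, with shrunken SE;
    * weak instruments — exposure SE inflated so F = (beta/se)² < 10 by
      construction (the source-reported p-value column is left untouched);
    * reverse-causal SNPs — primary effect moved onto the outcome (large
      outcome Z, just-significant exposure Z);
    * palindromic recodings — alleles set to A/T with near-0.5 frequency in
      both studies, making strand orientation unresolvable.
    """
    rng = np.random.default_rng(spec.seed)
    out = SyntheticStudy(
        exposure_gwas=study.exposure_gwas.with_df(study.exposure_gwas.df.copy()),
        mediator_gwas=study.mediator_gwas.with_df(study.mediator_gwas.df.copy()),
        outcome_gwas=study.outcome_gwas.with_df(study.outcome_gwas.df.copy()),
        ld=study.ld,
        truth=copy.deepcopy(study.truth),
    )
    exp_snps = list(out.truth["exposure_snps"])
    n_needed = (spec.n_pleiotropic + spec.n_outliers + spec.n_weak
                + spec.n_reverse + spec.n_palindromic)
    if n_needed > len(exp_snps):
        raise ValueError(
            f"requested {n_needed} defect SNPs but only {len(exp_snps)} "
            "exposure instruments exist"
        )
    chosen = list(rng.permutation(exp_snps))
    take = lambda k: [chosen.pop() for _ in range(k)]  # noqa: E731
    violations: dict[str, list[str]] = {}

    edf = out.exposure_gwas.df
    odf = out.outcome_gwas.df
    eidx = {s: i for i, s in zip(edf.index, edf["SNP"])}
    oidx = {s: i for i, s in zip(odf.index, odf["SNP"])}
    total = out.truth["total"]

    ids = take(spec.n_pleiotropic)
    for s in ids:
        odf.at[oidx[s], "BETA"] += spec.pleio_shift
    violations["pleiotropic"] = ids

    ids = take(spec.n_outliers)
    for s in ids:
        be = out.truth["true_effect_exposure"][s]
        odf.at[oidx[s], "BETA"] = spec.outlier_ratio_scale * total * be
        odf.at[oidx[s], "SE"] *= spec.outlier_se_factor
    violations["outlier"] = ids

    ids = take(spec.n_weak)
    for s in ids:
        b = edf.at[eidx[s], "BETA"]
        f_target = rng.uniform(1.0, 9.0)
        edf.at[eidx[s], "SE"] = abs(b) / np.sqrt(f_target) if b != 0 else 1.0
    violations["weak"] = ids

    ids = take(spec.n_reverse)
    for s in ids:
        se_e = edf.at[eidx[s], "SE"]
        z = spec.reverse_z_exp
        edf.at[eidx[s], "BETA"] = z * se_e
        edf.at[eidx[s], "P"] = max(2 * stats.norm.sf(z), np.finfo(float).tiny)
        odf.at[oidx[s], "BETA"] = spec.reverse_z_out * odf.at[oidx[s], "SE"]
        odf.at[oidx[s], "P"] = np.finfo(float).tiny
    violations["reverse"] = ids

    ids = take(spec.n_palindromic)
    for s in ids:
        for df, idx in ((edf, eidx), (odf, oidx)):
            df.at[idx[s], "EA"] = "A"
            df.at[idx[s], "OA"] = "T"
            df.at[idx[s], "EAF"] = spec.palindrome_eaf
    violations["palindromic"] = ids

    out.truth["violations"] = violations
    return out


def simulate_battery(
    configs: list[ChainSimConfig],
) -> list[SyntheticStudy]:
    """Simulate several chains with non-overlapping SNP id ranges."""
    return [simulate_chain(_with_offset(cfg, i)) for i, cfg in enumerate(configs)]


def _with_offset(cfg: ChainSimConfig, i: int) -> ChainSimConfig:
    from dataclasses import replace as dc_replace

    if cfg.snp_id_offset:
        return cfg
    return dc_replace(cfg, snp_id_offset=10_000 * (i + 1))


def merge_studies(studies: list[SyntheticStudy]):
    """Combine chains into pipeline inputs: exposure/mediator table lists and
    one pooled outcome table.

    All chains are assumed to target the same disease GWAS; their outcome
    rows (disjoint SNP sets) are concatenated.
    """
    exposures = [s.exposure_gwas for s in studies]
    mediators = [s.mediator_gwas for s in studies]
    all_ids = [sid for s in studies for sid in s.outcome_gwas.df["SNP"]]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("outcome SNP ids collide across studies; use distinct snp_id_offset")
    odf = pd.concat([s.outcome_gwas.df for s in studies], ignore_index=True)
    first = studies[0].outcome_gwas
    outcome = GwasTable(
        trait_id=first.trait_id,
        trait_type=first.trait_type,
        df=odf,
        provenance=first.provenance,
        n_cases=first.n_cases,
    )
    return exposures, mediators, outcome


def simulate_instrument_set(
    j: int,
    true_beta: float,
    n_exp: int = 30_000,
    n_out: int = 778_614,
    var_explained: float = 0.1,
    maf_range: tuple[float, float] = (0.05, 0.5),
    pleiotropy=None,
    prevalence: float | None = 8_434 / 778_614,
    rng=None,
    positive_effects: bool = False,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> HarmonizedInstrumentSet:
    """Directly simulate a harmonized instrument set (array level, no tables).

    A lightweight path for estimator validation at many replicates: draws
    instrument frequencies and strengths, computes nominal SEs from the
    sample sizes, and samples observed effects from their sampling normals.
    ``pleiotropy`` may be a scalar or array of per-SNP direct outcome
    effects; with ``positive_effects`` every true exposure effect is oriented
    positive (effect allele = exposure-increasing allele), so directional
    pleiotropy keeps its direction after Egger orientation.
    """
    rng = np.random.default_rng(rng)
    mafs = rng.uniform(*maf_range, size=j)
    hw = 2 * mafs * (1 - mafs)
    a = _scaled_effects(rng, mafs, var_explained)
    if positive_effects:
        a = np.abs(a)
    se_exp = 1.0 / np.sqrt(hw * n_exp)
    if prevalence is None:
        se_out = 1.0 / np.sqrt(hw * n_out)
    else:
        se_out = 1.0 / np.sqrt(hw * n_out * prevalence * (1 - prevalence))
    pleio = np.zeros(j) if pleiotropy is None else np.broadcast_to(
        np.asarray(pleiotropy, dtype=float), (j,)
    )
    beta_exp = a + rng.normal(0, se_exp)
    beta_out = true_beta * a + pleio + rng.normal(0, se_out)
    return HarmonizedInstrumentSet(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        snp_id=np.array([f"rs{i+1}" for i in range(j)], dtype=object),
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        eaf=mafs,
        n_exp=np.full(j, float(n_exp)),
        n_out=np.full(j, float(n_out)),
        n_cases_out=(prevalence * n_out) if prevalence is not None else None,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the study as canonical TSVs plus truth JSON (and LD if present)."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.exposure_gwas.df.to_csv(outdir / "exposure.tsv", sep="\t", index=False)
    study.mediator_gwas.df.to_csv(outdir / "mediator.tsv", sep="\t", index=False)
    study.outcome_gwas.df.to_csv(outdir / "outcome.tsv", sep="\t", index=False)
    if study.ld is not None:
        study.ld.to_square_file(outdir / "ld.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
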