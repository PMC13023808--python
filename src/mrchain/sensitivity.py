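"""Heterogeneity, pleiotropy, outlier, and influence diagnostics for one
harmonized MR analysis.

* :func:`cochran_q` — heterogeneity of per-SNP ratio estimates around the
  fixed-effect IVW estimate (chi-square on J−1 df);
* :func:`mr_presso` — simulation-based residual-sum-of-squares global test
  with per-SNP outlier p-values (Bonferroni-adjusted) and a distortion test
  comparing the outlier-corrected estimate against a random-removal null;
* :func:`leave_one_out` — IVW re-estimates with each SNP excluded in turn;
* :func:`diagnostics_points` — plain tables for scatter and funnel plots
  (plotting itself is left to the caller);
* :func:`sensitivity_report` — one bundle of all of the above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrResult, ivw, mr_egger
from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "cochran_q",
    "mr_presso",
    "PressoResult",
    "leave_one_out",
    "diagnostics_points",
    "SensitivityReport",
    "sensitivity_report",
]


def cochran_q(hset: HarmonizedInstrumentSet) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP ratios around the fixed-effect IVW estimate.

    Q = Σ w_j (r_j − β_IVW)² with ratio-scale weights w_j = beta_exp²/se_out²;
    p from chi-square with J−1 degrees of freedom. p > 0.05 is conventionally
    read as no significant heterogeneity.
    """
    j = hset.n_snp
    if j < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    w = hset.ivw_weights()
    r = hset.ratios()
    beta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta) ** 2))
    return q, j - 1, float(stats.chi2.sf(q, j - 1))


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes via sufficient-statistic downdating.

    bx, by may be 1-D (observed) or 2-D (n_sim × J simulated); returns an
    array of the same shape holding the slope with column j removed.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


@dataclass
class PressoResult:
    """MR-PRESSO output: global heterogeneity, per-SNP outliers, distortion."""

    global_p: float
    rss_obs: float
    outlier_table: pd.DataFrame  # snp_id, residual, p_raw, p_bonferroni, flagged
    outliers: list[str]
    distortion_p: float | None
    ivw_all: MrResult
    ivw_corrected: MrResult | None
    n_sim: int
    seed: int | None


def mr_presso(
    hset: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual sum and outlier test.

    The observed statistic is the weighted leave-one-out residual sum of
    squares RSS = Σ_j w_j (beta_out_j − β_IVW(−j)·beta_exp_j)² with
    w_j = 1/se_out². Its null distribution is simulated parametrically:
    beta_out*_j ~ N(β_IVW(−j)·beta_exp_j, se_out_j) and
    beta_exp*_j ~ N(beta_exp_j, se_exp_j), recomputing RSS* each time.
    Global p = (1 + #{RSS* ≥ RSS_obs}) / (n_sim + 1). Per-SNP outlier
    p-values come from each SNP's simulated residual distribution and are
    Bonferroni-adjusted by J; SNPs with adjusted p < ``alpha_outlier`` are
    flagged. When outliers are flagged, a distortion p compares the observed
    shift in the IVW estimate after removing them against the shift from
    removing equally many SNPs at random.
    """
    j = hset.n_snp
    if j < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    rng = np.random.default_rng(seed)
    bx, by = hset.beta_exp, hset.beta_out
    w = 1.0 / hset.se_out**2

    slopes_loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    bx_sim = rng.normal(bx, hset.se_exp, size=(n_sim, j))
    by_sim = rng.normal(slopes_loo * bx, hset.se_out, size=(n_sim, j))
    slopes_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = w * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (n_sim + 1)
    p_bonf = np.minimum(1.0, p_raw * j)
    flagged = p_bonf < alpha_outlier
    outliers = [str(s) for s in hset.snp_id[flagged]]

    outlier_table = pd.DataFrame(
        {
            "snp_id": hset.snp_id,
            "residual": resid_obs,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "flagged": flagged,
        }
    )

    ivw_all = ivw(hset)
    ivw_corrected = None
    distortion_p = None
    n_out = int(flagged.sum())
    if 0 < n_out < j - 1:
        ivw_corrected = ivw(hset.subset(~flagged))
        b_corr = ivw_corrected.beta
        if b_corr != 0:
            d_obs = (ivw_all.beta - b_corr) / abs(b_corr)
            n_null = min(n_sim, 1000)
            d_null = np.empty(n_null)
            idx = np.arange(j)
            for i in range(n_null):
                rem = rng.choice(idx, size=n_out, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[rem] = False
                b_i, _, _ = _ivw_fixed(bx[mask], by[mask], w[mask])
                d_null[i] = (ivw_all.beta - b_i) / abs(b_i) if b_i != 0 else np.inf
            distortion_p = float(
                (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_null + 1)
            )
    return PressoResult(
        global_p=global_p,
        rss_obs=rss_obs,
        outlier_table=outlier_table,
        outliers=outliers,
        distortion_p=distortion_p,
        ivw_all=ivw_all,
        ivw_corrected=ivw_corrected,
        n_sim=n_sim,
        seed=seed,
    )


def _ivw_fixed(bx, by, w):
    sxx = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / sxx
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return float(beta), float(np.sqrt(1 / sxx)), q


def leave_one_out(hset: HarmonizedInstrumentSet) -> pd.DataFrame:
    """IVW re-estimate with each instrument excluded in turn.

    One row per excluded SNP, each computed from the remaining J−1
    instruments.
    """
    if hset.n_snp < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    rows = []
    for k in range(hset.n_snp):
        mask = np.ones(hset.n_snp, dtype=bool)
        mask[k] = False
        res = ivw(hset.subset(mask))
        rows.append(
            {
                "excluded_snp": str(hset.snp_id[k]),
                "beta": res.beta,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "pval": res.pval,
                "n_snp": res.n_snp,
            }
        )
    return pd.DataFrame(rows)


def diagnostics_points(
    hset: HarmonizedInstrumentSet,
    results: list[MrResult] | None = None,
) -> dict[str, pd.DataFrame]:
    """Plain plotting tables for scatter and funnel diagnostics.

    scatter_points: per-SNP (beta_exp, beta_out) with SE bars;
    scatter_lines: intercept/slope per fitted method (origin-through for all
    but MR-Egger); funnel_points: per-SNP ratio vs its precision 1/se_ratio;
    funnel_reference: vertical line at each method's estimate.
    """
    results = results or []
    scatter_points = pd.DataFrame(
        {
            "snp_id": hset.snp_id,
            "beta_exp": hset.beta_exp,
            "se_exp": hset.se_exp,
            "beta_out": hset.beta_out,
            "se_out": hset.se_out,
        }
    )
    lines = []
    for res in results:
        icpt = res.extras.get("intercept", 0.0) if res.method == "mr_egger" else 0.0
        lines.append({"method": res.method, "intercept": icpt, "slope": res.beta})
    scatter_lines = pd.DataFrame(lines, columns=["method", "intercept", "slope"])
    ratio_se = hset.se_out / np.abs(hset.beta_exp)
    funnel_points = pd.DataFrame(
        {
            "snp_id": hset.snp_id,
            "ratio": hset.ratios(),
            "precision": 1.0 / ratio_se,
        }
    )
    funnel_reference = pd.DataFrame(
        [{"method": r.method, "beta": r.beta} for r in results],
        columns=["method", "beta"],
    )
    return {
        "scatter_points": scatter_points,
        "scatter_lines": scatter_lines,
        "funnel_points": funnel_points,
        "funnel_reference": funnel_reference,
    }


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure-outcome analysis."""

    exposure_id: str
    outcome_id: str
    n_snp: int
    q: float
    q_df: int
    q_pval: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    presso: PressoResult | None
    loo: pd.DataFrame | None
    plots: dict[str, pd.DataFrame] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "n_snp": self.n_snp,
            "q": self.q,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_p": self.egger_intercept_p,
            "notes": self.notes,
        }
        if self.presso is not None:
            d["presso"] = {
                "global_p": self.presso.global_p,
                "rss_obs": self.presso.rss_obs,
                "outliers": self.presso.outliers,
                "distortion_p": self.presso.distortion_p,
                "n_sim": self.presso.n_sim,
                "seed": self.presso.seed,
            }
        return d

    def write(self, outdir, prefix: str = "sensitivity") -> None:
        """JSON summary plus companion TSVs for loo / scatter / funnel."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"{prefix}.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
        if self.loo is not None:
            self.loo.to_csv(outdir / f"{prefix}_loo.tsv", sep="\t", index=False)
        for name, df in self.plots.items():
            df.to_csv(outdir / f"{prefix}_{name}.tsv", sep="\t", index=False)
        if self.presso is not None:
            self.presso.outlier_table.to_csv(
                outdir / f"{prefix}_presso_outliers.tsv", sep="\t", index=False
            )


def sensitivity_report(
    hset: HarmonizedInstrumentSet,
    results: list[MrResult] | None = None,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
) -> SensitivityReport:
    """Run the full diagnostic battery that the instrument count permits."""
    notes: list[str] = []
    q, q_df, q_pval = cochran_q(hset)
    eg_i = eg_se = eg_p = None
    if hset.n_snp >= 3:
        eg = mr_egger(hset)
        eg_i = eg.extras["intercept"]
        eg_se = eg.extras["intercept_se"]
        eg_p = eg.extras["intercept_p"]
    else:
        notes.append("egger_skipped: fewer than 3 instruments")
    presso = None
    if hset.n_snp >= 4:
        presso = mr_presso(hset, n_sim=n_sim, seed=seed, alpha_outlier=alpha_outlier)
    else:
        notes.append("presso_skipped: fewer than 4 instruments")
    loo = leave_one_out(hset) if hset.n_snp >= 3 else None
    if loo is None:
        notes.append("loo_skipped: fewer than 3 instruments")
    plots = diagnostics_points(hset, results)
    return SensitivityReport(
        exposure_id=hset.exposure_id,
        outcome_id=hset.outcome_id,
        n_snp=hset.n_snp,
        q=q,
        q_df=q_df,
        q_pval=q_pval,
        egger_intercept=eg_i,
        egger_intercept_se=eg_se,
        egger_intercept_p=eg_p,
        presso=presso,
        loo=loo,
        plots=plots,
        notes=notes,
    )
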