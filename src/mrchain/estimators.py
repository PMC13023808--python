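"""Causal-effect estimators for two-sample Mendelian randomization.

Implements the standard summary-data MR estimator family on a
:class:`~mrchain.sumstats.HarmonizedInstrumentSet`:

* :func:`wald_ratio` — single-SNP ratio estimate (base case);
* :func:`ivw` — inverse-variance-weighted estimate with multiplicative
  random effects (the primary method);
* :func:`mr_egger` — weighted regression with an unconstrained intercept,
  the intercept being a directional-pleiotropy diagnostic;
* :func:`weighted_median` — majority-valid estimator with bootstrap SE;
* :func:`mode_estimate` — simple / weighted mode (kernel-density mode of the
  per-SNP ratios, ZEMPA assumption) with bootstrap SE;
* :func:`run_all` — the full battery with per-method minimum-instrument rules.

All estimates are on the beta scale (log odds ratio for binary outcomes);
:func:`or_with_ci` converts to an odds-ratio triple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "MrResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimate",
    "run_all",
    "or_with_ci",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MrResult:
    """One estimator's causal estimate on the beta (log-odds) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    exposure_id: str = ""
    outcome_id: str = ""
    extras: dict = field(default_factory=dict)

    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, lower, upper) via exponentiation of the beta-scale CI."""
        return or_with_ci(self.beta, self.se)

    def to_row(self) -> dict:
        """Flat dict for tabular serialization."""
        or_, lo, hi = self.odds_ratio()
        return {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or_": or_,
            "or_low": lo,
            "or_high": hi,
        }


def _normal_result(method, beta, se, n_snp, exposure_id="", outcome_id="", extras=None):
    pval = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MrResult(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=float(pval),
        n_snp=int(n_snp),
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        extras=extras or {},
    )


def or_with_ci(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio with 95% CI from a log-odds estimate and its SE."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - _Z95 * se)),
        float(np.exp(beta + _Z95 * se)),
    )


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    exposure_id: str = "",
    outcome_id: str = "",
) -> MrResult:
    """Single-SNP causal estimate beta_out / beta_exp.

    SE by the first-order delta rule se_out / |beta_exp| (the exposure-side
    uncertainty is second order under the no-measurement-error convention).
    """
    if beta_exp == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _normal_result("wald_ratio", beta, se, 1, exposure_id, outcome_id)


def _ivw_core(beta_exp, se_out, beta_out):
    """Fixed-effect IVW slope, SE, and Cochran's Q (regression weights 1/se_out²)."""
    w = 1.0 / se_out**2
    sxx = np.sum(w * beta_exp**2)
    beta = np.sum(w * beta_exp * beta_out) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    q = float(np.sum(w * (beta_out - beta * beta_exp) ** 2))
    return float(beta), float(se_fixed), q


def ivw(hset: HarmonizedInstrumentSet) -> MrResult:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Weighted regression of beta_out on beta_exp through the origin with
    weights 1/se_out². The fixed-effect SE is inflated by
    max(1, sqrt(Q/(J−1))), the multiplicative random-effects convention.
    A single instrument delegates to :func:`wald_ratio`.
    """
    j = hset.n_snp
    if j == 1:
        res = wald_ratio(
            hset.beta_exp[0], hset.se_exp[0], hset.beta_out[0], hset.se_out[0],
            hset.exposure_id, hset.outcome_id,
        )
        res.method = "ivw"
        res.extras["single_snp_wald"] = True
        return res
    if np.all(hset.beta_exp == 0):
        raise ValueError("all exposure betas are zero")
    beta, se_fixed, q = _ivw_core(hset.beta_exp, hset.se_out, hset.beta_out)
    inflation = max(1.0, np.sqrt(q / (j - 1)))
    se = se_fixed * inflation
    q_pval = float(stats.chi2.sf(q, j - 1))
    return _normal_result(
        "ivw", beta, se, j, hset.exposure_id, hset.outcome_id,
        extras={"q": q, "q_df": j - 1, "q_pval": q_pval, "se_inflation": inflation},
    )


def _egger_core(beta_exp, beta_out, w):
    """Weighted least squares with intercept; returns coefficients and
    unscaled covariance."""
    x = np.column_stack([np.ones_like(beta_exp), beta_exp])
    xtw = x.T * w
    xtwx = xtw @ x
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ (xtw @ beta_out)
    resid = beta_out - x @ coef
    rss_w = float(np.sum(w * resid**2))
    return coef, cov_unscaled, rss_w


def mr_egger(hset: HarmonizedInstrumentSet) -> MrResult:
    """MR-Egger regression: slope = causal estimate, intercept = average
    directional pleiotropy.

    SNPs are oriented so every exposure beta is positive (joint sign flips
    leave ratio estimates unchanged). Weights are 1/se_out²; SEs use the
    multiplicative random-effects inflation max(1, sqrt(RSS_w/(J−2))) and
    t inference on J−2 degrees of freedom.
    """
    j = hset.n_snp
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.where(hset.beta_exp < 0, -1.0, 1.0)
    bx = hset.beta_exp * sign
    by = hset.beta_out * sign
    w = 1.0 / hset.se_out**2
    coef, cov_unscaled, rss_w = _egger_core(bx, by, w)
    df = j - 2
    sigma2 = max(1.0, rss_w / df)
    ses = np.sqrt(sigma2 * np.diag(cov_unscaled))
    slope, slope_se = float(coef[1]), float(ses[1])
    icpt, icpt_se = float(coef[0]), float(ses[0])
    tcrit = float(stats.t.ppf(0.975, df))
    slope_p = 2 * float(stats.t.sf(abs(slope) / slope_se, df))
    icpt_p = 2 * float(stats.t.sf(abs(icpt) / icpt_se, df))
    return MrResult(
        method="mr_egger",
        beta=slope,
        se=slope_se,
        ci_low=slope - tcrit * slope_se,
        ci_high=slope + tcrit * slope_se,
        pval=slope_p,
        n_snp=j,
        exposure_id=hset.exposure_id,
        outcome_id=hset.outcome_id,
        extras={
            "intercept": icpt,
            "intercept_se": icpt_se,
            "intercept_p": icpt_p,
            "df": df,
            "se_inflation": float(np.sqrt(sigma2)),
            "inference": "t",
        },
    )


def weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the standardized cumulative
    weight function.

    With ratios sorted, the cumulative standardized weight at rank j is
    p_j = (S_j − w_j/2) / S_total; the estimate interpolates linearly between
    the ratios whose p values bracket one half.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    s = np.cumsum(w)
    p = (s - w / 2) / s[-1]
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(p, 0.5))
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1]))


def _bootstrap_se(hset, estimator, n_boot, seed):
    """Parametric bootstrap SE: resample betas from their sampling normals."""
    rng = np.random.default_rng(seed)
    j = hset.n_snp
    bx = rng.normal(hset.beta_exp, hset.se_exp, size=(n_boot, j))
    by = rng.normal(hset.beta_out, hset.se_out, size=(n_boot, j))
    ests = np.array([estimator(bx[i], by[i]) for i in range(n_boot)])
    return float(np.std(ests, ddof=1))


def weighted_median(
    hset: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrResult:
    """Weighted-median MR estimate; consistent when valid instruments carry
    over half the weight.

    SE from a seeded parametric bootstrap (resampling beta_exp and beta_out
    from their reported sampling distributions).
    """
    if hset.n_snp < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap SEs", stacklevel=2)
    est = weighted_median_estimate(hset.ratios(), hset.ivw_weights())

    def _est(bx, by):
        return weighted_median_estimate(by / bx, bx**2 / hset.se_out**2)

    se = _bootstrap_se(hset, _est, n_boot, seed)
    res = _normal_result(
        "weighted_median", est, se, hset.n_snp, hset.exposure_id, hset.outcome_id,
        extras={"n_boot": n_boot, "seed": seed},
    )
    return res


def mode_estimate_core(
    ratios: np.ndarray,
    weights: np.ndarray,
    phi: float = 1.0,
    grid_size: int = 512,
) -> tuple[float, float]:
    """Mode of the Gaussian-kernel-smoothed weighted ratio density.

    Bandwidth h = phi · 0.9 · min(sd, IQR/1.349) · J^(−1/5) (a Silverman-type
    rule). Returns (mode, h). All-identical ratios (h = 0) return that ratio.
    """
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    j = len(r)
    sd = np.std(r, ddof=1) if j > 1 else 0.0
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = phi * 0.9 * scale * j ** (-1 / 5)
    if h <= 0 or not np.isfinite(h):
        return float(r[0]), 0.0
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_size)
    dens = np.sum(w[:, None] * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2), axis=0)
    return float(grid[np.argmax(dens)]), float(h)


def mode_estimate(
    hset: HarmonizedInstrumentSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    grid_size: int = 512,
) -> MrResult:
    """Simple or weighted mode estimate (ZEMPA: the modal ratio is causal).

    The weighted variant weights each kernel by the SNP's inverse-variance
    weight; the simple variant weights all SNPs equally. SE via seeded
    parametric bootstrap.
    """
    if hset.n_snp < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    weights = hset.ivw_weights() if weighted else np.ones(hset.n_snp)
    est, h = mode_estimate_core(hset.ratios(), weights, phi, grid_size)

    def _est(bx, by):
        w = bx**2 / hset.se_out**2 if weighted else np.ones(hset.n_snp)
        return mode_estimate_core(by / bx, w, phi, grid_size)[0]

    se = _bootstrap_se(hset, _est, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return _normal_result(
        method, est, se, hset.n_snp, hset.exposure_id, hset.outcome_id,
        extras={"phi": phi, "bandwidth": h, "grid_size": grid_size,
                "n_boot": n_boot, "seed": seed},
    )


def run_all(
    hset: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[list[MrResult], list[tuple[str, str]]]:
    """IVW plus the four alternates, skipping methods whose instrument minimum
    is not met.

    Returns (results, skipped) where skipped is a list of (method, reason).
    """
    results = [ivw(hset)]
    skipped: list[tuple[str, str]] = []
    j = hset.n_snp
    if j >= 3:
        results.append(mr_egger(hset))
        results.append(weighted_median(hset, n_boot=n_boot, seed=seed))
        results.append(mode_estimate(hset, weighted=False, n_boot=n_boot, seed=seed))
        results.append(mode_estimate(hset, weighted=True, n_boot=n_boot, seed=seed))
    else:
        reason = f"requires >= 3 instruments, have {j}"
        for m in ("mr_egger", "weighted_median", "simple_mode", "weighted_mode"):
            skipped.append((m, reason))
    return results, skipped
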