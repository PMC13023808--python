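"""Two-step MR mediation: product-of-coefficients decomposition.

Given three MR estimates — the total effect of an exposure on the outcome
(βall), the exposure→mediator effect (β1), and the mediator→outcome effect
(β2) — the indirect effect through the mediator is the product β1·β2, the
direct effect is the remainder βall − β1·β2, and the proportion mediated is
β1·β2 / βall. Standard errors come from first-order propagation of error
(the delta method); all confidence intervals are normal-theory 95% bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .estimators import MrResult

__all__ = ["MediationResult", "two_step_mediation", "mediation_screen"]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MediationResult:
    """Decomposition of one exposure→mediator→outcome triple.

    ``indirect + direct`` recomposes ``beta_total`` and
    ``proportion * beta_total`` recomposes ``indirect`` (to floating-point
    rounding; the direct effect is defined as the remainder total − indirect).
    Proportions outside [0, 1] are reported as computed, flagged
    ``inconsistent_mediation``.
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    se_total: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    ci_indirect: tuple[float, float]
    p_indirect: float
    direct: float
    se_direct: float
    ci_direct: tuple[float, float]
    proportion: float | None
    se_proportion: float | None
    ci_proportion: tuple[float, float] | None
    flags: list[str] = field(default_factory=list)
    methods_used: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "beta_total": self.beta_total,
            "se_total": self.se_total,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "indirect": self.indirect,
            "se_indirect": self.se_indirect,
            "ci_indirect_low": self.ci_indirect[0],
            "ci_indirect_high": self.ci_indirect[1],
            "p_indirect": self.p_indirect,
            "direct": self.direct,
            "se_direct": self.se_direct,
            "proportion": self.proportion,
            "se_proportion": self.se_proportion,
            "flags": ";".join(self.flags),
        }


def two_step_mediation(
    total: MrResult,
    step1: MrResult,
    step2: MrResult,
    second_order: bool = False,
) -> MediationResult:
    """Product-of-coefficients mediation from three MR estimates.

    Parameters
    ----------
    total
        Exposure → outcome MR estimate (βall).
    step1
        Exposure → mediator MR estimate (β1).
    step2
        Mediator → outcome MR estimate (β2).
    second_order
        Include the second-order term se1²·se2² in the indirect-effect
        variance (exact for the product of independent normals); the default
        first-order form matches the usual two-step MR convention.

    Notes
    -----
    * se_indirect² = β1²·se2² + β2²·se1² (+ se1²·se2²).
    * se_direct assumes independence of the total and indirect estimates;
      with overlapping instrument sets this is conservative.
    * The proportion CI uses the delta method on the ratio β12/βall.
    """
    labels_ok = _check_labels(total, step1, step2)
    if not labels_ok:
        raise ValueError(
            "trait labels disagree across total/step1/step2 results: "
            f"total {total.exposure_id}->{total.outcome_id}, "
            f"step1 {step1.exposure_id}->{step1.outcome_id}, "
            f"step2 {step2.exposure_id}->{step2.outcome_id}"
        )
    b1, se1 = step1.beta, step1.se
    b2, se2 = step2.beta, step2.se
    ball, se_all = total.beta, total.se

    indirect = b1 * b2
    # products instead of ** so extreme inputs saturate to inf, never raise
    var_ind = (b1 * se2) * (b1 * se2) + (b2 * se1) * (b2 * se1)
    if second_order:
        var_ind += (se1 * se2) * (se1 * se2)
    se_ind = math.sqrt(var_ind)
    direct = ball - indirect
    se_dir = math.sqrt(se_all * se_all + se_ind * se_ind)
    if se_ind > 0:
        p_ind = 2 * float(stats.norm.sf(abs(indirect) / se_ind))
    else:
        p_ind = 1.0 if indirect == 0 else 0.0

    flags: list[str] = []
    proportion = se_prop = ci_prop = None
    if ball == 0:
        flags.append("proportion_undefined_zero_total")
    else:
        proportion = indirect / ball
        if indirect != 0:
            se_prop = abs(proportion) * math.hypot(se_ind / indirect, se_all / ball)
        else:
            se_prop = se_ind / abs(ball)  # delta-method limit at β12 = 0
        ci_prop = (proportion - _Z95 * se_prop, proportion + _Z95 * se_prop)
        if not (0 <= proportion <= 1):
            flags.append("inconsistent_mediation")

    return MediationResult(
        exposure_id=total.exposure_id or step1.exposure_id,
        mediator_id=step2.exposure_id or step1.outcome_id,
        outcome_id=total.outcome_id or step2.outcome_id,
        beta_total=ball,
        se_total=se_all,
        beta1=b1,
        se1=se1,
        beta2=b2,
        se2=se2,
        indirect=indirect,
        se_indirect=se_ind,
        ci_indirect=(indirect - _Z95 * se_ind, indirect + _Z95 * se_ind),
        p_indirect=p_ind,
        direct=direct,
        se_direct=se_dir,
        ci_direct=(direct - _Z95 * se_dir, direct + _Z95 * se_dir),
        proportion=proportion,
        se_proportion=se_prop,
        ci_proportion=ci_prop,
        flags=flags,
        methods_used={
            "total": total.method,
            "step1": step1.method,
            "step2": step2.method,
            "second_order": second_order,
        },
    )


def _check_labels(total: MrResult, step1: MrResult, step2: MrResult) -> bool:
    """Labels must form a coherent chain wherever they are set."""

    def same(a: str, b: str) -> bool:
        return (not a) or (not b) or a == b

    return (
        same(total.exposure_id, step1.exposure_id)
        and same(step1.outcome_id, step2.exposure_id)
        and same(total.outcome_id, step2.outcome_id)
    )


def mediation_screen(
    exposure_outcome: dict[str, MrResult],
    mediator_outcome: dict[str, MrResult],
    exposure_mediator: dict[tuple[str, str], MrResult],
    alpha: float = 0.05,
) -> list[tuple[str, str]]:
    """Triples qualifying for mediation analysis.

    A pair (exposure, mediator) qualifies when all three links are
    significant at ``alpha`` on the primary (IVW) p-value: exposure→outcome,
    mediator→outcome, and exposure→mediator. Returned in deterministic
    (exposure, mediator) order.
    """
    sig_exp = {e for e, r in exposure_outcome.items() if r.pval < alpha}
    sig_med = {m for m, r in mediator_outcome.items() if r.pval < alpha}
    triples = [
        (e, m)
        for (e, m), r in sorted(exposure_mediator.items())
        if e in sig_exp and m in sig_med and r.pval < alpha
    ]
    return triples
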