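"""Per-day treatment effect (tumor growth inhibition) with delta-method CIs.

The effect of arm g versus control at a fixed day is the fractional
reduction in mean relative tumor volume,

    delta_g = (mu_C - mu_g) / mu_C,

estimated by the plug-in of sample means.  Its standard error follows
from the first-order delta method applied to the ratio of two independent
group means; the reported bound is the one-sided lower 100(1-alpha)%
confidence limit, i.e. evidence that the effect is at least that large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GroupTimeSummary
from .exceptions import PdxsynError

__all__ = ["TreatmentEffect", "tgi_effect", "tgi_se",
           "check_bliss_assumption", "BlissAssumptionReport"]


def tgi_se(mean_c, var_c, n_c, mean_g, var_g, n_g):
    """Delta-method standard error of the TGI estimate.

    se = sqrt( v_g^2 s_C^2 / (v_C^4 n_C) + s_g^2 / (v_C^2 n_g) )

    Accepts scalars or broadcastable arrays.
    """
    mean_c = np.asarray(mean_c, dtype=float)
    return np.sqrt(
        np.asarray(mean_g, dtype=float) ** 2 * np.asarray(var_c, dtype=float)
        / (mean_c ** 4 * np.asarray(n_c, dtype=float))
        + np.asarray(var_g, dtype=float)
        / (mean_c ** 2 * np.asarray(n_g, dtype=float))
    )


@dataclass
class TreatmentEffect:
    """TGI estimate for one arm at one day with its one-sided lower bound."""

    arm: str
    day: float
    delta_hat: float
    se: float
    lower_bound: float
    alpha: float
    interval: tuple[float, float] | None = None  # optional two-sided


def tgi_effect(control: GroupTimeSummary, treated: GroupTimeSummary,
               alpha: float = 0.05, two_sided: bool = False) -> TreatmentEffect:
    """Estimate the treatment effect of ``treated`` versus ``control``.

    Parameters
    ----------
    control, treated : GroupTimeSummary
        Same-day summaries; ``control`` must be the C arm summary.
    alpha : float
        One-sided significance level; the reported bound is the
        100(1-alpha)% lower confidence limit
        ``delta_hat - z_{1-alpha} * se``.
    two_sided : bool
        Additionally attach a two-sided 100(1-alpha)% interval.  Off by
        default: the scientific question is one-directional (is the drug
        at least this active?).
    """
    if control.day != treated.day:
        raise PdxsynError(
            f"mismatched days: control at {control.day:g}, "
            f"treated at {treated.day:g}"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    delta = (control.mean - treated.mean) / control.mean
    se = float(tgi_se(control.mean, control.variance, control.n,
                      treated.mean, treated.variance, treated.n))
    z = stats.norm.ppf(1 - alpha)
    eff = TreatmentEffect(
        arm=treated.arm, day=float(treated.day),
        delta_hat=float(delta), se=se,
        lower_bound=float(delta - z * se), alpha=alpha,
    )
    if two_sided:
        z2 = stats.norm.ppf(1 - alpha / 2)
        eff.interval = (float(delta - z2 * se), float(delta + z2 * se))
    return eff


@dataclass
class BlissAssumptionReport:
    """Where the probabilistic-effect assumption 0 <= delta <= 1 fails.

    The Bliss-independence index treats each arm's effect as a
    probability; an estimate outside [0, 1] (treated mean above control,
    or negative volumes which cannot occur) makes that reading suspect.
    Violations are flagged, never silently dropped.
    """

    passed: bool
    violations: list[tuple[str, float, float]]  # (arm, day, delta_hat)

    def __bool__(self):
        return self.passed


def check_bliss_assumption(effects) -> BlissAssumptionReport:
    """Flag every (arm, day) whose estimated effect falls outside [0, 1].

    ``effects`` is an iterable of :class:`TreatmentEffect` (typically A,
    B and AB across the analysis grid).  Bounds are inclusive: an effect
    of exactly 0 or 1 passes.
    """
    violations = [(e.arm, e.day, e.delta_hat)
                  for e in effects
                  if not (0.0 <= e.delta_hat <= 1.0)]
    return BlissAssumptionReport(passed=not violations, violations=violations)
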