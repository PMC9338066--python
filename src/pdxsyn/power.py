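"""Power and sample-size analysis for combination-index synergy tests.

The test is the asymptotic two-sided Wald test of H0: CI = 0 against
H1: CI = gamma, with var(CI) obtained by plugging prespecified
population means, standard deviations and group sizes into the
delta-method variance of the chosen reference model.  With
lambda = gamma / sqrt(var(CI)), the power of the level-alpha test is
the standard normal-shift expression

    1 - beta = Phi(-z_{1-alpha/2} + lambda) + Phi(-z_{1-alpha/2} - lambda),

which equals alpha exactly at gamma = 0 (a test's power at the null is
its size).  Also provided: the per-model synergy thresholds — the
largest combination-arm mean that still yields CI > 0 — and a minimal
sample-size search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .indices import MODELS

__all__ = ["PowerSpec", "ci_variance", "power", "synergy_threshold",
           "sample_size", "power_curve"]

_ARMS = ("C", "A", "B", "AB")


@dataclass
class PowerSpec:
    """Design parameters for a four-arm combination experiment.

    Attributes
    ----------
    means : mapping
        Population mean relative tumor volumes ``{"C": .., "A": ..,
        "B": .., "AB": ..}`` at the analysis day.
    sds : mapping
        Population standard deviations per arm (same keys).
    ns : mapping
        Mice per arm.
    alpha : float
        Two-sided type-I error rate.
    gamma : float
        Combination-index value under the alternative.
    model : str
        Reference model ("HSA", "RA" or "BI").
    """

    means: Mapping[str, float]
    sds: Mapping[str, float]
    ns: Mapping[str, int]
    alpha: float = 0.05
    gamma: float = 0.0
    model: str = "BI"

    def __post_init__(self):
        self.model = self.model.upper()
        if self.model not in MODELS:
            raise ConfigurationError(f"unknown reference model {self.model!r}")
        for name, d, lo in (("means", self.means, 0.0), ("sds", self.sds, None),
                            ("ns", self.ns, None)):
            missing = [a for a in _ARMS if a not in d]
            if missing:
                raise ConfigurationError(f"{name} missing arm(s) {missing}")
        if any(self.means[a] <= 0 for a in _ARMS):
            raise ConfigurationError("all means must be positive")
        if any(self.sds[a] < 0 for a in _ARMS):
            raise ConfigurationError("standard deviations must be >= 0")
        if any(self.ns[a] < 2 for a in _ARMS):
            raise ConfigurationError("each arm needs at least 2 animals")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


def _hsa_reference(spec: PowerSpec) -> str:
    """Population-level HSA reference arm: larger effect delta, ties to
    the arm with smaller sigma^2/n (mirrors the estimation tie rule)."""
    mc = spec.means["C"]
    d = {g: (mc - spec.means[g]) / mc for g in ("A", "B")}
    if d["A"] != d["B"]:
        return "A" if d["A"] > d["B"] else "B"
    prec = {g: spec.sds[g] ** 2 / spec.ns[g] for g in ("A", "B")}
    return "A" if prec["A"] <= prec["B"] else "B"


def ci_variance(spec: PowerSpec) -> float:
    """Delta-method variance of the index at the design's population values."""
    m = {a: float(spec.means[a]) for a in _ARMS}
    v = {a: float(spec.sds[a]) ** 2 for a in _ARMS}
    n = {a: float(spec.ns[a]) for a in _ARMS}
    if spec.model == "HSA":
        g = _hsa_reference(spec)
        return v[g] / (m[g] ** 2 * n[g]) + v["AB"] / (m["AB"] ** 2 * n["AB"])
    if spec.model == "RA":
        s_mono = m["A"] + m["B"]
        s_comb = m["C"] + m["AB"]
        return (v["A"] / (s_mono ** 2 * n["A"])
                + v["B"] / (s_mono ** 2 * n["B"])
                + v["C"] / (s_comb ** 2 * n["C"])
                + v["AB"] / (s_comb ** 2 * n["AB"]))
    return sum(v[a] / (m[a] ** 2 * n[a]) for a in _ARMS)  # BI


def power(spec: PowerSpec) -> float:
    """Power of the two-sided level-alpha Wald test of CI = 0 at CI = gamma."""
    var = ci_variance(spec)
    if var == 0.0:
        if spec.gamma == 0.0:
            return spec.alpha
        warnings.warn(
            "zero index variance with a nonzero alternative: the test "
            "rejects with certainty (degenerate design)",
            UserWarning, stacklevel=2,
        )
        return 1.0
    lam = spec.gamma / np.sqrt(var)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(-z + lam) + stats.norm.cdf(-z - lam))


def synergy_threshold(means: Mapping[str, float], model: str) -> float | None:
    """Largest combination-arm mean mu_AB that still gives CI > 0.

    Interpreted with monotherapies no worse than control
    (mu_A, mu_B <= mu_C).  Thresholds per model:

    - HSA:  min(mu_A, mu_B)
    - RA:   mu_A + mu_B - mu_C   (``None`` when <= 0: no positive tumor
      volume can satisfy it — the synergy call is unattainable)
    - BI:   mu_A * mu_B / mu_C

    Smaller thresholds demand deeper combination responses, so RA is the
    most conservative model and HSA the most permissive.
    """
    model = model.upper()
    for a in ("C", "A", "B"):
        if a not in means or means[a] <= 0:
            raise ConfigurationError(f"need positive mean for arm {a}")
    ma, mb, mc = means["A"], means["B"], means["C"]
    if model == "HSA":
        return float(min(ma, mb))
    if model == "RA":
        thr = ma + mb - mc
        return float(thr) if thr > 0 else None
    if model == "BI":
        return float(ma * mb / mc)
    raise ConfigurationError(f"unknown reference model {model!r}")


def sample_size(spec: PowerSpec, target_power: float,
                n_max: int = 100_000) -> int:
    """Smallest equal per-arm n achieving ``target_power``.

    ``spec.ns`` is ignored; the search assumes equal allocation and uses
    the 1/n scaling of the variance (power is monotone increasing in n),
    verified by a final check that n-1 falls short.
    """
    if spec.gamma == 0:
        raise ConfigurationError("gamma must be nonzero for a sample-size "
                                 "calculation")
    if not spec.alpha < target_power < 1:
        raise ConfigurationError(
            f"target power must lie in (alpha, 1); got {target_power}"
        )

    def power_at(n):
        return power(replace(spec, ns={a: n for a in _ARMS}))

    lo, hi = 2, 2
    while power_at(hi) < target_power:
        if hi >= n_max:
            raise ConfigurationError(
                f"target power {target_power} unreachable with n <= {n_max} "
                "per arm under this design"
            )
        lo, hi = hi, min(hi * 2, n_max)
    while lo < hi:  # bisect the bracketing interval
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)


def power_curve(spec: PowerSpec, mu_ab_grid) -> "pd.DataFrame":
    """Power as a function of the combination-arm mean.

    For each candidate mu_AB the alternative gamma is the model's index
    evaluated at the population means (the value the study would be
    powered to detect), and the variance is recomputed at those means.
    Returns a tidy table (model, mu_ab, gamma, power).
    """
    import pandas as pd

    rows = []
    for mu_ab in np.asarray(mu_ab_grid, dtype=float):
        means = dict(spec.means)
        means["AB"] = float(mu_ab)
        m = means
        if spec.model == "HSA":
            g = _hsa_reference(replace(spec, means=means))
            gamma = np.log(m[g]) - np.log(mu_ab)
        elif spec.model == "RA":
            gamma = np.log(m["A"] + m["B"]) - np.log(mu_ab + m["C"])
        else:
            gamma = (np.log(m["A"]) + np.log(m["B"])
                     - np.log(m["C"]) - np.log(mu_ab))
        sub = replace(spec, means=means, gamma=float(gamma))
        rows.append({"model": spec.model, "mu_ab": float(mu_ab),
                     "gamma": float(gamma), "power": power(sub)})
    return pd.DataFrame(rows)
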