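"""Per-day combination indices under the HSA, RA and Bliss reference models.

Each index contrasts the observed combination response with the response
a null model of "no interaction" predicts from the monotherapies, on the
log scale of mean relative tumor volumes, so that

    CI > 0  -> synergy,   CI = 0 -> independence,   CI < 0 -> antagonism.

With per-arm means mu_g (relative tumor volume; smaller = better):

    HSA (highest single agent):  CI = log(mu_g*) - log(mu_AB),
        g* the monotherapy with the larger effect delta;
    RA  (response additivity):   CI = log(mu_A + mu_B) - log(mu_AB + mu_C);
    BI  (Bliss independence):    CI = log(mu_A) + log(mu_B)
                                      - log(mu_C) - log(mu_AB).

Standard errors come from the first-order delta method; the per-day
asymptotic interval is the usual Wald interval.  The global index gCI is
the unweighted average of per-day indices over a study window (its
bootstrap interval lives in :mod:`pdxsyn.inference`).

The ``*_stat`` kernels are vectorised over leading axes so the bootstrap
machinery can evaluate thousands of resamples in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import GroupTimeSummary
from .effects import tgi_se
from .exceptions import PdxsynError

__all__ = [
    "MODELS", "CombinationIndexResult", "GlobalCIResult",
    "ci_hsa", "ci_ra", "ci_bi", "combination_index",
    "asymptotic_interval", "gci",
    "hsa_stat", "ra_stat", "bi_stat", "ci_stat",
]

MODELS = ("HSA", "RA", "BI")


# ---------------------------------------------------------------------------
# vectorised kernels: means/variances are broadcastable arrays
# ---------------------------------------------------------------------------

def hsa_stat(m_c, m_a, m_b, m_ab, v_c, v_a, v_b, v_ab, n_c, n_a, n_b, n_ab):
    """HSA index, its delta-method SE, and the chosen reference arm.

    The reference monotherapy is the one with the larger TGI effect; on
    an exact tie the arm whose TGI standard error is smaller (operational
    reading of "narrower confidence interval"), then A.  The control arm
    enters only through this selection — the index itself never uses it.

    Returns ``(ci, se, use_a)`` with ``use_a`` boolean (reference is A).
    """
    m_c, m_a, m_b, m_ab = (np.asarray(x, dtype=float)
                           for x in (m_c, m_a, m_b, m_ab))
    d_a = (m_c - m_a) / m_c
    d_b = (m_c - m_b) / m_c
    se_a = tgi_se(m_c, v_c, n_c, m_a, v_a, n_a)
    se_b = tgi_se(m_c, v_c, n_c, m_b, v_b, n_b)
    use_a = (d_a > d_b) | ((d_a == d_b) & (se_a <= se_b))
    m_g = np.where(use_a, m_a, m_b)
    v_g = np.where(use_a, np.asarray(v_a, dtype=float),
                   np.asarray(v_b, dtype=float))
    n_g = np.where(use_a, np.asarray(n_a, dtype=float),
                   np.asarray(n_b, dtype=float))
    ci = np.log(m_g) - np.log(m_ab)
    se = np.sqrt(v_g / (m_g ** 2 * n_g)
                 + np.asarray(v_ab, dtype=float)
                 / (m_ab ** 2 * np.asarray(n_ab, dtype=float)))
    return ci, se, use_a


def ra_stat(m_c, m_a, m_b, m_ab, v_c, v_a, v_b, v_ab, n_c, n_a, n_b, n_ab):
    """RA index and its delta-method SE."""
    m_c, m_a, m_b, m_ab = (np.asarray(x, dtype=float)
                           for x in (m_c, m_a, m_b, m_ab))
    s_mono = m_a + m_b
    s_comb = m_c + m_ab
    ci = np.log(s_mono) - np.log(s_comb)
    se = np.sqrt(
        np.asarray(v_a, dtype=float) / (s_mono ** 2 * np.asarray(n_a, float))
        + np.asarray(v_b, dtype=float) / (s_mono ** 2 * np.asarray(n_b, float))
        + np.asarray(v_c, dtype=float) / (s_comb ** 2 * np.asarray(n_c, float))
        + np.asarray(v_ab, dtype=float) / (s_comb ** 2 * np.asarray(n_ab, float))
    )
    return ci, se


def bi_stat(m_c, m_a, m_b, m_ab, v_c, v_a, v_b, v_ab, n_c, n_a, n_b, n_ab):
    """Bliss index and its delta-method SE."""
    m_c, m_a, m_b, m_ab = (np.asarray(x, dtype=float)
                           for x in (m_c, m_a, m_b, m_ab))
    ci = np.log(m_a) + np.log(m_b) - np.log(m_c) - np.log(m_ab)
    se = np.sqrt(
        np.asarray(v_a, dtype=float) / (m_a ** 2 * np.asarray(n_a, float))
        + np.asarray(v_b, dtype=float) / (m_b ** 2 * np.asarray(n_b, float))
        + np.asarray(v_c, dtype=float) / (m_c ** 2 * np.asarray(n_c, float))
        + np.asarray(v_ab, dtype=float) / (m_ab ** 2 * np.asarray(n_ab, float))
    )
    return ci, se


def ci_stat(model: str, m_c, m_a, m_b, m_ab,
            v_c, v_a, v_b, v_ab, n_c, n_a, n_b, n_ab):
    """Dispatch to the requested model's kernel; returns ``(ci, se)``."""
    model = model.upper()
    if model == "HSA":
        ci, se, _ = hsa_stat(m_c, m_a, m_b, m_ab, v_c, v_a, v_b, v_ab,
                             n_c, n_a, n_b, n_ab)
        return ci, se
    if model == "RA":
        return ra_stat(m_c, m_a, m_b, m_ab, v_c, v_a, v_b, v_ab,
                       n_c, n_a, n_b, n_ab)
    if model == "BI":
        return bi_stat(m_c, m_a, m_b, m_ab, v_c, v_a, v_b, v_ab,
                       n_c, n_a, n_b, n_ab)
    raise ValueError(f"unknown reference model {model!r}; expected "
                     f"one of {MODELS}")


# ---------------------------------------------------------------------------
# result containers and summary-level API
# ---------------------------------------------------------------------------

@dataclass
class CombinationIndexResult:
    """A combination index at one day under one reference model."""

    model: str
    day: float
    ci_hat: float
    se: float
    interval: tuple[float, float] | None = None
    interval_method: str | None = None
    hsa_reference_arm: str | None = None
    bliss_valid: bool = True  # all deltas in [0, 1] (BI interpretability)


@dataclass
class GlobalCIResult:
    """Average combination index over a study window."""

    model: str
    gci_hat: float
    window: np.ndarray
    interval: tuple[float, float] | None = None
    interval_method: str | None = None
    B: int | None = None
    L: int | None = None
    se: float | None = None
    n_redrawn: int = 0


def _unpack(summaries: Mapping[str, GroupTimeSummary]):
    try:
        c, a, b, ab = (summaries[k] for k in ("C", "A", "B", "AB"))
    except KeyError as exc:
        raise PdxsynError(f"missing arm summary: {exc}") from exc
    days = {s.day for s in (c, a, b, ab)}
    if len(days) != 1:
        raise PdxsynError(f"summaries span multiple days: {sorted(days)}")
    for s in (c, a, b, ab):
        if s.mean <= 0:
            raise PdxsynError(
                f"non-positive mean relative volume in arm {s.arm}"
            )
    return c, a, b, ab


def _bliss_valid(c, a, b, ab) -> bool:
    deltas = [(c.mean - s.mean) / c.mean for s in (a, b, ab)]
    return all(0.0 <= d <= 1.0 for d in deltas)


def ci_hsa(summaries: Mapping[str, GroupTimeSummary]) -> CombinationIndexResult:
    """Highest-single-agent index at one day (no interval attached yet)."""
    c, a, b, ab = _unpack(summaries)
    ci, se, use_a = hsa_stat(
        c.mean, a.mean, b.mean, ab.mean,
        c.variance, a.variance, b.variance, ab.variance,
        c.n, a.n, b.n, ab.n,
    )
    return CombinationIndexResult(
        model="HSA", day=c.day, ci_hat=float(ci), se=float(se),
        hsa_reference_arm="A" if bool(use_a) else "B",
        bliss_valid=_bliss_valid(c, a, b, ab),
    )


def ci_ra(summaries: Mapping[str, GroupTimeSummary]) -> CombinationIndexResult:
    """Response-additivity index at one day."""
    c, a, b, ab = _unpack(summaries)
    ci, se = ra_stat(
        c.mean, a.mean, b.mean, ab.mean,
        c.variance, a.variance, b.variance, ab.variance,
        c.n, a.n, b.n, ab.n,
    )
    return CombinationIndexResult(
        model="RA", day=c.day, ci_hat=float(ci), se=float(se),
        bliss_valid=_bliss_valid(c, a, b, ab),
    )


def ci_bi(summaries: Mapping[str, GroupTimeSummary]) -> CombinationIndexResult:
    """Bliss-independence index at one day.

    Always computed; ``bliss_valid`` is False when any arm's estimated
    effect lies outside [0, 1], in which case the probabilistic reading
    of the index is doubtful and the flag should travel with the value.
    """
    c, a, b, ab = _unpack(summaries)
    ci, se = bi_stat(
        c.mean, a.mean, b.mean, ab.mean,
        c.variance, a.variance, b.variance, ab.variance,
        c.n, a.n, b.n, ab.n,
    )
    return CombinationIndexResult(
        model="BI", day=c.day, ci_hat=float(ci), se=float(se),
        bliss_valid=_bliss_valid(c, a, b, ab),
    )


_DISPATCH = {"HSA": ci_hsa, "RA": ci_ra, "BI": ci_bi}


def combination_index(model: str,
                      summaries: Mapping[str, GroupTimeSummary],
                      ) -> CombinationIndexResult:
    """Compute the index for ``model`` ("HSA", "RA" or "BI")."""
    try:
        fn = _DISPATCH[model.upper()]
    except KeyError:
        raise ValueError(f"unknown reference model {model!r}") from None
    return fn(summaries)


def asymptotic_interval(result: CombinationIndexResult,
                        alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided 100(1-alpha)% Wald interval; also stored on ``result``."""
    if not np.isfinite(result.se):
        raise PdxsynError("standard error is not finite")
    z = stats.norm.ppf(1 - alpha / 2)
    lo = result.ci_hat - z * result.se
    hi = result.ci_hat + z * result.se
    result.interval = (float(lo), float(hi))
    result.interval_method = "asymptotic"
    return result.interval


def gci(per_day: Sequence[CombinationIndexResult]) -> GlobalCIResult:
    """Global combination index: the plain mean of per-day indices.

    All inputs must share one reference model; the window is whatever
    days they cover.  Inference for gCI requires the nested bootstrap
    (:func:`pdxsyn.inference.nested_bootstrap_gci_interval`) because
    repeated measures on the same mouse are correlated across days.
    """
    if not per_day:
        raise PdxsynError("empty per-day index sequence")
    models = {r.model for r in per_day}
    if len(models) != 1:
        raise PdxsynError(f"mixed reference models: {sorted(models)}")
    days = np.asarray([r.day for r in per_day], dtype=float)
    vals = np.asarray([r.ci_hat for r in per_day], dtype=float)
    return GlobalCIResult(
        model=per_day[0].model,
        gci_hat=float(vals.mean()),
        window=days,
    )
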