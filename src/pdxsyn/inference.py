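"""Bootstrap-t inference for combination indices.

Asymptotic (Wald) intervals for a combination index lean on the central
limit theorem for four small group means; with 5-10 mice per arm and
skewed tumor-volume distributions they can be too narrow.  The
bootstrap-t procedure recalibrates the interval: animals are resampled
with replacement *within* each arm, each resampled index is studentized
by its own delta-method standard error,

    Z*b = (CI*b - CI_hat) / se*(CI*b),

and the empirical percentiles of Z* replace the normal quantiles:

    ( CI_hat - t_hat(1-alpha/2) * se(CI_hat),
      CI_hat - t_hat(alpha/2)   * se(CI_hat) ).

For the global index gCI no analytic standard error exists (repeated
measures on one mouse are correlated across days), so whole growth
curves are resampled and each outer replicate's standard error is
estimated by a nested inner resampling loop (L replicates, default 25).

Resampling always operates on animals — per-day values or whole curves —
never on individual time points across animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .data import ARMS, ExperimentData
from .exceptions import InferenceError, PdxsynError
from .indices import GlobalCIResult, ci_stat

__all__ = [
    "BootstrapConfig", "BootstrapInterval",
    "empirical_t_percentile", "bootstrap_t_interval",
    "nested_bootstrap_gci_interval",
]

_MAX_REDRAW_PASSES = 100


@dataclass
class BootstrapConfig:
    """Settings for bootstrap-t interval construction.

    Attributes
    ----------
    B : int
        Outer resample count (default 1000).
    L : int
        Nested resample count for gCI standard errors (default 25).
    alpha : float
        Two-sided level; intervals are 100(1-alpha)%.
    seed : int or numpy Generator, optional
        Seeds a single generator that drives outer and inner loops in a
        fixed order, so results are reproducible bit-for-bit.
    percentile_rule : str
        Convention for the empirical percentile t_hat(alpha); only
        ``"ceil"`` (the ceil(alpha*B)-th order statistic) is implemented.
    """

    B: int = 1000
    L: int = 25
    alpha: float = 0.05
    seed: int | np.random.Generator | None = None
    percentile_rule: str = "ceil"

    def __post_init__(self):
        if self.B < 2 or self.L < 2:
            raise ValueError("B and L must both be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.percentile_rule != "ceil":
            raise ValueError("only the 'ceil' percentile rule is implemented")

    def rng(self) -> np.random.Generator:
        if isinstance(self.seed, np.random.Generator):
            return self.seed
        return np.random.default_rng(self.seed)


@dataclass
class BootstrapInterval:
    """A bootstrap-t interval plus diagnostics."""

    lower: float
    upper: float
    alpha: float
    B: int
    ci_hat: float
    se_hat: float
    t_lower: float
    t_upper: float
    n_redrawn: int = 0
    method: str = "bootstrap-t"

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)


def empirical_t_percentile(zs, alpha: float) -> float:
    """Empirical alpha-th percentile of studentized bootstrap values.

    Exact empirical-CDF inversion of ``#{Z* <= t_hat} / B = alpha``: the
    ``ceil(alpha * B)``-th order statistic (clamped to [1, B]).  Monotone
    in ``alpha`` by construction.
    """
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        raise PdxsynError("empty studentized sample")
    if not np.all(np.isfinite(zs)):
        raise PdxsynError(
            "non-finite studentized values; degenerate replicates must "
            "be redrawn upstream"
        )
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    b = zs.size
    # tiny slack so alpha*B that is mathematically integral is not pushed up
    k = min(max(int(math.ceil(alpha * b - 1e-9)), 1), b)
    return float(np.sort(zs)[k - 1])


# ---------------------------------------------------------------------------
# per-day bootstrap-t
# ---------------------------------------------------------------------------

def _check_values(values: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for a in ARMS:
        if a not in values:
            raise PdxsynError(f"missing arm {a!r} in per-day values")
        v = np.asarray(values[a], dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise InferenceError(f"arm {a}: need >= 2 animal values")
        out[a] = v
    return out


def _stat_from_moments(model, means, variances, ns):
    return ci_stat(
        model,
        means["C"], means["A"], means["B"], means["AB"],
        variances["C"], variances["A"], variances["B"], variances["AB"],
        ns["C"], ns["A"], ns["B"], ns["AB"],
    )


def bootstrap_t_interval(values: Mapping[str, np.ndarray], model: str,
                         cfg: BootstrapConfig | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> BootstrapInterval:
    """Bootstrap-t interval for a per-day combination index.

    Parameters
    ----------
    values : mapping
        ``{"C": ..., "A": ..., "B": ..., "AB": ...}``, each a 1-d array
        of per-animal relative tumor volumes at the analysis day.
    model : str
        Reference model ("HSA", "RA" or "BI"); for HSA the reference
        monotherapy is re-selected inside every resample.
    cfg : BootstrapConfig

    Notes
    -----
    A resample in which every arm happens to have zero within-arm
    variance has ``se* = 0`` and an undefined Z*; such replicates are
    redrawn and counted in ``n_redrawn``, keeping B effective
    replicates.  Data whose every arm is constant cannot be studentized
    at all and raise :class:`~pdxsyn.exceptions.InferenceError`.
    """
    cfg = cfg or BootstrapConfig()
    vals = _check_values(values)
    rng = rng if rng is not None else cfg.rng()
    ns = {a: v.size for a, v in vals.items()}

    means0 = {a: float(v.mean()) for a, v in vals.items()}
    vars0 = {a: float(v.var(ddof=1)) for a, v in vals.items()}
    ci_hat, se_hat = _stat_from_moments(model, means0, vars0, ns)
    ci_hat, se_hat = float(ci_hat), float(se_hat)
    if se_hat == 0.0 or not np.isfinite(se_hat):
        raise InferenceError(
            "all arms are degenerate (zero variance); the studentized "
            "bootstrap is undefined"
        )

    B = cfg.B
    means = {}
    variances = {}
    for a in ARMS:  # fixed arm order keeps runs seed-reproducible
        idx = rng.integers(0, ns[a], size=(B, ns[a]))
        s = vals[a][idx]
        means[a] = s.mean(axis=1)
        variances[a] = s.var(axis=1, ddof=1)
    ci_b, se_b = _stat_from_moments(model, means, variances, ns)

    n_redrawn = 0
    for _ in range(_MAX_REDRAW_PASSES):
        bad = ~np.isfinite(se_b) | (se_b == 0) | ~np.isfinite(ci_b)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        sub_means = {}
        sub_vars = {}
        nbad = int(bad.sum())
        for a in ARMS:
            idx = rng.integers(0, ns[a], size=(nbad, ns[a]))
            s = vals[a][idx]
            sub_means[a] = s.mean(axis=1)
            sub_vars[a] = s.var(axis=1, ddof=1)
        ci_b[bad], se_b[bad] = _stat_from_moments(model, sub_means, sub_vars, ns)
    else:  # pragma: no cover - requires pathological near-constant data
        raise InferenceError("could not draw non-degenerate resamples")

    z = (ci_b - ci_hat) / se_b
    t_lo = empirical_t_percentile(z, 1 - cfg.alpha / 2)
    t_hi = empirical_t_percentile(z, cfg.alpha / 2)
    return BootstrapInterval(
        lower=float(ci_hat - t_lo * se_hat),
        upper=float(ci_hat - t_hi * se_hat),
        alpha=cfg.alpha, B=B, ci_hat=ci_hat, se_hat=se_hat,
        t_lower=float(t_lo), t_upper=float(t_hi), n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# nested bootstrap for gCI
# ---------------------------------------------------------------------------

def _gci_from_index_matrices(model: str, mats: Mapping[str, np.ndarray],
                             idx: Mapping[str, np.ndarray] | None = None,
                             ) -> np.ndarray:
    """gCI for (possibly many) curve resamples.

    ``mats[arm]`` has shape ``(n_arm, T)``; ``idx[arm]`` (optional) has
    shape ``(..., n_arm)`` of animal indices.  Returns gCI with shape
    ``(...)`` (scalar array when ``idx`` is None).  Per-day indices use
    the same kernels as the point estimator, so the HSA reference arm is
    re-selected independently at every day of every resample.
    """
    means = {}
    variances = {}
    ns = {}
    for a, mat in mats.items():
        sub = mat if idx is None else mat[idx[a]]
        means[a] = sub.mean(axis=-2)
        variances[a] = sub.var(axis=-2, ddof=1)
        ns[a] = mat.shape[0]
    ci, _ = _stat_from_moments(model, means, variances, ns)
    return np.asarray(ci).mean(axis=-1)


def _nested_se(model, mats, L, rng):
    """SD of gCI over L whole-curve resamples (the inner-loop estimator)."""
    idx = {a: rng.integers(0, m.shape[0], size=(L, m.shape[0]))
           for a, m in mats.items()}
    reps = _gci_from_index_matrices(model, mats, idx)
    return float(np.std(reps, ddof=1)), reps


def nested_bootstrap_gci_interval(data, model: str,
                                  cfg: BootstrapConfig | None = None,
                                  window=None) -> GlobalCIResult:
    """Nested-bootstrap-t interval for the global combination index.

    Parameters
    ----------
    data : ExperimentData or mapping of arm -> (n, T) array
        Complete per-animal growth-curve matrices over the analysis
        window (interior gaps already interpolated).  When an
        :class:`~pdxsyn.data.ExperimentData` is given, matrices are
        built with :meth:`~pdxsyn.data.ExperimentData.curve_matrix`.
    model : str
        Reference model.
    cfg : BootstrapConfig
        ``cfg.B`` outer and ``cfg.L`` inner resamples.
    window : array-like, optional
        Analysis days; defaults to the experiment grid minus baseline.

    Notes
    -----
    The outer loop resamples whole animal curves within each arm
    (preserving within-mouse correlation across days) and computes
    gCI*b; the inner loop resamples curves from the b-th resample L
    times to estimate se*(gCI*b).  The standard error of the original
    gCI, needed by the interval formula, is estimated by the same
    inner-loop scheme applied once to the original data — the only
    estimator the nested procedure supplies, since no analytic variance
    exists.
    """
    cfg = cfg or BootstrapConfig()
    if isinstance(data, ExperimentData):
        mats, window = data.curve_matrix(window)
    else:
        mats = {a: np.atleast_2d(np.asarray(m, dtype=float))
                for a, m in data.items()}
        for a in ARMS:
            if a not in mats:
                raise PdxsynError(f"missing arm {a!r} in curve matrices")
        t_set = {m.shape[1] for m in mats.values()}
        if len(t_set) != 1:
            raise PdxsynError("curve matrices disagree on window length")
        if window is None:
            window = np.arange(1, t_set.pop() + 1, dtype=float)
        else:
            window = np.asarray(window, dtype=float)
    for a, m in mats.items():
        if m.shape[0] < 2:
            raise InferenceError(f"arm {a}: need >= 2 complete curves")

    rng = cfg.rng()
    gci_hat = float(_gci_from_index_matrices(model, mats))

    # draw order is fixed: se(gCI) pass, then outer, then inner
    se_hat, _ = _nested_se(model, mats, cfg.L, rng)
    if se_hat == 0.0 or not np.isfinite(se_hat):
        raise InferenceError(
            "gCI resamples are degenerate (identical curves within arms); "
            "the studentized interval is undefined"
        )

    B, L = cfg.B, cfg.L
    outer_idx = {a: rng.integers(0, m.shape[0], size=(B, m.shape[0]))
                 for a, m in mats.items()}
    gci_b = _gci_from_index_matrices(model, mats, outer_idx)

    inner = {}
    for a, m in mats.items():
        n = m.shape[0]
        raw = rng.integers(0, n, size=(B, L, n))
        # compose: inner resamples are drawn from the b-th outer resample
        inner[a] = np.take_along_axis(outer_idx[a][:, None, :], raw, axis=2)
    gci_bl = _gci_from_index_matrices(model, mats, inner)  # (B, L)
    se_b = gci_bl.std(axis=1, ddof=1)

    n_redrawn = 0
    for _ in range(_MAX_REDRAW_PASSES):
        bad = ~np.isfinite(se_b) | (se_b == 0) | ~np.isfinite(gci_b)
        if not bad.any():
            break
        nbad = int(bad.sum())
        n_redrawn += nbad
        sub_outer = {a: rng.integers(0, m.shape[0], size=(nbad, m.shape[0]))
                     for a, m in mats.items()}
        gci_b[bad] = _gci_from_index_matrices(model, mats, sub_outer)
        sub_inner = {}
        for a, m in mats.items():
            n = m.shape[0]
            raw = rng.integers(0, n, size=(nbad, L, n))
            sub_inner[a] = np.take_along_axis(
                sub_outer[a][:, None, :], raw, axis=2)
        se_b[bad] = _gci_from_index_matrices(model, mats, sub_inner).std(
            axis=1, ddof=1)
    else:  # pragma: no cover
        raise InferenceError("could not draw non-degenerate curve resamples")

    z = (gci_b - gci_hat) / se_b
    t_lo = empirical_t_percentile(z, 1 - cfg.alpha / 2)
    t_hi = empirical_t_percentile(z, cfg.alpha / 2)
    return GlobalCIResult(
        model=model.upper(), gci_hat=gci_hat,
        window=np.asarray(window, dtype=float),
        interval=(float(gci_hat - t_lo * se_hat),
                  float(gci_hat - t_hi * se_hat)),
        interval_method="bootstrap-t",
        B=B, L=L, se=se_hat, n_redrawn=n_redrawn,
    )
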