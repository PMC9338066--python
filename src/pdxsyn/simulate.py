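"""Synthetic four-arm PDX combination experiments.

Arm-level expected tumor growth follows the Gompertz law

    V(t) = V0 * exp( (a/b) * (1 - e^{-b t}) ),

a sigmoid in log-volume with initial specific growth rate ``a`` (1/day),
deceleration ``b`` (1/day) and plateau ``V0 * e^{a/b}``.  Treatment
attenuates ``a``.  Per-mouse relative volumes are the arm mean times
mean-one multiplicative lognormal noise (volumes stay positive, and the
arm *mean* equals the Gompertz curve exactly, so a combination arm built
from a reference model's null prediction has true combination index
exactly 0 at every day — the ground-truth anchor for coverage studies).

Default conditions mimic a typical PDX study: measurements every 2-3
days through day 21, control relative volume reaching about 2.8 by day
21 with monotherapies reaching about 2.4 and 2.0, per-arm SDs of about
0.7 (control) and 0.3 (treated) at day 21, and 10 mice per arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ARMS, ExperimentData, GrowthCurve
from .exceptions import ConfigurationError
from .indices import MODELS, ci_stat
from .inference import BootstrapConfig, bootstrap_t_interval
from scipy import stats as _stats

__all__ = [
    "GompertzParams", "SimulationConfig", "gompertz_mean",
    "gompertz_rate_for", "null_combination_mean", "arm_mean_curve",
    "simulate_records", "simulate_experiment", "simulate_day_values",
    "coverage_study",
]

DEFAULT_DAYS = (0.0, 2.0, 4.0, 7.0, 9.0, 11.0, 14.0, 16.0, 18.0, 21.0)


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth parameters: baseline volume V0 (mm^3), rate a
    (1/day), deceleration b (1/day)."""

    v0: float = 100.0
    a: float = 0.1
    b: float = 0.1

    def __post_init__(self):
        if self.v0 <= 0:
            raise ConfigurationError("V0 must be positive")
        if self.b <= 0:
            raise ConfigurationError("deceleration b must be positive")

    def relative(self, t):
        """Expected relative volume V(t)/V0 at day(s) t."""
        t = np.asarray(t, dtype=float)
        return np.exp(self.a / self.b * (1.0 - np.exp(-self.b * t)))


def gompertz_mean(t, params: GompertzParams):
    """Expected absolute tumor volume V(t) under ``params``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("day must be non-negative")
    return params.v0 * params.relative(t)


def gompertz_rate_for(target_relative: float, day: float,
                      b: float = 0.1) -> float:
    """Growth rate ``a`` so the relative volume hits a target at ``day``."""
    if target_relative <= 0 or day <= 0 or b <= 0:
        raise ConfigurationError("target, day and b must all be positive")
    return b * math.log(target_relative) / (1.0 - math.exp(-b * day))


def _default_gompertz() -> dict[str, GompertzParams]:
    # control reaches relative volume 2.8 at day 21; monotherapies 2.4 / 2.0;
    # the direct AB parameterisation (used only when no null model is set)
    # reaches 1.5 — a clearly synergistic combination
    targets = {"C": 2.8, "A": 2.4, "B": 2.0, "AB": 1.5}
    return {g: GompertzParams(v0=100.0, a=gompertz_rate_for(v, 21.0, 0.1),
                              b=0.1)
            for g, v in targets.items()}


def _default_noise_sd() -> dict[str, float]:
    return {"C": 0.7, "A": 0.3, "B": 0.3, "AB": 0.3}


def _default_ns() -> dict[str, int]:
    return {g: 10 for g in ARMS}


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic experiment.

    Attributes
    ----------
    gompertz : mapping of arm -> GompertzParams
        Mean-growth parameters per arm.  The AB entry is ignored when
        ``null_model`` is set (the AB mean is then derived from the
        other arms).
    noise_sd : mapping of arm -> float
        Target SD of relative volume at the *reference day* (the last
        scheduled day); internally converted to a constant per-arm
        lognormal coefficient of variation.
    ns : mapping of arm -> int
        Mice per arm.
    days : sequence of float
        Measurement schedule (must include day 0, the baseline).
    null_model : str or None
        When "HSA", "RA" or "BI", the AB arm mean is set to that model's
        no-interaction prediction at every day, making the true index 0.
    missingness : float
        Per-point dropout probability for non-baseline measurements.
    baseline_cv : float
        Lognormal CV of raw baseline volumes across mice (exercises the
        baseline normalisation; relative volumes are unaffected).
    seed : int, optional
    """

    gompertz: dict[str, GompertzParams] = field(default_factory=_default_gompertz)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    ns: dict[str, int] = field(default_factory=_default_ns)
    days: Sequence[float] = DEFAULT_DAYS
    null_model: str | None = None
    missingness: float = 0.0
    baseline_cv: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        self.days = tuple(sorted(float(d) for d in set(self.days)))
        if not self.days or self.days[0] != 0.0:
            raise ConfigurationError("schedule must start at day 0 (baseline)")
        if not 0.0 <= self.missingness < 1.0:
            raise ConfigurationError("missingness must be in [0, 1)")
        if self.null_model is not None:
            self.null_model = self.null_model.upper()
            if self.null_model not in MODELS:
                raise ConfigurationError(
                    f"unknown null model {self.null_model!r}"
                )
        for g in ARMS:
            if g == "AB" and self.null_model is not None:
                continue
            if g not in self.gompertz:
                raise ConfigurationError(f"missing Gompertz params for {g}")
        for g in ARMS:
            if self.ns.get(g, 0) < 2:
                raise ConfigurationError(f"need at least 2 mice in arm {g}")
            if self.noise_sd.get(g, -1.0) < 0:
                raise ConfigurationError(f"need noise_sd >= 0 for arm {g}")
        # RA null must predict a positive combination mean at every day
        if self.null_model == "RA":
            bad = arm_mean_curve(self, "A", self.days) \
                + arm_mean_curve(self, "B", self.days) \
                - arm_mean_curve(self, "C", self.days)
            if np.any(bad <= 0):
                raise ConfigurationError(
                    "RA null predicts a non-positive combination mean on "
                    "this schedule"
                )

    @property
    def reference_day(self) -> float:
        return self.days[-1]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def null_combination_mean(mu_a, mu_b, mu_c, model: str):
    """Combination-arm mean predicted by a reference model's null.

    HSA: min(mu_A, mu_B); RA: mu_A + mu_B - mu_C; BI: mu_A*mu_B/mu_C.
    Feeding the result back into the matching index yields exactly 0.
    Vectorised over days.
    """
    mu_a, mu_b, mu_c = (np.asarray(x, dtype=float) for x in (mu_a, mu_b, mu_c))
    if np.any(mu_a <= 0) or np.any(mu_b <= 0) or np.any(mu_c <= 0):
        raise ConfigurationError("means must be positive")
    model = model.upper()
    if model == "HSA":
        out = np.minimum(mu_a, mu_b)
    elif model == "RA":
        out = mu_a + mu_b - mu_c
        if np.any(out <= 0):
            raise ConfigurationError(
                "RA null mean is non-positive for these monotherapy means"
            )
    elif model == "BI":
        out = mu_a * mu_b / mu_c
    else:
        raise ConfigurationError(f"unknown reference model {model!r}")
    return out if out.ndim else float(out)


def arm_mean_curve(cfg: SimulationConfig, arm: str, days=None) -> np.ndarray:
    """True mean relative volume of ``arm`` on the schedule (or ``days``)."""
    days = np.asarray(cfg.days if days is None else days, dtype=float)
    if arm == "AB" and cfg.null_model is not None:
        return null_combination_mean(
            arm_mean_curve(cfg, "A", days),
            arm_mean_curve(cfg, "B", days),
            arm_mean_curve(cfg, "C", days),
            cfg.null_model,
        )
    return cfg.gompertz[arm].relative(days)


def _arm_sigma(cfg: SimulationConfig, arm: str) -> float:
    """Lognormal log-SD giving the target SD at the reference day."""
    mean_ref = float(arm_mean_curve(cfg, arm, [cfg.reference_day])[0])
    cv = cfg.noise_sd[arm] / mean_ref
    return math.sqrt(math.log1p(cv * cv))


def _noise(rng, sigma, size):
    """Mean-one multiplicative lognormal factors."""
    if sigma == 0.0:
        return np.ones(size)
    return np.exp(sigma * rng.standard_normal(size) - 0.5 * sigma * sigma)


def simulate_records(cfg: SimulationConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One synthetic experiment as a long raw-volume table.

    Output columns (mouse_id, arm, day, volume) are exactly what
    :func:`pdxsyn.data.read_tumor_table` produces, so simulated CSVs
    round-trip through the reader.  Baselines are never dropped.
    """
    rng = cfg.rng() if rng is None else rng
    days = np.asarray(cfg.days, dtype=float)
    rows = []
    for arm in ARMS:
        mean_curve = arm_mean_curve(cfg, arm, days)
        sigma = _arm_sigma(cfg, arm)
        n = cfg.ns[arm]
        v0_nominal = (cfg.gompertz.get(arm) or cfg.gompertz["C"]).v0
        baselines = v0_nominal * _noise(rng, math.sqrt(
            math.log1p(cfg.baseline_cv ** 2)) if cfg.baseline_cv else 0.0, n)
        for i in range(n):
            rel = mean_curve * _noise(rng, sigma, len(days))
            rel[0] = 1.0  # baseline is the normaliser, exactly 1
            keep = np.ones(len(days), dtype=bool)
            if cfg.missingness > 0:
                keep[1:] = rng.random(len(days) - 1) >= cfg.missingness
            for d, v, k in zip(days, rel, keep):
                if k:
                    rows.append({
                        "mouse_id": f"{arm}{i + 1}", "arm": arm,
                        "day": float(d),
                        "volume": float(baselines[i] * v),
                    })
    return pd.DataFrame(rows)


def simulate_experiment(cfg: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> ExperimentData:
    """Generate a preprocessed :class:`~pdxsyn.data.ExperimentData`."""
    return ExperimentData.from_records(simulate_records(cfg, rng))


def simulate_day_values(cfg: SimulationConfig, day: float,
                        rng: np.random.Generator | None = None,
                        arms: Sequence[str] = ARMS,
                        ) -> dict[str, np.ndarray]:
    """Per-arm relative volumes at a single day.

    Same marginal law as :func:`simulate_experiment` at that day (noise
    is independent across days), without building whole curves — the
    fast path for repeated-simulation studies.
    """
    rng = cfg.rng() if rng is None else rng
    out = {}
    for arm in arms:
        mean = float(arm_mean_curve(cfg, arm, [day])[0])
        out[arm] = mean * _noise(rng, _arm_sigma(cfg, arm), cfg.ns[arm])
    return out


def _asymptotic_covers(values: Mapping[str, np.ndarray], model: str,
                       alpha: float, truth: float) -> bool:
    m = {a: v.mean() for a, v in values.items()}
    v_ = {a: v.var(ddof=1) for a, v in values.items()}
    n = {a: v.size for a, v in values.items()}
    ci, se = ci_stat(model, m["C"], m["A"], m["B"], m["AB"],
                     v_["C"], v_["A"], v_["B"], v_["AB"],
                     n["C"], n["A"], n["B"], n["AB"])
    z = _stats.norm.ppf(1 - alpha / 2)
    return bool(ci - z * se <= truth <= ci + z * se)


def coverage_study(cfg: SimulationConfig, reps: int, alpha: float = 0.05,
                   use_bootstrap: bool = False, day: float | None = None,
                   B: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Empirical interval coverage of the true index under a null design.

    ``cfg.null_model`` must be set: the data-generating combination mean
    is then the null prediction and the true index is 0 at every day.
    Each replicate simulates fresh per-arm values at ``day`` (default:
    the last scheduled day), computes the model's index and its
    two-sided interval — asymptotic Wald or bootstrap-t with ``B``
    resamples — and records whether the interval covers 0.

    Returns a one-row table: model, day, method, reps, coverage (as a
    fraction) and its binomial standard error.
    """
    if cfg.null_model is None:
        raise ConfigurationError(
            "coverage_study needs cfg.null_model so the true index is known"
        )
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    model = cfg.null_model
    day = cfg.reference_day if day is None else float(day)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    boot_cfg = BootstrapConfig(B=B, alpha=alpha, seed=rng)

    covered = 0
    for _ in range(reps):
        values = simulate_day_values(cfg, day, rng)
        if use_bootstrap:
            bi = bootstrap_t_interval(values, model, boot_cfg, rng=rng)
            covered += bi.lower <= 0.0 <= bi.upper
        else:
            covered += _asymptotic_covers(values, model, alpha, 0.0)
    p = covered / reps
    return pd.DataFrame([{
        "model": model, "day": day,
        "method": "bootstrap-t" if use_bootstrap else "asymptotic",
        "reps": reps, "alpha": alpha, "coverage": p,
        "binom_se": math.sqrt(p * (1 - p) / reps),
    }])
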