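"""Model/Results interface tying the analysis pipeline together.

:class:`CombinationStudy` wraps one four-arm experiment (control C,
monotherapies A and B, combination AB).  Its :meth:`~CombinationStudy.fit`
runs preprocessing, per-day treatment effects (TGI), per-day combination
indices under the requested reference models with asymptotic or
bootstrap-t intervals, and the global index gCI with its nested-bootstrap
interval, returning a :class:`CombinationStudyResults` that carries the
tables, diagnostics and plotting helpers.

Example
-------
>>> from pdxsyn import CombinationStudy, SimulationConfig, simulate_records
>>> records = simulate_records(SimulationConfig(null_model="BI", seed=7))
>>> res = CombinationStudy(records).fit(models=("BI",))
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __about__
from .data import ARMS, ExperimentData, read_tumor_table
from .effects import check_bliss_assumption, tgi_effect
from .exceptions import PdxsynError
from .indices import (MODELS, asymptotic_interval, combination_index, gci)
from .inference import (BootstrapConfig, bootstrap_t_interval,
                        nested_bootstrap_gci_interval)


class CombinationStudy:
    """A fixed-dose four-arm PDX combination experiment, ready to fit.

    Parameters
    ----------
    data : pandas.DataFrame or ExperimentData
        Long-format validated records (columns mouse_id, arm, day,
        volume) or an already-preprocessed experiment.
    time_grid : array-like, optional
        Analysis days; defaults to every observed day on which all arms
        retain at least two mice.
    """

    def __init__(self, data, time_grid=None):
        if isinstance(data, ExperimentData):
            self.data = data
            self.records = None
        elif isinstance(data, pd.DataFrame):
            self.records = data
            self.data = ExperimentData.from_records(data, time_grid=time_grid)
        else:
            raise TypeError(
                "data must be a records DataFrame or ExperimentData"
            )
        self.data.require_arms(ARMS)

    @classmethod
    def from_csv(cls, source, column_map=None, arm_labels=None,
                 on_duplicate="error", time_grid=None) -> "CombinationStudy":
        """Build a study straight from a delimited text file."""
        records = read_tumor_table(source, column_map=column_map,
                                   arm_labels=arm_labels,
                                   on_duplicate=on_duplicate)
        return cls(records, time_grid=time_grid)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       time_grid=None) -> "CombinationStudy":
        """Build a study from an already-validated records DataFrame."""
        return cls(df, time_grid=time_grid)

    @property
    def analysis_days(self) -> np.ndarray:
        """Grid days after baseline (effects and indices are trivial at
        baseline, where every relative volume is 1)."""
        grid = self.data.time_grid
        return grid[grid > grid[0]]

    def fit(self, alpha: float = 0.05,
            models: Sequence[str] = MODELS,
            intervals: str = "asymptotic",
            B: int = 1000, L: int = 25,
            window=None, seed=None) -> "CombinationStudyResults":
        """Run the full analysis.

        Parameters
        ----------
        alpha : float
            1 - confidence level (default 0.05 -> 95% intervals).
        models : sequence of str
            Reference models to evaluate (default all three).
        intervals : {"asymptotic", "bootstrap"}
            Per-day interval method.  gCI intervals always use the
            nested bootstrap (no analytic variance exists) and are
            computed only under ``"bootstrap"``.
        B, L : int
            Outer / nested bootstrap resample counts.
        window : array-like, optional
            gCI study window; defaults to all analysis days.
        seed : int, optional
            Drives all resampling; identical inputs and seed reproduce
            identical results.
        """
        if intervals not in ("asymptotic", "bootstrap"):
            raise ValueError("intervals must be 'asymptotic' or 'bootstrap'")
        models = [m.upper() for m in models]
        for m in models:
            if m not in MODELS:
                raise ValueError(f"unknown reference model {m!r}")
        days = self.analysis_days
        if len(days) == 0:
            raise PdxsynError("no analysis days after the baseline")
        rng = np.random.default_rng(seed)

        # -- per-day treatment effects (TGI) --------------------------
        effect_rows, effect_objs = [], []
        for d in days:
            summaries = self.data.summaries_at(d)
            for arm in ("A", "B", "AB"):
                eff = tgi_effect(summaries["C"], summaries[arm], alpha=alpha)
                effect_objs.append(eff)
                effect_rows.append({
                    "arm": arm, "day": d, "delta_hat": eff.delta_hat,
                    "se": eff.se, "lower_bound": eff.lower_bound,
                    "alpha": alpha,
                })
        effects = pd.DataFrame(effect_rows)
        bliss = check_bliss_assumption(effect_objs)

        # -- per-day combination indices ------------------------------
        boot_cfg = BootstrapConfig(B=B, L=L, alpha=alpha, seed=rng)
        index_rows = []
        n_redrawn_total = 0
        for model in models:
            for d in days:
                summaries = self.data.summaries_at(d)
                res = combination_index(model, summaries)
                if intervals == "bootstrap":
                    values = {a: self.data.values_at(d, a)[0] for a in ARMS}
                    bi = bootstrap_t_interval(values, model, boot_cfg, rng=rng)
                    res.interval = bi.interval
                    res.interval_method = "bootstrap-t"
                    n_redrawn_total += bi.n_redrawn
                else:
                    asymptotic_interval(res, alpha=alpha)
                index_rows.append({
                    "model": model, "day": d, "ci_hat": res.ci_hat,
                    "se": res.se, "lower": res.interval[0],
                    "upper": res.interval[1],
                    "interval_method": res.interval_method,
                    "hsa_reference_arm": res.hsa_reference_arm,
                    "bliss_valid": res.bliss_valid,
                })
        indices = pd.DataFrame(index_rows)

        # -- global index ---------------------------------------------
        gci_rows = []
        win = days if window is None else np.asarray(window, dtype=float)
        for model in models:
            per_day = [r for r in index_rows
                       if r["model"] == model and r["day"] in set(win)]
            point = float(np.mean([r["ci_hat"] for r in per_day]))
            row = {"model": model, "gci_hat": point,
                   "window_start": float(win.min()),
                   "window_end": float(win.max()),
                   "lower": np.nan, "upper": np.nan,
                   "interval_method": None, "B": None, "L": None}
            if intervals == "bootstrap":
                g = nested_bootstrap_gci_interval(
                    self.data, model,
                    BootstrapConfig(B=B, L=L, alpha=alpha, seed=rng),
                    window=win)
                row.update({"gci_hat": g.gci_hat, "lower": g.interval[0],
                            "upper": g.interval[1],
                            "interval_method": "bootstrap-t",
                            "B": g.B, "L": g.L})
                n_redrawn_total += g.n_redrawn
            gci_rows.append(row)
        global_indices = pd.DataFrame(gci_rows)

        return CombinationStudyResults(
            study=self, alpha=alpha, models=tuple(models),
            effects=effects, indices=indices,
            global_indices=global_indices, bliss=bliss,
            metadata={
                "alpha": alpha, "intervals": intervals, "B": B, "L": L,
                "seed": seed, "window": list(map(float, win)),
                "n_bootstrap_redrawn": n_redrawn_total,
                "version": __about__.__version__,
            },
        )


@dataclass
class CombinationStudyResults:
    """Fitted tables and diagnostics for one combination experiment."""

    study: CombinationStudy
    alpha: float
    models: tuple[str, ...]
    effects: pd.DataFrame
    indices: pd.DataFrame
    global_indices: pd.DataFrame
    bliss: object
    metadata: dict = field(default_factory=dict)

    # -- reporting -----------------------------------------------------

    def summary(self, float_format: str = "%.4f") -> str:
        """Human-readable report of effects, indices and gCI."""
        lines = []
        pct = 100 * (1 - self.alpha)
        lines.append("Combination study results")
        lines.append("=" * 60)
        lines.append(f"models: {', '.join(self.models)}   "
                     f"confidence level: {pct:g}%   "
                     f"intervals: {self.metadata.get('intervals')}")
        lines.append("")
        lines.append(f"Treatment effects (TGI) with one-sided {pct:g}% "
                     "lower bounds")
        lines.append(self.effects.to_string(index=False,
                                            float_format=float_format))
        lines.append("")
        lines.append(f"Per-day combination indices (two-sided {pct:g}% "
                     "intervals; CI > 0 indicates synergy)")
        lines.append(self.indices.to_string(index=False,
                                            float_format=float_format))
        lines.append("")
        lines.append("Global combination index (mean over the study window)")
        lines.append(self.global_indices.to_string(index=False,
                                                   float_format=float_format))
        if not self.bliss.passed:
            lines.append("")
            lines.append("warning: Bliss assumption (0 <= delta <= 1) "
                         "violated at: "
                         + ", ".join(f"({a}, day {d:g})"
                                     for a, d, _ in self.bliss.violations))
        return "\n".join(lines)

    def save_tables(self, outdir, prefix: str = "") -> list[str]:
        """Write the result tables (and the per-arm summary) as CSVs."""
        import os

        os.makedirs(outdir, exist_ok=True)
        written = []
        tables = {
            "group_summary": self.study.data.summary_table(),
            "effects": self.effects,
            "combination_indices": self.indices,
            "global_indices": self.global_indices,
        }
        for name, tbl in tables.items():
            path = os.path.join(outdir, f"{prefix}{name}.csv")
            tbl.to_csv(path, index=False)
            written.append(path)
        return written

    # -- plotting ------------------------------------------------------

    _ARM_COLORS = {"C": "0.3", "A": "tab:blue", "B": "tab:orange",
                   "AB": "tab:red"}

    def plot_volumes(self, ax=None):
        """Per-mouse raw tumor-volume trajectories, colored by arm."""
        import matplotlib.pyplot as plt

        if self.study.records is None:
            raise PdxsynError("raw volumes unavailable (study built from "
                              "preprocessed data)")
        ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
        seen = set()
        for (mouse, arm), grp in self.study.records.groupby(
                ["mouse_id", "arm"]):
            grp = grp.sort_values("day")
            ax.plot(grp["day"], grp["volume"],
                    color=self._ARM_COLORS[arm], alpha=0.6,
                    label=arm if arm not in seen else None)
            seen.add(arm)
        ax.set_xlabel("day")
        ax.set_ylabel("tumor volume")
        ax.legend(title="arm")
        return ax

    def plot_relative_volumes(self, ax=None):
        """Arm means of relative volume with +/- 1 SD bars."""
        import matplotlib.pyplot as plt

        ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
        tbl = self.study.data.summary_table()
        for arm, grp in tbl.groupby("arm"):
            grp = grp.sort_values("day")
            ax.errorbar(grp["day"], grp["mean"],
                        yerr=np.sqrt(grp["variance"]),
                        color=self._ARM_COLORS[arm], marker="o",
                        capsize=3, label=arm)
        ax.set_xlabel("day")
        ax.set_ylabel("relative tumor volume")
        ax.legend(title="arm")
        return ax

    def plot_tgi(self, ax=None):
        """TGI per arm over time with one-sided lower confidence bounds."""
        import matplotlib.pyplot as plt

        ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
        for arm, grp in self.effects.groupby("arm"):
            grp = grp.sort_values("day")
            ax.plot(grp["day"], grp["delta_hat"],
                    color=self._ARM_COLORS[arm], marker="o", label=arm)
            ax.vlines(grp["day"], grp["lower_bound"], grp["delta_hat"],
                      color=self._ARM_COLORS[arm], alpha=0.5)
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("day")
        ax.set_ylabel(r"TGI  $\hat\delta_g$")
        ax.legend(title="arm")
        return ax

    def plot_combination_index(self, model: str, ax=None):
        """One model's per-day index trajectory with two-sided intervals."""
        import matplotlib.pyplot as plt

        model = model.upper()
        sub = self.indices[self.indices["model"] == model].sort_values("day")
        if sub.empty:
            raise PdxsynError(f"model {model!r} was not fitted")
        ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
        ax.plot(sub["day"], sub["ci_hat"], marker="o", color="tab:purple")
        ax.vlines(sub["day"], sub["lower"], sub["upper"],
                  color="tab:purple", alpha=0.5)
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("day")
        ax.set_ylabel(f"CI ({model})")
        ax.set_title(f"{model}: CI > 0 synergy, < 0 antagonism")
        return ax
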