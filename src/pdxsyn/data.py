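"""Reading, validation and preprocessing of longitudinal tumor-volume data.

A fixed-dose combination experiment follows four treatment arms — vehicle
control (``C``), two monotherapies (``A``, ``B``) and the combination
(``AB``) — and records each mouse's tumor volume every few days.  This
module turns the long-format measurement table into per-mouse
*relative-volume* growth curves (each volume divided by the same mouse's
baseline volume), fills interior missing days by linear interpolation, and
produces per-arm per-day summary statistics that feed every downstream
estimator.

The main entry points are :func:`read_tumor_table`,
:func:`compute_relative_volumes` and :class:`ExperimentData`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ArmLabelError,
    DataFormatError,
    DuplicateRecordError,
    ExtrapolationError,
    InsufficientDataError,
    ValidationError,
)

ARMS = ("C", "A", "B", "AB")

#: default synonyms recognised for the four canonical arm labels
DEFAULT_ARM_LABELS = {
    "c": "C", "control": "C", "vehicle": "C", "ctrl": "C",
    "a": "A", "drug a": "A", "druga": "A",
    "b": "B", "drug b": "B", "drugb": "B",
    "ab": "AB", "combo": "AB", "combination": "AB", "a+b": "AB",
}

#: default column names expected in the input table
DEFAULT_COLUMNS = {
    "mouse_id": "mouse_id",
    "arm": "arm",
    "day": "day",
    "volume": "volume",
}


class InterpolationWarning(UserWarning):
    """More than half of an arm's values at a day are interpolated."""


def _normalise_arm(label, mapping):
    key = str(label).strip()
    if key in ARMS:
        return key
    lowered = key.lower()
    if lowered in mapping:
        return mapping[lowered]
    raise ArmLabelError(
        f"unknown treatment label {label!r}; expected one of {ARMS} "
        f"or a mapped synonym"
    )


def read_tumor_table(
    source,
    column_map: Mapping[str, str] | None = None,
    arm_labels: Mapping[str, str] | None = None,
    on_duplicate: str = "error",
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format tumor-volume table into validated records.

    Parameters
    ----------
    source : path, file-like or str
        Delimited text (CSV/TSV) with a header row.  One row per
        measurement: mouse identifier, treatment arm, study day, raw
        tumor volume.
    column_map : mapping, optional
        Maps the canonical names ``mouse_id``, ``arm``, ``day``,
        ``volume`` to the column names actually present.
    arm_labels : mapping, optional
        Extra treatment-label synonyms, e.g. ``{"Vehicle": "C"}``.
        Matching is case-insensitive; the canonical labels C/A/B/AB are
        always accepted.
    on_duplicate : {"error", "mean"}
        Discrepant repeated (mouse, day) rows either raise
        :class:`~pdxsyn.exceptions.DuplicateRecordError` (default) or
        are averaged.
    sep : str, optional
        Field delimiter; sniffed when omitted.

    Returns
    -------
    pandas.DataFrame
        Columns ``mouse_id`` (str), ``arm`` (C/A/B/AB), ``day`` (float),
        ``volume`` (float), one row per validated measurement.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    labels = dict(DEFAULT_ARM_LABELS)
    if arm_labels:
        labels.update({str(k).strip().lower(): v for k, v in arm_labels.items()})

    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        raw = pd.read_csv(source, sep=sep, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataFormatError(f"could not parse input table: {exc}") from exc

    missing = [cols[k] for k in ("mouse_id", "arm", "day", "volume")
               if cols[k] not in raw.columns]
    if missing:
        raise DataFormatError(
            f"missing required column(s): {', '.join(missing)}; "
            f"available: {', '.join(map(str, raw.columns))}"
        )

    df = pd.DataFrame({
        "mouse_id": raw[cols["mouse_id"]].astype(str),
        "arm": raw[cols["arm"]],
        "day": pd.to_numeric(raw[cols["day"]], errors="coerce"),
        "volume": pd.to_numeric(raw[cols["volume"]], errors="coerce"),
    })

    bad_day = df.index[df["day"].isna() | (df["day"] < 0)]
    if len(bad_day):
        raise ValidationError(
            f"non-numeric or negative day in row(s) {list(bad_day)}",
            rows=bad_day,
        )
    bad_vol = df.index[df["volume"].isna() | (df["volume"] <= 0)]
    if len(bad_vol):
        raise ValidationError(
            f"non-positive or non-numeric volume in row(s) {list(bad_vol)}",
            rows=bad_vol,
        )

    df["arm"] = [_normalise_arm(v, labels) for v in df["arm"]]

    dup_mask = df.duplicated(subset=["mouse_id", "day"], keep=False)
    if dup_mask.any():
        conflicts = (
            df[dup_mask]
            .groupby(["mouse_id", "day"])["volume"]
            .apply(list)
        )
        if on_duplicate == "error":
            listing = "; ".join(
                f"mouse {m}, day {d:g}: volumes {v}"
                for (m, d), v in conflicts.items()
            )
            raise DuplicateRecordError(
                f"discrepant repeated measurements: {listing}",
                rows=df.index[dup_mask],
            )
        if on_duplicate == "mean":
            df = (
                df.groupby(["mouse_id", "arm", "day"], as_index=False)["volume"]
                .mean()
            )
        else:
            raise ValueError("on_duplicate must be 'error' or 'mean'")

    return df.reset_index(drop=True)


@dataclass
class GrowthCurve:
    """Per-mouse time series of baseline-normalised tumor volumes.

    ``values[0]`` is always exactly 1: every raw volume is divided by the
    volume at the mouse's earliest measured day (the baseline, which is
    not necessarily day 0).
    """

    mouse_id: str
    arm: str
    days: np.ndarray
    values: np.ndarray
    interpolated: np.ndarray = None  # type: ignore[assignment]
    baseline_day: float = 0.0

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.days), dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if np.any(np.diff(self.days) <= 0):
            raise ValidationError(
                f"days not strictly increasing for mouse {self.mouse_id}"
            )
        if np.any(self.values <= 0):
            raise ValidationError(
                f"non-positive relative volume for mouse {self.mouse_id}"
            )

    def __len__(self):
        return len(self.days)

    def value_at(self, day: float) -> tuple[float, bool]:
        """Relative volume at ``day``: measured, or linearly interpolated.

        Returns ``(value, was_interpolated)``.  Raises
        :class:`~pdxsyn.exceptions.ExtrapolationError` outside the
        mouse's observed span — mice that left the study are never
        extrapolated.
        """
        return interpolate_missing(self, day, _return_flag=True)


def compute_relative_volumes(records: pd.DataFrame) -> list[GrowthCurve]:
    """Convert validated volume records into per-mouse growth curves.

    The baseline is each mouse's earliest measured day; relative volume
    there is 1 by construction.  Mice with a single time point are kept
    (with a warning) but cannot support interpolation.
    """
    curves = []
    for (mouse, arm), grp in records.groupby(["mouse_id", "arm"], sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=float)
        vols = grp["volume"].to_numpy(dtype=float)
        if len(days) == 1:
            warnings.warn(
                f"mouse {mouse} has a single measurement (day {days[0]:g}); "
                "curve retained but unusable for interpolation",
                UserWarning,
                stacklevel=2,
            )
        curves.append(
            GrowthCurve(
                mouse_id=str(mouse),
                arm=arm,
                days=days,
                values=vols / vols[0],
                baseline_day=float(days[0]),
            )
        )
    return curves


def interpolate_missing(curve: GrowthCurve, target_day: float,
                        _return_flag: bool = False):
    """Linearly interpolate the relative volume at ``target_day``.

    Uses the nearest measured neighbours ``t0 < target_day < t1``:

    ``v_t = v_t0 + (v_t1 - v_t0) / (t1 - t0) * (t - t0)``

    A day that coincides with a measurement returns the measured value
    unchanged; a day outside the observed span raises
    :class:`~pdxsyn.exceptions.ExtrapolationError`.
    """
    days, vals = curve.days, curve.values
    if target_day < days[0] or target_day > days[-1]:
        raise ExtrapolationError(
            f"day {target_day:g} outside observed span "
            f"[{days[0]:g}, {days[-1]:g}] for mouse {curve.mouse_id}"
        )
    exact = np.nonzero(days == target_day)[0]
    if len(exact):
        v = float(vals[exact[0]])
        return (v, False) if _return_flag else v
    hi = int(np.searchsorted(days, target_day))
    lo = hi - 1
    t0, t1 = days[lo], days[hi]
    v = float(vals[lo] + (vals[hi] - vals[lo]) / (t1 - t0) * (target_day - t0))
    return (v, True) if _return_flag else v


@dataclass
class GroupTimeSummary:
    """Per-arm, per-day sample size, mean and variance of relative volume."""

    arm: str
    day: float
    n: int
    mean: float
    variance: float
    frac_interpolated: float = 0.0


@dataclass
class ExperimentData:
    """A preprocessed experiment: growth curves plus an analysis time grid.

    Parameters
    ----------
    curves : list of GrowthCurve
    time_grid : array-like, optional
        Analysis days.  Defaults to the sorted union of observed days at
        which every present arm has at least two contributing mice
        (measured or interpolable).
    """

    curves: list[GrowthCurve]
    time_grid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if not self.curves:
            raise ValidationError("experiment contains no growth curves")
        if self.time_grid is None:
            self.time_grid = self._default_grid()
        else:
            self.time_grid = np.asarray(sorted(set(np.asarray(
                self.time_grid, dtype=float))), dtype=float)
        observed = set()
        for c in self.curves:
            observed.update(c.days.tolist())
        extra = set(self.time_grid.tolist()) - observed
        if extra:
            raise ValidationError(
                f"time grid days {sorted(extra)} were never observed"
            )

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: pd.DataFrame,
                     time_grid=None) -> "ExperimentData":
        return cls(compute_relative_volumes(records), time_grid)

    @classmethod
    def from_csv(cls, source, time_grid=None, **read_kwargs) -> "ExperimentData":
        return cls.from_records(read_tumor_table(source, **read_kwargs),
                                time_grid)

    # -- basic queries ------------------------------------------------

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(a for a in ARMS
                     if any(c.arm == a for c in self.curves))

    def require_arms(self, arms: Sequence[str] = ARMS, min_n: int = 2):
        """Raise unless every requested arm has ``min_n`` mice."""
        counts = {a: sum(c.arm == a for c in self.curves) for a in arms}
        bad = [a for a, k in counts.items() if k < min_n]
        if bad:
            raise InsufficientDataError(
                f"arm(s) {', '.join(bad)} missing or with fewer than "
                f"{min_n} mice (counts: {counts})"
            )

    def _default_grid(self) -> np.ndarray:
        days = sorted({d for c in self.curves for d in c.days.tolist()})
        arms = {c.arm for c in self.curves}
        grid = []
        for d in days:
            ok = True
            for a in arms:
                k = 0
                for c in self.curves:
                    if c.arm != a:
                        continue
                    if c.days[0] <= d <= c.days[-1]:
                        k += 1
                if k < 2:
                    ok = False
                    break
            if ok:
                grid.append(d)
        return np.asarray(grid, dtype=float)

    def values_at(self, day: float, arm: str) -> tuple[np.ndarray, np.ndarray]:
        """All contributing relative volumes in ``arm`` at ``day``.

        Returns ``(values, interpolated_flags)``; mice whose span does
        not cover ``day`` are simply absent (no extrapolation).
        """
        vals, flags = [], []
        for c in self.curves:
            if c.arm != arm:
                continue
            try:
                v, interp = c.value_at(day)
            except ExtrapolationError:
                continue
            vals.append(v)
            flags.append(interp)
        return np.asarray(vals, dtype=float), np.asarray(flags, dtype=bool)

    def summarize(self, arm: str, day: float) -> GroupTimeSummary:
        """Sample size, mean and unbiased variance for one (arm, day).

        Warns when more than half of the contributing values are
        interpolated, the recommended limit for trustworthy inference.
        """
        vals, flags = self.values_at(day, arm)
        if len(vals) < 2:
            raise InsufficientDataError(
                f"fewer than 2 mice contribute to arm {arm} at day {day:g}"
            )
        frac = float(np.mean(flags))
        if frac > 0.5:
            warnings.warn(
                f"arm {arm}, day {day:g}: {frac:.0%} of values are "
                "interpolated (more than half); treat inference at this "
                "day with caution",
                InterpolationWarning,
                stacklevel=2,
            )
        return GroupTimeSummary(
            arm=arm,
            day=float(day),
            n=int(len(vals)),
            mean=float(np.mean(vals)),
            variance=float(np.var(vals, ddof=1)),
            frac_interpolated=frac,
        )

    def summaries_at(self, day: float,
                     arms: Sequence[str] = ARMS) -> dict[str, GroupTimeSummary]:
        return {a: self.summarize(a, day) for a in arms}

    def summary_table(self, days=None, arms=None) -> pd.DataFrame:
        """Tidy per-arm per-day summary table (arm, day, n, mean, ...)."""
        days = self.time_grid if days is None else np.asarray(days, dtype=float)
        arms = self.arms if arms is None else arms
        rows = []
        for d in days:
            for a in arms:
                try:
                    s = self.summarize(a, d)
                except InsufficientDataError:
                    continue
                rows.append({
                    "arm": s.arm, "day": s.day, "n": s.n, "mean": s.mean,
                    "variance": s.variance,
                    "frac_interpolated": s.frac_interpolated,
                })
        return pd.DataFrame(rows)

    def curve_matrix(self, window=None,
                     arms: Sequence[str] = ARMS,
                     ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Complete per-arm curve matrices on a common day window.

        Only mice whose observed span covers the whole window contribute
        (values measured or interpolated).  Days on which any arm would
        drop below two mice are removed from the window with a warning.

        Returns ``(matrices, window)`` where ``matrices[arm]`` has shape
        ``(n_mice, len(window))``.
        """
        if window is None:
            window = self.time_grid[self.time_grid > float(self.time_grid[0])]
        window = np.asarray(sorted(set(np.asarray(window, dtype=float))))

        kept = []
        for d in window:
            ok = True
            for a in arms:
                k = sum(1 for c in self.curves
                        if c.arm == a and c.days[0] <= d <= c.days[-1])
                if k < 2:
                    ok = False
                    break
            if ok:
                kept.append(d)
        if len(kept) < len(window):
            dropped = sorted(set(window.tolist()) - set(kept))
            warnings.warn(
                f"window days {dropped} dropped: fewer than 2 mice in some "
                "arm",
                UserWarning,
                stacklevel=2,
            )
        window = np.asarray(kept, dtype=float)
        if len(window) == 0:
            raise InsufficientDataError("empty analysis window")

        mats = {}
        for a in arms:
            rows = []
            for c in self.curves:
                if c.arm != a:
                    continue
                if c.days[0] <= window[0] and c.days[-1] >= window[-1]:
                    rows.append([c.value_at(d)[0] for d in window])
            if len(rows) < 2:
                raise InsufficientDataError(
                    f"arm {a}: fewer than 2 complete curves on the window"
                )
            mats[a] = np.asarray(rows, dtype=float)
        return mats, window

    def to_frame(self) -> pd.DataFrame:
        """Long-format relative-volume table (mouse_id, arm, day, rel_volume)."""
        rows = []
        for c in self.curves:
            for d, v, f in zip(c.days, c.values, c.interpolated):
                rows.append({"mouse_id": c.mouse_id, "arm": c.arm,
                             "day": d, "rel_volume": v, "interpolated": bool(f)})
        return pd.DataFrame(rows)


def summarize_group(data: ExperimentData, arm: str, day: float) -> GroupTimeSummary:
    """Module-level alias for :meth:`ExperimentData.summarize`."""
    return data.summarize(arm, day)
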