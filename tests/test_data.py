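import io

import numpy as np
import pandas as pd
import pytest

from pdxsyn import (ExperimentData, GrowthCurve, compute_relative_volumes,
                    interpolate_missing, read_tumor_table)
from pdxsyn.data import InterpolationWarning
from pdxsyn.exceptions import (ArmLabelError, DataFormatError,
                               DuplicateRecordError, ExtrapolationError,
                               InsufficientDataError, ValidationError)


class TestReadTumorTable:
    def test_basic_parse_maps_labels(self):
        csv = "mouse_id,arm,day,volume\nm1,Control,0,100\nm1,Control,3,150\n"
        rec = read_tumor_table(io.StringIO(csv))
        assert len(rec) == 2
        assert set(rec["arm"]) == {"C"}
        assert rec["volume"].tolist() == [100.0, 150.0]

    def test_negative_volume_identifies_row(self):
        csv = "mouse_id,arm,day,volume\nm1,C,0,100\nm1,C,3,-5\n"
        with pytest.raises(ValidationError) as err:
            read_tumor_table(io.StringIO(csv))
        assert 1 in err.value.rows

    def test_duplicate_rows_reported_with_mouse_and_day(self):
        csv = ("mouse_id,arm,day,volume\n"
               "m1,C,0,100\nm1,C,3,150\nm1,C,3,160\n")
        with pytest.raises(DuplicateRecordError, match="mouse m1, day 3"):
            read_tumor_table(io.StringIO(csv))
        rec = read_tumor_table(io.StringIO(csv), on_duplicate="mean")
        assert rec.loc[rec["day"] == 3, "volume"].item() == 155.0

    def test_missing_column_named(self):
        csv = "mouse_id,arm,day\nm1,C,0\n"
        with pytest.raises(DataFormatError, match="volume"):
            read_tumor_table(io.StringIO(csv))

    def test_unknown_arm_label(self):
        csv = "mouse_id,arm,day,volume\nm1,Placebo,0,100\n"
        with pytest.raises(ArmLabelError, match="Placebo"):
            read_tumor_table(io.StringIO(csv))

    def test_custom_column_map_and_labels(self):
        csv = "id,tx,t,v\nm1,Vehicle,0,90\nm1,Vehicle,2,110\n"
        rec = read_tumor_table(
            io.StringIO(csv),
            column_map={"mouse_id": "id", "arm": "tx", "day": "t",
                        "volume": "v"})
        assert rec["arm"].tolist() == ["C", "C"]


class TestRelativeVolumes:
    def test_direct_division(self):
        rec = pd.DataFrame({"mouse_id": ["m"] * 3, "arm": ["A"] * 3,
                            "day": [0, 3, 7], "volume": [100, 150, 300]})
        (curve,) = compute_relative_volumes(rec)
        assert curve.values.tolist() == [1.0, 1.5, 3.0]
        assert curve.baseline_day == 0

    def test_single_point_warns_and_is_kept(self):
        rec = pd.DataFrame({"mouse_id": ["m"], "arm": ["A"],
                            "day": [0], "volume": [100]})
        with pytest.warns(UserWarning, match="single measurement"):
            curves = compute_relative_volumes(rec)
        assert len(curves) == 1 and len(curves[0]) == 1

    def test_flat_growth_gives_unit_curve(self):
        rec = pd.DataFrame({"mouse_id": ["m"] * 2, "arm": ["B"] * 2,
                            "day": [0, 4], "volume": [80, 80]})
        (curve,) = compute_relative_volumes(rec)
        assert curve.values.tolist() == [1.0, 1.0]

    def test_baseline_is_earliest_day_not_day_zero(self):
        rec = pd.DataFrame({"mouse_id": ["m"] * 2, "arm": ["C"] * 2,
                            "day": [2, 5], "volume": [50, 100]})
        (curve,) = compute_relative_volumes(rec)
        assert curve.baseline_day == 2 and curve.values[0] == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        days = [0, 2, 5, 9]
        vols = rng.uniform(50, 300, size=4)
        for scale in (0.1, 1.0, 37.5):
            rec = pd.DataFrame({"mouse_id": ["m"] * 4, "arm": ["A"] * 4,
                                "day": days, "volume": vols * scale})
            (curve,) = compute_relative_volumes(rec)
            np.testing.assert_allclose(curve.values, vols / vols[0])


class TestInterpolation:
    @pytest.fixture
    def curve(self):
        return GrowthCurve("m", "A", days=[0, 4, 8], values=[1.0, 1.2, 2.0])

    @pytest.mark.parametrize("day,expected", [(6, 1.6), (5, 1.4), (4, 1.2)])
    def test_linear_formula(self, curve, day, expected):
        assert interpolate_missing(curve, day) == pytest.approx(expected)

    def test_no_extrapolation(self, curve):
        with pytest.raises(ExtrapolationError):
            interpolate_missing(curve, 9)
        with pytest.raises(ExtrapolationError):
            interpolate_missing(curve, -1)

    def test_bracketing_between_flanking_values(self):
        rng = np.random.default_rng(3)
        days = np.sort(rng.choice(np.arange(30), size=6, replace=False))
        vals = rng.uniform(0.5, 3.0, size=6)
        curve = GrowthCurve("m", "B", days=days, values=vals / vals[0])
        for t in np.linspace(days[0], days[-1], 40):
            v, interp = curve.value_at(t)
            hi = np.searchsorted(curve.days, t)
            if t in curve.days:
                assert not interp
            else:
                lo_v, hi_v = sorted((curve.values[hi - 1], curve.values[hi]))
                assert lo_v <= v <= hi_v and interp


class TestSummaries:
    def _experiment(self, arm_values, day=3.0):
        rows = []
        for arm, vals in arm_values.items():
            for i, v in enumerate(vals):
                rows += [
                    {"mouse_id": f"{arm}{i}", "arm": arm, "day": 0.0,
                     "volume": 100.0},
                    {"mouse_id": f"{arm}{i}", "arm": arm, "day": day,
                     "volume": 100.0 * v},
                ]
        return ExperimentData.from_records(pd.DataFrame(rows))

    def test_hand_arithmetic(self):
        data = self._experiment({"C": [1.0, 1.5, 2.0], "A": [1.0, 1.1, 1.2]})
        s = data.summarize("C", 3.0)
        assert (s.n, s.mean, s.variance) == (3, 1.5, 0.25)

    def test_single_mouse_errors(self):
        rows = pd.DataFrame({
            "mouse_id": ["c1", "c1", "c2", "c2", "a1", "a1"],
            "arm": ["C", "C", "C", "C", "A", "A"],
            "day": [0, 3, 0, 3, 0, 3],
            "volume": [100, 120, 100, 130, 100, 90],
        })
        data = ExperimentData(curves=compute_relative_volumes(rows),
                              time_grid=[0, 3])
        with pytest.raises(InsufficientDataError, match="arm A.*day 3"):
            data.summarize("A", 3)

    def test_majority_interpolated_warns(self):
        # 3 of 4 mice missing day 5: interpolated fraction 0.75 > 1/2
        rows = []
        for i in range(4):
            days = [0, 2, 5, 8] if i == 0 else [0, 2, 8]
            for d in days:
                rows.append({"mouse_id": f"m{i}", "arm": "C", "day": d,
                             "volume": 100.0 + d * i})
        data = ExperimentData.from_records(pd.DataFrame(rows))
        with pytest.warns(InterpolationWarning, match="interpolated"):
            s = data.summarize("C", 5)
        assert s.frac_interpolated == 0.75

    def test_matches_brute_force_when_no_missing(self, small_records,
                                                 small_experiment):
        tbl = small_experiment.summary_table()
        rel = small_records.copy()
        base = rel.groupby("mouse_id")["volume"].transform("first")
        # baseline = earliest day per mouse; small_csv is day-sorted
        rel["rv"] = rel["volume"] / base
        for _, row in tbl.iterrows():
            sub = rel[(rel["arm"] == row["arm"]) & (rel["day"] == row["day"])]
            assert row["n"] == len(sub)
            assert row["mean"] == pytest.approx(sub["rv"].mean())
            assert row["variance"] == pytest.approx(sub["rv"].var(ddof=1))

    def test_default_grid_is_subset_of_observed_days(self, small_experiment):
        observed = {d for c in small_experiment.curves for d in c.days}
        assert set(small_experiment.time_grid) <= observed


class TestCurveMatrix:
    def test_shapes_and_window(self, small_experiment):
        mats, window = small_experiment.curve_matrix()
        assert set(mats) == {"C", "A", "B", "AB"}
        for m in mats.values():
            assert m.shape == (3, len(window))
        assert window[0] > 0  # baseline excluded by default

    def test_short_curves_drop_late_days(self):
        rows = []
        for arm in ("C", "A", "B", "AB"):
            for i in range(3):
                last = 4 if (arm == "AB" and i > 0) else 8
                for d in (0, 4, 8):
                    if d <= last:
                        rows.append({"mouse_id": f"{arm}{i}", "arm": arm,
                                     "day": d, "volume": 100.0 + d})
        data = ExperimentData.from_records(pd.DataFrame(rows))
        with pytest.warns(UserWarning, match="dropped"):
            mats, window = data.curve_matrix(window=[4, 8])
        assert window.tolist() == [4.0]
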