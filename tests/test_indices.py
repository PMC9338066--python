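import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from _oracles import numeric_delta_se
from conftest import random_valid_summaries
from pdxsyn import (GroupTimeSummary, asymptotic_interval, ci_bi, ci_hsa,
                    ci_ra, combination_index, gci)
from pdxsyn.exceptions import PdxsynError


def _summaries(mc, ma, mb, mab, var=0.25, n=5):
    return {a: GroupTimeSummary(arm=a, day=21.0, n=n, mean=m, variance=var)
            for a, m in zip(("C", "A", "B", "AB"), (mc, ma, mb, mab))}


class TestPointEstimates:
    def test_hsa_picks_better_monotherapy(self, scenario_summaries):
        res = ci_hsa(scenario_summaries)
        assert res.hsa_reference_arm == "B"
        assert res.ci_hat == pytest.approx(np.log(2.0 / 1.5), abs=1e-9)

    def test_hsa_tie_broken_by_smaller_se(self):
        s = _summaries(2.8, 2.0, 2.0, 1.5)
        s["A"].variance = 0.01  # same effect, tighter arm A
        assert ci_hsa(s).hsa_reference_arm == "A"
        s["A"].variance, s["B"].variance = 0.25, 0.01
        assert ci_hsa(s).hsa_reference_arm == "B"

    def test_hsa_null_is_zero(self):
        s = _summaries(2.8, 2.4, 2.0, 2.0)  # mu_AB = min(mu_A, mu_B)
        assert ci_hsa(s).ci_hat == 0.0

    def test_hsa_ignores_control_mean(self, scenario_summaries):
        res = ci_hsa(scenario_summaries)
        shifted = _summaries(2.6, 2.4, 2.0, 1.5)  # control changed only
        res2 = ci_hsa(shifted)
        assert res2.ci_hat == res.ci_hat and res2.se == res.se

    def test_ra_value(self, scenario_summaries):
        assert ci_ra(scenario_summaries).ci_hat == pytest.approx(
            np.log(4.4 / 4.3), abs=1e-9)

    def test_ra_null_and_antagonism(self):
        assert ci_ra(_summaries(2.8, 2.4, 2.0, 1.6)).ci_hat == \
            pytest.approx(0.0, abs=1e-15)
        assert ci_ra(_summaries(2.8, 2.4, 2.0, 2.0)).ci_hat < 0

    def test_bi_value_and_se(self, scenario_summaries):
        res = ci_bi(scenario_summaries)
        assert res.ci_hat == pytest.approx(np.log(8 / 7), abs=1e-9)
        assert res.se == pytest.approx(0.2231150573, abs=1e-8)

    def test_bi_null_is_zero(self):
        s = _summaries(2.8, 2.4, 2.0, 2.4 * 2.0 / 2.8)
        assert ci_bi(s).ci_hat == pytest.approx(0.0, abs=1e-15)

    def test_bi_validity_flag_on_delta_violation(self):
        s = _summaries(2.0, 2.4, 1.5, 1.2)  # arm A worse than control
        res = ci_bi(s)
        assert not res.bliss_valid
        assert np.isfinite(res.ci_hat)  # still reported, just flagged

    def test_non_positive_mean_rejected(self, scenario_summaries):
        scenario_summaries["A"].mean = -1.0
        with pytest.raises(PdxsynError, match="non-positive"):
            ci_bi(scenario_summaries)

    def test_dispatch_by_name(self, scenario_summaries):
        assert combination_index("ra", scenario_summaries).ci_hat == \
            ci_ra(scenario_summaries).ci_hat
        with pytest.raises(ValueError):
            combination_index("loewe", scenario_summaries)


class TestAsymptoticInterval:
    def test_worked_example(self, scenario_summaries):
        res = ci_bi(scenario_summaries)
        lo, hi = asymptotic_interval(res, alpha=0.05)
        assert lo == pytest.approx(-0.3038, abs=5e-4)
        assert hi == pytest.approx(0.5708, abs=5e-4)
        assert lo < res.ci_hat < hi

    def test_zero_se_degenerates(self, scenario_summaries):
        res = ci_bi(scenario_summaries)
        res.se = 0.0
        assert asymptotic_interval(res) == (res.ci_hat, res.ci_hat)

    def test_alpha_one_collapses(self, scenario_summaries):
        res = ci_bi(scenario_summaries)
        lo, hi = asymptotic_interval(res, alpha=1.0 - 1e-12)
        assert hi - lo == pytest.approx(0.0, abs=1e-9)


class TestGci:
    def test_mean_of_per_day_values(self, scenario_summaries):
        per_day = []
        for day, mab in zip((3.0, 7.0, 10.0), (1.2, 1.5, 1.8)):
            s = _summaries(2.8, 2.4, 2.0, mab)
            for v in s.values():
                v.day = day
            per_day.append(ci_bi(s))
        res = gci(per_day)
        assert res.gci_hat == pytest.approx(
            np.mean([r.ci_hat for r in per_day]), abs=1e-15)

    def test_single_day_identity(self, scenario_summaries):
        res = gci([ci_bi(scenario_summaries)])
        assert res.gci_hat == ci_bi(scenario_summaries).ci_hat

    def test_cancellation(self):
        a = ci_bi(_summaries(2.8, 2.4, 2.0, 1.0))
        b = ci_bi(_summaries(2.8, 2.4, 2.0, 1.0))
        b.ci_hat = -a.ci_hat
        assert gci([a, b]).gci_hat == pytest.approx(0.0, abs=1e-15)

    def test_mixed_models_rejected(self, scenario_summaries):
        with pytest.raises(PdxsynError, match="mixed"):
            gci([ci_bi(scenario_summaries), ci_ra(scenario_summaries)])


class TestProperties:
    def test_hsa_dominates_bi_when_monotherapies_beat_control(self):
        rng = np.random.default_rng(11)
        for _ in range(2000):
            s = random_valid_summaries(rng, require_mono_better=True)
            assert ci_hsa(s).ci_hat >= ci_bi(s).ci_hat - 1e-12

    def test_model_ordering_when_ra_calls_synergy(self):
        # RA <= BI <= HSA whenever RA >= 0 and both monotherapy effects
        # lie in [0, 1] -- RA is the most conservative synergy caller
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 2000:
            s = random_valid_summaries(rng, require_mono_better=True)
            if ci_ra(s).ci_hat < 0:
                continue
            checked += 1
            ra, bi, hsa = (f(s).ci_hat for f in (ci_ra, ci_bi, ci_hsa))
            assert ra <= bi + 1e-12 <= hsa + 2e-12

    def test_common_rescaling_leaves_indices_unchanged(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            s = random_valid_summaries(rng)
            k = rng.uniform(0.2, 8.0)
            scaled = {
                a: GroupTimeSummary(a, v.day, v.n, v.mean * k,
                                    v.variance * k * k)
                for a, v in s.items()
            }
            for f in (ci_hsa, ci_ra, ci_bi):
                assert f(scaled).ci_hat == pytest.approx(f(s).ci_hat,
                                                         abs=1e-10)
                assert f(scaled).se == pytest.approx(f(s).se, rel=1e-10)

    @pytest.mark.parametrize("model", ["HSA", "RA", "BI"])
    def test_se_matches_numerical_delta_method(self, model):
        rng = np.random.default_rng(19)
        checked = 0
        while checked < 300:
            s = random_valid_summaries(rng)
            res = combination_index(model, s)
            if model == "HSA":
                # the max() selection is non-smooth; differentiate the
                # selected branch only, away from ties
                da = (s["C"].mean - s["A"].mean) / s["C"].mean
                db = (s["C"].mean - s["B"].mean) / s["C"].mean
                if abs(da - db) < 1e-3:
                    continue
                g = res.hsa_reference_arm
                stat = lambda m: np.log(m[0]) - np.log(m[1])
                oracle = numeric_delta_se(
                    stat, [s[g].mean, s["AB"].mean],
                    [s[g].variance, s["AB"].variance],
                    [s[g].n, s["AB"].n])
            elif model == "RA":
                stat = lambda m: np.log(m[1] + m[2]) - np.log(m[3] + m[0])
                oracle = numeric_delta_se(
                    stat,
                    [s[a].mean for a in ("C", "A", "B", "AB")],
                    [s[a].variance for a in ("C", "A", "B", "AB")],
                    [s[a].n for a in ("C", "A", "B", "AB")])
            else:
                stat = lambda m: (np.log(m[1]) + np.log(m[2])
                                  - np.log(m[0]) - np.log(m[3]))
                oracle = numeric_delta_se(
                    stat,
                    [s[a].mean for a in ("C", "A", "B", "AB")],
                    [s[a].variance for a in ("C", "A", "B", "AB")],
                    [s[a].n for a in ("C", "A", "B", "AB")])
            checked += 1
            assert res.se == pytest.approx(oracle, rel=1e-6)

    @given(mab=st.floats(0.05, 3.9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_synergy_sign_convention(self, mab):
        # deeper combination response than every null => positive index
        s = _summaries(2.8, 2.4, 2.0, mab)
        nulls = {"HSA": 2.0, "RA": 1.6, "BI": 2.4 * 2 / 2.8}
        for model, null in nulls.items():
            res = combination_index(model, s)
            if mab < null:
                assert res.ci_hat > 0
            elif mab > null:
                assert res.ci_hat < 0
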