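import io

import numpy as np
import pytest

from pdxsyn import ExperimentData, GroupTimeSummary, read_tumor_table

# the worked four-arm scenario used throughout: control mean 2.8,
# monotherapies 2.4 and 2.0, combination 1.5, common variance 0.25, n=5
SCENARIO_MEANS = {"C": 2.8, "A": 2.4, "B": 2.0, "AB": 1.5}


@pytest.fixture
def scenario_summaries():
    return {a: GroupTimeSummary(arm=a, day=21.0, n=5, mean=m, variance=0.25)
            for a, m in SCENARIO_MEANS.items()}


@pytest.fixture
def small_csv():
    """A tiny but complete four-arm experiment (3 mice/arm, 4 days)."""
    rng = np.random.default_rng(42)
    lines = ["mouse,treatment,day,vol"]
    arm_mean = {"Control": 1.0, "Drug A": 0.9, "Drug B": 0.85, "Combo": 0.75}
    prefix = {"Control": "c", "Drug A": "a", "Drug B": "b", "Combo": "ab"}
    for arm, daily in arm_mean.items():
        for i in range(3):
            v0 = rng.uniform(80, 120)
            for day in (0, 3, 7, 10):
                v = v0 * daily ** (day / 3) * rng.uniform(0.95, 1.05)
                lines.append(f"{prefix[arm]}{i},{arm},{day},{v:.3f}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def small_records(small_csv):
    return read_tumor_table(
        io.StringIO(small_csv),
        column_map={"mouse_id": "mouse", "arm": "treatment",
                    "day": "day", "volume": "vol"},
        arm_labels={"Drug A": "A", "Drug B": "B", "Combo": "AB"},
    )


@pytest.fixture
def small_experiment(small_records):
    return ExperimentData.from_records(small_records)


def random_valid_summaries(rng, day=21.0, n_lo=3, n_hi=12,
                           require_mono_better=False):
    """A random four-arm summary set with positive means and variances."""
    while True:
        means = {a: rng.uniform(0.3, 4.0) for a in ("C", "A", "B", "AB")}
        if require_mono_better:
            means["A"] = rng.uniform(0.3, means["C"])
            means["B"] = rng.uniform(0.3, means["C"])
        out = {}
        for a, m in means.items():
            out[a] = GroupTimeSummary(
                arm=a, day=day, n=int(rng.integers(n_lo, n_hi)),
                mean=m, variance=rng.uniform(0.01, 0.6),
            )
        return out
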