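import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def quantile_oracle(values, q):
    """Independent linear-interpolation quantile: explicit order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    frac = h - lo
    if frac == 0 or lo + 1 >= len(v):
        return float(v[lo])
    return float(v[lo] + frac * (v[lo + 1] - v[lo]))


def make_measurement_cohort(n, rng, genders=("man", "woman")):
    """Minimal cohort frame for threshold work: one value per measurement.

    Grip trials and walk times are set equal within a person so the summaries
    equal the underlying value, making oracle comparisons exact.
    """
    # values stay unrounded: continuous draws make ties with interpolated
    # cut-offs measure-zero, so oracle comparisons are exact
    gender = rng.choice(list(genders), size=n)
    height = rng.normal(158, 8, n)
    weight = np.clip(rng.normal(60, 10, n), 35, 100)
    grip = rng.uniform(5, 45, n)
    walk = rng.uniform(2, 12, n)
    pase = rng.uniform(5, 250, n)
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "gender": gender,
        "age": rng.uniform(60, 90, n).round(1),
        "height": height,
        "weight_current": weight,
        "weight_at25": weight * 1.05,
        "grip_left_1": grip, "grip_left_2": grip,
        "grip_right_1": grip, "grip_right_2": grip,
        "walk_time_1": walk, "walk_time_2": walk,
        "pase_score": pase,
        "gds_energy": rng.choice(["yes", "no"], size=n),
    })
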