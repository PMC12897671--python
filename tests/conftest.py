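import pandas as pd
import pytest

import mirprobe as mp


@pytest.fixture
def small_cohort():
    """Deterministic 15-sample cohort with one strong planted effect."""
    cfg = mp.SimulationConfig(
        n_features=30,
        group_sizes={"HC": 5, "LC": 5, "LC_BM": 5},
        planted_effects=(mp.EffectSpec("miR-sim-001", "LC_BM", 6.0),),
        seed=7,
    )
    matrix, truth = mp.generate_cp_matrix(cfg)
    return cfg, matrix, truth


@pytest.fixture
def noiseless_cohort():
    """Zero-noise, zero-shift cohort: every Cp equals its feature baseline."""
    cfg = mp.SimulationConfig(
        n_features=10,
        group_sizes={"HC": 3, "LC_BM": 3},
        noise_sd=0.0,
        sample_shift_sd=0.0,
        seed=1,
    )
    matrix, truth = mp.generate_cp_matrix(cfg)
    return cfg, matrix, truth


def manual_cp_matrix(values: dict, groups: dict) -> mp.CpMatrix:
    """Build a CpMatrix from plain dicts: values[assay][sample] = Cp."""
    frame = pd.DataFrame(values).T
    return mp.CpMatrix(values=frame, groups=pd.Series(groups))


@pytest.fixture
def qc_fixture_matrix():
    """All controls clean: spike-ins at 30, hemolysis delta 3."""
    samples = ["s1", "s2", "s3"]
    values = {
        "UniSp2": {s: 30.0 for s in samples},
        "UniSp4": {s: 30.0 for s in samples},
        "UniSp6": {s: 30.0 for s in samples},
        "miR-23a": {s: 24.0 for s in samples},
        "miR-451": {s: 21.0 for s in samples},
        "miR-x": {s: 25.0 for s in samples},
    }
    groups = {"s1": "HC", "s2": "LC", "s3": "LC_BM"}
    return manual_cp_matrix(values, groups)
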