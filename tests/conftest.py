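import numpy as np
import pandas as pd
import pytest

from scarray.array_io import ExperimentSet, _normalize_annotation, _normalize_meta
from scarray.synthetic_data import SimConfig, simulate_experiment


@pytest.fixture
def tiny_experiment() -> ExperimentSet:
    """3 probes x 2 samples, hand-written values."""
    annotation = _normalize_annotation(pd.DataFrame({
        "probe_id": ["p1", "p2", "p3"],
        "gene_symbol": ["GA", "GB", ""],
        "is_control": [False, False, True],
    }))
    samples = _normalize_meta(pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "group": ["1", "1"],
        "day": ["d1", "d2"],
        "replicate": [1, 2],
    }))
    af3 = pd.DataFrame([[100.0, 120.0], [500.0, 480.0], [60.0, 70.0]],
                       index=["p1", "p2", "p3"], columns=["s1", "s2"])
    af5 = pd.DataFrame([[200.0, 210.0], [400.0, 410.0], [55.0, 65.0]],
                       index=["p1", "p2", "p3"], columns=["s1", "s2"])
    return ExperimentSet(annotation, samples, af3, af5)


NOISE_FREE = dict(noise_logsd=0.0, nonspecific_floor_mean=0.0,
                  nonspecific_floor_sd=0.0, day_shift_af3=0.0,
                  day_shift_af5=0.0, capture_prob=1.0,
                  ref_divergence_logsd=0.0)


@pytest.fixture
def noise_free_config() -> SimConfig:
    # high abundance so Poisson zeros are (astronomically) improbable
    return SimConfig(n_probes=400, groups=((1, 5), (5, 5), (10, 5)),
                     abundance_logmean=5.0, abundance_logsd=0.5,
                     seed=7, **NOISE_FREE)


@pytest.fixture
def small_sim() -> ExperimentSet:
    return simulate_experiment(
        SimConfig(n_probes=500, groups=((1, 6), (5, 6), (10, 6)), seed=11))
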