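import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirdegrade.model import ExpressionMatrix, SampleMeta
from mirdegrade.preprocess import detection_filter, glog_normalize
from mirdegrade.simulate import SimConfig, SimulatedStudy, simulate_study

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


def make_matrix(values, mirna_ids=None, sample_ids=None, detected=None, state="raw"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    mirna_ids = mirna_ids or [f"miR-{i + 1}" for i in range(n)]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(p)]
    vdf = pd.DataFrame(values, index=mirna_ids, columns=sample_ids)
    if detected is None:
        ddf = pd.DataFrame(True, index=mirna_ids, columns=sample_ids)
    else:
        ddf = pd.DataFrame(np.asarray(detected, dtype=bool), index=mirna_ids,
                           columns=sample_ids)
    return ExpressionMatrix(vdf, ddf, state)


def timecourse_meta_row(sample_id="L1", tissue="liver", temperature="RT",
                        time_h=0, rin=9.5, replicate=1):
    return SampleMeta(sample_id=sample_id, tissue=tissue, temperature=temperature,
                      time_h=time_h, rin=rin, replicate=replicate)


@pytest.fixture(scope="session")
def default_study() -> SimulatedStudy:
    """The default simulated study (900 miRNAs, 48 + 24 arrays), seed 1."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def normalized_timecourse(default_study):
    return glog_normalize(detection_filter(default_study.timecourse, 5))


@pytest.fixture(scope="session")
def normalized_control(default_study):
    return glog_normalize(detection_filter(default_study.control, 5))


@pytest.fixture(scope="session")
def noise_free_study() -> SimulatedStudy:
    """Small noise-free study for exact cell-by-cell checks."""
    sim = SimConfig(
        n_resilient=8, n_sensitive=6, n_artifact=6, n_dna_background=4,
        noise_sd_log2=0.0, rin_noise_sd=0.0, seed=7,
    )
    return simulate_study(sim)
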