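"""Shared fixtures: small synthetic datasets with ground truth.

Module-scoped where generation is expensive, so the suite stays fast.
"""

import numpy as np
import pytest

import trpscope as t
from trpscope.synthgen import soma_label_image


@pytest.fixture(scope="session")
def protocol():
    return t.default_protocol()


@pytest.fixture(scope="session")
def short_protocol():
    return t.default_protocol(pre=12, stim_len=6, wash=12, labels=("M3", "K"))


@pytest.fixture(scope="session")
def soma_dataset(protocol):
    """Small DRG movie: 8 cells, known expression, WGA channel, truth masks."""
    truth = t.make_soma_truth((128, 128), n_cells=8, seed=1)
    shape = (protocol.last_end + 10, 128, 128)
    movie, wga, truth = t.gen_soma_movie(truth, protocol, shape, seed=2)
    return {
        "movie": movie,
        "wga": wga,
        "truth": truth,
        "labels": soma_label_image(truth, (128, 128)),
        "protocol": protocol,
    }


@pytest.fixture(scope="session")
def skin_dataset(protocol):
    """Skin-nerve movie: 5 disjoint branches with known expression."""
    truth = t.make_skin_truth((128, 128), n_branches=5, seed=3)
    shape = (protocol.last_end + 10, 128, 128)
    movie, truth = t.gen_skin_movie(truth, protocol, shape, seed=4)
    return {"movie": movie, "truth": truth, "protocol": protocol}


@pytest.fixture(scope="session")
def rnascope_dataset():
    """Synthetic slide: 100 cells, Poisson(8) dots, 20% clustered, SNR 10."""
    truth = t.make_rnascope_truth(seed=5)
    channels, truth = t.gen_rnascope_image(truth, (700, 700), 0.325, seed=6)
    return {"channels": channels, "truth": truth, "pixel_size_um": 0.325}


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0
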