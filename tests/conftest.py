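import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ubnexus.config import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def small_sim():
    """A reduced-size benchmark config for fast end-to-end tests."""
    cfg = SimConfig(seed=7, n_proteins=60, n_lost_ub=8, n_interactors=6,
                    n_context_genes=5, n_full_evidence=2)
    cfg.ip.n_detected = 40
    cfg.lfq.n_proteins = 200
    cfg.splice.n_events = 80
    cfg.splice.n_planted = 8
    cfg.image_control.n_images = 2
    cfg.image_fbxo11_low.n_images = 2
    return cfg
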