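"""Shared fixtures: small synthetic communities and a demo pipeline run."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pbinkit.pbin import BipartiteNetwork, ModulePartition, barber_modularity
from pbinkit.synthetic_data import SynthConfig, Synthesizer


@pytest.fixture(scope="session")
def small_artifacts():
    """Noise-free 3-module community at demo scale, seed 11."""
    return Synthesizer(SynthConfig(seed=11)).run()


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full pipeline run on the noise-free demo configuration."""
    from pbinkit.pipeline import run_all

    cfg = {
        "seed": 11,
        "n_null": 200,
        "mantel_permutations": 300,
        "min_bees": 10,
        "synthetic": {"n_samples": 20},
    }
    return run_all(cfg, tmp_path_factory.mktemp("demo_run"))
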