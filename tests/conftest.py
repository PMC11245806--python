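"""Shared fixtures: small synthetic communities generated at test time."""
from __future__ import annotations

import numpy as np
import pytest

from seedrecon.simulate import SimParams, build_community


@pytest.fixture(scope="session")
def small_community():
    """A 6-genome community with well-separated 16S genes (zero-error friendly)."""
    params = SimParams(
        n_genomes=6,
        n_samples_low=1,
        n_samples_high=1,
        n_shotgun_pairs=1000,
        n_amplicon_reads=400,
        substitution_error_rate=0.0,
        genome_divergence=(0.10, 0.35),
        rng_seed=11,
    )
    return build_community(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
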