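"""Shared fixtures: small deterministic synthetic structures."""

import numpy as np
import pytest

from ensa.synthetic import (GeneratorSpec, HELIX_TEMPLATE, build_backbone,
                            build_hairpin, generate_two_state_ensemble)


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue poly-alanine α-helix (topology, frame)."""
    return build_backbone([HELIX_TEMPLATE] * 20, "A" * 20)


@pytest.fixture(scope="session")
def hairpin():
    """Ideal antiparallel β-hairpin fixture (topology, frame)."""
    return build_hairpin()


@pytest.fixture(scope="session")
def two_state_small():
    """Small planted two-state ensemble: (ensemble, labels, spec)."""
    spec = GeneratorSpec(seed=11)
    ensemble, labels = generate_two_state_ensemble(spec, n_frames=60)
    return ensemble, labels, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
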