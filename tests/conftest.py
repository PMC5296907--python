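import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nomefoot import MoleculeStates, ReferenceLocus

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dense_molecule(length, protected=(), missing=(), molecule_id="m0",
                        locus_id="dense"):
    """A synthetic molecule with an informative site at every base.

    ``protected`` and ``missing`` are iterables of half-open intervals.
    """
    states = np.ones(length, dtype=np.int8)
    for a, b in protected:
        states[a:b] = 0
    for a, b in missing:
        states[a:b] = -1
    return MoleculeStates(molecule_id, locus_id, np.arange(length), states)


@pytest.fixture
def dense_ref():
    """600 bp reference for span tests; TSS at 300, TTS at 400."""
    return ReferenceLocus("dense", "A" * 600, 300, 400)


@pytest.fixture
def dense_molecule_factory():
    return make_dense_molecule
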