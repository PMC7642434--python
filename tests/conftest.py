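import numpy as np
import pytest

from teasig.tables_io import GenotypeMatrix, GroupAssignment


def build_gm(calls, positions=None, scaffold="scf1", sample_ids=None):
    """GenotypeMatrix from a (samples x sites) list/array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        scaffolds=np.full(n_sites, scaffold, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        calls=calls,
    )


@pytest.fixture
def two_group_assignment():
    def _make(n_a, n_b, labels=("pop_a", "pop_b")):
        mapping = {f"s{i}": labels[0] if i < n_a else labels[1] for i in range(n_a + n_b)}
        return GroupAssignment(mapping, list(labels))

    return _make


def random_gm(rng, n_samples, n_sites, missing_rate=0.1):
    """Random small genotype matrix including missing calls."""
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    return build_gm(calls)
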