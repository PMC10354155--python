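import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import absearch as ab
from absearch.canonical import PositionKey

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return ab.default_scheme()


@pytest.fixture(scope="session")
def regions(scheme):
    return ab.default_regions(scheme)


@pytest.fixture(scope="session")
def small_repertoire(scheme):
    """300 heavy sequences + metadata, fixed seed."""
    spec = ab.RepertoireSpec(n_sequences=300, seed=20240101)
    return ab.generate_repertoire(spec, scheme)


@pytest.fixture()
def built_db(tmp_path, scheme, small_repertoire):
    """A persisted database of the small repertoire, shard_size 64."""
    seqs, meta = small_repertoire
    ab.build_database(seqs, meta, scheme, tmp_path / "db", shard_size=64)
    return ab.load_database(tmp_path / "db" / "manifest.tsv")


def random_vectors(rng, scheme, n, occupancy=0.85):
    """Random aligned vectors with contiguous occupied spans (helper, not a fixture)."""
    L = len(scheme)
    n_codes = len(scheme.alphabet)
    vecs = rng.integers(1, n_codes + 1, size=(n, L)).astype(np.uint8)
    mask = rng.random((n, L)) < occupancy
    vecs[~mask] = 0
    return vecs


NUMBERING_TSV = """# sequence_id\tchain_type\tspecies\timgt_position\tinsertion_code\tresidue
seq1\tH\thuman\t1\t\tE
seq1\tH\thuman\t2\t\tV
seq1\tH\thuman\t3\t\tQ
seq2\tK\tmouse\t1\t\tD
seq2\tK\tmouse\t111\tA\tG
seq2\tK\tmouse\t112\t\tY
"""


@pytest.fixture()
def numbering_tsv():
    return NUMBERING_TSV
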