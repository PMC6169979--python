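import numpy as np
import pytest

from dhewscan.alignment_io import Alignment, seq_to_array


def make_alignment(seqs, gene_id="toy", ids=None, outgroups=None):
    """Alignment from sequence strings; outgroups = {name: seq string}."""
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    matrix = np.vstack([seq_to_array(s) for s in seqs])
    og = {k: seq_to_array(v) for k, v in (outgroups or {}).items()}
    return Alignment(gene_id, ids, matrix, og)


@pytest.fixture
def toy_alignment():
    # 4 samples x 12 columns; segregating at columns 2 (A/G), 5 (C/T), 8 (A/T)
    return make_alignment(
        [
            "ACATGCCGATGC",
            "ACATGCCGATGC",
            "ACGTGTCGATGC",
            "ACGTGTCGTTGC",
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
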