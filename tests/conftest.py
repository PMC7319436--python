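import numpy as np
import pytest

from motiflens import (
    Background,
    Genome,
    GenomicInterval,
    Motif,
    counts_to_frequencies,
    information_content,
    dynamic_threshold,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_bg():
    return Background()


def make_motif(counts, motif_id="M1", name="TEST", pseudocount=1.0):
    counts = np.asarray(counts, dtype=float)
    freqs = counts_to_frequencies(counts, pseudocount)
    ic = information_content(freqs)
    return Motif(
        id=motif_id,
        name=name,
        counts=counts,
        frequencies=freqs,
        pseudocount=pseudocount,
        threshold_p=dynamic_threshold(ic),
    )


@pytest.fixture
def simple_motif():
    # strongly biased 6-mer, consensus ACGTAC
    counts = np.zeros((6, 4))
    for i, b in enumerate("ACGTAC"):
        counts[i, "ACGT".index(b)] = 18.0
        counts[i] += 1.0  # slight degeneracy
    return make_motif(counts)


@pytest.fixture
def tiny_genome():
    return Genome(sequences={"chr1": "ACGTACGTAA", "chr2": "TTTTACGTAC"})


@pytest.fixture
def intervals_factory():
    def build(triples):
        return [GenomicInterval(c, s, e) for c, s, e in triples]

    return build
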