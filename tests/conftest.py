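import numpy as np
import pytest
from hypothesis import settings

from cpxscreen.motif import (
    BackgroundModel,
    BindingSiteCollection,
    build_matrix_from_sites,
    score_window,
)
from cpxscreen.scan import GenomeSequence

settings.register_profile("repeatable", derandomize=True, max_examples=50)
settings.load_profile("repeatable")

BASES = "ACGT"


@pytest.fixture
def toy_sites():
    """Four aligned 15-bp sites around the bipartite consensus."""
    return BindingSiteCollection.from_sequences([
        "GTAAACTGACGTAAA",
        "GTAAAGGCTAGTAAA",
        "GTTAACTGACGTAAC",
        "GAAAACTTTCGTAAA",
    ])


@pytest.fixture
def toy_matrix(toy_sites):
    return build_matrix_from_sites(toy_sites, pseudocount=0.5)


@pytest.fixture
def random_genome():
    def make(length: int, seed: int, alphabet: str = BASES) -> GenomeSequence:
        rng = np.random.default_rng(seed)
        seq = "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))
        return GenomeSequence(f"rand{seed}", seq)

    return make


@pytest.fixture
def brute_force_scan():
    """Independent scanner oracle: extract every substring, call score_window.

    Mirrors the published scoring semantics directly on strings: minus-strand
    windows are reverse-complemented before scoring and reported at the
    forward coordinate of the window.
    """
    from cpxscreen.motif import reverse_complement

    def oracle(matrix, genome: GenomeSequence, strands=("+", "-")):
        k = matrix.length
        records = []
        seq = genome.sequence
        for start in range(len(seq) - k + 1):
            window = seq[start:start + k]
            if set(window) - set(BASES):
                continue
            for strand in strands:
                w = window if strand == "+" else reverse_complement(window)
                records.append((start, strand, score_window(matrix, w)))
        return records

    return oracle
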