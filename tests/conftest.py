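import random

import pytest

from msapolish import (
    AlignedSequence,
    Alignment,
    nucleotide_scheme,
    protein_scheme,
    table1_scheme,
)
from msapolish.alignment import AMINO_ACIDS, GAP
from msapolish.pairs import implied_pair_score


@pytest.fixture(scope="session")
def linear_scheme():
    """BLOSUM62 with flat -6 gaps (the two-site worked example's scheme)."""
    return table1_scheme()


@pytest.fixture(scope="session")
def affine_scheme():
    """BLOSUM62 with affine GO=20 / GE=2."""
    return protein_scheme()


@pytest.fixture(scope="session")
def nuc_scheme():
    return nucleotide_scheme()


def random_alignment(rng: random.Random, n_seqs=4, n_cols=10,
                     gap_rate=0.2) -> Alignment:
    """Small random protein alignment; every column keeps >=1 residue."""
    while True:
        rows = []
        for i in range(n_seqs):
            rows.append("".join(
                GAP if rng.random() < gap_rate else rng.choice(AMINO_ACIDS)
                for _ in range(n_cols)
            ))
        if all(any(r[c] != GAP for r in rows) for c in range(n_cols)):
            return Alignment(
                tuple(AlignedSequence(f"s{i}", r) for i, r in enumerate(rows))
            )


def brute_force_optimal(a: str, b: str, scheme) -> float:
    """Independent oracle: enumerate every monotone global alignment of two
    ungapped sequences and score each with the implied-pair scorer; return
    the maximum.  Exponential, so only for tiny inputs."""
    best = [float("-inf")]

    def rec(i, j, top, bottom):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], implied_pair_score(top, bottom, scheme))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, top + a[i], bottom + b[j])
        if i < len(a):
            rec(i + 1, j, top + a[i], bottom + GAP)
        if j < len(b):
            rec(i, j + 1, top + GAP, bottom + b[j])

    rec(0, 0, "", "")
    return best[0]
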