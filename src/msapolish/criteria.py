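"""Whole-alignment criteria: SPS, weighted SPS, and the inconsistency index PAI.

SPS sums the MSA-implied pairwise scores over all pairs (shared gaps free);
WSPS weights each pair; PAI measures how far the implied pairwise alignments
fall short of their dynamic-programming optima (0 means every pair is already
optimal; larger means worse).  ``criterion_delta`` packages "after minus
before" with signs arranged so that positive always means the second
alignment is better.
"""

from __future__ import annotations

from .alignment import Alignment
from .pairs import all_pair_scores, implied_pair_score
from .scoring import ScoringScheme

CRITERIA = ("SPS", "WSPS", "PAI")


def sps(aln: Alignment, scheme: ScoringScheme) -> float:
    """Sum-of-pairs score: Σ over pairs of the MSA-implied pair score."""
    total = 0.0
    for i in range(aln.n_sequences):
        for j in range(i + 1, aln.n_sequences):
            total += implied_pair_score(aln[i], aln[j], scheme)
    return total


def wsps(aln: Alignment, scheme: ScoringScheme) -> float:
    """Weighted sum-of-pairs: Σ W_ij · S_ij.MSA (equals SPS when all W_ij = 1)."""
    total = 0.0
    for i in range(aln.n_sequences):
        for j in range(i + 1, aln.n_sequences):
            total += scheme.weight(i, j) * implied_pair_score(aln[i], aln[j], scheme)
    return total


def pai(aln: Alignment, scheme: ScoringScheme) -> float:
    """Pairwise alignment inconsistency: Σ S_ij − Σ S_ij.MSA (always ≥ 0)."""
    return sum(p.deficit for p in all_pair_scores(aln, scheme))


def _check_same_content(before: Alignment, after: Alignment) -> None:
    if before.ids() != after.ids():
        raise ValueError("alignments carry different sequence ids")
    for x, y in zip(before.members, after.members):
        if x.degapped() != y.degapped():
            raise ValueError(
                f"sequence {x.id!r} differs between alignments after gap removal"
            )


def criterion_delta(aln_before: Alignment, aln_after: Alignment,
                    criterion: str, scheme: ScoringScheme) -> float:
    """Signed improvement of ``aln_after`` over ``aln_before``.

    Positive always means the second alignment is better: after − before for
    SPS/WSPS, before − after for PAI.  Both alignments must hold the same
    sequences (identical ids and degapped content).
    """
    _check_same_content(aln_before, aln_after)
    criterion = criterion.upper()
    if criterion == "SPS":
        return sps(aln_after, scheme) - sps(aln_before, scheme)
    if criterion == "WSPS":
        return wsps(aln_after, scheme) - wsps(aln_before, scheme)
    if criterion == "PAI":
        return pai(aln_before, scheme) - pai(aln_after, scheme)
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
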