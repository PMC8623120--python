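"""Pairwise scores: MSA-implied (S_ij.MSA) and optimal (S_ij).

Each alignment of N sequences implies N(N−1)/2 pairwise alignments; their
implied scores, summed, are the sum-of-pairs score.  The optimal score of a
pair is what global dynamic programming over the two degapped sequences would
achieve under the same scheme, so optimal >= implied always holds — the total
shortfall is the pairwise alignment inconsistency index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Align import PairwiseAligner, substitution_matrices

from .alignment import GAP, AlignedSequence, Alignment
from .scoring import ScoringScheme


@dataclass(frozen=True)
class PairScore:
    """Implied vs optimal score for one sequence pair (0-based indices, i < j)."""

    i: int
    j: int
    implied_score: float
    optimal_score: float

    @property
    def deficit(self) -> float:
        """Non-negative inconsistency contribution of this pair."""
        return self.optimal_score - self.implied_score


def implied_pair_score(row_a: AlignedSequence | str,
                       row_b: AlignedSequence | str,
                       scheme: ScoringScheme) -> float:
    """Score the pairwise alignment implied by two MSA rows.

    Columns gapped in both rows are skipped entirely: they contribute nothing
    and, in affine mode, do not open, break or extend a gap run of either row
    (a run interrupted only by shared gaps counts as one run).  Terminal gap
    runs are charged or not according to ``scheme.terminal_gaps``.
    """
    a = row_a.residues if isinstance(row_a, AlignedSequence) else row_a
    b = row_b.residues if isinstance(row_b, AlignedSequence) else row_b
    if len(a) != len(b):
        raise ValueError(f"row lengths differ: {len(a)} vs {len(b)}")

    # drop shared-gap columns for this pair
    cols = [(x, y) for x, y in zip(a, b) if not (x == GAP and y == GAP)]
    score = 0.0
    for x, y in cols:
        if x != GAP and y != GAP:
            score += scheme.score(x, y)
    free_ends = scheme.terminal_gaps == "free"
    n = len(cols)
    for row in (0, 1):
        i = 0
        while i < n:
            if cols[i][row] == GAP:
                j = i
                while j < n and cols[j][row] == GAP:
                    j += 1
                terminal = i == 0 or j == n
                if not (free_ends and terminal):
                    score -= scheme.gap_run_cost(j - i)
                i = j
            else:
                i += 1
    return score


def _aligner_for(scheme: ScoringScheme) -> PairwiseAligner:
    cached = getattr(scheme, "_aligner", None)
    if cached is not None:
        return cached
    symbols = sorted({a for a, _ in scheme.matrix})
    arr = substitution_matrices.Array(alphabet="".join(symbols), dims=2)
    for a in symbols:
        for b in symbols:
            arr[a, b] = scheme.matrix[(a, b)]
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = arr
    if scheme.gap_model == "linear":
        open_, extend = -scheme.gap_site_penalty, -scheme.gap_site_penalty
    else:
        open_, extend = -scheme.gap_open, -scheme.gap_extend
    aligner.open_gap_score = open_
    aligner.extend_gap_score = extend
    if scheme.terminal_gaps == "free":
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    object.__setattr__(scheme, "_aligner", aligner)  # memoised on the scheme
    return aligner


def optimal_pair_score(seq_a: str, seq_b: str, scheme: ScoringScheme,
                       traceback: bool = False):
    """Optimal global pairwise alignment score of two ungapped sequences.

    Uses classic global dynamic programming for the linear gap model and
    three-state (Gotoh) dynamic programming for the affine model, with one
    maximal gap run of length k costing open + (k−1)·extend.  With
    ``traceback=True`` also returns one optimal aligned pair of rows.
    """
    if GAP in seq_a or GAP in seq_b:
        raise ValueError("optimal_pair_score expects ungapped sequences")
    if not seq_a or not seq_b:
        other = seq_b or seq_a
        cost = 0.0 if scheme.terminal_gaps == "free" else scheme.gap_run_cost(len(other))
        return (-cost, (GAP * len(seq_b) or seq_a, GAP * len(seq_a) or seq_b)) \
            if traceback else -cost
    aligner = _aligner_for(scheme)
    if not traceback:
        return float(aligner.score(seq_a, seq_b))
    best = next(iter(aligner.align(seq_a, seq_b)))
    return float(best.score), (best[0], best[1])


def all_pair_scores(aln: Alignment, scheme: ScoringScheme) -> list[PairScore]:
    """Implied and optimal scores for all N(N−1)/2 sequence pairs."""
    scores = []
    degapped = [m.degapped() for m in aln.members]
    for i in range(aln.n_sequences):
        for j in range(i + 1, aln.n_sequences):
            scores.append(
                PairScore(
                    i,
                    j,
                    implied_pair_score(aln[i], aln[j], scheme),
                    optimal_pair_score(degapped[i], degapped[j], scheme),
                )
            )
    return scores


def pair_table(scores: Iterable[PairScore]) -> str:
    """Tab-separated per-pair report: i, j, implied, optimal, deficit (1-based)."""
    lines = ["i\tj\timplied\toptimal\tdeficit"]
    for s in scores:
        lines.append(
            f"{s.i + 1}\t{s.j + 1}\t{s.implied_score:g}\t{s.optimal_score:g}"
            f"\t{s.deficit:g}"
        )
    return "\n".join(lines) + "\n"
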