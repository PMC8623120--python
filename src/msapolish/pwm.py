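"""Position weight matrices: construction, sequence scoring (PWMS), and the
move differential (PWMD).

A PWM built from an alignment of N sequences holds, for every alphabet symbol
a and column j with n_aj occurrences among the N_j non-gap observations,

    w_aj = log2( ((n_aj + c_a) / (N_j + Σ_b c_b)) / p_a )

where p_a is the background frequency of a and c_a its pseudocount.  By
default pseudocounts are background-proportional, c_a = p_a·m with total mass
m = 1, and the background is uniform over the alphabet; an empirical
background (frequencies pooled over the whole alignment, gaps excluded) is
available.  Gaps and the unknown residue X are excluded from counts and carry
no PWM row, so a sequence's score PWMS — the sum of its residues' weights at
their columns — is unchanged by shared-gap columns.

The PWM differential of a candidate rearrangement is

    PWMD = Σ_seq PWMS_after − Σ_seq PWMS_before

evaluated, by default, under the PWM of the *before* alignment ("before"
policy); alternatives score both states under the after-PWM ("after") or each
state under its own PWM ("refreshed").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, GAP, NUCLEOTIDES, AlignedSequence, Alignment


def _alphabet_symbols(alphabet: str) -> str:
    return AMINO_ACIDS if alphabet == "aa" else NUCLEOTIDES


class PWMError(ValueError):
    pass


def column_counts(aln: Alignment) -> pd.DataFrame:
    """Per-column symbol counts as a symbols × columns frame (1-based columns).

    Gaps and X are excluded, so each column sums to N minus its gap and X
    count.
    """
    symbols = _alphabet_symbols(aln.alphabet)
    counts = np.zeros((len(symbols), aln.n_columns), dtype=int)
    index = {s: k for k, s in enumerate(symbols)}
    for m in aln.members:
        for j, sym in enumerate(m.residues):
            k = index.get(sym)
            if k is not None:
                counts[k, j] += 1
    return pd.DataFrame(counts, index=list(symbols),
                        columns=range(1, aln.n_columns + 1))


def _background(aln: Alignment, background) -> dict[str, float]:
    symbols = _alphabet_symbols(aln.alphabet)
    if background == "uniform" or background is None:
        return {s: 1.0 / len(symbols) for s in symbols}
    if background == "empirical":
        counts = column_counts(aln).sum(axis=1)
        total = counts.sum()
        if total == 0:
            raise PWMError("empirical background undefined: alignment is all gaps")
        # residues never observed still need p_a > 0; blend in one pseudo-observation
        return {s: (counts[s] + 1.0 / len(symbols)) / (total + 1.0) for s in symbols}
    freqs = dict(background)
    if abs(sum(freqs.values()) - 1.0) > 1e-9 or set(freqs) != set(symbols):
        raise PWMError("background must cover the alphabet and sum to 1")
    return freqs


@dataclass(frozen=True)
class PWM:
    """Log₂-odds weight matrix with its pseudocount/background provenance."""

    weights: pd.DataFrame          # symbols × 1-based columns
    background: Mapping[str, float]
    pseudocount_mass: float

    @property
    def source_columns(self) -> int:
        return self.weights.shape[1]

    @property
    def symbols(self) -> list[str]:
        return list(self.weights.index)

    def weight(self, symbol: str, site: int) -> float:
        """w at 1-based column ``site`` for ``symbol``."""
        return float(self.weights.at[symbol, site])

    def to_tsv(self) -> str:
        """Symbols as rows, 1-based site columns (the tabular layout used in
        alignment-refinement reports)."""
        return self.weights.to_csv(sep="\t", float_format="%.4f")


def build_pwm(counts: pd.DataFrame, pseudocount_mass: float = 1.0,
              background: Optional[Mapping[str, float]] = None) -> PWM:
    """Build a PWM from a symbols × columns count frame.

    Pseudocounts are background-proportional: c_a = p_a · pseudocount_mass.
    ``background`` defaults to uniform over the count frame's symbols.
    """
    if pseudocount_mass <= 0:
        raise PWMError("pseudocount mass must be > 0 (log diverges otherwise)")
    symbols = list(counts.index)
    if background is None:
        background = {s: 1.0 / len(symbols) for s in symbols}
    p = np.array([background[s] for s in symbols], dtype=float)
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
        raise PWMError("background frequencies must be positive and sum to 1")
    n = counts.to_numpy(dtype=float)
    c = p[:, None] * pseudocount_mass
    n_j = n.sum(axis=0, keepdims=True)
    w = np.log2(((n + c) / (n_j + pseudocount_mass)) / p[:, None])
    frame = pd.DataFrame(w, index=symbols, columns=counts.columns)
    return PWM(frame, dict(background), pseudocount_mass)


def pwm_from_alignment(aln: Alignment, pseudocount_mass: float = 1.0,
                       background="uniform") -> PWM:
    """Counts + build in one step; ``background`` is ``"uniform"``,
    ``"empirical"`` or an explicit frequency map."""
    return build_pwm(column_counts(aln), pseudocount_mass,
                     _background(aln, background))


def pwms(row: AlignedSequence | str, pwm: PWM) -> float:
    """PWM score of one aligned row: Σ w(residue, column) over non-gap,
    non-X sites."""
    residues = row.residues if isinstance(row, AlignedSequence) else row
    if len(residues) != pwm.source_columns:
        raise PWMError(
            f"row length {len(residues)} != PWM columns {pwm.source_columns}"
        )
    w = pwm.weights
    sym_index = {s: k for k, s in enumerate(w.index)}
    arr = w.to_numpy()
    total = 0.0
    for j, sym in enumerate(residues):
        k = sym_index.get(sym)
        if k is not None:
            total += arr[k, j]
    return total


def total_pwms(aln: Alignment, pwm: PWM) -> float:
    """Σ over sequences of PWMS."""
    return sum(pwms(m, pwm) for m in aln.members)


def pwmd(aln_before: Alignment, aln_after: Alignment,
         pwm_policy: str = "before", pseudocount_mass: float = 1.0,
         background="uniform") -> float:
    """PWM differential between two gap-placements of the same sequences.

    Positive favours ``aln_after``.  Policies: ``"before"`` (default) scores
    both alignments under the PWM of ``aln_before``; ``"after"`` under the PWM
    of ``aln_after``; ``"refreshed"`` scores each under its own PWM.
    """
    if aln_before.n_columns != aln_after.n_columns:
        raise PWMError("alignments must have the same column count")
    if aln_before.ids() != aln_after.ids():
        raise PWMError("alignments must hold the same sequences")
    make = lambda a: pwm_from_alignment(a, pseudocount_mass, background)
    if pwm_policy == "before":
        m = make(aln_before)
        return total_pwms(aln_after, m) - total_pwms(aln_before, m)
    if pwm_policy == "after":
        m = make(aln_after)
        return total_pwms(aln_after, m) - total_pwms(aln_before, m)
    if pwm_policy == "refreshed":
        return total_pwms(aln_after, make(aln_after)) - total_pwms(
            aln_before, make(aln_before)
        )
    raise PWMError(f"unknown pwm_policy {pwm_policy!r}")
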