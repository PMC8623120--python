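"""Substitution matrices and gap models.

A :class:`ScoringScheme` bundles everything needed to score a pair of aligned
rows: the substitution matrix, the gap model (linear per-site penalty or
affine open/extend), the terminal-gap policy and optional per-pair weights.
Shared-gap columns — gapped in both members of a pair — never contribute,
which is fixed policy rather than an option.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Mapping, Optional

from Bio.Align import substitution_matrices

from .alignment import AMINO_ACIDS, NUCLEOTIDES


class ScoringError(ValueError):
    """Raised for invalid matrices or gap parameters."""


def _simple_matrix(symbols: str, match: float, mismatch: float) -> dict:
    m = {}
    for a in symbols:
        for b in symbols:
            m[(a, b)] = match if a == b else mismatch
    return m


def _add_unknown_symbol(matrix: dict, symbols: str) -> dict:
    """Score X as 0 against everything (neutral: never biases a criterion)."""
    for a in set(symbols) | {"X"}:
        matrix[(a, "X")] = 0.0
        matrix[("X", a)] = 0.0
    return matrix


def load_score_matrix(name_or_source) -> dict:
    """Load a substitution matrix as a symmetric ``(symbol, symbol) -> score`` map.

    Accepts the built-in names ``"BLOSUM62"`` (20 amino acids) and ``"NUC44"``
    (nucleotide match 5 / mismatch −4), a path to an NCBI-format matrix file,
    an open handle, or the matrix text itself.  The unknown residue ``X`` is
    added scoring 0 against every symbol.  Asymmetric or incomplete matrices
    raise :class:`ScoringError`.
    """
    if isinstance(name_or_source, str) and name_or_source.upper() == "BLOSUM62":
        arr = substitution_matrices.load("BLOSUM62")
        matrix = {
            (a, b): float(arr[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
        }
        return _add_unknown_symbol(matrix, AMINO_ACIDS)
    if isinstance(name_or_source, str) and name_or_source.upper() == "NUC44":
        return _add_unknown_symbol(
            _simple_matrix(NUCLEOTIDES, 5.0, -4.0), NUCLEOTIDES
        )

    if hasattr(name_or_source, "read"):
        handle = name_or_source
    elif isinstance(name_or_source, (str, os.PathLike)) and os.path.exists(
        str(name_or_source)
    ):
        handle = open(str(name_or_source))
    else:
        handle = io.StringIO(str(name_or_source))
    try:
        arr = substitution_matrices.read(handle)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise ScoringError(f"cannot parse NCBI-format matrix: {exc}") from exc
    finally:
        if handle is not name_or_source:
            handle.close()

    symbols = [s for s in arr.alphabet if s not in ("*", "X")]
    matrix = {}
    for a in symbols:
        for b in symbols:
            sab, sba = float(arr[a, b]), float(arr[b, a])
            if sab != sba:
                raise ScoringError(f"matrix not symmetric at ({a},{b}): {sab} vs {sba}")
            matrix[(a, b)] = sab
    return _add_unknown_symbol(matrix, "".join(symbols))


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap model.

    Parameters
    ----------
    matrix:
        Symmetric ``(symbol, symbol) -> score`` map; see :func:`load_score_matrix`.
    gap_model:
        ``"linear"`` — every gap site costs ``gap_site_penalty``; or
        ``"affine"`` — a run of k gap sites costs ``gap_open + (k-1)*gap_extend``.
    gap_site_penalty, gap_open, gap_extend:
        Penalty magnitudes (entered positive, applied as negative contributions).
    terminal_gaps:
        ``"penalized"`` (default) or ``"free"`` — whether gap runs touching
        either end of a pairwise alignment are charged.
    pair_weights:
        Optional ``(i, j) -> weight`` map (i < j, 0-based) for weighted
        sum-of-pairs scoring; absent means every pair weighs 1.
    """

    matrix: Mapping[tuple[str, str], float]
    gap_model: str = "linear"
    gap_site_penalty: float = 6.0
    gap_open: float = 20.0
    gap_extend: float = 2.0
    terminal_gaps: str = "penalized"
    pair_weights: Optional[Mapping[tuple[int, int], float]] = None

    def __post_init__(self) -> None:
        if self.gap_model not in ("linear", "affine"):
            raise ScoringError(f"unknown gap model {self.gap_model!r}")
        if self.terminal_gaps not in ("penalized", "free"):
            raise ScoringError(f"unknown terminal gap policy {self.terminal_gaps!r}")
        if self.gap_model == "affine" and not self.gap_open >= self.gap_extend >= 0:
            raise ScoringError("affine mode requires gap_open >= gap_extend >= 0")
        if self.gap_model == "linear" and self.gap_site_penalty < 0:
            raise ScoringError("gap_site_penalty must be non-negative")

    def score(self, a: str, b: str) -> float:
        try:
            return self.matrix[(a, b)]
        except KeyError as exc:
            raise ScoringError(f"no matrix entry for pair ({a},{b})") from exc

    def gap_run_cost(self, length: int) -> float:
        """Cost (positive magnitude) of one maximal gap run of ``length`` sites."""
        if length <= 0:
            return 0.0
        if self.gap_model == "linear":
            return self.gap_site_penalty * length
        return self.gap_open + (length - 1) * self.gap_extend

    def weight(self, i: int, j: int) -> float:
        if self.pair_weights is None:
            return 1.0
        key = (i, j) if i < j else (j, i)
        try:
            return float(self.pair_weights[key])
        except KeyError as exc:
            raise ScoringError(f"missing pair weight for ({i},{j})") from exc


def table1_scheme() -> ScoringScheme:
    """BLOSUM62 with a flat −6 gap penalty (the two-site worked example)."""
    return ScoringScheme(load_score_matrix("BLOSUM62"), gap_model="linear",
                         gap_site_penalty=6.0)


def protein_scheme(gap_open: float = 20.0, gap_extend: float = 2.0,
                   terminal_gaps: str = "penalized") -> ScoringScheme:
    """BLOSUM62 with affine gaps (default GO=20, GE=2)."""
    return ScoringScheme(load_score_matrix("BLOSUM62"), gap_model="affine",
                         gap_open=gap_open, gap_extend=gap_extend,
                         terminal_gaps=terminal_gaps)


def nucleotide_scheme(gap_site_penalty: float = 6.0) -> ScoringScheme:
    """Match 5 / mismatch −4 with a flat gap penalty (nucleotide/codon toy mode)."""
    return ScoringScheme(load_score_matrix("NUC44"), gap_model="linear",
                         gap_site_penalty=gap_site_penalty)
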