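"""Alignment containers, aligned-FASTA I/O, windowing and shared-gap handling.

Conventions used throughout the package:

* the gap character is ``-`` (``.`` and ``~`` are rejected);
* residues are stored upper-case; ``X`` denotes an unknown residue;
* all column/site coordinates exposed to users are 1-based and inclusive,
  matching the way alignment viewers number sites.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterator, TextIO

from Bio import SeqIO

GAP = "-"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

#: alphabet tag -> set of allowed residue symbols (gap and X handled separately)
ALPHABETS = {
    "aa": set(AMINO_ACIDS),
    "nt": set(NUCLEOTIDES),
    "codon": set(NUCLEOTIDES),
}

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Raised when an alignment violates a structural invariant."""


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment: an identifier and its gapped residue string."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        """Residues with all gap characters removed."""
        return self.residues.replace(GAP, "")

    def gap_runs(self) -> list[tuple[int, int]]:
        """Maximal gap runs as (start, length) in 0-based column coordinates."""
        runs = []
        i, n = 0, len(self.residues)
        while i < n:
            if self.residues[i] == GAP:
                j = i
                while j < n and self.residues[j] == GAP:
                    j += 1
                runs.append((i, j - i))
                i = j
            else:
                i += 1
        return runs


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment over one of the alphabets in ``ALPHABETS``.

    All members have identical length.  Codon alignments are stored as
    nucleotide columns with a reading-frame invariant: each member's ungapped
    length and every one of its gap runs is a multiple of three, so that
    triplet-constrained moves can be validated structurally.
    """

    members: tuple[AlignedSequence, ...]
    alphabet: str = "aa"

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise AlignmentError(f"unknown alphabet tag {self.alphabet!r}")
        if not self.members:
            raise AlignmentError("alignment has no sequences")
        n_cols = len(self.members[0].residues)
        allowed = ALPHABETS[self.alphabet] | {GAP, "X"}
        for m in self.members:
            if len(m.residues) != n_cols:
                raise AlignmentError(
                    f"ragged lengths: sequence {m.id!r} has length "
                    f"{len(m.residues)}, expected {n_cols}"
                )
            for col, sym in enumerate(m.residues, start=1):
                if sym not in allowed:
                    raise AlignmentError(
                        f"symbol {sym!r} at column {col} of {m.id!r} is outside "
                        f"the {self.alphabet!r} alphabet"
                    )
        if self.alphabet == "codon":
            for m in self.members:
                if len(m.degapped()) % 3:
                    raise AlignmentError(
                        f"codon sequence {m.id!r}: ungapped length not a multiple of 3"
                    )
                for start, length in m.gap_runs():
                    if length % 3:
                        raise AlignmentError(
                            f"codon sequence {m.id!r}: gap run not multiple of 3 "
                            f"at column {start + 1}"
                        )

    # -- basic geometry ----------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.members)

    @property
    def n_columns(self) -> int:
        return len(self.members[0].residues)

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.members)

    def __getitem__(self, i: int) -> AlignedSequence:
        return self.members[i]

    def column(self, site: int) -> str:
        """Symbols of 1-based column ``site``, top to bottom."""
        if not 1 <= site <= self.n_columns:
            raise AlignmentError(f"site {site} out of range 1..{self.n_columns}")
        return "".join(m.residues[site - 1] for m in self.members)

    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.members)

    def replace_row(self, index: int, residues: str) -> "Alignment":
        """New alignment with row ``index`` carrying ``residues``."""
        rows = list(self.members)
        rows[index] = AlignedSequence(rows[index].id, residues)
        return Alignment(tuple(rows), self.alphabet)


def read_fasta_alignment(source, alphabet: str = "aa") -> Alignment:
    """Read an aligned FASTA file (path, text, or handle) into an Alignment.

    Input may be wrapped or unwrapped; residue case is normalised to upper.
    Raises :class:`AlignmentError` on ragged rows, foreign symbols, fewer than
    two records, or codon-frame violations.
    """
    handle = _as_handle(source)
    records = list(SeqIO.parse(handle, "fasta"))
    if len(records) < 2:
        raise AlignmentError("aligned FASTA must contain at least 2 records")
    members = tuple(
        AlignedSequence(rec.id or rec.description, str(rec.seq).upper())
        for rec in records
    )
    return Alignment(members, alphabet)


def write_fasta_alignment(aln: Alignment, sink) -> None:
    """Write ``aln`` as aligned FASTA at 60 residues per line.

    Records with an empty identifier are written with a ``seq<k>`` placeholder
    (a warning is logged) so that the output always round-trips.
    """
    own, handle = _as_write_handle(sink)
    try:
        for k, m in enumerate(aln.members, start=1):
            ident = m.id
            if not ident:
                ident = f"seq{k}"
                logger.warning("record %d has an empty id; writing as %r", k, ident)
            handle.write(f">{ident}\n")
            for i in range(0, len(m.residues), 60):
                handle.write(m.residues[i : i + 60] + "\n")
    finally:
        if own:
            handle.close()


def window(aln: Alignment, first_site: int, last_site: int) -> Alignment:
    """Sub-alignment of 1-based columns ``first_site``..``last_site`` inclusive."""
    if not 1 <= first_site <= last_site <= aln.n_columns:
        raise AlignmentError(
            f"window {first_site}..{last_site} out of range 1..{aln.n_columns}"
        )
    members = tuple(
        AlignedSequence(m.id, m.residues[first_site - 1 : last_site])
        for m in aln.members
    )
    # a codon window need not satisfy the frame invariant; keep nt semantics
    alphabet = "nt" if aln.alphabet == "codon" else aln.alphabet
    return Alignment(members, alphabet)


def drop_shared_gap_columns(aln: Alignment) -> tuple[Alignment, list[int]]:
    """Remove columns gapped in every sequence.

    Returns the reduced alignment and the removed column indices in ascending
    1-based coordinates of the input.  In codon mode only complete shared-gap
    triplet runs are removed, preserving the reading frame.
    """
    shared = [
        site
        for site in range(1, aln.n_columns + 1)
        if all(m.residues[site - 1] == GAP for m in aln.members)
    ]
    if aln.alphabet == "codon":
        shared = _full_triplet_runs(shared)
    if not shared:
        return aln, []
    keep = [c for c in range(1, aln.n_columns + 1) if c not in set(shared)]
    members = tuple(
        AlignedSequence(m.id, "".join(m.residues[c - 1] for c in keep))
        for m in aln.members
    )
    return Alignment(members, aln.alphabet), shared


def _full_triplet_runs(columns: list[int]) -> list[int]:
    """Keep only columns belonging to maximal runs whose length is a multiple of 3."""
    out: list[int] = []
    run: list[int] = []
    for c in columns:
        if run and c == run[-1] + 1:
            run.append(c)
        else:
            if len(run) % 3 == 0:
                out.extend(run)
            run = [c]
    if run and len(run) % 3 == 0:
        out.extend(run)
    return out


def _as_handle(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    text = str(source)
    if "\n" in text or text.lstrip().startswith(">"):
        return io.StringIO(text)
    return open(text)


def _as_write_handle(sink) -> tuple[bool, TextIO]:
    if hasattr(sink, "write"):
        return False, sink
    return True, open(str(sink), "w")
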