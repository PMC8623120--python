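"""Synthetic alignment fixtures with planted, recoverable gap-shift errors.

Every generator returns ``(clean, perturbed, truth)``: a correct alignment, a
version of it in which residue blocks have been slid across adjacent gaps
(the kind of frozen suboptimal choice progressive aligners leave behind), and
the list of moves that undo the damage.  Clean and perturbed always agree
after gap removal, and generation is deterministic given the seed.

Three named presets emulate the structures the criteria were designed
around — all with synthetic residues, since the original data exist only as
published figures:

* ``ace2_preset`` — 11 protein sequences with a single residue on the wrong
  side of a gap at a two-column window (site 20: ten T plus the shifted
  sequence's gap; site 21: seven T and four I);
* ``codon_preset`` — three codon sequences where a triplet-respecting shift
  removes a spurious A↔G substitution, leaving only a triplet deletion;
* ``huntingtin_preset`` — 20 sequences with variable-length poly-Q tracts and
  a proline-rich tail, where three P residues are stranded in a Q-majority
  column five sites away from a P-only column.  Relocating them raises the
  PWM differential while costing extra gap openings, so PWMD and SPS/PAI
  disagree about the move.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alignment import AMINO_ACIDS, GAP, NUCLEOTIDES, AlignedSequence, Alignment
from .refine import Move, apply_move


@dataclass(frozen=True)
class PlantedShift:
    """One planted error: in ``seq_index``, a block of ``block_len`` residues
    sits ``gap_len`` columns away from where the other sequences say it
    belongs."""

    seq_index: int
    block_len: int = 1
    gap_len: int = 3
    direction: str = "right"  # direction of the *repairing* move


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic alignment with planted shift errors."""

    n_sequences: int = 8
    n_columns: int = 40
    alphabet: str = "aa"
    planted_moves: tuple[PlantedShift, ...] = (PlantedShift(seq_index=0),)
    repeat_tract: Optional[tuple[str, int, int]] = None   # residue, min, max run
    minority_residue: Optional[tuple[str, int, int]] = None  # residue, count, column
    substitution_rate: float = 0.05
    seed: int = 0


def _symbols(alphabet: str) -> str:
    return AMINO_ACIDS if alphabet == "aa" else NUCLEOTIDES


def make_shift_fixture(spec: FixtureSpec) -> tuple[Alignment, Alignment, list[Move]]:
    """Generate ``(clean, perturbed, truth)`` from a :class:`FixtureSpec`.

    The clean alignment derives every row from a random consensus with point
    substitutions; each planted shift reserves a protected region in which the
    target sequence carries a gap run next to a consensus-matching block, and
    the landing columns are built so the displaced block mismatches there —
    making the repair unambiguous under both pair scores and PWM weights.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = _symbols(spec.alphabet)
    n, L = spec.n_sequences, spec.n_columns
    if n < 2:
        raise ValueError("need at least 2 sequences")
    consensus = list(rng.choice(list(symbols), size=L))

    # reserve one disjoint region [s, s+b+g) per planted shift, away from ends
    regions: list[tuple[int, PlantedShift]] = []
    used: set[int] = set()
    for shift in spec.planted_moves:
        b, g = shift.block_len, shift.gap_len
        width = b + g
        if not 0 <= shift.seq_index < n:
            raise ValueError("planted move sequence index out of range")
        candidates = [
            s for s in range(2, L - width - 1)
            if not any(c in used for c in range(s - 2, s + width + 2))
        ]
        if not candidates:
            raise ValueError("infeasible spec: no room left for planted move")
        s = int(rng.choice(candidates))
        used.update(range(s - 1, s + width + 1))  # flanks protected too
        regions.append((s, shift))
        # landing/source columns must mismatch at lag g: alternate two residues;
        # a third residue on both flanks stops drag-along placements from tying
        r1, r2, r3 = rng.choice(list(symbols), size=3, replace=False)
        for j in range(width):
            consensus[s + j] = r1 if (j // g) % 2 == 0 else r2
        consensus[s - 1] = r3
        consensus[s + width] = r3

    protected = set(used)
    if spec.repeat_tract is not None:
        residue, lo, hi = spec.repeat_tract
        width = hi
        starts = [
            s for s in range(1, L - width)
            if not any(c in protected for c in range(s, s + width))
        ]
        if not starts:
            raise ValueError("infeasible spec: no room for repeat tract")
        tract_start = int(rng.choice(starts))
        protected.update(range(tract_start, tract_start + width))
    else:
        tract_start = None

    rows = []
    for i in range(n):
        row = list(consensus)
        for j in range(L):
            if j not in protected and rng.random() < spec.substitution_rate:
                row[j] = str(rng.choice(list(symbols)))
        if tract_start is not None:
            residue, lo, hi = spec.repeat_tract
            run = int(rng.integers(lo, hi + 1))
            for k in range(hi):  # right-aligned run, gaps padding the left
                row[tract_start + k] = residue if k >= hi - run else GAP
        rows.append(row)

    if spec.minority_residue is not None:
        residue, count, column = spec.minority_residue
        placed = 0
        for row in rows:
            if placed >= count:
                break
            if row[column - 1] != GAP:
                row[column - 1] = residue
                placed += 1

    # carve the planted gap runs into the clean alignment
    truth: list[Move] = []
    for s, shift in regions:
        b, g = shift.block_len, shift.gap_len
        row = rows[shift.seq_index]
        row[s : s + b + g] = list(consensus[s : s + b + g])  # block matches consensus
        if shift.direction == "right":
            row[s : s + g] = [GAP] * g           # clean: gaps, then block
            truth.append(Move(shift.seq_index, s, b, g, "right"))
        else:
            row[s + b : s + b + g] = [GAP] * g   # clean: block, then gaps
            truth.append(Move(shift.seq_index, s + g, b, g, "left"))

    clean = Alignment(
        tuple(AlignedSequence(f"seq{i + 1:02d}", "".join(r))
              for i, r in enumerate(rows)),
        spec.alphabet,
    )
    perturbed = clean
    for m in truth:
        perturbed = apply_move(perturbed, m.inverse())
    return clean, perturbed, truth


# -- named presets ---------------------------------------------------------

ACE2_SHIFTED_INDEX = 4  #: row holding the "-T"/"T-" ambiguity in the preset


def ace2_preset(seed: int = 0) -> tuple[Alignment, Alignment, list[Move]]:
    """Eleven protein sequences with the two-site single-residue ambiguity.

    At the window (sites 20–21) the perturbed state reads, down the columns:
    site 20 — ten T plus a gap in the shifted sequence; site 21 — the shifted
    sequence's T, six further T and four I.  The clean state carries "T-"
    instead of "-T" in the shifted sequence.  All other columns are identical
    between the two states (substituted consensus, no gaps), so criterion
    differences reduce to the window.
    """
    rng = np.random.default_rng(seed)
    n, L = 11, 25
    symbols = [s for s in AMINO_ACIDS if s not in "TI"]
    consensus = rng.choice(symbols, size=L)
    rows = []
    others = 0
    for i in range(n):
        row = [
            str(c) if rng.random() > 0.05 else str(rng.choice(symbols))
            for c in consensus
        ]
        if i == ACE2_SHIFTED_INDEX:
            row[19], row[20] = "T", GAP          # clean "T-"
        else:
            row[19] = "T"
            row[20] = "T" if others < 6 else "I"  # six T, four I at site 21
            others += 1
        rows.append(AlignedSequence(f"seq{i + 1:02d}", "".join(row)))
    clean = Alignment(tuple(rows), "aa")
    truth = [Move(ACE2_SHIFTED_INDEX, 20, 1, 1, "left")]
    perturbed = apply_move(clean, truth[0].inverse())
    return clean, perturbed, truth


def codon_preset(seed: int = 0) -> tuple[Alignment, Alignment, list[Move]]:
    """Three codon sequences where a triplet shift removes an A↔G mismatch.

    The third sequence lacks one codon.  The perturbed alignment places its
    GGG triplet against GGA (one A↔G substitution plus a triplet deletion);
    sliding the triplet across the gap leaves only the triplet deletion, the
    simpler hypothesis with the higher alignment score.
    """
    rng = np.random.default_rng(seed)
    lead = "".join(rng.choice(list(NUCLEOTIDES), size=3))  # shared first codon
    s1 = lead + "ATGGGAGGGTTT"
    s3_clean = lead + "ATG" + GAP * 3 + "GGGTTT"
    rows = (
        AlignedSequence("cds1", s1),
        AlignedSequence("cds2", s1),
        AlignedSequence("cds3", s3_clean),
    )
    clean = Alignment(rows, "codon")
    truth = [Move(2, len(lead) + 3, 3, 3, "right", frame_step=3)]
    perturbed = apply_move(clean, truth[0].inverse())
    return clean, perturbed, truth


def huntingtin_preset(seed: int = 0) -> tuple[Alignment, Alignment, list[Move]]:
    """Twenty sequences with poly-Q tracts and a displaced P group.

    Layout (1-based sites, 53 columns): sites 1–17 a conserved N-terminal
    region; sites 18–38 a glutamine tract of seeded variable length, right-
    aligned; site 38 mixes twelve Q with three P (five sequences gapped);
    three sequences carry P at site 39; sites 40–43 hold a sparse proline
    ramp ending in a column of P; sites 44–53 a conserved proline-rich tail.
    The perturbed state has three P residues at site 38; the clean state has
    them relocated to site 43.  The relocation raises PWMD but lowers SPS —
    the documented conflict between the criteria.
    """
    rng = np.random.default_rng(seed)
    nterm = "MATLEKLMKA FESLKSF".replace(" ", "")  # 17 cols, synthetic HTT-like
    tail = "PQLPQPPPQA"                             # 10 cols
    # groups: 10 Q@38, 2 Q@38 with P40-43, 3 P@38, 3 P@39, 2 P@42-43
    groups = (["Q"] * 10 + ["QP"] * 2 + ["P38"] * 3 + ["P39"] * 3 + ["P43"] * 2)
    rng.shuffle(groups)
    rows = []
    q_lengths = rng.integers(6, 21, size=20)
    q_lengths[0] = 21  # one full-length tract keeps every tract column occupied
    for i, grp in enumerate(groups):
        head = [
            c if rng.random() > 0.03
            else str(rng.choice([a for a in AMINO_ACIDS if a != "Q"]))
            for c in nterm
        ]
        mid = [GAP] * 26  # sites 18..43
        q_end = 21 if grp in ("Q", "QP") else 20  # tract ends at site 38 or 37
        q_len = min(int(q_lengths[i]), q_end)
        for k in range(q_end - q_len, q_end):
            mid[k] = "Q"
        if grp == "P38":
            mid[20] = "P"                 # site 38 (perturbed position)
        elif grp == "P39":
            mid[21] = "P"                 # site 39
        elif grp == "P43":
            mid[24] = mid[25] = "P"       # sites 42–43
        elif grp == "QP":
            mid[22:26] = ["P"] * 4        # sites 40–43
        rows.append(AlignedSequence(f"htt{i + 1:02d}", "".join(head + mid) + tail))
    perturbed = Alignment(tuple(rows), "aa")
    truth = [
        Move(i, 37, 1, 5, "right")
        for i, grp in enumerate(groups) if grp == "P38"
    ]
    clean = perturbed
    for m in truth:
        clean = apply_move(clean, m)
    return clean, perturbed, truth


PRESETS = {
    "ace2": ace2_preset,
    "codon": codon_preset,
    "huntingtin": huntingtin_preset,
}
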