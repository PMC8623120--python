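# Methods

## Scope and model

`msapolish` evaluates and locally repairs a *fixed* multiple sequence
alignment. It never re-aligns: every operation preserves each sequence's
degapped content and the relative order of its residues, so the search space
is exactly the set of gap placements reachable by sliding contiguous residue
blocks across adjacent gap runs. This matches the failure mode being
addressed — progressive alignment freezes an arbitrary choice between
equally-scoring local placements, and later sequences reveal one of them to
have been wrong.

## Scoring conventions

**Pair scores.** The implied score of a pair of rows sums substitution
scores over columns where both rows carry residues and subtracts gap costs
for maximal residue-vs-gap runs. Columns gapped in both rows are removed
before anything else, so they contribute nothing and a gap run interrupted
only by shared-gap columns is charged as a single run. Affine runs of length
k cost GO + (k−1)·GE; the first gap site carries the open penalty. Terminal
runs are charged by default (`terminal_gaps="free"` disables this; the
two-site worked example requires the penalised convention, since its
boundary T/- pairs are charged at full cost). Optimal pair scores come from
global dynamic programming (three-state in affine mode) over the degapped
sequences under the same scheme — a deliberate choice: a single
`ScoringScheme` governs both S_ij and S_ij.MSA, so PAI compares like with
like. The implementation delegates the DP to `Bio.Align.PairwiseAligner`,
whose gap convention matches the one above; tests verify it against an
exhaustive enumeration oracle over all monotone alignments for small inputs.

**Unknown residues.** `X` scores 0 against every symbol and is excluded from
PWM counts. Ambiguity is thus neutral under every criterion rather than
rewarded or punished by whatever a matrix happens to assign it.

**PWM.** Weights are w_aj = log₂(((n_aj + c_a)/(N_j + Σ_b c_b))/p_a) with
background-proportional pseudocounts c_a = p_a·m. Defaults: total mass
m = 1, uniform background p_a = 1/20 (1/4 for nucleotides); an empirical
background (frequencies pooled over the alignment, gaps excluded, with one
pseudo-observation so unseen residues stay finite) is selectable. Log base 2
throughout. Gaps have no PWM row, so a sequence's PWMS ignores its gap sites
and shared-gap columns never move any score. All-gap columns get the
pure-pseudocount weight (exactly 0 under the defaults) and are deletion
candidates anyway. These pseudocount/background defaults are a documented
package choice: published tabulations of this kind of matrix show slightly
symbol-dependent floors, indicating non-uniform defaults in other software
that are not stated anywhere; this package therefore targets the arithmetic
and qualitative structure of the criterion (majority residue has the largest
weight, absent residues share a column floor, differentials equal weight
differences) rather than bit-reproduction of any particular program's
output.

**PWMD policies.** A move's differential can be taken under the pre-move PWM
(`"before"`, the default — the decision is framed from the current
alignment's matrix), the post-move PWM (`"after"`), or each state under its
own matrix (`"refreshed"`). Under the fixed-matrix policies PWMD is exactly
antisymmetric; under `"refreshed"` it need not be.

## The refinement engine

Moves are enumerated deterministically (ascending sequence, block start,
block length, slide distance): every block of ≤ `max_block` residues
touching a gap run, slid 1..min(run length, `max_slide`) positions into it,
in `frame_step` units. Codon alignments are stored as nucleotide columns
with a frame invariant (ungapped lengths and gap runs ≡ 0 mod 3), and
`frame_step=3` keeps every move frame-preserving by construction.

Each sweep evaluates all moves and accepts the single best one with
delta > tolerance, ties broken by enumeration order — equally good
alternative placements are common, so a deterministic canonical choice is
required; a `first_improving` flag trades optimality of the step for speed.
Move deltas are computed incrementally: for SPS/WSPS/PAI only the pairs
involving the moved sequence are rescored, and for PWMD only the moved row
is rescored under the sweep's matrix. Because moves never change degapped
content, optimal pair scores are constants of the search and the PAI
improvement of any move equals its (unweighted) SPS improvement; PAI-greedy
and SPS-greedy therefore take identical trajectories, which a test pins
down. The PWM is rebuilt once per sweep, not per move: per-move refresh
makes deltas non-additive and order-dependent, while per-sweep refresh keeps
the accepted deltas summable into the log's total.

After every accepted move, columns that became all-gap are deleted (full
triplet runs only, in codon mode) — SPS, PAI and every PWMS are invariant
under that deletion. Default tolerances: 0 for SPS/WSPS/PAI (integer
matrices make deltas exact) and 1e-9 for PWMD (floating-point log-odds).
The log records each accepted move with its delta and the columns deleted
after it, sufficient for exact replay; non-convergence within `max_sweeps`
returns the best state so far with a warning flag.

## Synthetic fixtures

The generator (`make_shift_fixture`) emulates the one structural error the
engine is built to repair: every row derives from a random consensus with
i.i.d. point substitutions (default rate 0.05), and each planted shift
reserves a region where the target sequence carries a gap run beside a
consensus-matching block. The landing columns alternate two residues at the
gap-run lag so the displaced block mismatches everywhere it should not be,
and both flanking columns are fixed to a third residue so that dragging
flank residues along can never tie with the planted repair — making the
clean placement the strict optimum under both pair scores and PWM weights.
Defaults for the generic recovery family: 8 sequences × 40 columns, one
planted shift with blocks of 1–3 residues and gap runs of 1–4 — small
enough for the 200-fixture recovery harness to run in seconds, large enough
that pair scores are dominated by unperturbed columns as in real data.

What the fixtures deliberately do not model: phylogenetic correlation among
sequences (substitutions are i.i.d., i.e. a star tree), indel length
distributions, composition bias, or multiple interacting errors in one
region. Passing the recovery harness therefore shows the engine repairs
isolated frozen choices whose signal is unambiguous; it says nothing about
errors whose resolution depends on the tree, which all three criteria
ignore by design.

Three presets reconstruct published *column compositions* (the original
sequences exist only as figures, so the residues are synthetic):

* `ace2_preset` — 11 × 25, window composition site 20 = {10 T, 1 gap},
  site 21 = {7 T, 4 I}; the ten pairs involving the shifted sequence
  contribute −34 ("-T") vs −10 ("T-") under BLOSUM62 with flat −6 gaps,
  and all three criteria agree on the repair.
* `codon_preset` — 3 codon sequences in which the suboptimal placement shows
  a triplet deletion plus an A↔G mismatch and the repaired one only the
  deletion.
* `huntingtin_preset` — 20 × 53 with variable-length poly-Q tracts
  (right-aligned; lengths seeded in 6–21 with one full-length tract so no
  tract column is empty), a column mixing 12 Q with 3 P, sparse P residues
  at the intervening sites (so no column is all-gap) and a 4-P anchor column
  five sites downstream. Relocating the stray P residues raises PWMD while
  costing two extra gap opens per affected pair, so PWMD conflicts in sign
  with SPS/PAI — the documented disagreement between the criteria. The
  preset approximates the published counts (it has three rather than four P
  residues at the site after the mixed column) to keep 20 sequences with no
  all-gap column.

## Problem sizes and numerical notes

The test suite exercises: exhaustive-oracle agreement of the pairwise DP for
combined lengths ≤ 12 (sampled over the 20-letter alphabet, exhaustive over
a 2-letter one), PAI non-negativity on 1,000 random 4 × 8 alignments,
≥ 95% exact recovery on 200 seeded single-shift fixtures under SPS and
under PWMD, and determinism/replay of the refiner. These sizes were chosen
so the whole suite completes in well under a minute while each property is
still exercised across its combinatorial range. Integer-valued schemes make
SPS/PAI arithmetic exact (floats that happen to be integers); PWMD
comparisons use a 1e-9 tolerance.

## Known limitations

* The published 53-column sum-of-pairs pair (31,007 / 29,178) and step-level
  PWMD totals (9.198 / 101.4509) for the real 20-sequence huntingtin
  alignment are not reproduced: the aligned FASTA behind them was not
  redistributed and the figure panels are not machine-readable, so the
  synthetic preset stands in structurally but not numerically.
* Moves relocate one sequence's block at a time; coordinated multi-sequence
  rearrangements are reached only as sequences of single moves, each of
  which must individually improve the criterion.
* No tree-aware or likelihood-based criterion: all three criteria treat the
  sequences as exchangeable, and taxon sampling can legitimately reverse
  which placement is preferred.
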