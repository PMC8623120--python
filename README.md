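# msapolish

Progressive multiple-sequence aligners routinely freeze locally ambiguous
choices — a residue left on the wrong side of a gap, a codon split across an
indel, repeat-tract residues scattered over columns — that no amount of
guide-tree iteration will revisit. `msapolish` is a small toolkit for
*post-alignment* work on such alignments: it scores alternative gap
placements under three explicit criteria and automates the repair by
greedily sliding residue blocks across adjacent gaps until no shift improves
the chosen criterion.

## The three criteria

For an alignment of *N* sequences with substitution matrix *s* and gap
penalties (flat per-site, or affine open/extend with a run of *k* gap sites
costing GO + (k−1)·GE):

* **SPS** (sum-of-pairs score) — Σ over all N(N−1)/2 pairs of the pairwise
  score implied by the alignment, with columns gapped in *both* members of a
  pair contributing nothing. The weighted form **WSPS** = Σ W&#x2095;&#x2c;ⱼ·S&#x2095;&#x2c;ⱼ
  reduces to SPS at unit weights.
* **PAI** (pairwise alignment inconsistency) — Σ S&#x2095;&#x2c;ⱼ − Σ S&#x2095;&#x2c;ⱼ.MSA, where
  S&#x2095;&#x2c;ⱼ is each pair's optimal global dynamic-programming score and
  S&#x2095;&#x2c;ⱼ.MSA its alignment-implied score. Since the optimum dominates,
  PAI ≥ 0, and 0 means every implied pair is already optimal; larger is worse.
* **PWMD** (position-weight-matrix differential) — build the 20 × L log₂-odds
  matrix w&#x2090;ⱼ = log₂(((n&#x2090;ⱼ + c&#x2090;)/(Nⱼ + Σc))/p&#x2090;) from column counts
  (pseudocounts c&#x2090; = p&#x2090;·m, background p&#x2090;), score each sequence as the sum
  of its residues' weights (PWMS), and evaluate a candidate rearrangement as
  PWMD = Σ PWMS_after − Σ PWMS_before. Unlike the two pair-based criteria,
  PWMD uses information from all sequences at once — and can disagree with
  them, notably in repeat regions.

The refiner enumerates every bounded block-shift move, applies the best
strictly-improving one per sweep, deletes shared-gap columns as they appear,
and logs everything for exact replay. A `frame_step=3` mode restricts blocks
and slides to codon triplets.

## Worked example

```python
from msapolish import (ace2_preset, table1_scheme, window, sps, pai,
                       greedy_refine)

scheme = table1_scheme()               # BLOSUM62, flat -6 gap penalty
clean, perturbed, truth = ace2_preset(seed=0)

w1 = window(perturbed, 20, 21)         # shifted sequence reads "-T"
w2 = window(clean, 20, 21)             # shifted sequence reads "T-"
print(sps(w2, scheme) - sps(w1, scheme))   # 24.0
print(pai(w1, scheme) - pai(w2, scheme))   # 24.0

refined, log = greedy_refine(perturbed, "SPS", scheme)
print(refined == clean, len(log.accepted), log.accepted[0].delta)
# True 1 24.0
```

The two-column window of this 11-sequence preset has ten T and one gap at
site 20 and seven T plus four I at site 21. Scoring only the ten pairs that
involve the ambiguous sequence, the "-T" placement contributes −34 (ten T/-
at −6, six T/T at 5, four T/I at −1) and the "T-" placement −10, so both SPS
and PAI favour "T-" by 24, and the refiner repairs it in one accepted move.

The same API exposes the conflict case: on the 20-sequence poly-Q preset,

```python
from msapolish import huntingtin_preset, protein_scheme, explain_conflict
_, perturbed, _ = huntingtin_preset(0)
report = explain_conflict(perturbed, protein_scheme())
print(report[report.conflict].head())
```

lists moves (relocating stray P residues out of a Q-majority column into a
P-only column) with PWMD > 0 but SPS < 0 — better by the whole-column
criterion, worse by every pairwise one.

A `msapolish` console script wraps the library
(`score`, `pwm`, `refine`, `simulate`, `conflicts`; see `msapolish --help`).

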