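# foldbench

Topology-based benchmarking of protein structure alignment.

Pairwise structure comparison scores (TM-score, DALI Z, RMSD-based scores)
are routinely treated as proxies for *fold identity*: a TM-score of 0.5 or
more is conventionally read as "same fold".  `foldbench` tests that
assumption from the outside.  It builds Cα decoy models whose global fold is
**known by construction** — each model realizes a specific *topology string*
on an ideal three-layer α/β/α lattice — so every pairwise comparison can be
labelled same-fold or different-fold without using any structure-comparison
score.  The benchmark then measures how well geometric alignment scores
recover those labels, and exposes the characteristic failure mode: pairs
related by a **core β-strand swap** (a genuine change of fold, topological
edit distance 1) that nevertheless superpose well enough to clear standard
significance thresholds.

It is intended for structural bioinformaticians who develop or evaluate
structure-comparison methods, and for anyone analysing protein fold space
who needs to know what a "significant" alignment score does and does not
guarantee.

## What is inside

- **`topology`** — fold topology strings: tokens `<dir><layer><slot>`
  (e.g. `+B+0` for the first sheet strand), canonicalization of the
  labelling gauge, a unit-cost **topological edit distance** (strand/helix
  slot exchange, direction flip, insertion/deletion, helix slide) computed
  by bidirectional breadth-first search, and the taxonomy of central-strand
  swaps: excluding edge strands of a five-strand sheet leaves three central
  positions 1,2,3, and a single pairwise exchange yields exactly the
  orders 2,1,3 / 1,3,2 / 3,2,1.
- **`decoygen`** — enumeration of all topologically distinct folds on an
  ideal "form" (e.g. 2-5-2 = two helix slots / five strands / two helix
  slots), filtering of left-handed parallel β crossovers and crossing
  loops, and construction of ideal-geometry Cα models with seeded
  self-avoiding loop walks; `extract_topology` recovers the canonical
  string from coordinates.
- **`structalign`** — Kabsch superposition, TM-score
  (`d0 = 1.24 (L−15)^⅓ − 1.8`, floored at 0.5 Å), a generic iterated
  superposition / dynamic-programming aligner (global–local: terminal gaps
  free), and parsers for TM-align / DALI / SAP text output.
- **`scoring`** — the score transformations over matched length *n* and
  RMSD *r*: the ratios n/r and n²/r; the Gaussian-damped
  random-similarity limit `r = √n (1 − exp(−n²/2σ²))` with σ = 70 (RMSD
  divided by this limit gives a normalized score whose significance
  envelope is values < 1); the partition curve
  `r = a√n / (1 + exp((bN − n + c)/d))` whose scale *a* through a point is
  a ranking score, fitted by maximizing `s = 100(TP − w·FP)/(TP + FN)`
  with w = 0.5; and the ranked-list discrimination metric
  `(TP − FP)/(TP + FP + 100)`.
- **`benchmark`** — the orchestration: fixture decoy sets with seeded
  noise, all-vs-all comparison, the box filter (more than 90 matched
  residues, RMSD under 9 Å, at full scale), topological labelling,
  partition fit, DUF/DOF classification against a substring-closed library
  of known-fold strings, and the exhibit list of different-fold pairs above
  the significance thresholds.

## Worked example

`examples/06_strand_swaps.py` builds a five-strand decoy, applies each of
the three central-strand transpositions, rebuilds, and aligns each pair
with the internal aligner:

```
base fold: +B+0 +A+0 +B+1 -B+2 +C+0 -B+3 +B+4
  swap 1,2 -> class 2-1-3 edit distance 1 | n=68 r=3.97 A tm=0.521
  swap 1,3 -> class 3-2-1 edit distance 1 | n=64 r=6.72 A tm=0.425
  swap 2,3 -> class 1-3-2 edit distance 1 | n=70 r=3.82 A tm=0.560

best swap pair: class 1-3-2, TM 0.560 (above the 0.5 threshold) despite
being a different fold
```

Each line is one decoy pair that differs by exactly one exchange of two
central sheet strands — a different fold by construction — yet two of the
three pairs score above the conventional TM-score 0.5 same-fold threshold:
the aligner matches the bulk of both models and simply leaves the two
swapped strands sitting in each other's positions.  The other examples
cover parsing and canonical forms (`01`), fold enumeration (`02`), model
building and topology recovery (`03`), alignment scoring (`04`) and the
partition-curve benchmark (`05`).

A thin CLI mirrors the library: `foldbench enumerate | build | fixtures |
align | score | bench | classify`.

## Scope

Decoys are built from user-specified element and loop lengths on flat
(untwisted) lattices; there is no threading, sequence-based model ranking,
or large-scale SCOP/ASTRAL ingestion, and the internal aligner is a generic
stand-in, not a re-implementation of SAP, TM-align or DALI — output files
from those tools can be supplied instead via `parse_external`.
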