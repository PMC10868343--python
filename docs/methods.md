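# Methods

This note documents the models, algorithms, defaults and known
limitations of `perfumes`, in the order the pipeline applies them.

## Problem setting

The input is a *positive* set of short RNA sequences associated with
some binary property (e.g. late-cycle reads of an in vitro selection
against a protein) and a *background* set (e.g. first-cycle reads),
plus a library of hairpin / internal-loop motifs.  The question is
which motifs are over-represented among positive sequences, and whether
their occurrences are supported by the thermodynamics of the
surrounding secondary structure — i.e. whether the full sequence folds
so as to present the loop.

## Motif library and curation

A motif records loop type, per-strand loop lengths, closing pair(s),
annotated within-loop interactions, and aligned instance sequences
(strands joined by `&`, closing nucleotides included).  Model positions
are numbered 0-based along strand 1 then strand 2; closing-pair
nucleotides are part of the coordinate system because they carry
sequence information the scorer uses.

Curation makes a library statistically scannable:

1. motifs whose instances imply several distinct strand-length vectors
   are split into one motif per vector (ids suffixed `.s1`, `.s2`, …);
2. motifs with fewer than `min_unique_occurrences` unique instances
   (default 5; uniqueness judged on the case/T-U-normalised string) are
   removed — too few observations to estimate a probability model;
3. motifs with no unpaired base are removed — there is no loop to find.

Every action is logged; curation is idempotent.

## Dinucleotide-preserving shuffles

The per-sequence null preserves all 16 overlapping-2-mer counts and
both terminal nucleotides exactly, via the Altschul–Erikson
Eulerian-path construction (random last-edge selection until the chosen
last edges form a tree into the final vertex, then a shuffled walk).
The standard last-edge randomisation does **not** weight all Eulerian
paths uniformly; this mild, well-known bias is accepted because the
invariant that matters for the null — exact count preservation — holds
by construction.  Default 100 shuffles per sequence.

## Motif scoring: tree Bayesian networks

Each motif is scored with a directed tree BN over its model positions.
The dependency graph is the strand backbone plus closing pairs plus
annotated interactions; it is reduced to a maximum spanning tree under
the empirical mutual information of the instance alignment (ties broken
lexicographically for reproducibility), rooted at position 0.  CPTs are
pseudocount-smoothed ML estimates (default pseudocount 1.0; rows with
zero mass under pseudocount 0 fall back to uniform).  The score of a
candidate loop sequence is `log2 P(seq | BN) − log2 P(seq | background)`
in bits, with a `−inf` sentinel for zero-probability sequences under an
unsmoothed model.

Candidate placements on a sequence are the hairpin loops (for hairpin
motifs) and internal loops (for internal motifs) of exactly matching
strand lengths, extracted from the MFE structure plus `n_samples`
(default 20) Boltzmann samples; duplicate placements are scored once.
One best hit per (sequence, motif) is kept: sequence-level presence is
the unit the enrichment stage counts.

Per-(sequence, motif) calibration: the best-hit score on the original
sequence is compared to a normal fit (mean, sd with n−1 denominator, sd
floored at 0.05 bits) of best-hit scores on the shuffles of that same
sequence; shuffles with no candidate contribute a sentinel one bit
below the minimum observed score so the null stays defined, and the
sentinel count is recorded.  The p-value is the upper normal tail;
hits with p ≤ 0.05 (default) are retained.

The normal model is an approximation: best-hit scores are maxima over
few placements of a discrete function of loop k-mers, so on short
sequences with small motifs their distribution carries atoms.  The
calibration study below quantifies when the approximation is adequate.

## Enrichment testing

Per motif, the 2×2 table counts sequences with at least one calibrated
hit in each dataset.  "Binomial proportion test" is implemented as the
pooled two-sample one-sided z-test

    z = (p̂₁ − p̂₂) / sqrt( p̂(1−p̂)(1/n₁ + 1/n₂) ),   p̂ pooled,

with no continuity correction by default (flag available) and Fisher's
exact test as a small-count option.  Multiple testing across motifs
uses Benjamini–Hochberg at α = 0.05 by default; method `none` applies
the bare threshold.  A motif is *enriched* only when it also points in
the positive direction.

Variant analysis: each sequence contributes its best hit's loop
sequence (closing nucleotides included, strands `&`-joined); the
enrichment factor is the ratio of pseudocounted frequencies
`((c_pos+c)/(n_pos+c)) / ((c_bg+c)/(n_bg+c))`, default c = 1, finite
even for background-absent variants.

## Folding engines

Two engines implement one contract (MFE, partition function,
stochastic sampling — all under hard constraints):

* **Internal engine** (default): pairs {AU, UA, GC, CG, GU, UG},
  hairpin loops ≥ 3 nt, energy `n_pairs·e_pair + n_stacks·e_stack`
  (defaults −1, −1, arbitrary units, rt = 1).  These are deliberately
  not thermodynamic truth: the model is small enough that MFE,
  partition function, Boltzmann probabilities and helix statistics are
  all verifiable by exhaustive enumeration on short sequences, which is
  how the DP kernels are tested.  No lonely-pair rule is imposed (it
  would complicate the enumeration oracle).  The DP kernels (numba) use
  a three-table recursion (all structures / endpoint-paired / endpoints
  not mutually paired) so stacking energies factor exactly.
* **ViennaRNA adapter** (optional): Turner parameters in kcal/mol via
  the `RNA` bindings, same hard-constraint semantics.  Engines must
  pass the same ordering tests (constraining never lowers Z nor the
  MFE's optimality); energies naturally differ.

Hard constraints force loop positions unpaired and closing pair(s)
present.  Three interpretations of "structure compatible with a hit"
are exposed: `loop_only` (loop unpaired), `closed` (default; also the
closing pairs), `stacked` (additionally one outward stacked pair per
closing pair — outward means away from the loop, so `(a−1, b+1)` for an
outer pair and `(c+1, d−1)` for the inner pair of an internal loop).
Forced pairs must be non-crossing; an unsatisfiable constraint yields
an invalid MFE / zero ensemble rather than an error.

MFE tie-breaking is a deterministic 5'-greedy traceback: at the
leftmost undecided position prefer opening a pair over leaving it
unpaired, then the smallest partner index, and prefer the stacked
continuation inside a helix.  This selects the lexicographically
smallest first divergent character and makes reruns bit-identical,
which is the property downstream code relies on.

## Structural context metrics

Per hit: constrained MFE (never below the unconstrained MFE), the
compatibility probability `Z_constrained / Z` (the Boltzmann mass of
compatible structures; monotone non-increasing from `loop_only` to
`stacked` because the structure sets are nested), and — for hairpins —
the mean length of the helix stacked on the closing pair, where a
structure's helix length is the number of contiguous pairs
`(a−k, b+k)`, k = 0, 1, …, with no gap.  The helix mean is exact by
enumeration up to length 14 and otherwise a Boltzmann-sample mean
(default 1,000 samples).  Group summaries compare positive vs
background per (motif, variant) with one-sided Wilcoxon rank-sum tests
(positive expected lower constrained MFE, higher compatibility).

## Synthetic data

The generator emulates a selection contrast: random GC-balanced
sequences (default 200 + 200 of length 60) in which a stem-supported
loop variant is planted at frequency `f_pos` = 0.3 (positive) vs
`f_bg` = 0.05 (background), at a random admissible offset.  Hairpin
planting embeds `stem + variant + revcomp(stem)` (Watson–Crick-only
stems, default length 6, GC-rich, so the designed helix dominates
folding under both engines); internal-loop planting builds
`stem + strand1 + stem + UUCG cap + stem' + strand2 + stem'`.  Default
variants CGCACG : CGCAAG at 3 : 1 mirror the classic GCAC/GCAA
stem-loop binder loops.  The truth table records every planted
(record, variant, span) so recovery is scored exactly.

What the generator does *not* emulate: selection-cycle kinetics, PCR
amplification bias, sequencing error, length heterogeneity, and real
motifs' non-canonical-pair energetics.  Passing the recovery study
therefore shows the pipeline's statistics and plumbing are sound at a
realistic effect size — not that any particular biological motif would
be found in real selection data.

## Validation studies and problem sizes

`perfumes.experiments` contains the seeded studies; the test suite runs
them at full size, `scripts/acceptance.py` re-measures them at reduced
sizes chosen to keep a complete from-scratch run cheap on one CPU:

* shuffle exactness: 1,000 sequences (lengths 10–80), every shuffle
  checked against the full 16-count vector;
* folding oracle: DP vs exhaustive enumeration (tolerance 1e-9) on
  random sequences ≤ 14 nt, free and constrained;
* compatibility probability vs enumerated Boltzmann mass (1e-9) and
  mode monotonicity;
* null calibration: p-values of originals drawn from their own shuffle
  distribution, KS distance to uniform over 2,000 replicates (tests) /
  1,000 (script).  Conditions: loop-3 hairpin motif, length-40
  sequences, 100 shuffles, 4 samples — loop size 3 is the commonest
  under the internal model, so candidates are abundant and the no-hit
  sentinel stays rare; with sparse candidates the sentinel atom makes
  any normal null visibly non-uniform, which is a documented limitation
  of the method for rare loop geometries;
* enrichment type-I error: 2,000 draws from the equal-frequency
  planting null through the proportion test and direction rule;
* planted-motif recovery: 20 runs (tests) / 8 runs (script) at the
  generator defaults with a panel of six never-planted decoy motifs
  (hairpin loops of size 3-6 with unrelated consensus, plus an
  internal-loop decoy), 25 shuffles and 10 samples per sequence.  The
  panel size matters: the false-flag rate is estimated over
  runs x decoys Bernoulli trials, and a small panel would make that
  estimate hostage to single binomial events; a larger panel also
  tightens each decoy's Benjamini-Hochberg threshold the way a
  realistic many-motif library does;
* determinism: byte-identical reports across reruns and across
  serial/parallel execution.

## Known limitations

* The internal energy model ignores loop-size penalties, dangles and
  sequence-dependent stacking; it is a verification vehicle, not a
  thermodynamic predictor — use the ViennaRNA adapter for real data.
* The shuffle is exact but not uniform over Eulerian paths.
* Normal score nulls are approximate for small motifs on short
  sequences (score discreteness); the sentinel policy for candidate-free
  shuffles slightly inflates per-sequence significance for motifs whose
  loop geometry is rare, which cancels between datasets in the
  enrichment contrast but can elevate per-sequence hit counts.
* Multi-branch loops and pseudoknots are out of scope throughout.
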