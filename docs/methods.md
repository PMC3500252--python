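# Methods

## Problem and model

Given a protein and a candidate lysine, the predictor decides whether
the site is acetylated from the residues flanking it. The unit of
analysis is the lysine-centered window of `m` upstream and `n`
downstream residues (default `m = n = 10`, a 21-mer), indexed by signed
offsets with 0 at the central lysine; offsets falling past a protein
terminus carry the pad symbol `X`, an information-free placeholder
(all-zero one-hot block, property value 0, substitution similarity 0
against everything including itself).

The pipeline has four stages: corpus construction, position selection,
feature encoding, and SVM evaluation.

## Corpus construction

Site annotations are 1-based positions validated against the sequence
(the residue must be `K`). Negative candidates are every unannotated
lysine in the same proteins. Within each class, near-duplicate
fragments are removed by a greedy keep-first scan in (protein id,
position) order: a fragment is discarded iff its positional identity
with an already-retained fragment strictly exceeds 0.30. Identity is
the fraction of window offsets carrying the identical character
(ungapped — the windows are fixed-length aligned), with pad matching
pad. Classes are de-redundified independently; whole-protein homology
clustering is out of scope (users supply pre-clustered FASTA if they
need it). For evaluation, five equal-size negative sets are drawn
without replacement (independently, so sets may overlap one another)
to pair with the positives; a protein-level holdout split keeps every
protein's fragments on one side.

## Position selection

Offsets are scored by information gain in bits, `IG(c) = H(X) −
H_c(X|Y)`, with maximum-likelihood probabilities and the `0·log 0 ≡ 0`
convention. Choices that were genuinely open:

- log base 2; only rankings matter downstream, so the base is inert.
- the pad symbol is a 21st observable value of Y — truncated windows
  near termini are informative about position, and dropping them would
  bias the conditional probabilities. A Laplace pseudocount option
  exists for tiny corpora; the default is unsmoothed maximum
  likelihood, appropriate for corpora of thousands of fragments.
- offset 0 is constant (`K`) within a lysine-centered corpus and is
  reported with IG = 0; masks never include it.
- ties in the ranking break toward smaller |offset|, then upstream,
  making selection deterministic.

The IG corpus is the balanced corpus (positives plus one balanced
negative set), not the full negative pool. Preset masks IG9–IG17
record the published position-specific windows; `generalW` masks are
the contiguous symmetric comparators.

## Feature encoding

- **BE**: 20 slots per encoded position, `ACDEFGHIKLMNPQRSTVWY` order.
- **KNN**: the fragment distance is `D = 1 − (1/L)·Σ Sim(a,b)` with
  `Sim = (BLOSUM62 − min)/(max − min)` globally (min −4, max 11, so
  identical tryptophans score 1.0). The equation is adopted from the
  standard KNN-score construction in the PTM-prediction literature; a
  per-row normalization hook exists via `normalize_substitution_matrix`
  on a user matrix. Neighborhood sizes are fractions (0.025%–0.4%) of
  the reference-set size with `k = max(1, round-half-up(f·N))`;
  rounding was unspecified in the protocol this follows, round-half-up
  is our choice. Self-matches are excluded by (protein id, position)
  key — not by zero distance, so identical sequences from different
  proteins still count as neighbors. Distance ties break by reference
  key order, making scores bit-reproducible.
- **AASA**: the bundled Janin average accessible surface area index
  (AAindex1 format, Å²-scale units), min–max scaled to [0,1] by default
  so its magnitudes do not dwarf the 0/1 one-hot block; raw mode is
  retained. `NA` values in user-supplied AAindex entries become 0. A
  screening harness ranks arbitrary candidate indices by
  property-only CV accuracy with a default-parameter SVM.

All three blocks already lie in [0,1], so no additional feature scaling
is applied before the SVM by default.

## Evaluation protocol

RBF-kernel SVM; C and γ tuned by grid search (default LIBSVM-style
grids, C ∈ 2^−5..2^15, γ ∈ 2^−15..2^3, ×4 steps, 5-fold inner CV;
ties prefer smaller C then smaller γ). Cross-validation: for each of
the five balanced negative sets, stratified 10-fold splits; per fold,
the KNN reference set and the grid search see the training fold only —
a deliberate leakage-safe reading of a protocol that does not state it.
Metrics are Acc, Sn, Sp and MCC in percent, with MCC defined 0 when a
denominator factor vanishes. Aggregation: each metric is first averaged
over a set's folds, then reported as mean ± sample sd (ddof = 1) over
the five sets, so the ± tracks negative-set resampling variability.
Configurations are compared by Welch's unequal-variance t-test on the
per-set MCC values (a paired-t option exists; the "paired Welch" naming
found in the source protocol is self-contradictory, and Welch-unpaired
is the default here). Holdout evaluation requires the holdout proteins
to be disjoint from training proteins and uses the full training corpus
as the KNN reference.

## Synthetic data generator

The generator plants class-dependent residue enrichment at chosen
offsets of otherwise-background 21-mers: positives carry the enriched
residue at an informative offset with marginal probability exactly
`p_enrich` (remainder drawn from the background renormalized over the
other 19 residues, so `p_enrich` equal to the background rate makes the
classes exchangeable); negatives are pure background — the weakest
separable construction, with no anti-motif. Calibration defaults mirror
the qualitative upstream-lysine/downstream-arginine signal of real
acetylation corpora: K enriched at −8..−1, R at +1, `p_enrich = 0.35`
against a uniform background (0.05 per residue). Fragments can be
packaged into FASTA proteins (several fragments per protein, random
flanks) whose annotations round-trip exactly through the corpus
readers.

What the generator does *not* emulate: real proteome composition,
homology structure between proteins, KAT-family substructure
(multiple motifs), or positive-set label noise. Passing tests
therefore demonstrate that the machinery recovers planted positional
signal under controlled conditions — not that real acetylomes reach
any particular accuracy.

## Problem sizes and numerical choices

End-to-end checks run at 2,000 fragments per class: information-gain
ranking recovers the planted 9-offset set essentially always at this
size, balanced CV with all three feature blocks reaches ≈89% accuracy,
and the IG-selected 13-offset mask beats the contiguous 13 window by
≈4 MCC points when the planted signal is non-contiguous. These runs
use a single-point SVM grid (C = 1, γ = 1/278 ≈ 1/n_features, the
`scale`-style default) — with strongly planted signal the grid search
adds cost but not discrimination — and the mask comparison uses 3-fold
CV; both are declared parameters of the protocol, not changes to it.
The IG-vs-oracle agreement is asserted to 1e-12 (pure counting plus
logs); metric identities to 1e-9.

## Known limitations

- Fragment-level redundancy reduction is greedy and order-dependent by
  design (deterministic, but a different scan order would retain a
  different subset).
- `knn_score_matrix` computes K from the self-excluded reference size,
  minimized over the query batch; for the homogeneous batches used in
  training/evaluation this equals the per-query value, but a mixed
  batch of in-reference and out-of-reference queries would share the
  smaller K.
- The distance treats pad–pad pairs as similarity 0, so two windows
  truncated at the same terminus are *more* distant than their shared
  truncation might suggest; with ≤10 pad positions out of 21 this is a
  bounded effect.
- Grid-search determinism relies on scikit-learn's first-best candidate
  selection; exact tie behavior on pathological floating-point score
  ties follows that library.
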