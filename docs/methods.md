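# Methods

## Problem and model

B-cell epitopes are the antigen regions recognized by antibodies; linear
epitopes are contiguous in sequence, conformational ones only in 3-D.  The
package predicts, residue by residue, whether a position belongs to an
epitope, using only sequence-derived information.  The classifier is a
soft-margin SVM with RBF kernel `exp(−γ‖x_i − x_j‖²)` over per-residue
feature vectors built from a window of `w` residues centred on the position
being classified.  Labels are +1 when the central residue is annotated as
epitope, −1 otherwise; every residue of every protein yields one training
or evaluation row (termini are zero-padded, never dropped).

Three feature families enter the hybrid representation, one column each:

* the amino-acid-ratio (AAR) propensity scale, a label-derived statistic:
  the ratio of an amino acid's normalized frequency among epitope residues
  to its normalized frequency among non-epitope residues, min–max
  normalized to [−1, 1];
* the per-residue sum of the 20 PSSM log-likelihoods (evolutionary
  conservation signal);
* curated physicochemical scales (18 candidates; 14 in the `final16`
  preset).

Each per-residue series `s_i` is collapsed over the window by the linear
distance-weighted average `Σ_i (1 − f·|c − i|) s_i / w`.  The denominator
is `w` unconditionally, also near the termini where padded positions
contribute 0 — the weighted sum is deliberately *not* renormalized over the
visible positions, so terminal residues have systematically shrunken
feature values; this is a property of the averaging scheme, not a bug.
Weights are used exactly as written even where `w` and `f` combine to make
the outermost weight negative (possible only at w = 29, f = 0.10; the
defaults w = 19, f = 0.08 keep all weights positive).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `w` | window size (residues) | 19 | odd, 5–29; larger windows average more context |
| `f` | linear weighting factor (per residue of distance) | 0.08 | 0–0.10 in steps of 0.02 |
| `C` | SVM regularization | 1 | |
| `γ` | RBF width | 10 | on features scaled to [−1, 1] |
| `w₊₁ / w₋₁` | class weights multiplying C | 15 / 1 | 20 / 1 in the single-scale protocol |
| pseudocount | additive count in the AAR ratio | 1.0 | keeps the ratio finite when a residue type is missing from one class |

The single-scale protocol (one scale or the raw 20·w PSSM window as the
whole representation) uses w₊₁ = 20 and the SVM tool-family defaults C = 1,
γ = 1/n_features.

Ambiguous residues (X/B/Z/U) are accepted in sequences, excluded from AAR
composition counts (the ratio is defined over the 20 standard amino acids),
and contribute 0 to feature values and all-zero rows to pseudo-PSSMs.

## Leakage control

Splits are made at the protein level: overlapping windows of one protein
never straddle train and evaluation material.  Within every fold (or
three-way iteration) the AAR scale and the [−1, 1] column scaler are fitted
on the training proteins only and carried inside the trained model; fold
provenance records the training protein ids so this can be audited after
the fact.  Scaled evaluation values are not clipped, so they may fall
outside [−1, 1] — the standard behaviour of min–max scaling applied to
unseen data.  A constant training column scales to 0 (midpoint of the
range), as does a degenerate (all-equal) propensity scale.

## Three-way optimization

The dataset is split into five protein-level parts which rotate through the
roles 3×train / 1×validation / 1×test over five iterations.  Six steps run
in order — (1) window size, (2) C and γ, (3) w₊₁, (4) backward feature
elimination, (5) f, (6) w₊₁ again — each selecting by validation AUC with
earlier choices frozen.  Design choices where the protocol was open:

* selection criterion is validation AUC (the primary threshold-free
  measure); ties break toward the simpler configuration (smaller w, smaller
  C then γ, smaller weight, fewer features, smaller f), which also makes
  the procedure deterministic;
* feature elimination is a single backward pass in feature-set order,
  accepting a removal only if validation AUC does not decrease.  Note that
  on a finite validation part a pure-noise feature is retained roughly half
  the time (its removal shifts AUC by noise of either sign); elimination
  is a greedy heuristic, not an exact subset search;
* initial values of all parameters are the minima of their grids, so
  size-one grids freeze the configuration and the protocol degenerates to a
  plain train+validation vs test evaluation;
* the test part is scored exactly once per iteration, by a model retrained
  on train+validation with the final configuration.  Per-iteration and
  averaged test metrics are reported, plus a pooled report over the five
  test parts (which together cover the dataset).

Pooled ("micro") metrics concatenate all held-out predictions; per-fold
means are reported alongside, since the two differ under imbalance.

## Metrics

SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC = (TP+TN)/total, PPV = TP/(TP+FP),
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Any metric with a
zero denominator is reported as NaN and flagged `undefined`, never silently
0.  AUC is the rank-based (Mann–Whitney) statistic; tied scores count 1/2
per positive-negative pair.  Hard labels use decision threshold 0 (ties →
−1); no probability calibration is attempted, since parameter selection and
comparison rest on the threshold-free AUC.

## Bundled physicochemical scales

The 18 candidate scales are shipped in AAIndex1 flat-file format
(`data/aaindex18_curated.txt`) with one accession per cited property
family.  The accessions are documented interpretations of the cited
properties, and several of the rarer entries (interactivity, buriability,
charge-transfer capability, H-bond donors, B-value flexibility,
antigenicity) are approximate reconstructions of the published scales, as
flagged in the file header.  Nothing in the pipeline depends on the exact
values — any entry can be overridden by pointing the parser at a custom
AAIndex file — but analyses aiming at literature-exact scales should
substitute verified entries.  The `final16` preset removes accessible
surface area, polarity, interactivity and buriability from the candidate
set.

## Synthetic study conditions

The generator emulates curated linear-epitope datasets: proteins with
contiguous epitope segments covering a target fraction of residues, epitope
segments drawn from a composition enriched for a chosen residue set,
background from a uniform (optionally natural-frequency) composition.  The
default spec mirrors the composition of a protective linear-epitope
collection — 57 proteins of 300–900 residues, ~5% epitope density, segments
of 8–20 residues (typical linear epitope lengths), mild 2× enrichment of
hydrophilic residues.  Realized density approximates the target up to
segment granularity and is recorded in the dataset name.

Two canonical recovery conditions are fixed:

* **strongly-enriched** (`strongly_enriched_spec`): 60 proteins × 150–300
  residues (~13,500 residues), density 0.15, 25× enrichment of six
  hydrophilic residues, segments of 24–40 residues.  Segments at least as
  long as the window guarantee that every epitope-centred window is
  majority-epitope and every background window minority-epitope, so window
  composition separates the classes by construction; the pipeline's pooled
  five-fold AUC on this condition is ≥ 0.98 across generator seeds.
* **planted-feature** (`planted_recovery_spec`): 30 proteins × 160–320
  residues, same segment geometry, with a compact 3-residue signal set
  (D/E/K) so that decoy scales — seeded permutations of the informative
  scale's values — usually land their high values on residues disjoint
  from the signal and are genuinely uninformative.  Protein lengths are
  chosen so every protein's epitope budget fits at least one segment
  (avoiding all-negative proteins and single-class validation parts).
  In the feature-recovery run the decoys precede the informative scale in
  candidate order, so redundant noise is stripped before the signal feature
  is ever tested for removal (avoiding the redundancy-masking artifact of
  backward elimination).

What passing these recovery tests shows — and what it does not: the
synthetic conditions verify that the feature construction, leakage-safe
protocol and optimizer recover a known compositional signal.  Real epitope
data differ in essentially every hard respect: epitope signal is far weaker
and only partly compositional, the pseudo-PSSM carries residue identity
rather than alignment-derived conservation, segment lengths and densities
vary, and annotation noise is substantial.  Performance on the synthetic
conditions therefore bounds machinery correctness, not biological accuracy.

## Numerical choices and degenerate inputs

* Min–max normalization of a constant scale or feature column maps to 0.
* The AAR ratio raises a degenerate-scale error only if a denominator is
  zero after pseudocounting (possible only with pseudocount 0).
* Cross-validation folds whose training residues collapse to one class are
  marked failed and reported; the run continues with the remaining folds.
  Three-way iterations whose every candidate evaluation fails raise a
  single-class error naming the iteration.
* SVM fitting is deterministic for identical inputs; all sampling
  (generator, splits, decoys) flows from explicit integer seeds.
* PSI-BLAST invocation fails fast with a configuration error naming the
  missing executable or database; the nr-database provenance of any
  supplied PSSM files is the caller's responsibility.

## Known limitations

* The pseudo-PSSM is a substitution-matrix profile: deterministic and
  offline, but it encodes no multiple-alignment conservation; results with
  real PSI-BLAST PSSMs will differ.
* The bundled physicochemical values are curated interpretations (see
  above).
* Backward elimination is order-dependent and greedy; it reports the
  configuration it accepted, not a global optimum.
* Scaled-down problem sizes are used throughout the test and acceptance
  runs (thousands to ~13k residues); they were chosen as the smallest
  conditions under which the recovery properties are stable across seeds.
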