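# Methods

## Windows and geometry

The unit of analysis is a fixed-length nucleotide window with a conserved GT
dimer at a declared offset. The default geometry is (L = 15, G at position 9):
8 nt of exon, the GT, and 5 nt of intron. Coordinates are 1-based and
inclusive in all user-facing output. Loaders for the common benchmark
layouts cut the window out of longer records so the record's conserved GT
lands at the geometry's offset (140 nt records with GT at 71–72; 38 nt
records with GT at 9–10; 15 nt records pass through unchanged). Records that
violate the GT invariant, contain ambiguity codes inside the window, or are
too short are rejected with a logged reason — never imputed or silently
dropped. The FASTA scanner emits one window per forward-strand GT with
sufficient flanks; reverse-complement scanning is opt-in and reports
coordinates in the reverse-complement frame, since donor sites are
strand-specific and a default forward-only scan is the least surprising
behaviour.

## Frequency models

Two class-conditional models are estimated from labelled windows:

- per-position frequencies p(α at i), smoothed additively:
  (count + c) / (n + 4c);
- pairwise conditional frequencies q(α at i | β at j) for all L(L−1)
  ordered pairs: (pair count + c) / (count of β at j + 4c).

The smoothing pseudocount c defaults to 1 (Laplace). This is a deliberate
departure from the raw empirical frequencies: the log-scores f1/f2/f5/f6 are
undefined whenever a test window carries a nucleotide never observed at that
position in training, which is common at realistic training sizes, so
prediction would otherwise fail on valid inputs. With c = 0 the estimates
are exactly the empirical frequencies, and scoring raises a clear error if a
zero is hit. A conditioning nucleotide with zero support (possible only at
c = 0) yields the uniform 1/4 distribution — the maximum-entropy choice that
keeps the dependency scores finite.

The conserved GT columns are included in all sums, including the extremal
sums M (per-position maxima) and N (minima). At c = 0 they contribute
log₂ 1 = 0 to the log scores and symmetric amounts to M and to Σ p, so their
inclusion is essentially neutral; at c > 0 they contribute equally to every
window and shift all scores by a constant, which the classifier absorbs.

## Features

f1–f8 follow the printed formulas exactly, with base-2 logarithms. Two
conventions deserve note:

- The min–max normalized scores f3/f4 are implemented as printed:
  100·(Σ p − M)/(M − N), which is 0 for a per-position consensus window and
  negative otherwise. The classical variant of this score,
  100·(Σ p − N)/(M − N), which gives 100 at consensus, differs only by a
  constant affine shift per model and is therefore classifier-equivalent;
  the printed form is kept.
- k-mer compositions divide the overlapping-occurrence count by L − k + 1,
  the number of sliding windows, for every k.

The full feature order is f1…f8, then di-, tri-, tetramer blocks each in
lexicographic A<C<G<T order; the order is fixed so encoded matrices are
reproducible. The reduced 49-feature manifest (8 scores + 14 di + 15 tri +
12 tetramers) ships frozen as the default feature set, reproducing the
protocol of selecting features once on human data and reusing them across
species; re-running selection is supported but not required for prediction.

## Feature selection

The F-score filter is implemented in two variants. The `paper` variant is
the literal ratio |(x̄⁺ − x̄⁻)/(s̄⁺ − s̄⁻)| with sample (n−1) standard
deviations; when the class standard deviations coincide but the means differ
the ratio diverges, so such features receive an "undefined-large" sentinel
(+inf) that sorts above all finite scores, is logged prominently, and is
never auto-selected. The `classical` variant is the Chen–Lin filter score
(between-class squared mean deviations over summed within-class variances),
always finite for non-constant features. Which variant produced the frozen
49-feature list is not determinable; both are exposed, and selection is
inclusive at the threshold (F ≥ t).

## Classifier

An RBF-kernel SVM with γ = 0.2 (the value found optimal for this feature
set) and C = 1.0 (the common library default; the cost parameter is
exposed in the configuration). Features are z-scored with parameters fitted
on training data only — the log-score features span tens of units while
compositions live in [0, 1], and an unscaled RBF kernel would let the former
dominate; a `none` option preserves the literal unscaled reading. Constant
training features pass through unscaled with a warning. Probability outputs
use the library's seeded internal sigmoid calibration, thresholded at 0.5
for the binary call.

Inside cross-validation the frequency models and the scaler are re-fitted
from each training partition, so no information from the test partition
reaches the encoder (a `whole_dataset_models` flag reproduces the leak-prone
alternative of fitting the frequency models once on everything, for
comparison only). Evaluation scores use the raw SVM decision values: both
area metrics are invariant under the monotone probability mapping, so the
costlier calibration is skipped there.

## Evaluation protocol and metrics

The repeated protocol draws n_sets independent sets by seeded sampling
without replacement at an exact true:false ratio, then partitions each class
separately into k random folds (stratified, preserving the set's ratio in
every fold); each fold serves once as the test partition. The headline
numbers are the arithmetic means of per-fold AUC-ROC and AUC-PR over all
n_sets × k evaluations; folds with a single-class test partition are flagged
and excluded from the mean.

AUC-ROC is the trapezoidal area over the threshold sweep defined by the
distinct observed scores (tied scores change classification together),
which is the exact version of sweeping thresholds over [0, 1] and equals
the Mann–Whitney pair statistic with ties counted ½. AUC-PR uses
Davis–Goadrich interpolation: between achievable points, true positives are
stepped continuously with proportionally accrued false positives, making
precision hyperbolic in recall; each segment is integrated in closed form
([x/a − (b/a²) ln(ax + b)]/P). The curve is anchored at (tp, fp) = (0, 0),
which extends it to recall 0 at the precision of the first achievable
point; with all scores tied this yields an area equal to the class
prevalence.

## Synthetic benchmarks

The generator draws true sites position-independently from a position
weight matrix: at each non-GT position the consensus nucleotide carries
probability mass `conservation` and the remainder is split over the other
nucleotides in proportion to the background distribution (uniform by
default). False sites are pure background. Both classes carry the forced
GT, so the only signal is the partial conservation around the junction. The
default consensus `AAGCCCAGGTAAGTA` embeds the canonical donor context
(exon …CAG | GTAAGT… intron) at the default geometry; the default
conservation of 0.85 produces strong but imperfect per-position
conservation, in the range typical of the positions flanking real donor
junctions. Class counts and ratios are exact, not stochastic, and all
draws descend from a single seed.

At conservation 0.25 with uniform background the true and false classes
are distributionally identical — the null case used to verify that the
pipeline reports chance-level discrimination. An optional dependent-pair
mode copies one non-GT position onto another in the true class, planting
purely pairwise signal that the per-position matrix cannot represent, so
the dependency features can be shown to add discrimination exactly when
dependency exists.

What the generator does **not** emulate: inter-position dependencies of
real splice sites beyond the optional planted pair, compositional biases
of exons versus introns (real false sites come from genomic sequence, not
uniform background), species differences, and the extreme genome-scale
imbalance (the benchmark ratios stop at 1:19). Passing tests on these
benchmarks therefore demonstrate the correctness and calibration of the
pipeline — not the accuracy level to expect on real genomes.

## Problem sizes and numerical choices

Calibration experiments use 1000 windows per class under fivefold
cross-validation for the null, signal and conservation-sweep checks, three
sets of 500 + 500 (balanced) and 300 + 1500 (1:5) windows for the
balanced-versus-imbalanced contrast, and ten sets of 50 + 50 windows for
the protocol-shape check; these sizes give stable means (the null mean sits
within ±0.05 of 0.5) while keeping a full run in the tens of seconds.
Model and manifest serialization round-trip exactly (frequencies written
with full repr precision); fold partition uses a seeded permutation split,
and all subsampling is without replacement. Stable mergesort is used
wherever order could matter for reproducibility.

## Known limitations

- Acceptor (AG) sites and non-canonical (GC–AG, AT–AC) introns are out of
  scope; the scanner is GT-specific.
- The published species-level accuracy figures were measured on external
  curated datasets that are not redistributed here; this package verifies
  the method's internal identities and qualitative behaviour on synthetic
  data, and provides loaders so users with those datasets can reproduce
  the full experiments.
- The `paper` F-score variant can be numerically explosive by construction
  (near-equal class standard deviations); the sentinel mechanism makes this
  visible rather than hiding it.
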