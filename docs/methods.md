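# Methods

## Problem and scope

A protein chain is assigned one of 17 quaternary-structure attributes:
monomer, or homo-/hetero-oligomer with 2, 3, 4, 5, 6, 8, 10 or 12
subunits (heptamers and undecamers are too sparsely represented in
structural databases to learn). The package covers the whole
prediction workflow — dataset curation, three feature encoders,
filter-based feature selection, a three-layer stacked classifier, and
the evaluation harness — with external database searches replaced by a
self-contained, calibrated scanning criterion and a synthetic fixture
generator, so everything runs offline and deterministically.

## Curation

Training sets built from structural databases are filtered before use:

* minimum length 30 residues;
* at most 2 unknown residues (ambiguity codes B, Z, J, U, O and `*`
  are normalized to `X` on input and counted as unknown);
* redundancy removal by greedy longest-first clustering. Sequence
  identity is defined as the maximum number of identically aligned
  positions over all global alignments with unpenalized gaps, divided
  by the shorter length. The default threshold is 60%, raised to 90%
  for the pentamer/octamer/decamer/dodecamer classes so those minor
  classes retain enough members to be statistically useful; clustering
  runs per class (matching the per-class threshold exception). The
  clustering is a deliberately simple, deterministic stand-in for
  dedicated tools such as CD-HIT — it reproduces the *policy*
  (longest-first greedy representative selection at an identity
  threshold), not any particular tool's output, and no specific
  cluster membership is promised. Ties in the visiting order are
  broken by ascending record id.

The unpenalized-gap identity (equivalently, longest common subsequence
over the shorter length) was chosen over a gap-penalized alignment
identity because it is exactly reproducible by a 10-line dynamic
program, making the implementation independently checkable; it is an
upper bound on gap-penalized identity, i.e. clustering is slightly
conservative (merges at least as much).

Fold assignment for cross-validation is stratified: within each class,
members are shuffled (seeded) and dealt round-robin from a random
starting fold, so per-class fold sizes differ by at most one and no
fold systematically collects the remainders.

## Motif scanning

A block is stored as its aligned, gapless segments; its PSSM entry for
residue *a* at position *j* is

    log2( ((count(a at j) + c·q) / (n + c)) / q ),   q = 1/20,

with pseudocount *c* = 1 and a uniform background. Log base 2,
uniform background and unit pseudocount are stated explicitly so
scores are bit-exact reproducible. With *c* = 0, empty cells are
floored at −30 bits to keep every entry finite. A scan takes the
maximum ungapped window sum over the sequence (first offset wins
ties); unknown residues contribute 0 rather than a penalty, so an
isolated `X` cannot mask an otherwise strong hit. A sequence shorter
than the motif scores −∞ (no hit) rather than raising.

Real block/domain searches report significance through database-wide
statistics this package cannot reproduce offline. The hit criterion
here is therefore defined explicitly: a motif's threshold is the
0.999 empirical quantile of best-window scores over 1000 random
uniform-residue decoys of length 5× the motif width, seeded. This
pins the per-motif false-hit rate at roughly 10⁻³ per decoy-length
sequence; longer query sequences scan more windows and so see a
proportionally higher rate (still well below 1% per motif at typical
chain lengths). Users with genuine search output can bypass scanning
entirely via precomputed hit lists, which the encoders accept in place
of the scanner.

## Feature encodings

**Block / FunD composition.** Binary vectors over the loaded database
order; bit *i* is set iff motif *i* hits. All-zero vectors are legal
and handled throughout — a chain with no known domain is precisely the
failure mode that motivates combining several feature types.

**PseASA.** The chain is split by per-residue solvent-accessibility
labels (E/B, supplied as a sidecar file; accessibility predictors are
external) into an exposed and a buried subsequence, preserving order.
Each side is encoded by pseudo-amino-acid composition with
sequence-order correlation rank λ and weight *w*:

    p_u      = f_u / (Σf + w·Σθ)          u = 1..20
    p_{20+j} = w·θ_j / (Σf + w·Σθ)        j = 1..λ
    θ_j      = (1/(L−j)) Σ_i Θ(R_i, R_{i+j})

where Θ is the mean squared difference of the standardized property
values of the two residues. Defaults λ = 10, *w* = 0.05 and the
canonical property set {hydrophobicity, hydrophilicity, side-chain
mass}, each standardized to mean 0 / SD 1 over the 20 residues: these
are the classic defaults of the encoding and are config-overridable.
A side shorter than λ+1 has its correlation rank degraded to its
length −1 (warning logged) while the output dimension stays fixed at
`2·(20+λ)`; an empty side contributes a zero block. Unknown residues
are dropped before encoding. PseASA is fully implemented and
evaluated, but the shipped default stack uses block + FunD only, which
cross-validates best.

## Feature selection

Per (class, feature type), features are ranked by F-score — the
between-class squared mean deviations over the pooled (n−1)-normalized
within-class variances. Conventions: a feature constant everywhere
scores 0 (0/0), a feature constant within each class but different
between classes scores +∞. The ranking is cut into nested prefixes at
25/50/75/100% (sizes ⌈f·d⌉); the 25% cut (too little signal) and the
100% cut (no pruning benefit) are discarded, and the 50%/75%
candidates are compared by cross-validated MCC, ties broken by higher
Sn, then Sp, then the smaller subset. Pruning is applied per class
model, not globally, since each one-vs-rest problem has its own
informative features. The eligible set is configurable for users who
want the full sweep.

## The stack

* **Layer 1.** One-vs-rest RBF-SVMs per (class, feature type) on the
  selected subset, with balanced class weights and C chosen from a
  small log grid {0.1, 1, 10} by the same cross-validated criterion as
  the subset. Negatives default to the same assembly group
  (monomer / homo / hetero), mirroring how per-class performance is
  conventionally tabulated per group; a class alone in its group
  (monomer) falls back to global negatives, and a `global` mode is
  available.
* **Layer 2.** Per class, an SVM (C = 1) mapping the feature types'
  layer-1 decision values to one combined score. Its training inputs
  are strictly out-of-fold: each record's layer-1 value comes from the
  fold model that never saw it, so the combiner learns the
  generalization behaviour of layer 1, not its training fit. Signed
  margins (not hard labels) are passed between layers to preserve
  confidence information.
* **Layer 3.** A random forest (500 trees, seeded) over the
  per-class combined-score vector — input dimension equals the number
  of classes. Tree ensembles were chosen for the arbiter because
  margin-based multiclass arbiters tend to surrender the minor
  oligomer classes to the majority classes; forests keep every class's
  sensitivity above zero at a modest cost in headline accuracy, and
  the per-class score inputs make the arbitration problem
  low-dimensional. Layer-3 training likewise uses only out-of-fold
  layer-2 scores.

Determinism: fold assignment, decoy calibration and the forest are
seeded from the run seed; two trainings with identical config and seed
produce byte-identical model digests (a SHA-256 over the fitted SVM
support vectors/coefficients, the selected subsets and the forest's
tree arrays). Model bundles persist the digests of the databases used
at training time, and prediction refuses a database whose digest does
not match, since a different database silently permutes the feature
space.

## Evaluation

Binary metrics follow the standard definitions (Sn, Sp, ACC as
percentages; MCC; precision/recall/F-measure); multiclass reports give
CCI (% correctly classified), Cohen's kappa, and macro-averaged
F-measure, with a per-class one-vs-rest breakdown. Cross-validation
pools confusion counts over the stratified folds and computes metrics
once on the pooled counts (micro aggregation) — the deterministic
choice when single per-class values are reported without variance; a
mean-over-classes "overall" can be derived from the per-class table.
Zero-denominator conventions are explicit because minor classes make
empty cells likely: MCC with a zero factor in the radical is 0,
F-measure at precision + recall = 0 is 0, and Sn/Sp with empty
denominators are reported as NA, never as 0. The outer CV folds are
drawn from an offset seed so they are independent of the stacking
folds inside the trainer.

## Synthetic data

The generator emulates the discriminative structure the method
assumes: class identity carried by the presence of class-specific
conserved motifs. Defaults — the package's reference study
conditions — are 6 classes (monomer, homo-2/3/4, hetero-2/3), 60
records per class, 2 private blocks + 2 private domains per class from
12-motif databases, motif widths 8–12 with 5 segments mutated from a
consensus at rate 0.1 per position, planting probability 0.9 per
motif, background length uniform on [80, 300] with uniform residue
composition, and exposed/buried labels drawn independently at
probability 0.5. Sizes were chosen so that stratified 10-fold CV is
well-defined for every class and a full evaluation completes in tens
of seconds on one CPU; planting probability 0.9 leaves ~1% of records
with no class motif at all, exercising the all-zero-vector path.

What passing tests on this data do and do not show: they verify the
encoders, selection, stacking hygiene, determinism and the metric
layer end to end under a signal structure where class separability is
known and strong (a trivial "any class bit set" rule already reaches
≈90%; the stack must beat it). They do not certify accuracy on real
proteins, which depends on the coverage and specificity of the real
block/domain databases, real accessibility predictions, and homology
structure the uniform background does not model.

## Known limitations

* The identity measure ignores gap placement; clustering is a policy
  stand-in, not a CD-HIT replica.
* Decoy calibration assumes a uniform background; compositionally
  biased sequences (e.g. low-complexity regions) will see elevated
  false-hit rates. Precomputed hit lists sidestep this.
* Accessibility labels are taken as given; no predictor is bundled.
* With very small training sets (a handful of records per class),
  inner-fold selection can degenerate; the trainer guards degenerate
  folds with neutral scores but small-sample reports should be read
  cautiously.
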