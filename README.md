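# quatstack

Predicting the **quaternary-structure attribute** of a protein chain —
monomer, or homo-/hetero- dimer, trimer, tetramer, pentamer, hexamer,
octamer, decamer or dodecamer (17 classes in all) — from its amino-acid
sequence.

Many proteins only function as oligomeric assemblies, and determining
the assembly state experimentally is slow and expensive. `quatstack`
is a sequence-based predictor aimed at structural bioinformaticians who
want an offline, fully reproducible implementation of the
motif-composition approach to this problem, including the feature
encoders, the feature selection, the stacked classifier and the
evaluation harness.

## The method

Three feature encodings per chain *P*:

* **Block composition** — a binary vector `P_block = [B_1 … B_d]ᵀ`
  over a database of *d* blocks (short, gapless, highly conserved
  alignment segments). `B_i = 1` iff *P* hits block *i*, where a hit
  means the best ungapped window score of block *i*'s position-specific
  scoring matrix (log₂-odds vs a uniform background) reaches the
  block's calibrated threshold (a 0.999 decoy quantile by default).
* **Functional-domain composition (FunD)** — the same binary
  construction over a domain-model database, `D_i = 1` iff domain *i*
  is found in *P*.
* **PseASA** — pseudo-amino-acid composition computed separately on
  the solvent-exposed and the buried subsequence of the chain (split
  by per-residue exposed/buried labels) and concatenated, dimension
  `2·(20+λ)`. Implemented and evaluated, but excluded from the default
  stack, which performs best with block + FunD.

These feed a three-layer stacked classifier:

1. **Layer 1** — per class and per feature type, a one-vs-rest RBF-SVM
   on an F-score-selected feature subset. Features are ranked by
   `F = [(x̄⁺−x̄)² + (x̄⁻−x̄)²] / [s²⁺ + s²⁻]`, cut at the quartile
   fractions, the 25% and 100% cuts are discarded, and the surviving
   candidates are compared by cross-validated MCC (ties: Sn, Sp,
   subset size).
2. **Layer 2** — per class, an SVM that combines the layer-1 decision
   values of the feature types into one score. Trained strictly on
   out-of-fold layer-1 outputs.
3. **Layer 3** — a seeded random forest that maps the vector of
   per-class combined scores to the final label. Random forests resist
   the class imbalance that makes margin-based arbiters ignore the
   minor oligomer classes.

Evaluation follows the field's conventions: per-class Sn/Sp/ACC (%),
MCC, precision/recall/F-measure, plus multiclass CCI (%), Cohen's
kappa and macro F-measure, under stratified 10-fold cross-validation
(pooled confusion counts) and a self-consistency test.

Because the real block/domain databases and accessibility predictors
are external services, the package ships a seeded synthetic generator
that plants class-specific motifs into random background sequences —
the exact discriminative structure the encoders assume — so the whole
pipeline runs and is tested offline. Real search output can be
injected as precomputed hit lists (`load_precomputed_hits`).

## Worked example

```python
from quatstack import GeneratorSpec, StackConfig, generate_all, encode_features
from quatstack.metrics import cross_validate, self_consistency

spec = GeneratorSpec()  # 6 classes x 60 records, planting probability 0.9, seed 7
block_db, domain_db, records, truth = generate_all(spec)
feats = encode_features(records, block_db=block_db, domain_db=domain_db)
labels = [str(r.label) for r in records]

config = StackConfig(seed=7)  # block+fund stack, 10 folds, 500 trees
cv = cross_validate(feats, labels, config)
sc = self_consistency(feats, labels, config)
print(f"10-fold CV : CCI {cv.cci:.2f}%  Kappa {cv.kappa:.4f}  F-measure {cv.f_measure:.4f}")
print(f"self-cons. : CCI {sc.cci:.2f}%")
worst = min(cv.per_class, key=lambda c: cv.per_class[c].sn)
print(f"weakest class: {worst}  Sn {cv.per_class[worst].sn:.2f}%  MCC {cv.per_class[worst].mcc:.4f}")
```

prints

```
10-fold CV : CCI 98.89%  Kappa 0.9867  F-measure 0.9889
self-cons. : CCI 100.00%
weakest class: homo:4  Sn 96.67%  MCC 0.9799
```

CCI is the percentage of records assigned their true class by the
full stack under cross-validation; kappa corrects that agreement for
chance; the per-class Sn shows that even the hardest class recovers
nearly all of its members. Self-consistency (evaluating on the
training records) is an upper-bound diagnostic and should dominate CV.

The same workflow is available from the shell:

```bash
quatstack simulate --out fixtures --seed 7
quatstack train    --fasta fixtures/sequences.fasta --labels fixtures/labels.tsv \
                   --blocks fixtures/blocks.txt --domains fixtures/domains.txt \
                   --out model --seed 7
quatstack predict  --model model --fasta fixtures/sequences.fasta \
                   --blocks fixtures/blocks.txt --domains fixtures/domains.txt \
                   --out predictions.tsv
quatstack evaluate --fasta fixtures/sequences.fasta --labels fixtures/labels.tsv \
                   --blocks fixtures/blocks.txt --domains fixtures/domains.txt \
                   --out eval --seed 7
```

`curate` (length/unknown filters + greedy identity clustering) and
`encode` (sparse `label idx:val` feature files) complete the toolkit.

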