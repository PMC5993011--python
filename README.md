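# bacprom

Bacterial promoter window extraction and exhaustive SVM grid-search
prediction.

Promoters are the conserved DNA regions where RNA polymerase, guided by
a sigma factor, initiates transcription. In sigma-70-family bacterial
promoters two hexamer boxes carry most of the signal — the −35 element
(consensus `TTGACA`) and the −10 element (consensus `TATAAT`), separated
by a 15–19 nt spacer. `bacprom` is for researchers who have a bacterial
genome plus a curated promoter annotation table (operon, sigma factor,
absolute position, binding sequence — the layout used by *B. subtilis*
regulation databases) and want to (1) turn those annotations into a
clean set of fixed-length promoter sequences and (2) benchmark
support-vector classifiers that tell promoters from genomic background.

## What it does

**Extraction.** Each annotation row is resolved against the genome by
its absolute position first; if the annotated binding sequence is not
found at that anchor, an exact search over both strands is the fallback.
Every resolved record yields an 80 nt window (configurable) whose first
base is the annotated position. Misses and ambiguous (multi-hit) records
are reported, never silently dropped:
`|windows| + |misses| = |records|` on every run.

**Dataset preparation.** Negative examples are constructed
reproducibly — random genome windows that never overlap a promoter, or
dinucleotide-preserving shuffles of the promoters themselves. Sequences
are encoded either position-wise (one-hot, 4 channels per position,
A,C,G,T order) or compositionally (overlapping k-mer frequencies).

**Grid search.** Every combination of SVM formulation (C-SVC, ν-SVC,
one-class, ε-SVR, ν-SVR) and kernel (linear, polynomial, RBF, sigmoid,
precomputed) is evaluated over geometric series of the cost and kernel
width:

    C ∈ {0.00390625 · 16^k : k = 0..6}   (up to 65536)
    γ ∈ {1.52587890625e−5 · 16^k : k = 0..6}   (up to 256)

980 cells in the default grid, each scored by seeded stratified k-fold
cross-validation with pooled confusion counts and

    A  = (TP + TN) / (TP + TN + FP + FN)
    S  = TN / (TN + FP)
    SN = TP / (TP + FN)

Results are ranked (accuracy, then sensitivity, then smaller C and γ)
and exported as CSV; the best cell is refit and persisted with a
sidecar recording its encoding contract.

**Synthetic fixtures.** A generator plants −35/spacer/−10 promoters
into an i.i.d. background genome at any mutation rate and emits the
matching annotation table, so the whole pipeline can be exercised and
benchmarked without downloading anything.

The library is scikit-learn shaped: `DnaOneHotEncoder` /
`KmerFrequencyEncoder` are transformers and `SvmGridSearch` is an
estimator (`fit`, `predict`, `results_`, `best_estimator_`) that
composes with sklearn tooling.

## Worked example

```sh
# 1. a 60 kb genome with 60 planted promoters at 2% motif mutation
bacprom synth --length 60000 --n-promoters 60 --mutation-rate 0.02 \
    --seed 11 --out-dir fixture

# 2. resolve the annotation table against the genome
bacprom extract --genome fixture/genome.fasta \
    --annotations fixture/annotations.tsv --out-dir extracted
# -> extracted 60 windows (0 misses) to extracted

# 3. sweep a reduced grid with sampled negatives, 5-fold CV
bacprom grid --positives extracted/promoters.fasta \
    --genome fixture/genome.fasta \
    --svm-types C_SVC,NU_SVC --kernels LINEAR,RBF \
    --c-min 0.0625 --c-max 16 --c-factor 16 \
    --g-min 0.000244140625 --g-max 0.0625 --g-factor 16 \
    --folds 5 --seed 1 --out-dir sweep
# -> best cell: C_SVC RBF C=0.0625 gamma=0.0625 accuracy=100.00%
```

The ranked results file starts:

```
Type,Kernel,C,G,A,S,SN,TP,TN,FP,FN
C_SVC,RBF,0.0625,0.0625,100.00,100.00,100.00,60,60,0,0
NU_SVC,RBF,0.0625,0.0625,100.00,100.00,100.00,60,60,0,0
```

i.e. the RBF kernel at small C separates the 60 promoter windows from
60 background windows perfectly under 5-fold cross-validation: all 120
held-out examples land in TP or TN, so accuracy (A), specificity (S)
and sensitivity (SN) are all 100.00%. At this low mutation rate the
planted −35/−10 boxes are near-consensus, so perfect separation is the
expected outcome, and the saved `sweep/best_model.joblib` then labels
all 60 training promoters as `promoter`:

```sh
bacprom predict --model sweep/best_model.joblib \
    --sequences extracted/promoters.fasta --out calls.csv
# -> 60/60 promoter calls written to calls.csv
```

Every run writes a `manifest.json`; rerunning any subcommand with the
same inputs and `--seed` reproduces its outputs byte for byte.

## Layout

- `bacprom.sequence_io` — strict FASTA reading/writing, genome container,
  reverse complement, coordinate conventions.
- `bacprom.extraction` — annotation-table parsing and the
  position-first / sequence-fallback window extractor.
- `bacprom.catalog` — the packaged sigma-factor table with the
  sigma-54 / sigma-70 domain grouping.
- `bacprom.dataset` — negative sampling, one-hot and k-mer encoders,
  labeled datasets, sparse LibSVM-format interchange.
- `bacprom.svmgrid` — grid enumeration, cross-validation, metrics,
  ranking, model persistence, results export.
- `bacprom.synth` — the planted-promoter genome generator.
- `bacprom.cli` — the `bacprom` command (`synth`, `extract`, `build`,
  `grid`, `predict`, `report`).

See `docs/methods.md` for the modelling choices and their rationale.
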