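# Methods

This note records the models, conventions and numerical choices behind
`bacprom`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinates and window anchoring

Annotation tables use 1-based inclusive positions, the convention of
curated prokaryotic promoter databases. All internal coordinates are
0-based half-open; the conversion happens exactly once, when a locate
function consumes a record. Windows are anchored so that the annotated
absolute position is the **first base** of the emitted window: a record
at position *p* with window length *L* yields the 1-based span
*p … p+L−1*. Annotation practice varies on where the recorded position
sits relative to the binding site, so the anchor is deliberately the
simplest defensible convention and a signed `anchor_offset` shifts it
when a source uses a different one. The synthetic generator plants the
binding sequence (−35 box + spacer + −10 box) starting exactly at the
annotated position, which makes position lookup and exact sequence
search provably interchangeable on generated data — the basis of the
extraction equivalence tests.

Genomes are treated as linear by default. Bacterial chromosomes are
circular, but annotated promoters essentially never span the origin; a
`circular` flag enables wrap-around slicing for the rare case that one
does.

## Alphabet

Residues are normalised to uppercase `{A, C, G, T, N}` on load.
Degenerate IUPAC codes (R, Y, S, …) are rejected with an error naming
the character and line: every downstream consumer (one-hot encoding,
exact sequence search) assumes an unambiguous 4-letter alphabet, and
silently collapsing degenerate codes would corrupt both. Windows that
contain `N` are excluded from extraction output by default (reported as
misses with reason `ambiguous_base`) for the same reason; a flag keeps
them when only coordinates are needed.

## Extraction policy

Position lookup runs first. It fails softly — returning not-found
rather than raising — when the window would leave a linear genome or
when the record carries a binding sequence that the anchored slice does
not contain (a stale coordinate). The fallback is exact string search,
forward strand then reverse complement, all overlapping occurrences, in
ascending coordinate order. The first usable hit (forward-preferred,
lowest coordinate) defines the window; additional hits are surfaced in
the report's `ambiguous` list instead of being silently discarded or
treated as failure, because an exhaustive batch run must complete while
leaving an audit trail. No mismatch tolerance or degenerate-base
matching is applied: the search is a verification step for curated
sequences, not a motif scanner.

## Negative examples

Promoter/non-promoter classification needs constructed negatives; two
reproducible constructions are provided, both driven by an explicit
seed:

- `random_window` (default): windows drawn uniformly from the genome,
  rejected while they overlap any positive window's coordinates or
  contain `N`. A bounded rejection budget turns pathological inputs
  into a capacity error reporting the achievable count.
- `dinucleotide_shuffle`: each positive shuffled by the Euler-path
  (Altschul–Erickson) method, preserving its exact dinucleotide
  multiset. This controls for composition and neighbour frequencies, so
  only positional motif structure separates the classes.

The default ratio is 1:1 with the positives. Nothing in the annotation
data dictates a particular negative model; both constructions are
declared, seeded and tested rather than inferred.

## Feature encodings

- **One-hot** (default): 4 channels per position in fixed order
  A, C, G, T; feature index `4·i + channel`. Dimension 4·L, row sum
  exactly L. Chosen as the default because the biology of
  sigma-70-family promoters is positional — two boxes at conserved
  offsets — and a position-aware code preserves exactly that signal.
- **k-mer frequencies**: overlapping k-mer counts in lexicographic
  order divided by L−k+1; dimension 4^k, rows sum to 1 within 1e−12.
  The position-free alternative for composition-driven questions.

## The sweep

`GridSpec` defaults mirror the standard libsvm configuration surface:
degree 3, coef0 0, ν 0.5, 100 MB kernel cache, termination tolerance
(ε) 0.001, shrinking on, probability estimates off, unit class weight.
The ε here is the optimizer's stopping tolerance, not the ε-SVR tube
width, which stays at its libsvm default of 0.1. Cost and γ form
geometric series — by default factor 16 from 0.00390625 (2⁻⁸) to 65536
(2¹⁶) and from 1.52587890625e−5 (2⁻¹⁶) to 256 (2⁸), seven values each.
Series endpoints are snapped exactly when the accumulated product lands
within relative tolerance 1e−9; an unreachable maximum is a
specification error, not a silent truncation. The full default grid is
5 formulations × 4 kernels × 7 × 7 = 980 cells; precomputed-kernel
cells are emitted only when a Gram matrix is supplied.

Validation is stratified k-fold cross-validation (default k = 10,
seeded shuffling) with confusion counts pooled over held-out folds.
Design choices for the non-classifier formulations, which a complete
sweep must handle somehow:

- **One-class** cells train on the promoter examples of each training
  fold only and predict the entire held-out fold. On a positives-only
  dataset, specificity has an empty denominator and is reported as
  undefined (`NA` in exports), never coerced to 0.
- **SVR** cells regress on labels encoded 0/1 and classify at
  threshold 0.5.
- Cells whose backend fit raises (e.g. ν infeasible for the class
  ratio) are recorded with a failure flag and ranked last; a sweep
  never aborts mid-grid.

Ranking is by descending accuracy, ties broken by descending
sensitivity, then ascending C and γ (preferring the least complex
model among equals). Identical inputs and seed reproduce the ranked
CSV byte for byte; determinism is part of the contract, bit-identical
decision values across libsvm builds are not. The numeric backend is
scikit-learn's libsvm wrappers.

Metric preconditions: accuracy requires at least one evaluated
example; specificity and sensitivity are reported as undefined when
their denominators are empty.

## Synthetic fixture model

The generator emulates only what the classifier benchmark needs: an
i.i.d. background at a configurable GC fraction (default 0.43,
approximately the *B. subtilis* genomic composition) with promoters
planted at non-overlapping loci, each a mutated `TTGACA`, a spacer of
15–19 nt, and a mutated `TATAAT`, the canonical sigma-70 two-box
geometry. Window placement distributes the free slack multinomially
over inter-window gaps, so packing is exact and a too-small genome is a
capacity error reporting the feasible count.

Two deliberate choices keep the null clean: the spacer is drawn from
the *background* composition (not uniform ACGT), and a mutated position
is redrawn from the background distribution (possibly unchanged) rather
than forced to a different base. Under the different-base model no
mutation rate short of certainty removes the class signal — at rate 0.5
half the box positions still match consensus and a linear probe sits
well above chance — whereas with background-redraw the rate-1.0 limit
makes planted windows statistically identical to background, which the
no-signal tests verify (centroid accuracy ≈ 0.5).

What passing these benchmarks shows: the pipeline is wired correctly,
the sweep finds separating hyperparameters when separation exists, and
every step is reproducible. What it does not show: performance on real
genomes, where promoters overlap genes, composition is non-uniform,
annotations carry errors, and negatives are not i.i.d. background.
Reported benchmark accuracies characterise the fixture, not bacterial
biology.

## Problem sizes

The shipped benchmarks use a 50 kb genome with 20 planted promoters
for extraction checks and a 120 kb genome with 200 promoters plus 200
sampled negatives (one-hot, 320 features) for the classifier sanity
sweep — large enough that the statistics are stable (binomial noise on
400 CV predictions is ≈ 2.5%), small enough that the whole suite runs
in well under a minute on one core. The reduced sanity grid
(C-SVC × {linear, RBF} × 3 C × 3 γ, 5-fold) exercises every code path
of the full 980-cell sweep at a fraction of its cost.

## Known limitations

- Exact-match search only; promoters annotated with degenerate or
  approximate binding sequences will fall through to misses.
- The sigma-factor catalog stores operon counts only and computes no
  percentage shares: the natural denominators (operons vs. identified
  promoters) differ and any single percentage would be ambiguous.
- One-class evaluation on mixed data depends strongly on ν; the
  default 0.5 bounds the training inlier fraction and tends to produce
  low specificity, which is reported as measured.
- The annotation parser accepts TSV/CSV with a small set of header
  aliases; exotic dialects need the explicit delimiter flag.
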