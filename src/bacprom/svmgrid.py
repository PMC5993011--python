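"""Exhaustive support-vector hyperparameter sweep with cross-validation.

The sweep enumerates every combination of SVM formulation (C-SVC,
NU-SVC, ONE-CLASS, EPSILON-SVR, NU-SVR) and kernel (linear, polynomial,
RBF, sigmoid, optionally precomputed) over geometric series of the cost
C and kernel-width gamma.  The default series are

* ``C``: 0.00390625 (2^-8) up to 65536 (2^16) by factors of 16 — 7 values;
* ``gamma``: 1.52587890625e-5 (2^-16) up to 256 (2^8) by factors of 16 — 7 values.

Every grid cell is evaluated by seeded stratified k-fold
cross-validation; confusion counts are pooled over the held-out folds
and summarised as

* accuracy    A  = (TP + TN) / (TP + TN + FP + FN)
* specificity S  = TN / (TN + FP)
* sensitivity SN = TP / (TP + FN)

with TP/TN/FP/FN under standard confusion-matrix semantics
(positive class = promoter).

The numeric backend is scikit-learn's libsvm-based estimators; the
contract is the grid, the CV protocol, the metrics and determinism
under a fixed seed — not bit-identical decision values across libsvm
builds.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR, NuSVC, NuSVR, OneClassSVM

from .dataset import LABEL_NON_PROMOTER, LABEL_PROMOTER, FeatureEncoding, LabeledDataset, encode
from .errors import EncodingMismatchError, GridSpecError

logger = logging.getLogger(__name__)

SVM_TYPES = ("C_SVC", "NU_SVC", "ONE_CLASS", "EPSILON_SVR", "NU_SVR")
KERNELS = ("LINEAR", "POLY", "RBF", "SIGMOID", "PRECOMPUTED")

_SKLEARN_KERNEL = {
    "LINEAR": "linear",
    "POLY": "poly",
    "RBF": "rbf",
    "SIGMOID": "sigmoid",
    "PRECOMPUTED": "precomputed",
}


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter sweep specification.

    The geometric-series endpoints and factor, and the fixed libsvm
    defaults (degree 3, coef0 0, nu 0.5, 100 MB cache, termination
    tolerance 0.001, shrinking on, probability off, unit class weight),
    follow the standard libsvm configuration surface.
    """

    svm_types: tuple[str, ...] = SVM_TYPES
    kernels: tuple[str, ...] = KERNELS
    c_min: float = 0.00390625
    c_max: float = 65536.0
    c_factor: float = 16.0
    g_min: float = 1.52587890625e-5
    g_max: float = 256.0
    g_factor: float = 16.0
    degree: int = 3
    coef0: float = 0.0
    nu: float = 0.5
    cache_mb: float = 100.0
    epsilon: float = 0.001  # termination tolerance (libsvm -e)
    shrinking: bool = True
    probability: bool = False
    class_weight: float = 1.0

    def __post_init__(self):
        for t in self.svm_types:
            if t not in SVM_TYPES:
                raise GridSpecError(f"unknown svm type {t!r}")
        for k in self.kernels:
            if k not in KERNELS:
                raise GridSpecError(f"unknown kernel {k!r}")
        if not self.svm_types or not self.kernels:
            raise GridSpecError("svm_types and kernels must be non-empty")
        if self.c_min > self.c_max or self.g_min > self.g_max:
            raise GridSpecError("series minimum exceeds maximum")
        if min(self.c_min, self.g_min) <= 0:
            raise GridSpecError("series endpoints must be positive")
        if (self.c_min < self.c_max and self.c_factor <= 1) or (
            self.g_min < self.g_max and self.g_factor <= 1
        ):
            raise GridSpecError("multiplicative factors must exceed 1")

    @property
    def c_values(self) -> tuple[float, ...]:
        return geometric_series(self.c_min, self.c_max, self.c_factor)

    @property
    def g_values(self) -> tuple[float, ...]:
        return geometric_series(self.g_min, self.g_max, self.g_factor)


def geometric_series(vmin: float, vmax: float, factor: float,
                     rtol: float = 1e-9) -> tuple[float, ...]:
    """``vmin, vmin*factor, ...`` ending exactly at ``vmax``.

    The final element is snapped to ``vmax`` when it lands within
    relative tolerance ``rtol``; an unreachable ``vmax`` is a
    :class:`~bacprom.errors.GridSpecError`.
    """
    if vmin == vmax:
        return (vmin,)
    values = [vmin]
    v = vmin
    while v < vmax and not np.isclose(v, vmax, rtol=rtol, atol=0):
        v = v * factor
        values.append(v)
        if len(values) > 10_000:
            raise GridSpecError("geometric series did not terminate")
    if not np.isclose(values[-1], vmax, rtol=rtol, atol=0):
        raise GridSpecError(
            f"maximum {vmax} not reachable from {vmin} by factor {factor}"
        )
    values[-1] = vmax  # snap the endpoint exactly
    return tuple(values)


class GridCell(NamedTuple):
    svm_type: str
    kernel: str
    c: float
    gamma: float


def make_parameter_grid(spec: GridSpec, has_gram: bool = False) -> list[GridCell]:
    """Cartesian product types x kernels x C x gamma, deterministically ordered.

    PRECOMPUTED kernel cells are emitted only when a Gram matrix is
    supplied (``has_gram``); otherwise they are skipped with a notice.
    """
    kernels = list(spec.kernels)
    if "PRECOMPUTED" in kernels and not has_gram:
        kernels = [k for k in kernels if k != "PRECOMPUTED"]
        logger.info("PRECOMPUTED kernel skipped: no Gram matrix supplied")
    cells = []
    for t in spec.svm_types:
        for k in kernels:
            for c in spec.c_values:
                for g in spec.g_values:
                    cells.append(GridCell(t, k, c, g))
    if not cells:
        raise GridSpecError("empty parameter grid")
    return cells


# -- confusion counts and metrics --------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics(counts: ConfusionCounts) -> tuple[float, float | None, float | None]:
    """Accuracy, specificity, sensitivity from pooled confusion counts.

    Specificity is undefined (``None``) when no true negatives or false
    positives exist, and sensitivity likewise when no positives were
    evaluated — undefined, not zero.
    """
    if counts.total == 0:
        raise ValueError("metrics require at least one evaluated example")
    accuracy = (counts.tp + counts.tn) / counts.total
    specificity = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else None
    sensitivity = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    return accuracy, specificity, sensitivity


@dataclass(frozen=True)
class EvaluationResult:
    """One evaluated grid cell: parameters, pooled counts, metrics."""

    svm_type: str
    kernel: str
    c: float
    gamma: float
    counts: ConfusionCounts | None
    accuracy: float | None
    specificity: float | None
    sensitivity: float | None
    folds: int
    seed: int
    failed: bool = False
    error: str = ""

    @property
    def cell(self) -> GridCell:
        return GridCell(self.svm_type, self.kernel, self.c, self.gamma)


# -- estimator construction ---------------------------------------------------

def build_estimator(cell: GridCell, spec: GridSpec | None = None):
    """Instantiate the libsvm-backed estimator for one grid cell."""
    spec = spec or GridSpec()
    kernel = _SKLEARN_KERNEL[cell.kernel]
    common = dict(
        kernel=kernel, gamma=cell.gamma, degree=spec.degree, coef0=spec.coef0,
        tol=spec.epsilon, cache_size=spec.cache_mb, shrinking=spec.shrinking,
    )
    # `probability` is only forwarded when enabled: recent scikit-learn
    # deprecates passing it explicitly, and the sweep default is off.
    prob = {"probability": True} if spec.probability else {}
    if cell.svm_type == "C_SVC":
        return SVC(C=cell.c, **prob, **common)
    if cell.svm_type == "NU_SVC":
        return NuSVC(nu=spec.nu, **prob, **common)
    if cell.svm_type == "ONE_CLASS":
        return OneClassSVM(nu=spec.nu, **common)
    if cell.svm_type == "EPSILON_SVR":
        return SVR(C=cell.c, **common)  # tube epsilon stays the libsvm default 0.1
    if cell.svm_type == "NU_SVR":
        return NuSVR(C=cell.c, nu=spec.nu, **common)
    raise GridSpecError(f"unknown svm type {cell.svm_type!r}")


def _predict_binary(estimator, cell: GridCell, X: np.ndarray) -> np.ndarray:
    """Map a fitted estimator's output onto {0,1} promoter labels."""
    if cell.svm_type == "ONE_CLASS":
        raw = estimator.predict(X)  # +1 inlier / -1 outlier
        return (raw > 0).astype(int)
    if cell.svm_type in ("EPSILON_SVR", "NU_SVR"):
        return (estimator.predict(X) >= 0.5).astype(int)
    return estimator.predict(X).astype(int)


def _fit_cell(estimator, cell: GridCell, X: np.ndarray, y: np.ndarray):
    if cell.svm_type == "ONE_CLASS":
        estimator.fit(X[y == 1])
    elif cell.svm_type in ("EPSILON_SVR", "NU_SVR"):
        estimator.fit(X, y.astype(float))
    else:
        estimator.fit(X, y)
    return estimator


def cross_validate(
    cell: GridCell,
    dataset: LabeledDataset | tuple[np.ndarray, np.ndarray],
    folds: int = 10,
    seed: int = 0,
    spec: GridSpec | None = None,
) -> EvaluationResult:
    """Evaluate one grid cell by seeded stratified k-fold CV.

    Fold assignment is stratified and shuffled under ``seed``;
    confusion counts are pooled over the held-out folds.  ONE_CLASS
    cells train on the promoter examples of each training fold only and
    predict the full held-out fold.  SVR cells regress on labels
    encoded 0/1 and classify at threshold 0.5.  Cells whose backend fit
    raises (e.g. an infeasible nu for the class ratio) come back with
    ``failed=True`` rather than aborting the sweep.
    """
    if isinstance(dataset, LabeledDataset):
        X, y = dataset.features, dataset.y
    else:
        X, y = dataset
        y = np.asarray(y).astype(int)
    classes, counts_per_class = np.unique(y, return_counts=True)
    if len(classes) < 2 and cell.svm_type != "ONE_CLASS":
        raise ValueError(
            f"{cell.svm_type} requires both classes; dataset has only {classes.tolist()}"
        )
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if counts_per_class.min() < folds:
        raise ValueError(
            f"folds={folds} exceeds the minority class size {counts_per_class.min()}"
        )
    if len(classes) < 2:
        # positives-only one-class evaluation: stratification is moot
        skf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    try:
        for train_idx, test_idx in skf.split(X, y):
            est = build_estimator(cell, spec)
            _fit_cell(est, cell, X[train_idx], y[train_idx])
            pred = _predict_binary(est, cell, X[test_idx])
            truth = y[test_idx]
            tp += int(np.sum((pred == 1) & (truth == 1)))
            tn += int(np.sum((pred == 0) & (truth == 0)))
            fp += int(np.sum((pred == 1) & (truth == 0)))
            fn += int(np.sum((pred == 0) & (truth == 1)))
    except (ValueError, ArithmeticError) as exc:
        return EvaluationResult(
            svm_type=cell.svm_type, kernel=cell.kernel, c=cell.c, gamma=cell.gamma,
            counts=None, accuracy=None, specificity=None, sensitivity=None,
            folds=folds, seed=seed, failed=True, error=str(exc),
        )
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    accuracy, specificity, sensitivity = metrics(counts)
    return EvaluationResult(
        svm_type=cell.svm_type, kernel=cell.kernel, c=cell.c, gamma=cell.gamma,
        counts=counts, accuracy=accuracy, specificity=specificity,
        sensitivity=sensitivity, folds=folds, seed=seed,
    )


def rank_results(results: Sequence[EvaluationResult]) -> list[EvaluationResult]:
    """Rank by descending accuracy, then descending sensitivity, then
    ascending C, then ascending gamma; failed cells sort last."""
    def key(r: EvaluationResult):
        return (
            r.failed,
            -(r.accuracy if r.accuracy is not None else -1.0),
            -(r.sensitivity if r.sensitivity is not None else -1.0),
            r.c,
            r.gamma,
        )
    return sorted(results, key=key)


class SvmGridSearch(BaseEstimator, ClassifierMixin):
    """Exhaustive SVM-formulation/kernel/C/gamma sweep as an estimator.

    scikit-learn conventions: construct with hyperparameters, ``fit``
    on a numeric feature matrix ``X`` and binary labels ``y``
    (promoter=1), then inspect ``results_`` (ranked
    :class:`EvaluationResult` list), ``best_result_``, ``best_cell_``
    and predict with the refit ``best_estimator_``.

    Parameters
    ----------
    spec : GridSpec, optional
        Sweep specification; the full default grid (5 formulations,
        4 usable kernels, 7 C values, 7 gamma values = 980 cells) when
        omitted.
    folds : int
        Stratified CV folds (default 10).
    seed : int
        Seed for fold shuffling; fixes the sweep end to end.
    refit : bool
        Refit the best cell on the full data after the sweep.
    """

    def __init__(self, spec: GridSpec | None = None, folds: int = 10,
                 seed: int = 0, refit: bool = True):
        self.spec = spec
        self.folds = folds
        self.seed = seed
        self.refit = refit

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        y = y.astype(int)
        spec = self.spec or GridSpec()
        cells = make_parameter_grid(spec)
        results = []
        for cell in cells:
            results.append(cross_validate(cell, (X, y), self.folds, self.seed, spec))
        self.results_ = rank_results(results)
        self.best_result_ = self.results_[0]
        self.best_cell_ = self.best_result_.cell
        self.classes_ = np.array([0, 1])
        if self.refit and not self.best_result_.failed:
            est = build_estimator(self.best_cell_, spec)
            self.best_estimator_ = _fit_cell(est, self.best_cell_, X, y)
        return self

    def predict(self, X):
        if not hasattr(self, "best_estimator_"):
            raise ValueError("SvmGridSearch is not fitted (or refit was disabled)")
        X = np.asarray(X, dtype=np.float64)
        return _predict_binary(self.best_estimator_, self.best_cell_, X)


def grid_search(
    dataset: LabeledDataset,
    spec: GridSpec | None = None,
    folds: int = 10,
    seed: int = 0,
) -> list[EvaluationResult]:
    """Sweep every grid cell on a labeled dataset; ranked results."""
    search = SvmGridSearch(spec=spec, folds=folds, seed=seed, refit=False)
    search.fit(dataset.features, dataset.y)
    return search.results_


# -- final model and persistence ----------------------------------------------

@dataclass
class PromoterModel:
    """A trained promoter classifier plus the encoding it expects."""

    estimator: object
    cell: GridCell
    encoding: FeatureEncoding
    window_length: int


def train_final(
    cell: GridCell,
    dataset: LabeledDataset,
    spec: GridSpec | None = None,
) -> PromoterModel:
    """Fit one grid cell on the full dataset for downstream prediction."""
    est = build_estimator(cell, spec)
    _fit_cell(est, cell, dataset.features, dataset.y)
    return PromoterModel(
        estimator=est, cell=cell, encoding=dataset.encoding,
        window_length=dataset.window_length(),
    )


def predict(model: PromoterModel, sequences: Sequence[str],
            encoding: FeatureEncoding | None = None) -> list[str]:
    """Classify sequences with a trained model.

    The caller's encoding descriptor (when given) must match the one
    the model was trained under; a mismatch is a contract error naming
    both descriptors.
    """
    if encoding is not None and encoding != model.encoding:
        raise EncodingMismatchError(
            f"model was trained with {model.encoding.describe()} but input is "
            f"{encoding.describe()}"
        )
    seqs = list(sequences)
    if any(len(s) != model.window_length for s in seqs):
        raise EncodingMismatchError(
            f"model expects windows of length {model.window_length}; got lengths "
            f"{sorted({len(s) for s in seqs})}"
        )
    X = encode(seqs, model.encoding)
    pred = _predict_binary(model.estimator, model.cell, X)
    return [LABEL_PROMOTER if p == 1 else LABEL_NON_PROMOTER for p in pred]


def save_model(model: PromoterModel, path: str | Path) -> None:
    """Persist a model: backend-native dump plus a JSON sidecar recording
    the encoding scheme, window length, k and grid cell."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "cell": {"svm_type": model.cell.svm_type, "kernel": model.cell.kernel,
                 "c": model.cell.c, "gamma": model.cell.gamma},
        "encoding": {"scheme": model.encoding.scheme,
                     "window_length": model.encoding.window_length,
                     "k": model.encoding.k},
        "window_length": model.window_length,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def load_model(path: str | Path) -> PromoterModel:
    path = Path(path)
    estimator = joblib.load(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cell = GridCell(**sidecar["cell"])
    enc = sidecar["encoding"]
    encoding = FeatureEncoding(scheme=enc["scheme"],
                               window_length=enc["window_length"], k=enc["k"])
    return PromoterModel(estimator=estimator, cell=cell, encoding=encoding,
                         window_length=sidecar["window_length"])


# -- results export -----------------------------------------------------------

RESULTS_HEADER = ["Type", "Kernel", "C", "G", "A", "S", "SN", "TP", "TN", "FP", "FN"]


def _fmt_pct(value: float | None) -> str:
    return "NA" if value is None else f"{100.0 * value:.2f}"


def export_results(results: Sequence[EvaluationResult], path: str | Path) -> None:
    """Write ranked results as CSV.

    Columns: Type, Kernel, C, G, A, S, SN (percentages, 2 decimals;
    ``NA`` when undefined) plus the pooled TP/TN/FP/FN counts.
    """
    if not results:
        raise ValueError("no results to export")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_HEADER)
        for r in results:
            counts = r.counts
            writer.writerow([
                r.svm_type, r.kernel, repr(r.c), repr(r.gamma),
                _fmt_pct(r.accuracy), _fmt_pct(r.specificity), _fmt_pct(r.sensitivity),
                counts.tp if counts else "NA", counts.tn if counts else "NA",
                counts.fp if counts else "NA", counts.fn if counts else "NA",
            ])


def read_results(path: str | Path) -> list[dict]:
    """Re-parse an exported results CSV (numbers at printed precision)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            parsed = dict(row)
            parsed["C"] = float(row["C"])
            parsed["G"] = float(row["G"])
            for col in ("A", "S", "SN"):
                parsed[col] = None if row[col] == "NA" else float(row[col])
            for col in ("TP", "TN", "FP", "FN"):
                parsed[col] = None if row[col] == "NA" else int(row[col])
            rows.append(parsed)
    return rows
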