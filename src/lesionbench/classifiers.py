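"""Nine supervised voxel classifiers behind one fit / predict-probability contract.

Algorithms and tuning grids:

=====================  ==============================================
logistic_regression    unpenalized MLE, no tuning
lda                    linear discriminant analysis, no tuning
qda                    quadratic discriminant analysis, no tuning
gaussian_mixture       per-class mixtures, components/covariance by BIC
svm_linear             linear SVM, cost in {1/8, 1/4, 1/2, 1, 2, 4, 8}
random_forest          500 trees, mtry in 1..d (d = feature dimension)
knn                    k in {1, 10, 100}
neural_net             one hidden layer, size in {1, 5, 10}
super_learner          convex stack of every grid point of the above
=====================  ==============================================

Tuning values are selected by 10-fold stratified cross-validation, scoring
each grid point by the held-out scaled partial AUC at FPR <= 10% (the
benchmark's outcome metric), then refit on all rows.

The super learner is implemented from scratch: the library enumerates every
(algorithm, tuning value) pair; a cross-validation loop produces held-out
("level-one") probability predictions for every library member; the member
weights solve a non-negative least-squares regression of the labels on the
level-one matrix and are renormalized onto the simplex; finally every
member is refit on the full training set.  Predictions are the convex
combination of member probabilities.
"""

from __future__ import annotations

import time
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .evaluation import roc_curve, scaled_pauc
from .features import FeatureMatrix

ALGORITHM_NAMES = (
    "logistic_regression",
    "lda",
    "qda",
    "gaussian_mixture",
    "svm_linear",
    "random_forest",
    "knn",
    "neural_net",
    "super_learner",
)
BASE_ALGORITHM_NAMES = ALGORITHM_NAMES[:-1]

SVM_COSTS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
RF_N_TREES = 500
KNN_KS = (1, 10, 100)
NN_SIZES = (1, 5, 10)
_TUNING_FPR_MAX = 0.10


def _derive_seed(seed: int, label: str) -> int:
    tag = zlib.crc32(label.encode())
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class TuningGrid:
    """Candidate tuning values for one algorithm (empty for default fits)."""

    points: tuple[dict, ...]

    @staticmethod
    def for_algorithm(name: str, dimension: int) -> "TuningGrid":
        if name == "svm_linear":
            pts = tuple({"cost": c} for c in SVM_COSTS)
        elif name == "random_forest":
            pts = tuple({"mtry": m} for m in range(1, dimension + 1))
        elif name == "knn":
            pts = tuple({"k": k} for k in KNN_KS)
        elif name == "neural_net":
            pts = tuple({"size": s} for s in NN_SIZES)
        elif name in ALGORITHM_NAMES:
            pts = ({},)
        else:
            raise ValueError(f"unknown algorithm {name!r}")
        return TuningGrid(points=pts)


@dataclass(frozen=True)
class AlgorithmSpec:
    name: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise ValueError(f"unknown algorithm {self.name!r}; expected one of {ALGORITHM_NAMES}")


# ---------------------------------------------------------------------------
# learner wrappers: fit(X, y) / predict_proba1(X) -> P(lesion)
# ---------------------------------------------------------------------------

class _SkLearner:
    """Adapter around a scikit-learn probabilistic classifier."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SkLearner":
        self.estimator.fit(X, y)
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        classes = self.estimator.classes_
        p = self.estimator.predict_proba(X)
        pos = np.flatnonzero(classes == 1)
        if pos.size == 0:
            return np.zeros(len(X))
        return p[:, int(pos[0])]


class _PlattLinearSVM:
    """Linear SVM with Platt-style logistic calibration of decision values.

    The 1-D calibration logistic keeps a mild L2 penalty so it stays finite
    when the decision values are separable; the calibrated probabilities are
    monotone in the margin, so rank-based metrics are unaffected.
    """

    def __init__(self, cost: float, seed: int = 0):
        self.cost = cost
        self.svc = LinearSVC(C=cost, dual=False)
        self.calibrator = LogisticRegression(max_iter=1000)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PlattLinearSVM":
        self.svc.fit(X, y)
        d = self.svc.decision_function(X).reshape(-1, 1)
        self.calibrator.fit(d, y)
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        d = self.svc.decision_function(X).reshape(-1, 1)
        classes = self.calibrator.classes_
        return self.calibrator.predict_proba(d)[:, int(np.flatnonzero(classes == 1)[0])]


class GaussianMixtureClassifier:
    """Per-class Gaussian mixtures with BIC model search.

    For each class a mixture is fit for every combination of component count
    (1..max_components, capped by class size) and covariance model
    (spherical, diagonal, full); the lowest-BIC fit is retained.  Posterior
    class probabilities combine the class-conditional densities with the
    empirical class priors via Bayes' rule.
    """

    def __init__(self, seed: int = 0, max_components: int = 9,
                 covariance_types: tuple[str, ...] = ("spherical", "diag", "full")):
        self.seed = seed
        self.max_components = max_components
        self.covariance_types = covariance_types
        self.mixtures_: dict[int, GaussianMixture] = {}
        self.log_priors_: dict[int, float] = {}
        self.classes_: np.ndarray | None = None

    @staticmethod
    def _identifiable(n_samples: int, n_comp: int, d: int, cov: str) -> bool:
        # require enough samples per component to pin down the covariance,
        # else BIC rewards degenerate spikes with absurd densities
        if cov == "full":
            return n_samples >= n_comp * (d + 2)
        if cov == "diag":
            return n_samples >= n_comp * 3
        return n_samples >= n_comp * 2

    def _search(self, Xc: np.ndarray) -> GaussianMixture:
        d = Xc.shape[1]
        n_max = max(1, min(self.max_components, len(Xc) // 8))
        best, best_bic = None, np.inf
        for cov in self.covariance_types:
            for n in range(1, n_max + 1):
                if not self._identifiable(len(Xc), n, d, cov):
                    continue
                # features are z-scored (unit scale), so 1e-3 is a mild floor
                gm = GaussianMixture(n_components=n, covariance_type=cov,
                                     reg_covar=1e-3, random_state=self.seed,
                                     max_iter=200)
                try:
                    gm.fit(Xc)
                except ValueError:
                    continue
                bic = gm.bic(Xc)
                if bic < best_bic:
                    best, best_bic = gm, bic
        if best is None:  # tiny class: spherical 1-component fallback
            best = GaussianMixture(1, covariance_type="spherical",
                                   reg_covar=1e-2, random_state=self.seed)
            best.fit(np.vstack([Xc, Xc]))
        return best

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianMixtureClassifier":
        self.classes_ = np.unique(y)
        n = len(y)
        for c in self.classes_:
            Xc = X[y == c]
            self.mixtures_[int(c)] = self._search(Xc)
            self.log_priors_[int(c)] = np.log(len(Xc) / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logp = np.column_stack([
            self.mixtures_[int(c)].score_samples(X) + self.log_priors_[int(c)]
            for c in self.classes_
        ])
        # posterior via clipped log space: extreme density ratios saturate
        # instead of underflowing into rank-destroying exact ties
        logp = np.clip(logp - logp.max(axis=1, keepdims=True), -700.0, 0.0)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        pos = np.flatnonzero(self.classes_ == 1)
        if pos.size == 0:
            return np.zeros(len(X))
        return self.predict_proba(X)[:, int(pos[0])]


def make_learner(name: str, params: dict, seed: int = 0):
    """Instantiate an unfitted learner for one (algorithm, grid point)."""
    if name == "logistic_regression":
        # unpenalized maximum likelihood at GLM-like convergence tightness
        return _SkLearner(LogisticRegression(C=np.inf, max_iter=2000, tol=1e-8))
    if name == "lda":
        return _SkLearner(LinearDiscriminantAnalysis())
    if name == "qda":
        # small ridge keeps class covariances invertible at low lesion counts
        return _SkLearner(QuadraticDiscriminantAnalysis(reg_param=1e-3))
    if name == "gaussian_mixture":
        return GaussianMixtureClassifier(seed=seed)
    if name == "svm_linear":
        return _PlattLinearSVM(cost=params["cost"], seed=seed)
    if name == "random_forest":
        return _SkLearner(RandomForestClassifier(
            n_estimators=RF_N_TREES, max_features=params["mtry"],
            random_state=seed, n_jobs=1))
    if name == "knn":
        return _SkLearner(KNeighborsClassifier(n_neighbors=params["k"]))
    if name == "neural_net":
        return _SkLearner(MLPClassifier(
            hidden_layer_sizes=(params["size"],), activation="logistic",
            max_iter=200, random_state=seed))
    raise ValueError(f"no learner for algorithm {name!r}")


# ---------------------------------------------------------------------------
# fitting with cross-validated tuning
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    spec: AlgorithmSpec
    chosen_params: dict
    model_state: object
    columns: list[str]
    training_summary: dict = field(default_factory=dict)


def _check_trainable(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(y) < folds:
        raise ValueError(f"{len(y)} rows is fewer than {folds} folds")


@dataclass
class _LibEntry:
    algorithm: str
    params: dict
    label: str
    factory: Callable[[], object]
    fit_seconds: float = 0.0


def _algorithm_entries(name: str, dimension: int, seed: int) -> list[_LibEntry]:
    entries = []
    for params in TuningGrid.for_algorithm(name, dimension).points:
        label = name if not params else (
            name + "[" + ",".join(f"{k}={v}" for k, v in sorted(params.items())) + "]")
        sub = _derive_seed(seed, label)
        entries.append(_LibEntry(
            algorithm=name, params=dict(params), label=label,
            factory=(lambda n=name, p=dict(params), s=sub: make_learner(n, p, s))))
    return entries


def _feasible(entry: _LibEntry, min_train: int) -> bool:
    if entry.algorithm == "knn" and entry.params.get("k", 0) > min_train:
        warnings.warn(
            f"knn grid point k={entry.params['k']} exceeds fold training size "
            f"{min_train}; skipped")
        return False
    return True


def _level_one(entries, X, y, splits, active=None) -> np.ndarray:
    """Held-out fold predictions for every active library entry (rows x entries)."""
    Z = np.zeros((len(y), len(entries)))
    for tr, te in splits:
        for j, entry in enumerate(entries):
            if active is not None and not active[j]:
                continue
            t0 = time.perf_counter()
            learner = entry.factory()
            learner.fit(X[tr], y[tr])
            Z[te, j] = np.clip(learner.predict_proba1(X[te]), 0.0, 1.0)
            entry.fit_seconds += time.perf_counter() - t0
    return Z


def _fold_scores(Z: np.ndarray, y: np.ndarray, splits) -> np.ndarray:
    """Mean held-out scaled pAUC per entry, averaged over two-class folds."""
    per_entry = []
    for j in range(Z.shape[1]):
        vals = [scaled_pauc(roc_curve(Z[te, j], y[te]), _TUNING_FPR_MAX)
                for _, te in splits if len(np.unique(y[te])) == 2]
        per_entry.append(float(np.mean(vals)) if vals else -np.inf)
    return np.asarray(per_entry)


def _nnls_weights(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    w, _ = nnls(Z, y.astype(float))
    total = w.sum()
    if total <= 0:
        warnings.warn("NNLS returned all-zero weights; falling back to uniform")
        return np.full(Z.shape[1], 1.0 / Z.shape[1])
    return w / total


def fit_suite(
    algorithms: Sequence[str],
    features: FeatureMatrix,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, FittedModel]:
    """Fit several algorithms on one training matrix, sharing the CV work.

    Tuning for gridded algorithms and the super learner's level-one matrix
    use the same stratified fold predictions, so each (algorithm, grid
    point) is fit exactly once per fold and refit exactly once on the full
    data; the refit learners are shared between the tuned models and the
    super-learner library.
    """
    for name in algorithms:
        AlgorithmSpec(name)  # validates
    X = features.X.to_numpy(dtype=float)
    y = np.asarray(features.y, dtype=int)
    _check_trainable(y, folds)
    d = X.shape[1]
    need_sl = "super_learner" in algorithms
    base_requested = [n for n in algorithms if n != "super_learner"]
    lib_names = list(BASE_ALGORITHM_NAMES) if need_sl else []
    for n in base_requested:
        if n not in lib_names:
            lib_names.append(n)

    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=_derive_seed(seed, "cv"))
    splits = list(skf.split(X, y))
    min_train = min(len(tr) for tr, _ in splits)

    entries: list[_LibEntry] = []
    for name in lib_names:
        entries.extend(e for e in _algorithm_entries(name, d, seed)
                       if _feasible(e, min_train))
    by_alg: dict[str, list[int]] = {}
    for j, e in enumerate(entries):
        by_alg.setdefault(e.algorithm, []).append(j)
    for name in lib_names:
        if not by_alg.get(name):
            raise ValueError(f"no feasible grid point for {name}")

    # fold predictions are needed for gridded tuning and for the super learner
    active = [need_sl or len(by_alg[e.algorithm]) > 1 for e in entries]
    if any(active):
        Z = _level_one(entries, X, y, splits, active)
        scores = _fold_scores(Z, y, splits)
    else:
        Z = np.zeros((len(y), len(entries)))
        scores = np.zeros(len(entries))

    refits: dict[str, object] = {}
    refit_seconds: dict[str, float] = {}

    def refit(entry: _LibEntry):
        if entry.label not in refits:
            t0 = time.perf_counter()
            learner = entry.factory()
            learner.fit(X, y)
            refits[entry.label] = learner
            refit_seconds[entry.label] = time.perf_counter() - t0
        return refits[entry.label]

    summary_base = {"n_rows": len(y),
                    "class_counts": {int(c): int(n) for c, n in
                                     zip(*np.unique(y, return_counts=True))}}
    models: dict[str, FittedModel] = {}
    for name in base_requested:
        idx = by_alg[name]
        if len(idx) == 1:
            j = idx[0]
        else:
            # ties broken toward the earlier grid point
            j = idx[int(np.argmax(scores[idx]))]
        entry = entries[j]
        learner = refit(entry)
        summary = dict(summary_base)
        if len(idx) > 1:
            summary["cv_scores"] = {entries[i].label: float(scores[i]) for i in idx}
        summary["fit_seconds"] = entry.fit_seconds + refit_seconds[entry.label]
        models[name] = FittedModel(
            spec=AlgorithmSpec(name, seed=seed), chosen_params=entry.params,
            model_state=learner, columns=features.columns,
            training_summary=summary)

    if need_sl:
        w = _nnls_weights(Z, y)
        base_models = [refit(e) if w[j] > 0 else None
                       for j, e in enumerate(entries)]
        # zero-weight members never contribute to predictions; keep labels
        sl = SuperLearnerFit(labels=[e.label for e in entries], weights=w,
                             level_one=Z,
                             base_models=base_models,
                             columns=features.columns)
        cv_time = sum(e.fit_seconds for e in entries) + sum(refit_seconds.values())
        models["super_learner"] = FittedModel(
            spec=AlgorithmSpec("super_learner", seed=seed), chosen_params={},
            model_state=sl, columns=features.columns,
            training_summary={**summary_base, "library_size": len(entries),
                              "fit_seconds": cv_time})
    return models


def fit(spec: AlgorithmSpec, features: FeatureMatrix, folds: int = 10) -> FittedModel:
    """Tune (where applicable) by stratified CV on held-out scaled pAUC, refit on all rows."""
    return fit_suite([spec.name], features, folds=folds, seed=spec.seed)[spec.name]


def _check_columns(columns: list[str], features: FeatureMatrix) -> None:
    if features.columns != columns:
        raise ValueError(
            f"feature columns {features.columns} do not match training columns {columns}")


def predict_proba(model: FittedModel, features: FeatureMatrix) -> np.ndarray:
    """Per-row lesion probability in [0, 1] from a fitted model."""
    _check_columns(model.columns, features)
    if isinstance(model.model_state, SuperLearnerFit):
        return superlearner_predict(model.model_state, features)
    p = model.model_state.predict_proba1(features.X.to_numpy(dtype=float))
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# super learner
# ---------------------------------------------------------------------------

LearnerFactory = Callable[[], object]


@dataclass
class SuperLearnerFit:
    labels: list[str]
    weights: np.ndarray
    level_one: np.ndarray
    base_models: list[object]
    columns: list[str]


def _expand_library(
    library: Sequence, dimension: int, seed: int
) -> list[tuple[str, LearnerFactory]]:
    """Expand names to one library member per (algorithm, grid point).

    Entries may be algorithm names (expanded over their tuning grid) or
    ``(label, factory)`` pairs supplying a custom learner.
    """
    entries: list[tuple[str, LearnerFactory]] = []
    for item in library:
        if isinstance(item, AlgorithmSpec):
            item = item.name
        if isinstance(item, str):
            for params in TuningGrid.for_algorithm(item, dimension).points:
                label = item if not params else (
                    item + "[" + ",".join(f"{k}={v}" for k, v in sorted(params.items())) + "]")
                sub = _derive_seed(seed, label)
                entries.append((label, (lambda n=item, p=dict(params), s=sub: make_learner(n, p, s))))
        else:
            label, factory = item
            entries.append((str(label), factory))
    if not entries:
        raise ValueError("super learner library is empty")
    return entries


def superlearner_fit(
    library: Sequence,
    features: FeatureMatrix,
    folds: int = 10,
    seed: int = 0,
) -> SuperLearnerFit:
    """Cross-validated stacking with NNLS meta-learning on the simplex."""
    X = features.X.to_numpy(dtype=float)
    y = np.asarray(features.y, dtype=int)
    _check_trainable(y, folds)
    entries = _expand_library(library, X.shape[1], seed)

    # drop knn members whose k exceeds the smallest CV training fold
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=_derive_seed(seed, "sl-cv"))
    splits = list(skf.split(X, y))
    min_train = min(len(tr) for tr, _ in splits)
    kept = []
    for label, factory in entries:
        if label.startswith("knn[") or label == "knn":
            probe = factory()
            k = getattr(getattr(probe, "estimator", None), "n_neighbors", None)
            if k is not None and k > min_train:
                warnings.warn(f"super learner drops {label}: k exceeds fold size {min_train}")
                continue
        kept.append((label, factory))
    entries = kept
    if not entries:
        raise ValueError("no feasible library members")

    Z = np.zeros((len(y), len(entries)))
    for tr, te in splits:
        for j, (_, factory) in enumerate(entries):
            learner = factory()
            learner.fit(X[tr], y[tr])
            Z[te, j] = np.clip(learner.predict_proba1(X[te]), 0.0, 1.0)

    w = _nnls_weights(Z, y)

    base_models = []
    for _, factory in entries:
        learner = factory()
        learner.fit(X, y)
        base_models.append(learner)

    return SuperLearnerFit(labels=[lab for lab, _ in entries], weights=w,
                           level_one=Z, base_models=base_models,
                           columns=features.columns)


def superlearner_predict(fit: SuperLearnerFit, features: FeatureMatrix) -> np.ndarray:
    """Convex combination of base-model probabilities."""
    _check_columns(fit.columns, features)
    X = features.X.to_numpy(dtype=float)
    out = np.zeros(len(X))
    for w, model in zip(fit.weights, fit.base_models):
        if w > 0:
            out += w * np.clip(model.predict_proba1(X), 0.0, 1.0)
    # weights on the simplex keep the combination in [0, 1]
    return np.clip(out, 0.0, 1.0)
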