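"""Experiment orchestration: the algorithm x feature-vector comparison,
training-set downsampling, and super-learner weight tracking.

The benchmark splits a cohort into disjoint training and validation
subjects, fits every classifier on a modest per-subject sample of training
voxels, then scores *every* brain-tissue voxel of every validation subject.
Voxels excluded by the candidate-selection step receive probability 0, so
validation always covers the whole brain.  ROC curves are pooled over all
validation voxels across subjects; binary segmentations are thresholded at
a pooled FPR of 0.5% for Dice agreement.

The default configuration is desk-scale (10 train / 10 validation subjects
on 64^3 grids, 500 sampled voxels per subject, downsampling grid
1,000..5,000); a full-scale 49/49 configuration with a 1,000..24,000 grid
is a matter of changing the config fields.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifiers, evaluation
from .classifiers import ALGORITHM_NAMES, SuperLearnerFit
from .features import (
    FEATURE_KIND_NAMES,
    FeatureMatrix,
    FeatureParams,
    assemble_features,
    derive_volumes,
)
from .preprocessing import add_brain_mask
from .synthetic import MultimodalStudy


@dataclass(frozen=True)
class ExperimentConfig:
    n_train: int = 10
    n_validation: int = 10
    voxels_per_subject: int = 500
    folds: int = 10
    fpr_max: float = 0.10
    dice_fpr: float = 0.005
    downsample_grid: tuple[int, ...] = tuple(range(1000, 5001, 1000))
    mask_percentile: float = 0.15
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_train, self.n_validation, self.voxels_per_subject) < 0:
            raise ValueError("counts must be non-negative")
        pool = self.n_train * self.voxels_per_subject
        if self.downsample_grid and max(self.downsample_grid) > pool:
            raise ValueError(
                f"downsample grid exceeds the {pool}-voxel training pool")


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    agreement: dict[str, evaluation.AgreementMatrix]
    train_ids: list[str]
    validation_ids: list[str]
    superlearner_weights: dict[str, pd.Series]


def _ensure_masks(studies: Sequence[MultimodalStudy], percentile: float) -> list[MultimodalStudy]:
    return [s if s.brain_tissue_mask is not None else add_brain_mask(s, percentile)
            for s in studies]


def split_cohort(
    cohort: Sequence[MultimodalStudy], config: ExperimentConfig
) -> tuple[list[MultimodalStudy], list[MultimodalStudy]]:
    """Seeded random assignment into disjoint train/validation subject sets."""
    need = config.n_train + config.n_validation
    if len(cohort) < need:
        raise ValueError(f"cohort of {len(cohort)} subjects cannot fill {need}")
    perm = np.random.default_rng([config.seed, 7]).permutation(len(cohort))
    train = [cohort[i] for i in perm[: config.n_train]]
    val = [cohort[i] for i in perm[config.n_train: need]]
    return train, val


def sample_training_voxels(
    studies: Sequence[MultimodalStudy], per_subject: int, seed: int
) -> dict[str, np.ndarray]:
    """Uniform without-replacement sample of brain-tissue voxels per subject."""
    out: dict[str, np.ndarray] = {}
    for i, study in enumerate(studies):
        mask = study.brain_tissue_mask
        if mask is None:
            raise ValueError(f"study {study.subject_id} lacks a brain-tissue mask")
        coords = np.argwhere(mask)
        if per_subject > len(coords):
            raise ValueError(
                f"cannot sample {per_subject} voxels from a mask of {len(coords)}")
        rng = np.random.default_rng([seed, i])
        pick = rng.choice(len(coords), size=per_subject, replace=False)
        out[study.subject_id] = coords[np.sort(pick)]
    return out


# ---------------------------------------------------------------------------
# shared preparation
# ---------------------------------------------------------------------------

@dataclass
class _KindData:
    """Training pool and validation scaffolding for one feature kind."""

    kind_name: str
    train_pool: FeatureMatrix        # all sampled voxels, before selection
    train_candidate: np.ndarray      # bool per pool row: inside candidate mask
    val_features: FeatureMatrix | None   # validation rows actually scored
    val_flags: np.ndarray            # bool per pooled brain voxel: scored?
    val_labels: np.ndarray           # label per pooled brain voxel
    n_val_subjects: int

    def training_matrix(self, rows: np.ndarray | None = None) -> FeatureMatrix:
        """Pool rows (optionally a subset) with candidate selection applied."""
        keep = self.train_candidate.copy()
        if rows is not None:
            sub = np.zeros(len(keep), dtype=bool)
            sub[rows] = True
            keep &= sub
        return FeatureMatrix(
            kind=self.train_pool.kind,
            X=self.train_pool.X.loc[keep].reset_index(drop=True),
            y=self.train_pool.y[keep],
            voxels=self.train_pool.voxels[keep],
            subject_ids=self.train_pool.subject_ids[keep],
        )

    def full_scores(self, candidate_scores: np.ndarray) -> np.ndarray:
        """Embed scored-voxel probabilities into the whole-brain score vector."""
        out = np.zeros(len(self.val_flags))
        out[self.val_flags] = candidate_scores
        return out


def _prepare_kind(
    kind_name: str,
    train: Sequence[MultimodalStudy],
    val: Sequence[MultimodalStudy],
    sampled: Mapping[str, np.ndarray],
    derived: Mapping[str, object],
    params: FeatureParams,
) -> _KindData:
    uses_sel = kind_name in ("voxel_selection", "smoothed", "moments", "smoothed_and_moments")

    pool_parts, cand_parts = [], []
    for s in train:
        d = derived[s.subject_id]
        # pool rows are the raw sampled voxels; selection is applied per use
        fm = assemble_features(s, kind_name, params=params, derived=d,
                               voxels=sampled[s.subject_id], apply_selection=False)
        if uses_sel:
            flags = d.candidates.mask[tuple(fm.voxels.T)]
        else:
            flags = np.ones(fm.n_rows, dtype=bool)
        pool_parts.append(fm)
        cand_parts.append(flags)
    train_pool = FeatureMatrix.concat(pool_parts)
    train_candidate = np.concatenate(cand_parts)

    val_parts, flag_parts, label_parts = [], [], []
    for s in val:
        d = derived[s.subject_id]
        fm = assemble_features(s, kind_name, params=params, derived=d)
        mask = s.brain_tissue_mask.astype(bool)
        labels = s.manual_segmentation[mask].astype(np.int8)
        if uses_sel:
            flags = d.candidates.mask[mask]
        else:
            flags = np.ones(int(mask.sum()), dtype=bool)
        val_parts.append(fm)
        flag_parts.append(flags)
        label_parts.append(labels)
    return _KindData(
        kind_name=kind_name,
        train_pool=train_pool,
        train_candidate=train_candidate,
        val_features=FeatureMatrix.concat(val_parts) if val_parts else None,
        val_flags=(np.concatenate(flag_parts) if flag_parts
                   else np.zeros(0, dtype=bool)),
        val_labels=(np.concatenate(label_parts) if label_parts
                    else np.zeros(0, dtype=np.int8)),
        n_val_subjects=len(val),
    )


def _evaluate(
    model_scores: np.ndarray, kd: _KindData, config: ExperimentConfig
) -> tuple[float, float, np.ndarray]:
    curve = evaluation.roc_curve(model_scores, kd.val_labels)
    pauc = evaluation.scaled_pauc(curve, config.fpr_max)
    thr = evaluation.threshold_at_fpr(curve, config.dice_fpr)
    return pauc, thr, model_scores >= thr


class _PredictionCache:
    """Per-learner validation predictions, shared between tuned models and
    the super-learner library (which reference the same refit learners)."""

    def __init__(self, X: np.ndarray):
        self.X = X
        self._cache: dict[int, np.ndarray] = {}

    def learner_scores(self, learner) -> np.ndarray:
        key = id(learner)
        if key not in self._cache:
            self._cache[key] = np.clip(learner.predict_proba1(self.X), 0.0, 1.0)
        return self._cache[key]

    def model_scores(self, model: classifiers.FittedModel) -> np.ndarray:
        state = model.model_state
        if isinstance(state, SuperLearnerFit):
            out = np.zeros(len(self.X))
            for w, learner in zip(state.weights, state.base_models):
                if w > 0 and learner is not None:
                    out += w * self.learner_scores(learner)
            return np.clip(out, 0.0, 1.0)
        return self.learner_scores(state)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_comparison(
    cohort: Sequence[MultimodalStudy],
    config: ExperimentConfig,
    algorithms: Sequence[str] | None = None,
    kinds: Sequence[str] | None = None,
    progress: bool = False,
) -> ComparisonResult:
    """Fit every (algorithm, feature kind) cell and evaluate on whole brains."""
    config.validate()
    algorithms = tuple(algorithms or ALGORITHM_NAMES)
    kinds = tuple(kinds or FEATURE_KIND_NAMES)
    cohort = _ensure_masks(cohort, config.mask_percentile)
    train, val = split_cohort(cohort, config)
    sampled = sample_training_voxels(train, config.voxels_per_subject,
                                     _derive(config.seed, 11))
    derived = {s.subject_id: derive_volumes(s, config.feature_params)
               for s in list(train) + list(val)}

    rows = []
    agreement: dict[str, evaluation.AgreementMatrix] = {}
    sl_weights: dict[str, pd.Series] = {}
    for kind_name in kinds:
        if progress:
            print(f"[run] preparing kind={kind_name}", flush=True)
        kd = _prepare_kind(kind_name, train, val, sampled, derived,
                           config.feature_params)
        train_fm = kd.training_matrix()
        suite = classifiers.fit_suite(algorithms, train_fm, folds=config.folds,
                                      seed=_derive(config.seed, 13))
        cache = _PredictionCache(kd.val_features.X.to_numpy(dtype=float))
        segs: dict[str, np.ndarray] = {}
        for alg in algorithms:
            if progress:
                print(f"[run] kind={kind_name} algorithm={alg}", flush=True)
            model = suite[alg]
            t0 = time.perf_counter()
            scores = kd.full_scores(cache.model_scores(model))
            pred_s = (time.perf_counter() - t0) / max(kd.n_val_subjects, 1)
            pauc, thr, seg = _evaluate(scores, kd, config)
            segs[alg] = seg
            if alg == "super_learner" and isinstance(model.model_state, SuperLearnerFit):
                sl = model.model_state
                sl_weights[kind_name] = pd.Series(sl.weights, index=sl.labels)
            rows.append({
                "algorithm": alg, "feature_kind": kind_name,
                "scaled_pauc": pauc, "threshold": thr,
                "n_train_rows": train_fm.n_rows,
                "chosen_params": repr(model.chosen_params),
                "fit_seconds": model.training_summary.get("fit_seconds", np.nan),
                "predict_seconds_per_study": pred_s,
            })
        segs["manual"] = kd.val_labels.astype(bool)
        agreement[kind_name] = evaluation.agreement_matrix(
            segs, threshold_fpr=config.dice_fpr)
    table = pd.DataFrame(rows)
    return ComparisonResult(table=table, agreement=agreement,
                            train_ids=[s.subject_id for s in train],
                            validation_ids=[s.subject_id for s in val],
                            superlearner_weights=sl_weights)


def downsampling_study(
    cohort: Sequence[MultimodalStudy],
    config: ExperimentConfig,
    algorithms: Sequence[str] | None = None,
    kinds: Sequence[str] = ("smoothed_and_moments",),
    progress: bool = False,
) -> pd.DataFrame:
    """Learning curves over nested training subsamples.

    Grid sizes count sampled voxels *before* candidate selection; larger
    subsets contain smaller ones, so curves differ only through added rows.
    """
    config.validate()
    algorithms = tuple(algorithms or
                       ("logistic_regression", "lda", "gaussian_mixture", "knn"))
    cohort = _ensure_masks(cohort, config.mask_percentile)
    train, val = split_cohort(cohort, config)
    sampled = sample_training_voxels(train, config.voxels_per_subject,
                                     _derive(config.seed, 11))
    derived = {s.subject_id: derive_volumes(s, config.feature_params)
               for s in list(train) + list(val)}

    rows = []
    for kind_name in kinds:
        kd = _prepare_kind(kind_name, train, val, sampled, derived,
                           config.feature_params)
        pool_n = kd.train_pool.n_rows
        perm = np.random.default_rng([config.seed, 17]).permutation(pool_n)
        for n in config.downsample_grid:
            if n > pool_n:
                raise ValueError(f"grid point {n} exceeds pool of {pool_n}")
            if progress:
                print(f"[downsample] kind={kind_name} n={n}", flush=True)
            fm = kd.training_matrix(perm[:n])
            suite = classifiers.fit_suite(algorithms, fm, folds=config.folds,
                                          seed=_derive(config.seed, 13))
            cache = _PredictionCache(kd.val_features.X.to_numpy(dtype=float))
            for alg in algorithms:
                model = suite[alg]
                scores = kd.full_scores(cache.model_scores(model))
                pauc, _, _ = _evaluate(scores, kd, config)
                rows.append({"algorithm": alg, "feature_kind": kind_name,
                             "n_voxels": n, "n_train_rows": fm.n_rows,
                             "scaled_pauc": pauc,
                             "fit_seconds": model.training_summary.get(
                                 "fit_seconds", np.nan)})
    return pd.DataFrame(rows)


def track_superlearner_weights(
    cohort: Sequence[MultimodalStudy],
    config: ExperimentConfig,
    kinds: Sequence[str] = ("smoothed_and_moments",),
    library: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Super-learner weight vectors along the downsampling grid."""
    config.validate()
    cohort = _ensure_masks(cohort, config.mask_percentile)
    train, val = split_cohort(cohort, config)
    sampled = sample_training_voxels(train, config.voxels_per_subject,
                                     _derive(config.seed, 11))
    derived = {s.subject_id: derive_volumes(s, config.feature_params)
               for s in train}
    lib = list(library or classifiers.BASE_ALGORITHM_NAMES)

    rows = []
    for kind_name in kinds:
        kd = _prepare_kind(kind_name, train, [], sampled, derived,
                           config.feature_params)
        perm = np.random.default_rng([config.seed, 17]).permutation(kd.train_pool.n_rows)
        for n in config.downsample_grid:
            fm = kd.training_matrix(perm[:n])
            sl = classifiers.superlearner_fit(lib, fm, folds=config.folds,
                                              seed=_derive(config.seed, 13))
            for label, w in zip(sl.labels, sl.weights):
                rows.append({"feature_kind": kind_name, "n_voxels": n,
                             "learner": label, "weight": float(w)})
    return pd.DataFrame(rows)


def _derive(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))
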