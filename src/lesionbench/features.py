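"""Feature-extraction functions over multimodal MRI volumes.

Six feature vectors are built from the T1-w, T2-w and FLAIR volumes:

==================== =================================================== ====
kind                 columns                                             dim
==================== =================================================== ====
unnormalized         observed T1/T2/FLAIR intensities                      3
normalized           z-scored intensities over the brain-tissue mask       3
voxel_selection      normalized, rows restricted to candidate voxels       3
smoothed             normalized + Gaussian-smoothed (n=21,41) x 3 mods     9
moments              normalized + local moments (k=1..3, n=3,5) x 3 mods  21
smoothed_and_moments normalized || smoothed || moments blocks             27
==================== =================================================== ====

Normalization maps each modality to standard scores (sample SD, divisor
n-1) over the brain-tissue mask, making intensities comparable across
subjects.  Candidate ("voxel selection") voxels are brain-mask voxels at or
above the 85th percentile of the normalized FLAIR; since most lesions are
FLAIR-bright this concentrates the modeling space on plausible lesion
locations.  The smoothed volumes capture anatomical context over large
windows; the local moment volumes capture the clustered, multi-voxel nature
of lesions over small windows.

Column order is fixed: modality blocks in (t1, t2, flair) order; within the
smoothed block, window sizes ascending per modality; within the moments
block, moment order k ascending then window size ascending per modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import MODALITIES, MultimodalStudy


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborhoodSpec:
    """Cubic n x n x n voxel window; n must be odd and >= 3."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError(f"window edge length must be odd and >= 3, got {self.n}")


@dataclass(frozen=True)
class MomentSpec:
    """Raw k-th sample moment over an n x n x n window, k in {1, 2, 3}."""

    k: int
    n: int

    def __post_init__(self) -> None:
        if self.k not in (1, 2, 3):
            raise ValueError(f"moment order must be 1, 2 or 3, got {self.k}")
        NeighborhoodSpec(self.n)


@dataclass(frozen=True)
class FeatureParams:
    """Tunable knobs of the feature-extraction functions."""

    smooth_ns: tuple[int, ...] = (21, 41)
    moment_ns: tuple[int, ...] = (3, 5)
    moment_ks: tuple[int, ...] = (1, 2, 3)
    select_percentile: float = 0.85


@dataclass(frozen=True)
class FeatureVectorKind:
    name: str
    uses_voxel_selection: bool
    dimension: int


FEATURE_KIND_NAMES = (
    "unnormalized",
    "normalized",
    "voxel_selection",
    "smoothed",
    "moments",
    "smoothed_and_moments",
)

_SELECTED = {"voxel_selection", "smoothed", "moments", "smoothed_and_moments"}


def feature_kind(name: str, params: FeatureParams | None = None) -> FeatureVectorKind:
    """Resolve a kind name to its spec (dimension follows the params)."""
    if name not in FEATURE_KIND_NAMES:
        raise ValueError(f"unknown feature kind {name!r}; expected one of {FEATURE_KIND_NAMES}")
    params = params or FeatureParams()
    nmod = len(MODALITIES)
    n_smooth = nmod * len(params.smooth_ns)
    n_mom = nmod * len(params.moment_ks) * len(params.moment_ns)
    dims = {
        "unnormalized": nmod,
        "normalized": nmod,
        "voxel_selection": nmod,
        "smoothed": nmod + n_smooth,
        "moments": nmod + n_mom,
        "smoothed_and_moments": nmod + n_smooth + n_mom,
    }
    return FeatureVectorKind(name=name, uses_voxel_selection=name in _SELECTED,
                             dimension=dims[name])


# ---------------------------------------------------------------------------
# volume operators
# ---------------------------------------------------------------------------

def normalize_volume(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standard scores of ``vol`` over ``mask`` (sample SD); zero outside."""
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if vol.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    vals = vol[mask]
    if vals.size < 2:
        raise ValueError("mask must contain at least 2 voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero intensity variance over mask")
    out = np.zeros_like(vol)
    out[mask] = (vals - vals.mean()) / sd
    return out


@dataclass
class CandidateMask:
    mask: np.ndarray
    percentile: float
    threshold: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def select_candidates(
    flair_norm: np.ndarray,
    mask: np.ndarray,
    percentile: float = 0.85,
) -> CandidateMask:
    """Brain-mask voxels at or above the given FLAIR quantile ("and above")."""
    flair_norm = np.asarray(flair_norm)
    mask = np.asarray(mask).astype(bool)
    if flair_norm.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    if not mask.any():
        raise ValueError("mask is empty")
    threshold = float(np.quantile(flair_norm[mask], percentile))
    cand = mask & (flair_norm >= threshold)
    return CandidateMask(mask=cand, percentile=percentile, threshold=threshold)


def _gaussian_kernel(n: int) -> np.ndarray:
    # sigma = n/4 puts +-2 sigma at the window edge; hard truncation at n
    sigma = n / 4.0
    x = np.arange(n) - (n - 1) / 2.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(vol: np.ndarray, mask: np.ndarray, n: int | NeighborhoodSpec) -> np.ndarray:
    """Mask-renormalized separable 3D Gaussian smoothing over an n-cube window.

    output(v) = sum_w K(v-w) vol(w) mask(w) / sum_w K(v-w) mask(w), so a
    constant field over the mask is reproduced exactly and intensities never
    bleed in from outside the mask.  Voxels outside the mask are set to 0.
    """
    spec = n if isinstance(n, NeighborhoodSpec) else NeighborhoodSpec(int(n))
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if vol.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    k1d = _gaussian_kernel(spec.n)
    num = vol * mask
    den = mask.astype(float)
    for axis in range(vol.ndim):
        num = ndimage.correlate1d(num, k1d, axis=axis, mode="constant", cval=0.0)
        den = ndimage.correlate1d(den, k1d, axis=axis, mode="constant", cval=0.0)
    out = np.zeros_like(vol)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def local_moment(vol: np.ndarray, mask: np.ndarray, spec: MomentSpec) -> np.ndarray:
    """Raw k-th sample moment over the window intersected with the mask.

    output(v) = (1/r) sum_{w in N_n(v) & mask} vol(w)^k with r the number of
    mask voxels in the window.  Outside the mask the output is 0.
    """
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if vol.shape != mask.shape:
        raise ValueError("volume and mask grids differ")
    size = spec.n
    num = ndimage.uniform_filter((vol ** spec.k) * mask, size=size,
                                 mode="constant", cval=0.0)
    den = ndimage.uniform_filter(mask.astype(float), size=size,
                                 mode="constant", cval=0.0)
    out = np.zeros_like(vol)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


# ---------------------------------------------------------------------------
# derived-volume cache and feature assembly
# ---------------------------------------------------------------------------

@dataclass
class DerivedVolumes:
    """All normalized/smoothed/moment volumes of one study, computed once."""

    normalized: dict[str, np.ndarray]
    smoothed: dict[tuple[str, int], np.ndarray]
    moments: dict[tuple[str, int, int], np.ndarray]  # (modality, k, n)
    candidates: CandidateMask
    params: FeatureParams


def derive_volumes(study: MultimodalStudy, params: FeatureParams | None = None) -> DerivedVolumes:
    params = params or FeatureParams()
    mask = _require_brain_mask(study)
    normalized = {m: normalize_volume(study.modality(m), mask) for m in MODALITIES}
    candidates = select_candidates(normalized["flair"], mask, params.select_percentile)
    smoothed = {
        (m, n): gaussian_smooth(normalized[m], mask, n)
        for m in MODALITIES for n in params.smooth_ns
    }
    moments = {
        (m, k, n): local_moment(normalized[m], mask, MomentSpec(k, n))
        for m in MODALITIES for k in params.moment_ks for n in params.moment_ns
    }
    return DerivedVolumes(normalized=normalized, smoothed=smoothed,
                          moments=moments, candidates=candidates, params=params)


def _require_brain_mask(study: MultimodalStudy) -> np.ndarray:
    if study.brain_tissue_mask is None:
        raise ValueError(
            f"study {study.subject_id} has no brain-tissue mask; run preprocessing first"
        )
    return study.brain_tissue_mask.astype(bool)


def _column_volumes(
    study: MultimodalStudy, kind: FeatureVectorKind, derived: DerivedVolumes
) -> list[tuple[str, np.ndarray]]:
    params = derived.params
    if kind.name == "unnormalized":
        return [(m, np.asarray(study.modality(m), dtype=float)) for m in MODALITIES]
    cols: list[tuple[str, np.ndarray]] = [(f"{m}_norm", derived.normalized[m]) for m in MODALITIES]
    if kind.name in ("smoothed", "smoothed_and_moments"):
        cols += [
            (f"{m}_smooth_n{n}", derived.smoothed[(m, n)])
            for m in MODALITIES for n in params.smooth_ns
        ]
    if kind.name in ("moments", "smoothed_and_moments"):
        cols += [
            (f"{m}_mom{k}_n{n}", derived.moments[(m, k, n)])
            for m in MODALITIES for k in params.moment_ks for n in params.moment_ns
        ]
    return cols


@dataclass
class FeatureMatrix:
    """Per-voxel feature rows for one feature-vector kind."""

    kind: FeatureVectorKind
    X: pd.DataFrame
    y: np.ndarray
    voxels: np.ndarray          # (n_rows, 3) integer voxel coordinates
    subject_ids: np.ndarray     # (n_rows,) subject token per row

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def validate(self) -> None:
        if self.X.shape[1] != self.kind.dimension:
            raise ValueError(
                f"{self.kind.name}: {self.X.shape[1]} columns, expected {self.kind.dimension}"
            )
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if not (len(self.X) == len(self.y) == len(self.voxels) == len(self.subject_ids)):
            raise ValueError("row metadata lengths disagree")

    @staticmethod
    def concat(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        kinds = {p.kind.name for p in parts}
        if len(kinds) != 1:
            raise ValueError(f"cannot concatenate mixed kinds {kinds}")
        return FeatureMatrix(
            kind=parts[0].kind,
            X=pd.concat([p.X for p in parts], ignore_index=True),
            y=np.concatenate([p.y for p in parts]),
            voxels=np.concatenate([p.voxels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Exportable table: subject_id, x, y, z, label, then feature columns."""
        meta = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "x": self.voxels[:, 0],
                "y": self.voxels[:, 1],
                "z": self.voxels[:, 2],
                "label": self.y,
            }
        )
        return pd.concat([meta, self.X.reset_index(drop=True)], axis=1)


def assemble_features(
    study: MultimodalStudy,
    kind: str | FeatureVectorKind,
    params: FeatureParams | None = None,
    derived: DerivedVolumes | None = None,
    voxels: np.ndarray | None = None,
    apply_selection: bool = True,
) -> FeatureMatrix:
    """Build the feature matrix of one study for one feature-vector kind.

    Rows cover every brain-tissue-mask voxel (restricted to the candidate
    mask for kinds using voxel selection, unless ``apply_selection`` is
    False).  If ``voxels`` is given, rows are restricted to those
    coordinates that fall inside the row mask.  Labels come from the manual
    segmentation.
    """
    params = params or (derived.params if derived is not None else FeatureParams())
    if isinstance(kind, str):
        kind = feature_kind(kind, params)
    mask = _require_brain_mask(study)
    if study.manual_segmentation is None:
        raise ValueError("study has no manual segmentation")
    if derived is None:
        derived = derive_volumes(study, params)
    use_sel = kind.uses_voxel_selection and apply_selection
    row_mask = mask & derived.candidates.mask if use_sel else mask

    if voxels is None:
        coords = np.argwhere(row_mask)
    else:
        voxels = np.asarray(voxels)
        keep = row_mask[tuple(voxels.T)]
        coords = voxels[keep]
    idx = tuple(coords.T)
    data = {name: vol[idx] for name, vol in _column_volumes(study, kind, derived)}
    fm = FeatureMatrix(
        kind=kind,
        X=pd.DataFrame(data),
        y=study.manual_segmentation[idx].astype(np.int8),
        voxels=coords,
        subject_ids=np.full(len(coords), study.subject_id, dtype=object),
    )
    fm.validate()
    return fm
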