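"""Synthetic multimodal MRI cohorts with planted white-matter lesions.

Real MS cohorts with manual lesion delineations are rarely shareable, so this
module builds stand-in studies that reproduce the statistical structure a
voxel-classification benchmark relies on:

* three co-registered modalities (T1-w, T2-w, FLAIR) on a common 1 mm
  isotropic grid, already bias-corrected and skull-stripped;
* lesions hyperintense on FLAIR and T2-w, hypointense on T1-w, placed as
  clustered multi-voxel blobs inside white matter and biased toward the
  ventricular boundary (periventricular predominance);
* lesion load around 1% of brain-tissue voxels, the prevalence regime in
  which whole-brain voxel classification is strongly imbalanced;
* per-subject global gain/offset intensity differences, so that raw
  ("unnormalized") intensities are not comparable across subjects and
  z-score normalization materially changes separability.

Anatomy is a deliberately simple phantom: an ellipsoidal brain with a gray
matter shell, a white matter core and a central CSF "ventricle", with all
tissue boundaries perturbed by smooth Gaussian random fields so masks are
irregular rather than analytic surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

MODALITIES = ("t1", "t2", "flair")

#: Mean tissue intensity per modality (arbitrary scanner units).  Contrast
#: signs are fixed by MS imaging physics: lesions are bright on FLAIR and
#: T2-w, dark on T1-w; CSF is dark on FLAIR and T1-w and bright on T2-w.
DEFAULT_TISSUE_MEANS: dict[str, dict[str, float]] = {
    "t1": {"csf": 40.0, "gm": 90.0, "wm": 120.0, "lesion": 70.0},
    "t2": {"csf": 180.0, "gm": 120.0, "wm": 100.0, "lesion": 150.0},
    "flair": {"csf": 50.0, "gm": 105.0, "wm": 100.0, "lesion": 160.0},
}


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    grid_shape
        Voxels per axis, 1 mm isotropic.
    n_subjects
        Number of studies in the cohort.
    lesion_fraction_target
        Target fraction of brain-tissue-mask voxels that are lesion,
        constrained to [0.005, 0.02] (the whole-brain prevalence regime of
        MS cohorts).
    lesion_count_mean
        Mean of the Poisson draw for the number of lesions per subject.
    lesion_radius_range
        (min, max) lesion radius in mm before blob deformation.
    tissue_means
        Per-modality mean intensity for csf/gm/wm/lesion.
    noise_sd
        Standard deviation of additive i.i.d. Gaussian voxel noise.
    subject_gain_range, subject_offset_range
        Bounds of the uniform per-subject, per-modality global affine
        intensity perturbation (scanner-arbitrary units).
    seed
        Root seed; every study is a deterministic function of
        (seed, subject_index).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    n_subjects: int = 10
    lesion_fraction_target: float = 0.01
    lesion_count_mean: float = 8.0
    lesion_radius_range: tuple[float, float] = (1.5, 4.0)
    tissue_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_TISSUE_MEANS.items()}
    )
    noise_sd: float = 15.0
    subject_gain_range: tuple[float, float] = (0.7, 1.3)
    subject_offset_range: tuple[float, float] = (-40.0, 40.0)
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if not (0.005 <= self.lesion_fraction_target <= 0.02):
            raise ConfigurationError(
                f"lesion_fraction_target must lie in [0.005, 0.02], got {self.lesion_fraction_target}"
            )
        if self.lesion_count_mean <= 0:
            raise ConfigurationError("lesion_count_mean must be positive")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi) or hi >= min(self.grid_shape) / 2:
            raise ConfigurationError(f"lesion_radius_range {self.lesion_radius_range} invalid for grid")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        glo, ghi = self.subject_gain_range
        if not (0 < glo <= ghi):
            raise ConfigurationError("subject_gain_range must be positive and ordered")
        for m in MODALITIES:
            if m not in self.tissue_means:
                raise ConfigurationError(f"tissue_means missing modality {m!r}")
        tm = self.tissue_means
        if not (tm["flair"]["lesion"] > tm["flair"]["wm"]):
            raise ConfigurationError("FLAIR lesion mean must exceed FLAIR WM mean")
        if not (tm["t2"]["lesion"] > tm["t2"]["wm"]):
            raise ConfigurationError("T2 lesion mean must exceed T2 WM mean")
        if not (tm["t1"]["lesion"] < tm["t1"]["wm"]):
            raise ConfigurationError("T1 lesion mean must fall below T1 WM mean")


@dataclass
class MultimodalStudy:
    """One subject's aligned volumes, masks and manual segmentation."""

    subject_id: str
    t1: np.ndarray
    t2: np.ndarray
    flair: np.ndarray
    extracerebral_mask: np.ndarray
    manual_segmentation: np.ndarray
    brain_tissue_mask: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.flair.shape)

    def modality(self, name: str) -> np.ndarray:
        if name not in MODALITIES:
            raise KeyError(f"unknown modality {name!r}")
        return getattr(self, name)

    def validate(self) -> None:
        shapes = {v.shape for v in (self.t1, self.t2, self.flair,
                                    self.extracerebral_mask, self.manual_segmentation)}
        if self.brain_tissue_mask is not None:
            shapes.add(self.brain_tissue_mask.shape)
        if len(shapes) != 1:
            raise ValueError(f"volumes of {self.subject_id} do not share a grid: {shapes}")
        if np.any(self.manual_segmentation & ~self.extracerebral_mask.astype(bool)):
            raise ValueError("manual segmentation extends outside the extracerebral mask")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, ...], scale: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ``scale`` voxels."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _place_lesions(
    rng: np.random.Generator,
    wm: np.ndarray,
    weights: np.ndarray,
    wm_idx: np.ndarray,
    deform: np.ndarray,
    count: int,
    radius_range: tuple[float, float],
) -> np.ndarray:
    """Plant ``count`` deformed spherical blobs at weighted WM locations."""
    shape = wm.shape
    lesions = np.zeros(shape, dtype=bool)
    if count <= 0:
        return lesions
    count = min(count, wm_idx.size)
    centers = rng.choice(wm_idx, size=count, replace=False, p=weights)
    radii = rng.uniform(*radius_range, size=count)
    for flat, r in zip(centers, radii):
        cx, cy, cz = np.unravel_index(flat, shape)
        h = int(np.ceil(r * 1.5)) + 1
        sl = tuple(
            slice(max(c - h, 0), min(c + h + 1, s))
            for c, s in zip((cx, cy, cz), shape)
        )
        local = np.indices([s.stop - s.start for s in sl], dtype=float)
        offs = [c - s.start for c, s in zip((cx, cy, cz), sl)]
        dist = np.sqrt(sum((local[a] - offs[a]) ** 2 for a in range(3)))
        blob = dist <= r * (1.0 + 0.35 * deform[sl])
        lesions[sl] |= blob & wm[sl]
    return lesions


def generate_study(config: GeneratorConfig, subject_index: int) -> MultimodalStudy:
    """Generate one study; bit-deterministic given (config.seed, subject_index)."""
    config.validate()
    if subject_index < 0 or subject_index >= max(config.n_subjects, 1):
        raise ValueError(f"subject_index {subject_index} outside 0..{config.n_subjects - 1}")
    rng = np.random.default_rng([config.seed, subject_index])
    shape = tuple(int(s) for s in config.grid_shape)
    dims = np.asarray(shape, dtype=float)

    # --- anatomy: ellipsoidal brain, GM shell, WM core, central ventricle ---
    semi = np.array([0.42, 0.37, 0.33]) * dims
    center = (dims - 1) / 2.0
    coords = np.indices(shape, dtype=float)
    rho = np.sqrt(sum(((coords[a] - center[a]) / semi[a]) ** 2 for a in range(3)))

    eta_brain = _smooth_field(rng, shape, 4.0) * 0.03
    eta_core = _smooth_field(rng, shape, 4.0) * 0.04
    brain = (rho + eta_brain) <= 1.0
    core = ((rho + eta_core) <= 0.80) & brain

    vsemi = np.array([0.16, 0.07, 0.10]) * dims
    rho_v = np.sqrt(sum(((coords[a] - center[a]) / vsemi[a]) ** 2 for a in range(3)))
    eta_vent = _smooth_field(rng, shape, 3.0) * 0.10
    ventricle = ((rho_v + eta_vent) <= 1.0) & core

    gm = brain & ~core
    wm = core & ~ventricle

    # --- lesions: Poisson count, periventricular bias, deformed spheres ---
    deform = _smooth_field(rng, shape, 2.0)
    dist_vent = ndimage.distance_transform_edt(~ventricle)
    wm_idx = np.flatnonzero(wm)
    w = np.exp(-dist_vent.ravel()[wm_idx] / 8.0)
    w = w / w.sum()

    count = max(1, int(rng.poisson(config.lesion_count_mean)))
    lesions = _place_lesions(rng, wm, w, wm_idx, deform, count,
                             config.lesion_radius_range)
    # the brain-tissue mask later removes the FLAIR-darkest 15% of brain
    # voxels, so calibrate lesion load against ~85% of the brain volume
    denom = 0.85 * brain.sum()
    target = config.lesion_fraction_target
    frac = lesions.sum() / denom
    if abs(frac - target) > 0.5 * target:
        count2 = max(1, int(round(count * target / max(frac, 1e-9))))
        lesions = _place_lesions(rng, wm, w, wm_idx, deform, count2,
                                 config.lesion_radius_range)

    # lesions are clustered multi-voxel objects: drop stray single voxels
    labels, n_comp = ndimage.label(lesions)
    if n_comp:
        sizes = np.bincount(labels.ravel())
        tiny = sizes < 2
        tiny[0] = False
        lesions[tiny[labels]] = False
    if not lesions.any():
        # degenerate draw (all blobs clipped away): plant one minimal sphere
        flat = wm_idx[int(np.argmax(w))]
        fallback = np.zeros(shape, dtype=bool)
        fallback.ravel()[flat] = True
        lesions = ndimage.binary_dilation(fallback, iterations=2) & wm

    # --- intensities: tissue means -> subject affine -> additive noise ---
    tissue_base = {
        "csf": ventricle,
        "gm": gm,
        "wm": wm & ~lesions,
        "lesion": lesions,
    }
    vols: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        means = config.tissue_means[m]
        base = np.zeros(shape, dtype=float)
        for tissue, mask in tissue_base.items():
            base[mask] = means[tissue]
        gain = rng.uniform(*config.subject_gain_range)
        offset = rng.uniform(*config.subject_offset_range)
        vol = gain * base + offset + rng.normal(0.0, config.noise_sd, shape)
        vol[~brain] = 0.0
        vols[m] = vol.astype(np.float32)

    study = MultimodalStudy(
        subject_id=f"sub{subject_index:03d}",
        t1=vols["t1"],
        t2=vols["t2"],
        flair=vols["flair"],
        extracerebral_mask=brain,
        manual_segmentation=lesions,
    )
    study.validate()
    return study


def generate_cohort(config: GeneratorConfig) -> list[MultimodalStudy]:
    """Generate ``config.n_subjects`` studies on independent seeded substreams."""
    config.validate()
    return [generate_study(config, i) for i in range(config.n_subjects)]
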