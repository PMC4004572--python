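"""NIfTI and CSV readers/writers, config files, and run manifests.

Synthetic studies are stored one directory per subject as NIfTI-1 volumes
with RAS identity affines (1 mm isotropic): float32 intensities, uint8
masks.  Tabular outputs are CSV with a header row and 6 significant digits,
so results are human-diffable and round-trip losslessly at that precision.
"""

from __future__ import annotations

import ast
import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .evaluation import AgreementMatrix, ROCCurve
from .features import FeatureParams
from .synthetic import GeneratorConfig, MultimodalStudy

STUDY_FILES = {
    "t1": "t1.nii.gz",
    "t2": "t2.nii.gz",
    "flair": "flair.nii.gz",
    "extracerebral_mask": "extracerebral_mask.nii.gz",
    "manual_segmentation": "manual_seg.nii.gz",
}
BRAIN_MASK_FILE = "brain_mask.nii.gz"


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_study(study: MultimodalStudy, dir_path: str | Path) -> Path:
    """Write one study's volumes into a per-subject directory."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.voxel_size)
    for attr, fname in STUDY_FILES.items():
        vol = getattr(study, attr)
        if attr in ("extracerebral_mask", "manual_segmentation"):
            data = np.asarray(vol).astype(np.uint8)
        else:
            data = np.asarray(vol, dtype=np.float32)
        nib.save(nib.Nifti1Image(data, aff), out / fname)
    if study.brain_tissue_mask is not None:
        nib.save(nib.Nifti1Image(study.brain_tissue_mask.astype(np.uint8), aff),
                 out / BRAIN_MASK_FILE)
    return out


def _load_mask(path: Path) -> np.ndarray:
    data = np.asarray(nib.load(path).dataobj)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        warnings.warn(f"{path.name} contains values {vals.tolist()}; coercing to binary")
    return data > 0


def read_study(dir_path: str | Path) -> MultimodalStudy:
    """Load a study directory; verifies grid consistency, coerces masks."""
    d = Path(dir_path)
    fields: dict[str, np.ndarray] = {}
    for attr, fname in STUDY_FILES.items():
        path = d / fname
        if not path.exists():
            raise FileNotFoundError(f"study directory {d} is missing {fname} ({attr})")
        if attr in ("extracerebral_mask", "manual_segmentation"):
            fields[attr] = _load_mask(path)
        else:
            img = nib.load(path)
            fields[attr] = np.asarray(img.dataobj, dtype=np.float32)
    brain = _load_mask(d / BRAIN_MASK_FILE) if (d / BRAIN_MASK_FILE).exists() else None
    shapes = {v.shape for v in fields.values()}
    if brain is not None:
        shapes.add(brain.shape)
    if len(shapes) != 1:
        raise ValueError(f"volumes in {d} do not share a grid: {shapes}")
    voxel_size = tuple(float(z) for z in
                       nib.load(d / STUDY_FILES["flair"]).header.get_zooms()[:3])
    study = MultimodalStudy(subject_id=d.name, brain_tissue_mask=brain,
                            voxel_size=voxel_size, **fields)
    study.validate()
    return study


def write_cohort(studies, dir_path: str | Path) -> Path:
    root = Path(dir_path)
    for s in studies:
        write_study(s, root / s.subject_id)
    return root


def read_cohort(dir_path: str | Path) -> list[MultimodalStudy]:
    root = Path(dir_path)
    dirs = sorted(p for p in root.iterdir()
                  if p.is_dir() and (p / STUDY_FILES["flair"]).exists())
    return [read_study(p) for p in dirs]


# ---------------------------------------------------------------------------
# plain-text key=value config files
# ---------------------------------------------------------------------------

def write_config(config: GeneratorConfig, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {getattr(config, f.name)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config(path: str | Path) -> GeneratorConfig:
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kwargs[key.strip()] = ast.literal_eval(value.strip())
    return GeneratorConfig(**kwargs)


# ---------------------------------------------------------------------------
# tabular results
# ---------------------------------------------------------------------------

def write_results(obj, path: str | Path) -> Path:
    """CSV export for results tables, agreement matrices and ROC curves."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, AgreementMatrix):
        obj.table.to_csv(path, float_format="%.6g", index_label="method")
    elif isinstance(obj, ROCCurve):
        df = pd.DataFrame({"fpr": obj.fpr, "tpr": obj.tpr})
        if obj.thresholds is not None:
            df["threshold"] = obj.thresholds
        df.to_csv(path, float_format="%.6g", index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, float_format="%.6g", index=False)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config snapshot, seed, stages."""

    seed: int
    generator_config: dict
    experiment_config: dict
    stages: dict
    outputs: dict
    version: str = ""

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path

    @staticmethod
    def load(path: str | Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))


def config_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    if isinstance(d.get("feature_params"), FeatureParams):
        d["feature_params"] = dataclasses.asdict(d["feature_params"])
    return d
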