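"""Brain-tissue mask construction.

The skull-stripped ("extracerebral removal") mask still contains CSF, which
is dark on FLAIR.  The brain-tissue mask drops every voxel whose FLAIR
intensity falls strictly below the empirical 15th percentile of FLAIR over
the extracerebral mask; ties at the threshold are retained.  On real data
this removes ventricular and peripheral CSF; here it is a pure intensity
rule, so the CSF removal is emergent rather than enforced.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .synthetic import MultimodalStudy


@dataclass
class BrainMask:
    mask: np.ndarray
    source_percentile: float
    threshold: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def brain_tissue_mask(
    flair: np.ndarray,
    extracerebral_mask: np.ndarray,
    percentile: float = 0.15,
) -> BrainMask:
    """Keep extracerebral-mask voxels with FLAIR >= the given empirical quantile.

    The quantile uses linear interpolation between order statistics; removal
    is strict ("falling below"), so voxels equal to the threshold survive.
    """
    flair = np.asarray(flair)
    emask = np.asarray(extracerebral_mask).astype(bool)
    if flair.shape != emask.shape:
        raise ValueError(f"grid mismatch: flair {flair.shape} vs mask {emask.shape}")
    if not (0.0 <= percentile <= 1.0):
        raise ValueError("percentile must lie in [0, 1]")
    if not emask.any():
        raise ValueError("extracerebral mask is empty")
    threshold = float(np.quantile(flair[emask], percentile))
    mask = emask & (flair >= threshold)
    return BrainMask(mask=mask, source_percentile=percentile, threshold=threshold)


def add_brain_mask(study: MultimodalStudy, percentile: float = 0.15) -> MultimodalStudy:
    """Return a copy of the study with its brain-tissue mask computed."""
    bm = brain_tissue_mask(study.flair, study.extracerebral_mask, percentile)
    return dataclasses.replace(study, brain_tissue_mask=bm.mask)
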