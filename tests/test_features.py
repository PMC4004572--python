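"""Feature operators: normalization, candidate selection, smoothing, moments,
and assembly of the six feature vectors."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lesionbench as lb
from lesionbench.features import (
    FeatureParams,
    MomentSpec,
    NeighborhoodSpec,
    assemble_features,
    feature_kind,
    gaussian_smooth,
    local_moment,
    normalize_volume,
    select_candidates,
)


# ---------------------------------------------------------------------- norm

def test_normalize_three_point_case():
    vol = np.array([1.0, 2.0, 3.0]).reshape(-1, 1, 1)
    mask = np.ones_like(vol, dtype=bool)
    out = normalize_volume(vol, mask)
    assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])  # sample SD (n-1)


def test_normalize_zero_mean_unit_sd(study):
    mask = study.brain_tissue_mask
    out = normalize_volume(study.t2, mask)
    assert abs(out[mask].mean()) < 1e-10
    assert abs(out[mask].std(ddof=1) - 1.0) < 1e-10
    assert np.all(out[~mask] == 0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
def test_normalize_affine_invariance(a, b):
    rng = np.random.default_rng(12)
    vol = rng.normal(10, 4, (6, 6, 6))
    mask = rng.random((6, 6, 6)) < 0.7
    mask.flat[:2] = True
    assert np.allclose(normalize_volume(vol, mask),
                       normalize_volume(a * vol + b, mask), atol=1e-8)


def test_normalize_errors():
    vol = np.ones((4, 4, 4))
    with pytest.raises(ValueError):
        normalize_volume(vol, np.ones_like(vol, dtype=bool))  # zero variance
    tiny = np.zeros_like(vol, dtype=bool)
    tiny[0, 0, 0] = True
    with pytest.raises(ValueError):
        normalize_volume(vol, tiny)


# ----------------------------------------------------------------- selection

def test_select_candidates_enumeration():
    vol = np.arange(1, 101, dtype=float).reshape(-1, 1, 1)
    mask = np.ones_like(vol, dtype=bool)
    cand = select_candidates(vol, mask, percentile=0.85)
    assert cand.threshold == pytest.approx(85.15)
    assert cand.n_voxels == 15
    assert np.sort(vol[cand.mask])[0] == 86


def test_select_all_equal_retained():
    vol = np.full((4, 4, 4), 3.0)
    mask = np.ones_like(vol, dtype=bool)
    cand = select_candidates(vol, mask, 0.85)
    assert cand.n_voxels == 64  # "and above" keeps equality


def test_select_enriches_lesion_fraction(study, derived):
    """Candidate selection concentrates lesions by roughly 5-7x."""
    mask = study.brain_tissue_mask
    seg = study.manual_segmentation
    base = seg[mask].mean()
    enriched = seg[derived.candidates.mask].mean()
    assert 3.0 < enriched / base < 10.0


# ----------------------------------------------------------------- smoothing

def test_smooth_constant_preserved():
    vol = np.full((12, 12, 12), 4.2)
    mask = np.zeros_like(vol, dtype=bool)
    mask[2:10, 3:9, 2:11] = True
    out = gaussian_smooth(vol, mask, 5)
    assert np.allclose(out[mask], 4.2)
    assert np.all(out[~mask] == 0)


def test_smooth_spike_symmetric_and_mass_preserving():
    vol = np.zeros((15, 15, 15))
    vol[7, 7, 7] = 1.0
    mask = np.ones_like(vol, dtype=bool)
    out = gaussian_smooth(vol, mask, 5)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)
    for axis in range(3):
        assert np.allclose(out, np.flip(out, axis=axis))


@pytest.mark.parametrize("bad_n", [2, 4, 1, 0])
def test_smooth_rejects_bad_window(bad_n):
    vol = np.ones((5, 5, 5))
    with pytest.raises(ValueError):
        gaussian_smooth(vol, np.ones_like(vol, dtype=bool), bad_n)


def test_smooth_reduces_total_variation(study, derived):
    """Large-window smoothing yields a smoother field than its input."""
    def tv(v):
        return sum(np.abs(np.diff(v, axis=a)).sum() for a in range(3))

    flair_norm = derived.normalized["flair"]
    smoothed = derived.smoothed[("flair", 41)]
    assert tv(smoothed) < tv(flair_norm)


# ------------------------------------------------------------------- moments

def test_moment_constant_square():
    vol = np.full((8, 8, 8), 2.0)
    mask = np.ones_like(vol, dtype=bool)
    out = local_moment(vol, mask, MomentSpec(k=2, n=3))
    assert np.allclose(out, 4.0)


def test_moment_spike_center_value():
    vol = np.zeros((9, 9, 9))
    vol[4, 4, 4] = 1.0
    out = local_moment(vol, np.ones_like(vol, dtype=bool), MomentSpec(k=1, n=3))
    assert out[4, 4, 4] == pytest.approx(1 / 27)


@pytest.mark.parametrize("k,n", [(1, 3), (2, 3), (3, 5)])
def test_moment_matches_bruteforce(k, n):
    """Direct window enumeration oracle on a small masked volume."""
    rng = np.random.default_rng(5)
    vol = rng.normal(0, 1, (6, 5, 7))
    mask = rng.random((6, 5, 7)) < 0.8
    mask[3, 2, 3] = True
    out = local_moment(vol, mask, MomentSpec(k=k, n=n))
    h = n // 2
    for idx in np.argwhere(mask):
        sl = tuple(slice(max(c - h, 0), min(c + h + 1, s))
                   for c, s in zip(idx, vol.shape))
        w_vals = vol[sl][mask[sl]]
        expected = np.mean(w_vals ** k)
        assert out[tuple(idx)] == pytest.approx(expected, rel=1e-10)
    assert np.all(out[~mask] == 0)


def test_moment_k1_is_masked_box_mean():
    rng = np.random.default_rng(8)
    vol = rng.normal(0, 1, (10, 10, 10))
    mask = rng.random((10, 10, 10)) < 0.9
    from scipy import ndimage

    num = ndimage.uniform_filter(np.where(mask, vol, 0.0), 3, mode="constant")
    den = ndimage.uniform_filter(mask.astype(float), 3, mode="constant")
    expected = np.zeros_like(vol)
    expected[mask] = num[mask] / den[mask]
    assert np.allclose(local_moment(vol, mask, MomentSpec(1, 3)), expected)


@pytest.mark.parametrize("op", ["smooth", "moment"])
def test_operators_commute_with_axis_permutation(op):
    rng = np.random.default_rng(9)
    vol = rng.normal(0, 1, (8, 8, 8))
    mask = rng.random((8, 8, 8)) < 0.8
    perm = (2, 0, 1)
    if op == "smooth":
        f = lambda v, m: gaussian_smooth(v, m, 5)
    else:
        f = lambda v, m: local_moment(v, m, MomentSpec(2, 3))
    assert np.allclose(f(vol.transpose(perm), mask.transpose(perm)),
                       f(vol, mask).transpose(perm))


def test_neighborhood_spec_invariants():
    with pytest.raises(ValueError):
        NeighborhoodSpec(4)
    with pytest.raises(ValueError):
        MomentSpec(k=4, n=3)


# ------------------------------------------------------------------ assembly

TABLE_DIMENSIONS = {
    "unnormalized": 3,
    "normalized": 3,
    "voxel_selection": 3,
    "smoothed": 9,
    "moments": 21,
    "smoothed_and_moments": 27,
}


@pytest.mark.parametrize("kind,dim", sorted(TABLE_DIMENSIONS.items()))
def test_feature_vector_dimensions(study, derived, kind, dim):
    fm = assemble_features(study, kind, derived=derived)
    assert fm.kind.dimension == dim
    assert fm.X.shape[1] == dim
    assert not fm.X.isna().any().any()
    assert set(np.unique(fm.y)) <= {0, 1}


def test_selection_kinds_restrict_rows(study, derived):
    full = assemble_features(study, "normalized", derived=derived)
    sel = assemble_features(study, "voxel_selection", derived=derived)
    assert full.n_rows == int(study.brain_tissue_mask.sum())
    assert sel.n_rows == derived.candidates.n_voxels
    assert sel.n_rows < full.n_rows


def test_column_blocks_order(study, derived):
    fm = assemble_features(study, "smoothed_and_moments", derived=derived)
    cols = fm.columns
    assert cols[:3] == ["t1_norm", "t2_norm", "flair_norm"]
    assert cols[3:9] == [f"{m}_smooth_n{n}" for m in ("t1", "t2", "flair")
                         for n in (21, 41)]
    assert cols[9:] == [f"{m}_mom{k}_n{n}" for m in ("t1", "t2", "flair")
                        for k in (1, 2, 3) for n in (3, 5)]


def test_assembly_deterministic(study, derived):
    a = assemble_features(study, "smoothed", derived=derived)
    b = assemble_features(study, "smoothed", derived=derived)
    assert a.X.equals(b.X)
    assert np.array_equal(a.voxels, b.voxels)


def test_normalized_features_invariant_to_subject_affine(study):
    """Per-subject gain/offset cancels in every normalized-derived feature."""
    # perturb in float64 so the check isn't limited by float32 storage
    perturbed = dataclasses.replace(
        study,
        t1=1.7 * study.t1.astype(np.float64) + 11.0,
        t2=0.6 * study.t2.astype(np.float64) - 40.0,
        flair=2.2 * study.flair.astype(np.float64) + 5.0,
    )
    a = assemble_features(study, "smoothed_and_moments")
    b = assemble_features(perturbed, "smoothed_and_moments")
    assert np.allclose(a.X.to_numpy(), b.X.to_numpy(), atol=1e-8)


def test_missing_mask_errors(default_config):
    bare = lb.generate_study(default_config, 1)
    with pytest.raises(ValueError):
        assemble_features(bare, "normalized")


def test_unknown_kind_rejected():
    with pytest.raises(ValueError):
        feature_kind("banana")


def test_custom_params_change_dimension():
    params = FeatureParams(smooth_ns=(21,), moment_ns=(3,), moment_ks=(1, 2))
    assert feature_kind("smoothed", params).dimension == 6
    assert feature_kind("moments", params).dimension == 9
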