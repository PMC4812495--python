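"""Dice ratio properties and sliding-window segmentation contracts."""

import numpy as np
import pytest

from mscnnseg import LabelVolume, MultimodalVolume, dice_ratio, evaluate_case
from mscnnseg.errors import AlignmentError
from mscnnseg.network.model import Head, MultiscaleModel, build_pathway
from mscnnseg.segmenter import (SegmentationResult, _segment_slice_naive,
                                pixel_accuracy, segment_slice, segment_volume,
                                summarize_cases)
from mscnnseg.volume_io import MODALITIES


@pytest.fixture(scope="module")
def random_model():
    """Untrained desk model: enough to exercise inference mechanics."""
    pathways = {s: build_pathway(s, "desk", seed=s) for s in (48, 28, 12)}
    fused = sum(p.n_features for p in pathways.values())
    head = Head((fused, 16, 5)).init_weights(np.random.default_rng(99))
    return MultiscaleModel(pathways, head)


# ---------------------------------------------------------------- dice ratio

def test_dice_identity_is_one():
    a = np.zeros((5, 5), bool)
    a[1:3, 1:3] = True
    assert dice_ratio(a, a) == 1.0


def test_dice_disjoint_is_zero():
    a = np.zeros(10, bool); a[:3] = True
    b = np.zeros(10, bool); b[5:] = True
    assert dice_ratio(a, b) == 0.0


def test_dice_partial_overlap_matches_set_counting():
    # |A| = 4, |B| = 6, |A ∩ B| = 3 -> 2*3 / (4+6) = 0.6
    a = np.zeros(12, bool); a[:4] = True
    b = np.zeros(12, bool); b[1:7] = True
    assert dice_ratio(a, b) == pytest.approx(0.6)


def test_dice_symmetry_and_empty_convention(rng):
    a = rng.random((6, 6)) > 0.5
    b = rng.random((6, 6)) > 0.5
    assert dice_ratio(a, b) == dice_ratio(b, a)
    empty = np.zeros((6, 6), bool)
    assert dice_ratio(empty, empty) == 1.0


def test_dice_monotone_in_intersection():
    """Growing A ∩ B at fixed |A|, |B| never decreases the Dice ratio."""
    n = 20
    prev = -1.0
    for overlap in range(0, 11):
        a = np.zeros(n, bool); a[:10] = True
        b = np.zeros(n, bool)
        b[10 - overlap:10] = True          # overlap with A
        b[10:10 + (10 - overlap)] = True   # keep |B| = 10
        d = dice_ratio(a, b)
        assert d >= prev
        prev = d


def test_dice_shape_mismatch_rejected():
    with pytest.raises(AlignmentError):
        dice_ratio(np.zeros((3, 3), bool), np.zeros((4, 3), bool))


# ------------------------------------------------------------- segmentation

def test_dense_inference_matches_per_pixel_reference(random_model, rng):
    """Whole-slice convolutional inference equals patch-by-patch classification."""
    sl = rng.standard_normal((52, 50, 4)).astype(np.float32)
    for policy in ("reflect", "skip"):
        dense = segment_slice(random_model, sl, border_policy=policy)
        naive = _segment_slice_naive(random_model, sl, border_policy=policy)
        assert np.array_equal(dense, naive)


def test_output_shape_and_probability_simplex(random_model, rng):
    sl = rng.standard_normal((50, 56, 4)).astype(np.float32)
    labels, probs = segment_slice(random_model, sl, return_proba=True)
    assert labels.shape == (50, 56)
    assert probs.shape == (50, 56, 5)
    assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-5)


def test_skip_policy_zeroes_border_band(random_model, rng):
    sl = rng.standard_normal((60, 60, 4)).astype(np.float32)
    labels = segment_slice(random_model, sl, border_policy="skip")
    assert np.all(labels[:24, :] == 0)
    assert np.all(labels[:, :24] == 0)
    assert np.all(labels[-23:, :] == 0)


def test_volume_equals_slicewise_loop_and_is_deterministic(random_model, rng):
    arr = rng.standard_normal((50, 50, 3, 4)).astype(np.float32)
    vol = MultimodalVolume({m: np.ascontiguousarray(arr[..., i])
                            for i, m in enumerate(MODALITIES)})
    res = segment_volume(random_model, vol)
    assert res.predicted.shape == vol.shape
    stack = vol.stack()
    for z in range(3):
        assert np.array_equal(res.predicted.labels[:, :, z],
                              segment_slice(random_model, stack[:, :, z, :]))
    res2 = segment_volume(random_model, vol)
    assert np.array_equal(res.predicted.labels, res2.predicted.labels)


def test_slice_independence_under_permutation(random_model, rng):
    arr = rng.standard_normal((50, 50, 4, 4)).astype(np.float32)
    vol = MultimodalVolume({m: np.ascontiguousarray(arr[..., i])
                            for i, m in enumerate(MODALITIES)})
    perm = np.array([2, 0, 3, 1])
    vol_p = MultimodalVolume({m: np.ascontiguousarray(vol.channels[m][:, :, perm])
                              for m in MODALITIES})
    res = segment_volume(random_model, vol)
    res_p = segment_volume(random_model, vol_p)
    assert np.array_equal(res_p.predicted.labels, res.predicted.labels[:, :, perm])


def test_stride_inference_fills_every_pixel(random_model, rng):
    sl = rng.standard_normal((50, 50, 4)).astype(np.float32)
    full = segment_slice(random_model, sl)
    strided = segment_slice(random_model, sl, stride=2)
    assert strided.shape == full.shape
    assert np.array_equal(strided[::2, ::2], full[::2, ::2])


# --------------------------------------------------------------- evaluation

def test_perfect_prediction_gives_all_dice_one():
    ref = np.zeros((8, 8, 4), dtype=np.int16)
    ref[2:6, 2:6, 1:3] = 2
    ref[3:5, 3:5, 1:3] = 1
    rep = evaluate_case(LabelVolume(ref.copy()), LabelVolume(ref))
    assert all(r.dice == 1.0 for r in rep.values())


def test_all_zero_prediction_gives_whole_tumor_dice_zero():
    ref = np.zeros((8, 8, 4), dtype=np.int16)
    ref[2:6, 2:6, 1:3] = 4
    rep = evaluate_case(LabelVolume(np.zeros_like(ref)), LabelVolume(ref))
    assert rep["whole"].dice == 0.0
    assert rep["enhancing"].dice == 0.0


def test_summary_matches_hand_computed_mean_and_variance():
    # three toy cases with whole-tumor Dice 1.0, 0.6 and 0.0
    ref = np.zeros((6, 6, 2), dtype=np.int16)
    ref[1:4, 1:3, 0] = 2  # |B| = 6
    case1 = evaluate_case(LabelVolume(ref.copy()), LabelVolume(ref))
    pred2 = np.zeros_like(ref)
    pred2[1:3, 1:3, 0] = 2  # |A| = 4, overlap 4 -> wait: overlap = 4 -> 2*4/10 = 0.8
    pred2[0, 0, 1] = 2      # shrink overlap: |A|=5? adjust below
    # simpler: craft |A| = 4 with 3 overlapping -> dice 0.6
    pred2 = np.zeros_like(ref)
    pred2[1:4, 1, 0] = 2    # 3 overlapping voxels
    pred2[5, 5, 1] = 2      # 1 non-overlapping -> |A| = 4
    case2 = evaluate_case(LabelVolume(pred2), LabelVolume(ref))
    assert case2["whole"].dice == pytest.approx(0.6)
    case3 = evaluate_case(LabelVolume(np.zeros_like(ref)), LabelVolume(ref))
    summary = summarize_cases([case1, case2, case3])
    vals = np.array([1.0, 0.6, 0.0])
    assert summary["whole"]["mean"] == pytest.approx(vals.mean())
    assert summary["whole"]["variance"] == pytest.approx(vals.var())


def test_pixel_accuracy_with_mask():
    pred = np.array([[0, 1], [2, 2]])
    ref = np.array([[0, 1], [2, 3]])
    assert pixel_accuracy(pred, ref) == pytest.approx(0.75)
    mask = np.array([[True, True], [True, False]])
    assert pixel_accuracy(pred, ref, mask) == 1.0
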