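"""Cascade contracts: prior fusion, merging, training, checkpoints."""

import dataclasses

import numpy as np
import pytest

from cardiofab.anatomy import LARGE_CODES, SMALL_CODES
from cardiofab.phantom import PhantomSpec, generate_phantom
from cardiofab.segmentation import (CascadeModel, NetConfig, Prediction,
                                    TrainConfig, downsample_volume, fuse_prior,
                                    load_checkpoint, map_labels,
                                    normalize_intensity, predict,
                                    predict_cascade, save_checkpoint, train,
                                    train_cascade, upsample_prediction)

LS_CODES = (0,) + LARGE_CODES
SS_CODES = (0,) + SMALL_CODES


def _background_prediction(shape, codes):
    probs = np.zeros((len(codes),) + shape, np.float32)
    probs[0] = 1.0
    return Prediction(probs=probs, labels=np.zeros(shape, np.uint8),
                      class_codes=codes)


class _StubNet:
    """Stands in for a trained network; emits fixed logits."""

    trained = True

    def __init__(self, out_classes, fill_class=0, blob=None):
        self.out_classes = out_classes
        self.fill_class = fill_class
        self.blob = blob  # (slice_tuple, class_index)

    def forward(self, x):
        shape = x.shape[1:]
        z = np.full((self.out_classes,) + shape, -10.0, np.float32)
        z[self.fill_class] = 10.0
        if self.blob is not None:
            sl, k = self.blob
            z[:, sl[0], sl[1], sl[2]] = -10.0
            z[(k,) + sl] = 10.0
        return z


def _stub_cascade(use_prior=True, ls_net=None, ss_net=None, cf=1):
    ls_cfg = NetConfig(1, 8, 2, 8)
    ss_cfg = NetConfig(8 if use_prior else 1, 4, 2, 4)
    m = CascadeModel(ls_cfg, ss_cfg, use_prior=use_prior, coarse_factor=cf)
    m.ls_net = ls_net or _StubNet(8)
    m.ss_net = ss_net or _StubNet(4)
    return m


def test_fuse_prior_background_coarse_gives_zero_prior_channels():
    img = np.random.default_rng(0).normal(400, 10, (8, 8, 8)).astype(np.float32)
    fused = fuse_prior(img, _background_prediction((8, 8, 8), LS_CODES))
    assert fused.shape == (8, 8, 8, 8)
    assert np.allclose(fused[1:], 0.0)
    assert np.allclose(fused[0], normalize_intensity(img))


def test_fuse_prior_one_hot_coarse_binary_channels():
    shape = (6, 6, 6)
    probs = np.zeros((8,) + shape, np.float32)
    probs[0] = 1.0
    probs[3, 2:4, 2:4, 2:4] = 1.0  # one-hot LV region
    probs[0, 2:4, 2:4, 2:4] = 0.0
    pred = Prediction(probs=probs, labels=np.zeros(shape, np.uint8),
                      class_codes=LS_CODES)
    fused = fuse_prior(np.ones(shape, np.float32), pred)
    assert set(np.unique(fused[1:])) <= {0.0, 1.0}
    assert (fused[1:].sum(axis=0) <= 1.0 + 1e-6).all()


def test_fuse_prior_grid_mismatch_rejected():
    img = np.zeros((8, 8, 8), np.float32)
    with pytest.raises(ValueError, match="grid"):
        fuse_prior(img, _background_prediction((6, 6, 6), LS_CODES))


def test_prediction_probabilities_must_normalize():
    bad = np.full((2, 4, 4, 4), 0.6, np.float32)
    with pytest.raises(ValueError, match="sum to 1"):
        Prediction(probs=bad, labels=np.zeros((4, 4, 4), np.uint8),
                   class_codes=(0, 1))


def test_argmax_tie_breaks_to_lowest_code():
    net = _StubNet(4, fill_class=0)
    net.forward = lambda x: np.zeros((4,) + x.shape[1:], np.float32)  # all tied
    pred = predict(net, np.zeros((1, 4, 4, 4), np.float32), SS_CODES)
    assert (pred.labels == 0).all()


def test_merged_equals_coarse_when_fine_all_background():
    """SS-Net silent -> merged is exactly the LS-Net label map."""
    ls = _StubNet(8, fill_class=3)  # LV everywhere
    m = _stub_cascade(use_prior=True, ls_net=ls)
    pred = predict_cascade(m, np.zeros((8, 8, 8), np.float32))
    assert pred.provenance == "merged"
    assert (pred.labels == 3).all()  # LV code
    assert np.allclose(pred.probs.sum(axis=0), 1.0, atol=1e-5)


def test_merged_contains_exactly_the_fine_blob():
    """LS-Net silent, SS-Net emits an SVC blob -> merged is that blob."""
    blob = (slice(2, 4), slice(2, 4), slice(2, 4))
    ss = _StubNet(4, fill_class=0, blob=(blob, 1))  # local class 1 = SVC
    m = _stub_cascade(use_prior=True, ss_net=ss)
    pred = predict_cascade(m, np.zeros((8, 8, 8), np.float32))
    expected = np.zeros((8, 8, 8), np.uint8)
    expected[blob] = 5  # SVC code
    assert np.array_equal(pred.labels, expected)


def test_small_structures_take_precedence_on_conflict():
    ls = _StubNet(8, fill_class=3)  # LV everywhere
    blob = (slice(0, 2), slice(0, 2), slice(0, 2))
    ss = _StubNet(4, fill_class=0, blob=(blob, 2))  # IVC blob
    m = _stub_cascade(ls_net=ls, ss_net=ss)
    pred = predict_cascade(m, np.zeros((8, 8, 8), np.float32))
    assert (pred.labels[blob] == 6).all()  # IVC overrides LV
    outside = pred.labels.copy()
    outside[blob] = 3
    assert (outside == 3).all()


def test_untrained_model_rejected():
    net = NetConfig(1, 4, 2, 4).build()
    with pytest.raises(RuntimeError, match="trained"):
        predict(net, np.zeros((1, 8, 8, 8), np.float32), SS_CODES)


def test_ss_net_channel_contract_enforced():
    ls_cfg = NetConfig(1, 8, 2, 8)
    with pytest.raises(ValueError, match="input channels"):
        CascadeModel(ls_cfg, NetConfig(3, 4, 2, 4), use_prior=True)


def test_train_rejects_zero_epochs():
    with pytest.raises(ValueError, match="epochs"):
        TrainConfig(epochs=0)


def test_train_needs_two_cases(desk_phantom):
    net = NetConfig(1, 8, 2, 4).build()
    with pytest.raises(ValueError, match="2 training cases"):
        train(net, [desk_phantom], TrainConfig(epochs=1))


def test_absent_class_warns_but_continues():
    spec = PhantomSpec.desk((48, 48, 48))
    cases = [downsample_volume(generate_phantom(spec.with_seed(s)), 2)
             for s in (0, 1)]
    for c in cases:
        c.labels[c.labels == 9] = 0  # remove AA everywhere
    net = NetConfig(1, 8, 2, 4).build()
    with pytest.warns(UserWarning, match=r"\[9\]"):
        train(net, cases, TrainConfig(epochs=1, seed=0), class_codes=LS_CODES)


def test_training_loss_decreases_and_is_seed_deterministic():
    """Fixed-seed training halves the loss and reproduces bit-identically.

    Uses the coarse stage's setting (half-resolution grid) with the
    depth-3 variant on 4 cases.
    """
    spec = PhantomSpec.desk((48, 48, 48))
    cases = [downsample_volume(generate_phantom(spec.with_seed(100 + s)), 2)
             for s in range(4)]
    cfg = TrainConfig(epochs=30, seed=3, patch_size=None)
    hists = []
    for _ in range(2):
        net = NetConfig(1, 8, 3, 8, False, 3).build()
        hists.append(train(net, cases, cfg, class_codes=LS_CODES))
    assert hists[0] == hists[1]
    assert hists[0][-1] < 0.5 * hists[0][0]


def test_downsample_upsample_shapes(desk_phantom):
    small = downsample_volume(desk_phantom, 2)
    assert small.shape == (24, 24, 24)
    assert small.spacing == (2.0, 2.0, 2.0)
    pred = _background_prediction(small.shape, LS_CODES)
    up = upsample_prediction(pred, 2, desk_phantom.shape)
    assert up.probs.shape == (8,) + desk_phantom.shape


def test_map_labels_sends_foreign_codes_to_background():
    labels = np.array([[0, 5, 3], [9, 8, 6]], dtype=np.uint8)
    mapped = map_labels(labels, SS_CODES)
    # SVC(5)->1, IVC(6)->2, PV(8)->3, everything else 0
    assert mapped.tolist() == [[0, 1, 0], [0, 3, 2]]


def test_checkpoint_roundtrip(tmp_path):
    spec = PhantomSpec.desk((48, 48, 48))
    cases = [generate_phantom(spec.with_seed(s)) for s in (0, 1)]
    model = CascadeModel.create(seed=0)
    train_cascade(model, cases, TrainConfig(epochs=1, seed=0))
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    back = load_checkpoint(path)
    assert back.use_prior == model.use_prior
    assert back.coarse_factor == model.coarse_factor
    img = cases[0].intensity
    a = predict_cascade(model, img)
    b = predict_cascade(back, img)
    assert np.array_equal(a.labels, b.labels)
    assert np.allclose(a.probs, b.probs)
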