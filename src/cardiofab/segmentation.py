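"""Two-stage cascade segmentation of the ten cardiac substructures.

The coarse stage (LS-Net) segments the seven large structures (four
chambers, PA, AA, DA) from the raw image.  The fine stage (SS-Net)
segments the three small veins (SVC, IVC, PV); its input is the image
fused with the coarse stage's per-class probability maps, so the
anatomy of the large structures acts as a spatial prior for the hard,
low-contrast targets.  A spatial-channel co-attention block at the
encoder-decoder junction of either network can be enabled to reweight
features jointly across scales.

Networks are the numpy encoder-decoders from :mod:`cardiofab.nn`; they
are deliberately small so that training runs on a desktop CPU.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .anatomy import LARGE_CODES, SMALL_CODES
from .nn import Adam, UNet3D, dice_ce_loss, softmax
from .phantom import LabeledVolume

__all__ = [
    "NetConfig",
    "downsample_volume",
    "upsample_prediction",
    "TrainConfig",
    "Prediction",
    "CascadeModel",
    "normalize_intensity",
    "fuse_prior",
    "train",
    "predict",
    "train_cascade",
    "predict_cascade",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture of one encoder-decoder network."""

    in_channels: int = 1
    out_classes: int = 2
    depth: int = 2
    base_width: int = 4
    attention_enabled: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.out_classes < 2:
            raise ValueError("out_classes must be >= 2")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")

    def build(self) -> UNet3D:
        return UNet3D(self.in_channels, self.out_classes, self.depth,
                      self.base_width, self.attention_enabled, self.seed)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (soft-Dice + cross-entropy, Adam)."""

    w_dice: float = 1.0
    w_ce: float = 1.0
    lr: float = 3e-3
    epochs: int = 24
    batch_size: int = 1
    patch_size: tuple[int, int, int] | None = (32, 32, 32)
    seed: int = 0

    def __post_init__(self):
        if self.w_dice < 0 or self.w_ce < 0 or (self.w_dice == 0 and self.w_ce == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class Prediction:
    """Per-voxel class probabilities plus a hard label map.

    ``probs`` has shape (K, D, H, W) and sums to 1 over classes;
    ``class_codes`` maps each channel to a global substructure code
    (channel 0 is background).  ``labels`` holds global codes.
    Argmax ties break toward the lowest class code (first channel).
    """

    probs: np.ndarray
    labels: np.ndarray
    class_codes: tuple[int, ...]
    provenance: str = "coarse"

    def __post_init__(self):
        s = self.probs.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("class probabilities must sum to 1 per voxel")
        if self.provenance not in ("coarse", "fine", "merged"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance normalization (the network input scale)."""
    img = image.astype(np.float32)
    return (img - img.mean()) / (img.std() + 1e-6)


def map_labels(labels: np.ndarray, class_codes: tuple[int, ...]) -> np.ndarray:
    """Map global substructure codes to a net's contiguous class ids.

    Codes outside ``class_codes`` map to background (0).
    """
    out = np.zeros(labels.shape, dtype=np.int64)
    for local, code in enumerate(class_codes):
        if code != 0:
            out[labels == code] = local
    return out


def downsample_volume(vol: LabeledVolume, factor: int) -> LabeledVolume:
    """Average-pool the intensity and stride-subsample the labels."""
    if factor == 1:
        return vol
    z, y, x = (s // factor for s in vol.shape)
    inten = vol.intensity[:z * factor, :y * factor, :x * factor].reshape(
        z, factor, y, factor, x, factor).mean(axis=(1, 3, 5)).astype(np.float32)
    labels = vol.labels[::factor, ::factor, ::factor][:z, :y, :x]
    return LabeledVolume(intensity=inten, labels=labels,
                         spacing=tuple(s * factor for s in vol.spacing),
                         case_id=vol.case_id)


def upsample_prediction(pred: Prediction, factor: int,
                        shape: tuple[int, int, int]) -> Prediction:
    """Nearest-neighbour upsample a Prediction onto a finer grid."""
    if factor == 1:
        return pred
    probs = pred.probs.repeat(factor, axis=1).repeat(factor, axis=2) \
        .repeat(factor, axis=3)
    pz, py, px = probs.shape[1:]
    pad = [(0, 0)] + [(0, max(0, t - s)) for t, s in zip(shape, (pz, py, px))]
    probs = np.pad(probs, pad, mode="edge")[:, :shape[0], :shape[1], :shape[2]]
    labels = np.asarray(pred.class_codes, dtype=np.uint8)[probs.argmax(axis=0)]
    return Prediction(probs=probs, labels=labels,
                      class_codes=pred.class_codes, provenance=pred.provenance)


def fuse_prior(image: np.ndarray, coarse: Prediction) -> np.ndarray:
    """Stack the normalized image with the coarse prior probabilities.

    Channel 0 is the normalized intensity; channels 1..7 are the coarse
    per-class probability maps of the large structures, ordered by
    substructure code.  Probabilities (not hard labels) are used so the
    fine stage sees the coarse stage's uncertainty.
    """
    if coarse.probs.shape[1:] != image.shape:
        raise ValueError(
            f"prior grid {coarse.probs.shape[1:]} != image grid {image.shape}")
    return np.concatenate(
        [normalize_intensity(image)[None], coarse.probs[1:].astype(np.float32)],
        axis=0)


def _sample_patch(rng, inputs: np.ndarray, labels: np.ndarray,
                  patch: tuple[int, int, int], fg_voxels: dict):
    """Class-balanced foreground-biased random crop.

    With probability 0.7 the crop is centred on a voxel of one of the
    present foreground classes, the class drawn uniformly so rare
    targets (the small veins) are sampled as often as large chambers.
    """
    shape = labels.shape
    if all(p >= s for p, s in zip(patch, shape)):
        return inputs, labels
    present = list(fg_voxels)
    if present and rng.random() < 0.7:
        vox = fg_voxels[present[rng.integers(len(present))]]
        center = vox[rng.integers(len(vox))]
    else:
        center = np.array([rng.integers(s) for s in shape])
    lo = [int(np.clip(c - p // 2, 0, s - p)) for c, p, s in zip(center, patch, shape)]
    sl = tuple(slice(l, l + p) for l, p in zip(lo, patch))
    return inputs[(slice(None),) + sl], labels[sl]


def train(net: UNet3D, cases: list, config: TrainConfig,
          class_codes: tuple[int, ...] | None = None) -> list[float]:
    """Train one network; returns the per-epoch mean loss history.

    ``cases`` is a list of either :class:`LabeledVolume` (single-channel
    input) or ``(input_channels, label_map)`` pairs with global codes in
    the label map.  ``class_codes`` names the global codes of the net's
    non-background channels (defaults to 1..out_classes-1); labels
    outside the set are treated as background.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 training cases")
    if class_codes is None:
        class_codes = tuple(range(net.out_classes))
    elif class_codes[0] != 0:
        class_codes = (0,) + tuple(class_codes)
    prepared = []
    for c in cases:
        if isinstance(c, LabeledVolume):
            x, y = normalize_intensity(c.intensity)[None], c.labels
        else:
            x, y = c
            x = x.astype(np.float32)
        prepared.append((x, map_labels(np.asarray(y), class_codes)))
    fg_index = []
    counts = np.zeros(net.out_classes, dtype=np.int64)
    for _, y in prepared:
        uniq, cnt = np.unique(y, return_counts=True)
        counts[uniq] += cnt
        fg_index.append({int(k): np.argwhere(y == k) for k in uniq if k > 0})
    absent = [class_codes[k] for k in range(1, len(class_codes)) if counts[k] == 0]
    if absent:
        warnings.warn(f"classes {absent} absent from every training case; kept",
                      stacklevel=2)
    # inverse-sqrt-frequency CE weights: the veins are orders of
    # magnitude rarer than background and otherwise may never leave the
    # all-background optimum
    cw = 1.0 / np.sqrt(np.maximum(counts, 1).astype(np.float64))
    cw /= cw.mean()
    cw = cw.astype(np.float32)

    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params(), lr=config.lr)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(len(prepared))
        losses = []
        for i in order:
            x, y = prepared[i]
            if config.patch_size is not None:
                x, y = _sample_patch(rng, x, y, config.patch_size, fg_index[i])
            logits = net.forward(x)
            loss, dz = dice_ce_loss(logits, y, config.w_dice, config.w_ce,
                                    class_weights=cw)
            net.zero_grad()
            net.backward(dz)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    net.trained = True
    return history


def predict(net: UNet3D, inputs: np.ndarray,
            class_codes: tuple[int, ...], provenance: str = "coarse") -> Prediction:
    """Full-volume forward pass -> softmax probabilities + argmax labels."""
    if not getattr(net, "trained", False):
        raise RuntimeError("network has not been trained")
    logits = net.forward(inputs)
    probs = softmax(logits)
    local = probs.argmax(axis=0)  # first (lowest-code) channel wins ties
    codes = np.asarray(class_codes, dtype=np.uint8)
    return Prediction(probs=probs, labels=codes[local],
                      class_codes=tuple(class_codes), provenance=provenance)


@dataclass
class CascadeModel:
    """Paired coarse (large-structure) and fine (small-structure) nets.

    ``use_prior=False`` degrades the fine stage to a plain image-only
    network (the "two-stage" ablation arm).  The two networks share no
    parameters.
    """

    ls_config: NetConfig
    ss_config: NetConfig
    use_prior: bool = True
    coarse_factor: int = 1
    ls_codes: tuple[int, ...] = (0,) + LARGE_CODES
    ss_codes: tuple[int, ...] = (0,) + SMALL_CODES
    ls_net: UNet3D = field(default=None, repr=False)
    ss_net: UNet3D = field(default=None, repr=False)

    @classmethod
    def create(cls, depth: int = 2, ls_width: int = 8, ss_width: int = 6,
               use_prior: bool = True, attention: bool = False,
               coarse_factor: int = 2, seed: int = 0) -> "CascadeModel":
        """Study-default cascade: a wider coarse net on a grid coarsened
        by ``coarse_factor``, and a lean fine net at full resolution."""
        n_large = len(LARGE_CODES)
        ls_cfg = NetConfig(1, 1 + n_large, depth, ls_width, False, seed)
        ss_in = 1 + n_large if use_prior else 1
        ss_cfg = NetConfig(ss_in, 1 + len(SMALL_CODES), depth, ss_width,
                           attention, seed + 1)
        m = cls(ls_cfg, ss_cfg, use_prior=use_prior, coarse_factor=coarse_factor)
        m.ls_net = ls_cfg.build()
        m.ss_net = ss_cfg.build()
        return m

    def __post_init__(self):
        expected = 1 + (len(self.ls_codes) - 1 if self.use_prior else 0)
        if self.ss_config.in_channels != expected:
            raise ValueError(
                f"SS-Net expects {expected} input channels "
                f"(1 image + {expected - 1} prior), got {self.ss_config.in_channels}")


def _coarse_predict(model: CascadeModel, image: np.ndarray) -> Prediction:
    """Coarse-stage prediction on the full grid (trained at reduced
    resolution, probabilities upsampled back)."""
    cf = model.coarse_factor
    vol = LabeledVolume(intensity=np.asarray(image, dtype=np.float32),
                        labels=np.zeros(image.shape, np.uint8),
                        spacing=(1.0, 1.0, 1.0))
    small = downsample_volume(vol, cf)
    pred = predict(model.ls_net, normalize_intensity(small.intensity)[None],
                   model.ls_codes, "coarse")
    return upsample_prediction(pred, cf, image.shape)


def train_cascade(model: CascadeModel, cases: list[LabeledVolume],
                  config: TrainConfig,
                  ls_net=None) -> dict[str, list[float]]:
    """Train the coarse stage, then the fine stage on fused inputs.

    The fine stage's prior channels are the trained coarse stage's own
    probability maps on each training case (its actual test-time input
    distribution), not the ground truth.  An already-trained coarse net
    of the same configuration may be supplied to skip its (identical)
    training.
    """
    cf = model.coarse_factor
    if ls_net is not None:
        model.ls_net = ls_net
        hist_ls = []
    else:
        ls_cases = [downsample_volume(c, cf) for c in cases]
        hist_ls = train(model.ls_net, ls_cases, config, class_codes=model.ls_codes)
    if model.use_prior:
        ss_cases = []
        for c in cases:
            coarse = _coarse_predict(model, c.intensity)
            ss_cases.append((fuse_prior(c.intensity, coarse), c.labels))
    else:
        ss_cases = [(normalize_intensity(c.intensity)[None], c.labels) for c in cases]
    import dataclasses as _dc

    ss_config = _dc.replace(config, seed=config.seed + 1)
    hist_ss = train(model.ss_net, ss_cases, ss_config, class_codes=model.ss_codes)
    return {"ls": hist_ls, "ss": hist_ss}


def predict_cascade(model: CascadeModel, image: np.ndarray) -> Prediction:
    """Run the full coarse-to-fine cascade on one volume.

    The merged hard map is the coarse large-structure labels overwritten
    by the fine stage's small-structure labels wherever the fine stage
    is non-background (the small, hard targets take precedence).  The
    merged probabilities distribute the fine stage's background mass
    over the coarse classes, so they still sum to 1 per voxel.
    """
    coarse = _coarse_predict(model, image)
    ss_in = fuse_prior(image, coarse) if model.use_prior \
        else normalize_intensity(image)[None]
    fine = predict(model.ss_net, ss_in, model.ss_codes, "fine")
    merged_labels = coarse.labels.copy()
    small_fg = fine.labels > 0
    merged_labels[small_fg] = fine.labels[small_fg]
    probs = np.concatenate([coarse.probs * fine.probs[0][None], fine.probs[1:]])
    codes = model.ls_codes + model.ss_codes[1:]
    order = np.argsort(codes)
    return Prediction(probs=probs[order], labels=merged_labels,
                      class_codes=tuple(int(codes[i]) for i in order),
                      provenance="merged")


def save_checkpoint(model: CascadeModel, path) -> None:
    """Serialize both networks and their configs into one .npz file."""
    arrays = {}
    for name, net in (("ls", model.ls_net), ("ss", model.ss_net)):
        for i, p in enumerate(net.params()):
            arrays[f"{name}_{i}"] = p.v
    meta = {
        "ls_config": asdict(model.ls_config),
        "ss_config": asdict(model.ss_config),
        "use_prior": model.use_prior,
        "coarse_factor": model.coarse_factor,
        "ls_codes": list(model.ls_codes),
        "ss_codes": list(model.ss_codes),
        "trained": bool(getattr(model.ls_net, "trained", False)
                        and getattr(model.ss_net, "trained", False)),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_checkpoint(path) -> CascadeModel:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model = CascadeModel(
            ls_config=NetConfig(**meta["ls_config"]),
            ss_config=NetConfig(**meta["ss_config"]),
            use_prior=meta["use_prior"],
            coarse_factor=meta.get("coarse_factor", 1),
            ls_codes=tuple(meta["ls_codes"]),
            ss_codes=tuple(meta["ss_codes"]),
        )
        model.ls_net = model.ls_config.build()
        model.ss_net = model.ss_config.build()
        for name, net in (("ls", model.ls_net), ("ss", model.ss_net)):
            for i, p in enumerate(net.params()):
                p.v[:] = data[f"{name}_{i}"]
            net.trained = meta["trained"]
    return model
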