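"""Patch feature extraction: 512x512 RGB patches -> 1x256 feature vectors.

Two encoder kinds are provided behind one interface:

``fixture``
    A deterministic, dependency-free encoder for testing and synthetic
    cohorts: closed-form per-patch summary statistics (channel moments and
    a saturation histogram) pushed through a fixed, seeded random
    projection to 256 dimensions.

``truncated-residual-net``
    An 18-layer residual architecture truncated after its third residual
    stage (256 channels), globally average-pooled to a 256-vector.
    Implemented in NumPy, forward-only; weights come from an ``.npz`` file
    or are drawn from a seeded initialiser. Pretrained weights are a
    plug-in, never bundled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import h5py
import numpy as np

from .segment import PatchGrid

__all__ = [
    "FeatureBag",
    "EncoderSpec",
    "encode_patches",
    "iter_patches",
    "fixture_statistics",
    "fixture_projection",
    "save_bag",
    "load_bag",
]

FEATURE_DIM = 256
PATCH_SIZE = 512
_N_SAT_BINS = 16
_N_STATS = 12 + _N_SAT_BINS  # per-channel mean/var/min/max + saturation histogram

# Channel statistics conventionally paired with ImageNet-pretrained weights.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class EncoderSpec:
    """Configuration of a patch encoder; output dimension is fixed at 256."""

    kind: str = "fixture"  # {"fixture", "truncated-residual-net"}
    weights_source: str = "random"
    seed: int = 0
    normalization: str = "default"  # "default" | "identity"

    def __post_init__(self) -> None:
        if self.kind not in ("fixture", "truncated-residual-net"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")


@dataclass
class FeatureBag:
    """One patient's slide as a bag of M patch feature vectors (M x 256)."""

    slide_id: str
    features: np.ndarray  # (M, 256) float32
    coords: np.ndarray  # (M, 2) int64

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32).reshape(
            -1, FEATURE_DIM
        )
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if len(self.features) != len(self.coords):
            raise ValueError(
                f"feature rows ({len(self.features)}) != coords ({len(self.coords)})"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("bag contains non-finite feature values")

    def __len__(self) -> int:
        return len(self.features)


def iter_patches(image: np.ndarray, grid: PatchGrid) -> Iterator[np.ndarray]:
    """Yield the RGB pixel block of each patch in grid order."""
    p = grid.patch_size
    for x, y in grid.coords:
        yield image[y : y + p, x : x + p]


# ---------------------------------------------------------------------------
# fixture encoder
# ---------------------------------------------------------------------------


def fixture_statistics(patch: np.ndarray) -> np.ndarray:
    """Closed-form summary statistics of one RGB patch.

    Per channel: mean, variance, min, max of the [0, 1]-scaled intensities,
    followed by a 16-bin saturation histogram (fractions summing to 1).
    """
    x = np.asarray(patch, dtype=np.float32)
    # channel-major contiguous layout keeps the reductions cache-friendly
    xc = np.ascontiguousarray(x.transpose(2, 0, 1).reshape(3, -1)) / np.float32(255.0)
    stats = np.stack(
        [xc.mean(axis=1), xc.var(axis=1), xc.min(axis=1), xc.max(axis=1)], axis=1
    ).ravel()  # per channel: mean, var, min, max
    cmax = np.maximum(np.maximum(xc[0], xc[1]), xc[2])
    cmin = np.minimum(np.minimum(xc[0], xc[1]), xc[2])
    sat = np.divide(cmax - cmin, cmax, out=np.zeros_like(cmax), where=cmax > 0)
    hist, _ = np.histogram(sat, bins=_N_SAT_BINS, range=(0.0, 1.0))
    return np.concatenate([stats, hist / max(sat.size, 1)]).astype(np.float64)


def fixture_projection(seed: int) -> np.ndarray:
    """The fixed seeded Gaussian projection (256 x n_stats) of the fixture encoder."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((FEATURE_DIM, _N_STATS)) / np.sqrt(_N_STATS)


def _encode_fixture(patches: Iterable[np.ndarray], spec: EncoderSpec) -> np.ndarray:
    proj = fixture_projection(spec.seed)
    rows = [proj @ fixture_statistics(p) for p in patches]
    if not rows:
        return np.empty((0, FEATURE_DIM), dtype=np.float32)
    return np.asarray(rows, dtype=np.float32)


# ---------------------------------------------------------------------------
# truncated residual network (NumPy, forward-only)
# ---------------------------------------------------------------------------


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """im2col convolution; x: (C, H, W), w: (O, C, k, k) -> (O, H', W')."""
    c, h, wid = x.shape
    o, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (wid + 2 * pad - k) // stride + 1
    shape = (c, k, k, oh, ow)
    strides = (
        xp.strides[0],
        xp.strides[1],
        xp.strides[2],
        xp.strides[1] * stride,
        xp.strides[2] * stride,
    )
    col = np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)
    col = col.reshape(c * k * k, oh * ow)
    return (w.reshape(o, -1) @ col).reshape(o, oh, ow)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, : h2 * 2, : w2 * 2].reshape(c, h2, 2, w2, 2).max(axis=(2, 4))


def _bn(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    xn = (x - mu) / np.sqrt(var + 1e-5)
    return gamma[:, None, None] * xn + beta[:, None, None]


_STAGE_PLAN = [  # (out_channels, stride of first block), two basic blocks each
    (64, 1),
    (128, 2),
    (256, 2),
]


def _init_resnet_weights(seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)

    def he(shape):
        fan_in = int(np.prod(shape[1:]))
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    w: dict[str, np.ndarray] = {"conv1": he((64, 3, 7, 7))}
    w["bn1.gamma"], w["bn1.beta"] = np.ones(64, np.float32), np.zeros(64, np.float32)
    cin = 64
    for si, (cout, _) in enumerate(_STAGE_PLAN):
        for bi in range(2):
            c0 = cin if bi == 0 else cout
            pre = f"s{si}.b{bi}"
            w[f"{pre}.conv1"] = he((cout, c0, 3, 3))
            w[f"{pre}.conv2"] = he((cout, cout, 3, 3))
            for j in (1, 2):
                w[f"{pre}.bn{j}.gamma"] = np.ones(cout, np.float32)
                w[f"{pre}.bn{j}.beta"] = np.zeros(cout, np.float32)
            if bi == 0 and c0 != cout:
                w[f"{pre}.down"] = he((cout, c0, 1, 1))
        cin = cout
    return w


def _resnet_forward(x: np.ndarray, w: dict[str, np.ndarray]) -> np.ndarray:
    """Stages 1-3 of an 18-layer residual net; x: (3, H, W) -> (256,)."""
    y = _conv2d(x, w["conv1"], stride=2, pad=3)
    y = np.maximum(_bn(y, w["bn1.gamma"], w["bn1.beta"]), 0.0)
    y = _maxpool2(y)
    for si, (cout, stride) in enumerate(_STAGE_PLAN):
        for bi in range(2):
            pre = f"s{si}.b{bi}"
            s = stride if bi == 0 else 1
            out = _conv2d(y, w[f"{pre}.conv1"], stride=s, pad=1)
            out = np.maximum(_bn(out, w[f"{pre}.bn1.gamma"], w[f"{pre}.bn1.beta"]), 0.0)
            out = _conv2d(out, w[f"{pre}.conv2"], stride=1, pad=1)
            out = _bn(out, w[f"{pre}.bn2.gamma"], w[f"{pre}.bn2.beta"])
            identity = y
            if f"{pre}.down" in w:
                identity = _conv2d(y, w[f"{pre}.down"], stride=s, pad=0)
            elif s != 1:
                identity = y[:, ::s, ::s]
            y = np.maximum(out + identity, 0.0)
    return y.mean(axis=(1, 2))  # global average pool -> 256


def _encode_resnet(patches: Iterable[np.ndarray], spec: EncoderSpec) -> np.ndarray:
    if spec.weights_source == "random":
        weights = _init_resnet_weights(spec.seed)
    else:
        try:
            with np.load(spec.weights_source) as npz:
                weights = {k: npz[k] for k in npz.files}
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"encoder weights file not found: {spec.weights_source!r}"
            ) from exc
    rows = []
    for patch in patches:
        x = np.asarray(patch, dtype=np.float32) / 255.0
        if spec.normalization == "default":
            x = (x - IMAGENET_MEAN) / IMAGENET_STD
        rows.append(_resnet_forward(x.transpose(2, 0, 1), weights))
    if not rows:
        return np.empty((0, FEATURE_DIM), dtype=np.float32)
    return np.asarray(rows, dtype=np.float32)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def encode_patches(
    patches: Iterable[np.ndarray],
    spec: EncoderSpec,
    slide_id: str = "",
    coords: np.ndarray | None = None,
) -> FeatureBag:
    """Encode an iterable of 512x512 RGB patches into a :class:`FeatureBag`.

    ``coords`` must align with the patch iteration order; it defaults to a
    running index placed on the x axis when patches come without geometry.
    """
    patches = list(patches)
    for p in patches:
        p = np.asarray(p)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"patch must be RGB (H, W, 3), got {p.shape}")
        if p.shape[0] != PATCH_SIZE or p.shape[1] != PATCH_SIZE:
            raise ValueError(
                f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {p.shape[:2]}"
            )
    if spec.kind == "fixture":
        feats = _encode_fixture(patches, spec)
    else:
        feats = _encode_resnet(patches, spec)
    if coords is None:
        coords = np.stack(
            [np.arange(len(patches)), np.zeros(len(patches), dtype=np.int64)], axis=1
        )
    return FeatureBag(slide_id=slide_id, features=feats, coords=coords)


def encode_slide(
    image: np.ndarray, grid: PatchGrid, spec: EncoderSpec
) -> FeatureBag:
    """Encode every patch of ``grid`` cut from ``image``."""
    return encode_patches(
        iter_patches(image, grid), spec, slide_id=grid.slide_id, coords=grid.coords
    )


def save_bag(bag: FeatureBag, path: str, spec: EncoderSpec | None = None) -> None:
    """Write features + coords to HDF5 (same layout as the patch store)."""
    with h5py.File(path, "a") as f:
        for name in ("features", "coords"):
            if name in f:
                del f[name]
        f.create_dataset("features", data=bag.features, dtype=np.float32)
        f.create_dataset("coords", data=bag.coords, dtype=np.int64)
        f.attrs["slide_id"] = bag.slide_id
        if spec is not None:
            f.attrs["encoder_spec"] = json.dumps(
                {
                    "kind": spec.kind,
                    "weights_source": spec.weights_source,
                    "seed": spec.seed,
                    "normalization": spec.normalization,
                },
                sort_keys=True,
            )


def load_bag(path: str) -> FeatureBag:
    with h5py.File(path, "r") as f:
        for name in ("features", "coords"):
            if name not in f:
                raise KeyError(f"bag file {path!r} is missing dataset '/{name}'")
        feats = f["features"][...]
        coords = f["coords"][...]
        if len(feats) != len(coords):
            raise ValueError(
                f"bag file {path!r} is inconsistent: "
                f"{len(feats)} feature rows vs {len(coords)} coords"
            )
        return FeatureBag(
            slide_id=str(f.attrs.get("slide_id", "")), features=feats, coords=coords
        )
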