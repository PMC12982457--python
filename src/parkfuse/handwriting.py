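"""Handwriting pipeline: spiral images -> curvature profiles + residual CNN.

Spiral-tracing images are converted to grayscale, resized to 224x224 and
contrast-normalized; the drawn stroke can additionally be skeletonized
into an ordered centerline trace whose spline-smoothed derivatives yield
the signed curvature profile kappa(t) = (x'y'' - y'x'') / (x'^2+y'^2)^1.5
— an ancillary tremor diagnostic.  Classification uses a reduced residual
CNN (identity-shortcut blocks, GAP head); the GAP vector is the exported
handwriting embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.interpolate import splev, splprep
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from ._nn import AvgPool2d, Conv2d, Dense, ReLU, Residual, Sequential, softmax
from .errors import ConfigError, TraceError
from .types import Embedding, ModalitySample, class_index
from .speech import _train_encoder

IMAGE_SIZE = 224

# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------


@dataclass
class PreprocessedImage:
    pixels: np.ndarray  # 224x224 grayscale in [0, 1]
    original_size: tuple[int, int] = (IMAGE_SIZE, IMAGE_SIZE)
    contrast_range: tuple[float, float] = (0.0, 1.0)


def preprocess_image(raw: np.ndarray | Image.Image | str | Path) -> PreprocessedImage:
    """Grayscale -> bilinear resize to 224x224 -> min-max contrast
    normalization to [0, 1] (a constant image maps to all zeros)."""
    if isinstance(raw, (str, Path)):
        raw = Image.open(raw)
    if isinstance(raw, Image.Image):
        img = raw.convert("L").resize((IMAGE_SIZE, IMAGE_SIZE), Image.BILINEAR)
        size = raw.size
        px = np.asarray(img, dtype=float) / 255.0
    else:
        # float arrays stay float end-to-end (no 8-bit quantization), which
        # makes preprocess(preprocess(x)) == preprocess(x)
        arr = np.asarray(raw, dtype=float)
        if arr.ndim == 3:  # RGB(A) -> luminance
            arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
        if arr.max() > 1.0:
            arr = arr / 255.0
        size = (arr.shape[1], arr.shape[0])
        if arr.shape != (IMAGE_SIZE, IMAGE_SIZE):
            from skimage.transform import resize

            arr = resize(arr, (IMAGE_SIZE, IMAGE_SIZE), order=1,
                         anti_aliasing=False)
        px = arr
    lo, hi = float(px.min()), float(px.max())
    if hi - lo < 1e-12:
        px = np.zeros_like(px)
    else:
        px = (px - lo) / (hi - lo)
    return PreprocessedImage(pixels=px, original_size=size, contrast_range=(lo, hi))


# --------------------------------------------------------------------------
# stroke trace and curvature
# --------------------------------------------------------------------------


@dataclass
class Trace:
    """Ordered stroke centerline with spline-estimated derivatives."""

    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    ddx: np.ndarray
    ddy: np.ndarray

    @property
    def arc_length(self) -> np.ndarray:
        steps = np.hypot(np.diff(self.x), np.diff(self.y))
        return np.concatenate([[0.0], np.cumsum(steps)])


def extract_trace(image: np.ndarray | PreprocessedImage, threshold: float = 0.5,
                  smoothing: float | None = None, n_points: int = 400) -> Trace:
    """Skeletonize the dark stroke and order it from the spiral center
    outward; a smoothing spline provides the derivatives.

    Raises :class:`TraceError` for a blank image or a disconnected stroke.
    """
    px = image.pixels if isinstance(image, PreprocessedImage) else np.asarray(image)
    mask = px < threshold
    if not mask.any():
        raise TraceError("no dark stroke found (blank image?)")
    labels = cc_label(mask, connectivity=2)
    n_comp = labels.max()
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        main = int(sizes.argmax()) + 1
        if sizes.sum() - sizes.max() > 0.05 * sizes.sum():
            raise TraceError(
                f"stroke is disconnected: {n_comp} components with sizes {sizes.tolist()}")
        mask = labels == main
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    if xs.size < 5:
        raise TraceError("skeleton too short to trace")

    # order by nearest-neighbour walk seeded at the innermost point
    cy, cx = ys.mean(), xs.mean()
    pts = np.column_stack([xs, ys]).astype(float)
    d_center = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    current = int(d_center.argmin())
    remaining = np.ones(len(pts), dtype=bool)
    order = [current]
    remaining[current] = False
    while remaining.any():
        idx = np.flatnonzero(remaining)
        d = np.hypot(pts[idx, 0] - pts[current, 0], pts[idx, 1] - pts[current, 1])
        j = int(d.argmin())
        if d[j] > 5.0:  # gap: stop rather than jump across the spiral
            break
        current = int(idx[j])
        order.append(current)
        remaining[current] = False
    path = pts[order]
    if len(path) < 5:
        raise TraceError("ordered path too short")

    # spline fit for derivative estimation
    s = smoothing if smoothing is not None else 0.5 * len(path)
    tck, _ = splprep([path[:, 0], path[:, 1]], s=s, k=3)
    u = np.linspace(0.0, 1.0, n_points)
    x, y = splev(u, tck)
    dx, dy = splev(u, tck, der=1)
    ddx, ddy = splev(u, tck, der=2)
    return Trace(x=np.asarray(x), y=np.asarray(y), dx=np.asarray(dx),
                 dy=np.asarray(dy), ddx=np.asarray(ddx), ddy=np.asarray(ddy))


@dataclass
class CurvatureProfile:
    kappa: np.ndarray          # 1/px; NaN where speed < eps
    valid: np.ndarray          # bool mask of well-defined samples
    trace: Trace


def curvature_profile(trace: Trace, eps: float = 1e-9) -> CurvatureProfile:
    """kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^{3/2}; samples where the
    parametric speed falls below ``eps`` are masked NaN."""
    if trace.x.size < 5:
        raise ConfigError("trace needs >= 5 points")
    speed_sq = trace.dx**2 + trace.dy**2
    valid = speed_sq > eps
    kappa = np.full(trace.x.shape, np.nan)
    num = trace.dx[valid] * trace.ddy[valid] - trace.dy[valid] * trace.ddx[valid]
    kappa[valid] = num / speed_sq[valid] ** 1.5
    return CurvatureProfile(kappa=kappa, valid=valid, trace=trace)


def curvature_summary(profile: CurvatureProfile) -> np.ndarray:
    """(mean, SD, max) of |kappa| — the optional feature-channel stats."""
    k = np.abs(profile.kappa[profile.valid])
    return np.array([k.mean(), k.std(), k.max()])


# --------------------------------------------------------------------------
# residual CNN encoder
# --------------------------------------------------------------------------


@dataclass
class ResNetSpec:
    """Reduced residual encoder (identity shortcuts, GAP head).

    ``stages`` lists (out_channels, stride) for the downsampling conv that
    opens each stage; each stage is followed by ``blocks_per_stage``
    identity residual blocks at that width.
    """

    in_channels: int = 1
    stem_pool: int = 4  # average-pool factor applied before the stem conv
    stem_channels: int = 8
    stages: tuple[tuple[int, int], ...] = ((16, 2), (32, 2), (48, 2))
    blocks_per_stage: int = 1
    n_classes: int = 2

    @property
    def embedding_dim(self) -> int:
        return self.stages[-1][0]


class HandwritingEncoder:
    """Residual CNN over preprocessed spiral images."""

    def __init__(self, spec: ResNetSpec) -> None:
        self.spec = spec
        layers: list = []
        if spec.stem_pool > 1:
            layers.append(AvgPool2d(spec.stem_pool))
        layers.extend([Conv2d(spec.in_channels, spec.stem_channels, 3, stride=1), ReLU()])
        c = spec.stem_channels
        for c_out, stride in spec.stages:
            layers.extend([Conv2d(c, c_out, 3, stride=stride), ReLU()])
            for _ in range(spec.blocks_per_stage):
                layers.append(Residual([Conv2d(c_out, c_out, 3), ReLU(),
                                        Conv2d(c_out, c_out, 3)]))
                layers.append(ReLU())
            c = c_out
        self.features = Sequential(layers)
        self.head = Dense(c, spec.n_classes)

    def initialize(self, rng: np.random.Generator) -> None:
        self.features.initialize(rng)
        self.head.initialize(rng)
        for layer in self.features.layers:
            if isinstance(layer, Residual):
                layer.zero_init_tail()

    def params(self):
        return self.features.params() + self.head.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.features.forward(x)
        self._gap_shape = h.shape
        z = h.mean(axis=(2, 3))
        return self.head.forward(z)

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        gz = self.head.backward(grad_logits)
        b, c, hh, ww = self._gap_shape
        gh = np.broadcast_to(gz[:, :, None, None], self._gap_shape) / (hh * ww)
        return self.features.backward(gh.copy())

    def gap_embedding(self, x: np.ndarray) -> np.ndarray:
        h = self.features.forward(x)
        return h.mean(axis=(2, 3))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))


def train_handwriting_encoder(dataset, spec: ResNetSpec | None = None,
                              epochs: int = 20, lr: float = 3e-3, seed: int = 0):
    """Train on (image, label) pairs (or a pre-stacked (x, y) tuple);
    returns (model, loss trace, accuracy trace)."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        x, y = dataset
    else:
        x = np.stack([np.asarray(img.pixels if isinstance(img, PreprocessedImage) else img)
                      for img, _ in dataset])[:, None]
        y = np.array([class_index(lbl) for _, lbl in dataset])
    if np.unique(y).size < 2:
        raise ConfigError("training set must contain >= 2 classes")
    spec = spec or ResNetSpec(n_classes=int(y.max()) + 1)
    model = HandwritingEncoder(spec)
    loss_trace, acc_trace = _train_encoder(model, x, y, epochs, lr, seed,
                                           track_accuracy=True)
    return model, loss_trace, acc_trace


def embed_handwriting(model: HandwritingEncoder, image: np.ndarray | PreprocessedImage,
                      subject_id: str = "", label: str = "hc") -> Embedding:
    px = image.pixels if isinstance(image, PreprocessedImage) else np.asarray(image)
    if px.shape != (IMAGE_SIZE, IMAGE_SIZE):
        raise ConfigError(f"expected {IMAGE_SIZE}x{IMAGE_SIZE} image, got {px.shape}")
    vec = model.gap_embedding(px[None, None])[0]
    return Embedding(vector=vec, modality="handwriting", subject_id=subject_id,
                     label=label)


# --------------------------------------------------------------------------
# end-to-end unimodal handwriting model
# --------------------------------------------------------------------------


class HandwritingUnimodalModel:
    """Image -> preprocess -> residual CNN -> class probabilities.

    ``append_curvature=True`` additionally concatenates the (mean, SD, max)
    of |kappa| onto the exported embedding (off by default; the curvature
    profile is an ancillary diagnostic).
    """

    def __init__(self, spec: ResNetSpec | None = None, epochs: int = 10,
                 lr: float = 3e-3, seed: int = 0,
                 append_curvature: bool = False) -> None:
        self.spec = spec
        self.epochs, self.lr, self.seed = epochs, lr, seed
        self.append_curvature = append_curvature
        self.loss_trace_: list[float] = []
        self.acc_trace_: list[float] = []

    def _features(self, samples: list[ModalitySample]) -> np.ndarray:
        # the network sees ink intensity (1 - pixel): a sparse positive
        # stroke on a zero background conditions the convolutions far
        # better than a thin dark line on a saturated white field
        return 1.0 - np.stack([preprocess_image(s.data).pixels
                               for s in samples])[:, None]

    def fit(self, samples: list[ModalitySample]) -> "HandwritingUnimodalModel":
        x = self._features(samples)
        y = np.array([class_index(s.label) for s in samples])
        self.model_, self.loss_trace_, self.acc_trace_ = train_handwriting_encoder(
            (x, y), self.spec, epochs=self.epochs, lr=self.lr, seed=self.seed)
        return self

    def embed_subjects(self, samples: list[ModalitySample]) -> list[Embedding]:
        x = self._features(samples)
        vecs = self.model_.gap_embedding(x)
        out = []
        for v, s in zip(vecs, samples):
            if self.append_curvature:
                prof = curvature_profile(extract_trace(preprocess_image(s.data)))
                v = np.concatenate([v, curvature_summary(prof)])
            out.append(Embedding(vector=v, modality="handwriting",
                                 subject_id=s.subject_id, label=s.label))
        return out

    def predict_proba(self, samples: list[ModalitySample]) -> np.ndarray:
        return self.model_.predict_proba(self._features(samples))
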