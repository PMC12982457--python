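"""Gait pipeline: VGRF windows -> TCN autoencoder embeddings -> pseudo-labels.

Raw multi-channel vertical ground-reaction-force recordings are cut into
fixed 2-s windows (200 samples at 100 Hz), z-scored per channel, and
compressed by a dilated temporal-convolution (TCN) autoencoder whose
global-average-pooled encoder activations form the embedding.  Embeddings
are PCA-reduced and K-means clustered with silhouette model selection; the
cluster assignments act as pseudo-labels for a shallow softmax classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from ._nn import Adam, Conv1d, Dense, ReLU, Residual, Sequential, mse_loss, softmax
from .errors import (
    ConfigError,
    DegenerateClusteringError,
    DivergenceError,
    EmptyRecordingError,
)
from .types import Embedding, ModalitySample

# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------


@dataclass
class GaitWindow:
    """One [channels x Q] window; ``mask`` flags real (non-padded) samples."""

    values: np.ndarray
    mask: np.ndarray  # bool, length Q; True = real sample
    subject_id: str = ""
    label: str = "hc"

    @property
    def q(self) -> int:
        return self.values.shape[1]


def segment_windows(recording: ModalitySample, window_len: int = 200,
                    hop: int = 200) -> list[GaitWindow]:
    """Cover the recording with ceil(T / hop) windows of ``window_len``
    samples; the final short window is zero-padded and its padding masked."""
    if window_len <= 0 or hop <= 0:
        raise ConfigError("window_len and hop must be > 0")
    data = np.atleast_2d(recording.data)
    t = data.shape[1]
    if t == 0:
        raise EmptyRecordingError("cannot segment an empty recording")
    n_win = -(-t // hop)
    out = []
    for i in range(n_win):
        start = i * hop
        chunk = data[:, start: start + window_len]
        pad = window_len - chunk.shape[1]
        mask = np.ones(window_len, dtype=bool)
        if pad > 0:
            chunk = np.pad(chunk, ((0, 0), (0, pad)))
            mask[window_len - pad:] = False
        out.append(GaitWindow(values=chunk.astype(float), mask=mask,
                              subject_id=recording.subject_id, label=recording.label))
    return out


def zscore_normalize(window: GaitWindow) -> GaitWindow:
    """Per-channel z-score over the unpadded samples (population SD,
    ddof=0).  Zero-variance channels map to all-zeros; the padded tail is
    left exactly zero."""
    v = window.values
    m = window.mask
    out = np.zeros_like(v, dtype=float)
    real = v[:, m].astype(float)
    mean = real.mean(axis=1)
    sd = real.std(axis=1)  # population convention (ddof=0)
    ok = sd > 1e-12
    norm = np.zeros_like(real)
    norm[ok] = (real[ok] - mean[ok, None]) / sd[ok, None]
    out[:, m] = norm
    return GaitWindow(values=out, mask=m.copy(), subject_id=window.subject_id,
                      label=window.label)


# --------------------------------------------------------------------------
# TCN autoencoder
# --------------------------------------------------------------------------


@dataclass
class TCNSpec:
    """Dilated temporal-convolution encoder layout.

    The receptive field of the stack is 1 + (kernel_size - 1) * sum(dilations);
    the latent dimension equals the final channel count because the latent is
    the global-average-pooled last feature map.
    """

    in_channels: int = 18
    kernel_size: int = 3
    dilation_schedule: tuple[int, ...] = (1, 2, 4, 8)
    channels_per_layer: tuple[int, ...] = (32, 32, 64, 64)
    latent_dim: int = 64

    def __post_init__(self) -> None:
        if self.kernel_size < 2:
            raise ConfigError("kernel_size must be >= 2")
        if any(d < 1 for d in self.dilation_schedule):
            raise ConfigError("all dilations must be >= 1")
        if len(self.dilation_schedule) != len(self.channels_per_layer):
            raise ConfigError("dilation_schedule and channels_per_layer lengths differ")
        if self.latent_dim != self.channels_per_layer[-1]:
            raise ConfigError("latent_dim must equal the final channel count "
                              "(the latent is the GAP of the last feature map)")

    @property
    def receptive_field(self) -> int:
        return 1 + (self.kernel_size - 1) * sum(self.dilation_schedule)


def gap_embedding(feature_map: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Global average pooling over time: f = (1/Q) sum_t h_t, restricted to
    unmasked steps when a padding mask is given."""
    h = np.asarray(feature_map, dtype=float)
    if mask is None:
        return h.mean(axis=-1)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRecordingError("all-masked window has no unpadded samples")
    return h[..., mask].mean(axis=-1)


class TCNAutoencoder:
    """Encoder: stacked dilated causal conv blocks (residual where the
    channel count repeats) -> time-resolved feature maps H.  The exported
    latent is the (masked) GAP of H; the decoder is a small transposed
    temporal stack that reconstructs the window from H.

    Decoding from H rather than from the pooled vector is deliberate:
    window phase is unrecoverable after global average pooling, so a
    pooled-latent decoder can only emit per-channel constants and the
    reconstruction objective would leave the encoder untrained.
    """

    def __init__(self, spec: TCNSpec) -> None:
        self.spec = spec
        layers: list = []
        c_prev = spec.in_channels
        for c, d in zip(spec.channels_per_layer, spec.dilation_schedule):
            block = [Conv1d(c_prev, c, spec.kernel_size, dilation=d), ReLU()]
            if c == c_prev:
                layers.append(Residual(block))
            else:
                layers.extend(block)
            c_prev = c
        self.encoder = Sequential(layers)
        self.decoder = Sequential([
            Conv1d(spec.latent_dim, spec.latent_dim // 2, 3), ReLU(),
            Conv1d(spec.latent_dim // 2, spec.in_channels, 3),
        ])
        self._initialized = False

    def initialize(self, rng: np.random.Generator) -> None:
        self.encoder.initialize(rng)
        self.decoder.initialize(rng)
        self._initialized = True

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (batch, channels, Q) -> (latent (batch, latent_dim),
        reconstruction (batch, channels, Q))."""
        h = self.encoder.forward(x)
        u = h.mean(axis=2)
        xhat = self.decoder.forward(h)
        return u, xhat

    def backward(self, grad_xhat: np.ndarray) -> None:
        gh = self.decoder.backward(grad_xhat)
        self.encoder.backward(gh)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def embed(self, window: GaitWindow) -> Embedding:
        """Masked-GAP latent of one normalized window."""
        h = self.encoder.forward(window.values[None])
        vec = gap_embedding(h[0], window.mask)
        return Embedding(vector=vec, modality="gait", subject_id=window.subject_id,
                         label=window.label)


def build_tcn_autoencoder(spec: TCNSpec) -> TCNAutoencoder:
    """Untrained autoencoder matching ``spec`` (weights all zero until a
    training call initializes them)."""
    return TCNAutoencoder(spec)


def train_autoencoder(model: TCNAutoencoder, windows: list[GaitWindow],
                      epochs: int = 30, lr: float = 1e-3, seed: int = 0,
                      batch_size: int = 32) -> tuple[TCNAutoencoder, list[float]]:
    """Minimize reconstruction MSE; deterministic per seed (the seed drives
    both initialization and batch shuffling).  epochs=0 leaves the model
    untouched and returns an empty loss trace."""
    if not windows:
        raise EmptyRecordingError("need at least one window")
    trace: list[float] = []
    if epochs == 0:
        return model, trace
    rng = np.random.default_rng(seed)
    model.initialize(rng)
    x = np.stack([w.values for w in windows])
    opt = Adam(model.params(), lr=lr)
    n = x.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            xb = x[order[i: i + batch_size]]
            model.zero_grad()
            _, xhat = model.forward(xb)
            loss, g = mse_loss(xhat, xb)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite reconstruction loss at epoch {epoch}")
            model.backward(g)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def embed(model: TCNAutoencoder, window: GaitWindow) -> Embedding:
    return model.embed(window)


# --------------------------------------------------------------------------
# clustering and pseudo-label classifier
# --------------------------------------------------------------------------


@dataclass
class ClusterModel:
    scaler: "StandardScaler"
    pca: PCA
    kmeans: KMeans
    k: int
    silhouette: float
    assignments: np.ndarray
    silhouettes_by_k: dict[int, float] = field(default_factory=dict)

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return self.kmeans.predict(self.pca.transform(self.scaler.transform(vectors)))


def cluster_embeddings(embeddings: list[Embedding] | np.ndarray,
                       k_range: range | tuple = range(2, 7),
                       pca_var_retained: float = 0.95,
                       seed: int = 0) -> ClusterModel:
    """PCA (retaining ``pca_var_retained`` variance) then K-means, with K
    chosen by maximum mean silhouette over ``k_range`` (ties broken toward
    the smaller K)."""
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks):
        raise ConfigError("every candidate K must be >= 2")
    x = (np.stack([e.vector for e in embeddings])
         if len(embeddings) and isinstance(embeddings[0], Embedding)
         else np.asarray(embeddings, dtype=float))
    if x.shape[0] < max(ks) + 1:
        raise ConfigError(f"need at least max(k_range)+1={max(ks) + 1} embeddings")
    if np.allclose(x, x[0], atol=1e-12):
        raise DegenerateClusteringError(
            "all embeddings identical: silhouette is undefined for every K")
    # standardize dimensions first so a handful of high-variance (often
    # noise-dominated) filters cannot monopolize the retained components
    scaler = StandardScaler().fit(x)
    pca = PCA(n_components=pca_var_retained, svd_solver="full", random_state=seed)
    z = pca.fit_transform(scaler.transform(x))
    best: ClusterModel | None = None
    scores: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(z)
        if len(np.unique(labels)) < 2:
            continue
        s = float(silhouette_score(z, labels))
        scores[k] = s
        if best is None or s > best.silhouette + 1e-12:
            best = ClusterModel(scaler=scaler, pca=pca, kmeans=km, k=k,
                                silhouette=s, assignments=labels)
    if best is None:
        raise DegenerateClusteringError("no candidate K produced >= 2 clusters")
    best.silhouettes_by_k = scores
    return best


@dataclass
class SoftmaxClassifier:
    """Multinomial logistic head trained on pseudo-labels (full-batch GD).

    Inputs are standardized with the training statistics stored on the
    classifier (raw GAP activations are badly conditioned for GD).
    """

    weights: np.ndarray  # (D, K)
    biases: np.ndarray   # (K,)
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    loss_trace: list[float] = field(default_factory=list)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x) - self.feature_mean) / self.feature_scale
        return softmax(z @ self.weights + self.biases)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def train_pseudo_label_classifier(embeddings: np.ndarray, pseudo_labels: np.ndarray,
                                  epochs: int = 300, lr: float = 0.5,
                                  seed: int = 0) -> SoftmaxClassifier:
    """Cross-entropy training of the softmax head on cluster pseudo-labels."""
    x = (np.stack([e.vector for e in embeddings])
         if len(embeddings) and isinstance(embeddings[0], Embedding)
         else np.asarray(embeddings, dtype=float))
    y = np.asarray(pseudo_labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ConfigError("pseudo-labels contain a single class")
    mean = x.mean(axis=0)
    scale = np.where(x.std(axis=0) > 1e-12, x.std(axis=0), 1.0)
    x = (x - mean) / scale
    k = int(classes.max()) + 1
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 0.01, (x.shape[1], k))
    b = np.zeros(k)
    onehot = np.eye(k)[y]
    trace = []
    n = x.shape[0]
    for _ in range(epochs):
        p = softmax(x @ w + b)
        loss = float(-np.sum(onehot * np.log(p + 1e-12)) / n)
        if not np.isfinite(loss):
            raise DivergenceError("non-finite cross-entropy loss")
        trace.append(loss)
        g = (p - onehot) / n
        w -= lr * (x.T @ g)
        b -= lr * g.sum(axis=0)
    return SoftmaxClassifier(weights=w, biases=b, feature_mean=mean,
                             feature_scale=scale, loss_trace=trace)


def majority_vote_mapping(assignments: np.ndarray, true_labels: np.ndarray) -> dict[int, int]:
    """Map each cluster id to the majority true class inside it (how the
    unsupervised clusters are read as PD/HC for evaluation)."""
    mapping = {}
    for c in np.unique(assignments):
        members = true_labels[assignments == c]
        vals, counts = np.unique(members, return_counts=True)
        mapping[int(c)] = int(vals[counts.argmax()])
    return mapping


# --------------------------------------------------------------------------
# end-to-end unimodal gait model
# --------------------------------------------------------------------------


class GaitUnimodalModel:
    """Recording -> windows -> autoencoder -> clusters -> softmax classifier.

    ``fit`` learns everything from the training recordings alone; ``predict_proba``
    averages window-level class probabilities per subject.
    """

    def __init__(self, spec: TCNSpec | None = None, window_len: int = 200,
                 hop: int = 200, epochs: int = 15, lr: float = 2e-3,
                 k_range=range(2, 5), seed: int = 0) -> None:
        self.spec = spec
        self.window_len, self.hop = window_len, hop
        self.epochs, self.lr, self.seed = epochs, lr, seed
        self.k_range = k_range

    def _windows(self, samples: list[ModalitySample],
                 min_real_frac: float = 1.0) -> list[GaitWindow]:
        # trim each trial to its active span (silent lead-in / lead-out
        # windows otherwise dominate embedding variance), then keep only
        # full windows: a masked GAP over a short real segment has a larger
        # sampling variance than a 200-step mean, which turns padded
        # windows into embedding outliers that hijack the clustering
        out = []
        for s in samples:
            data = np.atleast_2d(s.data)
            activity = np.abs(data).sum(axis=0)
            active = np.flatnonzero(activity > 0.05 * activity.max())
            if active.size:
                s = ModalitySample(s.subject_id, s.cohort_id, s.modality, s.label,
                                   data[:, active[0]: active[-1] + 1], s.rate, s.meta)
            out.extend(zscore_normalize(w)
                       for w in segment_windows(s, self.window_len, self.hop)
                       if w.mask.mean() >= min_real_frac)
        return out

    def fit(self, samples: list[ModalitySample]) -> "GaitUnimodalModel":
        windows = self._windows(samples)
        spec = self.spec or TCNSpec(in_channels=windows[0].values.shape[0])
        self.model_ = build_tcn_autoencoder(spec)
        _, self.loss_trace_ = train_autoencoder(
            self.model_, windows, epochs=self.epochs, lr=self.lr, seed=self.seed)
        embs = [self.model_.embed(w) for w in windows]
        x = np.stack([e.vector for e in embs])
        self.cluster_ = cluster_embeddings(embs, self.k_range, seed=self.seed)
        self.classifier_ = train_pseudo_label_classifier(
            x, self.cluster_.assignments, seed=self.seed)
        from .types import class_index
        true = np.array([class_index(w.label) for w in windows])
        self.cluster_to_class_ = majority_vote_mapping(self.cluster_.assignments, true)
        return self

    def embed_subjects(self, samples: list[ModalitySample]) -> list[Embedding]:
        """Per-subject embedding: mean of its window embeddings."""
        out = []
        for s in samples:
            vecs = [self.model_.embed(w).vector for w in self._windows([s])]
            out.append(Embedding(vector=np.mean(vecs, axis=0), modality="gait",
                                 subject_id=s.subject_id, label=s.label))
        return out

    def predict_proba(self, samples: list[ModalitySample]) -> np.ndarray:
        """(n_samples, 2) class probabilities in (hc, pd) order."""
        probs = []
        for s in samples:
            x = np.stack([self.model_.embed(w).vector for w in self._windows([s])])
            p_clusters = self.classifier_.predict_proba(x).mean(axis=0)
            p = np.zeros(2)
            for c, pc in enumerate(p_clusters):
                p[self.cluster_to_class_.get(c, 0)] += pc
            probs.append(p)
        return np.stack(probs)
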