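"""Speech pipeline: phonation audio -> log-Mel spectrogram -> CNN encoder.

Sustained-vowel recordings (mono, 16 kHz; other rates are resampled) are
converted to log-Mel spectrograms and classified by a reduced
mobile-inverted-bottleneck CNN ("b0-mini": depthwise-separable
convolutions with squeeze-excitation, global average pooling, softmax
head).  The GAP vector before the head is the exported speech embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._nn import (
    Adam,
    Conv2d,
    Dense,
    DepthwiseConv2d,
    ReLU,
    Residual,
    Sequential,
    SqueezeExcite,
    softmax,
    softmax_cross_entropy,
)
from .errors import ConfigError, DivergenceError, EmptyRecordingError
from .types import Embedding, ModalitySample, class_index

TARGET_RATE = 16000.0

# --------------------------------------------------------------------------
# time-frequency front end
# --------------------------------------------------------------------------


def compute_stft(waveform: np.ndarray, window_len: int = 400, hop: int = 160,
                 window_fn: str = "hann") -> np.ndarray:
    """Complex STFT with ``1 + floor((T - window_len) / hop)`` frames.

    Returns an array of shape (window_len // 2 + 1, n_frames).
    """
    if hop <= 0:
        raise ConfigError("hop must be > 0")
    x = np.asarray(waveform, dtype=float)
    if x.size < window_len:
        raise EmptyRecordingError(
            f"signal ({x.size} samples) shorter than one STFT window ({window_len})")
    if window_fn == "hann":
        win = np.hanning(window_len)
    elif window_fn in ("rect", "rectangular", "boxcar"):
        win = np.ones(window_len)
    else:
        raise ConfigError(f"unknown window_fn {window_fn!r}")
    n_frames = 1 + (x.size - window_len) // hop
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    return np.fft.rfft(frames, axis=1).T


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """mel = 2595 * log10(1 + f / 700)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ConfigError("frequency must be >= 0")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    m = np.asarray(m, dtype=float)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def mel_filterbank(n_mels: int, n_fft_bins: int, rate: float,
                   f_min: float = 50.0, f_max: float = 8000.0) -> np.ndarray:
    """Triangular filters with unit peaks, centers equally spaced on the
    mel scale between ``f_min`` and ``f_max``.  Shape (n_mels, n_fft_bins)."""
    if n_mels < 2:
        raise ConfigError("n_mels must be >= 2")
    f_max = min(f_max, rate / 2.0)
    mels = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_mels + 2)
    edges = np.asarray(mel_to_hz(mels))
    freqs = np.arange(n_fft_bins) * rate / (2.0 * (n_fft_bins - 1))
    fb = np.zeros((n_mels, n_fft_bins))
    for j in range(n_mels):
        lo, c, hi = edges[j], edges[j + 1], edges[j + 2]
        rising = (freqs - lo) / max(c - lo, 1e-12)
        falling = (hi - freqs) / max(hi - c, 1e-12)
        fb[j] = np.clip(np.minimum(rising, falling), 0.0, None)
    # peak-normalize on the sampled grid (a filter centre rarely coincides
    # with an FFT bin); filters narrower than one bin are left empty
    peaks = fb.max(axis=1)
    fb[peaks > 0] /= peaks[peaks > 0, None]
    return fb


@dataclass
class LogMelSpectrogram:
    """Log-compressed Mel-filterbank magnitudes: log(E + b)."""

    values: np.ndarray  # (mel_bins, frames)
    mel_bins: int
    frame_hop: int
    window_len: int
    floor_constant: float
    filterbank: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-mel values must be finite")


def log_mel(spectrogram: np.ndarray, mel_bins: int = 64, rate: float = TARGET_RATE,
            f_range: tuple[float, float] = (50.0, 8000.0), b: float = 1e-6,
            hop: int = 160, window_len: int = 400) -> LogMelSpectrogram:
    """Apply the triangular mel filterbank to STFT magnitudes, then
    log-compress with stability constant ``b``."""
    if b <= 0:
        raise ConfigError("floor constant b must be > 0")
    mag = np.abs(np.asarray(spectrogram))
    fb = mel_filterbank(mel_bins, mag.shape[0], rate, *f_range)
    e = fb @ mag
    return LogMelSpectrogram(values=np.log(e + b), mel_bins=mel_bins, frame_hop=hop,
                             window_len=window_len, floor_constant=b, filterbank=fb)


def sample_to_logmel(sample: ModalitySample, mel_bins: int = 64,
                     window_len: int = 400, hop: int = 160,
                     b: float = 1e-6) -> LogMelSpectrogram:
    """Full front end for one recording, resampling to 16 kHz if needed."""
    x = np.asarray(sample.data, dtype=float)
    rate = sample.rate or TARGET_RATE
    if abs(rate - TARGET_RATE) > 1e-6:
        n_out = int(round(x.size * TARGET_RATE / rate))
        x = sps.resample(x, n_out)
    stft = compute_stft(x, window_len=window_len, hop=hop)
    return log_mel(stft, mel_bins=mel_bins, rate=TARGET_RATE, b=b, hop=hop,
                   window_len=window_len)


# --------------------------------------------------------------------------
# encoder
# --------------------------------------------------------------------------


@dataclass
class SpeechEncoderSpec:
    """Reduced mobile-inverted-bottleneck stack ("b0-mini").

    ``blocks`` lists (out_channels, stride, expansion); each block is a
    1x1 expansion, a depthwise 3x3 (with the given stride), squeeze-
    excitation, and a 1x1 projection, with an identity shortcut when the
    shape is preserved.
    """

    in_channels: int = 1
    stem_channels: int = 8
    blocks: tuple[tuple[int, int, int], ...] = ((16, 2, 2), (24, 2, 2), (32, 2, 2))
    use_se: bool = True
    n_classes: int = 2

    @property
    def embedding_dim(self) -> int:
        return self.blocks[-1][0]


def _mbconv(c_in: int, c_out: int, stride: int, expansion: int, use_se: bool) -> list:
    hidden = c_in * expansion
    inner: list = [Conv2d(c_in, hidden, 1), ReLU(),
                   DepthwiseConv2d(hidden, 3, stride=stride), ReLU()]
    if use_se:
        inner.append(SqueezeExcite(hidden))
    inner.append(Conv2d(hidden, c_out, 1))
    if stride == 1 and c_in == c_out:
        return [Residual(inner)]
    return inner


class SpeechEncoder:
    """CNN over log-Mel spectrograms; embedding = GAP of the last maps."""

    def __init__(self, spec: SpeechEncoderSpec) -> None:
        self.spec = spec
        layers: list = [Conv2d(spec.in_channels, spec.stem_channels, 3, stride=2), ReLU()]
        c = spec.stem_channels
        for c_out, stride, exp in spec.blocks:
            layers.extend(_mbconv(c, c_out, stride, exp, spec.use_se))
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
        """x: (batch, 1, mel, frames) -> logits (batch, n_classes)."""
        h = self.features.forward(x)
        self._gap_shape = h.shape
        z = h.mean(axis=(2, 3))
        self._z = z
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


def _train_encoder(model, x: np.ndarray, y: np.ndarray, epochs: int, lr: float,
                   seed: int, batch_size: int = 16,
                   track_accuracy: bool = False):
    """Shared minibatch Adam / cross-entropy loop for the 2-D encoders."""
    rng = np.random.default_rng(seed)
    model.initialize(rng)
    opt = Adam(model.params(), lr=lr)
    trace, acc_trace = [], []
    n = x.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            xb, yb = x[order[i:i + batch_size]], y[order[i:i + batch_size]]
            model.zero_grad()
            logits = model.forward(xb)
            loss, g = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            model.backward(g)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
        if track_accuracy:
            preds = np.concatenate([model.forward(x[j:j + 64]).argmax(axis=1)
                                    for j in range(0, n, 64)])
            acc_trace.append(float((preds == y).mean()))
    return (trace, acc_trace) if track_accuracy else trace


def train_speech_encoder(dataset: list[tuple[LogMelSpectrogram, str]] | tuple,
                         spec: SpeechEncoderSpec | None = None, epochs: int = 30,
                         lr: float = 3e-3, seed: int = 0):
    """Train the encoder on (log-mel, label) pairs; returns (model, loss trace)."""
    if isinstance(dataset, tuple) and len(dataset) == 2:
        x, y = dataset
    else:
        x = np.stack([d.values for d, _ in dataset])[:, None]
        y = np.array([class_index(lbl) for _, lbl in dataset])
    if np.unique(y).size < 2:
        raise ConfigError("training set must contain >= 2 classes")
    spec = spec or SpeechEncoderSpec(n_classes=int(y.max()) + 1)
    model = SpeechEncoder(spec)
    trace = _train_encoder(model, x, y, epochs, lr, seed)
    return model, trace


def embed_speech(model: SpeechEncoder, sample: ModalitySample,
                 **mel_kwargs) -> Embedding:
    """GAP vector (pre-softmax) for one recording."""
    lm = sample_to_logmel(sample, **mel_kwargs)
    vec = model.gap_embedding(lm.values[None, None])[0]
    return Embedding(vector=vec, modality="speech", subject_id=sample.subject_id,
                     label=sample.label)


# --------------------------------------------------------------------------
# end-to-end unimodal speech model
# --------------------------------------------------------------------------


class SpeechUnimodalModel:
    """Recording -> log-mel -> b0-mini encoder -> class probabilities."""

    def __init__(self, spec: SpeechEncoderSpec | None = None, epochs: int = 12,
                 lr: float = 3e-3, seed: int = 0, mel_bins: int = 64) -> None:
        self.spec = spec
        self.epochs, self.lr, self.seed = epochs, lr, seed
        self.mel_bins = mel_bins
        self.loss_trace_: list[float] = []

    def _features(self, samples: list[ModalitySample]) -> np.ndarray:
        mats = [sample_to_logmel(s, mel_bins=self.mel_bins).values for s in samples]
        return np.stack(mats)[:, None]

    def fit(self, samples: list[ModalitySample]) -> "SpeechUnimodalModel":
        x = self._features(samples)
        y = np.array([class_index(s.label) for s in samples])
        self.model_, self.loss_trace_ = train_speech_encoder(
            (x, y), self.spec, epochs=self.epochs, lr=self.lr, seed=self.seed)
        return self

    def embed_subjects(self, samples: list[ModalitySample]) -> list[Embedding]:
        x = self._features(samples)
        vecs = self.model_.gap_embedding(x)
        return [Embedding(vector=v, modality="speech", subject_id=s.subject_id,
                          label=s.label) for v, s in zip(vecs, samples)]

    def predict_proba(self, samples: list[ModalitySample]) -> np.ndarray:
        return self.model_.predict_proba(self._features(samples))
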