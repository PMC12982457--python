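"""Synthetic trimodal Parkinson's-disease study data.

Generates the three kinds of raw inputs the modality pipelines consume —
spiral-tracing images, multi-sensor vertical ground-reaction-force (VGRF)
gait recordings, and sustained-vowel phonation audio — with a controllable
class contrast between Parkinson's disease (PD) and healthy control (HC):

* spirals: an Archimedean trace ``r = b·theta`` perturbed by a radial
  tremor sinusoid plus stroke jitter (PD: large tremor; HC: near none);
* gait: per-sensor two-bump (heel-strike / toe-off) stride templates with
  class-dependent left/right amplitude asymmetry and stride-time
  variability;
* voice: a formant-shaped harmonic source (equivalently, a glottal pulse
  train through a spectral envelope) with per-cycle period jitter,
  per-cycle amplitude shimmer, and additive noise at a target SNR.

The three cohorts are independent — subject ids are disjoint across
modalities and no subject-level correspondence exists — mirroring the
study setting where each modality comes from a different public dataset.
Every generator is a pure function of its parameter record (which carries
the seed), so identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import (
    AliasingError,
    CohortOverlapError,
    ConfigError,
    EmptyRecordingError,
    SizingError,
)
from .types import MODALITIES, ModalitySample

# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpiralParams:
    """Archimedean spiral-tracing task parameters.

    ``tremor_arc`` optionally restricts the tremor perturbation to a polar
    angle interval (radians) so that localization methods (Grad-CAM) can be
    scored against a known ground-truth region.
    """

    turns: int = 4
    base_spacing: float = 4.0          # px per radian (b in r = b*theta)
    tremor_amplitude: float = 0.0      # px
    tremor_frequency: float = 1.5      # cycles per radian
    stroke_jitter_sd: float = 0.0      # px
    image_size: int = 224
    seed: int = 0
    tremor_arc: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.turns < 1:
            raise ConfigError("turns must be >= 1")
        if self.tremor_amplitude < 0:
            raise ConfigError("tremor_amplitude must be >= 0")
        if self.image_size < 64:
            raise ConfigError("image_size must be >= 64")


@dataclass(frozen=True)
class GaitParams:
    """Two-bump VGRF stride model parameters (8 sensors per foot mirrors
    the GAITPDB insole layout)."""

    n_strides: int = 20
    stride_time_mean: float = 1.1      # s
    stride_time_cv: float = 0.03       # fraction of the mean
    lr_asymmetry: float = 0.0          # left/right peak-force ratio offset
    sensors_per_foot: int = 8
    sampling_rate: float = 100.0       # Hz
    noise_sd: float = 0.0              # force units (N)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if not 0 <= self.lr_asymmetry < 1:
            raise ConfigError("lr_asymmetry must be in [0, 1)")
        if self.stride_time_cv < 0:
            raise ConfigError("stride_time_cv must be >= 0")


@dataclass(frozen=True)
class VoiceParams:
    """Sustained-vowel phonation parameters."""

    f0: float = 150.0                  # Hz
    duration: float = 2.0              # s
    jitter_pct: float = 0.0            # cycle-period SD as fraction of 1/f0
    shimmer_pct: float = 0.0           # cycle-amplitude SD as fraction of 1
    noise_snr: float = np.inf          # dB; inf = noiseless
    sampling_rate: float = 16000.0     # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be > 0")
        if not 0 < self.f0 < self.sampling_rate / 2:
            raise AliasingError(
                f"f0={self.f0} Hz must lie strictly below Nyquist "
                f"({self.sampling_rate / 2} Hz)")


@dataclass(frozen=True)
class CohortSpec:
    """One modality cohort: PD and HC groups with class-shifted parameters."""

    n_pd: int
    n_hc: int
    modality: str
    pd_params: SpiralParams | GaitParams | VoiceParams
    hc_params: SpiralParams | GaitParams | VoiceParams
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ConfigError(f"unknown modality {self.modality!r}")


# --------------------------------------------------------------------------
# spiral images
# --------------------------------------------------------------------------

_STROKE_SIGMA = 0.8  # px; ~2 px anti-aliased stroke


def ideal_spiral_curvature(theta: np.ndarray, b: float) -> np.ndarray:
    """Curvature of r = b*theta at polar angle theta:
    kappa = (theta^2 + 2) / (b * (theta^2 + 1)^1.5)."""
    theta = np.asarray(theta, dtype=float)
    return (theta**2 + 2.0) / (b * (theta**2 + 1.0) ** 1.5)


def _spiral_polar_trace(params: SpiralParams, rng: np.random.Generator):
    n = max(2000, 1500 * params.turns)
    theta = np.linspace(0.0, 2.0 * np.pi * params.turns, n)
    r_ideal = params.base_spacing * theta
    tremor = params.tremor_amplitude * np.sin(
        2.0 * np.pi * params.tremor_frequency * theta)
    if params.tremor_arc is not None:
        lo, hi = params.tremor_arc
        tremor = tremor * ((theta >= lo) & (theta <= hi))
    jitter = np.zeros(n)
    if params.stroke_jitter_sd > 0:
        raw = rng.normal(0.0, params.stroke_jitter_sd, n)
        # smooth over ~20 samples so jitter reads as hand wobble, not speckle
        k = np.hanning(21)
        jitter = np.convolve(raw, k / k.sum(), mode="same")
    r = r_ideal + tremor + jitter
    return theta, r_ideal, r


def generate_spiral_image(params: SpiralParams, label: str,
                          subject_id: str = "spiral-0", cohort_id: str = "hw") -> ModalitySample:
    """Rasterize one spiral-tracing sample as a grayscale image in [0, 1]
    (dark stroke on white ground), centered on the canvas.

    ``meta`` records the generating polar trace (theta, ideal radius, drawn
    radius) and, when the tremor is arc-localized, a pixel mask of the
    perturbed region, so downstream oracles can score against ground truth.
    """
    rng = np.random.default_rng(params.seed)
    theta, r_ideal, r = _spiral_polar_trace(params, rng)
    half = params.image_size / 2.0
    max_extent = np.abs(r).max() + 3.0 * _STROKE_SIGMA
    if max_extent > half - 1:
        raise SizingError(
            f"spiral radius {max_extent:.1f}px exceeds the canvas half-size "
            f"{half - 1:.1f}px; increase image_size or reduce turns/base_spacing")
    x = half + r * np.cos(theta)
    y = half + r * np.sin(theta)

    ink = np.zeros((params.image_size, params.image_size))
    ix, iy = np.floor(x).astype(int), np.floor(y).astype(int)
    fx, fy = x - ix, y - iy
    for dy in range(-2, 3):
        for dx in range(-2, 3):
            w = np.exp(-(((dx - fx) ** 2) + ((dy - fy) ** 2)) / (2 * _STROKE_SIGMA**2))
            np.add.at(ink, (iy + dy, ix + dx), w)
    ink = np.clip(ink / 1.8, 0.0, 1.0)
    img = 1.0 - ink
    img = np.round(img * 255.0) / 255.0  # pre-quantize: PNG round-trip is lossless

    meta: dict = {"params": params, "theta": theta, "r_ideal": r_ideal, "r": r,
                  "x": x, "y": y}
    if params.tremor_arc is not None:
        lo, hi = params.tremor_arc
        sel = (theta >= lo) & (theta <= hi)
        mask = np.zeros_like(img, dtype=bool)
        for dy in range(-3, 4):
            for dx in range(-3, 4):
                mask[iy[sel] + dy, ix[sel] + dx] = True
        meta["tremor_mask"] = mask
    return ModalitySample(subject_id=subject_id, cohort_id=cohort_id,
                          modality="handwriting", label=label, data=img, meta=meta)


def spiral_radial_deviation(sample: ModalitySample) -> float:
    """Mean absolute radial deviation of the drawn trace from the ideal
    Archimedean spiral (px) — the tremor-severity oracle statistic."""
    m = sample.meta
    return float(np.mean(np.abs(m["r"] - m["r_ideal"])))


# --------------------------------------------------------------------------
# gait recordings
# --------------------------------------------------------------------------


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def generate_gait_recording(params: GaitParams, label: str,
                            subject_id: str = "gait-0", cohort_id: str = "ga") -> ModalitySample:
    """Simulate a VGRF walking trial.

    Each stride contributes a heel-strike bump and a toe-off bump per
    sensor; heel sensors weight the early bump, toe sensors the late one.
    Both feet share the same stride-time sequence with the right foot
    phase-shifted by half a stride, and the left/right peak-force ratio is
    offset by ``lr_asymmetry``.  Channels: per-sensor forces L1..Ln, R1..Rn
    plus per-foot totals.  Stride start times are returned in ``meta`` for
    oracle use.
    """
    if params.n_strides == 0:
        raise EmptyRecordingError("n_strides must be >= 1")
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n_s = params.sensors_per_foot

    durations = params.stride_time_mean * np.maximum(
        0.4, 1.0 + params.stride_time_cv * rng.standard_normal(params.n_strides))
    # pad both ends so every Gaussian bump decays fully inside the recording
    # (keeps the two feet exactly symmetric when lr_asymmetry = 0)
    pad = params.stride_time_mean
    starts = pad + np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    total_time = float(np.sum(durations) + 3.0 * params.stride_time_mean)
    t = np.arange(int(round(total_time * fs))) / fs

    base_force = 380.0  # N per foot, desk-scale walking load
    amp_l = base_force * (1.0 + params.lr_asymmetry / 2.0)
    amp_r = base_force * (1.0 - params.lr_asymmetry / 2.0)
    # heel->toe sensor weighting across the insole
    pos = np.linspace(0.0, 1.0, n_s)
    w_heel = np.exp(-((pos - 0.15) ** 2) / 0.18)
    w_toe = np.exp(-((pos - 0.85) ** 2) / 0.18)

    def foot(amp: float, phase: float, stance_frac: float) -> np.ndarray:
        chans = np.zeros((n_s, t.size))
        for s0, d in zip(starts, durations):
            stance = stance_frac * d
            c_heel = s0 + phase + 0.20 * stance
            c_toe = s0 + phase + 0.68 * stance
            width = 0.10 * stance
            prof_h = _bump(t, c_heel, width)
            prof_t = _bump(t, c_toe, width)
            chans += amp * (np.outer(w_heel, prof_h) + np.outer(w_toe, prof_t))
        return chans

    # asymmetry shows up both as a peak-force ratio offset and as a shorter
    # stance (weaker push-off) on the lower-force side — the latter keeps the
    # class contrast visible after per-channel amplitude normalization
    stance_l = 0.62
    stance_r = 0.62 * (1.0 - 0.6 * params.lr_asymmetry)
    left = foot(amp_l, 0.0, stance_l)
    right = foot(amp_r, params.stride_time_mean / 2.0, stance_r)
    if params.noise_sd > 0:
        left = left + rng.normal(0.0, params.noise_sd, left.shape)
        right = right + rng.normal(0.0, params.noise_sd, right.shape)
    data = np.vstack([left, right, left.sum(axis=0, keepdims=True),
                      right.sum(axis=0, keepdims=True)])
    names = ([f"L{i + 1}" for i in range(n_s)] + [f"R{i + 1}" for i in range(n_s)]
             + ["L_total", "R_total"])
    meta = {"params": params, "time": t, "channel_names": names,
            "stride_starts": starts, "stride_durations": durations}
    return ModalitySample(subject_id=subject_id, cohort_id=cohort_id, modality="gait",
                          label=label, data=data, rate=fs, meta=meta)


def gait_peak_force_ratio(sample: ModalitySample) -> float:
    """Left/right per-stride peak total-force ratio (asymmetry oracle)."""
    names = sample.meta["channel_names"]
    lt = sample.data[names.index("L_total")]
    rt = sample.data[names.index("R_total")]
    fs = sample.rate
    starts = sample.meta["stride_starts"]
    durs = sample.meta["stride_durations"]
    ratios = []
    for s0, d in zip(starts, durs):
        i0, i1 = int(s0 * fs), min(int((s0 + d) * fs), lt.size)
        if i1 - i0 < 2:
            continue
        ratios.append(lt[i0:i1].max() / max(rt[i0:i1].max(), 1e-9))
    return float(np.mean(ratios))


# --------------------------------------------------------------------------
# voice recordings
# --------------------------------------------------------------------------

_FORMANTS = ((700.0, 130.0, 2.2), (1220.0, 180.0, 1.2))  # (Hz, width, gain) of /a/


def _harmonic_amplitudes(f0: float, nyquist: float) -> np.ndarray:
    """Spectral envelope of the source: 1/h glottal roll-off with modest
    Gaussian formant emphasis, truncated below Nyquist."""
    n_h = int(min(12, np.floor(nyquist / f0)))
    h = np.arange(1, n_h + 1)
    amps = 1.0 / h**2
    for fc, bw, gain in _FORMANTS:
        amps = amps * (1.0 + gain * np.exp(-(((h * f0) - fc) ** 2) / (2 * bw**2)))
    return amps


def generate_voice_recording(params: VoiceParams, label: str,
                             subject_id: str = "voice-0", cohort_id: str = "sp") -> ModalitySample:
    """Synthesize a sustained /a/ phonation.

    The source is a formant-shaped harmonic stack — equivalent to a glottal
    pulse train through a fixed spectral envelope — whose instantaneous
    period is re-drawn every cycle (jitter) and whose cycle amplitude is
    perturbed (shimmer); white noise is added at ``noise_snr`` dB.  The
    exact per-cycle periods are stored in ``meta['periods']`` as jitter
    ground truth.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    t0 = 1.0 / params.f0

    # draw cycles until they cover the duration
    periods, amps, total = [], [], 0.0
    while total < params.duration + t0:
        p = t0 * max(0.2, 1.0 + params.jitter_pct * rng.standard_normal())
        a = max(0.05, 1.0 + params.shimmer_pct * rng.standard_normal())
        periods.append(p)
        amps.append(a)
        total += p
    periods = np.asarray(periods)
    amps = np.asarray(amps)
    starts = np.concatenate([[0.0], np.cumsum(periods)[:-1]])

    t = np.arange(n) / fs
    cycle = np.searchsorted(starts, t, side="right") - 1
    phase = 2.0 * np.pi * (t - starts[cycle]) / periods[cycle]
    h_amps = _harmonic_amplitudes(params.f0, fs / 2.0)
    x = np.zeros(n)
    for h, a_h in enumerate(h_amps, start=1):
        x += a_h * np.sin(h * phase)
    x *= amps[cycle]

    if np.isfinite(params.noise_snr):
        p_sig = float(np.mean(x**2))
        p_noise = p_sig / (10.0 ** (params.noise_snr / 10.0))
        x = x + rng.normal(0.0, np.sqrt(p_noise), n)
    x = 0.9 * x / max(np.abs(x).max(), 1e-12)

    meta = {"params": params, "periods": periods, "cycle_amps": amps,
            "cycle_starts": starts}
    return ModalitySample(subject_id=subject_id, cohort_id=cohort_id, modality="speech",
                          label=label, data=x, rate=fs, meta=meta)


def voice_period_sd(sample: ModalitySample) -> float:
    """SD of the generated per-cycle periods (seconds) — jitter oracle."""
    return float(np.std(sample.meta["periods"]))


# --------------------------------------------------------------------------
# cohorts and presets
# --------------------------------------------------------------------------

_PREFIX = {"handwriting": "hw", "gait": "ga", "speech": "sp"}
_GENERATORS = {"handwriting": generate_spiral_image, "gait": generate_gait_recording,
               "speech": generate_voice_recording}
# per-subject heterogeneity: multiplicative spread on the class-shifted field
_VARY_FIELD = {"handwriting": "tremor_amplitude", "gait": "lr_asymmetry",
               "speech": "jitter_pct"}


@dataclass
class TrimodalCohorts:
    """Three label-consistent modality cohorts with disjoint subject ids."""

    cohorts: dict[str, list[ModalitySample]]

    def samples(self, modality: str) -> list[ModalitySample]:
        return self.cohorts[modality]

    def manifest(self) -> list[dict]:
        rows = []
        for modality, samples in self.cohorts.items():
            for s in samples:
                rows.append({"subject_id": s.subject_id, "cohort_id": s.cohort_id,
                             "modality": modality, "label": s.label,
                             "params": _params_dict(s.meta["params"])})
        return rows

    def write(self, out_dir: str | Path) -> Path:
        """Write media (PNG / WAV / TSV) plus a JSON-lines manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for modality, samples in self.cohorts.items():
            sub = out / modality
            sub.mkdir(exist_ok=True)
            for s in samples:
                if modality == "handwriting":
                    path = sub / f"{s.subject_id}.png"
                    write_png(s.data, path)
                elif modality == "speech":
                    path = sub / f"{s.subject_id}.wav"
                    write_wav(s.data, s.rate, path)
                else:
                    path = sub / f"{s.subject_id}.tsv"
                    write_gait_table(s, path)
                rows.append({"subject_id": s.subject_id, "cohort_id": s.cohort_id,
                             "modality": modality, "label": s.label,
                             "path": str(path.relative_to(out)),
                             "params": _params_dict(s.meta["params"])})
        manifest = out / "manifest.jsonl"
        with open(manifest, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
        return manifest


def _params_dict(params) -> dict:
    d = dataclasses.asdict(params)
    return {k: (v if (v is None or isinstance(v, (int, str, tuple, list)))
                else (float(v) if np.isfinite(v) else "inf"))
            for k, v in d.items()}


def _child_seed(master: int, stream: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master), int(stream), int(index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def make_trimodal_cohorts(specs: dict[str, CohortSpec] | list[CohortSpec]) -> TrimodalCohorts:
    """Generate the three independent cohorts described by ``specs``.

    Per-subject parameters are the class parameters with (a) a derived
    per-subject seed and (b) a mild multiplicative spread (U[0.75, 1.25])
    on the class-contrast field, so subjects within a class are not clones.
    """
    if isinstance(specs, list):
        specs = {s.modality: s for s in specs}
    if set(specs) != set(MODALITIES):
        raise ConfigError(f"need exactly one spec per modality {MODALITIES}")

    cohorts: dict[str, list[ModalitySample]] = {}
    seen: set[str] = set()
    for m_idx, modality in enumerate(MODALITIES):
        spec = specs[modality]
        gen = _GENERATORS[modality]
        prefix = _PREFIX[modality]
        samples = []
        counter = 0
        for label, n, base in (("pd", spec.n_pd, spec.pd_params),
                               ("hc", spec.n_hc, spec.hc_params)):
            for i in range(n):
                seed = _child_seed(spec.seed, m_idx, counter)
                vary_rng = np.random.default_rng(seed + 1)
                field = _VARY_FIELD[modality]
                value = getattr(base, field) * vary_rng.uniform(0.85, 1.15)
                params = dataclasses.replace(base, seed=seed, **{field: value})
                sid = f"{prefix}-{label}-{i:04d}"
                if sid in seen:
                    raise CohortOverlapError(f"duplicate subject id {sid}")
                seen.add(sid)
                samples.append(gen(params, label, subject_id=sid,
                                   cohort_id=f"{prefix}-cohort"))
                counter += 1
        cohorts[modality] = samples
    return TrimodalCohorts(cohorts)


def easy_cohort_specs(n_pd: int = 24, n_hc: int = 24, seed: int = 0,
                      hard: bool = False) -> dict[str, CohortSpec]:
    """Study-condition presets.

    ``easy`` (default) uses clearly separable class contrasts so that
    end-to-end checks exercise pipeline correctness rather than classifier
    power; ``hard=True`` shrinks every contrast for power studies.
    """
    shrink = 0.35 if hard else 1.0
    hw_pd = SpiralParams(tremor_amplitude=5.0 * shrink, tremor_frequency=2.0,
                         stroke_jitter_sd=1.0)
    hw_hc = SpiralParams(tremor_amplitude=0.4, tremor_frequency=2.0,
                         stroke_jitter_sd=0.4)
    # PD gait: shorter (shuffling) strides, higher stride-time variability,
    # larger left/right asymmetry
    ga_pd = GaitParams(lr_asymmetry=0.25 * shrink, stride_time_cv=0.15 * shrink,
                       stride_time_mean=1.15 - 0.3 * shrink, noise_sd=5.0)
    ga_hc = GaitParams(lr_asymmetry=0.02, stride_time_cv=0.03,
                       stride_time_mean=1.15, noise_sd=5.0)
    sp_pd = VoiceParams(jitter_pct=0.02 * shrink, shimmer_pct=0.08 * shrink,
                        noise_snr=15.0)
    sp_hc = VoiceParams(jitter_pct=0.002, shimmer_pct=0.01, noise_snr=28.0)
    return {
        "handwriting": CohortSpec(n_pd, n_hc, "handwriting", hw_pd, hw_hc,
                                  seed=_child_seed(seed, 11, 0)),
        "gait": CohortSpec(n_pd, n_hc, "gait", ga_pd, ga_hc,
                           seed=_child_seed(seed, 12, 0)),
        "speech": CohortSpec(n_pd, n_hc, "speech", sp_pd, sp_hc,
                             seed=_child_seed(seed, 13, 0)),
    }


# --------------------------------------------------------------------------
# media writers / readers
# --------------------------------------------------------------------------


def write_png(image: np.ndarray, path: str | Path) -> None:
    """8-bit grayscale PNG."""
    arr = np.clip(np.round(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0


def write_wav(waveform: np.ndarray, rate: float, path: str | Path) -> None:
    """16-bit PCM mono WAV."""
    q = np.clip(np.round(np.asarray(waveform) * 32767.0), -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(int(rate))
        fh.writeframes(q.tobytes())


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    with wave.open(str(path), "rb") as fh:
        rate = fh.getframerate()
        raw = fh.readframes(fh.getnframes())
    x = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32767.0
    return x, float(rate)


def write_gait_table(sample: ModalitySample, path: str | Path) -> None:
    """Tab-delimited VGRF table: time_s, L1..Ln, R1..Rn, L_total, R_total."""
    names = sample.meta["channel_names"]
    t = sample.meta["time"]
    header = "time_s\t" + "\t".join(names)
    body = np.column_stack([t, sample.data.T])
    np.savetxt(path, body, delimiter="\t", header=header, comments="", fmt="%.6f")


def read_gait_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (time, channels[C,T], channel names); accepts any table with
    a ``time_s`` first column in the GAITPDB-compatible ordering."""
    with open(path) as fh:
        names = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    return data[:, 0], data[:, 1:].T, names[1:]
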