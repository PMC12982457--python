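"""Shared in-memory containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

MODALITIES = ("handwriting", "gait", "speech")
CLASSES = ("hc", "pd")  # index 0 = healthy control, 1 = Parkinson's disease


def class_index(label: str) -> int:
    if label not in CLASSES:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")
    return CLASSES.index(label)


@dataclass
class ModalitySample:
    """One labelled raw input: a spiral image, gait recording, or phonation."""

    subject_id: str
    cohort_id: str
    modality: str
    label: str  # "pd" | "hc"
    data: np.ndarray  # image (H,W), gait (channels,T), or waveform (T,)
    rate: float | None = None  # Hz for time series, None for images
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        class_index(self.label)


@dataclass
class Embedding:
    """Fixed-length latent vector exported by a modality encoder."""

    vector: np.ndarray
    modality: str
    subject_id: str
    label: str
    model_version: str = "unversioned"

    def __len__(self) -> int:
        return len(self.vector)


@dataclass
class FusedVector:
    """Concatenated trimodal feature vector with per-modality index spans."""

    values: np.ndarray
    spans: dict[str, tuple[int, int]]  # modality -> (start, end), half-open
    label: str
    pseudo_subject: str = ""

    def __post_init__(self) -> None:
        total = sum(e - s for s, e in self.spans.values())
        if total != len(self.values):
            raise ValueError(
                f"span lengths ({total}) do not cover the fused vector ({len(self.values)})")

    def slice(self, modality: str) -> np.ndarray:
        s, e = self.spans[modality]
        return self.values[s:e]


@dataclass
class AttributionResult:
    """Per-feature (or per-location) importance values from one XAI method."""

    method: str  # shapley_exact | shapley_sampled | integrated_gradients | grad_cam
    values: np.ndarray
    baseline: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)
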