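"""Core data containers shared across the pipeline.

Conventions
-----------
* Hemoglobin time series are in micromolar (µM), channels along the first
  axis, time along the second.
* A physical optode channel contributes one Δ[HbO₂] row and one Δ[Hb] row;
  the two rows are always kept or dropped together.
* Per-sample labels use the n-back level (0..3) for task samples and
  ``BASELINE`` (−1) for baseline / rest samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Label sentinel for baseline / inter-task rest samples.
BASELINE: int = -1


@dataclass
class IntensityRecording:
    """Raw two-wavelength continuous-wave intensity recording.

    ``intensity`` has shape (n_channels, 2, n_samples); wavelength axis is
    ordered (760 nm, 850 nm). Intensities are in arbitrary units and must be
    strictly positive.
    """

    intensity: np.ndarray
    sampling_rate: float
    labels_per_sample: np.ndarray
    source_detector_distance: float = 3.0  # cm
    wavelengths: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.labels_per_sample = np.asarray(self.labels_per_sample, dtype=int)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError(
                "intensity must have shape (n_channels, 2 wavelengths, n_samples)"
            )
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be strictly positive")
        if self.labels_per_sample.shape[0] != self.intensity.shape[2]:
            raise ValueError("labels_per_sample length must match n_samples")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]


@dataclass
class HemoRecording:
    """Multichannel Δ[HbO₂]/Δ[Hb] recording with per-sample task labels.

    ``dHbO2`` and ``dHb`` share the shape (n_channels, n_samples) where
    *n_channels* counts physical optode channels currently retained.
    ``retained_channels`` records the indices of those channels in the
    original montage.
    """

    dHbO2: np.ndarray
    dHb: np.ndarray
    sampling_rate: float
    labels_per_sample: np.ndarray
    retained_channels: np.ndarray = field(default=None)  # type: ignore[assignment]
    session_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.dHbO2 = np.asarray(self.dHbO2, dtype=float)
        self.dHb = np.asarray(self.dHb, dtype=float)
        self.labels_per_sample = np.asarray(self.labels_per_sample, dtype=int)
        if self.dHbO2.shape != self.dHb.shape:
            raise ValueError("dHbO2 and dHb must share shape")
        if self.dHbO2.ndim != 2:
            raise ValueError("hemoglobin series must be 2-D (channels × time)")
        if self.labels_per_sample.shape[0] != self.dHbO2.shape[1]:
            raise ValueError("labels_per_sample length must match n_samples")
        if self.retained_channels is None:
            self.retained_channels = np.arange(self.dHbO2.shape[0])
        else:
            self.retained_channels = np.asarray(self.retained_channels, dtype=int)
            if self.retained_channels.shape[0] != self.dHbO2.shape[0]:
                raise ValueError("retained_channels must index every row")

    @property
    def n_channels(self) -> int:
        return self.dHbO2.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dHbO2.shape[1]

    def stacked(self) -> np.ndarray:
        """Return the (2·n_channels, n_samples) array of Δ[HbO₂] rows
        stacked over Δ[Hb] rows — the feature space used downstream."""
        return np.vstack([self.dHbO2, self.dHb])

    def copy(self) -> "HemoRecording":
        return HemoRecording(
            dHbO2=self.dHbO2.copy(),
            dHb=self.dHb.copy(),
            sampling_rate=self.sampling_rate,
            labels_per_sample=self.labels_per_sample.copy(),
            retained_channels=self.retained_channels.copy(),
            session_id=self.session_id,
            subject_id=self.subject_id,
        )


@dataclass
class SegmentSet:
    """Non-overlapping labeled windows cut from one session.

    ``segments`` has shape (N, d, w) with d = 2 × retained channels
    (Δ[HbO₂] rows stacked over Δ[Hb] rows) and w the window length in
    samples. ``labels`` holds the n-back level of each window.
    """

    segments: np.ndarray
    labels: np.ndarray
    window: int
    sampling_rate: float
    session_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.segments.ndim != 3:
            raise ValueError("segments must have shape (N, d, w)")
        if self.segments.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per segment required")
        if self.segments.shape[2] != self.window:
            raise ValueError("segment width must equal window")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def d(self) -> int:
        return self.segments.shape[1]
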