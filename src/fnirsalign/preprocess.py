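"""Raw-intensity conversion and session preparation.

Pipeline order: two-wavelength intensities → optical density changes →
modified Beer–Lambert inversion to Δ[HbO₂]/Δ[Hb] (µM) → linear detrend →
automated noisy-channel rejection (>1 Hz spectral power fraction) →
session admissibility check (>60% channels rejected voids the session) →
segmentation into non-overlapping labelled windows of w = 60 samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.signal

from .datatypes import BASELINE, HemoRecording, IntensityRecording, SegmentSet

__all__ = [
    "DEFAULT_EXTINCTION",
    "mbll_convert",
    "synthesize_intensity",
    "linear_detrend",
    "reject_noisy_channels",
    "session_admissible",
    "segment",
]

#: Molar extinction coefficients ε (L·mmol⁻¹·cm⁻¹) at the two laser lines,
#: from the standard tabulation of hemoglobin absorption spectra:
#: rows = wavelengths (760, 850 nm), columns = (HbO₂, Hb).
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    760.0: (0.586, 1.548),
    850.0: (1.058, 0.691),
}

#: Differential pathlength factors assumed for the two wavelengths.
DEFAULT_DPF: dict[float, float] = {760.0: 9.1, 850.0: 8.0}


def _extinction_matrix(
    extinction_table: dict[float, tuple[float, float]],
    wavelengths: tuple[float, float],
) -> np.ndarray:
    try:
        e = np.array([extinction_table[w] for w in wavelengths], dtype=float)
    except KeyError as err:
        raise ValueError(f"extinction_table lacks wavelength {err}") from None
    if abs(np.linalg.det(e)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    return e


def mbll_convert(
    rec: IntensityRecording,
    dpf760: float = 9.1,
    dpf850: float = 8.0,
    extinction_table: dict[float, tuple[float, float]] | None = None,
    baseline_duration: float = 155.0,
) -> HemoRecording:
    """Modified Beer–Lambert inversion of two-wavelength intensities.

    Per channel, ΔOD(λ, t) = −log₁₀ I(t)/I₀ with I₀ the mean intensity over
    the initial baseline window (first ``baseline_duration`` seconds, or the
    whole series if shorter).  Concentration changes solve the 2×2 system
    ΔOD(λ) = ε(λ)·ΔC·DPF(λ)·L for every sample; outputs are in µM
    (ε given in L·mmol⁻¹·cm⁻¹ and L in cm make ΔC mM; ×1000 → µM).
    """
    ext = _extinction_matrix(
        extinction_table or DEFAULT_EXTINCTION, rec.wavelengths
    )
    dpf = np.array([dpf760, dpf850], dtype=float)
    if np.any(dpf <= 0):
        raise ValueError("DPFs must be positive")
    length = rec.source_detector_distance
    n_base = min(int(round(baseline_duration * rec.sampling_rate)),
                 rec.n_samples)
    n_base = max(n_base, 1)
    i0 = rec.intensity[:, :, :n_base].mean(axis=2, keepdims=True)
    dod = -np.log10(rec.intensity / i0)  # (ch, wavelength, t)
    # ΔC (mM) = E⁻¹ · diag(1/(DPF·L)) · ΔOD
    rhs = dod / (dpf[None, :, None] * length)
    sol = np.einsum("cw,nwt->nct", np.linalg.inv(ext), rhs)  # c = (HbO2, Hb)
    return HemoRecording(
        dHbO2=1000.0 * sol[:, 0, :],
        dHb=1000.0 * sol[:, 1, :],
        sampling_rate=rec.sampling_rate,
        labels_per_sample=rec.labels_per_sample,
    )


def synthesize_intensity(
    dHbO2: np.ndarray,
    dHb: np.ndarray,
    sampling_rate: float,
    labels_per_sample: np.ndarray,
    dpf760: float = 9.1,
    dpf850: float = 8.0,
    extinction_table: dict[float, tuple[float, float]] | None = None,
    source_detector_distance: float = 3.0,
    i0: float = 1.0,
) -> IntensityRecording:
    """Forward Beer–Lambert model: turn known concentration changes (µM)
    into two-wavelength intensities, the exact inverse of
    :func:`mbll_convert` when the initial samples have zero concentration
    change (so the baseline mean reproduces I₀)."""
    ext = _extinction_matrix(
        extinction_table or DEFAULT_EXTINCTION, (760.0, 850.0)
    )
    dpf = np.array([dpf760, dpf850], dtype=float)
    conc = np.stack([dHbO2, dHb], axis=1) / 1000.0  # µM → mM
    dod = np.einsum("wc,nct->nwt", ext, conc) * (
        dpf[None, :, None] * source_detector_distance
    )
    intensity = i0 * 10.0 ** (-dod)
    return IntensityRecording(
        intensity=intensity,
        sampling_rate=sampling_rate,
        labels_per_sample=labels_per_sample,
        source_detector_distance=source_detector_distance,
    )


def linear_detrend(series: np.ndarray) -> np.ndarray:
    """Remove the per-channel least-squares line (idempotent projection)."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise ValueError("need at least 2 samples to detrend")
    return scipy.signal.detrend(series, axis=-1, type="linear")


def _hf_power_fraction(
    x: np.ndarray, fs: float, hf_cutoff: float
) -> np.ndarray:
    """Fraction of (detrended) spectral power above ``hf_cutoff`` per row."""
    freqs, psd = scipy.signal.periodogram(x, fs=fs, axis=-1, detrend="linear")
    total = psd.sum(axis=-1)
    high = psd[..., freqs > hf_cutoff].sum(axis=-1)
    total[total == 0] = 1.0
    return high / total


def reject_noisy_channels(
    rec: HemoRecording,
    hf_cutoff: float = 1.0,
    power_fraction_threshold: float = 0.25,
) -> tuple[HemoRecording, set[int]]:
    """Drop channels dominated by high-frequency noise.

    A physical channel is removed when the spectral power fraction above
    ``hf_cutoff`` of either of its hemoglobin rows exceeds the threshold;
    both rows always leave together.  Returns the reduced recording and the
    set of removed original channel indices.
    """
    if rec.sampling_rate <= 2 * hf_cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    frac_o = _hf_power_fraction(rec.dHbO2, rec.sampling_rate, hf_cutoff)
    frac_h = _hf_power_fraction(rec.dHb, rec.sampling_rate, hf_cutoff)
    noisy = (frac_o > power_fraction_threshold) | (
        frac_h > power_fraction_threshold
    )
    removed = {int(rec.retained_channels[i]) for i in np.flatnonzero(noisy)}
    if not removed:
        return rec, removed
    keep = ~noisy
    out = HemoRecording(
        dHbO2=rec.dHbO2[keep],
        dHb=rec.dHb[keep],
        sampling_rate=rec.sampling_rate,
        labels_per_sample=rec.labels_per_sample,
        retained_channels=rec.retained_channels[keep],
        session_id=rec.session_id,
        subject_id=rec.subject_id,
    )
    return out, removed


def session_admissible(
    rec: HemoRecording, removed: set[int], n_channels_total: int | None = None
) -> bool:
    """A session is kept unless *more than* 60% of its channels were
    rejected (13/20 gone → inadmissible; 12/20 → still admissible)."""
    total = n_channels_total or (rec.n_channels + len(removed))
    if total <= 0:
        raise ValueError("total channel count must be positive")
    return len(removed) / total <= 0.60


def segment(rec: HemoRecording, w: int = 60) -> SegmentSet:
    """Cut task blocks into non-overlapping labelled windows of w samples.

    Each maximal run of constant non-baseline label contributes
    ⌊run/w⌋ windows; the trailing remainder is discarded so windows stay
    comparable for covariance estimation.  Baseline samples never enter a
    segment.  A block shorter than w contributes nothing and warns.
    """
    if w < 1:
        raise ValueError("window must be positive")
    labels = rec.labels_per_sample
    data = rec.stacked()
    segments: list[np.ndarray] = []
    seg_labels: list[int] = []
    # maximal constant-label runs
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.shape[0]]])
    for s, e in zip(starts, stops):
        lab = int(labels[s])
        if lab == BASELINE:
            continue
        if e - s < w:
            warnings.warn(
                f"task block of label {lab} shorter than window ({e - s} < {w});"
                " contributing no segments",
                stacklevel=2,
            )
            continue
        n_win = (e - s) // w
        for j in range(n_win):
            segments.append(data[:, s + j * w : s + (j + 1) * w])
            seg_labels.append(lab)
    arr = (
        np.stack(segments)
        if segments
        else np.empty((0, data.shape[0], w))
    )
    return SegmentSet(
        segments=arr,
        labels=np.asarray(seg_labels, dtype=int),
        window=w,
        sampling_rate=rec.sampling_rate,
        session_id=rec.session_id,
        subject_id=rec.subject_id,
    )
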