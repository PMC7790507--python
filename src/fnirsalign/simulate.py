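"""Synthetic multichannel fNIRS sessions with controllable domain shift.

The generator emulates the statistical structure that covariance/mean-based
alignment relies on: every n-back level c has its own d×d covariance Σ_c and
mean vector µ_c in the stacked (Δ[HbO₂] over Δ[Hb]) feature space, so short
windows carry class information in exactly the features the inner metric
uses.  On top of that it reproduces the nuisance structure of real
recordings:

* block protocol — one contiguous 200 s task block per level in a
  session-specific random order, with 155 s head/tail baselines and 30 s
  rests in between;
* session-level shift — per-channel gain jitter, constant mean drift, and
  channel dropout (a physical channel drops both of its hemoglobin rows,
  giving sessions unequal dimensions);
* subject-level shift — a feature-space rotation, baseline offsets and a
  subject-specific channel subset, drawn once per subject and shared by all
  of its sessions;
* slow sinusoidal hemodynamic trends and band-limited Gaussian noise;
* sparse spike (1–3 samples) and step (persistent) motion artifacts at
  Poisson-distributed times, with ground truth returned for scoring.

Everything is deterministic given the configuration seed and the
session/subject indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .datatypes import BASELINE, HemoRecording

__all__ = [
    "SessionShift",
    "SubjectShift",
    "ArtifactParams",
    "GeneratorConfig",
    "GroundTruth",
    "SubjectTransform",
    "generate_session",
    "generate_subject",
    "inject_artifacts",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class SessionShift:
    """Between-session nuisance variation within one subject."""

    channel_dropout_probability: float = 0.1
    mean_drift_scale: float = 0.1  # µM
    gain_jitter: float = 0.05  # unitless multiplicative sd


@dataclass
class SubjectShift:
    """Between-subject variation, strictly larger than session shift by
    default so the cross-subject dispersion dominates."""

    rotation_angle_scale: float = 0.25  # radians
    baseline_offset_scale: float = 0.5  # µM
    #: subject montage size range; None → (80% of n_channels, n_channels)
    channel_set_size_range: tuple[int, int] | None = None


@dataclass
class ArtifactParams:
    """Rates (events/min) and typical amplitudes (µM) of motion artifacts."""

    spike_rate: float = 0.5
    spike_amplitude: float = 5.0
    step_rate: float = 0.1
    step_amplitude: float = 3.0


@dataclass
class GeneratorConfig:
    """Full specification of the synthetic study.

    Defaults mirror the acquisition conditions the pipeline targets:
    20 optode channels (40 stacked hemoglobin rows), four n-back levels,
    1562 samples per task (200 s at 7.81 Hz), 155 s head/tail baselines and
    30 s rests.  Class covariances default to a common spatially-correlated
    base matrix deformed per class by scaling plus a low-rank bump, which
    keeps classes separable in Hellinger geometry by a tunable margin.
    """

    n_channels: int = 20  # physical channels; stacked dim d = 2 × this
    n_classes: int = 4
    samples_per_task: int = 1562
    sampling_rate: float = 7.81  # Hz
    baseline_duration: float = 155.0  # s, head and tail
    rest_duration: float = 30.0  # s between tasks
    class_covariances: list[np.ndarray] | None = None
    class_means: list[np.ndarray] | None = None
    class_separation: float = 0.5  # scale of the per-class covariance bump
    session_shift: SessionShift = field(default_factory=SessionShift)
    subject_shift: SubjectShift = field(default_factory=SubjectShift)
    trend_amplitude: float = 0.2  # µM
    mean_ramp_duration: float = 8.0  # s, hemodynamic on/offset smoothing
    noise_sd: float = 0.1  # µM
    noise_cutoff: float = 2.0  # Hz, low-pass band edge of the noise
    temporal_autocorr: float = 0.95  # AR(1) of the slow hemodynamic part
    cardiac_fraction: float = 0.4  # variance share of the pulsatile part
    cardiac_freq: float = 0.9  # Hz, heart-rate band centre (54 bpm)
    cardiac_bandwidth: float = 0.97  # AR(2) pole radius (narrowness)
    artifact_params: ArtifactParams = field(default_factory=ArtifactParams)
    seed: int = 0

    @property
    def d(self) -> int:
        return 2 * self.n_channels

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_classes < 1:
            raise ValueError("n_channels and n_classes must be positive")
        if self.samples_per_task < 1:
            raise ValueError("samples_per_task must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 <= self.temporal_autocorr < 1.0:
            raise ValueError("temporal_autocorr must be in [0, 1)")
        if self.subject_shift.channel_set_size_range is None:
            self.subject_shift.channel_set_size_range = (
                max(1, int(round(0.8 * self.n_channels))), self.n_channels
            )
        lo, hi = self.subject_shift.channel_set_size_range
        if not 1 <= lo <= hi <= self.n_channels:
            raise ValueError(
                "channel_set_size_range must lie within [1, n_channels]"
            )
        if self.class_covariances is None:
            self.class_covariances = default_class_covariances(
                self.d, self.n_classes, self.class_separation
            )
        if self.class_means is None:
            self.class_means = default_class_means(
                self.n_channels, self.n_classes
            )
        if len(self.class_covariances) != self.n_classes:
            raise ValueError("one covariance per class required")
        if len(self.class_means) != self.n_classes:
            raise ValueError("one mean per class required")
        for k, cov in enumerate(self.class_covariances):
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (self.d, self.d):
                raise ValueError(f"class covariance {k} must be {self.d}×{self.d}")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"class covariance {k} must be symmetric")
            wmin = scipy.linalg.eigvalsh(cov, subset_by_index=[0, 0])[0]
            if wmin <= 0:
                raise ValueError(f"class covariance {k} must be positive definite")
            self.class_covariances[k] = cov
        self.class_means = [
            np.asarray(m, dtype=float).reshape(self.d)
            for m in self.class_means
        ]


#: per-class variance scale factors of the base covariance; paired layout
#: (0/1 close, 2/3 close, distinct gaps) mirrors the confusability structure
#: of real workload data and, crucially, makes the class chain
#: reflection-asymmetric so structure matching cannot lock onto a globally
#: flipped assignment
_CLASS_SCALES = (1.0, 1.1, 1.5, 1.65)
#: per-class magnitudes of the low-rank covariance bump
_CLASS_BUMPS = (0.3, 0.45, 0.8, 1.0)
#: per-class Δ[HbO₂] activation amplitudes (µM); Δ[Hb] is −0.35× these
_CLASS_AMPS = (0.0, 0.15, 0.5, 0.68)


def default_class_covariances(
    d: int, n_classes: int, separation: float = 0.5
) -> list[np.ndarray]:
    """Common exponential-kernel base covariance deformed per class.

    Base: 0.04 µM² variance with spatial correlation exp(−|i−j|/3).  Class c
    is scaled and bumped along a class-specific cosine pattern with
    non-uniform spacing (low workloads 0/1 similar, high 2/3 similar, the
    low/high split large), so classes are separable in Hellinger geometry
    with a margin scaled by ``separation`` while adjacent levels remain the
    natural confusers.
    """
    idx = np.arange(d)
    base = 0.04 * np.exp(-np.abs(idx[:, None] - idx[None, :]) / 3.0)
    covs = []
    for c in range(n_classes):
        u = np.cos(np.pi * (c + 1) * (idx + 0.5) / d)
        u /= np.linalg.norm(u)
        scale = _CLASS_SCALES[c % 4] ** (1 + (c // 4))
        bump = 2.0 * separation * _CLASS_BUMPS[c % 4] * (1 + (c // 4))
        covs.append(scale * base + bump * 0.04 * np.outer(u, u))
    return covs


def default_class_means(n_channels: int, n_classes: int) -> list[np.ndarray]:
    """Workload-graded activation: Δ[HbO₂] rises and Δ[Hb] falls with n,
    modulated by a smooth spatial profile across channels; amplitude steps
    are non-uniform to match the covariance spacing."""
    ch = np.arange(n_channels)
    profile = 0.5 + 0.5 * np.cos(2 * np.pi * ch / max(n_channels, 1))
    means = []
    for c in range(n_classes):
        amp = _CLASS_AMPS[c % 4] * (1 + (c // 4))
        means.append(np.concatenate([amp * profile, -0.35 * amp * profile]))
    return means


# --------------------------------------------------------------------------
# ground truth bookkeeping
# --------------------------------------------------------------------------

@dataclass
class SubjectTransform:
    """Subject-level shift drawn once per subject."""

    rotation: np.ndarray  # (d, d) orthogonal
    baseline_offset: np.ndarray  # (d,)
    channel_set: np.ndarray  # physical channel indices the subject uses


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages on generated data."""

    labels_per_sample: np.ndarray
    retained_channel_indices: np.ndarray
    injected_spikes: list[tuple[int, str, int, float]] = field(default_factory=list)
    injected_steps: list[tuple[int, str, int, float]] = field(default_factory=list)
    class_order: np.ndarray | None = None
    subject_transform: SubjectTransform | None = None
    clean_dHbO2: np.ndarray | None = None
    clean_dHb: np.ndarray | None = None


# --------------------------------------------------------------------------
# session generation
# --------------------------------------------------------------------------

def _rng(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config_seed), spawn_key=tuple(key))
    )


def _label_sequence(
    cfg: GeneratorConfig, class_order: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Per-sample labels plus (class, start, stop) task blocks."""
    fs = cfg.sampling_rate
    n_base = int(round(cfg.baseline_duration * fs))
    n_rest = int(round(cfg.rest_duration * fs))
    pieces = [np.full(n_base, BASELINE)]
    blocks: list[tuple[int, int, int]] = []
    pos = n_base
    for j, c in enumerate(class_order):
        pieces.append(np.full(cfg.samples_per_task, int(c)))
        blocks.append((int(c), pos, pos + cfg.samples_per_task))
        pos += cfg.samples_per_task
        if j < len(class_order) - 1:
            pieces.append(np.full(n_rest, BASELINE))
            pos += n_rest
    pieces.append(np.full(n_base, BASELINE))
    return np.concatenate(pieces), blocks


def _band_limited_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float,
    fs: float, cutoff: float,
) -> np.ndarray:
    """Gaussian noise low-passed at ``cutoff`` and rescaled to sd."""
    white = rng.standard_normal(shape)
    if sd == 0.0:
        return np.zeros(shape)
    nyq = fs / 2.0
    if cutoff >= nyq:
        return sd * white
    sos = scipy.signal.butter(4, cutoff / nyq, output="sos")
    filt = scipy.signal.sosfiltfilt(sos, white, axis=1)
    std = filt.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return sd * filt / std


def _ar1(rng: np.random.Generator, shape: tuple[int, int],
         rho: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) rows."""
    z = rng.standard_normal(shape)
    if rho <= 0.0:
        return z
    innov_sd = np.sqrt(1.0 - rho**2)
    z = scipy.signal.lfilter([1.0], [1.0, -rho], innov_sd * z, axis=1)
    z[:, 0] /= innov_sd
    return z


def _narrowband(rng: np.random.Generator, shape: tuple[int, int],
                freq: float, fs: float, pole: float) -> np.ndarray:
    """Unit-variance narrowband rows: AR(2) resonant at ``freq`` Hz.

    Emulates pulsatile (cardiac-band) physiology — locally periodic, so it
    carries fast covariance information without the step-like excursions a
    broadband process would produce."""
    w0 = 2.0 * np.pi * min(freq / fs, 0.499)
    a = [1.0, -2.0 * pole * np.cos(w0), pole**2]
    z = scipy.signal.lfilter([1.0], a, rng.standard_normal(shape), axis=1)
    # stationary variance of the AR(2) from its impulse response
    imp = scipy.signal.lfilter([1.0], a, np.r_[1.0, np.zeros(2000)])
    return z / np.sqrt((imp**2).sum())


def _draw_block(
    rng: np.random.Generator, chol: np.ndarray, mean: np.ndarray,
    n: int, autocorr: float, cardiac: tuple[float, float, float, float],
) -> np.ndarray:
    """(d, n) samples with covariance chol·cholᵀ and given mean.

    The temporal spectrum mixes a slow AR(1) hemodynamic part with a
    narrowband cardiac part (variance share ``cardiac[0]``); both share the
    spatial covariance, so window covariances stay class-informative even
    though the slow part decorrelates little within a window."""
    d = chol.shape[0]
    frac, freq, fs, pole = cardiac
    frac = float(np.clip(frac, 0.0, 1.0))
    z = np.sqrt(1.0 - frac) * _ar1(rng, (d, n), autocorr)
    if frac > 0.0:
        z += np.sqrt(frac) * _narrowband(rng, (d, n), freq, fs, pole)
    return chol @ z + mean[:, None]


def generate_session(
    config: GeneratorConfig,
    session_index: int,
    subject_transform: SubjectTransform | None = None,
    subject_index: int | None = None,
) -> tuple[HemoRecording, GroundTruth]:
    """Generate one labelled session.

    The task-block order, session perturbations and noise draws are all
    deterministic functions of (config.seed, subject_index, session_index).
    """
    if session_index < 0:
        raise ValueError("session_index must be nonnegative")
    skey = 0x5E55 if subject_index is None else int(subject_index)
    rng = _rng(config.seed, skey, int(session_index))
    d = config.d
    n_ch = config.n_channels

    covs = [c.copy() for c in config.class_covariances]
    means = [m.copy() for m in config.class_means]
    channel_pool = np.arange(n_ch)
    if subject_transform is not None:
        r = subject_transform.rotation
        covs = [r @ c @ r.T for c in covs]
        means = [r @ m + subject_transform.baseline_offset for m in means]
        channel_pool = subject_transform.channel_set

    class_order = rng.permutation(config.n_classes)
    labels, blocks = _label_sequence(config, class_order)
    n_samples = labels.shape[0]

    # session-level perturbations
    sh = config.session_shift
    gain = 1.0 + sh.gain_jitter * rng.standard_normal(n_ch)
    gain_rows = np.concatenate([gain, gain])  # both species of a channel
    drift = sh.mean_drift_scale * rng.standard_normal(d)

    # baseline covariance: average class structure at rest amplitude
    base_cov = sum(covs) / len(covs)
    chols = {c: np.linalg.cholesky(covs[c]) for c in range(config.n_classes)}
    chol_base = np.linalg.cholesky(base_cov)

    data = np.empty((d, n_samples))
    mask = labels == BASELINE
    # baseline/rest stretches: zero-mean resting fluctuations
    cardiac = (
        config.cardiac_fraction, config.cardiac_freq,
        config.sampling_rate, config.cardiac_bandwidth,
    )
    data[:, mask] = _draw_block(
        rng, chol_base, np.zeros(d), int(mask.sum()),
        config.temporal_autocorr, cardiac,
    )
    for c, start, stop in blocks:
        data[:, start:stop] = _draw_block(
            rng, chols[c], np.zeros(d), stop - start,
            config.temporal_autocorr, cardiac,
        )
    # task-evoked mean field: block indicators smoothed with a Hann window
    # (~8 s) so activation ramps like a hemodynamic response instead of
    # jumping — instantaneous mean steps would be artifacts by construction
    ramp = int(round(config.mean_ramp_duration * config.sampling_rate))
    if ramp >= 3:
        win = scipy.signal.windows.hann(ramp)
        win /= win.sum()
    for c, start, stop in blocks:
        w = np.zeros(n_samples)
        w[start:stop] = 1.0
        if ramp >= 3:
            w = scipy.signal.fftconvolve(w, win, mode="same")
        data += means[c][:, None] * w[None, :]

    # slow hemodynamic trend: one sinusoid per stacked row
    if config.trend_amplitude > 0:
        t = np.arange(n_samples) / config.sampling_rate
        freq = rng.uniform(0.005, 0.02, size=d)
        phase = rng.uniform(0, 2 * np.pi, size=d)
        data += config.trend_amplitude * np.sin(
            2 * np.pi * freq[:, None] * t[None, :] + phase[:, None]
        )

    data += _band_limited_noise(
        rng, (d, n_samples), config.noise_sd,
        config.sampling_rate, config.noise_cutoff,
    )
    data = gain_rows[:, None] * data + drift[:, None]

    # session channel dropout within the subject's channel set
    keep_mask = rng.random(channel_pool.shape[0]) >= sh.channel_dropout_probability
    if keep_mask.sum() < 2:
        keep_mask[:] = False
        keep_mask[:2] = True
    retained = channel_pool[keep_mask]
    rows = np.concatenate([retained, retained + n_ch])
    rec = HemoRecording(
        dHbO2=data[rows[: retained.size]],
        dHb=data[rows[retained.size:]],
        sampling_rate=config.sampling_rate,
        labels_per_sample=labels,
        retained_channels=retained,
        session_id=f"ses-{session_index}",
        subject_id="" if subject_index is None else f"sub-{subject_index}",
    )
    truth = GroundTruth(
        labels_per_sample=labels,
        retained_channel_indices=retained,
        class_order=class_order,
        subject_transform=subject_transform,
    )
    return rec, truth


# --------------------------------------------------------------------------
# subject generation
# --------------------------------------------------------------------------

def draw_subject_transform(
    config: GeneratorConfig, subject_index: int
) -> SubjectTransform:
    """Draw the once-per-subject shift: a small feature-space rotation
    exp(θ·S) with S a random unit-norm skew generator, baseline offsets,
    and the subject's channel subset."""
    rng = _rng(config.seed, 0x50B, int(subject_index))
    d = config.d
    ss = config.subject_shift
    theta = ss.rotation_angle_scale
    if theta > 0:
        g = rng.standard_normal((d, d))
        skew = (g - g.T) / 2.0
        nrm = np.linalg.norm(skew, 2)
        rotation = scipy.linalg.expm(theta * skew / max(nrm, 1e-12))
    else:
        rotation = np.eye(d)
    offset = ss.baseline_offset_scale * rng.standard_normal(d)
    lo, hi = ss.channel_set_size_range
    size = int(rng.integers(lo, hi + 1))
    channel_set = np.sort(rng.choice(config.n_channels, size=size, replace=False))
    return SubjectTransform(
        rotation=rotation, baseline_offset=offset, channel_set=channel_set
    )


def generate_subject(
    config: GeneratorConfig, subject_index: int, n_sessions: int = 4
) -> list[tuple[HemoRecording, GroundTruth]]:
    """Generate all sessions of one subject.

    The subject transform is drawn once per ``subject_index`` and applied to
    every session; session-level perturbations stay independent across
    sessions."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be ≥ 1")
    transform = draw_subject_transform(config, subject_index)
    return [
        generate_session(
            config, m, subject_transform=transform, subject_index=subject_index
        )
        for m in range(n_sessions)
    ]


# --------------------------------------------------------------------------
# artifact injection
# --------------------------------------------------------------------------

def inject_artifacts(
    recording: HemoRecording,
    artifact_params: ArtifactParams | None = None,
    seed: int = 0,
) -> tuple[HemoRecording, GroundTruth]:
    """Add sparse spike and step artifacts at Poisson-distributed times.

    Spikes are 1–3 sample pulses, steps are persistent level shifts; both
    have random sign and ±20% amplitude jitter.  The returned ground truth
    stores each event as (channel_row, species, onset_sample, amplitude)
    along with the pre-artifact clean series, so removal can be scored.
    """
    p = artifact_params or ArtifactParams()
    if p.spike_rate < 0 or p.step_rate < 0:
        raise ValueError("artifact rates must be nonnegative")
    rng = np.random.default_rng(seed)
    out = recording.copy()
    duration_min = recording.n_samples / recording.sampling_rate / 60.0
    truth = GroundTruth(
        labels_per_sample=recording.labels_per_sample.copy(),
        retained_channel_indices=recording.retained_channels.copy(),
        clean_dHbO2=recording.dHbO2.copy(),
        clean_dHb=recording.dHb.copy(),
    )
    for species, arr in (("HbO2", out.dHbO2), ("Hb", out.dHb)):
        for ch in range(recording.n_channels):
            n_spikes = rng.poisson(p.spike_rate * duration_min)
            for _ in range(n_spikes):
                t0 = int(rng.integers(0, recording.n_samples))
                width = int(rng.integers(1, 4))
                amp = (
                    p.spike_amplitude
                    * rng.uniform(0.8, 1.2)
                    * rng.choice([-1.0, 1.0])
                )
                arr[ch, t0 : t0 + width] += amp
                truth.injected_spikes.append((ch, species, t0, float(amp)))
            n_steps = rng.poisson(p.step_rate * duration_min)
            for _ in range(n_steps):
                t0 = int(rng.integers(0, recording.n_samples))
                amp = (
                    p.step_amplitude
                    * rng.uniform(0.8, 1.2)
                    * rng.choice([-1.0, 1.0])
                )
                arr[ch, t0:] += amp
                truth.injected_steps.append((ch, species, t0, float(amp)))
    return out, truth
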