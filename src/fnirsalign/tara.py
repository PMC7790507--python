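"""Transient-artifact removal by sparse decomposition.

A single-channel series y is modelled as

    y = f + x₁ + x₂ + w

with f a low-pass signal (below the cutoff fc), x₁ sparse spike artifacts,
x₂ step artifacts (sparse first difference) and w noise.  The artifacts are
estimated by minimising

    J(x₁, x₂) = ½‖H(y − x₁ − x₂)‖² + βσ‖x₁‖₁ + θσ‖Dx₁‖₁ + βσ‖Dx₂‖₁

where H is a zero-phase high-pass filter complementary to the fc low-pass
(so the low-pass part of y never has to be explained by the artifacts), D is
the first difference, σ the noise standard deviation and β, θ dimensionless
regularisation weights.  All penalty weights scale with σ, which makes the
decomposition scale-covariant: decomposing c·y with noise c·σ yields
c-scaled components.

H is built from banded matrices, H = A⁻¹B with B = (tridiag[−1,2,−1])^d and
A = B + α(tridiag[1,2,1])^d, α = tan^{2d}(ω_c/2) — a zero-phase
Butterworth-type filter of order 2d whose response lies in [0, 1].

The objective is minimised by block coordinate descent with a
non-increasing objective at every iteration: the x₁ block takes proximal
gradient steps with the exact fused-lasso prox (1-D total-variation
denoising followed by soft thresholding), and the x₂ block combines a
TV-prox step (which introduces new step support) with
majorisation–minimisation refinements solved exactly through banded linear
systems (which snap step plateaus to height — a capability plain
first-order updates lack, because plateau directions are nearly invisible
to the high-pass data term).  Detected step amplitudes are finally refit
by least squares on their support, removing the ℓ1 shrinkage bias.  The
returned decomposition satisfies low_pass + spikes + steps + residual = y
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .datatypes import HemoRecording

__all__ = [
    "TaraParams",
    "TaraDecomposition",
    "tara_decompose",
    "tara_clean",
    "TaraCleaner",
    "tv_denoise",
    "estimate_noise_sd",
]


# --------------------------------------------------------------------------
# 1-D total variation denoising (prox of λ‖D·‖₁), Condat's direct method
# --------------------------------------------------------------------------

def _tv1d_core(y, lam):
    n = y.shape[0]
    x = np.empty(n)
    if n == 0:
        return x
    if lam <= 0.0:
        x[:] = y
        return x
    # Condat (2013), direct non-iterative 1-D TV denoising
    k = 0
    k0 = 0
    km = 0
    kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0.0:
                for i in range(k0, km + 1):
                    x[i] = vmin
                km += 1
                k = km
                k0 = km
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                continue
            elif umax > 0.0:
                for i in range(k0, kp + 1):
                    x[i] = vmax
                kp += 1
                k = kp
                k0 = kp
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                continue
            else:
                val = vmin + umin / (k - k0 + 1)
                for i in range(k0, n):
                    x[i] = val
                return x
        if y[k + 1] + umin < vmin - lam:  # negative jump necessary
            for i in range(k0, km + 1):
                x[i] = vmin
            km += 1
            k = km
            k0 = km
            kp = km
            vmin = y[k]
            vmax = y[k] + 2.0 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:  # positive jump necessary
            for i in range(k0, kp + 1):
                x[i] = vmax
            kp += 1
            k = kp
            k0 = kp
            km = kp
            vmax = y[k]
            vmin = y[k] - 2.0 * lam
            umin = lam
            umax = -lam
        else:  # no jump; extend the current segment
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k


try:  # compiled TV prox; the pure-python path is identical but slower
    from numba import njit

    _tv1d_impl = njit(cache=False)(_tv1d_core)
except Exception:  # pragma: no cover
    _tv1d_impl = _tv1d_core


def tv_denoise(y: np.ndarray, lam: float) -> np.ndarray:
    """Solve min_x ½‖x − y‖² + λ‖Dx‖₁ exactly (1-D total variation)."""
    y = np.ascontiguousarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("tv_denoise expects a 1-D series")
    return _tv1d_impl(y, float(lam))


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


# --------------------------------------------------------------------------
# parameters / outputs
# --------------------------------------------------------------------------

@dataclass
class TaraParams:
    """Decomposition parameters.

    ``beta`` and ``sigma`` are session-specific in practice (per hemoglobin
    species); ``sigma`` may be left None to be estimated from the median
    absolute first difference of the series.
    """

    fc: float = 0.15  # Hz, low-pass cutoff
    filter_order: int = 1  # d; the filter has order 2d
    theta: float = 0.01  # fusing weight on spike differences
    beta: float = 2.5  # amplitude threshold in units of sigma
    sigma: float | None = None  # µM noise sd; None → MAD estimate
    max_iter: int = 20
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise ValueError("fc must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be a positive integer")
        if self.theta < 0 or self.beta <= 0:
            raise ValueError("theta must be ≥ 0 and beta > 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class TaraDecomposition:
    """Additive split of one series; components sum to the input exactly."""

    low_pass: np.ndarray
    spikes: np.ndarray
    steps: np.ndarray
    residual: np.ndarray
    converged: bool
    n_iter: int
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def cleaned(self) -> np.ndarray:
        """Input with artifacts subtracted (low-pass part kept)."""
        return self.low_pass + self.residual


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise sd from the median absolute first difference.

    A generic quick estimate; :func:`tara_decompose` itself prefers the
    MAD of the high-passed series, which matches the decomposition model's
    notion of noise."""
    dx = np.diff(np.asarray(x, dtype=float))
    mad = np.median(np.abs(dx - np.median(dx)))
    sd = 1.4826 * mad / np.sqrt(2.0)
    return float(max(sd, 1e-12))


# --------------------------------------------------------------------------
# banded high-pass operator
# --------------------------------------------------------------------------

def _highpass_matrices(n: int, fc: float, fs: float, order: int) -> tuple:
    """Banded operators of the zero-phase high-pass H = A⁻¹B.

    B = (tridiag[−1,2,−1])^order, A = B + α·(tridiag[1,2,1])^order with
    α = tan^{2·order}(ω_c/2).  Returns (B, A², LU(A), G) where G = B·S (S
    the cumulative-sum map of step increments, so G = (DᵀD)^{order−1}Dᵀ)
    feeds the step-update linear systems.
    """
    wc = 2.0 * np.pi * fc / fs
    alpha = float(np.tan(wc / 2.0) ** (2 * order))
    ones = np.ones(n)
    diag = 2.0 * np.ones(n)
    diag[0] = diag[-1] = 1.0  # DᵀD boundary: zero row sums, so B·S stays banded
    t1 = scipy.sparse.diags(
        [-ones[:-1], diag, -ones[:-1]], offsets=[-1, 0, 1], format="csc"
    )
    t2 = scipy.sparse.diags(
        [ones[:-1], diag, ones[:-1]], offsets=[-1, 0, 1], format="csc"
    )
    dmat = scipy.sparse.diags(  # (n-1) × n first difference
        [-ones[: n - 1], ones[: n - 1]], offsets=[0, 1], shape=(n - 1, n),
        format="csc",
    )
    b = t1
    a2 = t2
    for _ in range(order - 1):
        b = b @ t1
        a2 = a2 @ t2
    a = (b + alpha * a2).tocsc()
    lu = scipy.sparse.linalg.splu(a)
    g = dmat.T  # (DᵀD)^{order-1} Dᵀ
    for _ in range(order - 1):
        g = (t1 @ g).tocsc()
    return b.tocsc(), (a @ a).tocsc(), lu, g.tocsc()


def tara_decompose(
    x: np.ndarray, fs: float, params: TaraParams | None = None
) -> TaraDecomposition:
    """Decompose one series into low-pass + spikes + steps + residual.

    Block coordinate descent: the spike block takes proximal-gradient steps
    with the exact fused-lasso prox (spikes live above the cutoff, where
    the data term is well conditioned, so a few steps suffice); the step
    block is updated by majorisation–minimisation of the total-variation
    penalty, each update an exact banded solve of

        (G Λ Gᵀ + λ_step·A²) v = B(y − x₁),   u = Λ Gᵀ v,

    with Λ = diag|u_k| — this handles the step plateaus that first-order
    updates crawl along (the plateau direction is nearly invisible to the
    high-pass data term).  Both blocks are majorisation steps, so the
    objective is non-increasing at every iteration.  Non-convergence within
    ``max_iter`` outer iterations returns the last iterate flagged
    ``converged=False``.
    """
    p = params or TaraParams()
    x_in = np.ascontiguousarray(x, dtype=float)
    if x_in.ndim != 1:
        raise ValueError("tara_decompose expects a single-channel series")
    if x_in.shape[0] < 8:
        raise ValueError("series too short to decompose")
    if not np.all(np.isfinite(x_in)):
        raise ValueError("input must be finite")
    if fs <= 0 or p.fc >= fs / 2.0:
        raise ValueError("need 0 < fc < fs/2")
    # odd-symmetric padding continues the edge slope, so the high-pass sees
    # no spurious boundary kink that the step component would try to explain
    n_in = x_in.shape[0]
    pad = min(n_in - 1, int(np.ceil(1.5 * fs / p.fc)))
    left = 2.0 * x_in[0] - x_in[pad:0:-1]
    right = 2.0 * x_in[-1] - x_in[-2 : -pad - 2 : -1]
    x = np.concatenate([left, x_in, right])
    n = x.shape[0]
    bmat, a2mat, lu, gmat = _highpass_matrices(n, p.fc, fs, p.filter_order)
    if p.sigma is not None:
        sigma = p.sigma
    else:
        # the model calls everything above fc that is not artifact "noise":
        # estimate σ robustly from the high-passed series itself
        hx = lu.solve(bmat @ x)
        sigma = float(
            max(1.4826 * np.median(np.abs(hx - np.median(hx))), 1e-12)
        )
    lam_spike = p.beta * sigma
    lam_fuse = p.theta * sigma
    # a unit step carries e_step = ‖H(step)‖² of high-pass evidence (≈ the
    # filter's impulse-response width), against a spike's ≈ 1; scaling the
    # step penalty by e_step puts both artifact types on the same β·σ
    # amplitude-detection threshold
    step = np.zeros(n)
    step[n // 2 :] = 1.0
    hstep = lu.solve(bmat @ step)
    e_step = float(max(np.dot(hstep, hstep), 1.0))
    # floor against smooth-signal absorption: the step-evidence statistic of
    # the zero solution, g₀ = GᵀA⁻²Bx, measures how profitable a step is at
    # each sample; setting λ above twice its bulk (95th percentile) level
    # makes tracking in-band signal unprofitable while genuine steps, whose
    # evidence towers over the bulk, are still detected
    g0 = gmat.T @ lu.solve(lu.solve(bmat @ x))
    lam_step = max(
        p.beta * sigma * e_step,
        2.0 * float(np.quantile(np.abs(g0), 0.95)),
    )
    # upper banded storage of A² for the order-1 fast path
    a2_bands = np.zeros((3, n))
    a2_bands[2] = a2mat.diagonal(0)
    a2_bands[1, 1:] = a2mat.diagonal(1)
    a2_bands[0, 2:] = a2mat.diagonal(2)

    def hh(v: np.ndarray) -> np.ndarray:  # HᵀH v = B A⁻² B v
        return bmat @ lu.solve(lu.solve(bmat @ v))

    def h(v: np.ndarray) -> np.ndarray:  # H v = A⁻¹ B v
        return lu.solve(bmat @ v)

    def objective(x1: np.ndarray, u: np.ndarray) -> float:
        r = x - x1 - _cum(u)
        val = 0.5 * float(np.dot(h(r), h(r)))
        val += lam_spike * float(np.abs(x1).sum())
        if lam_fuse > 0:
            val += lam_fuse * float(np.abs(np.diff(x1)).sum())
        val += lam_step * float(np.abs(u).sum())
        return val

    def _cum(u: np.ndarray) -> np.ndarray:
        x2 = np.empty(n)
        x2[0] = 0.0
        np.cumsum(u, out=x2[1:])
        return x2

    eps = 1e-10 * max(float(np.abs(x).max()), 1.0)
    x1 = np.zeros(n)
    u = np.zeros(n - 1)  # step increments, x2 = cumsum
    mu = 0.9  # single-block step, ‖HᵀH‖ ≤ 1
    history = [objective(x1, u)]
    converged = False
    it = 0
    for it in range(1, p.max_iter + 1):
        # spike block: proximal gradient with fused-lasso prox
        x2 = _cum(u)
        for _ in range(3):
            g = hh(x - x2 - x1)
            v1 = x1 + mu * g
            if lam_fuse > 0:
                x1 = _soft(tv_denoise(v1, mu * lam_fuse), mu * lam_spike)
            else:
                x1 = _soft(v1, mu * lam_spike)
        # step block: one proximal-gradient TV step proposes increments
        # where the high-pass residual demands them (MM zero-locks, so new
        # support can only enter through this seed); seeds only enlarge the
        # current support, then MM banded solves snap plateaus to height
        # and shrink spurious increments geometrically
        x2 = _cum(u)
        g = hh(x - x1 - x2)
        u_ista = np.diff(tv_denoise(x2 + mu * g, mu * lam_step))
        u_cand = np.where(np.abs(u) >= np.abs(u_ista), u, u_ista)
        u_cand[np.abs(u_cand) < 1e2 * eps] = 0.0
        if np.any(u_cand):
            rhs = bmat @ (x - x1)
            for _ in range(4):
                lam_abs = np.abs(u_cand) + eps
                if p.filter_order == 1:
                    # G = Dᵀ: GΛGᵀ is tridiagonal — assemble the banded
                    # system directly and solve by banded Cholesky
                    ab = lam_step * a2_bands.copy()
                    ab[2, :-1] += lam_abs
                    ab[2, 1:] += lam_abs
                    ab[1, 1:] -= lam_abs
                    v = scipy.linalg.solveh_banded(ab, rhs, lower=False)
                else:
                    lam_d = scipy.sparse.diags(lam_abs, format="csc")
                    sys = (gmat @ lam_d @ gmat.T + lam_step * a2mat).tocsc()
                    v = scipy.sparse.linalg.splu(sys).solve(rhs)
                u_cand = lam_abs * (gmat.T @ v)
        # the prox step descends by construction; the seeded MM candidate
        # usually descends further but is not guaranteed to — keep the better
        u = u_cand if objective(x1, u_cand) <= objective(x1, u_ista) else u_ista
        obj = objective(x1, u)
        history.append(obj)
        prev = history[-2]
        if 0 <= prev - obj <= p.tol * max(abs(prev), 1e-15):
            converged = True
            break
    # prune increments below the model's own resolvable step amplitude
    # (λ_step/e_step is the soft-threshold shrinkage a true step suffers;
    # anything much smaller is sub-detection-floor residue of the MM path)
    u[np.abs(u) < 0.5 * lam_step / e_step] = 0.0
    # debias: refit the surviving step amplitudes by least squares on the
    # detected support, removing the ℓ1 shrinkage bias of ≈ λ_step/e_step
    support = np.flatnonzero(u)
    if 0 < support.size <= 200:
        hcols = np.stack([
            lu.solve(np.asarray(gmat[:, int(i)].todense()).ravel())
            for i in support
        ])
        hy_t = h(x - x1)
        gram = hcols @ hcols.T
        rhs_s = hcols @ hy_t
        try:
            u[support] = np.linalg.solve(
                gram + 1e-10 * np.eye(support.size), rhs_s
            )
        except np.linalg.LinAlgError:
            pass  # keep the (biased but valid) MM amplitudes
    x2 = _cum(u)
    r = x - x1 - x2
    hr = h(r)
    crop = slice(pad, pad + n_in)
    steps = x2[crop]
    steps = steps - steps[0]
    low_pass = (r - hr)[crop]
    spikes = x1[crop]
    # residual defined by the exact identity on the cropped window
    residual = x_in - low_pass - spikes - steps
    return TaraDecomposition(
        low_pass=low_pass,
        spikes=spikes,
        steps=steps,
        residual=residual,
        converged=converged,
        n_iter=it,
        objective_history=np.asarray(history),
    )


# --------------------------------------------------------------------------
# recording-level cleaning
# --------------------------------------------------------------------------

def tara_clean(
    rec: HemoRecording,
    params_hbo2: TaraParams | None = None,
    params_hb: TaraParams | None = None,
) -> tuple[HemoRecording, dict]:
    """Remove spike/step artifacts from every channel of a recording.

    Channels are processed independently per hemoglobin species with
    species-specific parameters (noise levels differ between Δ[HbO₂] and
    Δ[Hb]).  Cleaned = original − spikes − steps; the low-pass component is
    never subtracted.  A channel whose decomposition fails is returned
    unchanged with a warning.

    Returns the cleaned recording and a per-species report with artifact
    energy removed and iteration counts.
    """
    out = rec.copy()
    report: dict = {}
    for species, arr, p in (
        ("HbO2", out.dHbO2, params_hbo2 or TaraParams()),
        ("Hb", out.dHb, params_hb or TaraParams()),
    ):
        energies = []
        iters = []
        flags = []
        for ch in range(arr.shape[0]):
            try:
                dec = tara_decompose(arr[ch], rec.sampling_rate, p)
            except (ValueError, FloatingPointError) as err:
                warnings.warn(
                    f"TARA failed on {species} channel {ch}: {err}; "
                    "returned uncleaned",
                    stacklevel=2,
                )
                energies.append(0.0)
                iters.append(0)
                flags.append(False)
                continue
            arr[ch] = arr[ch] - dec.spikes - dec.steps
            energies.append(float(np.sum(dec.spikes**2 + dec.steps**2)))
            iters.append(dec.n_iter)
            flags.append(dec.converged)
        report[species] = {
            "artifact_energy": energies,
            "n_iter": iters,
            "converged": flags,
        }
    return out, report


class TaraCleaner:
    """Transformer-style wrapper around :func:`tara_clean`.

    Follows the scikit-learn estimator protocol: parameters are set in
    ``__init__`` and echoed by ``get_params``; ``transform`` maps a
    :class:`HemoRecording` to its cleaned version. There is nothing to fit.
    """

    def __init__(
        self,
        params_hbo2: TaraParams | None = None,
        params_hb: TaraParams | None = None,
    ) -> None:
        self.params_hbo2 = params_hbo2
        self.params_hb = params_hb

    def get_params(self, deep: bool = True) -> dict:
        return {"params_hbo2": self.params_hbo2, "params_hb": self.params_hb}

    def set_params(self, **kwargs) -> "TaraCleaner":
        for k, v in kwargs.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: HemoRecording | None = None, y=None) -> "TaraCleaner":
        self.report_ = None
        return self

    def transform(self, X: HemoRecording) -> HemoRecording:
        cleaned, report = tara_clean(X, self.params_hbo2, self.params_hb)
        self.report_ = report
        return cleaned

    def fit_transform(self, X: HemoRecording, y=None) -> HemoRecording:
        return self.fit(X).transform(X)
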