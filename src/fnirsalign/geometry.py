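"""Segment features and inner distance matrices on covariance geometry.

Each segment X ∈ R^{d×w} is summarised by its sample covariance P (d×d,
shrinkage-regularised to be strictly positive definite) and its row mean
h ∈ R^d.  Segments of one session are compared with the matrix Hellinger
distance between covariances,

    ρ_H(A, B) = { tr(A + B) − 2 tr[(A^{1/2} B A^{1/2})^{1/2}] }^{1/2},

optionally plus the Euclidean distance between means, normalised by the
stacked channel count d.  Two flavours of N×N inner distance matrix are
produced:

* ``session`` — (ρ_H(P_i, P_j) + ‖h_i − h_j‖₂) / d, used for
  session-by-session alignment where mean offsets are informative;
* ``subject`` — ρ_H(P_i, P_j) / d, mean-free, used for subject-by-subject
  alignment where baselines differ between people.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datatypes import SegmentSet

__all__ = [
    "SegmentFeatures",
    "DistanceMatrix",
    "segment_features",
    "hellinger",
    "session_distance_matrix",
    "subject_distance_matrix",
    "pairwise_hellinger",
]

#: eigenvalue floor used inside matrix square roots
_EIG_FLOOR = 1e-10
#: magnitude below which a negative value under a square root is clamped to 0
_NEG_CLAMP = 1e-8


@dataclass
class SegmentFeatures:
    """Per-segment covariance matrices and mean vectors of one session."""

    covariances: np.ndarray  # (N, d, d), symmetric positive definite
    means: np.ndarray  # (N, d)
    shrinkage: float
    session_id: str = ""
    subject_id: str = ""

    @property
    def n_segments(self) -> int:
        return self.covariances.shape[0]

    @property
    def d(self) -> int:
        return self.covariances.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative inner-metric matrix of one session."""

    values: np.ndarray  # (N, N)
    kind: str  # "session" | "subject"
    d_norm: int
    session_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < -1e-12):
            raise ValueError("distance matrix must be nonnegative")


def segment_features(
    segments: SegmentSet | np.ndarray, shrinkage: float = 0.05
) -> SegmentFeatures:
    """Compute covariance and mean features for every segment.

    The sample covariance over time is regularised as
    ``P + shrinkage · (tr P / d) · I`` which guarantees strict positive
    definiteness even when w < d (e.g. d = 40 stacked rows, w = 60 can be
    numerically rank-deficient; a constant segment is outright singular).

    Parameters
    ----------
    segments : SegmentSet or (N, d, w) array
    shrinkage : nonnegative regularisation weight; with 0 a degenerate
        segment raises.
    """
    if isinstance(segments, SegmentSet):
        arr = segments.segments
        sid, uid = segments.session_id, segments.subject_id
    else:
        arr = np.asarray(segments, dtype=float)
        sid = uid = ""
    if arr.ndim != 3:
        raise ValueError("expected (N, d, w) segments")
    n, d, w = arr.shape
    if w < 2:
        raise ValueError("window must contain at least 2 samples")
    if shrinkage < 0:
        raise ValueError("shrinkage must be nonnegative")

    means = arr.mean(axis=2)
    centred = arr - means[:, :, None]
    covs = np.einsum("nik,njk->nij", centred, centred) / (w - 1)
    traces = np.einsum("nii->n", covs)
    if shrinkage == 0.0 and np.any(traces <= 0):
        raise ValueError(
            "zero-variance segment encountered; positive shrinkage is required"
        )
    # a constant segment has tr P = 0; fall back to an absolute floor so the
    # regularised matrix is still strictly positive definite
    ridge = shrinkage * np.where(traces > 0, traces / d, 1.0)
    covs += ridge[:, None, None] * np.eye(d)[None]
    return SegmentFeatures(
        covariances=covs, means=means, shrinkage=shrinkage, session_id=sid,
        subject_id=uid,
    )


def _spd_sqrt(a: np.ndarray) -> np.ndarray:
    """Symmetric square root via eigendecomposition with an eigenvalue floor."""
    w, v = scipy.linalg.eigh(a)
    if w[0] < -1e-6 * max(1.0, abs(w[-1])):
        raise ValueError("matrix is not positive semidefinite")
    w = np.maximum(w, _EIG_FLOOR)
    return (v * np.sqrt(w)) @ v.T


def _check_spd(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(a, a.T, atol=1e-8 * max(1.0, np.abs(a).max())):
        raise ValueError(f"{name} must be symmetric")
    wmin = scipy.linalg.eigvalsh(a, subset_by_index=[0, 0])[0]
    if wmin <= 0:
        raise ValueError(f"{name} must be positive definite")
    return a


def hellinger(a: np.ndarray, b: np.ndarray) -> float:
    """Matrix Hellinger distance between two SPD matrices.

    Returns ``{tr(A+B) − 2 tr[(A^{1/2} B A^{1/2})^{1/2}]}^{1/2}``.  The
    cross term equals tr[A^{1/2}(A^{−1/2} B A^{−1/2})^{1/2}A^{1/2}]; the
    congruence-free form avoids inverting A.  Tiny negative values under
    the outer root (roundoff) are clamped to zero; larger ones raise.
    """
    a = _check_spd(a, "A")
    b = _check_spd(b, "B")
    if a.shape != b.shape:
        raise ValueError("A and B must share shape")
    sa = _spd_sqrt(a)
    inner = sa @ b @ sa
    ev = scipy.linalg.eigvalsh((inner + inner.T) / 2.0)
    cross = np.sqrt(np.maximum(ev, 0.0)).sum()
    val = np.trace(a) + np.trace(b) - 2.0 * cross
    if val < 0:
        if val > -_NEG_CLAMP:
            val = 0.0
        else:
            raise FloatingPointError(
                f"negative squared Hellinger distance {val:.3e}"
            )
    return float(np.sqrt(val))


def pairwise_hellinger(
    covs: np.ndarray, dtype: type = np.float32
) -> np.ndarray:
    """All-pairs Hellinger distances for a stack of SPD matrices.

    Uses the congruence identity eig(A^{1/2} B A^{1/2}) = eig(LᵀBL) with L
    the Cholesky factor of A, so each of the N(N−1)/2 pairs costs two small
    matrix products and one batched symmetric eigensolve.  Single precision
    by default (relative error ~1e−7, immaterial for a matching metric);
    pass ``dtype=np.float64`` for full precision.
    """
    covs = np.asarray(covs)
    if covs.ndim != 3 or covs.shape[1] != covs.shape[2]:
        raise ValueError("expected a (N, d, d) stack of SPD matrices")
    n = covs.shape[0]
    c = covs.astype(dtype)
    chol = np.linalg.cholesky(c)
    traces = np.einsum("nii->n", c)

    iu, ju = np.triu_indices(n, k=1)
    out = np.zeros((n, n))
    if iu.size:
        inner = np.swapaxes(chol[iu], 1, 2) @ c[ju] @ chol[iu]
        ev = np.linalg.eigvalsh(inner)
        cross = np.sqrt(np.maximum(ev, 0.0)).sum(axis=1)
        sq = (traces[iu] + traces[ju] - 2.0 * cross).astype(float)
        # cancellation tolerance follows the working precision
        neg_tol = 1e-5 if np.dtype(dtype).itemsize < 8 else _NEG_CLAMP
        if np.any(sq < -neg_tol * np.maximum(traces[iu] + traces[ju], 1.0)):
            raise FloatingPointError("negative squared Hellinger distance")
        dist = np.sqrt(np.maximum(sq, 0.0))
        out[iu, ju] = dist
        out[ju, iu] = dist
    return out


def session_distance_matrix(features: SegmentFeatures) -> DistanceMatrix:
    """Inner distance matrix mixing covariance and mean information:
    entry (i,j) = (ρ_H(P_i, P_j) + ‖h_i − h_j‖₂) / d."""
    d = features.d
    hel = pairwise_hellinger(features.covariances)
    diff = features.means[:, None, :] - features.means[None, :, :]
    mean_term = np.sqrt((diff**2).sum(axis=2))
    vals = (hel + mean_term) / d
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(
        values=vals, kind="session", d_norm=d,
        session_id=features.session_id, subject_id=features.subject_id,
    )


def subject_distance_matrix(features: SegmentFeatures) -> DistanceMatrix:
    """Mean-free inner distance matrix: entry (i,j) = ρ_H(P_i, P_j) / d.

    Dropping the mean term makes the metric invariant to per-subject
    baseline offsets, which differ across people but are stable within a
    subject."""
    d = features.d
    vals = pairwise_hellinger(features.covariances) / d
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(
        values=vals, kind="subject", d_norm=d,
        session_id=features.session_id, subject_id=features.subject_id,
    )
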