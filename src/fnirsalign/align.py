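"""Label transfer across sessions and subjects via optimal transport.

Two estimators implement the alignment procedures:

* :class:`GromovSessionAligner` — session-by-session transfer within one
  subject.  Fit on a labelled source session; predict labels for a target
  session by entropic Gromov–Wasserstein between the two sessions' inner
  distance matrices (covariance + mean metric), binarising the coupling
  column-wise and propagating source labels.
* :class:`BarycenterSubjectAligner` — subject-by-subject transfer.  Fit on
  all labelled sessions of a source subject by computing their fused G-W
  barycenter under the mean-free covariance metric; predict labels for any
  target session by G-W alignment of the barycenter to that session.

Both accept source and target sets with different channel counts (different
d) and different segment counts — the point of structure-based matching.
Module-level functions (`align_sessions`, `align_subjects`, ...) are thin
wrappers over the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import SegmentSet
from .geometry import (
    DistanceMatrix,
    segment_features,
    session_distance_matrix,
    subject_distance_matrix,
)
from .ot import Barycenter, TransportPlan, entropic_gw, fgw_barycenter, uniform

__all__ = [
    "AlignmentResult",
    "binarize_coupling",
    "transfer_labels",
    "merge_labels",
    "GromovSessionAligner",
    "BarycenterSubjectAligner",
    "align_sessions",
    "align_subjects",
    "build_source_barycenter",
]


@dataclass
class AlignmentResult:
    """Outcome of transferring labels onto one target segment set."""

    predicted_labels: np.ndarray
    coupling: TransportPlan
    binarized_coupling: np.ndarray
    source_id: str = ""
    target_id: str = ""
    config_snapshot: dict | None = None

    def accuracy(self, true_labels: np.ndarray) -> float:
        true_labels = np.asarray(true_labels)
        if true_labels.shape != self.predicted_labels.shape:
            raise ValueError("label vectors must share length")
        return float(np.mean(self.predicted_labels == true_labels))


# --------------------------------------------------------------------------
# coupling → labels
# --------------------------------------------------------------------------

def binarize_coupling(t: np.ndarray | TransportPlan) -> np.ndarray:
    """Per column, set the largest entry to 1 and the rest to 0.

    Ties break to the lowest row index (np.argmax convention), making the
    operation deterministic.  Every column of the output sums to 1.
    """
    m = t.matrix if isinstance(t, TransportPlan) else np.asarray(t, dtype=float)
    if m.ndim != 2:
        raise ValueError("coupling must be a matrix")
    if np.any(m < 0):
        raise ValueError("coupling must be nonnegative")
    out = np.zeros_like(m)
    out[np.argmax(m, axis=0), np.arange(m.shape[1])] = 1.0
    return out


def transfer_labels(
    t_cp: np.ndarray, source_labels: np.ndarray
) -> np.ndarray:
    """Propagate source labels through a binarised coupling: target j gets
    the label of the source row selected in column j (T_cpᵀ·y with one-hot
    columns)."""
    t_cp = np.asarray(t_cp)
    source_labels = np.asarray(source_labels)
    if t_cp.ndim != 2 or t_cp.shape[0] != source_labels.shape[0]:
        raise ValueError("rows of the coupling must match the source labels")
    rows = np.argmax(t_cp, axis=0)
    return source_labels[rows]


def merge_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse the four n-back levels into low {0,1} → 0 and high
    {2,3} → 1 workload classes."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() > 3):
        raise ValueError("labels must lie in {0, 1, 2, 3}")
    return (labels >= 2).astype(int)


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

def _resolve_labels(
    segments: SegmentSet | DistanceMatrix, y: np.ndarray | None
) -> np.ndarray:
    if isinstance(segments, DistanceMatrix):
        if y is None:
            raise ValueError(
                "labels are required when fitting on a precomputed distance"
            )
        n = segments.values.shape[0]
    else:
        n = segments.n_segments
    labels = np.asarray(segments.labels if y is None else y, dtype=int)
    if labels.shape[0] != n:
        raise ValueError("one label per source segment required")
    return labels


def _check_informative(c: DistanceMatrix, name: str) -> None:
    if not np.any(c.values > 0):
        raise ValueError(f"{name} distance matrix is identically zero")


class GromovSessionAligner(BaseEstimator):
    """Session-by-session label transfer by entropic Gromov–Wasserstein.

    Parameters
    ----------
    lam : entropic regularisation weight; None picks a small default from
        the cost scale (plans stay near-binary).
    shrinkage : covariance shrinkage used for segment features.
    metric : "session" (covariance + mean distance) or "subject"
        (mean-free); session-by-session transfer uses the former.
    tol, max_outer, sinkhorn_tol, sinkhorn_max_iter : solver controls.

    Attributes (after fit)
    ----------------------
    source_distance_ : DistanceMatrix of the source session.
    source_labels_ : label vector of the source segments.
    """

    def __init__(
        self,
        lam: float | None = None,
        shrinkage: float = 0.05,
        metric: str = "session",
        tol: float = 1e-6,
        max_outer: int = 40,
        sinkhorn_tol: float = 1e-7,
        sinkhorn_max_iter: int = 2000,
    ) -> None:
        self.lam = lam
        self.shrinkage = shrinkage
        self.metric = metric
        self.tol = tol
        self.max_outer = max_outer
        self.sinkhorn_tol = sinkhorn_tol
        self.sinkhorn_max_iter = sinkhorn_max_iter

    def _distance(self, segments: SegmentSet | DistanceMatrix) -> DistanceMatrix:
        if isinstance(segments, DistanceMatrix):
            return segments  # precomputed (e.g. cached by a grid run)
        feats = segment_features(segments, shrinkage=self.shrinkage)
        if self.metric == "session":
            return session_distance_matrix(feats)
        if self.metric == "subject":
            return subject_distance_matrix(feats)
        raise ValueError("metric must be 'session' or 'subject'")

    def fit(
        self, X: SegmentSet | DistanceMatrix, y: np.ndarray | None = None
    ) -> "GromovSessionAligner":
        """Compute and store the source session's inner distance matrix.

        ``X`` may be a labelled :class:`SegmentSet` or a precomputed
        :class:`DistanceMatrix` (then ``y`` must give the labels)."""
        self.source_labels_ = _resolve_labels(X, y)
        self.source_distance_ = self._distance(X)
        _check_informative(self.source_distance_, "source")
        self.source_id_ = X.session_id
        return self

    def predict(self, X: SegmentSet | DistanceMatrix) -> np.ndarray:
        """Transfer source labels onto the target segments."""
        return self.align(X).predicted_labels

    def align(self, X: SegmentSet | DistanceMatrix) -> AlignmentResult:
        """Full alignment: coupling, binarised coupling and labels."""
        if not hasattr(self, "source_distance_"):
            raise ValueError("fit the aligner on a labelled source first")
        ct = self._distance(X)
        _check_informative(ct, "target")
        cs = self.source_distance_
        plan = entropic_gw(
            cs.values, ct.values,
            uniform(cs.values.shape[0]), uniform(ct.values.shape[0]),
            lam=self.lam, tol=self.tol, max_outer=self.max_outer,
            sinkhorn_tol=self.sinkhorn_tol,
            sinkhorn_max_iter=self.sinkhorn_max_iter,
        )
        t_cp = binarize_coupling(plan)
        labels = transfer_labels(t_cp, self.source_labels_)
        self.last_plan_ = plan
        return AlignmentResult(
            predicted_labels=labels,
            coupling=plan,
            binarized_coupling=t_cp,
            source_id=self.source_id_,
            target_id=X.session_id,
            config_snapshot=self.get_params(),
        )

    def score(self, X: SegmentSet, y: np.ndarray | None = None) -> float:
        labels = _resolve_labels(X, y)
        return float(np.mean(self.predict(X) == labels))


class BarycenterSubjectAligner(BaseEstimator):
    """Subject-by-subject label transfer via an FG-W barycenter.

    Fit summarises all labelled source sessions into a single
    (distance matrix, label vector) barycenter under the mean-free
    covariance metric; predict aligns that barycenter to a target session
    with entropic G-W and propagates the (rounded) barycenter labels.

    Parameters
    ----------
    alpha : FG-W trade-off between label cost (1−α) and structure cost (α).
    q : exponent of the feature cost |f − g|^q (2 = squared loss).
    lam : entropic weight for couplings, None → automatic small default.
    n_bary : barycenter size; defaults to the common source session size.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        q: float = 2.0,
        lam: float | None = None,
        shrinkage: float = 0.05,
        n_bary: int | None = None,
        bary_tol: float = 1e-5,
        bary_max_iter: int = 8,
        tol: float = 1e-6,
        max_outer: int = 40,
        n_classes: int = 4,
    ) -> None:
        self.alpha = alpha
        self.q = q
        self.lam = lam
        self.shrinkage = shrinkage
        self.n_bary = n_bary
        self.bary_tol = bary_tol
        self.bary_max_iter = bary_max_iter
        self.tol = tol
        self.max_outer = max_outer
        self.n_classes = n_classes

    def _distance(self, s: SegmentSet | DistanceMatrix) -> DistanceMatrix:
        if isinstance(s, DistanceMatrix):
            return s
        return subject_distance_matrix(segment_features(s, self.shrinkage))

    def fit(
        self,
        X: list[SegmentSet | DistanceMatrix],
        y: list[np.ndarray] | None = None,
    ) -> "BarycenterSubjectAligner":
        """Build the source subject's FG-W barycenter from its sessions.

        Sessions may be labelled :class:`SegmentSet` objects or precomputed
        mean-free :class:`DistanceMatrix` objects (then ``y`` is required)."""
        if len(X) == 0:
            raise ValueError("need at least one labelled source session")
        labels = [
            _resolve_labels(s, None if y is None else y[k])
            for k, s in enumerate(X)
        ]
        alphabet = sorted({int(v) for lab in labels for v in lab})
        if any(v < 0 or v >= self.n_classes for v in alphabet):
            raise ValueError(
                f"session labels {alphabet} outside 0..{self.n_classes - 1}"
            )
        mats = []
        for s in X:
            c = self._distance(s)
            _check_informative(c, f"session {s.session_id!r}")
            mats.append(c.values)
        self.barycenter_ = fgw_barycenter(
            list(zip(mats, [lab.astype(float) for lab in labels])),
            alpha=self.alpha, q=self.q, n_bary=self.n_bary, lam=self.lam,
            tol=self.bary_tol, max_iter=self.bary_max_iter,
        )
        # half-up rounding of the real-valued barycenter features to labels
        self.barycenter_labels_ = np.clip(
            np.floor(self.barycenter_.features + 0.5).astype(int),
            0, self.n_classes - 1,
        )
        self.source_id_ = X[0].subject_id
        return self

    def predict(self, X: SegmentSet | DistanceMatrix) -> np.ndarray:
        return self.align(X).predicted_labels

    def align(self, X: SegmentSet | DistanceMatrix) -> AlignmentResult:
        """Align the fitted barycenter to one target session."""
        if not hasattr(self, "barycenter_"):
            raise ValueError("fit the aligner on source sessions first")
        ct = self._distance(X)
        _check_informative(ct, "target")
        cb = self.barycenter_.distance_matrix
        plan = entropic_gw(
            cb, ct.values, uniform(cb.shape[0]), uniform(ct.values.shape[0]),
            lam=self.lam, tol=self.tol, max_outer=self.max_outer,
        )
        t_cp = binarize_coupling(plan)
        labels = transfer_labels(t_cp, self.barycenter_labels_)
        return AlignmentResult(
            predicted_labels=labels,
            coupling=plan,
            binarized_coupling=t_cp,
            source_id=self.source_id_,
            target_id=X.session_id,
            config_snapshot=self.get_params(),
        )

    def score(self, X: SegmentSet, y: np.ndarray | None = None) -> float:
        labels = _resolve_labels(X, y)
        return float(np.mean(self.predict(X) == labels))


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def align_sessions(
    source: SegmentSet,
    target: SegmentSet,
    source_labels: np.ndarray | None = None,
    **params,
) -> AlignmentResult:
    """One-shot session-by-session alignment (see
    :class:`GromovSessionAligner`)."""
    est = GromovSessionAligner(**params)
    est.fit(source, source_labels)
    return est.align(target)


def build_source_barycenter(
    sessions: list[SegmentSet],
    labels: list[np.ndarray] | None = None,
    **params,
) -> Barycenter:
    """FG-W barycenter of a source subject's labelled sessions."""
    est = BarycenterSubjectAligner(**params)
    est.fit(sessions, labels)
    return est.barycenter_


def align_subjects(
    source_sessions: list[SegmentSet],
    target_sessions: list[SegmentSet],
    source_labels: list[np.ndarray] | None = None,
    **params,
) -> list[AlignmentResult]:
    """Subject-by-subject alignment: barycenter built once from the source
    subject, then aligned to every target session."""
    est = BarycenterSubjectAligner(**params)
    est.fit(source_sessions, source_labels)
    return [est.align(t) for t in target_sessions]
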