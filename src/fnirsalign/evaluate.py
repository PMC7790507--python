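"""Scoring of alignment runs: confusion matrices, per-pair accuracies,
inverse-variance weighted summaries and significance tests, plus the
experiment grid that evaluates all ordered session or subject pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .align import (
    BarycenterSubjectAligner,
    GromovSessionAligner,
    merge_labels,
)
from .datatypes import SegmentSet
from .geometry import DistanceMatrix, pairwise_hellinger, segment_features

__all__ = [
    "EvaluationReport",
    "confusion_matrix",
    "weighted_summary",
    "significance_tests",
    "prepare_distance_cache",
    "experiment_grid",
    "report_table",
]


@dataclass
class EvaluationReport:
    """Aggregate of one evaluation mode (sessions or subjects)."""

    confusion: np.ndarray  # K×K row-normalised, averaged over pairs
    accuracy: float
    per_pair_accuracies: list[float]
    per_subject_means: dict[str, float]
    per_subject_sds: dict[str, float]
    weighted_mean: float
    weighted_se: float
    tests: list[dict] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> np.ndarray:
    """Row-normalised confusion matrix: entry (r, c) is the fraction of
    truth-r segments predicted as c.  Rows without support stay zero."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("label vectors must share length")
    if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes))
    np.add.at(counts, (t, p), 1.0)
    support = counts.sum(axis=1, keepdims=True)
    out = np.divide(counts, support, out=np.zeros_like(counts),
                    where=support > 0)
    return out


def weighted_summary(
    values: np.ndarray, sds: np.ndarray
) -> tuple[float, float]:
    """Inverse-variance weighted mean and its standard error.

    Weights w_i = 1/sd_i²; mean = Σw_i v_i / Σw_i; SE = (Σw_i)^{−1/2}.
    Zero standard deviations are rejected (apply a floor upstream).
    """
    values = np.asarray(values, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if values.shape != sds.shape or values.ndim != 1 or values.size == 0:
        raise ValueError("values and sds must be equal-length 1-D vectors")
    if np.any(sds <= 0):
        raise ValueError("standard deviations must be positive; floor zeros")
    w = 1.0 / sds**2
    mean = float((w * values).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    return mean, se


def significance_tests(
    accuracies: np.ndarray,
    chance: float = 0.25,
    paired_a: np.ndarray | None = None,
    paired_b: np.ndarray | None = None,
) -> list[dict]:
    """One-sample t against chance and optional paired t between methods.

    Two-sided p-values throughout.  Degenerate (zero-variance) samples are
    flagged rather than raising.
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size < 2:
        raise ValueError("need at least two accuracy values")
    out = []
    if np.ptp(accuracies) == 0 and accuracies[0] == chance:
        out.append({
            "name": "one_sample_vs_chance", "statistic": 0.0,
            "p_value": 1.0, "df": accuracies.size - 1, "flag": None,
        })
    else:
        res = scipy.stats.ttest_1samp(accuracies, popmean=chance)
        flag = "degenerate_variance" if np.ptp(accuracies) == 0 else None
        out.append({
            "name": "one_sample_vs_chance",
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "df": int(accuracies.size - 1),
            "flag": flag,
        })
    if paired_a is not None or paired_b is not None:
        if paired_a is None or paired_b is None:
            raise ValueError("paired test needs both vectors")
        pa = np.asarray(paired_a, dtype=float)
        pb = np.asarray(paired_b, dtype=float)
        if pa.shape != pb.shape or pa.size < 2:
            raise ValueError("paired vectors must share length ≥ 2")
        diff = pa - pb
        if np.ptp(diff) == 0:
            out.append({
                "name": "paired", "statistic": np.nan, "p_value": np.nan,
                "df": pa.size - 1, "flag": "degenerate_variance",
            })
        else:
            res = scipy.stats.ttest_rel(pa, pb)
            out.append({
                "name": "paired", "statistic": float(res.statistic),
                "p_value": float(res.pvalue), "df": int(pa.size - 1),
                "flag": None,
            })
    return out


# --------------------------------------------------------------------------
# experiment grid
# --------------------------------------------------------------------------

def _accumulate(
    reports: list[tuple[str, str, np.ndarray, np.ndarray]],
    n_classes: int,
    chance: float,
) -> EvaluationReport:
    """Aggregate (subject, pair-id, truth, prediction) records."""
    if not reports:
        raise ValueError("no alignment pairs were evaluated")
    confusions = []
    accs = []
    pairs = []
    by_subject: dict[str, list[float]] = {}
    for subject, pair, truth, pred in reports:
        confusions.append(confusion_matrix(truth, pred, n_classes))
        acc = float(np.mean(truth == pred))
        accs.append(acc)
        pairs.append((subject, pair))
        by_subject.setdefault(subject, []).append(acc)
    means = {s: float(np.mean(v)) for s, v in by_subject.items()}
    sds = {
        s: float(max(np.std(v, ddof=1) if len(v) > 1 else 0.0, 1e-3))
        for s, v in by_subject.items()
    }
    subjects = sorted(means)
    if len(subjects) > 1:
        wmean, wse = weighted_summary(
            np.array([means[s] for s in subjects]),
            np.array([sds[s] for s in subjects]),
        )
    else:
        s0 = subjects[0]
        wmean, wse = means[s0], sds[s0]
    tests = (
        significance_tests(np.asarray(accs), chance=chance)
        if len(accs) >= 2
        else []
    )
    return EvaluationReport(
        confusion=np.mean(confusions, axis=0),
        accuracy=float(np.mean(accs)),
        per_pair_accuracies=accs,
        per_subject_means=means,
        per_subject_sds=sds,
        weighted_mean=wmean,
        weighted_se=wse,
        tests=tests,
        pairs=pairs,
    )


def prepare_distance_cache(
    subjects: dict[str, list[SegmentSet]], shrinkage: float = 0.05
) -> dict[str, list[tuple[DistanceMatrix, DistanceMatrix, np.ndarray]]]:
    """Precompute both inner distance matrices for every session.

    The pairwise Hellinger part is shared between the session metric
    (+ mean distance) and the mean-free subject metric, so computing both
    flavours costs the same as one.  The result can be fed to
    :func:`experiment_grid` via ``cache=`` to evaluate both modes without
    recomputation.
    """
    cache: dict[str, list[tuple[DistanceMatrix, DistanceMatrix, np.ndarray]]] = {}
    for sid, sessions in subjects.items():
        entries = []
        for s in sessions:
            feats = segment_features(s, shrinkage=shrinkage)
            hel = pairwise_hellinger(feats.covariances)
            diff = feats.means[:, None, :] - feats.means[None, :, :]
            mean_term = np.sqrt((diff**2).sum(axis=2))
            d = feats.d
            common = dict(
                d_norm=d, session_id=s.session_id, subject_id=s.subject_id
            )
            dm_session = DistanceMatrix(
                values=(hel + mean_term) / d, kind="session", **common
            )
            dm_subject = DistanceMatrix(values=hel / d, kind="subject", **common)
            entries.append((dm_session, dm_subject, s.labels.copy()))
        cache[sid] = entries
    return cache


def experiment_grid(
    subjects: dict[str, list[SegmentSet]] | None = None,
    mode: str = "sessions",
    merge: bool = False,
    n_classes: int = 4,
    cache: dict[str, list[tuple[DistanceMatrix, DistanceMatrix, np.ndarray]]] | None = None,
    **aligner_params,
) -> EvaluationReport:
    """Evaluate alignment over all ordered pairs.

    ``subjects`` maps subject id → list of labelled SegmentSets (sessions
    already preprocessed; inadmissible sessions simply absent).  Mode
    "sessions" aligns every ordered session pair (m, n), m ≠ n, within each
    subject; mode "subjects" builds one barycenter per source subject and
    aligns it to every session of every other subject.  With ``merge`` the
    4-level labels are collapsed to low/high before scoring.
    """
    if mode not in ("sessions", "subjects"):
        raise ValueError("mode must be 'sessions' or 'subjects'")
    shrinkage = aligner_params.pop("shrinkage", 0.05)
    # inner distance matrices are pair-independent: compute each session's
    # once (the Hellinger part is the expensive piece) and reuse across all
    # ordered pairs
    if cache is None:
        if subjects is None:
            raise ValueError("either subjects or cache must be given")
        cache = prepare_distance_cache(subjects, shrinkage=shrinkage)
    pick = 0 if mode == "sessions" else 1
    cached = {
        sid: [(entry[pick], entry[2]) for entry in entries]
        for sid, entries in cache.items()
    }

    records: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    if mode == "sessions":
        for sid, mats in cached.items():
            for m, (src_dm, src_labels) in enumerate(mats):
                est = GromovSessionAligner(
                    metric="session", **aligner_params
                ).fit(src_dm, src_labels)
                for n, (tgt_dm, tgt_labels) in enumerate(mats):
                    if m == n:
                        continue
                    pred = est.predict(tgt_dm)
                    records.append((sid, f"{m}->{n}", tgt_labels, pred))
    elif mode == "subjects":
        bary_params = dict(aligner_params)
        bary_params.setdefault("n_classes", n_classes)
        fitted = {
            sid: BarycenterSubjectAligner(**bary_params).fit(
                [dm for dm, _ in mats], [lab for _, lab in mats]
            )
            for sid, mats in cached.items()
            if mats
        }
        for src_id, est in fitted.items():
            for tgt_id, mats in cached.items():
                if tgt_id == src_id:
                    continue
                for n, (tgt_dm, tgt_labels) in enumerate(mats):
                    pred = est.predict(tgt_dm)
                    records.append(
                        (src_id, f"->{tgt_id}/{n}", tgt_labels, pred)
                    )

    k = n_classes
    chance = 1.0 / n_classes
    if merge:
        records = [
            (s, p, merge_labels(t), merge_labels(q)) for s, p, t, q in records
        ]
        k = 2
        chance = 0.5
    return _accumulate(records, n_classes=k, chance=chance)


def report_table(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Per-subject mean ± sd accuracy table (%) with a weighted Avg column,
    one row per evaluation mode."""
    rows = {}
    for name, rep in reports.items():
        row = {
            s: f"{100 * rep.per_subject_means[s]:.0f}"
            f"±{100 * rep.per_subject_sds[s]:.0f}"
            for s in sorted(rep.per_subject_means)
        }
        row["Avg."] = (
            f"{100 * rep.weighted_mean:.0f}±{100 * rep.weighted_se:.0f}"
        )
        rows[name] = row
    return pd.DataFrame(rows).T
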