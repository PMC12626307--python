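"""Scoring detector output against ground truth.

Calls are matched to truth sites one-to-one within a +-50 bp tolerance
(greedy nearest-neighbor).  The false-call rate reported here is the
fraction of calls that match no truth site (1 - precision).  Ranking
quality of true versus decoy candidates is summarized by the rank-statistic
AUC, AUC = P(score_true > score_decoy) + 0.5 * P(equal).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats


@dataclass
class EvalReport:
    n_truth: int
    n_called: int
    true_positives: int
    sensitivity: float
    false_call_rate: float
    auc: float | None = None

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def match_events(called, truth, tol: int = 50) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest matching of calls to truth within +-tol bp.

    ``called`` and ``truth`` are sequences of ``(chrom, pos)``.  Candidate
    pairs are taken in order of increasing distance (ties: leftmost truth,
    then leftmost call); each truth matches at most one call and vice versa.
    Returns (truth_index, called_index) pairs.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    truth_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ti, (chrom, pos) in enumerate(truth):
        truth_by_chrom.setdefault(chrom, []).append((pos, ti))
    for lst in truth_by_chrom.values():
        lst.sort()
    pairs = []
    for ci, (chrom, pos) in enumerate(called):
        lst = truth_by_chrom.get(chrom, [])
        positions = [p for p, _ in lst]
        lo = np.searchsorted(positions, pos - tol, side="left")
        hi = np.searchsorted(positions, pos + tol, side="right")
        for p, ti in lst[lo:hi]:
            pairs.append((abs(p - pos), p, pos, ti, ci))
    pairs.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    matches = []
    for _d, _tp, _cp, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matches.append((ti, ci))
    matches.sort()
    return matches


def evaluate_calls(called, truth, tol: int = 50, auc: float | None = None) -> EvalReport:
    matches = match_events(called, truth, tol=tol)
    tp = len(matches)
    n_called, n_truth = len(called), len(truth)
    return EvalReport(
        n_truth=n_truth,
        n_called=n_called,
        true_positives=tp,
        sensitivity=tp / n_truth if n_truth else 0.0,
        false_call_rate=(n_called - tp) / n_called if n_called else 0.0,
        auc=auc,
    )


def roc_auc(scores_pos, scores_neg) -> float:
    """Rank-statistic AUC: P(pos > neg) + 0.5 * P(pos == neg)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rp = float(np.sum(ranks[: len(pos)]))
    return (rp - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))


def roc_points(scores_pos, scores_neg) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs at every distinct score threshold, for plotting."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    return pts


def write_roc_tsv(points: list[tuple[float, float]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
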