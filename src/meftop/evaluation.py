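"""Model-quality labels and benchmark metrics.

Implements the length-normalized structural similarity score (TM-score) for
equal-length residue correspondences via iteratively refined Kabsch
superpositions, plus the selection metrics used to compare ranking schemes:
Top1% (fraction of targets whose selected model is native-like, TM > 0.4),
average true-quality rank of the selection, summed TM of selections, and the
per-target Pearson correlation between a predicted score and true quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .geometry import kabsch
from .io_structures import StructureModel

__all__ = [
    "tm_score",
    "tm_score_coords",
    "NATIVE_LIKE_TM",
    "top1_percent",
    "average_rank",
    "per_target_cc",
    "EvaluationReport",
]

#: Models with TM above this value are counted as native-like (strict >).
NATIVE_LIKE_TM = 0.4


def tm_d0(length: int) -> float:
    """Length-dependent distance scale, floored at 0.5 A."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _score_from_alignment(x: np.ndarray, y: np.ndarray, idx: np.ndarray, d0: float) -> tuple[float, np.ndarray]:
    """Superpose x on y over idx, return (score over all residues, distances)."""
    r, t = kabsch(x[idx], y[idx])
    d = np.linalg.norm(x @ r.T + t - y, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d


def tm_score_coords(x: np.ndarray, y: np.ndarray, max_iter: int = 20) -> float:
    """TM-score of coordinate set x against reference y (identity correspondence).

    The score is maximized over superpositions seeded by contiguous fragments
    of several lengths; each seed alignment is refined by re-superposing on
    the residues currently within the inclusion cutoff (starting at d0 and
    relaxed when fewer than four residues qualify) until the aligned set is
    stable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coordinate sets must have equal shape")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 residues")
    d0 = tm_d0(n)
    if n <= 40:
        # small chains have many competitive local superpositions: seed from
        # every contiguous fragment
        frag_lengths = list(range(n, 3, -1))
        step_of = lambda fl: 1
    elif n <= 48:
        frag_lengths = sorted({n, 3 * n // 4, n // 2, max(n // 4, 4), 12, 8, 6, 4}, reverse=True)
        step_of = lambda fl: 1
    else:
        frag_lengths = sorted({n, max(n // 2, 4), max(n // 4, 4), 4}, reverse=True)
        step_of = lambda fl: max(1, fl // 2)
    best = 0.0
    for fl in frag_lengths:
        step = step_of(fl)
        starts = list(range(0, n - fl + 1, step))
        if starts[-1] != n - fl:
            starts.append(n - fl)
        for s in starts:
            idx = np.arange(s, s + fl)
            prev: set[int] | None = None
            for _ in range(max_iter):
                score, d = _score_from_alignment(x, y, idx, d0)
                best = max(best, score)
                cut = d0
                sel = np.nonzero(d < cut)[0]
                while len(sel) < min(4, n):
                    cut += 0.5
                    sel = np.nonzero(d < cut)[0]
                cur = set(sel.tolist())
                if prev is not None and cur == prev:
                    break
                prev = cur
                idx = sel
    return best


def tm_score(model: StructureModel, native: StructureModel) -> float:
    """TM-score of a model against the native structure (CA atoms, equal length)."""
    if model.length != native.length:
        raise ValueError(
            f"length mismatch: model {model.length} vs native {native.length}"
        )
    return tm_score_coords(model.ca_coords, native.ca_coords)


def top1_percent(selected_tms, cutoff: float = NATIVE_LIKE_TM) -> float:
    """Percentage of targets whose selected model has TM strictly above the cutoff."""
    tms = np.asarray(list(selected_tms), dtype=float)
    if len(tms) == 0:
        raise ValueError("no targets")
    return float(100.0 * np.mean(tms > cutoff))


def average_rank(tm_lists, selected_indices) -> float:
    """Mean rank of the selected model when each pool is sorted by true TM
    descending (ties receive their average rank)."""
    ranks = []
    for tms, sel in zip(tm_lists, selected_indices):
        r = rankdata(-np.asarray(tms, dtype=float), method="average")
        ranks.append(r[sel])
    if not ranks:
        raise ValueError("no targets")
    return float(np.mean(ranks))


def per_target_cc(predicted_lists, tm_lists):
    """Mean and sd over targets of the Pearson correlation between a
    predicted score and true TM (0 for a degenerate, constant side)."""
    ccs = []
    for pred, tms in zip(predicted_lists, tm_lists):
        pred = np.asarray(pred, dtype=float)
        tms = np.asarray(tms, dtype=float)
        if pred.std() == 0.0 or tms.std() == 0.0:
            ccs.append(0.0)
        else:
            ccs.append(float(np.corrcoef(pred, tms)[0, 1]))
    if not ccs:
        raise ValueError("no targets")
    return float(np.mean(ccs)), float(np.std(ccs))


@dataclass
class EvaluationReport:
    metric: str
    n_targets: int
    top1_pct: float
    avg_rank: float
    sum_tm: float
    mean_cc: float
    sd_cc: float

    def to_text(self) -> str:
        return (
            f"metric: {self.metric}\n"
            f"targets: {self.n_targets}\n"
            f"Top1%: {self.top1_pct:.1f}\n"
            f"average rank: {self.avg_rank:.2f}\n"
            f"sum of TM-scores: {self.sum_tm:.2f}\n"
            f"per-target CC: {self.mean_cc:.3f} +/- {self.sd_cc:.3f}\n"
        )

    def to_tsv_row(self) -> str:
        return (
            f"{self.metric}\t{self.n_targets}\t{self.top1_pct:.2f}\t{self.avg_rank:.3f}"
            f"\t{self.sum_tm:.3f}\t{self.mean_cc:.4f}\t{self.sd_cc:.4f}"
        )

    TSV_HEADER = "metric\tn_targets\ttop1_pct\tavg_rank\tsum_tm\tmean_cc\tsd_cc"
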