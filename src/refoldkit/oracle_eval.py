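"""How well do refolding metrics predict binary experimental outcomes?

Given per-design metrics (mean pLDDT, scRMSD) paired with a binary
experimental-success label, this module computes threshold-independent
ROC AUCs (Mann–Whitney pair-counting convention, half credit for ties),
sweeps a grid of designability thresholds recording the confusion
matrix, precision, recall and F1 in every cell, selects the optimal cell
with a most-stringent tie-break, tests 2×2 association with Fisher's
exact test, and builds length-distribution-matched control subsets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .designability import DesignRecord

__all__ = [
    "OutcomeTable",
    "ThresholdGridResult",
    "roc_auc",
    "roc_curve_points",
    "threshold_grid_sweep",
    "select_optimum",
    "fisher_exact_2x2",
    "matched_subset_by_length",
    "DEFAULT_PLDDT_AXIS",
    "DEFAULT_SCRMSD_AXIS",
]

DEFAULT_PLDDT_AXIS = tuple(np.arange(50.0, 100.1, 5.0))   # 50..100 step 5
DEFAULT_SCRMSD_AXIS = tuple(np.arange(0.0, 5.01, 0.5))    # 0..5 step 0.5 Å


@dataclass
class OutcomeTable:
    """Per-design metrics paired with a binary experimental outcome."""

    data: pd.DataFrame

    REQUIRED = ("design_id", "plddt_mean", "scrmsd", "outcome")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        if "dataset" not in self.data.columns:
            self.data = self.data.assign(dataset="default")
        out = self.data["outcome"].to_numpy()
        if not np.isin(out, [0, 1]).all():
            raise ValueError("outcome labels must be 0/1")
        p = self.data["plddt_mean"].to_numpy(float)
        r = self.data["scrmsd"].to_numpy(float)
        if not (np.isfinite(p).all() and np.isfinite(r).all()):
            raise ValueError("non-finite metrics")
        if (p < 0).any() or (p > 100).any():
            raise ValueError("plddt_mean outside [0, 100]")
        if (r < 0).any():
            raise ValueError("negative scrmsd")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "OutcomeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, index=False)

    def by_dataset(self) -> dict[str, "OutcomeTable"]:
        return {
            name: OutcomeTable(group.reset_index(drop=True))
            for name, group in self.data.groupby("dataset")
        }


def roc_auc(scores, labels, higher_is_better: bool = True) -> float:
    """ROC AUC by the Mann–Whitney pair-counting convention.

    Equals P(score_pos > score_neg) + ½ P(tie) over all positive–negative
    pairs, computed from midranks; ``higher_is_better=False`` flips the
    score orientation (used for scRMSD, where low is good).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    if not higher_is_better:
        scores = -scores
    ranks = stats.rankdata(scores)  # midranks give the ½-credit tie handling
    # 2×U is integral, so the division below is the only rounding step
    u2 = int(round(2.0 * ranks[labels == 1].sum())) - n_pos * (n_pos + 1)
    return u2 / (2.0 * n_pos * n_neg)


def roc_curve_points(scores, labels, higher_is_better: bool = True) -> pd.DataFrame:
    """(FPR, TPR, threshold) points of the empirical ROC curve."""
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    if not higher_is_better:
        scores = -scores
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class ThresholdGridResult:
    """Confusion matrices and scores over a (pLDDT, scRMSD) threshold grid.

    All per-cell arrays are indexed ``[i_plddt, j_scrmsd]``; a cell
    predicts positive for a design iff ``plddt ≥ plddt_axis[i]`` and
    ``scrmsd ≤ scrmsd_axis[j]`` (inclusive, matching the designability
    predicate).  ``precision_defined`` marks cells with at least one
    predicted positive; precision and F1 are reported as 0 elsewhere.
    """

    plddt_axis: np.ndarray
    scrmsd_axis: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    precision_defined: np.ndarray
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.plddt_axis):
            for j, r in enumerate(self.scrmsd_axis):
                rows.append({
                    "plddt_min": p, "scrmsd_max": r,
                    "tp": self.tp[i, j], "fp": self.fp[i, j],
                    "fn": self.fn[i, j], "tn": self.tn[i, j],
                    "precision": self.precision[i, j],
                    "recall": self.recall[i, j],
                    "f1": self.f1[i, j],
                })
        return pd.DataFrame(rows)


def threshold_grid_sweep(
    table: OutcomeTable,
    plddt_axis=DEFAULT_PLDDT_AXIS,
    scrmsd_axis=DEFAULT_SCRMSD_AXIS,
) -> ThresholdGridResult:
    """Confusion matrix / precision / recall / F1 at every threshold pair."""
    plddt_axis = np.asarray(plddt_axis, dtype=float)
    scrmsd_axis = np.asarray(scrmsd_axis, dtype=float)
    if plddt_axis.size == 0 or scrmsd_axis.size == 0:
        raise ValueError("empty threshold axis")
    if len(table) == 0:
        raise ValueError("empty outcome table")
    p = table.data["plddt_mean"].to_numpy(float)
    r = table.data["scrmsd"].to_numpy(float)
    y = table.data["outcome"].to_numpy(int)

    pred = (p[:, None, None] >= plddt_axis[None, :, None]) & (
        r[:, None, None] <= scrmsd_axis[None, None, :]
    )
    pos = y[:, None, None] == 1
    tp = (pred & pos).sum(axis=0)
    fp = (pred & ~pos).sum(axis=0)
    fn = (~pred & pos).sum(axis=0)
    tn = (~pred & ~pos).sum(axis=0)

    npred = tp + fp
    precision_defined = npred > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(precision_defined, tp / np.maximum(npred, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    return ThresholdGridResult(
        plddt_axis=plddt_axis,
        scrmsd_axis=scrmsd_axis,
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1,
        precision_defined=precision_defined,
        n=len(table),
    )


@dataclass
class OptimumCell:
    plddt_min: float
    scrmsd_max: float
    index: tuple[int, int]
    criterion: str
    value: float
    degenerate: bool = False  # no cell anywhere predicted a positive


def select_optimum(grid: ThresholdGridResult, criterion: str = "f1") -> OptimumCell:
    """Maximal-criterion cell, ties broken by stringency.

    Among tied cells the highest pLDDT threshold wins, then the lowest
    scRMSD threshold.  When no cell in the whole grid predicts a single
    positive the result is flagged degenerate (stringent corner).
    """
    if criterion not in ("precision", "f1"):
        raise ValueError("criterion must be 'precision' or 'f1'")
    values = grid.precision if criterion == "precision" else grid.f1
    degenerate = not bool(grid.precision_defined.any())
    best = values.max()
    ties = np.argwhere(values == best)
    # stringency: highest pLDDT threshold first, then lowest scRMSD threshold
    order = sorted(
        (tuple(ij) for ij in ties),
        key=lambda ij: (-grid.plddt_axis[ij[0]], grid.scrmsd_axis[ij[1]]),
    )
    i, j = order[0]
    return OptimumCell(
        plddt_min=float(grid.plddt_axis[i]),
        scrmsd_max=float(grid.scrmsd_axis[j]),
        index=(int(i), int(j)),
        criterion=criterion,
        value=float(values[i, j]),
        degenerate=degenerate,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2×2 contingency table.

    Sums hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2×2")
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def matched_subset_by_length(
    cases: list[DesignRecord],
    pool: list[DesignRecord],
    n_bins: int = 10,
    rng_seed: int = 0,
) -> list[DesignRecord]:
    """Control subset of ``pool`` matching the length distribution of ``cases``.

    The cases' length range is split into ``n_bins`` equal-width bins;
    from each bin the pool contributes ``k × (case count)`` entries,
    where ``k = floor(min over non-empty case bins of pool/case count)``,
    sampled without replacement.  Deterministic for a given seed.
    """
    if not cases or not pool:
        raise ValueError("cases and pool must be non-empty")
    lengths = np.array([c.length for c in cases])
    lo, hi = lengths.min(), lengths.max()
    width = (hi - lo) / n_bins if hi > lo else 1.0

    def bin_of(length: int) -> int:
        if length < lo or length > hi:
            return -1
        return min(int((length - lo) / width), n_bins - 1)

    case_counts = np.zeros(n_bins, dtype=int)
    for c in cases:
        case_counts[bin_of(c.length)] += 1
    pool_bins: list[list[DesignRecord]] = [[] for _ in range(n_bins)]
    for p in pool:
        b = bin_of(p.length)
        if b >= 0:
            pool_bins[b].append(p)

    ratios = []
    for b in range(n_bins):
        if case_counts[b] == 0:
            continue
        if not pool_bins[b]:
            raise ValueError(
                f"no pool entries for non-empty case bin {b} "
                f"[{lo + b * width:.0f}, {lo + (b + 1) * width:.0f}]"
            )
        ratios.append(len(pool_bins[b]) / case_counts[b])
    k = int(np.floor(min(ratios)))
    if k < 1:
        raise ValueError("pool too small to match the case distribution")

    rng = np.random.default_rng(rng_seed)
    subset: list[DesignRecord] = []
    for b in range(n_bins):
        take = k * int(case_counts[b])
        if take == 0:
            continue
        chosen = rng.choice(len(pool_bins[b]), size=take, replace=False)
        subset.extend(pool_bins[b][i] for i in sorted(chosen))
    return subset
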