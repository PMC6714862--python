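"""Two-stage feature selection: significance-test filter, then greedy
sequential backward selection (SBS).

The filter stage splits every feature column into its positive-class and
negative-class samples and applies one two-sample test to all columns: a
pooled-variance Student's t-test when the majority of column-halves look
normally distributed, otherwise a two-sample Kolmogorov–Smirnov test.
Columns whose p-value falls below ``alpha`` are retained.

The wrapper stage starts from the retained set and repeatedly eliminates
the single feature whose removal maximises an evaluator's accuracy, down
to one remaining feature, recording the accuracy of every visited subset;
the best subset is the argmax (ties go to the larger subset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .datasets import DegenerateClassError
from .features import FeatureMatrix

__all__ = [
    "SelectionResult",
    "SBSTrace",
    "split_by_label",
    "normality_decision",
    "significance_filter",
    "sbs",
]


class EmptySelectionError(ValueError):
    """The filter stage retained no columns (consider relaxing alpha)."""


def split_by_label(values: np.ndarray, labels: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Split matrix rows into (positive-class rows, negative-class rows)."""
    values = np.asarray(values)
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("labels length must match the number of rows")
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateClassError("both classes must be present")
    return pos, neg


def normality_decision(values: np.ndarray, labels: np.ndarray,
                       alpha_norm: float = 0.05,
                       max_shapiro_n: int = 500) -> str:
    """Pick the two-sample test for the filter stage.

    Runs a Shapiro–Wilk normality test on each column-half (each class's
    sample of each column, subsampled to ``max_shapiro_n`` values for
    stability).  Returns ``"t_test"`` if strictly more than half the
    column-halves are consistent with normality (p >= alpha_norm),
    otherwise ``"ks_test"`` — one choice applied to all columns.
    """
    pos, neg = split_by_label(values, labels)
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("normality test needs >= 3 rows per class")
    n_pass = 0
    n_total = 0
    for half in (pos, neg):
        sub = half[:max_shapiro_n]
        for j in range(sub.shape[1]):
            col = sub[:, j]
            if np.ptp(col) == 0:  # constant column-half: not normal
                p = 0.0
            else:
                p = stats.shapiro(col).pvalue
            n_pass += p >= alpha_norm
            n_total += 1
    return "t_test" if n_pass / n_total > 0.5 else "ks_test"


@dataclass
class SelectionResult:
    """Per-column filter outcome and the retained (filtered) matrix."""

    test_used: str
    statistic: np.ndarray
    p_value: np.ndarray
    h: np.ndarray                  # 1 where p < alpha
    retained_mask: np.ndarray
    alpha: float
    filtered: FeatureMatrix | None = None

    @property
    def retained_count(self) -> int:
        return int(self.h.sum())

    def to_json(self, path: str | Path,
                column_names: Sequence[str] | None = None) -> None:
        names = (list(column_names) if column_names is not None
                 else [f"col{i}" for i in range(len(self.h))])
        records = [
            {"column": names[i], "statistic": float(self.statistic[i]),
             "p_value": float(self.p_value[i]), "h": int(self.h[i])}
            for i in range(len(self.h))
        ]
        Path(path).write_text(json.dumps(
            {"test_used": self.test_used, "alpha": self.alpha,
             "retained_count": self.retained_count, "columns": records},
            indent=2))


def significance_filter(fm: FeatureMatrix | np.ndarray,
                        labels: np.ndarray | None = None,
                        alpha: float = 0.05,
                        test_choice: str = "auto",
                        equal_var: bool = True) -> SelectionResult:
    """Screen feature columns by a per-column two-sample test.

    For every column the positive-class and negative-class values are
    compared with the chosen test (``"auto"`` delegates the t-vs-KS choice
    to :func:`normality_decision`); columns with ``p < alpha`` are flagged
    significant (h = 1) and retained in their original order.  No
    multiple-testing correction is applied — this is a screening step.

    Raises :class:`EmptySelectionError` when nothing survives.
    """
    if isinstance(fm, FeatureMatrix):
        values = fm.values
        y = fm.labels if labels is None else np.asarray(labels)
    else:
        values = np.asarray(fm, dtype=np.float64)
        if labels is None:
            raise ValueError("labels required when passing a bare array")
        y = np.asarray(labels)
    pos, neg = split_by_label(values, y)
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("significance_filter needs >= 3 rows per class")
    if test_choice == "auto":
        test_choice = normality_decision(values, y)
    if test_choice not in ("t_test", "ks_test"):
        raise ValueError(f"unknown test_choice {test_choice!r}")

    if test_choice == "t_test":
        res = stats.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
        statistic, p_value = np.asarray(res.statistic), np.asarray(res.pvalue)
        # zero-variance identical columns give nan; treat as no difference
        statistic = np.nan_to_num(statistic, nan=0.0)
        p_value = np.nan_to_num(p_value, nan=1.0)
    else:
        statistic = np.empty(values.shape[1])
        p_value = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            res = stats.ks_2samp(pos[:, j], neg[:, j])
            statistic[j], p_value[j] = res.statistic, res.pvalue

    h = (p_value < alpha).astype(np.int64)
    mask = h.astype(bool)
    if not mask.any():
        raise EmptySelectionError(
            f"no column significant at alpha={alpha} ({test_choice})")
    filtered = fm.select_columns(mask) if isinstance(fm, FeatureMatrix) else None
    return SelectionResult(test_used=test_choice, statistic=statistic,
                           p_value=p_value, h=h, retained_mask=mask,
                           alpha=alpha, filtered=filtered)


@dataclass
class SBSTrace:
    """Record of a greedy backward-elimination run.

    ``subset_sizes[k]`` and ``subset_accuracy[k]`` describe the k-th
    visited subset (sizes p, p−1, …, 1); ``elimination_order`` lists the
    removed columns in removal order; ``best_subset`` is the visited
    subset with maximal accuracy (the larger subset on ties).
    """

    elimination_order: list[str]
    subset_sizes: list[int]
    subset_accuracy: list[float]
    subsets: list[list[str]]
    best_subset: list[str]

    @property
    def best_accuracy(self) -> float:
        return max(self.subset_accuracy)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"elimination_order": self.elimination_order,
             "subset_sizes": self.subset_sizes,
             "subset_accuracy": self.subset_accuracy,
             "best_subset": self.best_subset}, indent=2))


def sbs(column_names: Sequence[str],
        evaluator: Callable[[list[int]], float]) -> SBSTrace:
    """Greedy sequential backward selection over feature columns.

    Starting from all ``p`` columns, the evaluator (mapping a list of
    column indices to an accuracy in [0, 1]) scores the removal of each
    remaining column; the removal with the highest resulting accuracy is
    applied, repeatedly, until one feature remains.  Exactly ``p`` subsets
    are visited.  Ties on removal are broken toward removing the
    largest-index column; ties on best subset toward the larger subset.
    """
    names = list(column_names)
    p = len(names)
    if p < 2:
        raise ValueError("sbs needs at least 2 columns")
    current = list(range(p))
    sizes = [p]
    accs = [float(evaluator(current))]
    subsets = [[names[i] for i in current]]
    elimination: list[str] = []
    while len(current) > 1:
        best_acc = -np.inf
        best_drop = None
        for pos_idx in range(len(current)):  # later index wins ties
            candidate = current[:pos_idx] + current[pos_idx + 1:]
            acc = float(evaluator(candidate))
            if acc >= best_acc:
                best_acc = acc
                best_drop = pos_idx
        elimination.append(names[current[best_drop]])
        current = current[:best_drop] + current[best_drop + 1:]
        sizes.append(len(current))
        accs.append(best_acc)
        subsets.append([names[i] for i in current])
    best_k = int(np.argmax(accs))  # earliest (largest) subset wins ties
    return SBSTrace(elimination_order=elimination, subset_sizes=sizes,
                    subset_accuracy=accs, subsets=subsets,
                    best_subset=subsets[best_k])
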