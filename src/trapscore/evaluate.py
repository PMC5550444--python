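"""Statistical evaluation toolkit for score sets.

ROC/AUC with specificity-first threshold reporting, Mann–Whitney U
comparisons, binned score–MAF correlation, non-parametric quantile–quantile
comparison of unequal-sized samples, and hypergeometric (Fisher) gene-list
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

logger = logging.getLogger(__name__)


@dataclass
class ScoredSet:
    """Parallel score/label/MAF/gene arrays for one evaluation dataset."""

    scores: np.ndarray
    labels: Optional[np.ndarray] = None
    maf: Optional[np.ndarray] = None
    gene: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        for name in ("labels", "maf"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != len(self.scores):
                    raise ValueError(f"{name} length does not match scores")
                setattr(self, name, arr)
        if self.gene is not None and len(self.gene) != len(self.scores):
            raise ValueError("gene length does not match scores")


@dataclass
class RocResult:
    """Threshold sweep of a score set against binary labels."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scored: ScoredSet) -> RocResult:
    """Trapezoidal AUC over the full threshold sweep (ties grouped)."""
    if scored.labels is None:
        raise ValueError("labels are required for ROC analysis")
    labels = np.asarray(scored.labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes in the labels")
    fpr, tpr, thresholds = _roc_curve(labels, scored.scores, drop_intermediate=False)
    return RocResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(_trapezoid_auc(fpr, tpr))
    )


def sens_spec_at(scored: ScoredSet, threshold: float) -> Tuple[float, float]:
    """(sensitivity, specificity) calling score >= threshold positive."""
    if scored.labels is None:
        raise ValueError("labels are required")
    y = np.asarray(scored.labels, dtype=int)
    called = scored.scores >= threshold
    tp = int(np.sum(called & (y == 1)))
    fn = int(np.sum(~called & (y == 1)))
    tn = int(np.sum(~called & (y == 0)))
    fp = int(np.sum(called & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann–Whitney U test of two score samples.

    Exact enumeration when both groups have n <= 8 and there are no ties;
    otherwise the tie-corrected normal approximation. Returns (U of the
    first sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def binned_maf_correlation(
    scored: ScoredSet, n_bins: int = 20
) -> Tuple[float, float, pd.DataFrame]:
    """Correlation of mean MAF with mean score over score-quantile bins.

    The score distribution is cut into ``n_bins`` equal-count (5% for 20
    bins) intervals; each bin contributes its mean score and mean MAF, and a
    Pearson correlation over the bin means is returned. Empty/duplicate
    quantile bins are merged with a logged note.
    """
    if scored.maf is None:
        raise ValueError("maf values are required")
    scores = scored.scores
    if len(np.unique(scores)) < n_bins:
        raise ValueError(f"need at least {n_bins} distinct scores")
    bins = pd.qcut(scores, q=n_bins, duplicates="drop")
    if len(bins.categories) < n_bins:
        logger.info(
            "merged %d empty quantile bins", n_bins - len(bins.categories)
        )
    df = pd.DataFrame({"score": scores, "maf": np.asarray(scored.maf, dtype=float)})
    table = (
        df.groupby(bins, observed=True)
        .agg(mean_score=("score", "mean"), mean_maf=("maf", "mean"), n=("score", "size"))
        .reset_index(names="bin")
    )
    r, p = stats.pearsonr(table["mean_score"], table["mean_maf"])
    return float(r), float(p), table


def qq_compare(
    small: Sequence[float], large: Sequence[float]
) -> List[Tuple[float, float]]:
    """Quantile–quantile pairs of a small sample against a larger one.

    The larger sample's order statistics are linearly interpolated at the
    plotting positions of the smaller sample, so a set compared against
    itself returns the identity line exactly.
    """
    small = np.sort(np.asarray(small, dtype=float))
    large = np.sort(np.asarray(large, dtype=float))
    if len(small) == 0 or len(large) == 0:
        raise ValueError("both samples must be non-empty")
    if len(small) > len(large):
        raise ValueError("first sample must be the smaller (or equal) one")
    if len(small) == 1:
        pos = np.array([(len(large) - 1) / 2.0])
    else:
        # fractional order-statistic positions; integer positions (equal
        # sizes) hit the large sample's elements exactly
        pos = np.linspace(0.0, len(large) - 1.0, num=len(small))
    interp = np.interp(pos, np.arange(len(large)), large)
    return list(zip(small.tolist(), interp.tolist()))


def fisher_enrichment(
    k_hits: int, n_list: int, K_background_hits: int, N_background: int
) -> float:
    """One-sided (enrichment) Fisher exact p for a gene-list hit count.

    ``k_hits`` of the ``n_list`` genes of interest belong to a category that
    covers ``K_background_hits`` of ``N_background`` genes in a genome-wide
    reference. The 2x2 table contrasts the list column (k, n-k) with the
    reference column (K, N-K) taken as-is — the construction used when a
    published gene catalog serves as the comparison column — and the
    reported value is the conditional upper tail P(X >= k).
    """
    if not (0 <= k_hits <= n_list):
        raise ValueError("require 0 <= k <= n")
    if not (0 <= K_background_hits <= N_background):
        raise ValueError("require 0 <= K <= N")
    table = [
        [k_hits, n_list - k_hits],
        [K_background_hits, N_background - K_background_hits],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])
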