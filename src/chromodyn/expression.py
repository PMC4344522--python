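"""Differential-expression filtering for two-group array experiments.

Per-gene one-way fixed-effects test (with two groups this is the
pooled-variance t-test) on log2-scale expression, Benjamini-Hochberg
q-values, and fold/q threshold filtering with up/down classification.

Fold-change convention: group b relative to group a on the linear scale,
with ratios below 1 reported as negative reciprocals, so a two-fold
decrease is -2 (the presentation used by the common array-analysis
suites).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["de_test", "fdr_bh", "filter_de", "de_pipeline"]


def de_test(matrix: pd.DataFrame, group_labels: Sequence[str]) -> pd.DataFrame:
    """Per-gene two-group test and fold-change.

    ``matrix`` is genes x samples on the log2 scale; ``group_labels``
    assigns each column to one of exactly two groups (first label
    encountered = group a, reference).  Returns a DataFrame indexed by
    gene with columns mean_a, mean_b, fold_change (signed linear scale)
    and p.  Genes with zero variance in both groups get p = 1 when the
    means are equal and p = 0 otherwise, by policy.
    """
    labels = np.asarray(group_labels)
    if len(labels) != matrix.shape[1]:
        raise ValueError("one group label per sample column required")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    a = matrix.loc[:, labels == uniq[0]].to_numpy(dtype=float)
    b = matrix.loc[:, labels == uniq[1]].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >=2 replicates per group")

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    degenerate = np.isnan(p)
    p = np.where(degenerate & (mean_a == mean_b), 1.0, p)
    p = np.where(degenerate & (mean_a != mean_b), 0.0, p)

    log2_fold = mean_b - mean_a
    fold = np.where(log2_fold >= 0, 2.0 ** log2_fold, -(2.0 ** (-log2_fold)))
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "fold_change": fold, "p": p},
        index=matrix.index,
    )


def fdr_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over {j : p_j >= p_i} of m * p_j / rank_j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0,1]")
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def filter_de(
    results: pd.DataFrame, min_fold: float = 2.0, max_q: float = 0.1
) -> dict:
    """Apply fold/q thresholds and classify genes up or down.

    A gene passes iff |fold_change| >= min_fold and q <= max_q; direction
    follows the fold sign.  Adds ``q`` and ``direction`` columns and
    returns the annotated table plus the up/down gene lists and counts.
    """
    if not min_fold > 1:
        raise ValueError("min_fold must exceed 1")
    if not 0 < max_q <= 1:
        raise ValueError("max_q must be in (0,1]")
    annotated = results.copy()
    if "q" not in annotated.columns:
        annotated["q"] = fdr_bh(annotated["p"].to_numpy())
    passing = (annotated["fold_change"].abs() >= min_fold) & (annotated["q"] <= max_q)
    direction = np.where(~passing, "ns",
                         np.where(annotated["fold_change"] > 0, "up", "down"))
    annotated["direction"] = direction
    up = annotated.index[annotated["direction"] == "up"].tolist()
    down = annotated.index[annotated["direction"] == "down"].tolist()
    return {
        "table": annotated,
        "up": up,
        "down": down,
        "n_up": len(up),
        "n_down": len(down),
        "min_fold": float(min_fold),
        "max_q": float(max_q),
    }


def de_pipeline(
    matrix: pd.DataFrame,
    group_labels: Sequence[str],
    min_fold: float = 2.0,
    max_q: float = 0.1,
) -> dict:
    """Test, correct and filter in one call."""
    results = de_test(matrix, group_labels)
    results["q"] = fdr_bh(results["p"].to_numpy())
    return filter_de(results, min_fold=min_fold, max_q=max_q)
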