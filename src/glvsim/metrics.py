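"""Realism summaries for comparing two count datasets.

Simulated read-count tables can be compared to empirical ones (or to other
simulations) along three axes: the distribution of per-sample alpha
diversities, per-feature differential abundance, and overall sparsity.
Differential abundance uses a two-sided Wilcoxon rank-sum test on per-sample
relative abundances with Benjamini-Hochberg adjustment across features — a
deliberately simple, replaceable default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dynamics import to_relative
from .exceptions import ConfigurationError, DomainError
from .types import Timecourse

__all__ = [
    "alpha_diversity",
    "alpha_diversities",
    "sparsity",
    "differential_abundance",
    "RealismReport",
    "compare_realism",
    "cohort_counts",
]

_INDICES = ("shannon", "simpson", "richness")


def alpha_diversity(counts_row: np.ndarray, index: str = "shannon") -> float:
    """Within-sample diversity of one count vector.

    shannon: -sum p ln p over nonzero p; simpson: 1 - sum p^2;
    richness: number of nonzero entries.
    """
    if index not in _INDICES:
        raise ConfigurationError(f"index must be one of {_INDICES}, got {index!r}")
    row = np.asarray(counts_row, dtype=float)
    if np.any(row < 0):
        raise DomainError("counts must be nonnegative")
    total = row.sum()
    if total == 0:
        raise DomainError("alpha diversity is undefined for an all-zero sample")
    if index == "richness":
        return float(np.count_nonzero(row))
    p = row[row > 0] / total
    if index == "shannon":
        return float(-(p * np.log(p)).sum())
    return float(1.0 - (p * p).sum())


def alpha_diversities(counts: np.ndarray, index: str = "shannon") -> np.ndarray:
    """Per-sample (row) alpha diversity of a count matrix."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    return np.array([alpha_diversity(row, index) for row in counts])


def sparsity(counts: np.ndarray) -> float:
    """Fraction of exactly-zero entries."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise DomainError("sparsity is undefined for an empty matrix")
    return float(np.count_nonzero(counts == 0) / counts.size)


def differential_abundance(counts_a: np.ndarray, counts_b: np.ndarray) -> pd.DataFrame:
    """Per-feature location shift and rank-sum test between two count tables.

    Rows are samples, columns are features (equal feature counts required).
    Returns a DataFrame with ``feature``, ``shift`` (mean relative abundance
    in ``b`` minus in ``a``), raw ``pvalue`` and BH-adjusted ``qvalue``.
    """
    A = np.atleast_2d(np.asarray(counts_a, dtype=float))
    B = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise DomainError(
            f"feature counts differ: {A.shape[1]} vs {B.shape[1]}"
        )
    RA, RB = to_relative(A), to_relative(B)
    shifts = RB.mean(axis=0) - RA.mean(axis=0)
    pvals = np.ones(A.shape[1])
    for j in range(A.shape[1]):
        a, b = RA[:, j], RB[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue  # identical constant feature: no evidence, p = 1
        pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature": np.arange(A.shape[1]),
            "shift": shifts,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )


@dataclass
class RealismReport:
    """Side-by-side summaries of two count datasets."""

    alpha_a: np.ndarray
    alpha_b: np.ndarray
    sparsity_a: float
    sparsity_b: float
    per_feature_stats: pd.DataFrame
    index: str = "shannon"

    def to_frame(self) -> pd.DataFrame:
        """Flat table view (one row per feature plus summary columns)."""
        df = self.per_feature_stats.copy()
        df["sparsity_a"] = self.sparsity_a
        df["sparsity_b"] = self.sparsity_b
        df["mean_alpha_a"] = float(np.mean(self.alpha_a))
        df["mean_alpha_b"] = float(np.mean(self.alpha_b))
        return df


def compare_realism(
    counts_a: np.ndarray, counts_b: np.ndarray, index: str = "shannon"
) -> RealismReport:
    """Compute all three realism axes between two count datasets."""
    A = np.atleast_2d(np.asarray(counts_a, dtype=float))
    B = np.atleast_2d(np.asarray(counts_b, dtype=float))
    return RealismReport(
        alpha_a=alpha_diversities(A, index),
        alpha_b=alpha_diversities(B, index),
        sparsity_a=sparsity(A),
        sparsity_b=sparsity(B),
        per_feature_stats=differential_abundance(A, B),
        index=index,
    )


def cohort_counts(
    timecourses: list[Timecourse], node: str | None = None, timepoint: str = "final"
) -> np.ndarray:
    """Extract a samples x features count matrix from a cohort.

    ``timepoint="final"`` takes each individual's last recorded sample (the
    endpoint comparison, the default); ``"all"`` pools every recorded time
    point as a separate sample.  ``node`` restricts to one node's columns.
    """
    if timepoint not in ("final", "all"):
        raise ConfigurationError("timepoint must be 'final' or 'all'")
    rows = []
    for tc in timecourses:
        cols = tc.node_slice(node) if node is not None else slice(None)
        Y = tc.Y[:, cols]
        rows.append(Y[-1:] if timepoint == "final" else Y)
    return np.vstack(rows)
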