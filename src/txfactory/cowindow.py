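"""Sliding-window co-expression clustering.

A 500 Kb window is slid along each chromosome in 5 Kb steps and the number of
expressed genes in each window is compared with a permutation null obtained
by shuffling the expressed calls over the gene positions.  A window is called
significant when its observed count exceeds the chosen quantile (default
0.95) of its own permutation distribution, i.e. when the empirical CDF of the
observed statistic among permuted statistics exceeds the quantile.
Significant windows are merged into maximal co-expressed regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CowindowParams",
    "enumerate_windows",
    "window_statistic",
    "permutation_test",
    "merge_significant",
]


@dataclass(frozen=True)
class CowindowParams:
    """Window geometry and permutation-null settings."""

    window_kb: float = 500.0
    step_kb: float = 5.0
    n_permutations: int = 1000
    significance_quantile: float = 0.95
    permutation_scope: str = "per_chromosome"  # or "genome_wide"
    statistic: str = "count"  # or "fraction"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window_kb <= 0 or self.step_kb <= 0:
            raise ValueError("window_kb and step_kb must be positive")
        if self.step_kb > self.window_kb:
            raise ValueError("step_kb must not exceed window_kb")
        if not 0 < self.significance_quantile < 1:
            raise ValueError("significance_quantile must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.permutation_scope not in ("per_chromosome", "genome_wide"):
            raise ValueError("permutation_scope must be per_chromosome or genome_wide")
        if self.statistic not in ("count", "fraction"):
            raise ValueError("statistic must be count or fraction")
        if self.seed is None:
            raise ValueError("a seed is required for the permutation null")


def enumerate_windows(chrom_length_kb: float, params: CowindowParams) -> np.ndarray:
    """Window starts/ends [k*step, k*step + window) for every start strictly
    inside the chromosome; trailing windows are truncated at the end."""
    if chrom_length_kb <= 0:
        raise ValueError("chrom_length_kb must be positive")
    starts = np.arange(0.0, chrom_length_kb, params.step_kb)
    ends = np.minimum(starts + params.window_kb, chrom_length_kb)
    return np.column_stack([starts, ends])


def window_statistic(window, genes: pd.DataFrame) -> int:
    """Number of expressed genes whose midpoint lies in the half-open window."""
    start, end = window
    mid = (genes["start_kb"].to_numpy() + genes["end_kb"].to_numpy()) / 2.0
    inside = (mid >= start) & (mid < end)
    return int((genes["expressed"].to_numpy()[inside] == 1).sum())


def _window_counts(mid_sorted: np.ndarray, labels_sorted: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Expressed counts per window from position-sorted midpoints, via a
    prefix sum over the sorted labels."""
    csum = np.concatenate([[0], np.cumsum(labels_sorted)])
    lo = np.searchsorted(mid_sorted, windows[:, 0], side="left")
    hi = np.searchsorted(mid_sorted, windows[:, 1], side="left")
    return csum[hi] - csum[lo]


def permutation_test(
    genes: pd.DataFrame,
    params: CowindowParams,
    chrom_length_kb: float | dict | None = None,
) -> pd.DataFrame:
    """Per-window permutation test of co-expression.

    For each permutation the expressed calls are shuffled over gene positions
    (within each chromosome, or genome-wide).  For every window the empirical
    p is the fraction of permutations whose statistic is strictly below the
    observed one, and the window is significant when empirical_p exceeds
    ``significance_quantile``.

    Returns a data frame with chrom, start_kb, end_kb, n_genes, n_expressed,
    statistic, empirical_p and significant columns.
    """
    rng = np.random.default_rng(params.seed)
    genes = genes.sort_values(["chrom", "start_kb"], ignore_index=True)
    labels_all = genes["expressed"].to_numpy().astype(np.int64)
    if labels_all.sum() == 0:
        warnings.warn("no expressed genes in scope; all windows non-significant")

    if params.permutation_scope == "genome_wide":
        perms_all = np.array([rng.permutation(labels_all) for _ in range(params.n_permutations)])

    results = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        mid = ((sub["start_kb"] + sub["end_kb"]) / 2.0).to_numpy()
        order = np.argsort(mid, kind="stable")
        mid_sorted = mid[order]
        labels = sub["expressed"].to_numpy().astype(np.int64)[order]
        if isinstance(chrom_length_kb, dict):
            clen = chrom_length_kb[chrom]
        elif chrom_length_kb is not None:
            clen = float(chrom_length_kb)
        else:
            clen = float(sub["end_kb"].max())
        windows = enumerate_windows(clen, params)
        observed = _window_counts(mid_sorted, labels, windows)
        n_genes_w = _window_counts(mid_sorted, np.ones_like(labels), windows)

        below = np.zeros(len(windows), dtype=np.int64)
        for p in range(params.n_permutations):
            if params.permutation_scope == "per_chromosome":
                perm = rng.permutation(labels)
            else:
                perm = perms_all[p][idx][order]
            below += _window_counts(mid_sorted, perm, windows) < observed
        emp_p = below / params.n_permutations

        obs_stat = observed.astype(float)
        if params.statistic == "fraction":
            with np.errstate(invalid="ignore", divide="ignore"):
                obs_stat = np.where(n_genes_w > 0, observed / n_genes_w, 0.0)
        results.append(
            pd.DataFrame(
                dict(
                    chrom=chrom,
                    start_kb=windows[:, 0],
                    end_kb=windows[:, 1],
                    n_genes=n_genes_w,
                    n_expressed=observed,
                    statistic=obs_stat,
                    empirical_p=emp_p,
                    significant=emp_p > params.significance_quantile,
                )
            )
        )
    return pd.concat(results, ignore_index=True)


def merge_significant(results: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended significant windows into maximal
    intervals per chromosome (the 'blue line' regions)."""
    sig = results[results["significant"]].sort_values(["chrom", "start_kb"])
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start_kb"], sub["end_kb"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start_kb", "end_kb"])
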