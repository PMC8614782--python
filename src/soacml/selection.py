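"""Unsupervised descriptor pruning.

Three stages, applied in order and merged into one report:

1. **zero variance** — constant columns carry no information;
2. **duplicates** — value-identical columns are redundant (the survivor
   of a duplicate group is the first in name order);
3. **correlation pruning** — while any pair of columns has
   ``|Pearson r| >= threshold``, the pair attaining the maximum is broken
   by deleting the member that is redundant with more of the table:
   more partners at ``|r| >= threshold`` first, then larger mean ``|r|``
   over all other features, then the later name in lexicographic order.
   The full correlation matrix is recomputed after every deletion.

The output certificate is direct: no surviving pair reaches the
threshold, and re-running the selection is the identity.  Applied to the
descriptor table only; fingerprint bits bypass pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .table import FeatureTable

ZERO_VARIANCE = "zero_variance"
DUPLICATE = "duplicate"
CORRELATION = "correlation"


@dataclass(frozen=True)
class Removal:
    feature: str
    stage: str                      # zero_variance | duplicate | correlation
    partner: Optional[str] = None   # the correlated/duplicate survivor
    abs_r: Optional[float] = None   # |r| at removal (correlation stage)


@dataclass
class SelectionReport:
    """Ordered removal log plus the surviving feature list."""

    removed: list[Removal] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    threshold: Optional[float] = None

    @property
    def removed_names(self) -> list[str]:
        return [r.feature for r in self.removed]

    def stage_removals(self, stage: str) -> list[Removal]:
        return [r for r in self.removed if r.stage == stage]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.feature, r.stage, r.partner or "", np.nan if r.abs_r is None else r.abs_r)
             for r in self.removed],
            columns=["feature", "stage", "partner", "abs_r"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def drop_zero_variance(table: FeatureTable) -> tuple[FeatureTable, list[Removal]]:
    """Remove constant columns (variance exactly zero)."""
    _require_rows(table)
    X = table.values
    constant = [c for c in table.feature_names if X[c].nunique(dropna=False) <= 1]
    removals = [Removal(c, ZERO_VARIANCE) for c in constant]
    return table.drop(constant), removals


def drop_duplicates(table: FeatureTable) -> tuple[FeatureTable, list[Removal]]:
    """Remove value-identical columns; survivor = first in name order."""
    _require_rows(table)
    groups: dict[bytes, list[str]] = {}
    for c in table.feature_names:
        key = table.values[c].to_numpy(dtype=float).tobytes()
        groups.setdefault(key, []).append(c)
    removals: list[Removal] = []
    doomed: list[str] = []
    for members in groups.values():
        if len(members) > 1:
            ordered = sorted(members)
            for loser in ordered[1:]:
                removals.append(Removal(loser, DUPLICATE, partner=ordered[0]))
                doomed.append(loser)
    # preserve input column-order semantics of the log: sort by feature name
    removals.sort(key=lambda r: r.feature)
    return table.drop(doomed), removals


def _abs_corr(X: pd.DataFrame) -> np.ndarray:
    r = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    if r.ndim == 0:  # single column
        r = np.ones((1, 1))
    r = np.maximum(r, r.T)  # enforce exact symmetry
    np.fill_diagonal(r, 0.0)
    return r


def correlation_prune(table: FeatureTable,
                      threshold: float = 0.95) -> tuple[FeatureTable, list[Removal]]:
    """Greedy elimination of the most correlated pair until none reaches
    the threshold.

    Requires zero-variance columns to have been removed (Pearson r is
    undefined for constants).  Recomputes the full correlation matrix at
    every step; with p <= a few hundred descriptors this is cheap and
    keeps the procedure trivially auditable.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    _require_rows(table)
    if any(table.values[c].nunique(dropna=False) <= 1 for c in table.feature_names):
        raise ValueError("zero-variance column present; run drop_zero_variance first")

    current = table
    removals: list[Removal] = []
    while current.n_features >= 2:
        names = current.feature_names
        r = _abs_corr(current.values)
        rmax = r.max()
        if rmax < threshold:
            break
        # pair attaining the max; ties broken by lexicographically smallest pair
        ii, jj = np.where(r == rmax)
        pairs = sorted({tuple(sorted((names[i], names[j])))
                        for i, j in zip(ii, jj) if i != j})
        a, b = pairs[0]
        victim = _pick_victim(a, b, names, r, threshold)
        survivor = b if victim == a else a
        removals.append(Removal(victim, CORRELATION, partner=survivor,
                                abs_r=float(rmax)))
        current = current.drop([victim])
    return current, removals


def _pick_victim(a: str, b: str, names: list[str], r: np.ndarray,
                 threshold: float) -> str:
    """Of a maximally-correlated pair, delete the member redundant with
    more of the table (partner count, then mean |r|, then later name)."""
    ia, ib = names.index(a), names.index(b)
    partners_a = int((r[ia] >= threshold).sum())
    partners_b = int((r[ib] >= threshold).sum())
    if partners_a != partners_b:
        return a if partners_a > partners_b else b
    if len(names) > 1:
        mean_a = r[ia].sum() / (len(names) - 1)
        mean_b = r[ib].sum() / (len(names) - 1)
        if not np.isclose(mean_a, mean_b, rtol=0.0, atol=1e-12):
            return a if mean_a > mean_b else b
    return max(a, b)  # later name order


def select_features(table: FeatureTable,
                    threshold: float = 0.95) -> tuple[FeatureTable, SelectionReport]:
    """Compose the three stages; return the pruned table and merged report."""
    t1, rem_zv = drop_zero_variance(table)
    t2, rem_dup = drop_duplicates(t1)
    t3, rem_corr = correlation_prune(t2, threshold=threshold)
    report = SelectionReport(removed=rem_zv + rem_dup + rem_corr,
                             kept=t3.feature_names, threshold=threshold)
    return t3, report


def max_abs_correlation(table: FeatureTable) -> float:
    """Largest off-diagonal |Pearson r| — the selection certificate."""
    if table.n_features < 2:
        return 0.0
    return float(_abs_corr(table.values).max())


def _require_rows(table: FeatureTable) -> None:
    if table.n_samples < 2:
        raise ValueError(f"need at least 2 rows, got {table.n_samples}")
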