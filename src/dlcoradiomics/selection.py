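"""Redundancy screening and iterative correlation-clustering selection.

The selection chain, applied to a patients x features table with a binary
abnormal-DLCO label:

1. **Near-zero-variance filter** — drops constant columns and columns whose
   most-common/second-most-common value frequency ratio exceeds a threshold
   while the distinct-value fraction stays small (the widely used caret
   convention: ratio 95/5 = 19, unique fraction 0.1).
2. **High-correlation pruning** — among any pair with \\|Spearman\\| above
   ``prune_rho`` (default 0.95), the member less associated with the label
   is removed, greedily by descending pairwise correlation.
3. **Iterative correlation clustering** — features are grouped into the
   connected components of the graph whose edges are \\|Spearman\\| >
   ``cluster_rho`` (default 0.75); per cluster only the feature with the
   smallest label-association p-value (two-sided Wilcoxon rank-sum)
   survives.  The step repeats until no pair of surviving features exceeds
   the threshold, so the result satisfies max pairwise \\|Spearman\\| <
   ``cluster_rho`` by construction.

All steps are deterministic: ties are broken by the lexicographically
smallest feature name.  Absolute correlation is used throughout —
anti-correlated features are equally redundant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "near_zero_variance_filter",
    "prune_high_correlation",
    "association_pvalue",
    "rank_sum_pvalues",
    "iterative_cluster_select",
    "spearman_matrix",
]


@dataclass(frozen=True)
class SelectionConfig:
    prune_rho: float = 0.95
    cluster_rho: float = 0.75
    nzv_freq_ratio: float = 19.0
    nzv_unique_frac: float = 0.1
    association_test: str = "wilcoxon-rank-sum"

    def __post_init__(self) -> None:
        if not (0 < self.cluster_rho < self.prune_rho <= 1):
            raise ValueError("require 0 < cluster_rho < prune_rho <= 1")
        if self.association_test != "wilcoxon-rank-sum":
            raise ValueError("only the Wilcoxon rank-sum association test is supported")


@dataclass(frozen=True)
class SelectionResult:
    """Selected features plus a per-iteration audit trail."""

    selected: tuple[str, ...]
    iterations: int
    audit_trail: tuple[dict, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "iterations": self.iterations,
            "audit_trail": [dict(rec) for rec in self.audit_trail],
        }


def near_zero_variance_filter(
    table: pd.DataFrame, config: SelectionConfig = SelectionConfig()
) -> pd.DataFrame:
    """Drop uninformative (near-constant) feature columns."""
    if table.shape[1] == 0:
        raise ValueError("no feature columns")
    keep = []
    n = len(table)
    for col in table.columns:
        counts = table[col].value_counts()
        if len(counts) <= 1:
            continue  # constant
        freq_ratio = counts.iloc[0] / counts.iloc[1]
        unique_frac = len(counts) / n
        if freq_ratio > config.nzv_freq_ratio and unique_frac < config.nzv_unique_frac:
            continue
        keep.append(col)
    if not keep:
        raise ValueError("near-zero-variance filter removed every feature")
    return table[keep]


def association_pvalue(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value of a feature against a binary label.

    Exact when both groups have n <= 10 and the data carry no ties,
    otherwise the tie-corrected normal approximation (no continuity
    correction).  Returns 1.0 for identical degenerate groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    a = values[labels]
    b = values[~labels]
    if a.size == 0 or b.size == 0:
        raise ValueError("both label groups must be non-empty")
    if np.ptp(values) == 0:
        return 1.0
    has_ties = np.unique(values).size < values.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def spearman_matrix(table: pd.DataFrame) -> np.ndarray:
    """Pairwise Spearman correlations (constant columns yield 0, not NaN)."""
    ranks = table.rank().to_numpy()
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    bad = sd == 0
    rho[bad, :] = 0.0
    rho[:, bad] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def rank_sum_pvalues(table: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """Column-wise two-sided Wilcoxon rank-sum p-values against a binary label.

    Vectorized tie-corrected normal approximation (matches
    :func:`association_pvalue`'s asymptotic branch); falls back to the
    per-column exact computation when both groups are small.
    """
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both label groups must be non-empty")
    if n1 <= 10 and n2 <= 10:
        return pd.Series(
            {c: association_pvalue(table[c].to_numpy(), labels) for c in table.columns}
        )
    X = table.to_numpy(dtype=float)
    n = n1 + n2
    ranks = stats.rankdata(X, axis=0)
    u = ranks[labels].sum(axis=0) - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    # tie correction: sum(t^3 - t) per column over tied groups
    xs = np.sort(X, axis=0)
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(xs[:, j], return_counts=True)
        tie_term[j] = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(X.shape[1])
    ok = var > 0
    z = np.zeros_like(p)
    z[ok] = (u[ok] - mean) / np.sqrt(var[ok])
    p[ok] = np.minimum(2.0 * stats.norm.sf(np.abs(z[ok])), 1.0)
    return pd.Series(p, index=table.columns)


def _association_series(
    table: pd.DataFrame, labels: np.ndarray, precomputed: pd.Series | None = None
) -> pd.Series:
    if precomputed is not None:
        return precomputed[table.columns]
    return rank_sum_pvalues(table, labels)


def prune_high_correlation(
    table: pd.DataFrame,
    labels: np.ndarray,
    prune_rho: float = 0.95,
    pvalues: pd.Series | None = None,
) -> pd.DataFrame:
    """Remove the label-weaker member of every \\|Spearman\\| > prune_rho pair.

    Greedy by descending pairwise correlation; deterministic (ties broken by
    feature name).  ``prune_rho = 1.0`` disables pruning except for exact
    duplicates, of which exactly one copy survives.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    cols = list(table.columns)
    rho = np.abs(spearman_matrix(table))
    pvals = _association_series(table, np.asarray(labels), pvalues)
    alive = {c: True for c in cols}
    # candidate pairs above threshold, strongest first, name-tie-broken
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = rho[i, j]
            if r > prune_rho:
                pairs.append((-r, cols[i], cols[j]))
    pairs.sort()
    for _negr, ci, cj in pairs:
        if not (alive[ci] and alive[cj]):
            continue
        pi, pj = pvals[ci], pvals[cj]
        if pi < pj or (pi == pj and ci < cj):
            alive[cj] = False
        else:
            alive[ci] = False
    return table[[c for c in cols if alive[c]]]


def iterative_cluster_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    pvalues: pd.Series | None = None,
) -> SelectionResult:
    """Iterated connected-component clustering at \\|Spearman\\| > cluster_rho.

    Each iteration groups the surviving features into connected components
    of the correlation graph and keeps, per component, the feature with the
    smallest label-association p-value.  Iterates until the graph has no
    edges; the selected set therefore has max pairwise \\|Spearman\\| below
    the threshold.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("labels are degenerate: need both classes")
    if table.shape[1] == 0:
        raise ValueError("no features to select from")
    current = table.copy()
    all_pvals = _association_series(table, labels, pvalues)
    trail: list[dict] = []
    iteration = 0
    while True:
        iteration += 1
        cols = list(current.columns)
        if len(cols) == 1:
            trail.append({"iteration": iteration, "clusters": [[cols[0]]], "winners": cols})
            break
        rho = np.abs(spearman_matrix(current))
        adj = rho > config.cluster_rho
        np.fill_diagonal(adj, False)
        if not adj.any():
            trail.append(
                {"iteration": iteration, "clusters": [[c] for c in cols], "winners": cols}
            )
            break
        n_comp, comp = connected_components(csr_matrix(adj), directed=False)
        pvals = all_pvals[current.columns]
        winners = []
        clusters_rec = []
        for c in range(n_comp):
            members = sorted(np.array(cols)[comp == c].tolist())
            # min p-value, name as deterministic tie-break
            winner = min(members, key=lambda name: (pvals[name], name))
            winners.append(winner)
            clusters_rec.append(
                {
                    "members": members,
                    "p_values": {m: float(pvals[m]) for m in members},
                    "winner": winner,
                }
            )
        trail.append({"iteration": iteration, "clusters": clusters_rec, "winners": sorted(winners)})
        current = current[sorted(winners)]
    selected = tuple(current.columns)
    return SelectionResult(selected, iteration, tuple(trail))
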