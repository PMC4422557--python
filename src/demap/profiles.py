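"""Genetic-profile correlation analysis.

Each query gene's vector of S-scores across the array — its genetic
"finger print" — is compared with every other query's by Pearson correlation,
per condition.  Hierarchical clustering of the correlation matrix groups
queries by shared function, and condition-induced *shifts* in cross-group
correlation are tested against the background of all other query pairs with a
Wilcoxon rank-sum test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import rank_sum_test
from .types import ScorePanel, normalize_gene

__all__ = [
    "CorrelationMatrix",
    "profile_corr",
    "cluster_corr",
    "DeltaCorrResult",
    "delta_corr_test",
]


@dataclass
class CorrelationMatrix:
    """Queries x queries Pearson correlations for one condition.

    ``r`` holds the pairwise-complete correlations (NaN where fewer than
    ``min_overlap`` array genes are scored for both queries or a profile has
    zero variance); ``n`` holds the per-cell overlap counts.
    """

    condition: str
    r: pd.DataFrame
    n: pd.DataFrame
    min_overlap: int


def profile_corr(
    panel: ScorePanel,
    condition: str,
    screen: Optional[str] = None,
    min_overlap: int = 30,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation of query genetic profiles.

    Cells whose shared (non-missing) array-gene count falls below
    ``min_overlap`` are masked; zero-variance profiles give undefined r and
    are masked with a warning.
    """
    table = panel.table(condition, screen)
    if len(table.index) < 2:
        raise ValueError("need at least two query profiles")
    # profiles are rows; pandas corr works column-wise
    r = table.T.corr(min_periods=min_overlap)
    notna = table.notna().to_numpy().astype(np.int64)
    n = notna @ notna.T
    ndf = pd.DataFrame(n, index=table.index, columns=table.index)
    np.fill_diagonal(r.values, 1.0)
    if r.isna().to_numpy()[np.triu_indices(len(r), k=1)].any():
        warnings.warn(
            f"{condition}: some query pairs have overlap < {min_overlap} "
            "or zero-variance profiles; cells masked"
        )
    return CorrelationMatrix(condition=condition, r=r, n=ndf, min_overlap=min_overlap)


def cluster_corr(
    corr: CorrelationMatrix | pd.DataFrame,
) -> Tuple[List[str], np.ndarray]:
    """Average-linkage hierarchical clustering on distance 1 - r.

    Returns the leaf ordering (query labels) and the scipy linkage matrix.
    Masked correlation cells are imputed as 0 (uncorrelated) with a warning.
    Input rows are pre-sorted by label so the result is deterministic and
    tie-breaks resolve by leaf label.
    """
    r = corr.r if isinstance(corr, CorrelationMatrix) else corr
    if len(r) < 2:
        raise ValueError("need at least two queries to cluster")
    labels = sorted(r.index)
    r = r.loc[labels, labels].copy()
    if r.isna().any().any():
        warnings.warn("masked correlation cells imputed as 0 for clustering")
        r = r.fillna(0.0)
    d = 1.0 - r.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    order = hierarchy.leaves_list(Z)
    return [labels[i] for i in order], Z


@dataclass
class DeltaCorrResult:
    """Condition-induced correlation shift of cross-group query pairs."""

    mean_cross: float
    mean_background: float
    p_value: float
    n_cross: int
    n_background: int
    statistic: float


def delta_corr_test(
    corr_stress: CorrelationMatrix,
    corr_control: CorrelationMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_random: Optional[int] = None,
    seed: Optional[int] = None,
) -> DeltaCorrResult:
    """Test whether correlations between two query groups shift under stress.

    delta_r = r_stress - r_control for every cross-group query pair (defined
    in both conditions) is compared against the delta_r of all other query
    pairs (or ``n_random`` sampled ones) with a two-sided Wilcoxon rank-sum
    test: exact enumeration when the combined sample is small, tie-corrected
    normal approximation otherwise.
    """
    ga = [normalize_gene(g) for g in group_a]
    gb = [normalize_gene(g) for g in group_b]
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    rs, rc = corr_stress.r, corr_control.r
    queries = [q for q in rs.index if q in rc.index]

    def delta(q1: str, q2: str) -> float:
        if q1 not in queries or q2 not in queries:
            return float("nan")
        return rs.at[q1, q2] - rc.at[q1, q2]

    cross_pairs = {frozenset((a, b)) for a in ga for b in gb}
    cross = [delta(a, b) for a in ga for b in gb]
    cross = [d for d in cross if np.isfinite(d)]
    if len(cross) < 2:
        raise ValueError("need at least two cross-group pairs with defined r")

    background: List[float] = []
    for i, q1 in enumerate(queries):
        for q2 in queries[i + 1:]:
            if frozenset((q1, q2)) in cross_pairs:
                continue
            d = delta(q1, q2)
            if np.isfinite(d):
                background.append(d)
    if n_random is not None and n_random < len(background):
        rng = np.random.default_rng(seed)
        background = list(rng.choice(background, size=n_random, replace=False))
    if not background:
        raise ValueError("no background query pairs with defined r")

    w, p = rank_sum_test(cross, background)
    return DeltaCorrResult(
        mean_cross=float(np.mean(cross)),
        mean_background=float(np.mean(background)),
        p_value=p,
        n_cross=len(cross),
        n_background=len(background),
        statistic=w,
    )
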