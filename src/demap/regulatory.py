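"""Integration of differential networks with conditional regulatory evidence.

Differential interactions reflect condition-specific function; phosphoproteome
changes, expression changes and kinase-substrate relationships are orthogonal
condition-specific readouts.  This module quantifies their agreement: a
gene-level 2x2 overlap (Fisher's exact test over the array-gene universe) and
pair-level fold enrichments of annotated gene-pair classes among differential
edges (hypergeometric upper tail).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import hypergeom_tail
from .types import InteractionNetwork, PairSet, normalize_gene

__all__ = [
    "OverlapTest",
    "gene_overlap_test",
    "pair_class_enrichment",
    "query_type_fractions",
]


@dataclass
class OverlapTest:
    """2x2 overlap of {>= min_degree differential interactions} x {regulated}.

    ``a`` counts array genes in both sets; ``fold`` is the observed regulated
    fraction among differential genes over the universe-wide regulated
    fraction, so fold > 1 flags enrichment and fold < 1 depletion.  Two-sided
    Fisher p uses the sum-of-smaller-probabilities convention; the one-sided
    tails are also reported.
    """

    a: int  # differential & regulated
    b: int  # differential & not regulated
    c: int  # not differential & regulated
    d: int  # neither
    fold: float
    p_two_sided: float
    p_enrichment: float
    p_depletion: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def gene_overlap_test(
    diff_nets: Union[InteractionNetwork, Iterable[InteractionNetwork]],
    regulated: Iterable[str],
    universe: Iterable[str],
    min_degree: int = 2,
) -> OverlapTest:
    """Fisher's exact overlap between conditionally interacting array genes
    and a conditional regulatory gene set.

    An array gene is "conditionally interacting" when it carries at least
    ``min_degree`` differential interactions across the supplied network(s).
    The universe is the array genes testable in the relevant condition.
    """
    if isinstance(diff_nets, InteractionNetwork):
        diff_nets = [diff_nets]
    uni = sorted({normalize_gene(g) for g in universe})
    if not uni:
        raise ValueError("empty array-gene universe")
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    degree: Dict[str, int] = {}
    for net in diff_nets:
        for arr, d in net.degree_by_array().items():
            degree[arr] = degree.get(arr, 0) + int(d)
    diff_genes = {g for g in uni if degree.get(g, 0) >= min_degree}
    reg = {normalize_gene(g) for g in regulated} & set(uni)

    a = len(diff_genes & reg)
    b = len(diff_genes - reg)
    c = len(reg - diff_genes)
    d = len(uni) - a - b - c
    table = [[a, b], [c, d]]
    _, p_two = stats.fisher_exact(table, alternative="two-sided")
    _, p_gr = stats.fisher_exact(table, alternative="greater")
    _, p_ls = stats.fisher_exact(table, alternative="less")
    N = len(uni)
    diff_frac = a / (a + b) if (a + b) else float("nan")
    reg_frac = (a + c) / N
    fold = diff_frac / reg_frac if reg_frac > 0 else float("nan")
    return OverlapTest(
        a=a, b=b, c=c, d=d, fold=fold,
        p_two_sided=float(p_two), p_enrichment=float(p_gr), p_depletion=float(p_ls),
    )


def pair_class_enrichment(
    diff_net: InteractionNetwork,
    pair_set: PairSet,
    universe: Iterable[Tuple[str, str]],
) -> Tuple[float, float]:
    """Fold enrichment of an annotated gene-pair class among differential edges.

    fold = (class pairs in network / network size) divided by
    (class pairs in universe / universe size); p is the hypergeometric upper
    tail for the observed in-network class count.  A class absent from the
    universe gives (NaN, 1.0).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty pair universe")
    N = len(universe)
    K = sum(1 for p in universe if p in pair_set)
    net_pairs = diff_net.pairs & universe
    n = len(net_pairs)
    k = sum(1 for p in net_pairs if p in pair_set)
    if K == 0:
        return float("nan"), 1.0
    if n == 0:
        return 0.0, 1.0
    fold = (k / n) / (K / N)
    p = float(hypergeom_tail(k, N, K, n))
    return fold, p


def query_type_fractions(
    diff_net: InteractionNetwork,
    type_map: Mapping[str, str],
) -> Dict[str, float]:
    """Fraction of differential interactions explained by each query type.

    ``type_map`` assigns each query a functional class (sensor, kinase,
    transcription factor, adaptor, ...); untyped queries fall into "other".
    Fractions sum to 1 for a non-empty network.
    """
    types = {normalize_gene(q): t for q, t in type_map.items()}
    total = len(diff_net)
    counts: Dict[str, int] = {}
    for q, d in diff_net.degree_by_query().items():
        t = types.get(normalize_gene(q), "other")
        counts[t] = counts.get(t, 0) + int(d)
    if total == 0:
        return {}
    return {t: c / total for t, c in sorted(counts.items())}
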