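"""Set enrichment, gene-complex association and query ranking.

All enrichment tests condition on testability: the sampling universe is the
set of (query, array) pairs — or array genes — actually measured in the
relevant condition, never the whole genome.  Significance uses the
hypergeometric upper tail; gene-complex associations additionally carry a
permutation-based false-discovery rate obtained by shuffling complex
membership labels over the array genes, which preserves complex sizes and
each query's differential degree.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import hypergeom_tail
from .differential import DifferentialTable
from .types import GeneSetCatalog, InteractionNetwork, ThresholdConfig, normalize_gene

__all__ = [
    "EnrichmentResult",
    "sensitive_pair_enrichment",
    "complex_association",
    "complex_summary",
    "rank_queries",
    "top_queries",
    "degree_fitness_correlation",
]


@dataclass
class EnrichmentResult:
    """Observed/expected counts and significance for one tested association."""

    label: str
    observed: int
    expected: float
    fold: float  # observed / expected; NaN when expected is undefined
    p_value: float
    universe_size: int
    draws: int
    successes_in_universe: int
    fdr: Optional[float] = None


def sensitive_pair_enrichment(
    network: InteractionNetwork,
    sensitive: Iterable[str],
    universe: Iterable[Tuple[str, str]],
    both_endpoints: bool = True,
) -> EnrichmentResult:
    """Enrichment of stress-sensitive gene pairs among network edges.

    A "sensitive pair" has both endpoints in the sensitivity list (with
    ``both_endpoints=False``, at least one).  The universe is the set of
    (query, array) pairs testable in the condition; the network's pairs are
    treated as a draw of that size from the universe and the hypergeometric
    upper tail gives the p-value for observing at least as many sensitive
    pairs.
    """
    sens = {normalize_gene(g) for g in sensitive}
    universe = set(universe)
    if not universe:
        raise ValueError("empty pair universe")

    def is_sensitive(pair: Tuple[str, str]) -> bool:
        inside = (pair[0] in sens) + (pair[1] in sens)
        return inside == 2 if both_endpoints else inside >= 1

    N = len(universe)
    K = sum(1 for p in universe if is_sensitive(p))
    net_pairs = network.pairs & universe
    n = len(net_pairs)
    k = sum(1 for p in net_pairs if is_sensitive(p))
    if K == 0:
        return EnrichmentResult(
            label="sensitive_pairs", observed=k, expected=0.0, fold=float("nan"),
            p_value=1.0, universe_size=N, draws=n, successes_in_universe=0,
        )
    expected = n * K / N
    fold = k / expected if expected > 0 else float("nan")
    p = hypergeom_tail(k, N, K, n)
    return EnrichmentResult(
        label="sensitive_pairs", observed=k, expected=expected, fold=fold,
        p_value=float(p), universe_size=N, draws=n, successes_in_universe=K,
    )


def complex_association(
    diff_tables: Mapping[str, DifferentialTable],
    complexes: GeneSetCatalog,
    thresholds: ThresholdConfig = ThresholdConfig(),
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Query-gene / protein-complex association from differential interactions.

    For each stress condition, each query gene and each complex with at least
    ``min_complex_size`` members on the array, tests whether the query's
    differential partners (|z| >= tau_diff_complex) overlap the complex more
    than expected by chance, given the query's differential degree, the
    complex size and the query's testable array universe (hypergeometric
    upper tail).

    False-discovery rates are estimated per (query, condition) family by
    ``n_perm`` random permutations of the complex membership labels across
    array genes: FDR(p0) = mean permuted count of associations with p <= p0,
    divided by the observed count, clipped to [0, 1] and made monotone
    non-decreasing in p.  Associations with FDR < ``fdr_complex`` are flagged
    significant.

    Returns a tidy DataFrame with one row per (condition, query, complex).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; FDR estimates will be coarse")
    rng = np.random.default_rng(seed)
    tau = thresholds.tau_diff_complex
    records: List[Dict] = []

    for cond in diff_tables:
        table = diff_tables[cond]
        z = table.z
        arrays = np.asarray(z.columns)
        queries = np.asarray(z.index)
        catalog = complexes.restricted(arrays, min_size=thresholds.min_complex_size)
        names = sorted(catalog.names())
        dropped = sorted(set(complexes.names()) - set(names))
        if dropped:
            warnings.warn(
                f"{cond}: {len(dropped)} complexes below size "
                f"{thresholds.min_complex_size} on the array were skipped"
            )
        if not names:
            continue
        member = np.zeros((len(names), len(arrays)), dtype=bool)
        arr_index = {a: j for j, a in enumerate(arrays)}
        for i, name in enumerate(names):
            for g in catalog[name]:
                member[i, arr_index[g]] = True

        zv = z.to_numpy()
        testable = np.isfinite(zv)  # queries x arrays
        partners = testable & (np.abs(zv) >= tau)
        N_q = testable.sum(axis=1)  # testable universe per query
        n_q = partners.sum(axis=1)  # differential degree per query

        T = testable.astype(np.float64)
        P = partners.astype(np.float64)
        K_obs = T @ member.T.astype(np.float64)  # queries x complexes
        k_obs = P @ member.T.astype(np.float64)
        p_obs = hypergeom_tail(k_obs, N_q[:, None], K_obs, n_q[:, None])
        p_obs = np.atleast_2d(p_obs)

        # permutations: one shuffle of the array-gene labels per iteration
        exceed = np.zeros_like(p_obs)  # mean permuted count with p <= p_obs
        for _ in range(n_perm):
            perm = rng.permutation(len(arrays))
            member_p = member[:, perm].astype(np.float64)
            K_p = T @ member_p.T
            k_p = P @ member_p.T
            p_perm = np.atleast_2d(hypergeom_tail(k_p, N_q[:, None], K_p, n_q[:, None]))
            # per query family: count permuted p <= each observed p
            exceed += (p_perm[:, None, :] <= p_obs[:, :, None]).sum(axis=2)
        exceed /= n_perm

        for qi, q in enumerate(queries):
            p_row = p_obs[qi]
            obs_counts = (p_row[None, :] <= p_row[:, None]).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                fdr_raw = np.clip(exceed[qi] / obs_counts, 0.0, 1.0)
            # monotone non-decreasing in p: reverse cumulative minimum
            order = np.argsort(p_row, kind="stable")
            fdr = np.empty_like(fdr_raw)
            running = 1.0
            for idx in order[::-1]:
                running = min(running, fdr_raw[idx])
                fdr[idx] = running
            for ci, name in enumerate(names):
                expected = n_q[qi] * K_obs[qi, ci] / N_q[qi] if N_q[qi] else 0.0
                records.append(
                    {
                        "condition": cond,
                        "query": q,
                        "complex": name,
                        "observed": int(k_obs[qi, ci]),
                        "expected": float(expected),
                        "fold": float(k_obs[qi, ci] / expected) if expected > 0 else float("nan"),
                        "p_value": float(p_row[ci]),
                        "fdr": float(fdr[ci]),
                        "significant": bool(fdr[ci] < thresholds.fdr_complex),
                        "universe_size": int(N_q[qi]),
                        "complex_size": int(K_obs[qi, ci]),
                        "degree": int(n_q[qi]),
                    }
                )
    return pd.DataFrame.from_records(records)


def complex_summary(associations: pd.DataFrame) -> pd.Series:
    """Per-complex total of significant (query, condition) associations,
    sorted descending — the ranking used to find stress-responsive complexes."""
    if associations.empty:
        return pd.Series(dtype=int)
    sig = associations[associations["significant"]]
    counts = sig.groupby("complex").size()
    return counts.sort_values(ascending=False, kind="stable")


def rank_queries(
    diff_nets: Mapping[str, InteractionNetwork]
) -> pd.DataFrame:
    """Per condition, differential degree and fraction of all differential
    interactions explained by each query, ranked descending (ties broken
    alphabetically)."""
    rows = []
    for cond, net in diff_nets.items():
        total = len(net)
        if total == 0:
            warnings.warn(f"{cond}: empty differential network; all fractions 0")
        degrees = net.degree_by_query()
        queries = sorted(degrees.index)
        ranked = sorted(queries, key=lambda q: (-degrees[q], q))
        for rank, q in enumerate(ranked, start=1):
            rows.append(
                {
                    "condition": cond,
                    "query": q,
                    "degree": int(degrees[q]),
                    "fraction": degrees[q] / total if total else 0.0,
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows, columns=["condition", "query", "degree", "fraction", "rank"])


def top_queries(ranking: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """The top-k most differentially interacting queries per condition."""
    return (
        ranking[ranking["rank"] <= k]
        .sort_values(["condition", "rank"], kind="stable")
        .reset_index(drop=True)
    )


def degree_fitness_correlation(
    degrees: Mapping[str, float],
    smf: Mapping[str, float],
    exclude: Iterable[str] = (),
) -> Tuple[float, int, float]:
    """Pearson correlation of differential degree with single-mutant fitness.

    Computed over genes present in both mappings, minus ``exclude`` (used to
    check whether a correlation is driven by a few dominant genes).  Returns
    (r, n, two-sided p from the t-distribution with n-2 df).
    """
    excl = {normalize_gene(g) for g in exclude}
    genes = sorted(
        (set(map(normalize_gene, degrees)) & set(map(normalize_gene, smf))) - excl
    )
    deg_norm = {normalize_gene(g): v for g, v in degrees.items()}
    smf_norm = {normalize_gene(g): v for g, v in smf.items()}
    if len(genes) < 3:
        raise ValueError("need at least 3 shared genes after exclusion")
    x = np.array([deg_norm[g] for g in genes], dtype=float)
    y = np.array([smf_norm[g] for g in genes], dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), len(genes), float(p)
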