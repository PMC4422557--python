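"""Core domain types shared by all pipeline stages.

A dE-MAP screen crosses a set of query gene deletions against an array of
deletions and scores each double mutant with a quantitative genetic-interaction
S-score, once per growth condition.  Exactly one condition is the unstressed
control; the remaining conditions are stresses whose score changes relative to
the control are the object of the analysis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "normalize_gene",
    "ScorePanel",
    "ThresholdConfig",
    "GeneSetCatalog",
    "PairSet",
    "InteractionNetwork",
]


def normalize_gene(name: str) -> str:
    """Canonical gene identifier: whitespace-stripped, uppercase.

    Both systematic (YLR113W) and standard (HOG1) names are accepted; the
    screen's own naming is preserved apart from case and whitespace.
    """
    return str(name).strip().upper()


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and cut-offs used across the pipeline.

    tau_static
        |S-score| at or above which a pair is a strong static interaction.
    tau_diff
        |z-score| at or above which a pair is a differential interaction.
    tau_diff_complex
        relaxed |z| threshold used only for gene-complex association, which
        trades per-pair stringency for per-complex counting power.
    fdr_complex
        permutation false-discovery-rate cut-off for reported associations.
    min_complex_size
        complexes represented on the array by fewer genes are not tested.
    min_diff_degree_gene
        minimum number of differential interactions for an array gene to be
        counted as "conditionally interacting" in gene-level overlap tests.
    """

    tau_static: float = 3.0
    tau_diff: float = 2.0
    tau_diff_complex: float = 1.7
    fdr_complex: float = 0.15
    min_complex_size: int = 4
    min_diff_degree_gene: int = 2

    def __post_init__(self) -> None:
        for name in ("tau_static", "tau_diff", "tau_diff_complex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.fdr_complex < 1.0:
            raise ValueError("fdr_complex must lie in (0, 1)")
        if self.min_complex_size < 1:
            raise ValueError("min_complex_size must be >= 1")
        if self.min_diff_degree_gene < 1:
            raise ValueError("min_diff_degree_gene must be >= 1")


class ScorePanel:
    """S-score tables for one screen panel, keyed by (condition, screen).

    Each table is a queries x arrays DataFrame of S-scores (NaN = missing).
    Exactly one condition label is flagged as the unstressed control.  Screens
    with overlapping queries are kept as separate tables and never silently
    averaged; any merging is an explicit pipeline step.
    """

    def __init__(
        self,
        queries: Iterable[str],
        arrays: Iterable[str],
        tables: Mapping[Tuple[str, str], pd.DataFrame],
        control: str,
    ) -> None:
        self.queries: List[str] = [normalize_gene(q) for q in queries]
        self.arrays: List[str] = [normalize_gene(a) for a in arrays]
        if len(set(self.queries)) != len(self.queries):
            raise ValueError("duplicate query gene identifiers")
        if len(set(self.arrays)) != len(self.arrays):
            raise ValueError("duplicate array gene identifiers")
        self.control = str(control)
        self.tables: Dict[Tuple[str, str], pd.DataFrame] = {}
        for (cond, screen), df in tables.items():
            df = df.reindex(index=self.queries, columns=self.arrays).astype(float)
            if df.shape != (len(self.queries), len(self.arrays)):
                raise ValueError("score table does not align with panel genes")
            df.index.name = None
            df.columns.name = None
            self.tables[(str(cond), str(screen))] = df
        if not any(cond == self.control for cond, _ in self.tables):
            raise ValueError(f"no table for control condition {self.control!r}")

    # -- structure ---------------------------------------------------------
    @property
    def conditions(self) -> List[str]:
        seen: List[str] = []
        for cond, _ in self.tables:
            if cond not in seen:
                seen.append(cond)
        return seen

    @property
    def stress_conditions(self) -> List[str]:
        return [c for c in self.conditions if c != self.control]

    @property
    def screens(self) -> List[str]:
        seen: List[str] = []
        for _, screen in self.tables:
            if screen not in seen:
                seen.append(screen)
        return seen

    def screens_for(self, condition: str) -> List[str]:
        return [s for c, s in self.tables if c == condition]

    def table(self, condition: str, screen: Optional[str] = None) -> pd.DataFrame:
        if screen is None:
            screens = self.screens_for(condition)
            if not screens:
                raise KeyError(f"condition {condition!r} not in panel")
            if len(screens) > 1:
                raise KeyError(
                    f"condition {condition!r} present in screens {screens}; "
                    "specify which"
                )
            screen = screens[0]
        try:
            return self.tables[(condition, screen)]
        except KeyError:
            raise KeyError(f"no table for condition {condition!r}, screen {screen!r}")

    def control_table(self, screen: Optional[str] = None) -> pd.DataFrame:
        return self.table(self.control, screen)

    def testable_mask(self, stress: str, screen: Optional[str] = None) -> pd.DataFrame:
        """Pairs with a non-missing score in both control and the stress."""
        return self.control_table(screen).notna() & self.table(stress, screen).notna()

    def n_measurements(self) -> int:
        """Total number of non-missing S-score measurements in the panel."""
        return int(sum(df.notna().to_numpy().sum() for df in self.tables.values()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ScorePanel({len(self.queries)} queries x {len(self.arrays)} arrays, "
            f"{len(self.tables)} tables, control={self.control!r})"
        )


class GeneSetCatalog:
    """Named gene sets (complexes, stress-sensitivity lists, regulatory sets).

    Members are de-duplicated and normalized to uppercase so membership tests
    are case-stable.  Each set carries a kind tag (``complex``, ``sensitivity``
    or ``regulatory``) and the catalog records a free-text provenance note.
    """

    KINDS = ("complex", "sensitivity", "regulatory")

    def __init__(self, provenance: str = "") -> None:
        self.sets: Dict[str, FrozenSet[str]] = {}
        self.kinds: Dict[str, str] = {}
        self.provenance = provenance

    def add(self, name: str, members: Iterable[str], kind: str = "complex") -> None:
        if kind not in self.KINDS:
            raise ValueError(f"unknown set kind {kind!r}")
        self.sets[name] = frozenset(normalize_gene(m) for m in members)
        self.kinds[name] = kind

    def __getitem__(self, name: str) -> FrozenSet[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self, kind: Optional[str] = None) -> List[str]:
        if kind is None:
            return list(self.sets)
        return [n for n, k in self.kinds.items() if k == kind]

    def restricted(self, universe: Iterable[str], min_size: int = 1) -> "GeneSetCatalog":
        """Catalog with members restricted to ``universe``; sets falling below
        ``min_size`` after restriction are dropped."""
        uni = {normalize_gene(g) for g in universe}
        out = GeneSetCatalog(self.provenance)
        for name, members in self.sets.items():
            kept = members & uni
            if len(kept) >= min_size:
                out.add(name, kept, self.kinds[name])
        return out


class PairSet:
    """An unordered set of gene pairs with symmetric membership.

    (a, b) and (b, a) are the same pair; self-pairs are rejected.
    """

    def __init__(self, pairs: Iterable[Tuple[str, str]] = ()) -> None:
        self._pairs: set = set()
        for a, b in pairs:
            self.add(a, b)

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        a, b = normalize_gene(a), normalize_gene(b)
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        a2, b2 = normalize_gene(a), normalize_gene(b)
        if a2 == b2:
            raise ValueError(f"self-pair ({a!r}, {b!r}) is not allowed")
        self._pairs.add(self._key(a, b))

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        a, b = pair
        return self._key(a, b) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(sorted(self._pairs))

    def restricted(self, universe: Iterable[str]) -> "PairSet":
        uni = {normalize_gene(g) for g in universe}
        out = PairSet()
        out._pairs = {p for p in self._pairs if p[0] in uni and p[1] in uni}
        return out


_EDGE_COLUMNS = ["query", "array", "score", "z", "sign"]


@dataclass
class InteractionNetwork:
    """A thresholded set of signed (query, array) interaction edges.

    ``mode`` is ``"static"`` (edges called on the S-score at tau_static) or
    ``"differential"`` (edges called on the z-score at tau_diff).  ``edges``
    holds one row per (query, array) edge with the score used for the call,
    its sign, and, for differential networks, the z value.
    """

    condition: str
    mode: str
    edges: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        if self.mode not in ("static", "differential"):
            raise ValueError(f"unknown network mode {self.mode!r}")
        df = pd.DataFrame(self.edges, columns=_EDGE_COLUMNS)
        if df.duplicated(subset=["query", "array"]).any():
            raise ValueError("duplicate (query, array) edges")
        self.edges = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def pairs(self) -> FrozenSet[Tuple[str, str]]:
        return frozenset(zip(self.edges["query"], self.edges["array"]))

    @property
    def signed_pairs(self) -> FrozenSet[Tuple[str, str, int]]:
        return frozenset(
            zip(self.edges["query"], self.edges["array"], self.edges["sign"])
        )

    def degree_by_query(self) -> pd.Series:
        return self.edges.groupby("query").size()

    def degree_by_array(self) -> pd.Series:
        return self.edges.groupby("array").size()
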