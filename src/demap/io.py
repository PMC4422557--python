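"""Readers and writers for screen score tables, gene sets and networks.

Formats are deliberately plain text:

* long score TSV with columns ``query, array, condition, screen, score``;
* matrix score TSV, one file per (condition, screen), queries as rows;
* GMT gene sets (name, description, tab-separated members);
* one-gene-per-line lists and two-column pair TSVs;
* network edge lists with columns ``query, array, condition, score, z, sign``.

Missing scores are written as empty fields; both empty fields and the literal
``NA`` are accepted on read.  Floats are written with 6 decimals, which is
lossless for S-scores as reported in practice (2-4 decimals).
"""
from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    GeneSetCatalog,
    InteractionNetwork,
    PairSet,
    ScorePanel,
    ThresholdConfig,
    normalize_gene,
)

__all__ = [
    "read_score_table",
    "read_panel_long",
    "write_panel_long",
    "assemble_panel",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_list",
    "read_pair_set",
    "write_network",
    "read_network",
    "load_config",
]

_NA_STRINGS = ("", "NA", "NaN", "nan")
FLOAT_FORMAT = "%.6f"

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed file structure (bad header, wrong field count)."""


class IntegrityError(ValueError):
    """Duplicate keys or inconsistent content."""


def _parse_score(text: str, path: PathLike, line_no: int) -> float:
    text = text.strip()
    if text in _NA_STRINGS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric score {text!r} at line {line_no}"
        ) from None


def read_score_table(
    path: PathLike,
    format: str = "long",
    condition: Optional[str] = None,
    screen: str = "S1",
) -> Dict[Tuple[str, str], pd.DataFrame]:
    """Read one score file into ``{(condition, screen): DataFrame}``.

    ``format="long"`` expects the 5-column long TSV and may contain several
    conditions/screens; ``format="matrix"`` expects array genes as columns and
    query genes as rows and requires ``condition`` (one table per file).
    Duplicate (query, array, condition, screen) entries raise IntegrityError.
    """
    path = Path(path)
    if format == "long":
        return _read_long(path)
    if format == "matrix":
        if condition is None:
            raise ValueError("matrix format requires an explicit condition label")
        return {(condition, screen): _read_matrix(path)}
    raise ValueError(f"unknown score table format {format!r}")


def _read_long(path: Path) -> Dict[Tuple[str, str], pd.DataFrame]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["query", "array", "condition", "screen", "score"]
        if [h.strip().lower() for h in header] != expected:
            raise FormatError(f"{path}: expected header {expected}, got {header}")
        rows: List[Tuple[str, str, str, str, float]] = []
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}: expected 5 fields at line {line_no}")
            q, a, cond, scr, score = fields
            rows.append(
                (
                    normalize_gene(q),
                    normalize_gene(a),
                    cond.strip(),
                    scr.strip(),
                    _parse_score(score, path, line_no),
                )
            )
    df = pd.DataFrame(rows, columns=["query", "array", "condition", "screen", "score"])
    dup = df.duplicated(subset=["query", "array", "condition", "screen"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate entry for (query={first['query']}, "
            f"array={first['array']}, condition={first['condition']}, "
            f"screen={first['screen']})"
        )
    out: Dict[Tuple[str, str], pd.DataFrame] = {}
    for (cond, scr), sub in df.groupby(["condition", "screen"], sort=False):
        out[(cond, scr)] = sub.pivot(index="query", columns="array", values="score")
    return out


def _read_matrix(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: matrix header needs at least one array gene")
        arrays = [normalize_gene(a) for a in header[1:]]
        queries: List[str] = []
        data: List[List[float]] = []
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}: row at line {line_no} has {len(fields)} fields, "
                    f"expected {len(header)}"
                )
            queries.append(normalize_gene(fields[0]))
            data.append([_parse_score(v, path, line_no) for v in fields[1:]])
    if len(set(queries)) != len(queries):
        raise IntegrityError(f"{path}: duplicate query gene row")
    return pd.DataFrame(data, index=queries, columns=arrays, dtype=float)


def assemble_panel(
    tables: Mapping[Tuple[str, str], pd.DataFrame], control: str
) -> ScorePanel:
    """Build a ScorePanel from table fragments, on the union of genes."""
    queries: List[str] = []
    arrays: List[str] = []
    for df in tables.values():
        for q in df.index:
            if q not in queries:
                queries.append(q)
        for a in df.columns:
            if a not in arrays:
                arrays.append(a)
    return ScorePanel(queries, arrays, tables, control)


def read_panel_long(path: PathLike, control: str) -> ScorePanel:
    """Read a long-format score TSV holding the full panel."""
    return assemble_panel(read_score_table(path, "long"), control)


def write_panel_long(panel: ScorePanel, path: PathLike) -> None:
    """Write the full panel as a long-format TSV (missing cells omitted)."""
    with open(path, "w") as fh:
        fh.write("query\tarray\tcondition\tscreen\tscore\n")
        for (cond, scr), df in panel.tables.items():
            values = df.to_numpy()
            for i, q in enumerate(df.index):
                for j, a in enumerate(df.columns):
                    v = values[i, j]
                    if np.isnan(v):
                        continue
                    fh.write(f"{q}\t{a}\t{cond}\t{scr}\t{FLOAT_FORMAT % v}\n")


def read_gene_sets(
    path: PathLike,
    kind: str = "complex",
    restrict_to: Optional[Iterable[str]] = None,
    min_size: int = 1,
) -> GeneSetCatalog:
    """Read a GMT-style gene-set file.

    Each line is ``name <TAB> description <TAB> member...``.  With
    ``restrict_to`` the members are intersected with the given gene universe
    (e.g. the array genes) and sets below ``min_size`` after restriction are
    dropped, matching the size floor used for complex testing.
    """
    path = Path(path)
    catalog = GeneSetCatalog(provenance=str(path))
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {line_no} has fewer than 2 fields"
                )
            name, _desc, *members = fields
            catalog.add(name.strip(), members, kind=kind)
    if restrict_to is not None:
        catalog = catalog.restricted(restrict_to, min_size=min_size)
    return catalog


def write_gene_sets(catalog: GeneSetCatalog, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name in catalog:
            members = "\t".join(sorted(catalog[name]))
            fh.write(f"{name}\t{catalog.kinds[name]}\t{members}\n")


def read_gene_list(path: PathLike) -> List[str]:
    """One gene per line; blank lines and ``#`` comments ignored."""
    genes: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(normalize_gene(line))
    return sorted(set(genes))


def read_pair_set(path: PathLike) -> PairSet:
    """Two-column TSV of unordered gene pairs (header optional)."""
    pairs = PairSet()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {line_no} needs two genes")
            if line_no == 1 and fields[0].lower() in ("genea", "gene_a", "a"):
                continue
            pairs.add(fields[0], fields[1])
    return pairs


def write_network(network: InteractionNetwork, path: PathLike, sif: bool = False) -> None:
    """Write a network as a TSV edge list (or SIF-like 3-column file).

    The TSV round-trips losslessly with :func:`read_network`; a missing z
    (static networks) is preserved as an empty field.
    """
    with open(path, "w") as fh:
        if sif:
            for row in network.edges.itertuples(index=False):
                rel = "pos" if row.sign > 0 else "neg"
                fh.write(f"{row.query}\t{rel}\t{row.array}\n")
            return
        fh.write("query\tarray\tcondition\tscore\tz\tsign\n")
        for row in network.edges.itertuples(index=False):
            score = "" if pd.isna(row.score) else FLOAT_FORMAT % row.score
            z = "" if pd.isna(row.z) else FLOAT_FORMAT % row.z
            fh.write(
                f"{row.query}\t{row.array}\t{network.condition}\t{score}\t{z}\t{row.sign:+d}\n"
            )


def read_network(path: PathLike, mode: str, threshold: float) -> InteractionNetwork:
    """Read an edge-list TSV written by :func:`write_network`."""
    path = Path(path)
    rows = []
    condition = ""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["query", "array", "condition", "score", "z", "sign"]:
            raise FormatError(f"{path}: unexpected network header {header}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            q, a, cond, score, z, sign = line.rstrip("\n").split("\t")
            condition = cond
            rows.append(
                (
                    normalize_gene(q),
                    normalize_gene(a),
                    _parse_score(score, path, line_no),
                    _parse_score(z, path, line_no),
                    int(sign),
                )
            )
    edges = pd.DataFrame(rows, columns=["query", "array", "score", "z", "sign"])
    return InteractionNetwork(condition=condition, mode=mode, edges=edges, threshold=threshold)


def load_config(path: PathLike) -> Tuple[ThresholdConfig, Dict]:
    """Load a YAML config; threshold keys feed ThresholdConfig, the rest
    (paths, window settings, seeds) are returned as a plain dict."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a key-value mapping")
    thr_fields = ThresholdConfig.__dataclass_fields__.keys()
    thr_kwargs = {k: raw[k] for k in thr_fields if k in raw}
    rest = {k: v for k, v in raw.items() if k not in thr_fields}
    return ThresholdConfig(**thr_kwargs), rest
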