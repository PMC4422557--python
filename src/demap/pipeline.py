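"""End-to-end pipeline orchestration and the run manifest.

``run_pipeline`` executes the stages in dependency order on a synthetic or
file-based screen: local moments -> z-scores -> networks -> overlaps ->
pair enrichment -> complex associations -> query ranking -> profile
correlations -> delta-correlation test -> summary.  Outputs are TSV edge
lists and score tables plus a machine-readable ``summary.json``; the manifest
records the config snapshot, seed, tool version and a digest per output so a
re-run with the same manifest is byte-reproducible.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .differential import call_network, compute_z_all, cross_condition_overlap, overlap_static_differential
from .enrichment import complex_association, complex_summary, rank_queries
from .io import write_gene_sets, write_network, write_panel_long
from .profiles import delta_corr_test, profile_corr
from .simulate import SimConfig, evaluate_calls, generate_screen
from .types import ScorePanel, ThresholdConfig

logger = logging.getLogger("demap")

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    version: str
    seed: int
    thresholds: Dict
    sim_config: Optional[Dict]
    outputs: Dict[str, Dict] = field(default_factory=dict)

    def record(self, path: Path, rows: int) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = {"rows": rows, "sha256": digest}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def run_pipeline(
    outdir,
    sim_config: Optional[SimConfig] = None,
    panel: Optional[ScorePanel] = None,
    thresholds: ThresholdConfig = ThresholdConfig(),
    window_size: Optional[int] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> RunManifest:
    """Run every stage on a synthetic (default) or supplied screen panel.

    Returns the manifest; all stage outputs are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        sim_config = sim_config or SimConfig(seed=seed)
        logger.info("simulating screen: %d x %d, seed %d",
                    sim_config.n_queries, sim_config.n_arrays, sim_config.seed)
        panel, catalog, truth = generate_screen(sim_config)
    else:
        catalog = truth = None

    manifest = RunManifest(
        version=__version__,
        seed=seed,
        thresholds=dataclasses.asdict(thresholds),
        sim_config=dataclasses.asdict(sim_config) if sim_config else None,
    )
    summary: Dict = {"version": __version__, "seed": seed,
                     "thresholds": dataclasses.asdict(thresholds),
                     "n_measurements": panel.n_measurements()}

    panel_path = outdir / "scores_long.tsv"
    write_panel_long(panel, panel_path)
    manifest.record(panel_path, panel.n_measurements())
    if catalog is not None:
        sets_path = outdir / "complexes.gmt"
        write_gene_sets(catalog, sets_path)
        manifest.record(sets_path, len(catalog))

    logger.info("thresholds: static |S|>=%.3g, differential |z|>=%.3g, "
                "complex |z|>=%.3g, FDR<%.3g",
                thresholds.tau_static, thresholds.tau_diff,
                thresholds.tau_diff_complex, thresholds.fdr_complex)

    # z-scores and networks (first screen of each condition)
    diff_tables = compute_z_all(panel, window_size=window_size)
    screen0 = panel.screens[0]
    diff_nets = {}
    static_nets = {}
    overlap: Dict[str, float] = {}
    for (cond, screen), table in diff_tables.items():
        if screen != screen0:
            continue
        dnet = call_network(table, "differential", thresholds)
        snet = call_network(panel.table(cond, screen), "static", thresholds, condition=cond)
        diff_nets[cond] = dnet
        static_nets[cond] = snet
        overlap[cond] = overlap_static_differential(dnet, snet)
        for net, tag in ((dnet, "differential"), (snet, "static")):
            path = outdir / f"network_{tag}_{cond}.tsv"
            write_network(net, path)
            manifest.record(path, len(net))
    summary["network_sizes"] = {
        c: {"differential": len(diff_nets[c]), "static": len(static_nets[c])}
        for c in diff_nets
    }
    summary["static_differential_overlap"] = overlap
    if len(diff_nets) >= 2:
        venn = cross_condition_overlap(diff_nets)
        summary["cross_condition_overlap"] = {
            "+".join(sorted(k)): v for k, v in venn.items()
        }

    # query ranking
    ranking = rank_queries(diff_nets)
    rank_path = outdir / "query_ranking.tsv"
    ranking.to_csv(rank_path, sep="\t", index=False, float_format="%.6f")
    manifest.record(rank_path, len(ranking))
    summary["top_queries"] = {
        cond: ranking[ranking["condition"] == cond].nsmallest(5, "rank")["query"].tolist()
        for cond in diff_nets
    }

    # complex associations
    if catalog is not None and len(catalog):
        first_screen_tables = {
            cond: t for (cond, screen), t in diff_tables.items() if screen == screen0
        }
        assoc = complex_association(
            first_screen_tables, catalog, thresholds, n_perm=n_perm, seed=seed
        )
        assoc_path = outdir / "complex_associations.tsv"
        assoc.to_csv(assoc_path, sep="\t", index=False, float_format="%.6g")
        manifest.record(assoc_path, len(assoc))
        summary["significant_associations"] = int(assoc["significant"].sum()) if len(assoc) else 0
        summary["complex_ranking"] = complex_summary(assoc).to_dict()
        if truth is not None:
            planted = {(c, q, x) for c, q, x in truth.associations}
            hit = sum(
                1
                for row in assoc[assoc["significant"]].itertuples(index=False)
                if (row.condition, row.query, row.complex) in planted
            )
            summary["association_recall"] = hit / len(planted) if planted else None

    # profile correlations and the rewiring test
    if truth is not None and truth.rewired_pair is not None:
        stress = truth.rewired_stress
        corr_ctrl = profile_corr(panel, panel.control, screen0)
        corr_stress = profile_corr(panel, stress, screen0)
        ga = truth.modules[truth.rewired_pair[0]]
        gb = truth.modules[truth.rewired_pair[1]]
        res = delta_corr_test(corr_stress, corr_ctrl, ga, gb)
        summary["rewired_module_test"] = {
            "stress": stress,
            "mean_delta_r_cross": res.mean_cross,
            "mean_delta_r_background": res.mean_background,
            "p_value": res.p_value,
        }

    # planted differential recovery
    if truth is not None:
        per_cond = {}
        for cond, net in diff_nets.items():
            mask = panel.testable_mask(cond, screen0)
            qi, ai = mask.to_numpy().nonzero()
            testable = set(zip(mask.index[qi], mask.columns[ai]))
            tp = truth.differential_pairs(cond)
            if tp:
                sens, fpr, prec = evaluate_calls(tp, net, testable)
                per_cond[cond] = {"sensitivity": sens, "fpr": fpr, "precision": prec}
        summary["planted_recovery"] = per_cond

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.record(summary_path, len(summary))
    manifest.write(outdir / "manifest.json")
    logger.info("pipeline complete: %d outputs under %s", len(manifest.outputs), outdir)
    return manifest
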