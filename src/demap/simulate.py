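"""Seeded synthetic dE-MAP screens with planted ground truth.

The generator emulates the structure of a MAPK stress-response screen: a
control condition plus five stresses over ~49 query x ~1,200 array double
mutants, S-score measurement noise whose standard deviation grows with the
interaction magnitude (sd = sd0 + slope*|S|^gamma, capped at sd_max), a
sparse backbone of strong static interactions, protein complexes whose
members share a few strong query interactions (hence correlated profiles),
correlated query modules, and four kinds of planted condition-specific
signal:

* scattered differential pairs whose stress score is shifted by a multiple of
  the local noise sd;
* query-complex associations: a query whose shifted partners concentrate
  inside one complex at a configurable multiple of the background
  differential-call rate;
* a rewired query-module pair: under one stress, two query modules acquire a
  shared interaction signature, raising their cross-group profile
  correlations;
* a matched null module pair that does not rewire (negative control).

Everything is deterministic given the seed.  Simulation operates at the
S-score level; ``collapse_colony_replicates`` offers an optional toy layer
that turns replicate pseudo-colony sizes into a score via a simple modified
t-statistic (a deliberately minimal stand-in, not a full colony-image
scoring method).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSetCatalog, InteractionNetwork, ScorePanel

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_screen",
    "evaluate_calls",
    "collapse_colony_replicates",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the synthetic screen.

    The noise model min(sd0 + slope*|S|^gamma, sd_max) applies to every
    measurement, with |S| the latent strength of the measured interaction
    (planted shift included for stress measurements).  ``n_diff_pairs``
    scattered differential shifts of ``diff_shift_range`` x the pair's own
    noise sd are planted per stress; ``n_assoc`` query-complex associations concentrate
    shifts inside large complexes at ``assoc_concentration`` times the
    background differential-call rate at the association threshold.
    """

    n_queries: int = 49
    n_arrays: int = 1200
    control: str = "UT"
    stresses: Tuple[str, ...] = ("SO", "OX", "ZY", "CR", "CA")
    n_screens: int = 1

    # static interaction backbone
    interaction_density: float = 0.05
    interaction_scale: Tuple[float, float] = (3.0, 8.0)

    # measurement noise: sd = min(sd0 + slope * |S|^gamma, sd_max)
    noise_sd0: float = 1.0
    noise_slope: float = 0.25
    noise_gamma: float = 1.0
    noise_sd_max: float = 3.0

    # scattered planted differential pairs (per stress)
    n_diff_pairs: int = 200
    diff_shift_range: Tuple[float, float] = (4.0, 10.0)

    # planted complexes (array side) and query-complex associations
    n_complexes: int = 15
    complex_size_range: Tuple[int, int] = (4, 20)
    complex_shared_queries: int = 3
    complex_shared_jitter: float = 0.5
    n_assoc: int = 10
    assoc_complex_size_range: Tuple[int, int] = (25, 30)
    assoc_concentration: float = 5.0
    assoc_threshold: float = 1.7  # |z| threshold defining the background rate

    # query modules and stress rewiring (profile-correlation signal)
    n_modules: int = 4
    module_size: int = 4
    module_signal: float = 0.6
    rewired_stress: str = "ZY"
    rewire_strength: float = 1.2

    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("interaction_density", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_queries < 1 or self.n_arrays < 1:
            raise ValueError("panel dimensions must be positive")
        if self.noise_sd0 <= 0:
            raise ValueError("noise_sd0 must be positive")
        if self.n_modules * self.module_size > self.n_queries:
            raise ValueError("query modules exceed the number of queries")
        need = (
            self.n_assoc * self.assoc_complex_size_range[1]
            + max(self.n_complexes - self.n_assoc, 0) * self.complex_size_range[1]
        )
        if need > self.n_arrays:
            raise ValueError("planted complexes exceed the array size")
        if self.rewired_stress not in self.stresses and self.n_modules >= 2:
            raise ValueError(f"rewired_stress {self.rewired_stress!r} not a stress")

    def noise_sd(self, magnitude) -> np.ndarray:
        raw = self.noise_sd0 + self.noise_slope * np.abs(magnitude) ** self.noise_gamma
        return np.minimum(raw, self.noise_sd_max)

    @property
    def background_call_rate(self) -> float:
        """Expected per-pair differential-call rate at the association
        threshold for a query with no planted association: the two-sided
        Gaussian null tail plus the scattered planted-pair rate."""
        null_tail = 2.0 * stats.norm.sf(self.assoc_threshold)
        scattered = self.n_diff_pairs / (self.n_queries * self.n_arrays)
        return float(null_tail + scattered)


@dataclass
class GroundTruth:
    """Planted signal, recorded for downstream evaluation."""

    diff_pairs: pd.DataFrame  # condition, query, array, shift, local_sd
    complexes: Dict[str, List[str]]
    associations: List[Tuple[str, str, str]]  # (condition, query, complex)
    assoc_pairs: pd.DataFrame  # condition, query, array, shift, complex
    modules: Dict[str, List[str]]
    rewired_pair: Optional[Tuple[str, str]]
    null_pair: Optional[Tuple[str, str]]
    rewired_stress: str
    latent: Optional[np.ndarray] = None  # queries x arrays latent interaction strengths

    def differential_pairs(self, condition: str, include_assoc: bool = True):
        """Set of planted differential (query, array) pairs for a condition."""
        pairs = set(
            zip(
                self.diff_pairs.loc[self.diff_pairs["condition"] == condition, "query"],
                self.diff_pairs.loc[self.diff_pairs["condition"] == condition, "array"],
            )
        )
        if include_assoc and not self.assoc_pairs.empty:
            sel = self.assoc_pairs["condition"] == condition
            pairs |= set(
                zip(self.assoc_pairs.loc[sel, "query"], self.assoc_pairs.loc[sel, "array"])
            )
        return pairs


def _draw_shifts(
    rng, cfg: "SimConfig", latent: np.ndarray, lo: float, hi: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Planted shifts of (lo..hi) x the pair's own measurement noise sd.

    The noise applies to the shifted stress score, so the magnitude solves
    |shift| = multiple * noise_sd(latent + shift) by fixed-point iteration
    (convergent because the noise curve is capped at noise_sd_max).  Returns
    (shift, local_sd) with local_sd the noise sd of the shifted measurement.
    """
    latent = np.asarray(latent, dtype=float)
    mult = rng.uniform(lo, hi, size=latent.shape)
    sign = rng.choice([-1.0, 1.0], size=latent.shape)
    mag = mult * cfg.noise_sd(latent)
    for _ in range(50):
        mag = mult * cfg.noise_sd(latent + sign * mag)
    local_sd = cfg.noise_sd(latent + sign * mag)
    return sign * mag, local_sd


def generate_screen(config: SimConfig) -> Tuple[ScorePanel, GeneSetCatalog, GroundTruth]:
    """Generate a seeded synthetic screen with planted ground truth."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    nq, na = cfg.n_queries, cfg.n_arrays
    queries = [f"Q{i + 1:03d}" for i in range(nq)]
    arrays = [f"A{j + 1:04d}" for j in range(na)]

    # --- latent interaction backbone -------------------------------------
    latent = np.zeros((nq, na))
    hit = rng.random((nq, na)) < cfg.interaction_density
    lo, hi = cfg.interaction_scale
    latent[hit] = rng.choice([-1.0, 1.0], size=int(hit.sum())) * rng.uniform(
        lo, hi, size=int(hit.sum())
    )

    # --- planted complexes (array side) -----------------------------------
    order = rng.permutation(na)
    complexes: Dict[str, List[str]] = {}
    cursor = 0
    sizes: List[int] = []
    for i in range(cfg.n_complexes):
        if i < cfg.n_assoc:
            s_lo, s_hi = cfg.assoc_complex_size_range
        else:
            s_lo, s_hi = cfg.complex_size_range
        sizes.append(int(rng.integers(s_lo, s_hi + 1)))
    for i, size in enumerate(sizes):
        members_idx = order[cursor:cursor + size]
        cursor += size
        name = f"CPX{i + 1:02d}"
        complexes[name] = sorted(arrays[j] for j in members_idx)
        # members share a few strong query interactions (with per-member
        # jitter), which is what correlates complex-member profiles in
        # real screens
        if cfg.complex_shared_queries:
            shared_q = rng.choice(nq, size=min(cfg.complex_shared_queries, nq), replace=False)
            lo_i, hi_i = cfg.interaction_scale
            for q in shared_q:
                v = rng.choice([-1.0, 1.0]) * rng.uniform(lo_i, hi_i)
                latent[q, members_idx] += v + rng.normal(
                    0.0, cfg.complex_shared_jitter, size=len(members_idx)
                )

    catalog = GeneSetCatalog(provenance="synthetic planted complexes")
    for name, members in complexes.items():
        catalog.add(name, members, kind="complex")

    # --- query modules (correlated profiles) ------------------------------
    q_order = rng.permutation(nq)
    modules: Dict[str, List[str]] = {}
    for m in range(cfg.n_modules):
        idx = q_order[m * cfg.module_size:(m + 1) * cfg.module_size]
        modules[f"M{m}"] = sorted(queries[i] for i in idx)
        g = rng.normal(0.0, 1.0, size=na)
        latent[idx, :] += cfg.module_signal * g[None, :]

    rewired_pair = ("M0", "M1") if cfg.n_modules >= 2 else None
    null_pair = ("M2", "M3") if cfg.n_modules >= 4 else None

    # --- planted differential shifts per stress ---------------------------
    q_index = {q: i for i, q in enumerate(queries)}
    a_index = {a: j for j, a in enumerate(arrays)}
    shift_mats: Dict[str, np.ndarray] = {s: np.zeros((nq, na)) for s in cfg.stresses}
    diff_records: List[Dict] = []
    lo_s, hi_s = cfg.diff_shift_range
    for stress in cfg.stresses:
        if cfg.n_diff_pairs:
            flat = rng.choice(nq * na, size=cfg.n_diff_pairs, replace=False)
            qi, ai = np.unravel_index(flat, (nq, na))
            shifts, local_sd = _draw_shifts(rng, cfg, latent[qi, ai], lo_s, hi_s)
            shift_mats[stress][qi, ai] += shifts
            for q, a, sh, sd in zip(qi, ai, shifts, local_sd):
                diff_records.append(
                    {
                        "condition": stress,
                        "query": queries[q],
                        "array": arrays[a],
                        "shift": float(sh),
                        "local_sd": float(sd),
                    }
                )

    # --- planted query-complex associations --------------------------------
    assoc: List[Tuple[str, str, str]] = []
    assoc_records: List[Dict] = []
    if cfg.n_assoc:
        p_in = min(1.0, cfg.assoc_concentration * cfg.background_call_rate)
        assoc_complexes = [f"CPX{i + 1:02d}" for i in range(cfg.n_assoc)]
        assoc_queries = rng.choice(nq, size=cfg.n_assoc, replace=False)
        for k, (cname, qi) in enumerate(zip(assoc_complexes, assoc_queries)):
            stress = cfg.stresses[k % len(cfg.stresses)]
            assoc.append((stress, queries[qi], cname))
            for a in complexes[cname]:
                if rng.random() < p_in:
                    aj = a_index[a]
                    sh_arr, _sd_arr = _draw_shifts(
                        rng, cfg, np.atleast_1d(latent[qi, aj]), lo_s, hi_s
                    )
                    sh = float(sh_arr[0])
                    shift_mats[stress][qi, aj] += sh
                    assoc_records.append(
                        {
                            "condition": stress,
                            "query": queries[qi],
                            "array": a,
                            "shift": sh,
                            "complex": cname,
                        }
                    )

    # --- stress rewiring of a module pair ----------------------------------
    rewire_add = np.zeros((nq, na))
    if rewired_pair is not None and cfg.rewire_strength > 0:
        h_rw = rng.normal(0.0, 1.0, size=na)
        rew_idx = [q_index[q] for m in rewired_pair for q in modules[m]]
        rewire_add[rew_idx, :] = cfg.rewire_strength * h_rw[None, :]

    # --- emit score tables --------------------------------------------------
    tables: Dict[Tuple[str, str], pd.DataFrame] = {}
    for s in range(cfg.n_screens):
        screen = f"S{s + 1}"
        for cond in (cfg.control,) + cfg.stresses:
            if cond == cfg.control:
                signal = latent
            else:
                signal = latent + shift_mats[cond]
                if cond == cfg.rewired_stress:
                    signal = signal + rewire_add
            noise = rng.normal(0.0, 1.0, size=(nq, na)) * cfg.noise_sd(signal)
            scores = signal + noise
            if cfg.missing_rate > 0:
                miss = rng.random((nq, na)) < cfg.missing_rate
                scores = np.where(miss, np.nan, scores)
            tables[(cond, screen)] = pd.DataFrame(scores, index=queries, columns=arrays)

    panel = ScorePanel(queries, arrays, tables, control=cfg.control)
    truth = GroundTruth(
        diff_pairs=pd.DataFrame(
            diff_records, columns=["condition", "query", "array", "shift", "local_sd"]
        ),
        complexes=complexes,
        associations=assoc,
        assoc_pairs=pd.DataFrame(
            assoc_records, columns=["condition", "query", "array", "shift", "complex"]
        ),
        modules=modules,
        rewired_pair=rewired_pair,
        null_pair=null_pair,
        rewired_stress=cfg.rewired_stress,
        latent=latent,
    )
    return panel, catalog, truth


def evaluate_calls(
    truth_pairs,
    calls: InteractionNetwork,
    testable_pairs,
) -> Tuple[float, float, float]:
    """Confusion metrics of network calls against planted truth.

    All three quantities are computed over the testable (measured) pair
    universe: sensitivity = recalled fraction of testable true pairs, false
    positive rate = called fraction of testable non-true pairs, precision =
    true fraction of calls.
    """
    testable = set(testable_pairs)
    truth = set(truth_pairs) & testable
    called = calls.pairs & testable
    tp = len(called & truth)
    sensitivity = tp / len(truth) if truth else float("nan")
    negatives = len(testable) - len(truth)
    fpr = (len(called) - tp) / negatives if negatives else float("nan")
    precision = tp / len(called) if called else float("nan")
    return sensitivity, fpr, precision


def collapse_colony_replicates(
    case: Sequence[float],
    reference: Sequence[float],
    sd_floor: float = 1e-6,
) -> float:
    """Collapse replicate pseudo-colony sizes into a score via a simple
    modified t-statistic: the mean difference over a variance-floored pooled
    standard error.  A deliberately minimal toy scorer for simulated colony
    sizes — not a replacement for a full colony-scoring pipeline.
    """
    case = np.asarray(case, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if case.size < 2 or reference.size < 2:
        raise ValueError("need at least two replicates per group")
    var = (np.var(case, ddof=1) / case.size) + (np.var(reference, ddof=1) / reference.size)
    se = max(np.sqrt(var), sd_floor)
    return float((case.mean() - reference.mean()) / se)
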