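"""Differential interaction scoring.

The screen's measurement noise is not constant: the spread of S-scores grows
with the magnitude of the underlying interaction.  A stress score is therefore
judged against a *local* null learned from the control condition.  Gene pairs
are ranked by their control score S_control and, inside a sliding window of
fixed size over that ranking, the mean and standard deviation of the paired
stress scores estimate the conditional moments

    mu(S_control) = E[S_stress | S_control],
    sigma(S_control) = sd[S_stress | S_control],

as non-parametric (piecewise-constant) functions of S_control.  The
differential z-score of a pair is then

    z = (S_stress - mu(S_control)) / sigma(S_control),

approximately standard normal for pairs whose interaction does not change with
the stress.  |z| >= 2 defines differential (conditional) interactions;
|S| >= 3 defines strong static interactions.

``fit_local_moments`` can also be run on the control scores alone
(``stress=None``), in which case the window moments describe the control score
distribution itself; that degenerate mode is occasionally useful for
inspecting the magnitude-dependence of the control spread, but z-scoring
always uses the paired (conditional) moments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import InteractionNetwork, ScorePanel, ThresholdConfig

__all__ = [
    "LocalMoments",
    "DifferentialTable",
    "default_window_size",
    "fit_local_moments",
    "compute_z",
    "call_network",
    "overlap_static_differential",
    "cross_condition_overlap",
    "replicate_reproducibility",
    "group_score_medians",
]


def default_window_size(n: int) -> int:
    """Window = max(50, 2.5% of the control observations), clamped to n.

    Large enough for a stable standard-deviation estimate, small enough to
    track the non-linear magnitude dependence of the noise.
    """
    return min(n, max(50, round(0.025 * n)))


@dataclass
class LocalMoments:
    """Sliding-window null moments, evaluable at any finite control score.

    ``sorted_control`` holds the control scores in ascending order; ``mu`` and
    ``sigma`` give the window moments for the window centred (with clamping at
    the ends) on each sorted position.  Evaluation at an arbitrary score s
    uses the window of the rank position where s would be inserted, so mu and
    sigma are defined for every finite s and piecewise constant between
    control values.
    """

    sorted_control: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    window_size: int
    sigma_floor: float

    def _index(self, s) -> np.ndarray:
        idx = np.searchsorted(self.sorted_control, np.asarray(s, dtype=float), side="left")
        return np.clip(idx, 0, len(self.sorted_control) - 1)

    def __call__(self, s) -> Tuple[np.ndarray, np.ndarray]:
        idx = self._index(s)
        return self.mu[idx], self.sigma[idx]

    def mu_at(self, s) -> np.ndarray:
        return self.mu[self._index(s)]

    def sigma_at(self, s) -> np.ndarray:
        return self.sigma[self._index(s)]


def fit_local_moments(
    control: Sequence[float],
    stress: Optional[Sequence[float]] = None,
    window_size: Optional[int] = None,
    sigma_floor: Optional[float] = None,
) -> LocalMoments:
    """Fit sliding-window moments over pairs ranked by control score.

    With ``stress`` given (the normal case for z-scoring), each window
    collects the ``window_size`` pairs nearest in control-score rank and the
    moments are the mean and sample sd of their *stress* scores.  Without
    ``stress``, the moments are taken over the control scores themselves.

    Windows are clamped at the ends of the ranking so every window has exactly
    ``window_size`` members.  ``sigma`` is floored at ``sigma_floor`` (default
    10% of the global sd of the windowed variable) so flat windows cannot
    produce divide-by-zero z-scores.
    """
    control = np.asarray(control, dtype=float).ravel()
    if stress is not None:
        stress = np.asarray(stress, dtype=float).ravel()
        if stress.shape != control.shape:
            raise ValueError("control and stress score vectors must align")
        keep = np.isfinite(control) & np.isfinite(stress)
        control, stress = control[keep], stress[keep]
    else:
        control = control[np.isfinite(control)]
    n = control.size
    if window_size is None:
        window_size = default_window_size(n)
    if window_size < 3:
        raise ValueError("window_size must be >= 3")
    if n < window_size:
        raise ValueError(
            f"need at least window_size={window_size} non-missing control scores, got {n}"
        )

    order = np.argsort(control, kind="stable")
    cs = control[order]
    target = stress[order] if stress is not None else cs

    w = window_size
    # rolling mean/sd over all length-w windows via cumulative sums
    csum = np.concatenate(([0.0], np.cumsum(target)))
    csum2 = np.concatenate(([0.0], np.cumsum(target**2)))
    win_sum = csum[w:] - csum[:-w]
    win_sum2 = csum2[w:] - csum2[:-w]
    win_mean = win_sum / w
    win_var = np.maximum(win_sum2 - w * win_mean**2, 0.0) / (w - 1)
    win_sd = np.sqrt(win_var)

    if sigma_floor is None:
        global_sd = float(np.std(target, ddof=1)) if n > 1 else 0.0
        sigma_floor = 0.1 * global_sd if global_sd > 0 else 1e-12

    starts = np.clip(np.arange(n) - w // 2, 0, n - w)
    return LocalMoments(
        sorted_control=cs,
        mu=win_mean[starts],
        sigma=np.maximum(win_sd[starts], sigma_floor),
        window_size=w,
        sigma_floor=float(sigma_floor),
    )


@dataclass
class DifferentialTable:
    """Differential z-scores for one (stress condition, screen), aligned to
    the panel; NaN where either the control or the stress score is missing."""

    condition: str
    screen: str
    z: pd.DataFrame
    moments: Optional[LocalMoments] = None


def compute_z(
    panel: ScorePanel,
    stress: str,
    screen: Optional[str] = None,
    moments: Optional[LocalMoments] = None,
    window_size: Optional[int] = None,
    sigma_floor: Optional[float] = None,
) -> DifferentialTable:
    """z = (S_stress - mu(S_control)) / sigma(S_control) for testable pairs.

    Moments are fitted from this screen's own control/stress score pairs
    unless a pre-fitted ``LocalMoments`` is supplied (the two screens of a
    panel had separate control platings, so moments are never pooled across
    screens).
    """
    if stress not in panel.conditions:
        raise KeyError(f"condition {stress!r} not in panel")
    if screen is None:
        screens = panel.screens_for(stress)
        if len(screens) > 1:
            raise KeyError(f"{stress!r} present in screens {screens}; specify which")
        screen = screens[0]
    ctrl = panel.control_table(screen).to_numpy()
    st = panel.table(stress, screen).to_numpy()
    mask = np.isfinite(ctrl) & np.isfinite(st)
    if moments is None:
        moments = fit_local_moments(
            ctrl[mask], st[mask], window_size=window_size, sigma_floor=sigma_floor
        )
    z = np.full(ctrl.shape, np.nan)
    mu, sigma = moments(ctrl[mask])
    z[mask] = (st[mask] - mu) / sigma
    zdf = pd.DataFrame(z, index=panel.queries, columns=panel.arrays)
    return DifferentialTable(condition=stress, screen=screen, z=zdf, moments=moments)


def compute_z_all(
    panel: ScorePanel,
    window_size: Optional[int] = None,
    sigma_floor: Optional[float] = None,
) -> Dict[Tuple[str, str], DifferentialTable]:
    """Differential tables for every (stress condition, screen) in the panel."""
    out: Dict[Tuple[str, str], DifferentialTable] = {}
    for cond, screen in panel.tables:
        if cond == panel.control:
            continue
        if (panel.control, screen) not in panel.tables:
            continue
        out[(cond, screen)] = compute_z(
            panel, cond, screen, window_size=window_size, sigma_floor=sigma_floor
        )
    return out


def call_network(
    scores: Union[pd.DataFrame, DifferentialTable],
    mode: str,
    thresholds: ThresholdConfig = ThresholdConfig(),
    condition: Optional[str] = None,
    threshold: Optional[float] = None,
) -> InteractionNetwork:
    """Call edges at |score| >= threshold (boundary inclusive); sign = sign(score).

    ``mode="static"`` thresholds an S-score matrix at tau_static;
    ``mode="differential"`` thresholds a z matrix (or DifferentialTable) at
    tau_diff.  An explicit ``threshold`` overrides the config (used e.g. for
    the relaxed complex-association calls at tau_diff_complex).
    """
    if isinstance(scores, DifferentialTable):
        if condition is None:
            condition = scores.condition
        scores = scores.z
    if condition is None:
        raise ValueError("condition label required when passing a bare matrix")
    if threshold is None:
        threshold = thresholds.tau_static if mode == "static" else thresholds.tau_diff
    values = scores.to_numpy()
    qi, ai = np.nonzero(np.abs(values) >= threshold)
    vals = values[qi, ai]
    edges = pd.DataFrame(
        {
            "query": np.asarray(scores.index)[qi],
            "array": np.asarray(scores.columns)[ai],
            "score": vals,
            "z": vals if mode == "differential" else np.nan,
            "sign": np.where(vals > 0, 1, -1).astype(int),
        }
    )
    return InteractionNetwork(condition=condition, mode=mode, edges=edges, threshold=float(threshold))


def overlap_static_differential(
    diff_net: InteractionNetwork,
    static_net: InteractionNetwork,
    sign_matched: bool = False,
) -> float:
    """Fraction of differential pairs also present in the static network.

    Pair identity is sign-agnostic by default; ``sign_matched=True`` requires
    the interaction sign to agree as well.  Returns 0 (with a warning) for an
    empty differential network.
    """
    if len(diff_net) == 0:
        warnings.warn("empty differential network; overlap fraction set to 0")
        return 0.0
    if sign_matched:
        inter = diff_net.signed_pairs & static_net.signed_pairs
    else:
        inter = diff_net.pairs & static_net.pairs
    return len(inter) / len(diff_net)


def cross_condition_overlap(
    diff_nets: Mapping[str, InteractionNetwork]
) -> Dict[FrozenSet[str], int]:
    """Venn-style counts: for every non-empty subset of conditions, the number
    of (query, array) pairs differential in exactly that subset."""
    if len(diff_nets) < 2:
        raise ValueError("need at least two networks")
    membership: Dict[Tuple[str, str], set] = {}
    for cond, net in diff_nets.items():
        for pair in net.pairs:
            membership.setdefault(pair, set()).add(cond)
    counts: Dict[FrozenSet[str], int] = {}
    for conds in membership.values():
        key = frozenset(conds)
        counts[key] = counts.get(key, 0) + 1
    return counts


def replicate_reproducibility(
    net1: InteractionNetwork,
    net2: InteractionNetwork,
    scores2: pd.DataFrame,
    threshold: Optional[float] = None,
) -> Tuple[float, float]:
    """Cross-replicate agreement of interaction calls.

    Returns ``(fraction_redetected, r_shared)``: the fraction of ``net1``
    edges whose replicate score in ``scores2`` passes the same threshold, and
    the Pearson correlation of scores over pairs called in *both* replicate
    networks.  Comparison is restricted to the shared (query, array) universe,
    i.e. pairs measured (non-missing) in the replicate.
    """
    if threshold is None:
        threshold = net1.threshold
    notna = scores2.notna().to_numpy()
    qi, ai = np.nonzero(notna)
    shared = set(zip(np.asarray(scores2.index)[qi], np.asarray(scores2.columns)[ai]))
    if not shared:
        raise ValueError("no shared (query, array) universe between replicates")
    edges1 = [
        (row.query, row.array, row.score)
        for row in net1.edges.itertuples(index=False)
        if (row.query, row.array) in shared
    ]
    if not edges1:
        raise ValueError("no net1 edges inside the shared universe")
    redetected = [
        abs(scores2.at[q, a]) >= threshold for q, a, _ in edges1
    ]
    fraction = float(np.mean(redetected))

    both = sorted(net1.pairs & net2.pairs & shared)
    if len(both) >= 3:
        score1 = {(r.query, r.array): r.score for r in net1.edges.itertuples(index=False)}
        s1 = [score1[p] for p in both]
        s2 = [scores2.at[q, a] for q, a in both]
        r_shared = float(stats.pearsonr(s1, s2)[0])
    else:
        r_shared = float("nan")
    return fraction, r_shared


def group_score_medians(
    values: Sequence[float],
    labels: Sequence,
    classes: Optional[Sequence] = None,
) -> Dict:
    """Median score per (ordinal) class label.

    Used e.g. to summarize differential z-scores within qualitative phenotype
    groups.  Even-sized classes use the midpoint of the two central values;
    classes named in ``classes`` but holding no values get NaN with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape != labels.shape:
        raise ValueError("every value must carry a label")
    if classes is None:
        classes = list(dict.fromkeys(labels.tolist()))
    out: Dict = {}
    for cls in classes:
        sel = values[labels == cls]
        if sel.size == 0:
            warnings.warn(f"class {cls!r} is empty; median undefined")
            out[cls] = float("nan")
        else:
            out[cls] = float(np.median(sel))
    return out
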