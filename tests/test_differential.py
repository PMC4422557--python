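"""Sliding-window null moments, z-scores, network calling and overlaps."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from demap import (
    ThresholdConfig,
    call_network,
    compute_z,
    cross_condition_overlap,
    fit_local_moments,
    group_score_medians,
    overlap_static_differential,
    replicate_reproducibility,
)
from demap.differential import DifferentialTable, default_window_size

from conftest import make_panel


def brute_force_moments(control, target, w, floor, probe):
    """Independent re-sort-and-window evaluation of the sliding-window rule."""
    order = np.argsort(control, kind="stable")
    cs = np.asarray(control, dtype=float)[order]
    ts = np.asarray(target, dtype=float)[order]
    n = len(cs)
    idx = int(np.searchsorted(cs, probe, side="left"))
    idx = min(max(idx, 0), n - 1)
    start = min(max(idx - w // 2, 0), n - w)
    window = ts[start:start + w]
    return float(np.mean(window)), max(float(np.std(window, ddof=1)), floor)


class TestLocalMoments:
    def test_degenerate_identical_scores_floor_sigma(self):
        m = fit_local_moments([1.0, 1.0, 1.0, 1.0], window_size=4, sigma_floor=0.2)
        for probe in (-5.0, 1.0, 7.0):
            assert m.mu_at(probe) == 1.0
            assert m.sigma_at(probe) == 0.2

    def test_full_window_equals_global_moments(self, rng):
        x = rng.normal(size=40)
        m = fit_local_moments(x, window_size=40, sigma_floor=1e-9)
        assert np.allclose(m.mu_at(0.0), x.mean())
        assert np.allclose(m.sigma_at(0.0), x.std(ddof=1))

    @pytest.mark.parametrize("paired", [False, True])
    def test_matches_brute_force_windowing(self, paired):
        """Vectorized rolling-window moments equal a naive re-sort-and-slice
        oracle, over many random vectors and probe points."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(10, 1000))
            w = int(r.integers(3, n + 1))
            control = r.normal(0, 1 + np.abs(r.normal(size=n)))
            target = r.normal(size=n) if paired else control
            floor = 0.05
            m = fit_local_moments(
                control, target if paired else None, window_size=w, sigma_floor=floor
            )
            probes = np.concatenate([r.normal(size=8), control[:2]])
            for p in probes:
                mu_o, sd_o = brute_force_moments(control, target, w, floor, p)
                assert abs(m.mu_at(p) - mu_o) < 1e-12
                assert abs(m.sigma_at(p) - sd_o) < 1e-10

    def test_too_few_scores_is_error(self):
        with pytest.raises(ValueError, match="window_size"):
            fit_local_moments([1.0, 2.0], window_size=5)

    def test_default_window_rule(self):
        assert default_window_size(100) == 50
        assert default_window_size(10000) == 250
        assert default_window_size(30) == 30


class TestComputeZ:
    def test_centered_case_and_threshold_example(self):
        """S_stress equal to mu gives z=0; (2.5 - (-0.5))/1.5 = 2.0 reaches
        the differential threshold."""
        from demap.differential import LocalMoments

        m = LocalMoments(
            sorted_control=np.array([0.0]),
            mu=np.array([-0.5]),
            sigma=np.array([1.5]),
            window_size=1,
            sigma_floor=0.1,
        )
        panel = make_panel(
            {("UT", "S1"): [[0.0, 0.0]], ("SO", "S1"): [[-0.5, 2.5]]}
        )
        table = compute_z(panel, "SO", moments=m)
        assert table.z.iloc[0, 0] == 0.0
        assert table.z.iloc[0, 1] == pytest.approx(2.0)
        assert abs(table.z.iloc[0, 1]) >= ThresholdConfig().tau_diff

    def test_elementwise_formula_on_toy_panel(self, rng):
        ctrl = rng.normal(size=(5, 5))
        stress = rng.normal(size=(5, 5))
        panel = make_panel({("UT", "S1"): ctrl, ("SO", "S1"): stress})
        table = compute_z(panel, "SO", window_size=10, sigma_floor=0.05)
        m = table.moments
        for i in range(5):
            for j in range(5):
                mu_o, sd_o = brute_force_moments(
                    ctrl.ravel(), stress.ravel(), 10, 0.05, ctrl[i, j]
                )
                assert table.z.iloc[i, j] == pytest.approx(
                    (stress[i, j] - mu_o) / sd_o, abs=1e-10
                )

    def test_missing_pairs_excluded(self, small_panel):
        table = compute_z(small_panel, "SO", window_size=5, sigma_floor=0.1)
        assert np.isnan(table.z.at["Q002", "A0001"])  # stress missing
        assert np.isfinite(table.z.drop(index="Q002").to_numpy()).all()

    def test_unknown_condition_is_lookup_error(self, small_panel):
        with pytest.raises(KeyError):
            compute_z(small_panel, "OX")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(s_low=st.floats(-5, 5), delta=st.floats(0.01, 5))
    def test_z_strictly_increasing_in_stress_score(self, s_low, delta):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(size=50)
        m = fit_local_moments(ctrl, window_size=10, sigma_floor=0.1)
        s_control = 0.3
        z1 = (s_low - m.mu_at(s_control)) / m.sigma_at(s_control)
        z2 = (s_low + delta - m.mu_at(s_control)) / m.sigma_at(s_control)
        assert z2 > z1

    def test_scaling_control_noise_shrinks_z(self, rng):
        """Scaling all scores by c > 1 scales sigma and shrinks z of a fixed
        stress observation on re-fit."""
        ctrl = rng.normal(size=500)
        stress = rng.normal(size=500)
        m1 = fit_local_moments(ctrl, stress, window_size=100, sigma_floor=1e-6)
        m3 = fit_local_moments(ctrl * 3, stress * 3, window_size=100, sigma_floor=1e-6)
        probe = 0.5
        assert m3.sigma_at(3 * probe) == pytest.approx(3 * m1.sigma_at(probe), rel=1e-9)


class TestCallNetwork:
    def test_boundary_inclusive_and_signs(self):
        scores = pd.DataFrame(
            [[3.0, 0.0, -3.2], [2.9, -2.0, 5.0]],
            index=["Q1", "Q2"],
            columns=["A1", "A2", "A3"],
        )
        net = call_network(scores, "static", ThresholdConfig(), condition="UT")
        assert ("Q1", "A1") in net.pairs  # |S| = 3.0 exactly
        assert ("Q2", "A1") not in net.pairs
        assert ("Q1", "A2") not in net.pairs
        signs = dict(((r.query, r.array), r.sign) for r in net.edges.itertuples())
        assert signs[("Q1", "A3")] == -1 and signs[("Q2", "A3")] == 1

    def test_differential_mode_uses_tau_diff(self):
        z = pd.DataFrame([[2.0, -1.9]], index=["Q1"], columns=["A1", "A2"])
        net = call_network(z, "differential", ThresholdConfig(), condition="SO")
        assert net.pairs == {("Q1", "A1")}
        assert net.threshold == 2.0


class TestOverlaps:
    def _net(self, cond, pairs, mode="differential", thr=2.0):
        edges = pd.DataFrame(
            [(q, a, 2.5, 2.5, 1) for q, a in pairs],
            columns=["query", "array", "score", "z", "sign"],
        )
        from demap import InteractionNetwork

        return InteractionNetwork(cond, mode, edges, thr)

    def test_identical_networks_overlap_fully(self):
        pairs = [("Q1", f"A{i}") for i in range(5)]
        d = self._net("SO", pairs)
        s = self._net("SO", pairs, mode="static", thr=3.0)
        assert overlap_static_differential(d, s) == 1.0

    def test_partial_overlap_fraction(self):
        d = self._net("SO", [("Q", "a"), ("Q", "b"), ("Q", "c"), ("Q", "d")])
        s = self._net("SO", [("Q", "c"), ("Q", "d"), ("Q", "e")], mode="static", thr=3.0)
        assert overlap_static_differential(d, s) == 0.5

    def test_empty_differential_warns_and_returns_zero(self):
        d = self._net("SO", [])
        s = self._net("SO", [("Q", "a")], mode="static", thr=3.0)
        with pytest.warns(UserWarning):
            assert overlap_static_differential(d, s) == 0.0

    def test_cross_condition_counts_match_enumeration(self, rng):
        """Exclusive-subset counts equal a direct set enumeration and sum to
        the union size."""
        arrays = [f"A{i}" for i in range(30)]
        nets = {}
        planted = {}
        for cond in ("SO", "OX", "ZY"):
            chosen = set(rng.choice(arrays, size=12, replace=False))
            planted[cond] = {("Q1", a) for a in chosen}
            nets[cond] = self._net(cond, sorted(planted[cond]))
        counts = cross_condition_overlap(nets)
        union = set.union(*planted.values())
        assert sum(counts.values()) == len(union)
        for subset, count in counts.items():
            expected = sum(
                1
                for p in union
                if {c for c in planted if p in planted[c]} == set(subset)
            )
            assert count == expected

    def test_disjoint_and_identical_cases(self):
        a = self._net("SO", [("Q", "a"), ("Q", "b"), ("Q", "c")])
        b = self._net("OX", [("Q", "x"), ("Q", "y"), ("Q", "z")])
        counts = cross_condition_overlap({"SO": a, "OX": b})
        assert counts[frozenset({"SO"})] == 3 and counts[frozenset({"OX"})] == 3
        assert frozenset({"SO", "OX"}) not in counts
        same = cross_condition_overlap({"SO": a, "OX": self._net("OX", sorted(a.pairs))})
        assert same == {frozenset({"SO", "OX"}): 3}


class TestReplicateReproducibility:
    def test_identical_replicates(self):
        scores = pd.DataFrame(
            [[3.5, -4.0, 1.0], [0.0, 5.0, -3.0]],
            index=["Q1", "Q2"], columns=["A1", "A2", "A3"],
        )
        net = call_network(scores, "static", condition="UT")
        frac, r = replicate_reproducibility(net, net, scores)
        assert frac == 1.0 and r == pytest.approx(1.0)

    def test_fraction_matches_direct_recount(self, rng):
        s1 = pd.DataFrame(rng.normal(scale=2, size=(6, 30)))
        s2 = s1 + rng.normal(scale=1.0, size=s1.shape)
        s1.index = s2.index = [f"Q{i}" for i in range(6)]
        s1.columns = s2.columns = [f"A{j}" for j in range(30)]
        n1 = call_network(s1, "static", condition="UT")
        n2 = call_network(s2, "static", condition="UT")
        frac, _ = replicate_reproducibility(n1, n2, s2)
        manual = np.mean(
            [abs(s2.at[q, a]) >= 3.0 for q, a in n1.pairs]
        )
        assert frac == pytest.approx(manual)

    def test_empty_shared_universe_is_error(self):
        scores = pd.DataFrame([[3.5]], index=["Q1"], columns=["A1"])
        net = call_network(scores, "static", condition="UT")
        empty = scores * np.nan
        with pytest.raises(ValueError):
            replicate_reproducibility(net, net, empty)


class TestGroupMedians:
    def test_even_class_uses_midpoint(self):
        med = group_score_medians([-4.0, -3.0], ["neg", "neg"])
        assert med["neg"] == -3.5

    def test_matches_sort_and_pick_oracle(self, rng):
        values = rng.normal(size=15)
        labels = np.repeat(["--", "-", "n", "+", "++"], 3)
        med = group_score_medians(values, labels)
        for cls in ("--", "-", "n", "+", "++"):
            sel = np.sort(values[labels == cls])
            assert med[cls] == sel[1]  # middle of three

    def test_empty_class_warns(self):
        with pytest.warns(UserWarning):
            med = group_score_medians([1.0], ["a"], classes=["a", "b"])
        assert np.isnan(med["b"])
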