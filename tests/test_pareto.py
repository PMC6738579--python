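"""Greedy construction, Pareto front geometry, and the derived features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shootpareto as sp
from shootpareto.pareto import DEFAULT_ALPHA_GRID

from conftest import make_skeleton, prufer_trees, random_terminal_set
from test_reference import spanning_tree_objectives


class TestGreedy:
    def test_alpha_one_is_satellite(self, rng):
        """Pure travel weight must reproduce the star exactly."""
        ts = random_terminal_set(rng, 12)
        t = sp.greedy_tree(ts, sp.GreedyConfig(alpha=1.0, k=10))
        sat = sp.satellite_tree(ts)
        assert t.travel_distance() == pytest.approx(
            sat.travel_distance(), abs=1e-9
        )
        assert t.total_length() == pytest.approx(sat.total_length(), abs=1e-9)

    def test_alpha_zero_hand_enumeration(self):
        """Two nearby terminals: cheapest wiring goes through the first."""
        ts = sp.TerminalSet(
            root=(0, 0, 0),
            terminals=(((0, 10, 0), "flower"), ((1, 10, 0), "flower")),
        )
        t = sp.greedy_tree(ts, sp.GreedyConfig(alpha=0.0, k=10))
        assert t.total_length() == pytest.approx(11.0)
        assert t.travel_distance() == pytest.approx(21.0)

    def test_runs_n_insertion_steps(self, rng):
        ts = random_terminal_set(rng, 7)
        k = 4
        t = sp.greedy_tree(ts, sp.GreedyConfig(alpha=0.2, k=k))
        assert t.n_nodes == 1 + 7 * (k + 1)
        assert len(t.terminal_rows) == 7
        t.validate()

    @pytest.mark.parametrize("seed", range(20))
    def test_alpha_zero_near_brute_force_optimum(self, seed):
        """Greedy length within 5% of the exhaustive spanning-tree optimum."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        ts = random_terminal_set(rng, n)
        greedy_len = sp.greedy_tree(
            ts, sp.GreedyConfig(alpha=0.0, k=10)
        ).total_length()
        best = min(
            spanning_tree_objectives(ts, edges)[0]
            for edges in prufer_trees(n + 1)
        )
        assert greedy_len <= 1.05 * best + 1e-9

    def test_grower_staging_matches_one_shot(self, rng):
        """Adding terminals in one call or in stages grows the same tree."""
        ts = random_terminal_set(rng, 8)
        pts = ts.coords()
        one = sp.greedy_tree(ts, sp.GreedyConfig(alpha=0.3, k=3))
        grower = sp.pareto.GreedyGrower(ts.root, 0.3, 3)
        grower.add_terminals(pts)
        staged = grower.snapshot()
        assert np.allclose(one.coords, staged.coords)
        assert np.array_equal(one.parent, staged.parent)


class TestFront:
    def test_default_grid_has_101_entries(self, rng):
        ts = random_terminal_set(rng, 5)
        front = sp.build_front(ts)
        assert len(front.entries) == 101
        assert front.alphas()[0] == 0.0 and front.alphas()[-1] == 1.0

    def test_single_terminal_front_degenerate(self):
        ts = sp.TerminalSet(root=(0, 0, 0), terminals=(((0, 0, 10), "flower"),))
        front = sp.build_front(ts, grid=np.linspace(0, 1, 11))
        assert np.allclose(front.lengths(), 10.0)
        assert np.allclose(front.travels(), 10.0)

    def test_endpoint_consistency(self, rng):
        ts = random_terminal_set(rng, 10)
        front = sp.build_front(ts, grid=np.array([0.0, 0.5, 1.0]))
        sat = sp.satellite_travel(ts)
        assert front.satellite_travel_entry() == pytest.approx(sat, abs=1e-9)
        steiner = sp.greedy_tree(ts, sp.GreedyConfig(alpha=0.0)).total_length()
        assert front.steiner_length() == pytest.approx(steiner)

    def test_nondominated_is_monotone_staircase(self, rng):
        ts = random_terminal_set(rng, 15)
        pts = sp.build_front(ts).nondominated()
        assert np.all(np.diff(pts[:, 0]) > 0)
        assert np.all(np.diff(pts[:, 1]) < 0)


class TestEpsilon:
    def test_hand_geometry(self):
        front = sp.ParetoFront(
            entries=[(0.0, 1.0, 3.0), (1.0, 3.0, 1.0)], grid=np.array([0.0, 1.0])
        )
        eps = sp.epsilon_distance(front, sp.ObjectivePair(3.0, 3.0))
        assert eps == pytest.approx(1.5)

    def test_on_front_entry_is_one(self, rng):
        ts = random_terminal_set(rng, 8)
        front = sp.build_front(ts, grid=np.linspace(0, 1, 21))
        for _, L, T in front.entries[::5]:
            assert sp.epsilon_distance(front, sp.ObjectivePair(L, T)) == (
                pytest.approx(1.0, abs=1e-9)
            )

    def test_doubled_entry_gives_two(self, rng):
        ts = random_terminal_set(rng, 8)
        front = sp.build_front(ts, grid=np.linspace(0, 1, 21))
        _, L, T = front.entries[10]
        eps = sp.epsilon_distance(front, sp.ObjectivePair(2 * L, 2 * T))
        assert eps == pytest.approx(2.0, abs=1e-9)

    def test_epsilon_scales_with_plant(self, rng):
        """Inflating both plant objectives by c multiplies epsilon by c."""
        ts = random_terminal_set(rng, 8)
        front = sp.build_front(ts, grid=np.linspace(0, 1, 21))
        plant = sp.ObjectivePair(1000.0, 5000.0)
        e1 = sp.epsilon_distance(front, plant)
        e3 = sp.epsilon_distance(front, sp.ObjectivePair(3000.0, 15000.0))
        assert e3 == pytest.approx(3 * e1)

    def test_axis_extensions_cover_extreme_plants(self, rng):
        ts = random_terminal_set(rng, 6)
        front = sp.build_front(ts, grid=np.linspace(0, 1, 11))
        # far more travel than any front tree: hits the vertical extension
        sp.epsilon_distance(front, sp.ObjectivePair(front.lengths().min(), 1e9))
        # far more length: hits the horizontal extension
        sp.epsilon_distance(front, sp.ObjectivePair(1e9, front.travels().min()))


class TestClosestAlpha:
    def test_recovers_exact_entry(self, rng):
        """A plant equal to a front entry maps to that entry's alpha run.

        Adjacent grid alphas can produce identical greedy trees; ties break
        to the smallest alpha of the run of identical entries.
        """
        ts = random_terminal_set(rng, 8)
        front = sp.build_front(ts)
        i = int(np.flatnonzero(front.alphas() == 0.30)[0])
        _, L, T = front.entries[i]
        got = sp.closest_alpha(front, sp.ObjectivePair(L, T))
        tied = [a for a, l, t in front.entries if (l, t) == (L, T)]
        assert got == pytest.approx(min(tied))
        assert min(tied) <= 0.30 <= max(tied)

    def test_degenerate_front_ties_to_zero(self):
        ts = sp.TerminalSet(root=(0, 0, 0), terminals=(((0, 0, 10), "flower"),))
        front = sp.build_front(ts, grid=np.linspace(0, 1, 11))
        assert sp.closest_alpha(front, sp.ObjectivePair(10.0, 10.0)) == 0.0

    def test_parameter_recovery_with_jitter(self):
        """Greedy plants at alpha*=0.5 with 1% jitter recover alpha within 0.15."""
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            ts = random_terminal_set(rng, 12)
            t = sp.greedy_tree(ts, sp.GreedyConfig(alpha=0.5, k=10))
            L, T = t.total_length(), t.travel_distance()
            jit = 1.0 + 0.01 * rng.standard_normal(2)
            front = sp.build_front(ts, grid=np.linspace(0, 1, 51))
            a = sp.closest_alpha(
                front, sp.ObjectivePair(L * jit[0], T * jit[1])
            )
            errs.append(abs(a - 0.5))
        assert max(errs) <= 0.15


class TestTradeoff:
    def test_satellite_plant(self, rng):
        ts = random_terminal_set(rng, 8)
        sat = sp.satellite_tree(ts)
        steiner = sp.greedy_tree(ts, sp.GreedyConfig(alpha=0.0))
        ratio = sp.tradeoff_ratio(
            sp.ObjectivePair(sat.total_length(), sat.travel_distance()),
            steiner.total_length(),
            sp.satellite_travel(ts),
        )
        # denominator is 1; satellite is at least as long as the Steiner proxy
        assert ratio == pytest.approx(
            sat.total_length() / steiner.total_length()
        )
        assert ratio >= 1.0 - 1e-9

    def test_steiner_plant(self, rng):
        ts = random_terminal_set(rng, 8)
        steiner = sp.greedy_tree(ts, sp.GreedyConfig(alpha=0.0))
        ratio = sp.tradeoff_ratio(
            sp.ObjectivePair(steiner.total_length(), steiner.travel_distance()),
            steiner.total_length(),
            sp.satellite_travel(ts),
        )
        assert ratio == pytest.approx(
            sp.satellite_travel(ts) / steiner.travel_distance()
        )
        assert ratio <= 1.0 + 1e-9

    def test_synthetic_plants_in_sanity_band(self, small_params):
        for seed in range(5):
            plant = sp.generate_plant(small_params, seed)
            assert 0.5 < sp.quick_tradeoff(plant) < 3.0

    def test_quick_matches_full_pipeline(self, small_params):
        plant = sp.generate_plant(small_params, 5)
        res = sp.analyze_plant(plant)
        assert sp.quick_tradeoff(plant) == pytest.approx(res.features.tradeoff)


class TestSugarTransport:
    def test_collinear_chain_zero_excess(self):
        s = make_skeleton(
            {
                "r": ((0, 0, 0), "root"),
                "b": ((0, 0, 3), "branch"),
                "l": ((0, 0, 5), "rosette_leaf"),
                "f": ((0, 0, 1), "flower"),
            },
            [("r", "b"), ("b", "l"), ("b", "f")],
        )
        # leaf and flower collinear through the branch point: the tree path
        # equals the straight-line distance, so the excess is zero
        pct_worse, _ = sp.sugar_transport_comparison(s)
        assert pct_worse == pytest.approx(0.0, abs=1e-9)

    def test_star_single_pair(self):
        s = make_skeleton(
            {
                "r": ((0, 0, 0), "root"),
                "l": ((5, 0, 0), "rosette_leaf"),
                "f": ((0, 5, 0), "flower"),
            },
            [("r", "l"), ("r", "f")],
        )
        pct_worse, pct_lower = sp.sugar_transport_comparison(s)
        straight = 5 * np.sqrt(2.0)
        assert pct_worse == pytest.approx(100 * (10 - straight) / straight)
        assert pct_lower == pytest.approx(100 * (straight - 10) / 10)

    def test_matches_double_loop_oracle(self, small_params):
        plant = sp.generate_plant(small_params, 9)
        pct_worse, pct_lower = sp.sugar_transport_comparison(plant)
        leaves = [
            t for t in plant.terminal_ids()
            if plant.nodes[t].label in ("rosette_leaf", "cauline_leaf")
        ]
        flowers = [
            t for t in plant.terminal_ids()
            if plant.nodes[t].label in ("flower", "silique")
        ]
        plant_sum = sum(
            plant.path_length(a, b) for a in leaves for b in flowers
        )
        bip = sum(
            np.linalg.norm(
                np.subtract(plant.nodes[a].coord, plant.nodes[b].coord)
            )
            for a in leaves
            for b in flowers
        )
        assert pct_worse == pytest.approx(100 * (plant_sum - bip) / bip)


class TestAnalyzePlant:
    def test_synthetic_plant_near_front(self, small_params):
        for seed in range(8):
            res = sp.analyze_plant(sp.generate_plant(small_params, seed))
            assert res.features.epsilon < 1.15

    def test_satellite_shaped_skeleton(self, rng):
        ts = random_terminal_set(rng, 6)
        nodes = {"r": ((0.0, 0.0, 0.0), "root")}
        edges = []
        for i, (c, l) in enumerate(ts.terminals):
            nodes[f"t{i}"] = (c, l)
            edges.append(("r", f"t{i}"))
        s = make_skeleton(nodes, edges)
        res = sp.analyze_plant(s, grid=np.linspace(0, 1, 21))
        # a star plant sits at the satellite end of its own front
        assert res.features.epsilon == pytest.approx(1.0, abs=1e-6)
        assert res.features.alpha_closest == pytest.approx(1.0)

    def test_baseline_fed_as_plant_is_worse(self, small_params):
        """A uniform-random tree on the same points lies farther out."""
        worse = 0
        for seed in range(6):
            plant = sp.generate_plant(small_params, seed)
            res = sp.analyze_plant(plant)
            ts = sp.extract_terminals(plant)
            rt = sp.random_spanning_tree(ts, seed)
            eps_rand = sp.epsilon_distance(
                res.front,
                sp.ObjectivePair(rt.total_length(), rt.travel_distance()),
            )
            worse += eps_rand > res.features.epsilon
        assert worse == 6

    def test_rosette_excluded_mode(self, small_params):
        plant = sp.generate_plant(small_params, 3)
        res = sp.analyze_plant(
            plant, grid=np.linspace(0, 1, 11), exclude_labels={"rosette_leaf"}
        )
        assert res.features.n_rosette == 0
        assert res.features.epsilon > 0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(min_value=0.1, max_value=50.0),
)
def test_scale_invariance_of_dimensionless_features(seed, scale):
    """Rescaling all coordinates leaves epsilon, closest alpha, trade-off fixed."""
    rng = np.random.default_rng(seed)
    ts = random_terminal_set(rng, 6)
    scaled = sp.TerminalSet(
        root=tuple(c * scale for c in ts.root),
        terminals=tuple(
            (tuple(c * scale for c in coord), lab) for coord, lab in ts.terminals
        ),
    )
    grid = np.linspace(0, 1, 11)
    f1, f2 = sp.build_front(ts, grid=grid), sp.build_front(scaled, grid=grid)
    plant1 = sp.ObjectivePair(f1.lengths()[5] * 1.1, f1.travels()[5] * 1.1)
    plant2 = sp.ObjectivePair(
        plant1.total_length * scale, plant1.travel_distance * scale
    )
    assert sp.epsilon_distance(f1, plant1) == pytest.approx(
        sp.epsilon_distance(f2, plant2), rel=1e-9
    )
    assert sp.closest_alpha(f1, plant1) == sp.closest_alpha(f2, plant2)
    assert sp.tradeoff_ratio(
        plant1, f1.steiner_length(), sp.satellite_travel(ts)
    ) == pytest.approx(
        sp.tradeoff_ratio(plant2, f2.steiner_length(), sp.satellite_travel(scaled)),
        rel=1e-9,
    )
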