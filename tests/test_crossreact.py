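"""Cross-reactivity matrix construction, pruning and the antibody graph."""

import numpy as np
import pytest

from abdeconv.crossreact import (
    CognateSignalError,
    CrossReactivityMatrix,
    build_graph,
    build_matrix,
    prune_antibodies,
)
from abdeconv.panel import default_panel
from abdeconv.quantify import estimate_background, summarize_replicates
from abdeconv.simulate import NoiseModel, make_reference_universe, simulate_crossreactivity_panel


def panel_assays_from_signals(signals_by_assay, background, profile_factory):
    """{assay j: {spot i: F}} -> panel assay profiles."""
    return {
        code: profile_factory(spots, background=background)
        for code, spots in signals_by_assay.items()
    }


class TestBuildMatrix:
    def test_background_subtracted_ratio(self, profile_factory):
        # assay j: cognate 2100, cross spot 600, B = 100 -> 500/2000 = 0.25
        assays = panel_assays_from_signals(
            {
                "A": {"A": 2100.0, "B": 600.0, "C": 120.0},
                "B": {"A": 110.0, "B": 2100.0, "C": 105.0},
                "C": {"A": 100.0, "B": 100.0, "C": 1100.0},
            },
            100.0,
            profile_factory,
        )
        m = build_matrix(assays, antibody_order=["A", "B", "C"])
        assert m.G[m.index("B"), m.index("A")] == pytest.approx(0.25)
        # spots below the 2.5x rule contribute exactly zero
        assert m.G[m.index("C"), m.index("A")] == 0.0
        assert np.allclose(np.diag(m.G), 1.0)

    def test_only_cognate_bright_gives_unit_column(self, profile_factory):
        assays = panel_assays_from_signals(
            {"A": {"A": 5000.0, "B": 50.0}, "B": {"A": 50.0, "B": 5000.0}},
            100.0,
            profile_factory,
        )
        m = build_matrix(assays)
        assert np.allclose(m.G, np.eye(2))

    def test_positivity_gate_zeroes_off_diagonal(self, profile_factory):
        # F_i = 240 with B = 100 is below 2.5 x B -> entry forced to 0
        assays = panel_assays_from_signals(
            {"A": {"A": 2100.0, "B": 240.0}, "B": {"A": 100.0, "B": 2100.0}},
            100.0,
            profile_factory,
        )
        m = build_matrix(assays)
        assert m.G[1, 0] == 0.0

    def test_failing_cognate_is_reported_not_kept(self, profile_factory):
        assays = panel_assays_from_signals(
            {"A": {"A": 200.0, "B": 100.0}, "B": {"A": 100.0, "B": 2100.0}},
            100.0,
            profile_factory,
        )
        with pytest.raises(CognateSignalError, match="A"):
            build_matrix(assays)

    def test_scaling_invariance(self, profile_factory):
        """Scaling all fluorescences of an assay leaves G unchanged."""
        base = {
            "A": {"A": 2100.0, "B": 600.0},
            "B": {"A": 300.0, "B": 1100.0},
        }
        m1 = build_matrix(panel_assays_from_signals(base, 100.0, profile_factory))
        scaled = {
            code: {k: 3.0 * v for k, v in spots.items()} for code, spots in base.items()
        }
        m2 = build_matrix(panel_assays_from_signals(scaled, 300.0, profile_factory))
        assert np.allclose(m1.G, m2.G)

    def test_weak_link_floor(self, profile_factory):
        assays = panel_assays_from_signals(
            # ratio 5/2000 = 0.0025 < 0.01 floor, though positivity passes
            {"A": {"A": 2100.0, "B": 255.0}, "B": {"A": 100.0, "B": 2100.0}},
            100.0,
            profile_factory,
        )
        m = build_matrix(assays, multiplier=2.5, weak_link_floor=0.1)
        assert m.G[1, 0] == 0.0


class TestPrune:
    def test_metadata_flags_prune_to_sixteen(self, profile_factory):
        panel = default_panel()
        assays = {
            e.code: profile_factory({c: 1000.0 for c in panel.codes}, background=100.0)
            for e in panel.entries
        }
        retained = prune_antibodies(assays, panel=panel)
        assert len(retained) == 16
        assert "L2S2" not in retained and "A-Cld" not in retained

    def test_identity_pruning_when_no_failures(self, profile_factory):
        assays = panel_assays_from_signals(
            {"A": {"A": 1000.0}, "B": {"B": 1000.0}}, 100.0, profile_factory
        )
        assert prune_antibodies(assays) == ["A", "B"]

    def test_weak_self_signal_removed(self, profile_factory):
        # self-signal exactly 2.0 x B fails the strict 2.5 x rule
        assays = panel_assays_from_signals(
            {"A": {"A": 200.0, "B": 100.0}, "B": {"A": 100.0, "B": 1000.0}},
            100.0,
            profile_factory,
        )
        assert prune_antibodies(assays) == ["B"]

    def test_empty_retained_set_errors(self, profile_factory):
        assays = panel_assays_from_signals(
            {"A": {"A": 100.0}}, 100.0, profile_factory
        )
        with pytest.raises(ValueError, match="every antibody"):
            prune_antibodies(assays)

    def test_prune_then_build_equals_build_then_subset(self, profile_factory):
        signals = {
            "A": {"A": 2100.0, "B": 700.0, "C": 400.0},
            "B": {"A": 600.0, "B": 3100.0, "C": 100.0},
            "C": {"A": 100.0, "B": 800.0, "C": 1600.0},
        }
        assays = panel_assays_from_signals(signals, 100.0, profile_factory)
        full = build_matrix(assays, antibody_order=["A", "B", "C"])
        sub_direct = build_matrix(
            {k: assays[k] for k in ("A", "C")}, antibody_order=["A", "C"]
        )
        assert np.allclose(full.subset(["A", "C"]).G, sub_direct.G)


class TestGraph:
    def test_identity_matrix_all_b_type(self):
        m = CrossReactivityMatrix(("A", "B", "C"), np.eye(3))
        g = build_graph(m)
        assert g.n_links == 0
        assert all(g.node_type(n) == "B" for n in g.nodes)

    def test_single_entry_graph(self):
        G = np.eye(2)
        G[0, 1] = 0.5  # immunogen of antibody 2 lights spot 1
        g = build_graph(CrossReactivityMatrix(("ab1", "ab2"), G))
        assert g.n_links == 1
        assert list(g.graph.edges) == [("ab2", "ab1")]
        assert g.node_type("ab2") == "A"
        assert g.node_type("ab1") == "B"

    def test_link_count_matches_positive_offdiagonals(self, rng):
        for _ in range(20):
            n = 8
            G = np.eye(n)
            mask = (rng.random((n, n)) < 0.2) & ~np.eye(n, dtype=bool)
            G[mask] = rng.uniform(0.05, 0.9, mask.sum())
            g = build_graph(CrossReactivityMatrix(tuple(f"a{i}" for i in range(n)), G))
            assert g.n_links == int(mask.sum())

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError, match="diagonal"):
            CrossReactivityMatrix(("A", "B"), np.array([[1.0, 0.0], [0.0, 0.5]]))
        with pytest.raises(ValueError, match="non-negative"):
            CrossReactivityMatrix(("A", "B"), np.array([[1.0, -0.1], [0.0, 1.0]]))


class TestSimulatedPanelRecovery:
    def test_zero_noise_panel_recovers_affinities(self):
        """Noise-free single-immunogen panel reproduces the simulator's R."""
        universe = make_reference_universe(seed=11)
        tables = simulate_crossreactivity_panel(
            universe, noise=NoiseModel(replicate_cv=0.0), seed=3
        )
        assays = {
            code: estimate_background(summarize_replicates(t))
            for code, t in tables.items()
        }
        m = build_matrix(assays, antibody_order=universe.antibody_order)
        assert np.max(np.abs(m.G - universe.onchip_affinity_matrix())) < 1e-6

    def test_reference_universe_graph_scale(self):
        universe = make_reference_universe(seed=0)
        m = CrossReactivityMatrix(
            universe.antibody_order, universe.onchip_affinity_matrix()
        )
        g = build_graph(m)
        assert (g.n_nodes, g.n_links) == (16, 28)
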