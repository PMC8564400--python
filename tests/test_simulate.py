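import math

import numpy as np
import pytest

from hexconn.connect import build_graph
from hexconn.geometry import OUTSIDE, LatticeSpec, PatternIndex
from hexconn.simulate import (
    PlacementError,
    SimulationParams,
    default_axon_coverage_dist,
    occupancy_summary,
    simulate_circuit,
)

from .conftest import annotation_of, make_cell


@pytest.fixture(scope="module")
def recovery_run():
    """One large circuit shared by the parameter-recovery checks."""
    spec = LatticeSpec(55, 70, rows=60, cols=54)
    params = SimulationParams(n_cells=5000, seed=42)
    annotation, truth = simulate_circuit(spec, params)
    return spec, params, annotation, truth


class TestDistributions:
    def test_axon_coverage_dist_calibration(self):
        support, probs = default_axon_coverage_dist()
        assert support[0] == 1 and support[-1] == 25
        assert sum(probs) == pytest.approx(1.0)
        assert float(np.dot(support, probs)) == pytest.approx(6.7, abs=1e-9)
        # the same parameterization places 80.8% of mass below 10 patterns
        assert sum(p for k, p in zip(support, probs) if k <= 9) == pytest.approx(0.808, abs=0.005)

    def test_rpa_dist_mass_on_one_or_two(self):
        params = SimulationParams(n_cells=10)
        support, probs = params.rpa_dist()
        mass12 = sum(p for k, p in zip(support, probs) if k <= 2)
        assert mass12 == pytest.approx(0.762, abs=1e-9)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        spec = LatticeSpec(55, 70, rows=12, cols=12)
        params = SimulationParams(n_cells=50, seed=7)
        a1, g1 = simulate_circuit(spec, params)
        a2, g2 = simulate_circuit(spec, params)
        assert a1 == a2
        assert g1.edges == g2.edges and g1.evidence == g2.evidence

    def test_different_seed_differs(self):
        spec = LatticeSpec(55, 70, rows=12, cols=12)
        a1, _ = simulate_circuit(spec, SimulationParams(n_cells=50, seed=7))
        a2, _ = simulate_circuit(spec, SimulationParams(n_cells=50, seed=8))
        assert a1 != a2


class TestParameterRecovery:
    def test_soma_inside_fraction(self, recovery_run):
        _, params, annotation, _ = recovery_run
        inside = np.mean([c.soma_pattern is not OUTSIDE for c in annotation.cells])
        p = params.p_soma_inside
        se = math.sqrt(p * (1 - p) / len(annotation))
        assert abs(inside - p) < 3 * se

    def test_rpa_mass_recovered(self, recovery_run):
        _, _, annotation, _ = recovery_run
        rpa = np.array([len(c.dendrite_patterns) for c in annotation.cells])
        se = math.sqrt(0.762 * 0.238 / len(rpa))
        assert abs(np.mean(rpa <= 2) - 0.762) < 3 * se

    def test_axon_coverage_mean_recovered(self, recovery_run):
        _, _, annotation, _ = recovery_run
        cover = np.array([len(c.axon_patterns) for c in annotation.cells])
        se = cover.std() / math.sqrt(len(cover))
        assert abs(cover.mean() - 6.7) < 3 * se

    def test_every_cell_has_neurites(self, recovery_run):
        _, _, annotation, _ = recovery_run
        assert all(c.dendrite_patterns and c.axon_patterns for c in annotation.cells)
        for c in annotation.cells:
            if c.soma_pattern is not OUTSIDE:
                assert c.soma_pattern in c.dendrite_patterns
                assert c.soma_pattern in c.axon_patterns


class TestTruthGraph:
    def test_edges_backed_by_contact(self, recovery_run):
        _, _, annotation, truth = recovery_run
        by_id = {c.cell_id: c for c in annotation.cells}
        for pre, post in truth.edges:
            contact = by_id[pre].axon_patterns & by_id[post].dendrite_patterns
            assert contact
            assert truth.evidence[(pre, post)] <= contact

    def test_certain_synapses_match_reconstruction_exactly(self):
        spec = LatticeSpec(55, 70, rows=12, cols=12)
        params = SimulationParams(n_cells=60, seed=3, p_synapse_given_contact=1.0)
        annotation, truth = simulate_circuit(spec, params)
        rebuilt = build_graph(annotation)
        assert rebuilt.edges == truth.edges
        assert rebuilt.evidence == truth.evidence

    def test_subunity_synapse_probability_thins_edges(self):
        spec = LatticeSpec(55, 70, rows=12, cols=12)
        full = simulate_circuit(spec, SimulationParams(n_cells=60, seed=3, p_synapse_given_contact=1.0))[1]
        thinned = simulate_circuit(spec, SimulationParams(n_cells=60, seed=3, p_synapse_given_contact=0.5))[1]
        assert thinned.edges < full.edges


class TestPlacement:
    def test_overcrowded_lattice_raises(self):
        spec = LatticeSpec(55, 70, rows=2, cols=2)
        params = SimulationParams(n_cells=500, seed=0, min_soma_separation_um=30.0)
        with pytest.raises(PlacementError):
            simulate_circuit(spec, params)

    def test_density_resolves_to_cell_count(self):
        spec = LatticeSpec(55, 70, rows=20, cols=20)
        params = SimulationParams(density=55.0, seed=0)
        n = params.resolve_n_cells(spec)
        area_mm2 = 400 * math.sqrt(3) / 2 * spec.spacing**2 / 1e6
        assert n == round(55.0 * area_mm2)


class TestOccupancySummary:
    def test_single_cell_fractions(self):
        spec = LatticeSpec(55, 70, rows=2, cols=5)
        idx = spec.index_at(0, 0)
        cell = make_cell(1, idx, {idx}, {idx}, soma_point=(0.0, 0.0))
        s = occupancy_summary(spec, annotation_of(cell))
        assert s["frac_patterns_with_soma"] == pytest.approx(0.1)
        assert s["frac_patterns_with_dendrite"] == pytest.approx(0.1)
        assert s["frac_patterns_with_axon"] == pytest.approx(0.1)
        assert math.isnan(s["mean_dist_3_nearest_cells"])

    def test_three_nearest_hand_case(self, spec55):
        """Three collinear cells 100 μm apart plus one 1000 μm away."""
        idx = PatternIndex(0, 0)
        pts = [(0.0, 0.0), (100.0, 0.0), (200.0, 0.0), (1200.0, 0.0)]
        cells = [make_cell(i + 1, OUTSIDE, {idx}, {idx}, soma_point=p) for i, p in enumerate(pts)]
        s = occupancy_summary(spec55, annotation_of(*cells))
        per_cell = [
            (100 + 200 + 1200) / 3,   # cell at 0
            (100 + 100 + 1100) / 3,   # cell at 100
            (100 + 200 + 1000) / 3,   # cell at 200
            (1000 + 1100 + 1200) / 3, # far cell
        ]
        assert s["mean_dist_3_nearest_cells"] == pytest.approx(np.mean(per_cell))

    def test_histograms_sum_to_cell_count(self, recovery_run):
        spec, _, annotation, _ = recovery_run
        s = occupancy_summary(spec, annotation)
        assert sum(s["rpa_count_hist"].values()) == len(annotation)
        assert sum(s["axon_coverage_hist"].values()) == len(annotation)
        for frac in ("frac_patterns_with_soma", "frac_patterns_with_dendrite", "frac_patterns_with_axon"):
            assert 0.0 <= s[frac] <= 1.0
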