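"""Aggregate analysis: clustering, labels, sizes, CMC, ergodicity, phases."""

import math

import numpy as np
import pytest

from cookesim.analysis import (Aggregate, FrameAnalysis, PlateauEstimate,
                               aggregate_size, analyze_frame,
                               build_phase_diagram, cluster_frame,
                               cmc_from_concentration_scan,
                               cmc_from_size_scan, ergodic_measure,
                               free_lipid_series, make_aggregates,
                               radius_of_gyration, size_distribution_qq,
                               unwrap_cluster)
from cookesim.engine import SystemState
from cookesim.fixtures import generate_fixture
from cookesim.sysbuild import SystemSpec, build_initial_state
from cookesim.topology import assemble_system
from cookesim.units import DEFAULT_UNITS

from conftest import oracle_clusters

SIG = DEFAULT_UNITS.sigma_nm  # 0.6 nm
CUTOFF_SIGMA = 0.9 / SIG      # cluster cutoff in reduced units


def _lipid_state(positions_by_molecule, box=60.0):
    """Lipids with H at p, tails stacked +z above (all in sigma units)."""
    n = len(positions_by_molecule)
    topo = assemble_system(n, 0)
    pos = []
    for p in positions_by_molecule:
        p = np.asarray(p, dtype=float)
        pos += [p, p + (0, 0, 1.0), p + (0, 0, 2.0)]
    pos = np.array(pos)
    return SystemState(pos, np.zeros_like(pos), box), topo


class TestClustering:
    def test_far_molecules_are_singletons(self):
        st, topo = _lipid_state([(5, 5, 5), (20, 20, 20)])
        clusters = cluster_frame(st, topo)
        assert sorted(map(sorted, clusters)) == [[0], [1]]

    def test_single_linkage_transitivity(self):
        # A-B and B-C within cutoff, A-C beyond: one 3-molecule cluster
        d = 1.2  # sigma, below the 1.5 sigma cutoff
        st, topo = _lipid_state([(10, 10, 10), (10 + d, 10, 10),
                                 (10 + 2 * d, 10, 10)])
        clusters = cluster_frame(st, topo)
        assert clusters == [frozenset({0, 1, 2})]

    def test_only_hydrophobic_beads_count(self):
        # heads 1.2 sigma apart but tails pointing away: no link
        st, topo = _lipid_state([(10, 10, 10)])
        n = 2
        topo = assemble_system(n, 0)
        pos = np.array([
            [10.0, 10, 10], [10, 10, 11], [10, 10, 12],     # tails up
            [10.0, 11.2, 10], [10, 11.2, 9], [10, 11.2, 8],  # tails down
        ])
        st = SystemState(pos, np.zeros_like(pos), 60.0)
        clusters = cluster_frame(st, topo)
        # nearest tail beads are 2 sigma apart -> separate clusters
        assert len(clusters) == 2

    def test_matches_union_find_oracle(self, rng):
        spec = SystemSpec(n_lipids=60, n_peptides=4,
                          lipid_concentration_mM=50.0, base_seed=8)
        st, topo = build_initial_state(spec, seed=8)
        got = set(cluster_frame(st, topo))
        want = oracle_clusters(st, topo, CUTOFF_SIGMA)
        assert got == want

    def test_translation_and_periodic_shift_invariance(self):
        st, topo = _lipid_state([(1, 1, 1), (2.2, 1, 1), (30, 30, 30)],
                                box=40.0)
        base = set(cluster_frame(st, topo))
        for shift in ([3.7, -2.1, 9.9], [40.0, 0, 0], [13.3, 40.0, -40.0]):
            pos = st.positions + np.asarray(shift)
            st2 = SystemState(pos, st.velocities, st.box_edge)
            assert set(cluster_frame(st2, topo)) == base

    def test_cluster_spanning_boundary(self):
        # two molecules touching through the periodic wall
        st, topo = _lipid_state([(0.4, 10, 10), (39.4, 10, 10)], box=40.0)
        clusters = cluster_frame(st, topo)
        assert clusters == [frozenset({0, 1})]


class TestAggregates:
    def test_small_clusters_discarded(self):
        # 4 molecules in contact: below the 5-molecule threshold
        st, topo = _lipid_state([(10 + 1.2 * k, 10, 10) for k in range(4)])
        clusters = cluster_frame(st, topo)
        assert make_aggregates(clusters, st, topo) == []
        fa = analyze_frame(st, topo)
        assert fa.n_free_lipids == 4  # sub-threshold molecules count free

    def test_micelle_fixture_labeled_micelle(self):
        st, topo, _ = generate_fixture("micelle", 30)
        fa = analyze_frame(st, topo)
        assert len(fa.aggregates) == 1
        agg = fa.aggregates[0]
        assert agg.n_lipids == 30 and agg.label == "micelle"
        assert agg.rg < 2.5
        assert fa.n_free_lipids == 0

    def test_disc_fixture_labeled_disc(self):
        st, topo, _ = generate_fixture("disc", 200, 8)
        fa = analyze_frame(st, topo)
        assert len(fa.aggregates) == 1
        agg = fa.aggregates[0]
        assert agg.label == "disc" and agg.rg >= 2.5
        assert agg.n_peptides == 8

    def test_mixture_fixture_planted_labels_recovered(self):
        st, topo, truth = generate_fixture("mixture", 200, 6)
        fa = analyze_frame(st, topo)
        got = {a.member_molecule_ids: a.label for a in fa.aggregates}
        for members, label in truth["aggregates"]:
            assert got[members] == label

    def test_unwrap_across_boundary(self):
        st, topo = _lipid_state([(0.4, 10, 10), (39.4, 10, 10)], box=40.0)
        coords = unwrap_cluster(np.arange(6), st, topo)
        # unwrapped extent along x must be ~1 sigma, not ~39
        assert np.ptp(coords[:, 0]) < 2.0

    def test_molecule_conservation(self):
        st, topo, _ = generate_fixture("mixture", 200, 6)
        fa = analyze_frame(st, topo)
        in_aggs = sum(a.n_lipids for a in fa.aggregates)
        assert in_aggs + fa.n_free_lipids == 200


class TestSizeMetric:
    def test_sphere_size_converges_to_diameter(self, rng):
        from cookesim.fixtures import _fibonacci_sphere
        R = 5.0
        pts = R * _fibonacci_sphere(800)
        assert aggregate_size(pts) == pytest.approx(2 * R, rel=0.05)

    def test_disc_size_converges_to_diameter(self, rng):
        R = 6.0
        r = R * np.sqrt(rng.random(2000))
        th = rng.uniform(0, 2 * math.pi, 2000)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th),
                               np.zeros(2000)])
        assert aggregate_size(pts) == pytest.approx(2 * R, rel=0.05)

    def test_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        pts = rng.normal(size=(200, 3)) * np.array([3.0, 1.5, 0.4])
        s0 = aggregate_size(pts)
        for seed in range(5):
            rot = Rotation.random(rng=np.random.default_rng(seed))
            assert aggregate_size(rot.apply(pts)) == pytest.approx(
                s0, abs=1e-9)

    def test_degenerate_collinear_warns(self):
        pts = np.column_stack([np.linspace(0, 10, 50),
                               np.zeros(50), np.zeros(50)])
        with pytest.warns(UserWarning, match="degenerate"):
            size = aggregate_size(pts)
        assert size == pytest.approx(10.0)

    def test_rg_of_spherical_shell(self):
        from cookesim.fixtures import _fibonacci_sphere
        pts = 4.0 * _fibonacci_sphere(2000)
        assert radius_of_gyration(pts) == pytest.approx(4.0, rel=0.01)


class TestFreeLipidsAndCMC:
    def _frames(self, concs):
        return [FrameAnalysis([], 0, c, frame_time=float(i))
                for i, c in enumerate(concs)]

    def test_plateau_is_window_mean(self):
        frames = self._frames([9.0, 7.0, 5.0, 1.0, 1.2, 0.8])
        est = free_lipid_series(frames, window_fraction=0.5)
        assert est.mean_mM == pytest.approx(1.0)

    def test_no_aggregates_free_equals_total(self):
        st, topo, _ = generate_fixture("dispersed", 20,
                                       concentration_mM=0.01)
        fa = analyze_frame(st, topo)
        assert fa.aggregates == []
        assert fa.n_free_lipids == 20
        assert fa.free_lipid_concentration_mM == pytest.approx(0.01,
                                                               rel=1e-9)

    def test_all_in_one_aggregate_zero_free(self):
        st, topo, _ = generate_fixture("micelle", 30)
        fa = analyze_frame(st, topo)
        assert fa.n_free_lipids == 0
        assert fa.free_lipid_concentration_mM == 0.0

    def test_size_scan_uses_largest_system(self):
        plateaus = {
            50: PlateauEstimate(0.1, 0.02, np.array([0.1])),
            200: PlateauEstimate(0.45, 0.05, np.array([0.45])),
            1000: PlateauEstimate(0.5, 0.05, np.array([0.5])),
        }
        est = cmc_from_size_scan(plateaus)
        assert est.cmc_mM == pytest.approx(0.5)
        assert est.flags.get("artificially_low") == [50]

    def test_size_scan_identical_plateaus(self):
        plateaus = {n: PlateauEstimate(0.42, 0.0, np.array([0.42]))
                    for n in (100, 200, 400)}
        est = cmc_from_size_scan(plateaus)
        assert est.cmc_mM == pytest.approx(0.42)
        assert "artificially_low" not in est.flags

    def test_concentration_scan_plateau_mean(self):
        plateaus = {
            0.1: PlateauEstimate(0.1, 0.0, np.array([0.1])),
            1.0: PlateauEstimate(1.0, 0.0, np.array([1.0])),
            2.0: PlateauEstimate(0.48, 0.02, np.array([0.48])),
            10.0: PlateauEstimate(0.52, 0.02, np.array([0.52])),
            100.0: PlateauEstimate(0.50, 0.02, np.array([0.50])),
        }
        formed = {0.1: False, 1.0: False, 2.0: True, 10.0: True,
                  100.0: True}
        est = cmc_from_concentration_scan(plateaus, formed)
        assert est.cmc_mM == pytest.approx(0.5)
        assert est.flags["plateau_concentrations"] == [2.0, 10.0, 100.0]

    def test_concentration_scan_without_plateau_errors(self):
        plateaus = {0.1: PlateauEstimate(0.1, 0.0, np.array([0.1]))}
        with pytest.raises(ValueError, match="no plateau"):
            cmc_from_concentration_scan(plateaus, {0.1: False})


class TestErgodicMeasure:
    def test_identical_replicas_zero(self):
        counts = np.tile(np.array([3, 3, 2, 2, 2]), (4, 1))
        assert np.all(ergodic_measure(counts) == 0.0)

    def test_constant_offset_one(self):
        counts = np.array([[3, 3, 3], [4, 4, 4]])
        np.testing.assert_allclose(ergodic_measure(counts), 1.0)

    def test_poisson_counts_fluctuate_about_2lambda(self):
        # for independent Poisson(lam) replicas E[(n_i - n_j)^2] = 2 lam
        lam = 4.0
        rng = np.random.default_rng(0)
        counts = rng.poisson(lam, size=(6, 4000))
        d = ergodic_measure(counts)
        assert d.mean() == pytest.approx(2 * lam, rel=0.05)

    def test_requires_two_replicas(self):
        with pytest.raises(ValueError):
            ergodic_measure(np.array([[1, 2, 3]]))


class TestSizeDistributionQQ:
    def _aggs(self, values):
        return [Aggregate(frozenset({i}), int(v), 0, 1.0, 1.0, "micelle",
                          0) for i, v in enumerate(values)]

    def test_normal_sample_on_identity_line(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(50, 8, size=400)
        res = size_distribution_qq(self._aggs(vals))
        # order statistics track the fitted Gaussian quantiles
        err = np.abs(res.order_statistics - res.theoretical_quantiles)
        assert np.median(err) < 1.0
        # extreme order statistics scatter by a few units of SD/sqrt(n);
        # anything below ~0.75 SD is consistent with a Gaussian
        assert res.upper_tail_deviation < 0.75 * res.sd

    def test_disc_outliers_produce_upper_tail(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(40, 5, size=200),
                               rng.normal(200, 10, size=10)])
        res = size_distribution_qq(self._aggs(vals))
        assert res.upper_tail_deviation > 20.0

    def test_too_few_aggregates_refused(self):
        with pytest.raises(ValueError, match=">= 10"):
            size_distribution_qq(self._aggs([10] * 9))


class TestPhaseDiagram:
    def _agg(self, n_lip, label):
        return Aggregate(frozenset(), n_lip, 2, 1.0, 1.0, label, 0)

    def test_planted_grid_recovered(self):
        grid = {
            (100, 0.5): [self._agg(10, "micelle")] * 3,
            (200, 0.5): [self._agg(10, "micelle")] * 6,
            (100, 0.05): [self._agg(90, "disc")],
            (200, 0.05): [self._agg(80, "disc"), self._agg(20, "micelle")],
        }
        points = {(p.n_lipids, p.p_over_l): p
                  for p in build_phase_diagram(grid)}
        assert points[(100, 0.5)].phase == "micelle"
        assert points[(200, 0.5)].phase == "micelle"
        assert points[(100, 0.05)].phase == "disc"
        assert points[(200, 0.05)].phase == "mixture"

    def test_finite_size_flag_three_times_rule(self):
        # preferred size from the largest system at each P/L
        grid = {
            (100, 0.1): [self._agg(40, "micelle")],
            (500, 0.1): [self._agg(50, "micelle")] * 5,
        }
        points = {p.n_lipids: p for p in build_phase_diagram(grid)}
        # preferred size 50 -> boundary at 150 lipids
        assert points[100].finite_size_flag is True
        assert points[500].finite_size_flag is False
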