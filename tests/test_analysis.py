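"""Analysis suite exercised on synthetic mappings with known ground truth."""

import numpy as np
import pytest

from ephmap.analysis import (
    InjectionError,
    central_third_mask,
    collapse_point,
    cv_bandwidth,
    kde_contour,
    lattice_analysis,
    projection_histogram,
    sc_coverage,
    segregation,
    strongest_target_mapping,
)
from ephmap.analysis.collapse import two_means_1d
from ephmap.analysis.kde import _contour_area_pct, _grid_density
from ephmap.analysis.lattice import farthest_point_sample
from ephmap.connections import ConnectionState
from ephmap.fixtures import FixtureSpec, make_mapping
from ephmap.substrate import Circle


@pytest.fixture(scope="module")
def fixture_maps(wt_medium):
    def build(kind, **kw):
        return make_mapping(FixtureSpec(kind=kind, seed=5, **kw), wt_medium)

    return build


class TestLattice:
    def test_ideal_map_is_fully_ordered(self, fixture_maps):
        mapping, _ = fixture_maps("identity")
        lat = lattice_analysis(mapping)
        assert lat.pct_nodes == 100.0
        assert lat.pct_edges == 100.0
        assert lat.ap_polarity == 100.0
        assert lat.ml_polarity == 100.0
        assert lat.orientation_diff_deg == pytest.approx(0.0, abs=1e-9)

    def test_scrambled_map_loses_order(self, fixture_maps):
        mapping, _ = fixture_maps("random")
        lat = lattice_analysis(mapping)
        assert abs(lat.ap_polarity - 50.0) < 10.0
        assert abs(lat.ml_polarity - 50.0) < 10.0
        assert lat.pct_nodes < 15.0

    def test_ap_mirror_reverses_polarity_without_crossings(self, fixture_maps):
        mapping, _ = fixture_maps("mirrored")
        lat = lattice_analysis(mapping)
        assert lat.ap_polarity < 5.0
        assert lat.ml_polarity > 95.0
        # a pure reflection does not fold the map
        assert lat.pct_edges == 100.0

    def test_retained_submap_has_no_crossings_audited(self, fixture_maps):
        # the function asserts the crossing-free postcondition internally;
        # a noisy map exercises the removal loop
        mapping, _ = fixture_maps("noisy", noise=0.08)
        lat = lattice_analysis(mapping)
        assert 0 < len(lat.removed_nodes) < 100
        assert lat.pct_nodes < 100.0

    def test_farthest_point_sampling_spreads_centers(self, wt_medium):
        idx = farthest_point_sample(wt_medium.retina, 100)
        assert len(np.unique(idx)) == 100
        from scipy.spatial.distance import pdist

        spacing = pdist(wt_medium.retina[idx]).min()
        assert spacing > 0.04  # approximately equidistant, not clustered

    def test_too_few_mapped_rgcs_rejected(self, fixture_maps):
        mapping, _ = fixture_maps("identity")
        with pytest.raises(ValueError):
            lattice_analysis(mapping.subset(np.arange(len(mapping)) < 50))


class TestCollapse:
    def test_merge_position_recovered(self, fixture_maps):
        for merge_at in (0.5, 0.7):
            mapping, _ = fixture_maps("merged_at", merge_at=merge_at)
            res = collapse_point(mapping.subset(central_third_mask(mapping)))
            assert res.kind == "collapse"
            assert res.collapse_position == pytest.approx(100 * merge_at, abs=4.0)

    def test_full_duplication_never_merges(self, fixture_maps):
        mapping, _ = fixture_maps("duplicated")
        res = collapse_point(mapping.subset(central_third_mask(mapping)))
        assert res.kind == "no_merge"
        assert res.collapse_position is None

    def test_single_map_reports_no_split(self, fixture_maps):
        mapping, _ = fixture_maps("identity")
        res = collapse_point(mapping.subset(central_third_mask(mapping)))
        assert res.kind == "no_split"
        assert res.collapse_position is None

    def test_two_means_1d_exact_split(self):
        vals = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.3])
        labels, sep = two_means_1d(vals)
        assert len(np.unique(labels[:3])) == 1
        assert len(np.unique(labels[3:])) == 1
        assert labels[0] != labels[-1]
        assert sep == pytest.approx(np.mean(vals[3:]) - np.mean(vals[:3]))

    def test_insufficient_data_rejected(self, fixture_maps):
        mapping, _ = fixture_maps("identity")
        with pytest.raises(ValueError):
            collapse_point(mapping.subset(np.arange(len(mapping)) < 60))


class TestSegregation:
    def test_disjoint_projections_fully_segregated(self, fixture_maps):
        mapping, _ = fixture_maps("noisy", noise=0.03)
        assert segregation(mapping, [[0.2, 0.5], [0.8, 0.5]], 0.08) == 1.0

    def test_random_labels_give_half(self, fixture_maps, rng):
        # permutation null: colours shuffled within one labelled cloud
        mapping, _ = fixture_maps("identity")
        from ephmap.analysis.injections import label_injection
        from scipy.spatial import cKDTree

        labelled, colour = label_injection(mapping, [[0.45, 0.5], [0.55, 0.5]], 0.12)
        pts = mapping.retina[labelled]
        vals = []
        for _ in range(200):
            col = rng.permutation(colour[labelled])
            tree = cKDTree(pts)
            _, nn = tree.query(pts, k=2)
            vals.append(np.mean(col == col[nn[:, 1]]))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_overlapping_projections_near_half(self, fixture_maps):
        # a very imprecise map: the two labelled retinal clouds coincide
        mapping, _ = fixture_maps("noisy", noise=0.5)
        val = segregation(mapping, [[0.5, 0.45], [0.5, 0.55]], 0.15)
        assert 0.4 < val < 0.65

    def test_label_symmetry(self, fixture_maps):
        mapping, _ = fixture_maps("noisy", noise=0.05)
        a = segregation(mapping, [[0.3, 0.5], [0.7, 0.5]], 0.08)
        b = segregation(mapping, [[0.7, 0.5], [0.3, 0.5]], 0.08)
        assert a == b

    def test_too_few_labelled_raises(self, fixture_maps):
        mapping, _ = fixture_maps("identity")
        with pytest.raises(InjectionError):
            segregation(mapping, [[-5.0, -5.0], [0.5, 0.5]], 0.05)


class TestKDE:
    def test_density_integrates_to_one(self, rng):
        pts = rng.normal(0.5, 0.08, size=(80, 2))
        dens, inside, cell_area = _grid_density(
            pts, np.ones(80), 0.05, Circle(), n_grid=100
        )
        # over the full bounding square the KDE mass is close to 1
        assert np.sum(dens) * cell_area == pytest.approx(1.0, abs=0.02)

    def test_tight_cluster_covers_less_than_dispersed(self, rng):
        tight = 0.5 + rng.normal(0, 0.02, size=(60, 2))
        spread = 0.5 + rng.uniform(-0.4, 0.4, size=(60, 2))
        _, a_tight = kde_contour(tight, 95)
        _, a_spread = kde_contour(spread, 95)
        assert a_tight < a_spread

    def test_cv_bandwidth_matches_silverman_scale(self, rng):
        # simulation oracle: draws from a known isotropic Gaussian
        ratios = []
        for _ in range(5):
            pts = rng.normal(0.5, 0.1, size=(150, 2))
            k = cv_bandwidth(pts)
            sigma = pts.std(ddof=1)
            silverman = sigma * 150 ** (-1.0 / 6.0)
            ratios.append(k / silverman)
        assert all(0.5 < r < 2.0 for r in ratios)

    def test_degenerate_points_floored(self):
        pts = np.full((10, 2), 0.5)
        with pytest.warns(UserWarning):
            k = cv_bandwidth(pts)
        assert k == pytest.approx(1e-3)

    def test_coverage_uniform_and_half(self, wt_medium, rng):
        # uniform weight on every SC neuron: 99% mass covers ~99% of area
        W = np.ones((1, wt_medium.n_sc))
        full = sc_coverage(W, wt_medium, mass=0.99)
        assert full > 90.0
        # anterior half only: analytic contour of a uniform half
        W_half = (wt_medium.sc[:, 0] < 0.5).astype(float)[None, :]
        half = sc_coverage(W_half, wt_medium, mass=0.99)
        assert half == pytest.approx(49.5, abs=6.0)

    def test_point_mass_coverage_small(self, wt_medium):
        # all synaptic weight on one tight cluster of SC neurons
        from scipy.spatial import cKDTree

        _, idx = cKDTree(wt_medium.sc).query([0.5, 0.5], k=5)
        W = np.zeros((1, wt_medium.n_sc))
        W[0, idx] = 1.0
        assert sc_coverage(W, wt_medium, mass=0.99) < 5.0


class TestProjectionHistogram:
    def test_ideal_map_concentrates_on_antidiagonal(self, fixture_maps):
        mapping, _ = fixture_maps("identity")
        H, r_edges, s_edges = projection_histogram(mapping, bins=20)
        # mass sits where AP ~ 1 - NT
        ii, jj = np.nonzero(H)
        r_mid = 0.5 * (r_edges[ii] + r_edges[ii + 1])
        s_mid = 0.5 * (s_edges[jj] + s_edges[jj + 1])
        assert np.max(np.abs((1.0 - r_mid) - s_mid)) < 0.11

    def test_duplicated_map_has_two_ridges(self, fixture_maps):
        mapping, _ = fixture_maps("duplicated")
        H, _, _ = projection_histogram(mapping, bins=20)
        mid = H[10]  # one NT column
        peaks = np.nonzero(mid > 0)[0]
        assert np.ptp(peaks) >= 4  # ridges separated by the offset

    def test_random_map_spreads_rows(self, fixture_maps):
        mapping, _ = fixture_maps("random")
        H, _, _ = projection_histogram(mapping, bins=10)
        row_spread = (H > 0).sum(axis=1)
        assert np.median(row_spread[2:-2]) >= 8


class TestMapping:
    def test_strongest_target_excludes_empty_rows(self, wt_small):
        W = np.zeros((wt_small.n_rgc, wt_small.n_sc))
        W[0, 5] = 2.0
        W[1, 7] = 1.0
        state = ConnectionState(W=W, w_min=0.5)
        mapping = strongest_target_mapping(state, wt_small)
        assert len(mapping) == 2
        assert mapping.n_excluded == wt_small.n_rgc - 2
        assert np.array_equal(mapping.rgc_index, [0, 1])

    def test_threshold_respected(self, wt_small):
        W = np.zeros((wt_small.n_rgc, wt_small.n_sc))
        W[0, 5] = 0.4  # below w_min
        state = ConnectionState(W=W, w_min=0.5)
        assert len(strongest_target_mapping(state, wt_small)) == 0
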