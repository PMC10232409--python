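import numpy as np
import pytest

from connectotype import synthetic as syn, variability as vb
from connectotype.atlas import Atlas
from connectotype.parcellation import IndividualParcellation, parcellate_subject
from connectotype.qc import ValidationError


def _parc(labels, n_rois):
    labels = np.asarray(labels, dtype=np.int64)
    return IndividualParcellation(network_of_vertex=np.ones_like(labels),
                                 roi_of_vertex=labels,
                                 provenance=np.ones_like(labels),
                                 n_rois=n_rois)


class TestSizeVariability:
    def test_identical_parcellations_zero(self, atlas162):
        p = _parc(atlas162.roi_of_vertex, 24)
        assert np.all(vb.size_variability([p, p, p]) == 0.0)

    def test_two_subject_hand_formula(self):
        # sizes 10 and 14 -> sample SD sqrt((2^2+2^2)/1) = 2.8284
        a = _parc([1] * 10 + [2] * 14, 2)
        b = _parc([1] * 14 + [2] * 10, 2)
        out = vb.size_variability([a, b])
        assert out[0] == pytest.approx(2.8284, abs=1e-4)

    def test_three_subject_hand_formula(self):
        parcs = [_parc([1] * n + [2] * (20 - n), 2) for n in (8, 10, 12)]
        assert vb.size_variability(parcs)[0] == pytest.approx(2.0)

    def test_unmatched_roi_counts_as_zero(self):
        a = _parc([1, 1, 2, 2], 2)
        b = _parc([1, 1, 1, 1], 2)  # ROI 2 unmatched -> size 0
        out = vb.size_variability([a, b])
        assert out[1] == pytest.approx(np.std([2, 0], ddof=1))


class TestPositionVariability:
    def test_identical_parcellations_zero(self, grid100):
        labels = (np.arange(100) // 50 + 1).astype(np.int64)
        p = _parc(labels, 2)
        out = vb.position_variability([p, p], grid100)
        np.testing.assert_allclose(out, 0.0)

    def test_centers_three_edges_apart(self, grid100):
        # single-vertex ROIs: the medoid is the vertex itself; unit-edge grid
        a = np.zeros(100, dtype=np.int64)
        b = np.zeros(100, dtype=np.int64)
        a[0] = 1
        b[3] = 1   # three edges along a row
        out = vb.position_variability([_parc(a, 1), _parc(b, 1)], grid100)
        assert out[0] == pytest.approx(3.0)

    def test_mean_over_subject_pairs(self, grid100):
        # centers at 0, 1, 3 along a row: pairwise distances 1, 2, 3 -> mean 2
        parcs = []
        for v in (0, 1, 3):
            lab = np.zeros(100, dtype=np.int64)
            lab[v] = 1
            parcs.append(_parc(lab, 1))
        assert vb.position_variability(parcs, grid100)[0] == pytest.approx(2.0)

    def test_scales_exactly_with_mesh(self, grid100):
        rng = np.random.default_rng(0)
        parcs = []
        for s in range(3):
            lab = np.zeros(100, dtype=np.int64)
            lab[rng.choice(100, 4, replace=False)] = 1
            parcs.append(_parc(lab, 1))
        base = vb.position_variability(parcs, grid100)
        scaled = vb.position_variability(parcs, grid100.scaled(2.5))
        np.testing.assert_allclose(scaled, 2.5 * base, rtol=1e-12)


class TestVertexVariability:
    def test_identical_subjects_zero(self, atlas162):
        rng = np.random.default_rng(1)
        prof = rng.normal(0, 1, (162, 24))
        per_vertex, per_roi = vb.vertex_variability([prof, prof.copy()], atlas162)
        np.testing.assert_allclose(per_vertex, 0.0, atol=1e-12)
        np.testing.assert_allclose(per_roi, 0.0, atol=1e-12)

    def test_known_profile_correlation(self, atlas162):
        # construct two subjects whose profiles at every vertex correlate 0.6
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (162, 24))
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(0, 1, (162, 24))
        per_vertex, _ = vb.vertex_variability([x, y], atlas162)
        # empirical 1 - r concentrates near 0.4
        assert abs(np.nanmean(per_vertex) - 0.4) < 0.1

    def test_planted_boundary_contrast(self, ico162, atlas162, geo162):
        # with network-boundary perturbation, boundary vertices should show
        # higher cross-subject profile variability than interior vertices
        profs = []
        netcov = np.full((6, 6), 0.1) + 0.5 * np.eye(6)
        for s in range(12):
            lab = syn.perturb_topography(atlas162, ico162, 1.5, seed=100 + s)
            sig, _ = syn.simulate_timeseries(lab, atlas162.network_of_roi, 120,
                                             netcov, 0.3, seed=200 + s)
            profs.append(vb.vertex_connectivity_profiles(sig, atlas162))
        per_vertex, _ = vb.vertex_variability(profs, atlas162)
        boundary = syn.truth_variability_map(atlas162, ico162) == 1.0
        assert np.nanmean(per_vertex[boundary]) > np.nanmean(per_vertex[~boundary])


class TestRoiConnectivityVariability:
    def test_identical_matrices_zero(self):
        m = np.random.default_rng(3).normal(0, 0.3, (5, 5))
        m = (m + m.T) / 2
        np.testing.assert_allclose(vb.roi_connectivity_variability([m, m, m]), 0.0,
                                   atol=1e-12)

    def test_single_varying_connection_hand_value(self):
        base = np.full((5, 5), 0.2)
        np.fill_diagonal(base, 1.0)
        a, b = base.copy(), base.copy()
        a[0, 2] = a[2, 0] = 0.2 + 0.2
        b[0, 2] = b[2, 0] = 0.2 - 0.2
        out = vb.roi_connectivity_variability([a, b])
        sd = np.std([0.4, 0.0], ddof=1)           # 0.2828...
        expected_endpoint = sd / 4                 # mean over 4 incident pairs
        assert out[0] == pytest.approx(expected_endpoint, abs=1e-12)
        assert out[2] == pytest.approx(expected_endpoint, abs=1e-12)
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(4)
        mats = [(lambda m: (m + m.T) / 2)(rng.normal(0, 0.3, (6, 6))) for _ in range(4)]
        a = vb.roi_connectivity_variability(mats)
        b = vb.roi_connectivity_variability(mats[::-1])
        np.testing.assert_allclose(a, b)


class TestCorrelateProfiles:
    def test_perfect_and_inverse_correlation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = vb.correlate_profiles(a, a)
        assert r == pytest.approx(1.0)
        r, p = vb.correlate_profiles(a, -a)
        assert r == pytest.approx(-1.0)

    def test_constant_input_reported_missing(self):
        r, p = vb.correlate_profiles(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    def test_size_coupled_profiles_correlate_above_uncoupled(self):
        # two-condition contrast: connectivity variability generated as a
        # linear function of size variability plus noise versus generated
        # independently of it
        rng = np.random.default_rng(12)
        size_var = rng.gamma(2.0, 1.5, size=116)
        coupled = 0.1 * size_var + rng.normal(0, 0.05, 116)
        uncoupled = 0.1 * rng.permutation(size_var) + rng.normal(0, 0.05, 116)
        r_coupled, _ = vb.correlate_profiles(size_var, np.abs(coupled))
        r_uncoupled, _ = vb.correlate_profiles(size_var, np.abs(uncoupled))
        assert r_coupled > r_uncoupled

    def test_boundary_shift_couples_size_and_connectivity_variability(
            self, ico162, atlas162, geo162):
        # in a shifted-topography cohort, the ROIs whose size varies most are
        # also the ROIs whose individual-specific connectivity varies most
        netcov = np.full((6, 6), 0.1) + 0.5 * np.eye(6)
        vm = syn.truth_variability_map(atlas162, ico162)
        from connectotype.connectome import connectivity_matrix
        from connectotype.parcellation import roi_timeseries
        parcs, mats = [], []
        for s in range(10):
            lab = syn.perturb_topography(atlas162, ico162, 1.5, seed=300 + s)
            sig, _ = syn.simulate_timeseries(lab, atlas162.network_of_roi,
                                             120, netcov, 0.4, seed=400 + s)
            p = parcellate_subject(sig, atlas162, ico162, vm,
                                   syn.truth_snr_map(0.4, 162), geodesics=geo162)
            parcs.append(p)
            ts, _ = roi_timeseries(sig, p.roi_of_vertex, 24)
            mats.append(connectivity_matrix(ts).values)
        r, _ = vb.correlate_profiles(vb.size_variability(parcs),
                                     vb.roi_connectivity_variability(mats))
        assert r > 0


def test_all_profiles_zero_on_degenerate_cohort(ico162, atlas162, geo162):
    # shift 0, noise 0: identical parcellations and matrices across subjects
    cfg_labels = atlas162.roi_of_vertex
    netcov = np.full((6, 6), 0.1) + 0.5 * np.eye(6)
    parcs, mats, profs = [], [], []
    from connectotype.connectome import connectivity_matrix
    from connectotype.parcellation import roi_timeseries
    for s in range(3):
        sig, _ = syn.simulate_timeseries(cfg_labels, atlas162.network_of_roi,
                                         100, netcov, 0.0, seed=77)  # same seed
        p = parcellate_subject(sig, atlas162, ico162,
                               syn.truth_variability_map(atlas162, ico162),
                               syn.truth_snr_map(0.0, 162), geodesics=geo162)
        parcs.append(p)
        ts, _ = roi_timeseries(sig, p.roi_of_vertex, 24)
        mats.append(connectivity_matrix(ts).values)
        profs.append(vb.vertex_connectivity_profiles(sig, atlas162))
    assert np.all(vb.size_variability(parcs) == 0)
    np.testing.assert_allclose(vb.position_variability(parcs, ico162, geo162), 0)
    np.testing.assert_allclose(vb.roi_connectivity_variability(mats), 0, atol=1e-12)
    pv, pr = vb.vertex_variability(profs, atlas162)
    np.testing.assert_allclose(pv, 0, atol=1e-10)
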