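import numpy as np
import pytest

from bordergrid import arena, deformation, metrics
from bordergrid.arena import E, N, S, W
from bordergrid.fixtures import hex_rate_pattern, make_fixtures


@pytest.fixture(scope="module")
def labelled_walk(square100):
    traj = arena.random_walk(square100, duration_s=120.0, seed=11)
    labels = arena.label_boundary_contacts(traj, square100)
    return traj, labels


@pytest.fixture(scope="module")
def walk_spikes(labelled_walk, rng):
    traj, _ = labelled_walk
    return np.sort(np.random.default_rng(5).uniform(0, traj.times_s[-1], 800))


class TestBoundaryRateMaps:
    def test_maps_built_per_contacted_boundary(self, labelled_walk,
                                               walk_spikes, square100):
        traj, labels = labelled_walk
        brm = deformation.boundary_rate_maps(traj, walk_spikes, labels,
                                             square100)
        contacted = set(np.unique(labels.labels)) - {arena.LABEL_NONE}
        for b in (N, S, E, W):
            assert (brm.maps[b] is not None) == (b in contacted)

    def test_single_boundary_path(self, square100):
        n = 200
        pts = np.column_stack([np.linspace(20, 80, n), np.full(n, 95.0)])
        traj = arena.Trajectory(np.arange(n) * 0.003, pts, 0.003)
        labels = arena.label_boundary_contacts(traj, square100)
        brm = deformation.boundary_rate_maps(traj, [0.1], labels, square100)
        assert brm.maps[N] is not None
        assert brm.maps[S] is None and brm.maps[E] is None

    def test_matched_occupancy_exact(self, labelled_walk, walk_spikes,
                                     square100):
        traj, labels = labelled_walk
        brm = deformation.boundary_rate_maps(traj, walk_spikes, labels,
                                             square100, matched=True, seed=0)
        pix = deformation._pixel_ids(traj, square100)
        n_pix = square100.raster_shape[0] * square100.raster_shape[1]
        for a, b in deformation.WALL_PAIRS.values():
            if brm.masks[a].any() and brm.masks[b].any():
                ca = deformation._per_pixel_counts(pix, brm.masks[a], n_pix)
                cb = deformation._per_pixel_counts(pix, brm.masks[b], n_pix)
                np.testing.assert_array_equal(ca, cb)  # exact integer match

    def test_prefirst_contact_excluded(self, labelled_walk, walk_spikes,
                                       square100):
        traj, labels = labelled_walk
        brm = deformation.boundary_rate_maps(traj, walk_spikes, labels,
                                             square100)
        none_mask = labels.labels == arena.LABEL_NONE
        for m in brm.masks.values():
            assert not (m & none_mask).any()


class TestGridShift:
    def test_identical_maps_zero_shift(self):
        m, meta = make_fixtures("hex_map", seed=1, spacing_cm=50.0)
        res = deformation.grid_shift(m, m, meta["scale_cm"], "x")
        assert res.shift_cm == 0.0
        assert res.shift_ratio == 0.0

    def test_known_translation_recovered(self):
        (a, b), meta = make_fixtures("shifted_pair", seed=2, delta_cm=5.0,
                                     dimension="x", spacing_cm=50.0)
        res = deformation.grid_shift(a, b, meta["scale_cm"], "x")
        assert res.shift_cm == pytest.approx(5.0, abs=2.5)

    def test_half_scale_translation_ratio_one(self):
        (a, b), meta = make_fixtures("shifted_pair", seed=3, delta_cm=25.0,
                                     dimension="x", spacing_cm=50.0,
                                     orientation_deg=0.0,
                                     phase_cm=(0.0, 0.0))
        res = deformation.grid_shift(a, b, meta["scale_cm"], "x")
        assert res.shift_ratio == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("seed", range(12))
    def test_shift_recovery_property(self, seed):
        rng = np.random.default_rng(seed)
        delta = float(rng.uniform(2.5, 20.0))
        dim = rng.choice(["x", "y"])
        (a, b), meta = make_fixtures("shifted_pair", seed=seed, delta_cm=delta,
                                     dimension=dim, spacing_cm=45.0)
        res = deformation.grid_shift(a, b, meta["scale_cm"], dim)
        assert res.shift_cm == pytest.approx(delta, abs=2.5)

    def test_undefined_without_positive_blob(self):
        a = np.outer(np.ones(30), np.linspace(0, 1, 30))
        b = -a
        res = deformation.grid_shift(a, b, 20.0, "x")
        assert not res.defined

    def test_matched_shift_zero_for_shared_process(self, labelled_walk,
                                                   walk_spikes, square100):
        traj, labels = labelled_walk
        m = hex_rate_pattern((40, 40), 50.0)
        res = deformation.grid_shift(m, m, 50.0, "x")
        assert res.shift_cm == 0.0


class TestAlignmentTest:
    def _compressed_setup(self):
        fam = hex_rate_pattern((40, 40), 50.0, orientation_deg=8.0)
        # deformed arena 70 cm wide: E-anchored crop of the familiar map
        e_map = fam[:, -28:]
        w_map = fam[:, :28]
        return fam, e_map, w_map

    def test_corresponding_wins_for_anchored_map(self):
        fam, e_map, w_map = self._compressed_setup()
        winner, rc, ro = deformation.alignment_test(e_map, fam, E, 100.0, 70.0)
        assert winner == "corresponding"
        assert rc > 0.99

    def test_opposite_wins_for_opposite_anchor(self):
        fam, e_map, w_map = self._compressed_setup()
        winner, rc, ro = deformation.alignment_test(w_map, fam, E, 100.0, 70.0)
        assert winner == "opposite"

    def test_undeformed_tie_goes_corresponding(self):
        fam = hex_rate_pattern((40, 40), 50.0)
        winner, rc, ro = deformation.alignment_test(fam, fam, E, 100.0, 100.0)
        assert winner == "corresponding"
        assert rc == pytest.approx(ro)


class TestRescalingFactor:
    def test_identity(self):
        fam = hex_rate_pattern((40, 40), 50.0)
        res = deformation.rescaling_factor(fam, fam, 100.0, 100.0, "x")
        assert res.factor == pytest.approx(1.0)
        assert np.isnan(res.normalized_pct)  # undefined for undeformed

    def test_candidate_grid_100_to_70(self):
        c = deformation.candidate_lengths(100.0, 70.0)
        np.testing.assert_allclose(c, np.arange(60.0, 111.0, 5.0))

    def test_known_compression_recovered(self):
        (fam, deformed), meta = make_fixtures("compressed_pair", seed=4,
                                              factor=0.7, spacing_cm=50.0)
        res = deformation.rescaling_factor(fam, deformed, meta["fam_len_cm"],
                                           meta["def_len_cm"], "x")
        assert res.factor == pytest.approx(0.7, abs=0.051)
        assert res.normalized_pct == pytest.approx(100.0, abs=18.0)

    @pytest.mark.parametrize("factor", [0.8, 0.9, 1.1])
    def test_recovery_across_factors(self, factor):
        (fam, deformed), meta = make_fixtures("compressed_pair", seed=5,
                                              factor=factor, spacing_cm=45.0,
                                              shape=(48, 40))
        res = deformation.rescaling_factor(fam, deformed, meta["fam_len_cm"],
                                           meta["def_len_cm"], "x")
        assert res.factor == pytest.approx(factor, abs=0.051)

    def test_two_phase_mixture_mechanism(self):
        # a boundary map that is a pure (unrescaled) phase-anchored crop keeps
        # factor ~1, while the two-phase whole-trial mixture looks rescaled
        # (< 1) when the grid spacing exceeds twice the boundary shift -- the
        # scale-dependent rescaling regime
        fam = hex_rate_pattern((40, 40), 70.0, orientation_deg=3.0)
        def_cols = 28  # 100 -> 70 cm compression
        e_crop = fam[:, -def_cols:]
        w_crop = fam[:, :def_cols]
        mixture = (e_crop + w_crop) / 2.0
        res_bound = deformation.rescaling_factor(fam, e_crop, 100.0, 70.0,
                                                 "x", alignments=E)
        res_whole = deformation.rescaling_factor(fam, mixture, 100.0, 70.0,
                                                 "x", alignments=E)
        assert res_bound.factor == pytest.approx(1.0, abs=0.051)
        assert res_whole.factor < res_bound.factor


class TestRescaleMap:
    def test_pitch_preserved(self):
        fam = hex_rate_pattern((40, 40), 50.0)
        out = deformation.rescale_map(fam, "x", 28)
        assert out.shape == (40, 28)

    def test_identity_when_same_size(self):
        fam = hex_rate_pattern((20, 20), 50.0)
        np.testing.assert_array_equal(deformation.rescale_map(fam, "x", 20), fam)

    def test_nan_propagation(self):
        fam = hex_rate_pattern((20, 20), 50.0)
        fam[:, 5] = np.nan
        out = deformation.rescale_map(fam, "x", 10)
        assert np.isfinite(out).sum() >= 10 * 18  # isolated NaNs bridged


class TestPrediction:
    def _setup(self):
        env_f = arena.make_environment("rectangle", 100.0, 100.0)
        env_d = arena.make_environment("rectangle", 70.0, 100.0)
        fam = hex_rate_pattern((40, 40), 50.0, orientation_deg=5.0)
        traj = arena.random_walk(env_d, duration_s=60.0, seed=3)
        labels = arena.label_boundary_contacts(traj, env_d)
        return env_f, env_d, fam, traj, labels

    def test_undeformed_prediction_is_smoothed_familiar(self, square100):
        fam = hex_rate_pattern((40, 40), 50.0)
        traj = arena.random_walk(square100, duration_s=60.0, seed=2)
        labels = arena.label_boundary_contacts(traj, square100)
        pred = deformation.predict_deformed_map(fam, traj, labels,
                                                square100, square100)
        expect = metrics.smooth_map(fam, np.ones_like(fam, dtype=bool))
        np.testing.assert_allclose(pred.rate, expect, atol=1e-9)
        assert pred.visited.all()  # all pixels retained

    def test_all_north_labels_single_crop(self):
        env_f, env_d, fam, traj, labels = self._setup()
        forced = arena.BoundaryContactLabels(
            labels=np.full(len(traj), N, dtype=np.int8))
        pred = deformation.predict_deformed_map(fam, traj, forced,
                                                env_f, env_d, smooth=False)
        crop = deformation._anchored_copy(fam, env_d.raster_shape, N)
        vis_rows, vis_cols = np.nonzero(np.isfinite(pred.rate) & (pred.rate != 0))
        got = pred.rate
        expect = np.where(np.isfinite(crop), crop, 0.0)
        # wherever the rat sampled, the prediction equals the north crop
        sampled = pred.occupancy_s > 0
        np.testing.assert_allclose(got[sampled], expect[sampled], atol=1e-9)

    def test_ew_mixture_lowers_peak(self):
        env_f, env_d, fam, traj, labels = self._setup()
        lab = np.where(np.arange(len(traj)) % 2 == 0, E, W).astype(np.int8)
        mixed = arena.BoundaryContactLabels(labels=lab)
        pred = deformation.predict_deformed_map(fam, traj, mixed, env_f, env_d,
                                                smooth=False)
        e_only = arena.BoundaryContactLabels(
            labels=np.full(len(traj), E, dtype=np.int8))
        pred_e = deformation.predict_deformed_map(fam, traj, e_only, env_f,
                                                  env_d, smooth=False)
        assert np.nanmax(pred.rate) < np.nanmax(pred_e.rate) + 1e-9
        assert np.nanmax(pred.rate) < 0.95 * np.nanmax(fam)

    def test_matched_rescaling_map_shapes(self):
        env_f, env_d, fam, traj, labels = self._setup()
        out = deformation.matched_rescaling_map(fam, env_d)
        assert out.shape == env_d.raster_shape

    def test_matched_rescaling_identity(self, square100):
        fam = hex_rate_pattern((40, 40), 50.0)
        out = deformation.matched_rescaling_map(fam, square100)
        np.testing.assert_allclose(out, fam)


class TestPredictionSimilarity:
    def test_identical_maps(self):
        m = hex_rate_pattern((30, 30), 40.0)
        r, z = deformation.prediction_similarity(m, m)
        assert r == pytest.approx(1.0)
        assert np.isfinite(z)

    def test_independent_noise_near_zero(self, rng):
        a = rng.normal(size=(40, 40))
        b = rng.normal(size=(40, 40))
        r, _ = deformation.prediction_similarity(a, b)
        assert abs(r) < 0.1

    def test_symmetry(self, rng):
        a = rng.normal(size=(20, 20))
        b = rng.normal(size=(20, 20)) + 0.5 * a
        r1, _ = deformation.prediction_similarity(a, b)
        r2, _ = deformation.prediction_similarity(b, a)
        assert r1 == pytest.approx(r2)


class TestPopulationVector:
    def test_identical_stacks(self, rng):
        stack = [rng.random((20, 20)) for _ in range(15)]
        r, cols = deformation.population_vector_correlation(stack, stack)
        np.testing.assert_allclose(r[np.isfinite(r)], 1.0)
        np.testing.assert_allclose(cols[np.isfinite(cols)], 1.0)

    def test_depression_near_displaced_wall(self, rng):
        # fields within 20 cm (8 px) of the east wall are scrambled;
        # elsewhere identical -> r depressed only near that wall
        fam = [rng.random((20, 20)) for _ in range(25)]
        deformed = []
        for m in fam:
            d = m.copy()
            d[:, -8:] = rng.random((20, 8))
            deformed.append(d)
        r, cols = deformation.population_vector_correlation(fam, deformed)
        assert np.nanmean(cols[:10]) > 0.95
        assert np.nanmean(cols[-6:]) < 0.5

    def test_unit_count_mismatch(self, rng):
        a = [rng.random((10, 10))] * 3
        b = [rng.random((10, 10))] * 4
        with pytest.raises(ValueError):
            deformation.population_vector_correlation(a, b)
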