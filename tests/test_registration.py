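"""Similarity metrics, robust transform estimation and registration."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from hsifuse.core_data import pseudo_rgb, to_grayscale
from hsifuse.registration import (MatchSet, RegistrationError, TransformModel,
                                  crop_common_roi, detect_features, estimate_msac,
                                  fit_transform, iqr, largest_interior_rectangle,
                                  match_features, mutual_information, pcc,
                                  register_features, register_intensity,
                                  select_transform_model, ssim, warp, warp_image)
from hsifuse.spectral_fusion import upsample_bilinear
from hsifuse.synthetic_scenes import SceneSpec, make_registration_target, zero_noise


def naive_ssim(a, b, win=7):
    """Independent sliding-window SSIM oracle (sample variance, uniform
    window, mean over fully interior windows)."""
    dr = max(a.max(), b.max()) - min(a.min(), b.min())
    c1, c2 = (0.01 * dr) ** 2, (0.03 * dr) ** 2
    np_ = win * win
    vals = []
    for i in range(a.shape[0] - win + 1):
        for j in range(a.shape[1] - win + 1):
            pa = a[i:i + win, j:j + win]
            pb = b[i:i + win, j:j + win]
            ua, ub = pa.mean(), pb.mean()
            va, vb = pa.var(ddof=1), pb.var(ddof=1)
            cov = ((pa - ua) * (pb - ub)).sum() / (np_ - 1)
            vals.append(((2 * ua * ub + c1) * (2 * cov + c2))
                        / ((ua ** 2 + ub ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


def textured(shape=(64, 64), seed=0, sigma=2.0):
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.standard_normal(shape), sigma)


class TestMetrics:
    def test_ssim_self_is_one(self):
        x = textured()
        assert ssim(x, x) == pytest.approx(1.0)

    def test_ssim_inverted_checkerboard_negative(self):
        x = np.indices((32, 32)).sum(axis=0) % 2 * 1.0
        assert ssim(x, 1 - x) < 0

    def test_ssim_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(size=(32, 32)), rng.uniform(size=(32, 32))
        assert ssim(a, b) == pytest.approx(naive_ssim(a, b), abs=1e-6)

    def test_mi_constant_images_zero(self):
        assert mutual_information(np.zeros((8, 8)), np.ones((8, 8))) == pytest.approx(0.0)

    def test_mi_self_equals_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(16, 16))
        hist, _ = np.histogram(x, bins=64)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mutual_information(x, x) == pytest.approx(entropy, abs=1e-9)

    def test_mi_hand_computed_one_bit(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert mutual_information(a, a, bins=2) == pytest.approx(1.0)

    def test_pcc_extremes(self):
        x = textured(seed=1)
        assert pcc(x, x) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_pcc_matches_textbook_formula(self):
        a = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 10.0]])
        b = np.array([[2.0, 1.0, 4.0], [3.0, 6.0, 5.0], [9.0, 7.0, 8.0]])
        af, bf = a.ravel(), b.ravel()
        num = ((af - af.mean()) * (bf - bf.mean())).sum()
        den = np.sqrt(((af - af.mean()) ** 2).sum() * ((bf - bf.mean()) ** 2).sum())
        assert pcc(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_pcc_constant_raises(self):
        with pytest.raises(ValueError):
            pcc(np.ones((4, 4)), textured(shape=(4, 4)))

    @pytest.mark.parametrize("metric", [ssim, mutual_information, pcc])
    def test_metrics_symmetric(self, metric):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(size=(24, 24)), rng.uniform(size=(24, 24))
        assert metric(a, b) == pytest.approx(metric(b, a), abs=1e-12)

    def test_iqr_linear_interpolation_quartiles(self):
        # sorted [1,2,3,4,100]: Q1 at position 1 -> 2, Q3 at position 3 -> 4
        assert iqr(np.array([1, 2, 3, 4, 100])) == pytest.approx(2.0)


class TestTransformModel:
    def test_non_projective_requires_affine_bottom_row(self):
        m = np.eye(3)
        m[2, 0] = 0.01
        with pytest.raises(ValueError, match="bottom row"):
            TransformModel("affine", m)

    def test_inverse_roundtrip(self):
        t = TransformModel("projective", np.array([[1.1, 0.1, 3.0],
                                                   [-0.05, 0.95, -2.0],
                                                   [1e-4, -2e-4, 1.0]]))
        pts = np.array([[3.0, 4.0], [10.0, 20.0]])
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_json_roundtrip(self, tmp_path):
        t = TransformModel("similarity", np.array([[0.9, -0.1, 2.0],
                                                   [0.1, 0.9, -1.0],
                                                   [0.0, 0.0, 1.0]]),
                           {"technique": "test"})
        t.to_json(tmp_path / "t.json")
        back = TransformModel.from_json(tmp_path / "t.json")
        np.testing.assert_allclose(back.matrix, t.matrix)
        assert back.kind == "similarity"


class TestIntensityRegistration:
    def test_identity_recovered(self):
        img = textured((64, 64), seed=2)
        t = register_intensity(img, img, kind="translation")
        assert np.abs(t.matrix[:2, 2]).max() < 0.1

    def test_translation_recovered(self):
        rng = np.random.default_rng(4)
        blob_img = gaussian_filter(rng.standard_normal((96, 96)), 3.0)
        fixed = blob_img[8:72, 8:72]
        moving = blob_img[8 + 3:72 + 3, 8 + 5:72 + 5]   # moving(r,c) = fixed(r+3,c+5)
        t = register_intensity(fixed, moving, kind="translation", levels=2)
        np.testing.assert_allclose(t.matrix[:2, 2], [5.0, 3.0], atol=0.25)

    def test_similarity_rotation_recovered(self):
        truth = TransformModel("similarity", np.array(
            [[np.cos(np.deg2rad(4)), -np.sin(np.deg2rad(4)), 0.0],
             [np.sin(np.deg2rad(4)), np.cos(np.deg2rad(4)), 0.0],
             [0.0, 0.0, 1.0]]))
        fixed = textured((80, 80), seed=5, sigma=3.0)
        moving, _ = warp_image(fixed, truth.inverse(), fixed.shape)
        t = register_intensity(fixed, moving, kind="similarity", levels=2)
        angle = np.rad2deg(np.arctan2(t.matrix[1, 0], t.matrix[0, 0]))
        assert angle == pytest.approx(4.0, abs=0.2)


class TestFeatures:
    def test_constant_image_no_features(self):
        assert len(detect_features(np.full((32, 32), 0.5))) == 0

    def test_detection_deterministic(self):
        img = textured((64, 64), seed=6, sigma=1.5)
        a, b = detect_features(img), detect_features(img)
        np.testing.assert_array_equal(a.keypoints, b.keypoints)

    def test_rotated_copy_matches_majority(self, registration_scene):
        from skimage.transform import rotate
        img = to_grayscale(pseudo_rgb(registration_scene.vnir))
        rot = rotate(img, 10, mode="reflect")
        f, m = detect_features(img), detect_features(rot)
        matches = match_features(f, m)
        # match fraction over distinct keypoint locations (multi-orientation
        # keypoints share coordinates and are deduplicated by the matcher)
        n_f = len(np.unique(f.keypoints, axis=0))
        n_m = len(np.unique(m.keypoints, axis=0))
        assert len(matches) / min(n_f, n_m) >= 0.5

    def test_self_match_is_identity_pairing(self):
        img = textured((64, 64), seed=8, sigma=1.5)
        f = detect_features(img)
        matches = match_features(f, f)
        np.testing.assert_array_equal(matches.fixed_points, matches.moving_points)
        assert len(matches) == len(np.unique(f.keypoints, axis=0))

    def test_zero_ratio_empty(self):
        rng = np.random.default_rng(9)
        from hsifuse.registration import Features
        a = Features(rng.uniform(size=(5, 2)), rng.uniform(size=(5, 16)))
        b = Features(rng.uniform(size=(5, 2)), rng.uniform(size=(5, 16)))
        assert len(match_features(a, b, ratio=0.0)) == 0

    def test_mser_detects_regions(self, registration_scene):
        img = to_grayscale(pseudo_rgb(registration_scene.vnir))
        feats = detect_features(img, "mser")
        assert len(feats) >= 4


class TestMSAC:
    def _exact_matches(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        truth = TransformModel("projective", np.array([[1.05, 0.02, 4.0],
                                                       [-0.03, 0.97, -2.0],
                                                       [2e-4, -1e-4, 1.0]]))
        moving = rng.uniform(5, 95, size=(n, 2))
        fixed = truth.apply(moving)
        return truth, MatchSet(fixed, moving, np.zeros(n))

    def test_outlier_free_matches_least_squares(self):
        truth, matches = self._exact_matches()
        est = estimate_msac(matches, "projective", seed=0, trials=200)
        lsq = fit_transform(matches.fixed_points, matches.moving_points, "projective")
        for m in (est.matrix, lsq.matrix, truth.matrix):
            assert m[2, 2] == pytest.approx(1.0)
        assert np.linalg.norm(est.matrix - lsq.matrix) < 1e-6
        assert np.linalg.norm(est.matrix - truth.matrix) < 1e-6

    def test_outliers_all_excluded(self):
        truth, matches = self._exact_matches(seed=1, n=28)
        rng = np.random.default_rng(2)
        n_out = 12  # 30% of the total 40
        out_moving = rng.uniform(5, 95, size=(n_out, 2))
        out_fixed = truth.apply(out_moving) + rng.uniform(15, 40, size=(n_out, 2))
        all_fixed = np.vstack([matches.fixed_points, out_fixed])
        all_moving = np.vstack([matches.moving_points, out_moving])
        est = estimate_msac(MatchSet(all_fixed, all_moving, np.zeros(40)),
                            "projective", seed=3, trials=500, inlier_tol_px=1.5)
        inliers = np.array(est.provenance["inlier_mask"])
        assert not inliers[28:].any()          # every outlier excluded
        assert inliers[:28].all()
        assert est.provenance["inlier_rmse_px"] < 1.5

    def test_seed_determinism(self):
        _, matches = self._exact_matches(seed=4)
        a = estimate_msac(matches, "projective", seed=11, trials=100)
        b = estimate_msac(matches, "projective", seed=11, trials=100)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_too_few_matches_signaled(self):
        with pytest.raises(RegistrationError, match="matches"):
            estimate_msac(MatchSet(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2)),
                          "projective")


class TestRegisterFeatures:
    def test_identity_on_identical_images(self, registration_scene):
        img = to_grayscale(pseudo_rgb(registration_scene.vnir))
        t = register_features(img, img, seed=0, trials=100)
        pts = np.array([[10.0, 10.0], [100.0, 50.0], [60.0, 110.0]])
        np.testing.assert_allclose(t.apply(pts), pts, atol=0.05)

    def test_recovers_synthetic_projective(self):
        """Median control-point RMSE under 0.5 px across random projective
        truths at 128x128."""
        rmses = []
        for seed in range(5):
            pair = make_registration_target(
                SceneSpec(seed=seed, vnir_dims=(128, 128), nir_dims=(64, 64)))
            fixed = to_grayscale(pseudo_rgb(pair.vnir))
            moving = to_grayscale(pseudo_rgb(
                upsample_bilinear(pair.nir, pair.vnir.shape[:2])))
            t = register_features(fixed, moving, seed=0, trials=500)
            vr, vc = pair.vnir.shape[:2]
            nr, nc = pair.nir.shape[:2]
            down = np.diag([(nc - 1) / (vc - 1), (nr - 1) / (vr - 1), 1.0])
            cp_vnir = pair.meta["control_points_vnir"]
            cp_up = pair.meta["control_points_nir"] @ np.linalg.inv(down)[:2, :2].T
            rmses.append(np.sqrt(np.mean(
                np.sum((t.apply(cp_up) - cp_vnir) ** 2, axis=1))))
        assert np.median(rmses) < 0.5

    def test_blob_projective_beats_mser_similarity(self):
        """Scale-covariant blobs + projective outperform stable extremal
        regions + similarity in mean post-registration SSIM."""
        blob, mser = [], []
        for seed in range(10):
            pair = make_registration_target(
                SceneSpec(seed=seed, vnir_dims=(128, 128), nir_dims=(64, 64)))
            fixed = to_grayscale(pseudo_rgb(pair.vnir))
            moving = to_grayscale(pseudo_rgb(
                upsample_bilinear(pair.nir, pair.vnir.shape[:2])))
            base = ssim(fixed, moving)
            for det, kind, acc in (("blob", "projective", blob),
                                   ("mser", "similarity", mser)):
                try:
                    t = register_features(fixed, moving, detector=det, kind=kind,
                                          seed=0, trials=300)
                    w, mask = warp_image(moving, t, fixed.shape)
                    r0, r1, c0, c1 = largest_interior_rectangle(mask)
                    acc.append(ssim(fixed[r0:r1, c0:c1], w[r0:r1, c0:c1]))
                except RegistrationError:
                    acc.append(base)
        assert np.mean(blob) >= np.mean(mser)


class TestWarpAndRoi:
    def test_identity_warp_unchanged(self, small_cube):
        out, mask = warp(small_cube, TransformModel.identity(), small_cube.shape[:2])
        np.testing.assert_allclose(out.data, small_cube.data, atol=1e-9)
        assert mask.all()

    def test_integer_translation_exact_shift(self, rng):
        from hsifuse.core_data import HSCube
        cube = HSCube(rng.uniform(size=(16, 16, 3)), [500.0, 600.0, 700.0])
        m = np.eye(3)
        m[0, 2], m[1, 2] = 2.0, 3.0
        out, mask = warp(cube, TransformModel("translation", m), (16, 16))
        np.testing.assert_allclose(out.data[3:, 2:, :], cube.data[:-3, :-2, :], atol=1e-9)
        assert not mask[:3, :].any() and not mask[:, :2].any()

    def test_warp_inverse_roundtrip_interior(self, rng):
        from hsifuse.core_data import HSCube
        data = gaussian_filter(rng.standard_normal((32, 32, 2)), (2, 2, 0)) + 2.0
        cube = HSCube(data, [500.0, 600.0])
        t = TransformModel("projective", np.array([[1.02, 0.01, 1.5],
                                                   [-0.01, 0.98, -0.8],
                                                   [1e-4, 5e-5, 1.0]]))
        fwd, _ = warp(cube, t, (32, 32))
        back, mask = warp(fwd, t.inverse(), (32, 32))
        interior = np.zeros((32, 32), dtype=bool)
        interior[4:-4, 4:-4] = True
        interior &= mask
        mae = np.abs(back.data - cube.data)[interior].mean()
        grad_bound = np.abs(np.diff(data, axis=0)).max()
        assert mae < 2 * grad_bound

    def test_full_mask_no_crop(self, small_cube):
        f, w = crop_common_roi(small_cube, small_cube, np.ones(small_cube.shape[:2], bool))
        assert f.shape == small_cube.shape

    def test_missing_rows_cropped(self, rng):
        from hsifuse.core_data import HSCube
        cube = HSCube(rng.uniform(size=(20, 12, 3)), [500.0, 600.0, 700.0])
        mask = np.ones((20, 12), bool)
        mask[:10, :] = False
        f, w = crop_common_roi(cube, cube, mask)
        assert f.shape[:2] == (10, 12)
        np.testing.assert_array_equal(f.data, cube.data[10:])

    def test_largest_rectangle_matches_brute_force(self, rng):
        mask = rng.random((32, 32)) > 0.25
        r0, r1, c0, c1 = largest_interior_rectangle(mask)
        assert mask[r0:r1, c0:c1].all()
        best = (r1 - r0) * (c1 - c0)
        integral = np.pad(mask.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
        brute = 0
        for i0 in range(32):
            for i1 in range(i0 + 1, 33):
                for j0 in range(32):
                    for j1 in range(j0 + 1, 33):
                        area = (i1 - i0) * (j1 - j0)
                        if area <= brute:
                            continue
                        s = (integral[i1, j1] - integral[i0, j1]
                             - integral[i1, j0] + integral[i0, j0])
                        if s == area:
                            brute = area
        assert best == brute


@pytest.fixture(scope="module")
def noisy_edge_search():
    """Band search on a scene where only bands 7-13 (VNIR) and 3-6 (NIR)
    are clean; everything else carries 50x noise."""
    from hsifuse.registration import coarse_to_fine_band_search

    def profile(wl):
        wl = np.asarray(wl)
        clean = ((wl >= 610) & (wl <= 815)) | ((wl >= 1190) & (wl <= 1510))
        return np.where(clean, 0.005, 0.25)

    spec = SceneSpec(seed=2, vnir_dims=(64, 64), nir_dims=(48, 48),
                     vnir_grid=np.linspace(400, 1000, 20),
                     nir_grid=np.linspace(900, 1700, 9),
                     noise_profile=profile)
    pair = make_registration_target(spec)
    return coarse_to_fine_band_search(pair.vnir, pair.nir, (7, 3),
                                      seed=0, trials=100)


class TestBandSearch:
    def test_coarse_grid_dims_follow_steps(self, noisy_edge_search):
        assert noisy_edge_search.grid.shape == (int(np.ceil(20 / 7)), int(np.ceil(9 / 3)))

    def test_best_pair_in_clean_region(self, noisy_edge_search):
        bi, bj = noisy_edge_search.best_pair
        assert 7 <= bi <= 13 and 3 <= bj <= 6

    def test_fine_improves_or_ties_coarse(self, noisy_edge_search):
        coarse_best = np.nanmax(noisy_edge_search.grid)
        assert noisy_edge_search.best_score >= coarse_best - 1e-12

    def test_best_score_is_fine_grid_max(self, noisy_edge_search):
        assert noisy_edge_search.best_score == pytest.approx(
            np.nanmax(noisy_edge_search.fine_grid))


class TestSelectTransformModel:
    def test_single_candidate_returned(self):
        t = TransformModel.identity("projective")
        winner, report = select_transform_model([t], [])
        assert winner is t

    def test_true_transform_wins_over_perturbed(self):
        truth = random_truth = None
        dataset = []
        for seed in range(3):
            spec = SceneSpec(seed=seed, vnir_dims=(64, 64), nir_dims=(48, 48),
                             true_transform=_shared_truth())
            dataset.append(make_registration_target(spec))
        truth = dataset[0].true_transform
        # candidates act on raw NIR coords; perturb translation by 4 px
        pm = truth.matrix.copy()
        pm[0, 2] += 4.0
        perturbed = TransformModel("projective", pm)
        winner, report = select_transform_model([truth, perturbed], dataset)
        assert winner is truth
        assert report["iqr"][0] <= report["iqr"][1]
        assert report["mean"][0] > report["mean"][1]


def _shared_truth():
    m = np.array([[1.36, 0.03, 2.0],
                  [-0.02, 1.34, 1.0],
                  [1e-4, -1e-4, 1.0]])
    return TransformModel("projective", m)
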