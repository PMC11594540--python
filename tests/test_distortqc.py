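"""Expansion factor, registration recovery, error curves, plate ANOVA."""

import numpy as np
import pytest
from scipy import stats

from exmplate import distortqc, synthim
from exmplate.distortqc import DeformationField, SimilarityParams


def make_field(displacement, mask=None, pixel_size=1.0):
    d = np.asarray(displacement, dtype=float)
    if mask is None:
        mask = np.ones(d.shape[1:], bool)
    return DeformationField(
        displacement=d,
        feature_mask=mask,
        similarity=SimilarityParams(scale=1.0, rotation=0.0, translation=(0.0, 0.0)),
        pixel_size=pixel_size,
    )


class TestExpansionFactor:
    def test_single_pair_ratio(self):
        est = distortqc.estimate_expansion_factor([(((0, 0), (0, 10)), ((0, 0), (0, 42)))])
        assert est.factor == pytest.approx(4.2)

    def test_identity_landmarks(self):
        pairs = [(((0, 0), (3, 4)), ((0, 0), (3, 4)))]
        assert distortqc.estimate_expansion_factor(pairs).factor == 1.0

    def test_coincident_pre_landmarks_rejected(self):
        with pytest.raises(ValueError):
            distortqc.estimate_expansion_factor([(((1, 1), (1, 1)), ((0, 0), (5, 5)))])

    def test_recovery_from_synthetic_pair(self, multi_nucleus_field):
        pre, post, _ = synthim.make_expansion_pair(
            multi_nucleus_field, scale=4.16, deform_amplitude=0.0, seed=4
        )
        pts_pre = distortqc.detect_landmarks(pre.planes[0], min_area=50)
        pts_post = distortqc.detect_landmarks(post.planes[0], min_area=50)
        est = distortqc.estimate_expansion_factor(
            distortqc.match_landmarks(pts_pre, pts_post)
        )
        assert est.factor == pytest.approx(4.16, rel=0.01)


class TestRegisterNonrigid:
    def test_identity_pair(self, multi_nucleus_field):
        img = multi_nucleus_field.planes[0]
        f = distortqc.register_nonrigid(img, img)
        assert f.similarity.scale == pytest.approx(1.0, abs=0.01)
        assert abs(f.similarity.rotation) < 0.01
        assert np.hypot(*f.displacement)[f.feature_mask].max() < 0.1

    def test_pure_scale_recovered(self, multi_nucleus_field):
        pre, post, _ = synthim.make_expansion_pair(
            multi_nucleus_field, scale=4.0, deform_amplitude=0.0, seed=1
        )
        f = distortqc.register_nonrigid(pre.planes[0], post.planes[0])
        assert f.similarity.scale == pytest.approx(4.0, rel=0.01)
        assert np.hypot(*f.displacement)[f.feature_mask].mean() < 0.5

    def test_known_sinusoidal_field_recovered(self, multi_nucleus_field):
        field = synthim.sinusoidal_field((400, 400), amplitude=2.0, smoothness=50.0)
        pre, post, truth = synthim.make_expansion_pair(
            multi_nucleus_field, scale=1.0, displacement=field, seed=1
        )
        f = distortqc.register_nonrigid(pre.planes[0], post.planes[0])
        m = f.feature_mask
        tr = truth.displacement - truth.displacement[:, m].mean(axis=1)[:, None, None]
        epe = np.hypot(*(f.displacement - tr))[m]
        assert epe.mean() < 0.5

    def test_zero_mean_over_feature_mask(self, multi_nucleus_field):
        pre, post, _ = synthim.make_expansion_pair(
            multi_nucleus_field, scale=1.0, deform_amplitude=2.0, smoothness=60.0, seed=8
        )
        f = distortqc.register_nonrigid(pre.planes[0], post.planes[0])
        assert np.allclose(f.displacement[:, f.feature_mask].mean(axis=1), 0.0, atol=1e-9)

    def test_featureless_pair_unregistrable(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (128, 128))
        b = rng.normal(0, 1, (128, 128))
        with pytest.raises(distortqc.UnregistrableError):
            distortqc.register_nonrigid(a, b, corr_floor=0.2)


class TestErrorCurve:
    def test_zero_field(self):
        f = make_field(np.zeros((2, 100, 100)))
        c = distortqc.error_curve(f, n_pairs_per_bin=200, bin_width=5.0, seed=0)
        assert np.allclose(c.rmse, 0.0)
        assert c.average_percent_error == 0.0

    def test_uniform_translation_invisible(self):
        f = make_field(np.broadcast_to(np.array([2.0, -1.0])[:, None, None], (2, 80, 80)))
        c = distortqc.error_curve(f, n_pairs_per_bin=200, bin_width=5.0, seed=0)
        assert np.allclose(c.rmse, 0.0)

    @pytest.mark.parametrize("eps", [0.01, 0.03])
    def test_linear_field_closed_form(self, eps):
        """d(x) = eps * x gives pair error eps*l exactly, so rmse(l) = eps*l
        and the average percent error is 100*eps."""
        rr, cc = np.mgrid[0:150, 0:150].astype(float)
        f = make_field(np.stack([eps * rr, eps * cc]))
        c = distortqc.error_curve(f, n_pairs_per_bin=500, bin_width=5.0, cutoff=100.0, seed=1)
        assert np.allclose(c.rmse, eps * c.lengths, rtol=1e-9)
        assert c.average_percent_error == pytest.approx(100 * eps, rel=1e-9)

    def test_seeded_and_deterministic(self):
        f = make_field(np.random.default_rng(1).normal(0, 1, (2, 60, 60)))
        c1 = distortqc.error_curve(f, seed=7, n_pairs_per_bin=100, bin_width=5.0)
        c2 = distortqc.error_curve(f, seed=7, n_pairs_per_bin=100, bin_width=5.0)
        assert np.array_equal(c1.rmse, c2.rmse)
        assert c1.average_percent_error == c2.average_percent_error

    def test_cutoff_without_bins_rejected(self):
        f = make_field(np.zeros((2, 50, 50)), pixel_size=10.0)
        with pytest.raises(ValueError):
            distortqc.error_curve(f, cutoff=1.0, bin_width=2.0, n_pairs_per_bin=50)

    def test_error_independent_of_distance_to_center(self):
        """Fields with identical deformation statistics placed at different
        distances from the gel center show no error-vs-distance trend."""
        rng = np.random.default_rng(11)
        distances, apes = [], []
        for i in range(24):
            d = synthim.smooth_random_field((80, 80), amplitude=1.5, smoothness=20.0,
                                            seed=int(rng.integers(2**31)))
            c = distortqc.error_curve(make_field(d), n_pairs_per_bin=300, bin_width=5.0,
                                      cutoff=60.0, seed=i)
            distances.append(rng.uniform(0, 100))
            apes.append(c.average_percent_error)
        r = stats.linregress(distances, apes)
        assert r.rvalue**2 < 0.3


class TestComparePlates:
    def test_identical_plates_null(self):
        res = distortqc.compare_plates({"p1": [1, 2, 3], "p2": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.pairwise["significant"].any()

    def test_outlier_plate_detected(self):
        res = distortqc.compare_plates(
            {"p1": [1, 2, 3], "p2": [1, 2, 3], "p3": [10, 11, 12]}
        )
        assert res.p_value < 0.05
        sig = res.pairwise.set_index(["plate_a", "plate_b"])["significant"]
        assert sig[("p1", "p3")] and sig[("p2", "p3")] and not sig[("p1", "p2")]

    def test_two_groups_f_equals_t_squared(self):
        a, b = [1.0, 2.0, 2.5, 3.0], [2.5, 3.5, 4.0, 5.0]
        res = distortqc.compare_plates({"p1": a, "p2": b})
        t, _ = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)

    def test_short_group_rejected(self):
        with pytest.raises(ValueError):
            distortqc.compare_plates({"p1": [1.0], "p2": [1.0, 2.0]})
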