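import numpy as np
import pytest

from syntroscan.grouping import (
    ConfidenceEllipse,
    EllipseGroupClassifier,
    contains,
    fit_ellipse,
    intersection_area,
    overlap_fraction,
)

CHI2_95 = -2 * np.log(0.05)  # closed-form chi^2_2 0.95 quantile


def unit_ellipse(center=(0.0, 0.0), level=0.95):
    return ConfidenceEllipse(
        group_label="u",
        center=np.asarray(center, float),
        shape=np.eye(2),
        level=level,
        radius_sq=-2 * np.log(1 - level),
    )


class TestFitEllipse:
    def test_radius_matches_closed_form_quantile(self, rng):
        pts = rng.standard_normal(size=(10_000, 2))
        e = fit_ellipse(pts, level=0.95)
        assert e.radius_sq == pytest.approx(CHI2_95, abs=1e-6)
        assert np.linalg.norm(e.center) < 0.05

    def test_identical_points_give_singular_covariance(self):
        pts = np.ones((3, 2))
        with pytest.raises(ValueError, match="singular covariance"):
            fit_ellipse(pts)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="singular covariance"):
            fit_ellipse(pts)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_affine_equivariance_of_membership(self, rng):
        pts = rng.standard_normal(size=(200, 2))
        test = rng.standard_normal(size=(500, 2))
        A = np.array([[2.0, 0.7], [-0.3, 1.5]])
        b = np.array([5.0, -2.0])
        e = fit_ellipse(pts)
        eT = fit_ellipse(pts @ A.T + b)
        # untransformed oracle: membership decisions must map 1:1
        assert np.array_equal(e.contains(test), eT.contains(test @ A.T + b))

    def test_level_monotonicity(self, rng):
        pts = rng.standard_normal(size=(50, 2)) @ np.array([[1.5, 0.3], [0.0, 0.7]])
        lo = fit_ellipse(pts, level=0.90)
        hi = fit_ellipse(pts, level=0.99)
        assert hi.radius_sq > lo.radius_sq
        # every boundary point of the 0.90 ellipse is interior to the 0.99 one
        assert np.all(hi.contains(lo.boundary(128)))

    def test_t_family_is_wider_than_normal_at_small_n(self, rng):
        pts = rng.standard_normal(size=(10, 2))
        e_norm = fit_ellipse(pts, family="normal")
        e_t = fit_ellipse(pts, family="t")
        assert e_t.radius_sq > e_norm.radius_sq


class TestContains:
    def test_center_is_inside(self, rng):
        e = fit_ellipse(rng.standard_normal(size=(20, 2)))
        assert contains(e, e.center)

    def test_point_just_outside_unit_ellipse(self):
        e = unit_ellipse()
        r = np.sqrt(CHI2_95)
        assert contains(e, [r - 0.01, 0.0])
        assert not contains(e, [r + 0.01, 0.0])

    def test_central_symmetry(self, rng):
        e = fit_ellipse(rng.standard_normal(size=(30, 2)))
        p = e.center + np.array([0.3, -0.2])
        reflected = 2 * e.center - p
        assert contains(e, p) == contains(e, reflected)

    def test_boundary_vertices_on_the_boundary(self, rng):
        pts = rng.standard_normal(size=(40, 2)) @ np.array([[2.0, 0.0], [0.5, 0.8]])
        e = fit_ellipse(pts)
        d2 = e.mahalanobis_sq(e.boundary(64))
        assert np.allclose(d2, e.radius_sq, atol=1e-9)


class TestOverlap:
    def test_identical_ellipses(self):
        e = unit_ellipse()
        assert overlap_fraction(e, e, method="grid") == pytest.approx(1.0, abs=0.01)
        assert overlap_fraction(e, e, method="monte_carlo", seed=1) == pytest.approx(
            1.0, abs=0.01
        )

    def test_distant_ellipses_do_not_overlap(self):
        e1 = unit_ellipse((0.0, 0.0))
        e2 = unit_ellipse((100.0, 0.0))
        assert overlap_fraction(e1, e2, method="grid") == 0.0
        assert overlap_fraction(e1, e2, method="monte_carlo", seed=1) == 0.0

    def test_grid_and_monte_carlo_agree(self):
        e1 = unit_ellipse((0.0, 0.0))
        e2 = unit_ellipse((2.0, 0.0))
        grid = overlap_fraction(e1, e2, method="grid", resolution=512)
        mc = overlap_fraction(e1, e2, method="monte_carlo",
                              n_samples=200_000, seed=7)
        assert abs(grid - mc) < 0.02

    def test_area_formula(self):
        e = unit_ellipse()
        assert e.area == pytest.approx(np.pi * CHI2_95)
        inter = intersection_area(e, e, method="grid", resolution=512)
        assert inter == pytest.approx(e.area, rel=0.01)

    def test_invalid_resolution(self):
        e = unit_ellipse()
        with pytest.raises(ValueError, match="resolution"):
            overlap_fraction(e, e, method="grid", resolution=2)
        with pytest.raises(ValueError, match="method"):
            overlap_fraction(e, e, method="exact")


class TestClassifier:
    @pytest.fixture()
    def fitted(self, rng):
        syn = rng.standard_normal(size=(30, 2)) + [6.0, 6.0]
        non = rng.standard_normal(size=(40, 2))
        X = np.vstack([syn, non])
        y = ["potentially_syntrophic"] * 30 + ["non_syntrophic"] * 40
        return EllipseGroupClassifier(level=0.95).fit(X, y)

    def test_calls_are_consistent_with_memberships(self, fitted):
        e_syn, e_non = fitted.ellipses_
        pts = np.array([[6.0, 6.0], [0.0, 0.0], [100.0, 100.0], [3.0, 3.0]])
        for r in fitted.classify(pts):
            if r.in_syntrophic and r.in_non_syntrophic:
                assert r.call == "ambiguous"
            elif r.in_syntrophic:
                assert r.call == "syntrophic"
            elif r.in_non_syntrophic:
                assert r.call == "non_syntrophic"
            else:
                assert r.call == "neither"

    def test_separated_groups_classified_by_their_own_ellipse(self, fitted):
        assert fitted.predict([[6.0, 6.0]])[0] == "syntrophic"
        assert fitted.predict([[0.0, 0.0]])[0] == "non_syntrophic"
        assert fitted.predict([[100.0, -50.0]])[0] == "neither"

    def test_overlapping_groups_give_ambiguous_calls(self, rng):
        a = rng.standard_normal(size=(50, 2))
        b = rng.standard_normal(size=(50, 2)) + [0.5, 0.0]
        y = ["syntrophic_culture"] * 50 + ["non_syntrophic"] * 50
        clf = EllipseGroupClassifier().fit(np.vstack([a, b]), y)
        assert clf.predict([[0.25, 0.0]])[0] == "ambiguous"
        assert clf.overlap(method="grid") > 0.5

    def test_other_samples_excluded_from_ellipse_fit(self, rng):
        syn = rng.standard_normal(size=(20, 2)) + [6.0, 6.0]
        non = rng.standard_normal(size=(20, 2))
        far = np.full((5, 2), 1e3)  # extreme "other" samples
        X = np.vstack([syn, non, far])
        y = (["syntrophic_culture"] * 20 + ["non_syntrophic"] * 20
             + ["other"] * 5)
        clf = EllipseGroupClassifier().fit(X, y)
        e_syn, e_non = clf.ellipses_
        # ellipses unaffected by the extreme points
        assert np.linalg.norm(e_syn.center - [6, 6]) < 1.0
        assert np.linalg.norm(e_non.center) < 1.0


def test_coverage_of_held_out_normal_points(rng):
    """0.95 ellipse fitted on 10^3 points covers ~95% of 10^4 new points."""
    cov = np.array([[2.0, 0.6], [0.6, 1.0]])
    L = np.linalg.cholesky(cov)
    train = rng.standard_normal(size=(1000, 2)) @ L.T
    test = rng.standard_normal(size=(10_000, 2)) @ L.T
    e = fit_ellipse(train, level=0.95)
    frac = np.mean(e.contains(test))
    assert 0.94 <= frac <= 0.96
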