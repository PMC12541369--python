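"""SMLM filtering, model densities, ML fitting and normAICc selection."""

import numpy as np
import pandas as pd
import pytest

from meioquant import (
    EllipseParams,
    LocalizationCloud,
    classify_focus,
    filter_localizations,
    fit_shape_model,
    gen_focus_localizations,
    hollow_fraction,
    model_density,
    norm_aicc,
)
from meioquant.smlm import _rotation, default_init


def make_cloud(x, y, z=None, prec_xy=5.0, prec_z=10.0, focus_id="f") -> LocalizationCloud:
    x = np.asarray(x, dtype=float)
    n = x.size
    return LocalizationCloud(
        focus_id,
        pd.DataFrame(
            {
                "x_nm": x,
                "y_nm": np.asarray(y, dtype=float),
                "z_nm": np.zeros(n) if z is None else np.asarray(z, dtype=float),
                "locprec_nm": np.broadcast_to(prec_xy, n).astype(float),
                "locprec_z_nm": np.broadcast_to(prec_z, n).astype(float),
                "channel": "msh5",
            }
        ),
    )


class TestFilterLocalizations:
    def test_precision_boundary_is_inclusive(self):
        """Exclusion is strictly >15 nm lateral (and >25 nm axial): a
        localization at exactly the bound stays."""
        cloud = make_cloud([0, 1, 2], [0, 0, 0], prec_xy=1.0)
        cloud.data.loc[0, "locprec_nm"] = 15.0
        cloud.data.loc[1, "locprec_nm"] = 15.1
        cloud.data.loc[2, "locprec_z_nm"] = 25.1
        out = filter_localizations(cloud)
        assert list(out.data["x_nm"]) == [0.0]

    def test_z_window_around_median(self):
        z = [0, 100, -100, 700, -700]
        cloud = make_cloud(np.arange(5), np.zeros(5), z=z)
        out = filter_localizations(cloud, z_halfwindow=300)
        assert list(out.data["z_nm"]) == [0, 100, -100]

    def test_empty_input_empty_output(self):
        cloud = make_cloud([], [])
        assert len(filter_localizations(cloud)) == 0

    def test_order_preserved(self):
        cloud = make_cloud([3, 1, 2], [0, 0, 0])
        out = filter_localizations(cloud)
        assert list(out.data["x_nm"]) == [3, 1, 2]


class TestModelDensity:
    def test_filled_zero_precision_closed_form(self, canonical_ellipse):
        """Zero blur: uniform disk density 1/(pi*a*b) inside, 0 outside."""
        d_in = model_density("filled", canonical_ellipse, [(5.0, 3.0)], 0.0)[0]
        d_out = model_density("filled", canonical_ellipse, [(40.0, 0.0)], 0.0)[0]
        assert d_in == pytest.approx(1.0 / (np.pi * 32.5 * 17.5))
        assert d_out == 0.0

    def test_hollow_perimeter_exceeds_center(self, canonical_ellipse):
        d_edge = model_density("hollow", canonical_ellipse, [(32.5, 0.0)], 2.0)[0]
        d_center = model_density("hollow", canonical_ellipse, [(0.0, 0.0)], 2.0)[0]
        assert d_edge / d_center > 10

    @pytest.mark.parametrize("kind", ["hollow", "filled"])
    def test_density_integrates_to_one(self, kind):
        par = EllipseParams(0.0, 0.0, 65.0, 35.0, 0.4)
        g = np.linspace(-150, 150, 301)
        X, Y = np.meshgrid(g, g)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        dens = model_density(kind, par, pts, 5.0)
        assert dens.sum() * (g[1] - g[0]) ** 2 == pytest.approx(1.0, abs=0.01)

    def test_hollow_zero_blur_rejected(self, canonical_ellipse):
        with pytest.raises(ValueError):
            model_density("hollow", canonical_ellipse, [(0.0, 0.0)], 0.0)

    def test_degenerate_ellipse_rejected(self):
        with pytest.raises(ValueError):
            EllipseParams(0, 0, 30.0, -1.0)
        with pytest.raises(ValueError):
            EllipseParams(0, 0, 30.0, 40.0)


class TestNormAicc:
    def test_direct_formula(self):
        """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1), normalized by n."""
        assert norm_aicc(-500.0, 5, 100) == pytest.approx(1010.6383 / 100, abs=1e-6)

    def test_monotone_in_log_likelihood(self):
        assert norm_aicc(-400.0, 5, 100) < norm_aicc(-500.0, 5, 100)

    @pytest.mark.parametrize("n", [5, 6])
    def test_boundary_rejected(self, n):
        with pytest.raises(ValueError):
            norm_aicc(-10.0, 5, n)


class TestFitShapeModel:
    def test_recovers_perimeter_cloud(self):
        """Noiseless points on an 80x40 nm perimeter (precision declared
        1 nm) are recovered to a few percent in axes and 0.05 rad."""
        truth = EllipseParams(5.0, -3.0, 80.0, 40.0, 0.3)
        rng = np.random.default_rng(7)
        t = rng.uniform(0, 2 * np.pi, 1000)
        local = np.column_stack([truth.a * np.cos(t), truth.b * np.sin(t)])
        pts = local @ _rotation(truth.theta).T + [truth.cx, truth.cy]
        cloud = make_cloud(pts[:, 0], pts[:, 1], prec_xy=1.0)
        fit = fit_shape_model(cloud, "hollow", maxfev=800)
        assert fit.params.full_major_axis == pytest.approx(80.0, rel=0.05)
        assert fit.params.full_minor_axis == pytest.approx(40.0, rel=0.05)
        assert abs(fit.params.theta - 0.3) < 0.05

    def test_default_init_axes_and_median_center(self):
        cloud = make_cloud([0, 0, 10, 20, 20], [0, 5, 5, 5, 10])
        init = default_init(cloud)
        assert init.full_major_axis == 65.0
        assert init.full_minor_axis == 35.0
        assert init.cx == 10.0 and init.cy == 5.0

    def test_too_few_localizations_rejected(self):
        cloud = make_cloud([0, 1, 2, 3], [0, 1, 2, 3])
        with pytest.raises(ValueError):
            fit_shape_model(cloud, "hollow")

    def test_likelihood_not_below_initialization(self, canonical_ellipse):
        cloud = gen_focus_localizations(
            "hollow", canonical_ellipse, 200, precision_xy=5.0, precision_z=10.0, seed=3
        )
        init = default_init(cloud)
        fit = fit_shape_model(cloud, "hollow", init=init)
        ll_init = np.log(
            model_density("hollow", init, cloud.xy, cloud.data["locprec_nm"].to_numpy())
        ).sum()
        assert fit.log_likelihood >= ll_init - 1e-9

    def test_rigid_motion_equivariance(self, canonical_ellipse):
        """Translating + rotating a cloud moves the fitted center and theta
        accordingly and leaves the axes unchanged (1% / 0.02 rad)."""
        cloud = gen_focus_localizations(
            "hollow", canonical_ellipse, 600, precision_xy=2.0, precision_z=5.0, seed=11
        )
        fit0 = fit_shape_model(cloud, "hollow", maxfev=800)
        phi, shift = 0.5, np.array([50.0, -30.0])
        moved = cloud.data.copy()
        xy = cloud.xy @ _rotation(phi).T + shift
        moved["x_nm"], moved["y_nm"] = xy[:, 0], xy[:, 1]
        fit1 = fit_shape_model(LocalizationCloud("m", moved), "hollow", maxfev=800)
        expected_center = np.array([fit0.params.cx, fit0.params.cy]) @ _rotation(phi).T + shift
        assert fit1.params.cx == pytest.approx(expected_center[0], abs=1.0)
        assert fit1.params.cy == pytest.approx(expected_center[1], abs=1.0)
        assert fit1.params.full_major_axis == pytest.approx(
            fit0.params.full_major_axis, rel=0.01
        )
        assert fit1.params.full_minor_axis == pytest.approx(
            fit0.params.full_minor_axis, rel=0.01
        )
        dtheta = (fit1.params.theta - fit0.params.theta - phi) % np.pi
        assert min(dtheta, np.pi - dtheta) < 0.02

    def test_more_localizations_tighten_axis_recovery(self, canonical_ellipse):
        """Mean axis-recovery error shrinks when the cloud is upsampled
         4x (n=1000 vs n=250)."""
        errs = {250: [], 1000: []}
        for n in errs:
            for seed in range(3):
                cloud = gen_focus_localizations(
                    "hollow", canonical_ellipse, n, precision_xy=3.0, precision_z=5.0,
                    seed=seed,
                )
                fit = fit_shape_model(cloud, "hollow", maxfev=800)
                errs[n].append(
                    abs(fit.params.full_major_axis - 65.0) + abs(fit.params.full_minor_axis - 35.0)
                )
        assert np.mean(errs[1000]) < np.mean(errs[250])


class TestClassifyFocus:
    @pytest.mark.parametrize("kind", ["hollow", "filled"])
    def test_generator_label_recovered(self, canonical_ellipse, kind):
        cloud = gen_focus_localizations(
            kind, canonical_ellipse, 500, precision_xy=5.0, precision_z=10.0, seed=42
        )
        cls = classify_focus(cloud)
        assert cls.label == kind

    def test_decision_reduces_to_likelihood_comparison(self, canonical_ellipse):
        """With k and n equal for both models, the normAICc ordering is the
        reversed log-likelihood ordering, so the label only depends on
        which model is more likely."""
        for seed, kind in [(1, "hollow"), (2, "filled")]:
            cloud = gen_focus_localizations(
                kind, canonical_ellipse, 300, precision_xy=5.0, precision_z=10.0, seed=seed
            )
            cls = classify_focus(cloud)
            assert cls.fit_hollow.n_used == cls.fit_filled.n_used
            assert cls.fit_hollow.k_params == cls.fit_filled.k_params
            by_likelihood = (
                "filled"
                if cls.fit_filled.log_likelihood > cls.fit_hollow.log_likelihood
                else "hollow"
            )
            assert cls.label == by_likelihood

    def test_exact_tie_goes_hollow(self):
        """The designation rule is a strict inequality: equal normAICc
        values keep the hollow label."""
        from meioquant.smlm import select_label

        assert select_label(1.0, 1.0) == "hollow"
        assert select_label(2.0, 1.0) == "filled"
        assert select_label(1.0, 2.0) == "hollow"

    def test_background_only_cloud_still_classifies(self, canonical_ellipse):
        cloud = gen_focus_localizations(
            "filled", canonical_ellipse, 100, precision_xy=5.0, precision_z=10.0,
            background_frac=1.0, seed=5,
        )
        cls = classify_focus(cloud)
        assert cls.label in ("hollow", "filled")


class TestHollowFraction:
    def test_published_percentages_from_counts(self):
        """13 hollow of 21 is 61.9%; 4 of 15 is 26.7%."""
        labels = (
            [{"genotype": "wt", "label": "hollow"}] * 13
            + [{"genotype": "wt", "label": "filled"}] * 8
            + [{"genotype": "hd", "label": "hollow"}] * 4
            + [{"genotype": "hd", "label": "filled"}] * 11
        )
        summary, pairwise = hollow_fraction(pd.DataFrame(labels))
        wt = summary[summary["genotype"] == "wt"].iloc[0]
        hd = summary[summary["genotype"] == "hd"].iloc[0]
        assert wt["hollow_pct"] == 61.9
        assert hd["hollow_pct"] == 26.7
        assert pairwise.iloc[0]["p_value"] == pytest.approx(0.049, abs=5e-4)

    def test_zero_hollow(self):
        df = pd.DataFrame([{"genotype": "g", "label": "filled"}] * 5)
        summary, _ = hollow_fraction(df)
        assert summary.iloc[0]["hollow_pct"] == 0.0
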