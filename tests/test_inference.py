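"""Regression battery: LPM with cluster-robust SEs, frame OLS, winsorizing,
binned scatterplots, per-camera fits, and Krippendorff's alpha."""

import numpy as np
import pandas as pd
import pytest

from crowdcontact.inference import (
    binscatter,
    fit_frame_ols,
    fit_lpm_clustered,
    fit_per_camera,
    fits_table,
    krippendorff_alpha,
    winsorize_upper,
)
from crowdcontact.scene import GeneratorConfig, simulate_lpm_persons

from _oracles import (
    cr1_sandwich_se,
    krippendorff_interval_literal,
    ols_normal_equations,
    quantile_type7,
    sort_and_chunk_binscatter,
)


def person_table(y, x, clusters, cam="c1"):
    return pd.DataFrame(
        {
            "camera_id": cam,
            "frame_id": clusters,
            "person_id": range(len(y)),
            "n_present": x,
            "violation": y,
        }
    )


def clustered_fixture(n_clusters=200, seed=3):
    """Synthetic person table with heterogeneous cluster sizes."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_clusters):
        m = int(rng.integers(2, 9))
        x = float(rng.integers(2, 40))
        p = np.clip(0.1 + 0.01 * x + rng.normal(0, 0.05), 0, 1)
        for i in range(m):
            rows.append((f"f{g}", i, x, int(rng.random() < p)))
    return pd.DataFrame(rows, columns=["frame_id", "person_id", "n_present", "violation"]).assign(
        camera_id="c1"
    )


class TestLpmClustered:
    def test_closed_form_point_estimates(self):
        tab = person_table([0, 1, 0, 1], [1, 2, 3, 4], ["A", "A", "B", "B"])
        fit = fit_lpm_clustered(tab)
        assert fit.slope == pytest.approx(0.2, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.n_obs == 4 and fit.n_clusters == 2
        assert fit.ci_low <= fit.slope <= fit.ci_high

    def test_constant_outcome_gives_zero_slope_and_se(self):
        tab = person_table([1, 1, 1, 1], [1, 2, 3, 4], ["A", "A", "B", "B"])
        fit = fit_lpm_clustered(tab)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.se_cluster == pytest.approx(0.0, abs=1e-12)

    def test_preconditions(self):
        one_cluster = person_table([0, 1], [1, 2], ["A", "A"])
        with pytest.raises(ValueError, match="clusters"):
            fit_lpm_clustered(one_cluster)
        const_x = person_table([0, 1, 0, 1], [3, 3, 3, 3], ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="constant"):
            fit_lpm_clustered(const_x)

    def test_sandwich_matches_independent_cr1_oracle(self):
        """Cluster-robust SE agrees with a from-scratch sandwich to 1e-10."""
        tab = clustered_fixture()
        fit = fit_lpm_clustered(tab)
        X = np.column_stack(
            [np.ones(len(tab)), tab["n_present"].to_numpy(float)]
        )
        se = cr1_sandwich_se(
            tab["violation"].to_numpy(float), X, tab["frame_id"].to_numpy()
        )
        assert fit.se_cluster == pytest.approx(se[1], rel=1e-10)

    def test_singleton_clusters_reduce_to_hc1(self):
        """One observation per cluster: CR1 equals HC1 exactly."""
        import statsmodels.api as sm

        tab = clustered_fixture(n_clusters=150, seed=8)
        tab = tab.groupby("frame_id", sort=False).head(1).reset_index(drop=True)
        tab["frame_id"] = np.arange(len(tab)).astype(str)  # each row its own cluster
        fit = fit_lpm_clustered(tab)
        X = sm.add_constant(tab["n_present"].to_numpy(float))
        hc1 = sm.OLS(tab["violation"].to_numpy(float), X).fit(cov_type="HC1")
        assert fit.se_cluster == pytest.approx(float(hc1.bse[1]), rel=1e-10)

    def test_camera_fixed_effects_match_dummy_expansion(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        parts = []
        for cam, shift in [("c1", 0.0), ("c2", 0.3)]:
            x = rng.integers(2, 30, size=120).astype(float)
            p = np.clip(shift + 0.008 * x, 0, 1)
            y = (rng.random(120) < p).astype(int)
            parts.append(
                person_table(y, x, [f"{cam}f{i // 4}" for i in range(120)], cam=cam)
            )
        tab = pd.concat(parts, ignore_index=True)
        fit = fit_lpm_clustered(tab, fixed_effects="camera")
        dummies = pd.get_dummies(tab["camera_id"], drop_first=False).to_numpy(float)
        X = np.column_stack([tab["n_present"].to_numpy(float), dummies])
        beta = np.linalg.lstsq(X, tab["violation"].to_numpy(float), rcond=None)[0]
        assert fit.slope == pytest.approx(beta[0], rel=1e-9)
        assert fit.fixed_effects == "camera"

    def test_parameter_recovery_smoke(self):
        """Refitting data simulated with a known slope recovers it closely."""
        cfg = GeneratorConfig()
        rng = np.random.default_rng(17)
        tab = simulate_lpm_persons(0.009, 0.25, 3000, cfg, rng)
        fit = fit_lpm_clustered(tab)
        assert fit.ci_low <= 0.009 <= fit.ci_high
        assert fit.slope == pytest.approx(0.009, rel=0.25)


class TestFrameOls:
    def test_perfectly_collinear_frames(self):
        frames = pd.DataFrame(
            {"n_present": [2, 4, 6], "n_violators": [0, 2, 4]}
        )
        fit = fit_frame_ols(frames)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.integers(2, 40, size=10).astype(float)
        y = 0.6 * x + rng.normal(0, 1.5, size=10)
        fit = fit_frame_ols(pd.DataFrame({"n_present": x, "n_violators": y}))
        slope, intercept, r2 = ols_normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.r_squared == pytest.approx(r2, rel=1e-12)

    def test_r_squared_equals_squared_correlation_of_fit(self, rng):
        x = rng.integers(2, 40, size=200).astype(float)
        y = 0.5 * x + rng.normal(0, 3, size=200)
        fit = fit_frame_ols(pd.DataFrame({"n_present": x, "n_violators": y}))
        fitted = fit.intercept + fit.slope * x
        assert fit.r_squared == pytest.approx(np.corrcoef(fitted, y)[0, 1] ** 2)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_frame_ols(pd.DataFrame({"n_present": [2, 3], "n_violators": [0, 1]}))
        with pytest.raises(ValueError, match="variance"):
            fit_frame_ols(pd.DataFrame({"n_present": [5, 5, 5], "n_violators": [0, 1, 2]}))

    def test_calibrated_synthetic_slope_and_r2(self, default_dataset):
        """Frame-level association on the default synthetic data: slope in
        [0.4, 0.8] with R^2 > 0.6, matching the regime the generator is calibrated to."""
        _, _, _, frames = default_dataset
        fit = fit_frame_ols(frames)
        assert 0.4 <= fit.slope <= 0.8
        assert fit.r_squared > 0.6


class TestWinsorize:
    def test_tukey_outer_fence_example(self):
        res = winsorize_upper(list(range(1, 12)) + [40])
        assert res.q3 == pytest.approx(quantile_type7(list(range(1, 12)) + [40], 0.75))
        assert res.q3 == pytest.approx(9.25)
        assert res.iqr == pytest.approx(5.5)
        assert res.upper_fence == pytest.approx(25.75)
        assert res.n_capped == 1
        assert res.values.max() == pytest.approx(25.75)
        assert (np.sort(res.values)[:-1] == np.arange(1, 12)).all()

    def test_no_extremes_is_identity(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = winsorize_upper(v)
        assert res.n_capped == 0
        assert (res.values == v).all()

    def test_idempotence(self):
        v = np.concatenate([np.arange(50.0), [500.0, 900.0]])
        once = winsorize_upper(v)
        twice = winsorize_upper(once.values)
        assert (twice.values == once.values).all()
        assert twice.n_capped == 0

    def test_small_or_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            winsorize_upper([])
        with pytest.raises(ValueError):
            winsorize_upper([1.0, 2.0, np.nan, 4.0])


class TestBinscatter:
    def test_constant_y(self, rng):
        x = rng.random(100)
        bs = binscatter(x, np.full(100, 7.0), 10)
        assert np.allclose(bs.bin_y_means, 7.0)

    def test_single_bin_is_overall_mean(self, rng):
        x, y = rng.random(30), rng.random(30)
        bs = binscatter(x, y, 1)
        assert bs.bin_x_means[0] == pytest.approx(x.mean())
        assert bs.bin_y_means[0] == pytest.approx(y.mean())

    def test_identity_series_matches_sort_chunk_oracle(self):
        x = np.linspace(0, 1, 100)
        bs = binscatter(x, x, 10)
        ox, oy, oc = sort_and_chunk_binscatter(x, x, 10)
        assert np.allclose(bs.bin_x_means, ox)
        assert np.allclose(bs.bin_y_means, oy)
        assert (bs.bin_counts == oc).all()
        assert np.allclose(bs.bin_x_means, bs.bin_y_means)

    def test_bin_counts_differ_by_at_most_one(self, rng):
        x, y = rng.random(103), rng.random(103)
        bs = binscatter(x, y, 7)
        assert bs.bin_counts.sum() == 103
        assert bs.bin_counts.max() - bs.bin_counts.min() <= 1
        assert (np.diff(bs.bin_x_means) >= 0).all()

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            binscatter([1.0, 1.0, 2.0], [0.0, 1.0, 2.0], 3)


class TestPerCamera:
    def test_identical_cameras_get_identical_fits(self, random_frames_table):
        from crowdcontact.proximity import score_dataset

        det2 = random_frames_table.copy()
        det2["camera_id"] = "camB"
        det = pd.concat([random_frames_table, det2], ignore_index=True)
        persons, frames = score_dataset(det, 1.5)
        fits = fit_per_camera(persons, frames)
        assert len(fits) == 2
        a, b = fits
        assert a.lpm.slope == pytest.approx(b.lpm.slope)
        assert a.agg.r_squared == pytest.approx(b.agg.r_squared)

    def test_equals_manual_subsetting(self, default_dataset):
        _, _, persons, frames = default_dataset
        cam = persons["camera_id"].iloc[0]
        fits = {c.camera_id: c for c in fit_per_camera(persons, frames)}
        manual = fit_lpm_clustered(persons[persons["camera_id"] == cam])
        assert fits[cam].lpm.slope == pytest.approx(manual.slope, rel=1e-12)

    def test_failing_camera_is_reported_not_skipped(self):
        persons = person_table([0, 1, 1, 0], [3, 3, 3, 3], ["A", "A", "B", "B"], cam="bad")
        frames = pd.DataFrame(
            {"camera_id": "bad", "frame_id": ["A", "B"], "n_present": [3, 3],
             "n_violators": [1, 1], "n_violating_pairs": [1, 1]}
        )
        fits = fit_per_camera(persons, frames)
        assert len(fits) == 1
        assert fits[0].lpm is None and fits[0].error is not None


class TestKrippendorff:
    def test_perfect_agreement(self):
        res = krippendorff_alpha([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.alpha == 1.0
        assert not res.degenerate

    def test_all_identical_ratings_flagged_degenerate(self):
        res = krippendorff_alpha([2, 2, 2], [2, 2, 2])
        assert res.alpha == 1.0 and res.degenerate

    def test_matches_literal_coincidence_matrix(self):
        a = [1, 2, 3, 4, 2, 0]
        b = [1, 2, 3, 5, 2, 1]
        res = krippendorff_alpha(a, b)
        assert res.alpha == pytest.approx(krippendorff_interval_literal(a, b), rel=1e-12)

    def test_interval_alpha_known_small_case(self):
        # single disagreeing unit out of four, hand-checkable
        a, b = [1, 2, 3, 4], [1, 2, 3, 5]
        res = krippendorff_alpha(a, b)
        assert res.alpha == pytest.approx(krippendorff_interval_literal(a, b), rel=1e-12)
        assert 0.8 < res.alpha < 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            krippendorff_alpha([1], [1])
        with pytest.raises(ValueError):
            krippendorff_alpha([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            krippendorff_alpha([1, 2], [1, 2], metric_level="nominal")


def test_fits_table_schema():
    tab = person_table([0, 1, 0, 1], [1, 2, 3, 4], ["A", "A", "B", "B"])
    lpm = fit_lpm_clustered(tab)
    frames = pd.DataFrame({"n_present": [2, 4, 6], "n_violators": [0, 2, 4]})
    agg = fit_frame_ols(frames)
    out = fits_table([("lpm_main", lpm), ("frame_ols", agg)])
    assert list(out.columns) == [
        "model", "outcome", "fixed_effects", "slope", "se", "ci_level",
        "ci_low", "ci_high", "n", "clusters", "r_squared",
    ]
    assert out.loc[1, "r_squared"] == pytest.approx(1.0)
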