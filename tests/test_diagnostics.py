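import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import facedefender as fd
from facedefender.diagnostics import (
    DiagnosticsError,
    MeasurementSchema,
    X_ASYM,
    Y_ASYM,
    resolve_roles,
)


class TestMeasureDistances:
    def test_zero_distance_when_iris_on_reference(self):
        # droop the lid until its apex sits at iris height minus zero:
        # construct directly with a custom schema is simpler — use the
        # renderer with aperture equal to droop offsetting GH to a known value
        p = fd.SyntheticFaceParams(noise_sd=0.0, left_iris_offset=(0.0, -5.0))
        _, lm = fd.render_face(p)
        m = fd.measure_distances(lm)
        assert m["GH"] == pytest.approx(p.eyelid_aperture_up - 5.0, abs=1e-9)

    def test_symmetric_face_zero_asymmetry(self, neutral_face):
        m = fd.measure_distances(neutral_face[1])
        assert m.x_asymmetry == pytest.approx(0.0, abs=1e-9)

    def test_esotropic_offset_recovered_exactly(self):
        p = fd.SyntheticFaceParams(noise_sd=0.0, left_iris_offset=(12.0, 0.0))
        _, lm = fd.render_face(p)
        assert fd.measure_distances(lm).x_asymmetry == pytest.approx(12.0, abs=1e-6)

    def test_roles_resolve_to_distinct_points(self, neutral_face):
        roles = resolve_roles(neutral_face[1], "left")
        assert len(set(roles.values())) == len(roles)


class TestIqrFilter:
    def test_regular_sequence_untouched(self):
        kept, out = fd.iqr_filter(list(range(1, 10)))
        assert len(out) == 0 and len(kept) == 9

    def test_gross_outlier_removed_with_interpolated_quartiles(self):
        kept, out = fd.iqr_filter([10, 11, 12, 13, 14, 100])
        # Q1 = 11.25, Q3 = 13.75 under linear interpolation -> fence 17.5
        assert list(kept) == [10, 11, 12, 13, 14]
        assert list(out) == [5]

    def test_degenerate_spread_keeps_everything(self):
        kept, out = fd.iqr_filter([5.0] * 10)
        assert len(kept) == 10 and len(out) == 0

    def test_too_few_samples_raises(self):
        with pytest.raises(DiagnosticsError, match="at least 4"):
            fd.iqr_filter([1.0, 2.0, 3.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=40))
    def test_permutation_invariant_and_median_kept(self, xs):
        xs = np.asarray(xs)
        kept1, _ = fd.iqr_filter(xs)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(xs))
        kept2, _ = fd.iqr_filter(xs[perm])
        assert sorted(kept1) == pytest.approx(sorted(kept2))
        # the Tukey fences always bracket the median, so any sample at
        # the median survives filtering
        med = np.median(xs)
        n_med = int(np.sum(xs == med))
        assert int(np.sum(kept1 == med)) == n_med


class TestNormalityCheck:
    def test_normal_draws_usually_pass(self):
        hits = 0
        for rep in range(100):
            x = np.random.default_rng(rep).normal(30, 3.3, 200)
            hits += fd.normality_check(x) == "normal"
        assert hits >= 90

    def test_lognormal_draws_fail(self):
        hits = 0
        for rep in range(100):
            x = np.random.default_rng(rep).lognormal(0, 1, 200)
            hits += fd.normality_check(x) == "non_normal"
        assert hits >= 99

    def test_constant_vector_non_normal(self):
        assert fd.normality_check([3.0] * 20) == "non_normal"


class TestIntervalNormal:
    def test_closed_form_ci_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1)  # exact mean 0, sd 1
        x = 10 + 2 * x
        iv = fd.interval_normal(x, 0.95, "ci_mean")
        assert iv.lower == pytest.approx(9.608, abs=5e-4)
        assert iv.upper == pytest.approx(10.392, abs=5e-4)

    def test_zero_spread_degenerate(self):
        iv = fd.interval_normal([4.0, 4.0, 4.0], 0.95, "reference_range")
        assert iv.lower == iv.upper == 4.0

    def test_reference_range_contains_ci_mean(self):
        x = np.random.default_rng(1).normal(30, 3.3, 50)
        ci = fd.interval_normal(x, 0.95, "ci_mean")
        rr = fd.interval_normal(x, 0.95, "reference_range")
        assert rr.lower <= ci.lower and ci.upper <= rr.upper

    def test_ci_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(2)
        widths = {}
        for n in (50, 200, 800):
            w = [
                fd.interval_normal(rng.normal(0, 1, n), 0.95, "ci_mean").half_width
                for _ in range(200)
            ]
            widths[n] = np.mean(w)
        assert widths[50] / widths[200] == pytest.approx(2.0, rel=0.1)
        assert widths[200] / widths[800] == pytest.approx(2.0, rel=0.1)


class TestIntervalBootstrap:
    def test_constant_sample_degenerate(self):
        iv = fd.interval_bootstrap([2.0] * 10, seed=1)
        assert iv.lower == iv.upper == 2.0

    def test_same_seed_identical(self):
        x = np.random.default_rng(3).normal(size=50)
        iv1 = fd.interval_bootstrap(x, seed=42)
        iv2 = fd.interval_bootstrap(x, seed=42)
        assert (iv1.lower, iv1.upper) == (iv2.lower, iv2.upper)

    def test_missing_seed_raises(self):
        with pytest.raises(DiagnosticsError, match="seed"):
            fd.interval_bootstrap(np.arange(20.0))

    def test_ci_mean_close_to_normal_theory(self):
        x = np.random.default_rng(4).normal(30, 3.3, 200)
        boot = fd.interval_bootstrap(x, seed=5, mode="ci_mean")
        norm = fd.interval_normal(x, mode="ci_mean")
        assert boot.lower == pytest.approx(norm.lower, abs=0.15)
        assert boot.upper == pytest.approx(norm.upper, abs=0.15)


class TestBenchmarkModel:
    def test_all_normal_measures_use_normal_method(self, fitted_benchmark):
        methods = {
            k: iv.method
            for k, iv in fitted_benchmark.intervals.items()
            if k not in (X_ASYM, Y_ASYM)
        }
        assert set(methods.values()) == {"normal"}

    def test_folded_asymmetries_use_bootstrap(self, fitted_benchmark):
        assert fitted_benchmark.intervals[X_ASYM].method == "bootstrap"
        assert fitted_benchmark.intervals[Y_ASYM].method == "bootstrap"

    def test_lognormal_measure_routed_to_bootstrap(self):
        dists = fd.synthetic._default_distributions()
        dists["EF"] = ("lognormal", 3.4, 0.5)
        cohort, _ = fd.generate_cohort(fd.CohortSpec(n=200, seed=8, distributions=dists))
        res = fd.BenchmarkModel.from_measurements(cohort).fit(seed=1)
        assert res.intervals["EF"].method == "bootstrap"
        assert res.intervals["A"].method == "normal"

    def test_gross_outliers_excluded_and_width_stable(self, clean_cohort):
        cohort, _ = clean_cohort
        res_clean = fd.BenchmarkModel.from_measurements(cohort).fit(seed=1)
        corrupted = []
        rng = np.random.default_rng(12)
        bad = set(rng.choice(len(cohort), 10, replace=False))
        for i, m in enumerate(cohort):
            vals = dict(m.values)
            if i in bad:
                vals = {k: v * 10 for k, v in vals.items()}
            corrupted.append(
                fd.EyeMeasurements(vals, m.x_asymmetry, m.y_asymmetry)
            )
        res = fd.BenchmarkModel.from_measurements(corrupted).fit(seed=1)
        for name in ("A", "B", "GH"):
            assert res.intervals[name].n_used <= len(cohort) - 10
            w_clean = res_clean.intervals[name].half_width
            assert res.intervals[name].half_width == pytest.approx(w_clean, rel=0.15)

    def test_small_cohort_rejected(self):
        cohort, _ = fd.generate_cohort(fd.CohortSpec(n=8, seed=1))
        with pytest.raises(DiagnosticsError, match="below required"):
            fd.BenchmarkModel.from_measurements(cohort[:6] + cohort[:2], min_required=60)

    def test_summary_lists_every_measure(self, fitted_benchmark):
        text = fitted_benchmark.summary()
        for name in MeasurementSchema.default().all_names:
            assert name in text

    def test_benchmark_json_round_trip(self, fitted_benchmark, tmp_path):
        path = tmp_path / "bench.json"
        fitted_benchmark.benchmark.to_json(path)
        loaded = fd.Benchmark.from_json(path)
        for name, iv in fitted_benchmark.intervals.items():
            assert loaded[name].lower == pytest.approx(iv.lower)
            assert loaded[name].method == iv.method


class TestClassify:
    def test_cohort_means_are_normal(self, fitted_benchmark):
        values = {
            name: fitted_benchmark.intervals[name].midpoint
            for name in MeasurementSchema.default().names
        }
        m = fd.EyeMeasurements(values, x_asymmetry=0.5, y_asymmetry=0.5)
        d = fitted_benchmark.classify(m)
        assert d.labels == {"left": "normal", "right": "normal"}

    @pytest.mark.parametrize("label", ["esotropia", "exotropia", "ptosis"])
    def test_injected_abnormality_recovered(self, fitted_benchmark, label):
        bench = fitted_benchmark.benchmark
        cohort, _ = fd.generate_cohort(fd.CohortSpec(n=100, seed=33))
        hits = 0
        for m in cohort:
            vals = dict(m.values)
            if label == "esotropia":
                vals["A"] = max(vals["A"] - 3 * bench["A"].half_width, 0.0)
            elif label == "exotropia":
                vals["A"] += 3 * bench["A"].half_width
            else:
                vals["GH"] = max(vals["GH"] - 3 * bench["GH"].half_width, 0.0)
            m2 = fd.EyeMeasurements(
                vals, abs(vals["A"] - vals["B"]), m.y_asymmetry
            )
            hits += fitted_benchmark.classify(m2).labels["left"] == label
        assert hits >= 95

    def test_vertical_strabismus_recovered(self, fitted_benchmark):
        # a 15 px vertical iris displacement (the cohort generator's
        # physical effect size; larger offsets would put the iris above
        # the lid and fold the absolute distance back into range)
        cohort, _ = fd.generate_cohort(fd.CohortSpec(n=100, seed=34))
        delta = 15.0
        hits = 0
        for m in cohort:
            vals = dict(m.values)
            vals["GH"] = abs(vals["GH"] - delta)
            vals["left_lower_lid"] += delta
            m2 = fd.EyeMeasurements(
                vals, m.x_asymmetry, m.y_asymmetry + delta
            )
            hits += fitted_benchmark.classify(m2).labels["left"] == "vertical_strabismus"
        assert hits >= 90

    def test_false_positive_rate_controlled(self, fitted_benchmark):
        cohort, _ = fd.generate_cohort(fd.CohortSpec(n=200, seed=99))
        fp = sum(
            1
            for m in cohort
            for side in ("left", "right")
            if fitted_benchmark.classify(m).labels[side] != "normal"
        )
        assert fp / 400 <= 0.07

    def test_anatomical_relabel_swaps_sides(self, fitted_benchmark):
        bench = fitted_benchmark.benchmark
        values = {name: bench[name].midpoint for name in MeasurementSchema.default().names}
        values["A"] = max(values["A"] - 3 * bench["A"].half_width, 0.0)
        m = fd.EyeMeasurements(values, abs(values["A"] - values["B"]), 0.5)
        d = fitted_benchmark.classify(m)
        assert d.labels["left"] == "esotropia"
        assert d.relabel("anatomical")["right"] == "esotropia"


class TestPilotFormulas:
    def test_margin_of_error_reference_value(self):
        assert fd.margin_of_error(3.31, 50) == pytest.approx(0.92, abs=0.005)

    def test_required_sample_size_reference_value(self):
        n, n_ceil = fd.required_sample_size(3.63, 0.92)
        assert n == pytest.approx(59.81, abs=0.005)
        assert n_ceil == 60

    def test_zero_sigma_zero_margin(self):
        assert fd.margin_of_error(0.0, 50) == 0.0

    def test_quadrupling_n_halves_margin(self):
        e1 = fd.margin_of_error(3.3, 50)
        e2 = fd.margin_of_error(3.3, 200)
        assert e1 / e2 == pytest.approx(2.0)

    def test_unit_sample_size_when_z_sigma_equals_margin(self):
        n, _ = fd.required_sample_size(1.0, 1.96)
        assert n == pytest.approx(1.0)

    def test_doubling_sigma_quadruples_n(self):
        n1, _ = fd.required_sample_size(2.0, 0.5)
        n2, _ = fd.required_sample_size(4.0, 0.5)
        assert n2 / n1 == pytest.approx(4.0)

    @given(
        st.floats(min_value=0.5, max_value=20.0),
        st.integers(min_value=2, max_value=2000),
    )
    def test_formulas_are_exact_inverses(self, sigma, n):
        E = fd.margin_of_error(sigma, n, z_policy="exact")
        n_back, _ = fd.required_sample_size(sigma, E, z_policy="exact")
        assert n_back == pytest.approx(n, rel=1e-9)

    def test_exact_z_policy_differs_slightly(self):
        rounded = fd.margin_of_error(3.31, 50, z_policy="rounded")
        exact = fd.margin_of_error(3.31, 50, z_policy="exact")
        assert rounded != exact
        assert rounded == pytest.approx(exact, abs=1e-3)

    def test_pilot_stats_wrapper(self):
        p = fd.PilotStats(sigma_pilot=3.31, n_pilot=50)
        assert p.margin_of_error == pytest.approx(0.92, abs=0.005)


class TestCohenKappa:
    def test_perfect_agreement(self):
        res = fd.cohen_kappa(np.diag([10, 10]))
        assert res.kappa == pytest.approx(1.0, abs=1e-9)

    def test_independent_margins_zero(self):
        res = fd.cohen_kappa([[9, 21], [21, 49]])
        assert res.kappa == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_example(self):
        res = fd.cohen_kappa([[20, 5], [10, 65]])
        assert res.kappa == pytest.approx(0.625, abs=1e-9)
        assert res.p_observed == pytest.approx(0.85)
        assert res.p_expected == pytest.approx(0.60)
        assert res.p_value < 1e-6

    def test_matches_statsmodels(self):
        sm_irr = pytest.importorskip("statsmodels.stats.inter_rater")
        table = np.array([[20, 5, 2], [10, 65, 3], [1, 4, 30]])
        res = fd.cohen_kappa(table)
        ref = sm_irr.cohens_kappa(table)
        assert res.kappa == pytest.approx(ref.kappa, abs=1e-9)
        assert res.p_value == pytest.approx(float(ref.pvalue_two_sided), abs=1e-9)

    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4))
    def test_transpose_symmetric_and_bounded(self, cells):
        t = np.array(cells, dtype=float).reshape(2, 2)
        if t.sum() < 2 or t.sum(0).max() == t.sum() or t.sum(1).max() == t.sum():
            return
        try:
            k1 = fd.cohen_kappa(t).kappa
            k2 = fd.cohen_kappa(t.T).kappa
        except DiagnosticsError:
            return
        assert k1 == pytest.approx(k2, abs=1e-12)
        assert -1.0 - 1e-9 <= k1 <= 1.0 + 1e-9

    def test_degenerate_table_raises(self):
        with pytest.raises(DiagnosticsError, match="undefined"):
            fd.cohen_kappa([[10, 0], [0, 0]])


class TestQualityFlag:
    def test_frontal_face_passes(self, neutral_face):
        assert fd.quality_flag(neutral_face[1]) == (False, "")

    def test_roll_flagged(self):
        _, lm = fd.render_face(fd.SyntheticFaceParams(noise_sd=0.0, roll_deg=10.0))
        flagged, reason = fd.quality_flag(lm)
        assert flagged and reason.startswith("roll")

    def test_yaw_flagged(self):
        _, lm = fd.render_face(fd.SyntheticFaceParams(noise_sd=0.0, yaw_asymmetry=1.5))
        flagged, reason = fd.quality_flag(lm)
        assert flagged and reason.startswith("yaw")

    def test_mild_pose_not_flagged(self):
        _, lm = fd.render_face(
            fd.SyntheticFaceParams(noise_sd=0.0, roll_deg=3.0, yaw_asymmetry=1.1)
        )
        assert fd.quality_flag(lm)[0] is False
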