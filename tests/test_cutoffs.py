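import numpy as np
import pytest

from pupyscreen import simulate as sim
from pupyscreen.cutoffs import (
    CutoffConfig,
    build_cutoff_table,
    percentile_cutoff,
    test_age_dependency,
    trim_extremes,
    write_cutoff_table,
)
from pupyscreen.panel import get_cutoff, load_panel, validate_panel, PanelRegistry

Z975 = 1.959963984540054


def _sorted_quantile_oracle(values, q):
    """Independent sort-based linear-interpolation order statistic."""
    v = np.sort(np.asarray(values, dtype=float))
    h = q * (v.size - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, v.size - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def _uniform_bin_ages(rng, n_per_bin, bins=((0, 1), (1, 3), (3, 6), (6, 18))):
    return np.concatenate([rng.uniform(lo, hi, n_per_bin) for lo, hi in bins])


class TestTrimExtremes:
    def test_251_values_remove_at_most_two(self):
        values = np.arange(1.0, 252.0)
        retained = trim_extremes(values)
        removed = 251 - retained.size
        # oracle: count strictly above the interpolated 99.5th percentile
        thr = _sorted_quantile_oracle(values, 0.995)
        assert removed == int(np.sum(values > thr))
        assert removed <= 2

    def test_constant_vector_untouched(self):
        values = np.full(50, 3.3)
        assert trim_extremes(values).size == 50

    def test_outlier_removed_cutoff_stable(self):
        rng = np.random.default_rng(0)
        clean = rng.lognormal(1.0, 0.5, 251)
        spiked = clean.copy()
        spiked[0] = 100.0 * np.median(clean)
        retained = trim_extremes(spiked)
        assert spiked[0] not in retained
        assert percentile_cutoff(retained, 0.975) == pytest.approx(
            percentile_cutoff(trim_extremes(clean), 0.975), rel=0.02
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            trim_extremes(np.arange(10.0))


class TestPercentileCutoff:
    def test_oracle_1_to_100(self):
        values = np.arange(1.0, 101.0)
        assert percentile_cutoff(values, 0.975) == pytest.approx(
            _sorted_quantile_oracle(values, 0.975)
        )

    def test_constant_vector(self):
        assert percentile_cutoff(np.full(30, 7.0), 0.975) == 7.0

    def test_lognormal_analytic_quantile(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(0.0, 0.7, 10_000)
        analytic = np.exp(0.7 * Z975)
        assert percentile_cutoff(values, 0.975) == pytest.approx(analytic, rel=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_cutoff(np.array([]), 0.975)

    def test_oracle_equivalence_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            values = rng.lognormal(0, 1, rng.integers(5, 200))
            q = rng.uniform(0.01, 0.99)
            assert percentile_cutoff(values, q) == pytest.approx(
                _sorted_quantile_oracle(values, q), rel=1e-12
            )


class TestAgeDependency:
    def test_type_one_error_near_alpha(self):
        # exchangeable bins: split rate must track alpha (within MC error)
        rng = np.random.default_rng(0)
        cfg = CutoffConfig(n_resamples=199)
        reps = 300
        hits = 0
        for r in range(reps):
            values = rng.lognormal(0, 0.7, 240)
            ages = _uniform_bin_ages(rng, 60)
            hits += test_age_dependency(values, ages, cfg, seed=r).split
        rate = hits / reps
        # exact resampling level is 9/200 = 0.045; 3 MC sigmas ~ 0.036
        assert abs(rate - 0.045) < 0.036

    def test_power_threefold_infant_effect(self):
        rng = np.random.default_rng(1)
        cfg = CutoffConfig(n_resamples=199)
        reps = 200
        hits = 0
        for r in range(reps):
            values = np.concatenate(
                [3.0 * rng.lognormal(0, 0.7, 60), rng.lognormal(0, 0.7, 180)]
            )
            ages = _uniform_bin_ages(rng, 60)
            hits += test_age_dependency(values, ages, cfg, seed=r).split
        assert hits / reps >= 0.95

    def test_alpha_zero_always_merges(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [10.0 * rng.lognormal(0, 0.5, 60), rng.lognormal(0, 0.5, 180)]
        )
        ages = _uniform_bin_ages(rng, 60)
        res = test_age_dependency(values, ages, CutoffConfig(alpha=0.0), seed=0)
        assert not res.split
        assert res.partition == ((0.0, 18.0),)

    def test_empty_bin_rejected_with_name(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(0, 0.5, 120)
        ages = np.concatenate(
            [rng.uniform(3, 6, 60), rng.uniform(6, 18, 60)]
        )
        with pytest.raises(ValueError, match=r"\[0.0, 1.0\)"):
            test_age_dependency(values, ages, CutoffConfig(), seed=0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        values = np.concatenate(
            [2.0 * rng.lognormal(0, 0.5, 60), rng.lognormal(0, 0.5, 180)]
        )
        ages = _uniform_bin_ages(rng, 60)
        res1 = test_age_dependency(values, ages, CutoffConfig(), seed=5)
        perm = rng.permutation(values.size)
        res2 = test_age_dependency(values[perm], ages[perm], CutoffConfig(), seed=5)
        assert res1 == res2

    def test_clinical_override_merge(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [5.0 * rng.lognormal(0, 0.5, 60), rng.lognormal(0, 0.5, 180)]
        )
        ages = _uniform_bin_ages(rng, 60)
        cfg = CutoffConfig(clinical_override={"Xanthine": "merge"})
        res = test_age_dependency(values, ages, cfg, seed=0, analyte="Xanthine")
        assert not res.split

    def test_bootstrap_method_available(self):
        rng = np.random.default_rng(6)
        values = np.concatenate(
            [3.0 * rng.lognormal(0, 0.5, 60), rng.lognormal(0, 0.5, 180)]
        )
        ages = _uniform_bin_ages(rng, 60)
        res = test_age_dependency(values, ages, CutoffConfig(method="bootstrap"), seed=0)
        assert res.split


def _cohort_with_true_cutoffs(registry, n, seed, sigma=0.2, effects=None):
    """Cohort whose per-analyte marginal 97.5th percentile equals the
    bundled cutoff (older group)."""
    models = {}
    for a in registry.measured_analytes:
        rc = get_cutoff(registry, a, 10.0)
        if rc.detection_is_abnormal:
            models[a] = sim.CohortModel(0.0, 0.0, zero=True)
            continue
        models[a] = sim.CohortModel(
            rc.upper / np.exp(Z975 * sigma), sigma,
            (effects or {}).get(a, (1.0, 1.0, 1.0, 1.0)),
        )
    return sim.generate_cohort(sim.CohortSpec(n=n, seed=seed, models=models), registry)


class TestBuildCutoffTable:
    def test_no_age_effect_pooled(self, registry):
        cohort = _cohort_with_true_cutoffs(registry, n=251, seed=0)
        rules = build_cutoff_table(cohort, CutoffConfig(), registry, seed=0)
        for analyte, rr in rules.items():
            assert len(rr) == 1, analyte
            assert (rr[0].age_min, rr[0].age_max) == (0.0, 18.0)

    def test_parameter_recovery_within_ten_percent(self, registry):
        cohort = _cohort_with_true_cutoffs(registry, n=251, seed=0)
        rules = build_cutoff_table(cohort, CutoffConfig(), registry, seed=0)
        for analyte, rr in rules.items():
            rc = get_cutoff(registry, analyte, 10.0)
            if rc.detection_is_abnormal:
                assert rr[0].detection_is_abnormal
                continue
            for rule in rr:
                assert abs(rule.upper / rc.upper - 1) < 0.10, analyte

    def test_recovers_generating_age_structure(self, registry):
        effects = {
            "Dihydrouracil": (34 / 12, 1, 1, 1),
            "Xanthine": (43 / 31, 1, 1, 1),
            "Inosine": (2.5, 2.5, 1, 1),
            "Pseudouridine": (37 / 30, 1, 1, 1),
        }
        cohort = _cohort_with_true_cutoffs(
            registry, n=600, seed=0, sigma=0.3, effects=effects
        )
        rules = build_cutoff_table(cohort, CutoffConfig(), registry, seed=0)
        split = sorted(a for a, rr in rules.items() if len(rr) > 1)
        assert split == sorted(effects)
        assert [(r.age_min, r.age_max) for r in rules["Inosine"]] == [(0.0, 3.0), (3.0, 18.0)]
        assert [(r.age_min, r.age_max) for r in rules["Dihydrouracil"]] == [
            (0.0, 1.0), (1.0, 18.0)
        ]

    def test_pseudouridine_lower_cutoff_emitted(self, registry):
        cohort = _cohort_with_true_cutoffs(registry, n=251, seed=0)
        rules = build_cutoff_table(cohort, CutoffConfig(), registry, seed=0)
        for rule in rules["Pseudouridine"]:
            assert rule.lower is not None and 0 < rule.lower < rule.upper
        for analyte, rr in rules.items():
            if analyte != "Pseudouridine":
                assert all(r.lower is None for r in rr)

    def test_detection_is_abnormal_passthrough(self, registry):
        cohort = _cohort_with_true_cutoffs(registry, n=251, seed=0)
        rules = build_cutoff_table(cohort, CutoffConfig(), registry, seed=0)
        assert rules["Allopurinol"][0].detection_is_abnormal

    def test_scaling_covariance(self, registry):
        cohort = _cohort_with_true_cutoffs(registry, n=251, seed=1)
        scaled = cohort.copy()
        mask = scaled["analyte"] == "Uracil"
        scaled.loc[mask, "value_mmol_per_mol"] *= 3.0
        r1 = build_cutoff_table(cohort, CutoffConfig(), registry, seed=0)
        r2 = build_cutoff_table(scaled, CutoffConfig(), registry, seed=0)
        assert r2["Uracil"][0].upper == pytest.approx(3.0 * r1["Uracil"][0].upper)

    def test_row_order_invariance(self, registry):
        cohort = _cohort_with_true_cutoffs(registry, n=251, seed=2)
        shuffled = cohort.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert build_cutoff_table(cohort, CutoffConfig(), registry, seed=0) == (
            build_cutoff_table(shuffled, CutoffConfig(), registry, seed=0)
        )

    def test_output_round_trips_through_registry(self, registry, tmp_path):
        cohort = _cohort_with_true_cutoffs(registry, n=251, seed=0)
        rules = build_cutoff_table(cohort, CutoffConfig(), registry, seed=0)
        path = tmp_path / "cutoffs.tsv"
        write_cutoff_table(rules, path, header_lines=["test emission"])
        reloaded = load_panel("bundled", cutoffs_path=path)
        candidate = PanelRegistry(
            analytes=registry.analytes, cutoffs=reloaded.cutoffs
        )
        assert validate_panel(candidate) == []

    def test_convergence_to_generating_quantiles(self, registry):
        cohort = _cohort_with_true_cutoffs(registry, n=10_000, seed=3)
        rules = build_cutoff_table(cohort, CutoffConfig(), registry, seed=0)
        for analyte, rr in rules.items():
            rc = get_cutoff(registry, analyte, 10.0)
            if rc.detection_is_abnormal:
                continue
            for rule in rr:
                assert abs(rule.upper / rc.upper - 1) < 0.03, analyte
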