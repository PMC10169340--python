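"""Synthetic cohort generator: determinism, marginal calibration, and the
visit renewal process with its flag-probability calibration."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from temporeg.cohort import build_cohort
from temporeg.errors import ConfigError
from temporeg.regularity import TRScore
from temporeg.simulate import (CohortBundle, GeneratorConfig,
                               _renewal_positions, _sample_cov,
                               _truncated_poisson, flag_probability_from_cov,
                               generate_cohort,
                               regularity_from_linear_predictor,
                               sample_visit_series)


class TestConfig:
    def test_defaults_are_valid(self):
        cfg = GeneratorConfig()
        assert cfg.n_patients == 70_095
        assert cfg.window_days == 729

    @pytest.mark.parametrize("kw", [
        {"n_patients": 0},
        {"clinic_size_concentration": 0.0},
        {"study_window": ("2019-12-31", "2018-01-01")},
        {"baseline_flag_rate": 1.5},
        {"prevalences": {"diabetes": -0.1}},
        {"clinic_effect_sd": -1.0},
        {"mean_visits_per_2y": 0.0},
        {"ineligible_fractions": {"under_40": 0.6, "hemodialysis": 0.6}},
        {"true_log_odds": {"not_a_term": 0.5}},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            GeneratorConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_patients=123, seed=9, clinic_effect_sd=0.1)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert GeneratorConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = GeneratorConfig(n_patients=300, n_clinics=8, seed=4)
        for run in ("a", "b"):
            generate_cohort(cfg).write(tmp_path / run)
        for f in sorted((tmp_path / "a").glob("*.csv")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seed_differs(self):
        b1 = generate_cohort(GeneratorConfig(n_patients=300, n_clinics=8, seed=1))
        b2 = generate_cohort(GeneratorConfig(n_patients=300, n_clinics=8, seed=2))
        assert not b1.demographics.equals(b2.demographics)


class TestVisitSeries:
    WINDOW = ("2018-01-01", "2019-01-01")

    def test_zero_cov_gives_identical_gaps(self):
        rng = np.random.default_rng(0)
        dates = sample_visit_series(0.0, 6, self.WINDOW, rng)
        gaps = np.diff(dates).astype(int)
        assert len(set(gaps)) == 1
        assert (dates >= np.datetime64("2018-01-01")).all()
        assert (dates < np.datetime64("2019-01-01")).all()

    def test_invalid_arguments(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_visit_series(0.5, 1, self.WINDOW, rng)
        with pytest.raises(ValueError):
            sample_visit_series(-0.1, 5, self.WINDOW, rng)

    def test_sample_cov_converges_to_target(self):
        # gamma renewal with shape k has interval COV k^(-1/2); at 200
        # visits the sample COV mean should sit within 0.05 of the target.
        # The window must keep gaps long relative to day resolution,
        # otherwise integer-day rounding truncates the shortest gaps.
        rng = np.random.default_rng(12)
        pos, mask = _renewal_positions(np.full(500, 1.0), np.full(500, 200),
                                       7300, rng)
        covs = _sample_cov(pos, mask)
        assert abs(np.nanmean(covs) - 1.0) < 0.05

    def test_mean_sample_cov_is_monotone_in_target(self):
        rng = np.random.default_rng(3)
        means = []
        for target in (0.5, 1.5):
            pos, mask = _renewal_positions(np.full(300, target),
                                           np.full(300, 100), 729, rng)
            means.append(np.nanmean(_sample_cov(pos, mask)))
        assert means[0] < means[1]

    def test_truncated_poisson_respects_minimum(self):
        draws = _truncated_poisson(np.random.default_rng(1), 3.5, 3, 2000)
        assert draws.min() >= 3


class TestCalibration:
    def test_flag_rate_at_baseline(self):
        """At lp = clinic_effect = 0 the realised flag rate over many
        simulated patients matches the configured baseline (0.20)."""
        cfg = GeneratorConfig(n_patients=10, seed=0)
        target = regularity_from_linear_predictor(0.0, 0.0, cfg)
        rng = np.random.default_rng(99)
        m = 6000
        nv = _truncated_poisson(rng, cfg.mean_visits_per_2y, 3, m)
        pos, mask = _renewal_positions(np.full(m, float(target)), nv, 729, rng)
        covs = _sample_cov(pos, mask)
        rate = np.mean(covs[~np.isnan(covs)] >= cfg.cov_threshold)
        assert rate == pytest.approx(0.20, abs=0.025)

    def test_logistic_link_between_lp_levels(self):
        """Raising lp by 1 multiplies the realised flag odds by ~e."""
        cfg = GeneratorConfig(n_patients=10, seed=0)
        rng = np.random.default_rng(7)
        m = 12000
        rates = []
        for lp in (0.0, 1.0):
            target = regularity_from_linear_predictor(lp, 0.0, cfg)
            nv = _truncated_poisson(rng, cfg.mean_visits_per_2y, 3, m)
            pos, mask = _renewal_positions(np.full(m, float(target)), nv,
                                           729, rng)
            covs = _sample_cov(pos, mask)
            rates.append(np.mean(covs[~np.isnan(covs)] >= cfg.cov_threshold))
        odds = [r / (1 - r) for r in rates]
        assert odds[1] / odds[0] == pytest.approx(np.e, rel=0.15)

    def test_monotone_in_linear_predictor(self):
        cfg = GeneratorConfig(n_patients=10, seed=0)
        lps = np.linspace(-2, 2, 9)
        targets = regularity_from_linear_predictor(lps, 0.0, cfg)
        assert np.all(np.diff(targets) > 0)

    def test_forward_and_inverse_are_consistent(self):
        cfg = GeneratorConfig(n_patients=10, seed=0)
        p = np.array([0.1, 0.2, 0.4])
        lp = logit(p) - logit(cfg.baseline_flag_rate)
        target = regularity_from_linear_predictor(lp, 0.0, cfg)
        np.testing.assert_allclose(flag_probability_from_cov(target, cfg), p,
                                   atol=1e-6)


class TestGenerateCohort:
    def test_prevalence_calibration_among_eligible(self):
        """Condition prevalences in the built cohort match the configured
        marginals within 3 binomial standard errors (n = 10,000)."""
        cfg = GeneratorConfig(n_patients=10_000, n_clinics=40, seed=21)
        cohort = build_cohort(generate_cohort(cfg).tables())
        pts = cohort.patients
        n = len(pts)
        for cond in ("diabetes", "heart_failure", "chronic_lung_disease",
                     "osteoporosis", "anxiety", "cancer"):
            p = cfg.prevalences[cond]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(pts[cond].mean() - p) < 3 * se, cond

    def test_planned_ineligible_fractions_drive_attrition(self, small_bundle):
        cfg, bundle = small_bundle
        cohort = build_cohort(bundle.tables())
        att = cohort.attrition.set_index("step")
        planned = bundle.ground_truth_patients["planned_ineligible"]
        counts = planned.value_counts()
        assert att.loc["age_under_40", "removed"] == counts.get("under_40", 0)
        assert att.loc["hemodialysis", "removed"] == counts.get("hemodialysis", 0)
        # every planned-eligible patient survives all filters
        assert att["remaining"].iloc[-1] == counts.get("eligible", 0)

    def test_no_filters_bite_when_fractions_are_zero(self):
        cfg = GeneratorConfig(
            n_patients=400, n_clinics=5, seed=3,
            ineligible_fractions={k: 0.0 for k in
                                  ("under_40", "no_index_condition",
                                   "hemodialysis", "under_3_visits")})
        bundle = generate_cohort(cfg)
        cohort = build_cohort(bundle.tables())
        assert len(cohort.patients) == 400

    def test_referential_integrity_and_clinic_assignment(self, small_bundle):
        _, bundle = small_bundle
        known = set(bundle.demographics["patient_id"])
        for name, df in bundle.tables().items():
            assert set(df["patient_id"]) <= known, name
        assert bundle.demographics["clinic_id"].notna().all()
        assert bundle.demographics["patient_id"].is_unique

    def test_visit_durations_straddle_threshold(self, small_bundle):
        _, bundle = small_bundle
        fp = bundle.visits[bundle.visits["provider_role"] == "family_physician"]
        dur = fp["duration_minutes"]
        assert (dur < 5).mean() > 0.05
        assert (dur >= 5).mean() > 0.5

    def test_diagnoses_use_concrete_matching_codes(self, small_bundle, code_lists):
        _, bundle = small_bundle
        dx = bundle.diagnoses
        assert len(dx)
        diabetic_codes = dx.loc[
            dx["code"].str.startswith(("250", "357", "362", "366")), "code"]
        assert all(code_lists["diabetes"].matches(c) for c in diabetic_codes)

    def test_realised_flags_track_true_probabilities(self, small_bundle,
                                                     scored_cohort):
        """Group patients by ground-truth flag probability; realised flag
        rates (fixed 1.2 threshold) follow the true probabilities."""
        _, bundle = small_bundle
        gt = bundle.ground_truth_patients.set_index("patient_id")
        df = scored_cohort.set_index("patient_id").join(gt)
        df["fixed_flag"] = df["tr"] >= 1.2
        lo = df[df["flag_probability"] < df["flag_probability"].median()]
        hi = df[df["flag_probability"] >= df["flag_probability"].median()]
        assert hi["fixed_flag"].mean() > lo["fixed_flag"].mean()
        overall = df["fixed_flag"].mean()
        assert overall == pytest.approx(df["flag_probability"].mean(),
                                        abs=3 * np.sqrt(0.2 * 0.8 / len(df)))

    def test_bundle_write_produces_all_tables(self, small_bundle, tmp_path):
        _, bundle = small_bundle
        bundle.write(tmp_path)
        names = {p.name for p in tmp_path.glob("*.csv")}
        assert names == {"demographics.csv", "visits.csv", "diagnoses.csv",
                         "labs.csv", "procedures.csv",
                         "ground_truth_patients.csv",
                         "ground_truth_clinics.csv"}
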