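"""Synthetic cohort generator and MetS classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metsim.cohort import (
    GeneratorConfig,
    LinearModel,
    MetSComponents,
    classify_mets,
    config_from_yaml,
    config_to_yaml,
    criterion_indicators,
    default_mediator_distributions,
    generate_cohort,
    generate_components,
    read_cohort_csv,
    write_cohort_csv,
)
from metsim.core import MEDIATOR_CATEGORIES, MEDIATORS


def _components_meeting(flags, sex="male"):
    """Build a component vector meeting exactly the criteria marked True in
    ``flags`` (waist, bp, tg, hdl, glucose)."""
    waist = 105.0 if flags[0] else 80.0
    if sex == "female":
        waist = 90.0 if flags[0] else 70.0
    return MetSComponents(
        waist_cm=waist,
        sbp_mmHg=140.0 if flags[1] else 115.0,
        dbp_mmHg=75.0,
        triglycerides_mmol_l=2.0 if flags[2] else 1.0,
        hdl_mmol_l=(0.8 if sex == "male" else 1.1) if flags[3] else (1.5 if sex == "male" else 1.6),
        glucose_mmol_l=6.0 if flags[4] else 4.8,
    )


class TestClassifier:
    def test_three_of_five_positive(self):
        # waist, blood pressure and glucose criteria met; TG and HDL clear
        comp = MetSComponents(
            waist_cm=105, sbp_mmHg=135, dbp_mmHg=80,
            triglycerides_mmol_l=1.2, hdl_mmol_l=1.2, glucose_mmol_l=5.8,
        )
        assert criterion_indicators(comp, "male") == (True, True, False, False, True)
        assert classify_mets(comp, "male") is True

    def test_all_clear_negative(self):
        comp = MetSComponents(
            waist_cm=75, sbp_mmHg=110, dbp_mmHg=70,
            triglycerides_mmol_l=1.0, hdl_mmol_l=1.6, glucose_mmol_l=4.9,
        )
        assert classify_mets(comp, "female") is False

    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_all_32_criterion_combinations(self, sex):
        """The classifier agrees with a brute-force 'at least 3 of 5' count
        on every possible combination of criterion indicators."""
        for flags in itertools.product([False, True], repeat=5):
            comp = _components_meeting(flags, sex)
            assert criterion_indicators(comp, sex) == flags
            assert classify_mets(comp, sex) == (sum(flags) >= 3)

    def test_medication_counts_as_criterion(self):
        comp = MetSComponents(
            waist_cm=105, sbp_mmHg=110, dbp_mmHg=70,
            triglycerides_mmol_l=1.0, hdl_mmol_l=1.6, glucose_mmol_l=4.9,
            bp_medication=True, glucose_medication=True,
        )
        assert classify_mets(comp, "male") is True

    @pytest.mark.parametrize("field,value", [
        ("waist_cm", -1.0), ("hdl_mmol_l", 0.0), ("glucose_mmol_l", float("nan")),
    ])
    def test_invalid_measurements_rejected(self, field, value):
        comp = MetSComponents(
            waist_cm=90, sbp_mmHg=120, dbp_mmHg=75,
            triglycerides_mmol_l=1.2, hdl_mmol_l=1.4, glucose_mmol_l=5.0,
        )
        setattr(comp, field, value)
        with pytest.raises(ValueError):
            classify_mets(comp, "male")

    @settings(derandomize=True, max_examples=50)
    @given(
        flags=st.tuples(*[st.booleans()] * 5),
        extra=st.integers(min_value=0, max_value=4),
        sex=st.sampled_from(["male", "female"]),
    )
    def test_monotone_in_criteria(self, flags, extra, sex):
        """Turning one more criterion on never flips a positive to negative."""
        before = classify_mets(_components_meeting(flags, sex), sex)
        raised = list(flags)
        raised[extra] = True
        after = classify_mets(_components_meeting(tuple(raised), sex), sex)
        if before:
            assert after


class TestGenerateComponents:
    def test_contract_holds_over_draws(self):
        rng = np.random.default_rng(1)
        for target in (True, False):
            for sex in ("male", "female"):
                for _ in range(500):
                    comp = generate_components(target, sex, rng)
                    assert classify_mets(comp, sex) == target


class TestGenerator:
    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_participants=1000, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(GeneratorConfig(n_participants=1000, seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_incidence_hazard_limit(self):
        """With incidence hazard ~0, nobody healthy at baseline converts."""
        cfg = GeneratorConfig(n_participants=5000, seed=3)
        cfg.incidence_model = LinearModel(intercept=-300.0)
        df = generate_cohort(cfg)
        healthy = df[df.mets_t1 == 0]
        assert (healthy.mets_t4 == 0).all()

    def test_education_only_rates_match_closed_form(self):
        """Education-only hazards: the incident fraction over the follow-up
        matches the exponential closed form 1 - exp(-lambda * dt) per group."""
        lam = {"low": 0.04, "high": 0.02}
        cfg = GeneratorConfig(n_participants=200_000, seed=7)
        cfg.baseline_model = LinearModel(intercept=-30.0)  # everyone starts healthy
        cfg.incidence_model = LinearModel(
            intercept=np.log(lam["high"]), edu_low=np.log(lam["low"] / lam["high"])
        )
        cfg.recovery_model = LinearModel(intercept=-300.0)
        cfg.followup_years_sd = 0.0  # dt exactly 4 years
        df = generate_cohort(cfg)
        for edu, years in (("low", 10), ("high", 16)):
            sub = df[df.edu_years == years]
            expected = 1.0 - np.exp(-4.0 * lam[edu])
            se = np.sqrt(expected * (1 - expected) / len(sub))
            assert abs(sub.mets_t4.mean() - expected) < 3 * se

    def test_mediator_frequencies_match_config(self):
        df = generate_cohort(GeneratorConfig(n_participants=100_000, seed=11))
        dists = default_mediator_distributions()
        for factor in MEDIATORS:
            for edu, years in (("low", 10), ("high", 16)):
                sub = df[df.edu_years == years]
                n = len(sub)
                for cat, p in dists[factor][edu].items():
                    observed = (sub[factor] == cat).mean()
                    se = np.sqrt(p * (1 - p) / n)
                    assert abs(observed - p) < 3 * se, (factor, edu, cat)

    def test_invalid_distribution_rejected(self):
        cfg = GeneratorConfig(n_participants=10)
        cfg.mediator_distributions = dict(default_mediator_distributions())
        cfg.mediator_distributions["smoking"] = {
            "low": {"never": 0.5, "former": 0.2, "current": 0.2},  # sums to 0.9
            "high": {"never": 0.6, "former": 0.3, "current": 0.1},
        }
        with pytest.raises(ValueError):
            generate_cohort(cfg)

    def test_followup_gap_bounds(self):
        df = generate_cohort(GeneratorConfig(n_participants=5000, seed=5))
        gap = df.age_t4 - df.age_t1
        assert (gap >= 1.0).all() and (gap <= 8.0).all()


class TestIO:
    def test_cohort_csv_roundtrip(self, tmp_path):
        df = generate_cohort(GeneratorConfig(n_participants=200, seed=8))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(df, path)
        back = read_cohort_csv(path)
        pd.testing.assert_frame_equal(df, back)

    def test_config_yaml_roundtrip(self):
        cfg = GeneratorConfig(n_participants=123, seed=9)
        text = config_to_yaml(cfg)
        back = config_from_yaml(text)
        assert back.n_participants == 123
        assert back.incidence_model.intercept == cfg.incidence_model.intercept
        assert back.mediator_distributions == cfg.mediator_distributions
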