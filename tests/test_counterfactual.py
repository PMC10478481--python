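"""Mediation ranking and counterfactual reweighting."""

import numpy as np
import pandas as pd
import pytest

from metsim.cohort import (
    GeneratorConfig,
    LinearModel,
    default_mediator_distributions,
    generate_cohort,
)
from metsim.core import Stratum
from metsim.counterfactual import (
    CounterfactualSpec,
    counterfactual_rates,
    factor_marginals,
    mediation_percentages,
    reweighting_weights,
    scenario_rates,
)
from metsim.rates import _assign_age_bins, _at_risk, estimate_rates, stratum_mask


def _education_via_smoking_config(n=150_000, seed=31, direct=0.0):
    """Education shifts smoking; smoking raises incidence; the direct
    education effect on incidence is ``direct``."""
    cfg = GeneratorConfig(n_participants=n, seed=seed)
    cfg.baseline_model = LinearModel(intercept=-30.0)  # all start healthy
    cfg.incidence_model = LinearModel(
        intercept=-4.0,
        age_slope=0.0,
        edu_low=direct,
        mediators={"smoking": {"former": 0.5, "current": 1.2}},
    )
    cfg.recovery_model = LinearModel(intercept=-2.0)
    return cfg


class TestMediation:
    def test_null_mediator_mediates_nothing(self):
        """A factor with identical distributions across education and no
        outcome effect shows ~0% mediation."""
        cfg = _education_via_smoking_config(direct=0.4)
        # make diet independent of education (same distribution both levels)
        dists = default_mediator_distributions()
        dists["diet"]["low"] = dists["diet"]["high"]
        cfg.mediator_distributions = dists
        df = generate_cohort(cfg)
        res = {m.factor: m for m in mediation_percentages(df, "incidence")}
        assert abs(res["diet"].mediated_percent_incidence) < 5.0

    def test_fully_mediated_education_effect(self):
        """When education affects incidence only through smoking, adding
        smoking to the model removes (almost) the whole education
        coefficient."""
        df = generate_cohort(_education_via_smoking_config(n=200_000, direct=0.0))
        res = {m.factor: m for m in mediation_percentages(df, "incidence")}
        assert res["smoking"].mediated_percent_incidence == pytest.approx(100.0, abs=20.0)

    def test_invariant_to_category_relabeling(self):
        df = generate_cohort(_education_via_smoking_config(n=60_000))
        base = {m.factor: m for m in mediation_percentages(df, "incidence")}
        relabeled = df.copy()
        relabeled["smoking"] = relabeled["smoking"].map(
            {"never": "zz_never", "former": "aa_former", "current": "mm_current"}
        )
        new = {m.factor: m for m in mediation_percentages(relabeled, "incidence")}
        assert new["smoking"].mediated_percent_incidence == pytest.approx(
            base["smoking"].mediated_percent_incidence, abs=1e-6
        )

    def test_single_education_group_rejected(self, default_cohort):
        low_only = default_cohort[default_cohort.edu_years == 10]
        with pytest.raises(ValueError):
            mediation_percentages(low_only, "incidence")


class TestReweighting:
    def test_identity_counterfactual_leaves_rates_unchanged(self, default_cohort):
        """Targeting the low group's own marginals gives unit weights and
        reproduces the observed rates to machine precision."""
        spec = CounterfactualSpec(("smoking",))
        own_targets = {}
        for sex in ("female", "male"):
            low_df = _at_risk(
                default_cohort[stratum_mask(default_cohort, Stratum(sex, "low"))],
                "incidence",
            )
            own_targets[sex] = {"smoking": factor_marginals(low_df, "smoking")}
        cf = counterfactual_rates(
            default_cohort, spec, "incidence", target_marginals=own_targets
        )
        observed = [
            r
            for r in estimate_rates(default_cohort, "incidence")
            if r.stratum.education == "low"
        ]
        assert len(cf) == len(observed)
        for a, b in zip(sorted(cf, key=lambda r: (r.stratum.label, r.age_lo)),
                        sorted(observed, key=lambda r: (r.stratum.label, r.age_lo))):
            assert abs(a.rate_per_year - b.rate_per_year) < 1e-12

    def test_binary_mediator_two_term_mixture(self):
        """For a model with a single binary mediator, the weighted mean of
        predictions equals the hand-computed mixture sum P_target(m) p(m)."""
        rng = np.random.default_rng(37)
        n = 40_000
        lit = np.where(rng.random(n) < 0.7, "low", "high")  # P_low = (0.7, 0.3)
        p_event = np.where(lit == "low", 0.25, 0.10)
        rows = pd.DataFrame(
            {
                "id": np.arange(n),
                "sex": "female",
                "edu_years": 10,
                "age_t1": rng.uniform(30, 35, n),  # single age cell
                "mets_t1": 0,
                "mets_t4": (rng.random(n) < p_event).astype(int),
                "smoking": "never",
                "alcohol": "none",
                "diet": "healthy",
                "health_literacy": lit,
            }
        )
        rows["age_t4"] = rows["age_t1"] + 4.0
        # mirror records for the other strata so estimation has all four
        others = []
        for sex, edu in (("female", 16), ("male", 10), ("male", 16)):
            alt = rows.copy()
            alt["sex"] = sex
            alt["edu_years"] = edu
            others.append(alt)
        cohort = pd.concat([rows] + others, ignore_index=True)
        cohort["id"] = np.arange(len(cohort))

        targets = {
            sex: {"health_literacy": {"low": 0.3, "high": 0.7}}
            for sex in ("female", "male")
        }
        cf = counterfactual_rates(
            cohort,
            CounterfactualSpec(("health_literacy",)),
            "incidence",
            target_marginals=targets,
        )
        female_low = [r for r in cf if r.stratum.sex == "female"]
        assert len(female_low) == 1
        # hand mixture: 0.3 * p(low) + 0.7 * p(high) with empirical cell rates
        obs = rows
        p_low = obs[obs.health_literacy == "low"].mets_t4.mean()
        p_high = obs[obs.health_literacy == "high"].mets_t4.mean()
        mixture_prob = 0.3 * p_low + 0.7 * p_high
        expected_rate = -np.log(1 - mixture_prob) / 4.0
        assert female_low[0].rate_per_year == pytest.approx(expected_rate, rel=5e-3)

    def test_joint_weights_factor_into_single_weights(self, default_cohort):
        """With independently generated factors, joint weights equal the
        product of the single-factor weights record by record."""
        low_df = _at_risk(
            default_cohort[stratum_mask(default_cohort, Stratum("female", "low"))],
            "incidence",
        )
        high_df = _at_risk(
            default_cohort[stratum_mask(default_cohort, Stratum("female", "high"))],
            "incidence",
        )
        factors = ("smoking", "alcohol", "diet", "health_literacy")
        targets = {f: factor_marginals(high_df, f) for f in factors}
        joint = reweighting_weights(low_df, CounterfactualSpec(factors), targets)
        product = np.ones(len(low_df))
        for f in factors:
            product *= reweighting_weights(
                low_df, CounterfactualSpec((f,)), {f: targets[f]}
            )
        assert np.allclose(joint, product, rtol=1e-12)

    def test_per_cell_weights_average_to_one(self, default_cohort):
        """Weights computed from a cell's own marginals average to 1 there."""
        spec = CounterfactualSpec(("smoking",))
        for sex in ("female", "male"):
            low_df = _assign_age_bins(
                _at_risk(
                    default_cohort[stratum_mask(default_cohort, Stratum(sex, "low"))],
                    "incidence",
                )
            )
            for label in low_df["_age_bin"].unique():
                cell = low_df[low_df["_age_bin"] == label]
                targets = {"smoking": factor_marginals(cell, "smoking")}
                w = reweighting_weights(cell, spec, targets)
                assert np.mean(w) == pytest.approx(1.0, abs=1e-9)

    def test_category_missing_in_target_errors(self, default_cohort):
        spec = CounterfactualSpec(("smoking",))
        targets = {
            sex: {"smoking": {"never": 1.0, "former": 0.0, "current": 0.0}}
            for sex in ("female", "male")
        }
        with pytest.raises(ValueError, match="former|current"):
            counterfactual_rates(
                default_cohort, spec, "incidence", target_marginals=targets
            )

    def test_scenario_keeps_high_education_rates(self, default_cohort):
        observed = {
            kind: estimate_rates(default_cohort, kind)
            for kind in ("incidence", "recovery")
        }
        rates = scenario_rates(default_cohort, CounterfactualSpec(("smoking",)), observed)
        for kind in ("incidence", "recovery"):
            high_obs = {
                (r.stratum.label, r.age_lo): r.rate_per_year
                for r in observed[kind]
                if r.stratum.education == "high"
            }
            high_cf = {
                (r.stratum.label, r.age_lo): r.rate_per_year
                for r in rates[kind]
                if r.stratum.education == "high"
            }
            assert high_obs == high_cf


class TestSpec:
    def test_joint_detection_and_labels(self):
        assert CounterfactualSpec(("smoking",)).label == "counterfactual_smoking"
        joint = CounterfactualSpec(("smoking", "alcohol", "diet", "health_literacy"))
        assert joint.joint and joint.label == "counterfactual_joint"

    def test_empty_or_unknown_rejected(self):
        with pytest.raises(ValueError):
            CounterfactualSpec(())
        with pytest.raises(ValueError):
            CounterfactualSpec(("exercise",))
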