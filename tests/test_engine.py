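"""Continuous-time simulation engine."""

import numpy as np
import pytest

from metsim.core import HEALTHY, METS, Stratum, all_strata
from metsim.curves import RateCurve
from metsim.engine import (
    CurveSampler,
    LifeCourse,
    SimulationSpec,
    life_courses_from_json,
    life_courses_to_json,
    read_life_courses_csv,
    simulate_cohort,
    simulate_stratum,
    write_life_courses_csv,
)

from conftest import constant_incidence, constant_recovery

ST = Stratum("female", "low")


def _zero_curves():
    return constant_incidence(0.0), constant_recovery(0.0)


class TestLifeCourseInvariants:
    def test_episode_spans_partition_47_years(self):
        lc = LifeCourse(0, ST, HEALTHY, (30.0, 40.5, 60.0))
        spans = lc.episode_spans()
        assert spans[0][1] == 18.0
        assert sum(end - start for _, start, end in spans) == pytest.approx(47.0)
        states = [s for s, _, _ in spans]
        assert states == [HEALTHY, METS, HEALTHY, METS]

    def test_invalid_transition_ages_rejected(self):
        with pytest.raises(ValueError):
            LifeCourse(0, ST, HEALTHY, (30.0, 30.0))
        with pytest.raises(ValueError):
            LifeCourse(0, ST, HEALTHY, (17.0,))

    def test_occupancy_and_onset(self):
        lc = LifeCourse(0, ST, HEALTHY, (40.0, 45.0, 60.0))
        assert lc.mets_occupancy() == pytest.approx(10.0)  # 40-45 and 60-65
        assert lc.first_onset_age() == 40.0
        assert lc.ever_mets()
        initial = LifeCourse(1, ST, METS, ())
        assert initial.first_onset_age() is None
        assert initial.mets_occupancy() == pytest.approx(47.0)


class TestSingleTrajectories:
    def test_null_process_stays_healthy(self):
        inc, rec = _zero_curves()
        lcs = simulate_stratum(ST, inc, rec, 0.0, 50, seed=1)
        for lc in lcs:
            assert lc.first_state == HEALTHY
            assert lc.transition_ages == ()

    def test_absorbing_mets_state(self):
        inc, _ = _zero_curves()
        rec = constant_recovery(0.0)
        lcs = simulate_stratum(ST, inc, rec, 1.0, 50, seed=2)
        for lc in lcs:
            assert lc.first_state == METS
            assert lc.mets_occupancy() == pytest.approx(47.0)

    def test_constant_hazard_transition_fraction(self):
        """lambda = 0.05, no recovery: P(>=1 transition) = 1 - exp(-2.35)."""
        inc = constant_incidence(0.05)
        rec = constant_recovery(0.0)
        lcs = simulate_stratum(ST, inc, rec, 0.0, 100_000, seed=3)
        frac = np.mean([len(lc.transition_ages) > 0 for lc in lcs])
        expected = 1.0 - np.exp(-0.05 * 47)
        se = np.sqrt(expected * (1 - expected) / len(lcs))
        assert abs(frac - expected) < 3 * se

    def test_hazard_bound_guard(self):
        sampler = CurveSampler(RateCurve(ST, "incidence", "logit3", (0.1, 0.0, 40.0)))
        # corrupt the bound table (bound 0.01 < hazard 0.05) to trigger the
        # internal consistency guard
        sampler._suffix_max = [0.01] * len(sampler._suffix_max)
        rec = CurveSampler(constant_recovery(0.0))
        from metsim.engine import simulate_individual, _philox_rng

        with pytest.raises(RuntimeError):
            for i in range(100):
                simulate_individual(i, ST, sampler, rec, 0.0, _philox_rng(1, i))


class TestCohortSimulation:
    def _spec(self, n=200, seed=5):
        curves = {}
        init = {}
        for s in all_strata():
            curves[(s.label, "incidence")] = constant_incidence(0.03, s)
            curves[(s.label, "recovery")] = constant_recovery(0.1, s)
            init[s.label] = 0.05
        return SimulationSpec(curves, init, n, seed)

    def test_reproducible_and_evenly_sized(self):
        spec = self._spec()
        a = simulate_cohort(spec)
        b = simulate_cohort(self._spec())
        assert len(a) == 4 * spec.n_per_group
        for x, y in zip(a, b):
            assert x.first_state == y.first_state
            assert x.transition_ages == y.transition_ages
        for s in all_strata():
            assert sum(lc.stratum == s for lc in a) == spec.n_per_group

    def test_trajectories_independent_of_cohort_size(self):
        """Per-individual random streams: the first 100 individuals are the
        same whether 100 or 1000 are simulated."""
        inc, rec = constant_incidence(0.05), constant_recovery(0.1)
        small = simulate_stratum(ST, inc, rec, 0.1, 100, seed=7)
        large = simulate_stratum(ST, inc, rec, 0.1, 1000, seed=7)
        for a, b in zip(small, large[:100]):
            assert a.first_state == b.first_state
            assert a.transition_ages == b.transition_ages

    def test_missing_curve_rejected(self):
        spec = self._spec()
        del spec.curves[("male_low", "recovery")]
        with pytest.raises(ValueError):
            simulate_cohort(spec)


class TestStochasticOrdering:
    def test_higher_incidence_never_decreases_occupancy_without_recovery(self):
        """With no recovery and a shared candidate stream (common bound and
        per-individual substreams), raising the incidence hazard can only
        move the first accepted event earlier, so per-individual occupancy is
        monotone."""
        rec = constant_recovery(0.0)
        lo = constant_incidence(0.03)
        hi = constant_incidence(0.06)
        bound = 0.12 * 1.01
        occ_lo = [
            lc.mets_occupancy()
            for lc in simulate_stratum(ST, lo, rec, 0.0, 2000, seed=11, bound_override=bound)
        ]
        occ_hi = [
            lc.mets_occupancy()
            for lc in simulate_stratum(ST, hi, rec, 0.0, 2000, seed=11, bound_override=bound)
        ]
        assert all(h >= l - 1e-12 for l, h in zip(occ_lo, occ_hi))

    def test_higher_incidence_increases_mean_occupancy_with_recovery(self):
        """With recovery active only the population mean is ordered (paths
        diverge after the first differing acceptance)."""
        rec = constant_recovery(0.1)
        lo = constant_incidence(0.03)
        hi = constant_incidence(0.06)
        mean_lo = np.mean(
            [lc.mets_occupancy() for lc in simulate_stratum(ST, lo, rec, 0.0, 20_000, seed=13)]
        )
        mean_hi = np.mean(
            [lc.mets_occupancy() for lc in simulate_stratum(ST, hi, rec, 0.0, 20_000, seed=13)]
        )
        assert mean_hi > mean_lo


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        inc, rec = constant_incidence(0.05), constant_recovery(0.1)
        lcs = simulate_stratum(ST, inc, rec, 0.2, 100, seed=17)
        path = tmp_path / "lcs.csv"
        write_life_courses_csv(lcs, path)
        back = read_life_courses_csv(path)
        assert len(back) == len(lcs)
        for a, b in zip(lcs, back):
            assert a.first_state == b.first_state
            assert np.allclose(a.transition_ages, b.transition_ages)

    def test_json_roundtrip(self):
        inc, rec = constant_incidence(0.05), constant_recovery(0.1)
        lcs = simulate_stratum(ST, inc, rec, 0.2, 50, seed=19)
        back = life_courses_from_json(life_courses_to_json(lcs))
        for a, b in zip(lcs, back):
            assert a.stratum == b.stratum
            assert a.transition_ages == tuple(b.transition_ages)
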