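"""Numerical ground truth for the two-state illness process.

The simulator draws individual trajectories; this module instead solves the
forward (Kolmogorov) equations of the same process, giving deterministic
targets the stochastic engine must agree with:

* point prevalence     P'(a) = lambda(a) (1 - P) - mu(a) P,  P(18) = p0
* never-MetS survival  S'(a) = -lambda(a) S,                 S(18) = 1 - p0
* expected occupancy   O'(a) = P(a)
* onset density        f(a) = lambda(a) S(a)  (first onsets among those
  entering healthy), accumulated as its zeroth and first moments.

All five quantities are integrated as one ODE system with an adaptive
stiff-capable integrator (LSODA) at tight tolerance, so oracle error is
negligible next to Monte-Carlo error at any feasible simulation size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import AGE_MAX, AGE_MIN
from .curves import RateCurve, evaluate


def _rhs(incidence: RateCurve, recovery: RateCurve):
    def rhs(a, y):
        P, S, O, m0, m1 = y
        lam = evaluate(incidence, min(max(a, AGE_MIN), AGE_MAX))
        mu = evaluate(recovery, min(max(a, AGE_MIN), AGE_MAX))
        f = lam * S
        return [lam * (1.0 - P) - mu * P, -f, P, f, a * f]

    return rhs


@dataclass
class OracleSolution:
    """Forward-equation solution on an age grid."""

    grid: np.ndarray
    point_prevalence: np.ndarray  # P(a)
    never_prob: np.ndarray  # S(a)
    expected_occupancy: float  # integral of P over [18, 65]
    onset_mass: float  # integral of lambda S
    onset_first_moment: float  # integral of a lambda S

    @property
    def ever_prevalence(self) -> np.ndarray:
        return 1.0 - self.never_prob


def solve(
    incidence: RateCurve,
    recovery: RateCurve,
    p0: float,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
) -> OracleSolution:
    if grid is None:
        grid = np.linspace(AGE_MIN, AGE_MAX, 95)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < AGE_MIN or grid.max() > AGE_MAX:
        raise ValueError("grid must lie within [18, 65]")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 must be in [0,1], got {p0}")
    eval_grid = np.union1d(grid, [AGE_MIN, AGE_MAX])
    sol = solve_ivp(
        _rhs(incidence, recovery),
        (AGE_MIN, AGE_MAX),
        [p0, 1.0 - p0, 0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=eval_grid,
        rtol=rtol,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"forward-equation integration failed: {sol.message}")
    interp_P = np.interp(grid, sol.t, np.clip(sol.y[0], 0.0, 1.0))
    interp_S = np.interp(grid, sol.t, np.clip(sol.y[1], 0.0, 1.0))
    return OracleSolution(
        grid=grid,
        point_prevalence=interp_P,
        never_prob=interp_S,
        expected_occupancy=float(sol.y[2, -1]),
        onset_mass=float(sol.y[3, -1]),
        onset_first_moment=float(sol.y[4, -1]),
    )


def point_prevalence(
    incidence: RateCurve, recovery: RateCurve, p0: float, grid: np.ndarray
) -> np.ndarray:
    return solve(incidence, recovery, p0, grid).point_prevalence


def ever_prevalence(
    incidence: RateCurve, recovery: RateCurve, p0: float, grid: np.ndarray
) -> np.ndarray:
    return solve(incidence, recovery, p0, grid).ever_prevalence


def summary_expectations(
    incidence: RateCurve, recovery: RateCurve, p0: float
) -> tuple[float, float | None, float | None]:
    """Analytic twins of the three life-course summary measures.

    Returns ``(ever_65, mean_onset_age, mean_duration)``:

    * ``ever_65`` — probability of ever occupying the MetS state by 65
      (initial cases count);
    * ``mean_onset_age`` — mean of the first-onset age density
      f(a) = lambda(a) S(a), i.e. among those who enter healthy and develop
      MetS before 65 (None if nobody does);
    * ``mean_duration`` — expected MetS occupancy divided by ``ever_65``:
      never-cases contribute zero occupancy, so the ratio is the mean
      duration among those who ever have MetS (None if ``ever_65`` is 0)."""
    sol = solve(incidence, recovery, p0)
    ever_65 = float(1.0 - sol.never_prob[-1])
    mean_onset = (
        sol.onset_first_moment / sol.onset_mass if sol.onset_mass > 1e-12 else None
    )
    mean_duration = sol.expected_occupancy / ever_65 if ever_65 > 1e-12 else None
    return ever_65, mean_onset, mean_duration
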