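"""Continuous-age parameterization of the age-group transition rates.

The microsimulation needs hazards at arbitrary ages, so the per-age-group
rates are smoothed into parametric curves evaluated at the bin midpoints:

* recovery — a fourth-degree polynomial ``c0 + c1 a + ... + c4 a^4`` fitted
  by ordinary least squares;
* incidence — a three-parameter logistic in age,
  ``L / (1 + exp(-k (a - a0)))``, fitted by nonlinear least squares with
  multi-start initialization (the asymptote L is free).

Evaluations are clipped below at zero: a polynomial may dip negative between
bins, and a hazard cannot be negative, so clipped regions carry hazard
exactly 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import AGE_MAX, AGE_MIN, AgeGroupRate, Stratum


@dataclass
class RateCurve:
    """A continuous-age hazard curve for one stratum and transition kind.

    ``form`` is ``"poly4"`` (params = c0..c4) or ``"logit3"``
    (params = (L, k, a0))."""

    stratum: Stratum
    kind: str
    form: str
    params: tuple

    def __post_init__(self) -> None:
        if self.form not in ("poly4", "logit3"):
            raise ValueError(f"unknown curve form {self.form!r}")
        if self.form == "poly4" and len(self.params) != 5:
            raise ValueError("poly4 curve needs 5 coefficients")
        if self.form == "logit3":
            if len(self.params) != 3:
                raise ValueError("logit3 curve needs 3 parameters (L, k, a0)")
            if self.params[0] < 0:
                raise ValueError("logit3 asymptote L must be nonnegative")
        self.params = tuple(float(p) for p in self.params)


def _raw_evaluate(curve: RateCurve, age: np.ndarray) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if curve.form == "poly4":
        c = curve.params
        return c[0] + age * (c[1] + age * (c[2] + age * (c[3] + age * c[4])))
    L, k, a0 = curve.params
    return L / (1.0 + np.exp(-k * (age - a0)))


def evaluate(curve: RateCurve, age) -> np.ndarray | float:
    """Hazard at ``age`` (years), clipped below at 0.  Ages must lie in the
    simulated range [18, 65]."""
    arr = np.asarray(age, dtype=float)
    if np.any(arr < AGE_MIN) or np.any(arr > AGE_MAX):
        raise ValueError(f"age outside [{AGE_MIN}, {AGE_MAX}]")
    values = np.maximum(_raw_evaluate(curve, arr), 0.0)
    if np.isscalar(age) or arr.ndim == 0:
        return float(values)
    return values


def _points_arrays(points: Sequence[AgeGroupRate]) -> tuple[np.ndarray, np.ndarray]:
    ages = np.array([p.midpoint for p in points], dtype=float)
    rates = np.array([p.rate_per_year for p in points], dtype=float)
    return ages, rates


def fit_recovery_poly(points: Sequence[AgeGroupRate]) -> RateCurve:
    """OLS quartic through the bin-midpoint recovery rates."""
    if len(points) < 5:
        raise ValueError(f"need at least 5 points for a quartic fit, got {len(points)}")
    ages, rates = _points_arrays(points)
    # Vandermonde OLS; rescale age to keep the normal equations well-conditioned.
    scale = 50.0
    V = np.vander(ages / scale, 5, increasing=True)
    coef_scaled, *_ = np.linalg.lstsq(V, rates, rcond=None)
    coef = coef_scaled / scale ** np.arange(5)
    return RateCurve(points[0].stratum, points[0].kind, "poly4", tuple(coef))


def _logistic(age, L, k, a0):
    return L / (1.0 + np.exp(-np.clip(k * (age - a0), -500, 500)))


def fit_incidence_logit(points: Sequence[AgeGroupRate]) -> RateCurve:
    """Three-parameter logistic fit to the bin-midpoint incidence rates.

    Nonlinear least squares from a grid of starting values
    (a0 in {30, 40, 50}, k in {0.05, 0.2}, L = 1.5 x max rate); the start
    with the smallest residual sum of squares wins."""
    if len(points) < 4:
        raise ValueError(f"need at least 4 points for a logistic fit, got {len(points)}")
    ages, rates = _points_arrays(points)
    L0 = 1.5 * max(rates.max(), 1e-8)
    best = None
    best_rss = np.inf
    errors = []
    for a0 in (30.0, 40.0, 50.0):
        for k in (0.05, 0.2):
            try:
                popt, _ = curve_fit(
                    _logistic,
                    ages,
                    rates,
                    p0=(L0, k, a0),
                    bounds=([0.0, -5.0, -100.0], [10.0, 5.0, 200.0]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError) as exc:
                errors.append(str(exc))
                continue
            rss = float(np.sum((_logistic(ages, *popt) - rates) ** 2))
            if rss < best_rss:
                best_rss = rss
                best = popt
    if best is None:
        raise RuntimeError(
            f"logistic fit failed from all starts: {errors[-1] if errors else 'no attempts'}"
        )
    return RateCurve(points[0].stratum, points[0].kind, "logit3", tuple(best))


def fit_curve(points: Sequence[AgeGroupRate]) -> RateCurve:
    """Dispatch on transition kind: logistic for incidence, quartic for recovery."""
    if not points:
        raise ValueError("no points to fit")
    kind = points[0].kind
    if kind == "incidence":
        return fit_incidence_logit(points)
    return fit_recovery_poly(points)


def mean_absolute_error(curve: RateCurve, points: Sequence[AgeGroupRate]) -> float:
    """Internal-validity check: mean |predicted - observed| over the bins."""
    if not points:
        raise ValueError("no points")
    ages, rates = _points_arrays(points)
    return float(np.mean(np.abs(evaluate(curve, ages) - rates)))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def curves_to_json(curves: Sequence[RateCurve]) -> str:
    doc = {}
    for c in curves:
        doc.setdefault(c.stratum.label, {})[c.kind] = {
            "form": c.form,
            "params": list(c.params),
        }
    return json.dumps(doc, indent=2)


def curves_from_json(text: str) -> dict[tuple[str, str], RateCurve]:
    """Parse the curve document into ``{(stratum_label, kind): RateCurve}``."""
    doc = json.loads(text)
    out = {}
    for label, kinds in doc.items():
        sex, education = label.split("_")
        for kind, spec in kinds.items():
            out[(label, kind)] = RateCurve(
                Stratum(sex, education), kind, spec["form"], tuple(spec["params"])
            )
    return out
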