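"""Hill-curve fitting, Loewe additivity surfaces and excess-volume synergy.

The synergy score of a dose-combination matrix is the difference between
the observed viability surface and the Loewe-additive surface expected from
the two monotherapy curves, averaged over the interior cells and scaled by
100 so that clearly synergistic fixtures land near the conventional ">20"
synergy threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

_EC50_UPPER = 1e6  # relative to the largest tested dose


@dataclass
class HillCurve:
    """Decreasing viability curve v(d) = e_inf + (1 - e_inf)/(1 + (d/ec50)^slope)."""

    e_inf: float
    ec50: float
    slope: float
    rmse: float = 0.0
    no_response: bool = False

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if not 0 <= self.e_inf < 1:
            raise ValueError("e_inf must lie in [0, 1)")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def viability(self, dose):
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, (dose / self.ec50) ** self.slope, 0.0)
        return self.e_inf + (1.0 - self.e_inf) / (1.0 + ratio)

    def inverse(self, effect: float) -> float:
        """Dose producing viability ``effect``; inf if unreachable."""
        if effect >= 1.0:
            return 0.0
        if effect <= self.e_inf:
            return np.inf
        return self.ec50 * ((1.0 - effect) / (effect - self.e_inf)) ** (1.0 / self.slope)


@dataclass
class DoseSurface:
    """Viability fractions on a dose grid including the zero-dose margins."""

    doses_1: np.ndarray  # ascending, first element 0
    doses_2: np.ndarray
    values: np.ndarray  # len(doses_1) x len(doses_2)
    clamped: np.ndarray | None = field(default=None)  # bool mask, solver boundary hits

    def __post_init__(self) -> None:
        self.doses_1 = np.asarray(self.doses_1, dtype=float)
        self.doses_2 = np.asarray(self.doses_2, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for d in (self.doses_1, self.doses_2):
            if d[0] != 0 or np.any(np.diff(d) <= 0):
                raise ValueError("doses must be ascending and start at 0")
        if self.values.shape != (len(self.doses_1), len(self.doses_2)):
            raise ValueError("values shape must match the dose grid")
        if np.any(self.values < 0) or np.any(self.values > 1.5):
            raise ValueError("viability values must lie in [0, 1.5]")


def _hill(d, e_inf, ec50, slope):
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ec50) ** slope, 0.0)
    return e_inf + (1.0 - e_inf) / (1.0 + ratio)


def fit_hill(doses, viabilities) -> HillCurve:
    """Bounded least-squares Hill fit; flat data is flagged as no-response."""
    doses = np.asarray(doses, dtype=float)
    viabilities = np.asarray(viabilities, dtype=float)
    if np.sum(doses > 0) < 3:
        raise ValueError("need at least 3 positive doses")
    if not np.isfinite(viabilities).all():
        raise ValueError("viabilities must be finite")
    d_max = doses.max()
    bounds = ([0.0, 1e-9 * d_max, 0.05], [1.0 - 1e-9, _EC50_UPPER * d_max, 10.0])
    p0 = [max(0.0, min(0.99, viabilities.min())), np.median(doses[doses > 0]), 1.0]
    try:
        popt, _ = curve_fit(
            _hill, doses, viabilities, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge (best iterate {p0})") from exc
    e_inf, ec50, slope = popt
    rmse = float(np.sqrt(np.mean((_hill(doses, *popt) - viabilities) ** 2)))
    no_response = ec50 >= 0.99 * _EC50_UPPER * d_max or np.allclose(
        viabilities, 1.0, atol=1e-6
    )
    return HillCurve(
        e_inf=float(min(e_inf, 1 - 1e-12)),
        ec50=float(ec50),
        slope=float(slope),
        rmse=rmse,
        no_response=bool(no_response),
    )


def _loewe_effect(curve1: HillCurve, curve2: HillCurve, d1: float, d2: float):
    """Solve d1/D1(E) + d2/D2(E) = 1 for the expected viability E.

    A drug contributes nothing at effects it cannot reach (its dose-
    equivalent is infinite below its floor e_inf), so the sum is continued
    with that term set to 0; the solved E is flagged as clamped when it
    falls at or below either drug's floor.
    """
    if d1 == 0 and d2 == 0:
        return 1.0, False
    if d2 == 0:
        return float(curve1.viability(d1)), False
    if d1 == 0:
        return float(curve2.viability(d2)), False

    floor = min(curve1.e_inf, curve2.e_inf)

    def index_minus_one(E):
        total = 0.0
        for d, curve in ((d1, curve1), (d2, curve2)):
            D = curve.inverse(E)
            if np.isfinite(D):
                total += d / D
        return total - 1.0

    lo, hi = floor + 1e-12, 1.0 - 1e-12
    if index_minus_one(hi) <= 0:  # doses too small to move below v ~ 1
        return 1.0, False
    if index_minus_one(lo) >= 0:  # doses saturate both drugs
        return floor, True
    E = brentq(index_minus_one, lo, hi, xtol=1e-12, rtol=1e-14)
    clamped = E <= max(curve1.e_inf, curve2.e_inf)
    return float(E), bool(clamped)


def loewe_surface(
    curve1: HillCurve, curve2: HillCurve, doses_1, doses_2
) -> DoseSurface:
    """Expected additive viability surface on the given dose grid.

    ``doses_1``/``doses_2`` are the positive tested doses; the zero-dose
    margins are prepended and filled with the monotherapy curves exactly.
    """
    doses_1 = np.concatenate([[0.0], np.asarray(doses_1, dtype=float)])
    doses_2 = np.concatenate([[0.0], np.asarray(doses_2, dtype=float)])
    values = np.empty((len(doses_1), len(doses_2)))
    clamped = np.zeros_like(values, dtype=bool)
    for i, d1 in enumerate(doses_1):
        for j, d2 in enumerate(doses_2):
            values[i, j], clamped[i, j] = _loewe_effect(curve1, curve2, d1, d2)
    return DoseSurface(doses_1=doses_1, doses_2=doses_2, values=values, clamped=clamped)


def synergy_volume(observed: DoseSurface, expected: DoseSurface) -> dict:
    """Excess-volume synergy score on the shared dose grid.

    score = 100 * mean over interior (non-margin) cells of
    (expected - observed) viability; positive means the combination kills
    more than Loewe additivity predicts.
    """
    if not (
        np.array_equal(observed.doses_1, expected.doses_1)
        and np.array_equal(observed.doses_2, expected.doses_2)
    ):
        raise ValueError("observed and expected surfaces use different dose grids")
    diff = expected.values[1:, 1:] - observed.values[1:, 1:]
    return {
        "score": float(100.0 * diff.mean()),
        "n_cells": int(diff.size),
    }
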