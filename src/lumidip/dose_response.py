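"""Basal-rate normalization, 4PL dose-response fitting, and effect classes.

Rates from drugged conditions are divided by the undrugged basal rate of the
same cell line, so that 1 means "no drug effect", 0 means a static
population (cytostatic), and negative values mean population contraction
(cytotoxic).  The normalized rates across a concentration series are then
fitted to the four-parameter log-logistic model

    y(c) = Emax + (E0 - Emax) / (1 + (c / EC50)^h)

with a free upper asymptote E0 (initialized at 1), lower asymptote Emax
("maximal response"), midpoint EC50 (molar) and Hill coefficient h > 0.
Fitting is done against log10 concentration with multi-start initialization,
because steep-Hill sigmoids have abundant local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .plate_io import RESULT_COLUMNS, PlateValidationError, validate_result_table
from .rate_extraction import RateResult

__all__ = [
    "DoseResponseError",
    "DoseResponsePoint",
    "FitConfig",
    "EffectClass",
    "DoseResponseFit",
    "four_pl",
    "normalize_rates",
    "fit_4pl",
    "classify_effect",
    "classify_effect_coarse",
    "build_result_table",
]


class DoseResponseError(ValueError):
    pass


@dataclass(frozen=True)
class DoseResponsePoint:
    """One concentration's normalized rate (drugged rate / basal rate)."""

    concentration: float  # molar, > 0
    normalized_rate: float

    def __post_init__(self) -> None:
        if not (self.concentration > 0) or not np.isfinite(self.concentration):
            raise DoseResponseError(
                "dose-response points need concentration > 0 (the control enters "
                "as the normalization denominator, not as a point)"
            )


@dataclass(frozen=True)
class FitConfig:
    """Bounds and tolerances for the 4PL fit.

    The Emax floor of -5 and Hill ceiling of 15 keep pathological fits on a
    finite box (screens routinely produce curves with no information below
    the lowest tested dose); estimates landing on a bound are flagged in
    ``bounds_hit`` rather than hidden.
    """

    emax_floor: float = -5.0
    emax_ceiling: float = 1.5
    hill_max: float = 15.0
    ec50_min: float = 1e-12
    ec50_max: float = 1e3
    e0_min: float = -5.0
    e0_max: float = 1.5
    hill_starts: tuple[float, ...] = (0.5, 1.0, 3.0, 8.0)
    max_nfev: int = 2000


class EffectClass(str, Enum):
    NO_EFFECT = "no_effect"
    ANTI_PROLIFERATIVE = "anti_proliferative"
    CYTOSTATIC = "cytostatic"
    CYTOTOXIC = "cytotoxic"
    # Coarse grouping used for cross-channel mechanism concordance: any
    # growth-slowing but non-killing response.
    GROWTH_INHIBITING = "anti_proliferative/cytostatic"


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters plus fit diagnostics."""

    e0: float
    emax: float
    ec50: float
    hill: float
    residuals: float  # sum of squared errors
    effect_class: EffectClass | None = None
    converged: bool = True
    bounds_hit: set[str] = field(default_factory=set)

    def predict(self, concentration) -> np.ndarray:
        return four_pl(concentration, self.e0, self.emax, self.ec50, self.hill)


def four_pl(c, e0: float, emax: float, ec50: float, hill: float):
    """Four-parameter log-logistic response at concentration(s) c (molar)."""
    c = np.asarray(c, dtype=float)
    return emax + (e0 - emax) / (1.0 + (c / ec50) ** hill)


def normalize_rates(
    rates: Iterable[RateResult], basal: RateResult
) -> list[DoseResponsePoint]:
    """Divide each drugged condition's rate by the basal (control) rate.

    The control itself maps to 1 by construction and is excluded from the
    returned points (it anchors the fitted E0 instead).
    """
    if basal.rate == 0:
        raise DoseResponseError(
            f"basal rate for {basal.cell_line} is exactly 0; normalization undefined"
        )
    points = []
    for r in rates:
        if r.concentration == 0:
            continue
        points.append(
            DoseResponsePoint(
                concentration=r.concentration,
                normalized_rate=r.rate / basal.rate,
            )
        )
    return points


def fit_4pl(
    points: Sequence[DoseResponsePoint], config: FitConfig | None = None
) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialization.

    Requires >= 4 points over >= 3 distinct concentrations.  Starts span
    Hill coefficients ``config.hill_starts`` crossed with EC50 seeds at the
    quartiles of the tested concentrations (log10 scale); the best
    converged start by residual sum of squares wins.  If no start
    converges, the best attempt is returned with ``converged=False``.
    """
    config = config or FitConfig()
    if len(points) < 4:
        raise DoseResponseError(f"need >= 4 dose-response points, got {len(points)}")
    conc = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.normalized_rate for p in points], dtype=float)
    if len(np.unique(conc)) < 3:
        raise DoseResponseError("need >= 3 distinct concentrations")

    logc = np.log10(conc)
    lo = np.array([config.e0_min, config.emax_floor,
                   np.log10(config.ec50_min), 1e-6])
    hi = np.array([config.e0_max, config.emax_ceiling,
                   np.log10(config.ec50_max), config.hill_max])

    def resid(p):
        e0, emax, log_ec50, hill = p
        return emax + (e0 - emax) / (1.0 + 10 ** ((logc - log_ec50) * hill)) - y

    emax0 = float(np.clip(np.min(y), config.emax_floor, config.emax_ceiling))
    ec50_seeds = np.percentile(logc, [25, 50, 75])
    best = None
    best_sse = np.inf
    any_converged = False
    for h0 in config.hill_starts:
        for lec0 in ec50_seeds:
            p0 = np.clip(np.array([1.0, emax0, lec0, h0]), lo, hi)
            sol = least_squares(resid, p0, bounds=(lo, hi),
                                max_nfev=config.max_nfev)
            sse = float(np.sum(sol.fun**2))
            if sse < best_sse - 1e-15 or best is None:
                best, best_sse = sol, sse
                any_converged = bool(sol.success) or any_converged
            if sol.success:
                any_converged = True

    e0, emax, log_ec50, hill = best.x
    atol = 1e-8
    bounds_hit = {
        name
        for name, val, lo_v, hi_v in (
            ("e0", e0, lo[0], hi[0]),
            ("emax", emax, lo[1], hi[1]),
            ("ec50", log_ec50, lo[2], hi[2]),
            ("hill", hill, lo[3], hi[3]),
        )
        if abs(val - lo_v) < atol or abs(val - hi_v) < atol
    }
    return DoseResponseFit(
        e0=float(e0),
        emax=float(emax),
        ec50=float(10**log_ec50),
        hill=float(hill),
        residuals=best_sse,
        converged=any_converged,
        bounds_hit=bounds_hit,
    )


def classify_effect(
    fit: DoseResponseFit | float, tol_zero: float = 0.1, tol_one: float = 0.1
) -> EffectClass:
    """Four-class drug-effect mechanism from the maximal response Emax.

    Within ``tol_one`` of 1 -> no effect; within ``tol_zero`` of 0 ->
    cytostatic (population static at saturating drug); below ``-tol_zero``
    -> cytotoxic (population contracts); anything else -> anti-proliferative
    (growth slowed but positive).
    """
    emax = fit.emax if isinstance(fit, DoseResponseFit) else float(fit)
    if abs(emax - 1.0) <= tol_one:
        return EffectClass.NO_EFFECT
    if abs(emax) <= tol_zero:
        return EffectClass.CYTOSTATIC
    if emax < -tol_zero:
        return EffectClass.CYTOTOXIC
    return EffectClass.ANTI_PROLIFERATIVE


def classify_effect_coarse(
    fit: DoseResponseFit | float, tol_one: float = 0.1
) -> EffectClass:
    """Sign-based three-way mechanism grouping used for channel concordance.

    Negative maximal response -> cytotoxic; approximately 1 -> no effect;
    otherwise (non-negative, below 1) -> anti-proliferative/cytostatic.
    The cytostatic/anti-proliferative distinction is deliberately collapsed:
    near-zero responses sit on the boundary between the two and the sign is
    the robust, mechanism-bearing feature.
    """
    emax = fit.emax if isinstance(fit, DoseResponseFit) else float(fit)
    if emax < 0:
        return EffectClass.CYTOTOXIC
    if abs(emax - 1.0) <= tol_one:
        return EffectClass.NO_EFFECT
    return EffectClass.GROWTH_INHIBITING


def build_result_table(
    fits: Iterable[tuple[tuple[str, str, str], DoseResponseFit]]
) -> pd.DataFrame:
    """Assemble fitted parameters into the canonical result table.

    ``fits`` yields ((cell_line, drug, data_type), fit) pairs; data_type is
    "Lum" or "Direct".  Duplicate keys raise.
    """
    rows = []
    seen = set()
    for (cell_line, drug, data_type), fit in fits:
        key = (cell_line, drug, data_type)
        if key in seen:
            raise PlateValidationError(f"duplicate result key {key}")
        seen.add(key)
        rows.append(
            {
                "cell_line": cell_line,
                "drug": drug,
                "data_type": data_type,
                "hill_coef": fit.hill,
                "max_resp": fit.emax,
                "ec50_M": fit.ec50,
                "residuals": fit.residuals,
            }
        )
    table = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    return validate_result_table(table)
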