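"""Rate extraction from continuous luminescence (or count) trajectories.

The central algorithm: within an analysis window ending at the control
condition's luminescence peak ("end of assay"), enumerate every contiguous
trailing slice of at least ``min_points`` timepoints, fit each by ordinary
least squares, and keep the slope of the slice with the highest R².  For the
undrugged control this slope is the *basal rate*; for drugged wells the
window additionally starts at that well's own luminescence peak, so that
post-peak declines (cytotoxic responses) dominate the fit.

Direct-count rates are the classic proliferation-rate estimate: the OLS
slope of log2(counts) versus time over the whole series, in doublings/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .plate_io import WellTimeSeries

__all__ = [
    "RateExtractionError",
    "SliceFit",
    "RateResult",
    "LinearityResult",
    "StaticFit",
    "ols_line",
    "channel_values",
    "peak_time",
    "enumerate_trailing_slices",
    "select_best_slice",
    "extract_rate",
    "count_rate",
    "linearity_check",
    "static_regression",
    "pool_replicates",
]

DEFAULT_MIN_POINTS = 5
DEFAULT_LINEARITY_THRESHOLD = 0.90


class RateExtractionError(ValueError):
    """Raised when a series cannot support the requested rate extraction."""


@dataclass(frozen=True)
class SliceFit:
    """OLS fit over one trailing slice of a series.

    Indices are 0-based and inclusive into the *full* series; ``r2`` is the
    squared Pearson correlation of (t, y) over the slice, which for simple
    linear regression equals the coefficient of determination.
    """

    start_index: int
    end_index: int
    slope: float
    intercept: float
    r2: float

    @property
    def n_points(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class RateResult:
    """A per-condition extracted rate with provenance of the winning slice."""

    cell_line: str
    drug: str
    concentration: float
    replicate: int
    channel: str  # "lum" or "count"
    rate: float
    chosen_slice: SliceFit
    window: tuple[float, float]  # search window [t_start, t_end], hours
    slice_times: tuple[float, float] = (np.nan, np.nan)  # chosen slice span, hours
    warnings: set[str] = field(default_factory=set)

    @property
    def r2(self) -> float:
        return self.chosen_slice.r2


@dataclass(frozen=True)
class LinearityResult:
    r2: float
    passes: bool


@dataclass(frozen=True)
class StaticFit:
    slope: float
    intercept: float
    r2: float


def ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Simple linear regression of y on t: returns (slope, intercept, r2).

    A constant-y slice is fitted exactly by a flat line, so r2 is defined
    as 1.0 there (the Pearson correlation is undefined but the residuals
    vanish identically).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 1.0
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def channel_values(series: WellTimeSeries, channel: str) -> np.ndarray:
    """Return the y-axis for a channel: raw RLU, or log2 cell counts."""
    if channel == "lum":
        return series.rlu
    if channel == "count":
        if series.counts is None:
            raise RateExtractionError(
                f"well {series.cell_line}/{series.drug}: no count channel"
            )
        bad = np.nonzero(series.counts <= 0)[0]
        if len(bad):
            raise RateExtractionError(
                f"well {series.cell_line}/{series.drug}: nonpositive count at "
                f"t={series.times[bad[0]]:g} h cannot be log-transformed"
            )
        return np.log2(series.counts)
    raise ValueError(f"unknown channel {channel!r}")


def peak_time(series: WellTimeSeries, channel: str = "lum") -> float:
    """Time (hours) of the channel's maximum; ties go to the earliest time."""
    y = series.rlu if channel == "lum" else channel_values(series, channel)
    return float(series.times[int(np.argmax(y))])


def enumerate_trailing_slices(
    series: WellTimeSeries,
    window: tuple[float, float],
    min_points: int = DEFAULT_MIN_POINTS,
    channel: str = "lum",
) -> list[SliceFit]:
    """Fit every trailing slice of the window by OLS.

    The window ``[t_start, t_end]`` (inclusive) selects sample times; one
    :class:`SliceFit` is produced per length L = min_points..n_window, each
    slice being the *last* L window points (anchored at the window's final
    timepoint and extending backward contiguously).
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    t_start, t_end = window
    y = channel_values(series, channel)
    idx = np.nonzero((series.times >= t_start) & (series.times <= t_end))[0]
    if len(idx) < min_points:
        raise RateExtractionError(
            f"window [{t_start:g}, {t_end:g}] h holds {len(idx)} samples, "
            f"fewer than min_points={min_points}"
        )
    end = int(idx[-1])
    fits = []
    for length in range(min_points, len(idx) + 1):
        start = int(idx[len(idx) - length])
        slope, intercept, r2 = ols_line(
            series.times[start : end + 1], y[start : end + 1]
        )
        fits.append(SliceFit(start, end, slope, intercept, r2))
    return fits


#: R² differences below this are treated as ties (numerically identical
#: fits, e.g. nested slices of an exact line that differ by one ulp).
R2_TIE_TOL = 1e-9


def select_best_slice(slices: list[SliceFit]) -> SliceFit:
    """The slice with maximal R²; ties broken by the largest point count.

    Ties are resolved at a tolerance of ``R2_TIE_TOL`` so that slices whose
    fits are numerically indistinguishable favor the longer (statistically
    more stable) slice.
    """
    if not slices:
        raise RateExtractionError("no candidate slices to select from")
    best_r2 = max(s.r2 for s in slices)
    tied = [s for s in slices if s.r2 >= best_r2 - R2_TIE_TOL]
    return max(tied, key=lambda s: s.n_points)


def extract_rate(
    series: WellTimeSeries,
    control_peak: float,
    channel: str = "lum",
    min_points: int = DEFAULT_MIN_POINTS,
    is_control: bool = False,
    linearity_threshold: float = DEFAULT_LINEARITY_THRESHOLD,
) -> RateResult:
    """Extract the condition's rate by trailing-slice R² maximization.

    The analysis window ends at ``control_peak`` (the control condition's
    luminescence maximum, defining "end of assay").  Controls are windowed
    from their first timepoint; drugged wells from their own peak, so a
    post-peak decline is what gets fitted.  If the window holds fewer than
    ``min_points`` samples the last ``min_points`` samples ending at
    ``control_peak`` are used instead and a ``short_window_fallback``
    warning is set.
    """
    if len(series.times) < min_points:
        raise RateExtractionError(
            f"series has {len(series.times)} points, fewer than "
            f"min_points={min_points}"
        )
    warnings: set[str] = set()
    t_start = series.times[0] if is_control else peak_time(series, channel)
    window = (float(t_start), float(control_peak))
    in_reach = np.nonzero(series.times <= control_peak)[0]
    if len(in_reach) < min_points:
        raise RateExtractionError(
            f"only {len(in_reach)} samples at or before control peak "
            f"{control_peak:g} h; need {min_points}"
        )
    n_window = int(np.count_nonzero(
        (series.times >= window[0]) & (series.times <= window[1])
    ))
    if n_window < min_points:
        # Drugged peak too close to (or beyond) the assay end: the
        # between-peaks region cannot support a fit.  Fall back to the full
        # pre-end window -- the same treatment the control receives -- so a
        # drug with no effect reproduces the control computation and
        # normalizes to exactly 1.
        warnings.add("short_window_fallback")
        window = (float(series.times[0]), float(control_peak))
    slices = enumerate_trailing_slices(series, window, min_points, channel)
    best = select_best_slice(slices)
    if is_control and best.slope < 0:
        warnings.add("negative_control_rate")
    if best.r2 <= linearity_threshold:
        warnings.add("sub_threshold_linearity")
    return RateResult(
        cell_line=series.cell_line,
        drug=series.drug,
        concentration=series.concentration,
        replicate=series.replicate,
        channel=channel,
        rate=best.slope,
        chosen_slice=best,
        window=window,
        slice_times=(
            float(series.times[best.start_index]),
            float(series.times[best.end_index]),
        ),
        warnings=warnings,
    )


def count_rate(series: WellTimeSeries) -> RateResult:
    """Proliferation rate from direct counts: OLS slope of log2(counts) vs
    time over the full series, in doublings per hour."""
    y = channel_values(series, "count")
    slope, intercept, r2 = ols_line(series.times, y)
    fit = SliceFit(0, len(series.times) - 1, slope, intercept, r2)
    return RateResult(
        cell_line=series.cell_line,
        drug=series.drug,
        concentration=series.concentration,
        replicate=series.replicate,
        channel="count",
        rate=slope,
        chosen_slice=fit,
        window=(float(series.times[0]), float(series.times[-1])),
        slice_times=(float(series.times[0]), float(series.times[-1])),
        warnings=set(),
    )


def linearity_check(
    series: WellTimeSeries,
    threshold: float = DEFAULT_LINEARITY_THRESHOLD,
    channel: str = "lum",
) -> LinearityResult:
    """Full-series linearity QC gate: passes iff full-series R² is *strictly*
    above the threshold (default 0.90)."""
    _, _, r2 = ols_line(series.times, channel_values(series, channel))
    return LinearityResult(r2=r2, passes=bool(r2 > threshold))


def static_regression(cells: np.ndarray, rlu: np.ndarray) -> StaticFit:
    """Static calibration: OLS of single-timepoint RLU on seeded cell number."""
    cells = np.asarray(cells, dtype=float)
    rlu = np.asarray(rlu, dtype=float)
    if cells.shape != rlu.shape or cells.ndim != 1 or len(cells) < 3:
        raise RateExtractionError("need equal-length 1-D vectors with n >= 3")
    if np.ptp(cells) == 0.0:
        raise RateExtractionError("degenerate regressor: all cell numbers equal")
    slope, intercept, r2 = ols_line(cells, rlu)
    return StaticFit(slope=slope, intercept=intercept, r2=r2)


def pool_replicates(wells: list[WellTimeSeries]) -> WellTimeSeries:
    """Average replicate wells of one condition onto their common time grid.

    All replicates must share the same sampling times; RLU (and counts when
    present on every replicate) are averaged pointwise.
    """
    if not wells:
        raise RateExtractionError("no wells to pool")
    first = wells[0]
    for w in wells[1:]:
        if (w.cell_line, w.drug, w.concentration) != (
            first.cell_line, first.drug, first.concentration
        ):
            raise RateExtractionError("cannot pool wells from different conditions")
        if len(w.times) != len(first.times) or not np.allclose(w.times, first.times):
            raise RateExtractionError(
                f"replicates of {first.cell_line}/{first.drug} sample different "
                "time grids; use per-replicate mode"
            )
    counts = None
    if all(w.counts is not None for w in wells):
        counts = np.mean([w.counts for w in wells], axis=0)
        counts = np.round(counts)
    return WellTimeSeries(
        cell_line=first.cell_line,
        drug=first.drug,
        concentration=first.concentration,
        replicate=1,
        times=first.times.copy(),
        rlu=np.mean([w.rlu for w in wells], axis=0),
        counts=counts,
    )
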