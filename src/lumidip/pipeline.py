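"""High-level pipeline: plate -> rates -> dose-response fits -> comparison.

These functions are the library face of the CLI subcommands.  Replicates
are averaged per condition before slicing by default (per-replicate
extraction with post-hoc rate averaging is available); the luminescence
channel drives the end-of-assay definition via the control peak, and the
count channel applies the same trailing-slice machinery to log2 counts.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

import numpy as np
import pandas as pd

from .dose_response import (
    DoseResponseFit,
    FitConfig,
    classify_effect,
    build_result_table,
    fit_4pl,
    normalize_rates,
)
from .plate_io import RATE_COLUMNS, PlateDataset, PlateValidationError, WellTimeSeries
from .rate_extraction import (
    DEFAULT_LINEARITY_THRESHOLD,
    DEFAULT_MIN_POINTS,
    RateExtractionError,
    RateResult,
    extract_rate,
    peak_time,
    pool_replicates,
)

__all__ = [
    "extract_plate_rates",
    "rates_to_table",
    "fit_plate_rates",
    "compare_report",
    "CHANNEL_DATA_TYPE",
]

#: Result-table data_type label per measurement channel.
CHANNEL_DATA_TYPE = {"lum": "Lum", "count": "Direct"}


def _group_conditions(
    dataset: PlateDataset,
) -> dict[tuple[str, str, float], list[WellTimeSeries]]:
    groups: dict[tuple[str, str, float], list[WellTimeSeries]] = defaultdict(list)
    for w in dataset.wells:
        groups[(w.cell_line, w.drug, w.concentration)].append(w)
    return dict(groups)


def extract_plate_rates(
    dataset: PlateDataset,
    channel: str = "lum",
    min_points: int = DEFAULT_MIN_POINTS,
    per_replicate: bool = False,
    linearity_threshold: float = DEFAULT_LINEARITY_THRESHOLD,
) -> list[RateResult]:
    """Extract one rate per condition (default) or per replicate well.

    The end-of-assay timepoint for every condition of a cell line is the
    peak of that line's replicate-averaged control trace.
    """
    groups = _group_conditions(dataset)
    results: list[RateResult] = []
    control_peaks: dict[str, float] = {}
    for (cl, drug, conc), wells in sorted(groups.items()):
        if conc == 0.0 and cl not in control_peaks:
            control_peaks[cl] = peak_time(pool_replicates(wells), channel)
    missing = sorted({cl for cl, _, _ in groups} - set(control_peaks))
    if missing:
        raise PlateValidationError(
            f"no control (concentration 0) wells for cell line(s) {missing}"
        )
    for (cl, drug, conc), wells in sorted(groups.items()):
        peak = control_peaks[cl]
        is_control = conc == 0.0
        targets = wells if per_replicate else [pool_replicates(wells)]
        for series in targets:
            results.append(
                extract_rate(
                    series,
                    control_peak=peak,
                    channel=channel,
                    min_points=min_points,
                    is_control=is_control,
                    linearity_threshold=linearity_threshold,
                )
            )
    return results


def rates_to_table(rates: Iterable[RateResult]) -> pd.DataFrame:
    rows = []
    for r in rates:
        rows.append(
            {
                "cell_line": r.cell_line,
                "drug": r.drug,
                "concentration_M": r.concentration,
                "replicate": r.replicate,
                "channel": r.channel,
                "rate": r.rate,
                "r2": r.r2,
                "slice_start_h": r.slice_times[0],
                "slice_end_h": r.slice_times[1],
                "n_points": r.chosen_slice.n_points,
            }
        )
    return pd.DataFrame(rows, columns=list(RATE_COLUMNS))


def _mean_rates(rates: list[RateResult]) -> list[RateResult]:
    """Average per-replicate rates of each condition into one RateResult."""
    groups: dict[tuple, list[RateResult]] = defaultdict(list)
    for r in rates:
        groups[(r.cell_line, r.drug, r.concentration, r.channel)].append(r)
    out = []
    for (cl, drug, conc, channel), grp in sorted(groups.items()):
        mean_rate = float(np.mean([g.rate for g in grp]))
        rep = grp[0]
        out.append(
            RateResult(
                cell_line=cl,
                drug=drug,
                concentration=conc,
                replicate=1,
                channel=channel,
                rate=mean_rate,
                chosen_slice=rep.chosen_slice,
                window=rep.window,
                slice_times=rep.slice_times,
                warnings=set().union(*(g.warnings for g in grp)),
            )
        )
    return out


def fit_plate_rates(
    rates: list[RateResult],
    fit_config: FitConfig | None = None,
    tol_zero: float = 0.1,
    tol_one: float = 0.1,
    control_drug: str | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], DoseResponseFit]]:
    """Normalize rates to each cell line's basal rate and fit 4PL curves.

    Returns the canonical result table plus the fit objects keyed by
    (cell_line, drug, data_type).  Rates from multiple replicates of one
    condition are averaged before normalization.
    """
    rates = _mean_rates(rates)
    basal: dict[tuple[str, str], RateResult] = {}
    for r in rates:
        if r.concentration == 0.0:
            basal[(r.cell_line, r.channel)] = r
    fits: dict[tuple[str, str, str], DoseResponseFit] = {}
    by_drug: dict[tuple[str, str, str], list[RateResult]] = defaultdict(list)
    for r in rates:
        if r.concentration > 0:
            by_drug[(r.cell_line, r.drug, r.channel)].append(r)
    for (cl, drug, channel), grp in sorted(by_drug.items()):
        if (cl, channel) not in basal:
            raise PlateValidationError(f"no basal rate for {cl} on channel {channel}")
        points = normalize_rates(grp, basal[(cl, channel)])
        fit = fit_4pl(points, fit_config)
        fit.effect_class = classify_effect(fit, tol_zero=tol_zero, tol_one=tol_one)
        fits[(cl, drug, CHANNEL_DATA_TYPE.get(channel, channel))] = fit
    table = build_result_table(sorted(fits.items()))
    return table, fits


def compare_report(
    table: pd.DataFrame,
    alpha: float = 0.05,
    tol_one: float = 0.1,
    channel_a: str = "Lum",
    channel_b: str = "Direct",
) -> dict:
    """Cross-channel comparison report from a two-channel result table:
    exact Wilcoxon on lnEC50 pairs plus mechanism concordance."""
    from .compare_stats import (
        critical_value,
        mechanism_concordance,
        paired_ln_ec50,
        paired_max_resp,
        wilcoxon_exact,
    )

    ec50_pairs = paired_ln_ec50(table, channel_a, channel_b)
    wres = wilcoxon_exact(ec50_pairs)
    emax_pairs = paired_max_resp(table, channel_a, channel_b)
    conc = mechanism_concordance(
        {p.key: p.value_a for p in emax_pairs},
        {p.key: p.value_b for p in emax_pairs},
        tol_one=tol_one,
    )
    crit = critical_value(wres.n_used, alpha) if 5 <= wres.n_used <= 25 else None
    return {
        "n_pairs": wres.n_used,
        "w": wres.w,
        "w_plus": wres.w_plus,
        "w_minus": wres.w_minus,
        "p_two_sided": wres.p_two_sided,
        "method": wres.method,
        "alpha": alpha,
        "critical_value": crit,
        "significant": bool(crit is not None and wres.w <= crit),
        "n_concordant": conc.n_concordant,
        "discordant_keys": [list(k) for k in conc.discordant_keys],
    }
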