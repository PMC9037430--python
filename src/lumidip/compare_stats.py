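"""Paired cross-channel comparison: exact Wilcoxon signed-rank and
mechanism concordance.

EC50s estimated from the luminescence channel are compared with those from
direct cell counting on the natural-log scale, pairwise per (cell line,
drug).  The signed-rank statistic is the *min* rank-sum convention
W = min(W+, W-), so significance is read against a lower-tail critical
value.  P-values and critical values are exact: the full null distribution
over all 2^n sign assignments is enumerated (as a rank-sum convolution,
which visits exactly the same assignment space) whenever n <= 25, with a
continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import DoseResponseFit, EffectClass, classify_effect, classify_effect_coarse

__all__ = [
    "ComparisonError",
    "PairedMetric",
    "WilcoxonResult",
    "ConcordanceResult",
    "EXACT_ENUMERATION_LIMIT",
    "signed_rank_null_distribution",
    "wilcoxon_exact",
    "critical_value",
    "mechanism_concordance",
    "paired_ln_ec50",
    "paired_max_resp",
]

#: Largest n for which the exact null distribution is enumerated; beyond
#: this a normal approximation with continuity correction is used.
EXACT_ENUMERATION_LIMIT = 25


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class PairedMetric:
    """One matched pair of metric values from two measurement channels."""

    key: tuple
    value_a: float
    value_b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.value_a) and np.isfinite(self.value_b)):
            raise ComparisonError(f"non-finite paired value for {self.key}")


@dataclass(frozen=True)
class WilcoxonResult:
    n_used: int
    w_plus: float
    w_minus: float
    w: float
    p_two_sided: float
    method: str  # "exact_enumeration" | "normal_approx"


@dataclass(frozen=True)
class ConcordanceResult:
    n_pairs: int
    n_concordant: int
    discordant_keys: tuple
    classes_a: dict = field(compare=False, default_factory=dict)
    classes_b: dict = field(compare=False, default_factory=dict)


def signed_rank_null_distribution(doubled_ranks: Sequence[int]) -> np.ndarray:
    """Exact null pmf of W+ over all 2^n sign assignments of the given ranks.

    Ranks arrive doubled so that midranks (halves) become integers; the
    returned array pmf[s] is P(2*W+ = s).  The convolution over ranks is
    algebraically identical to summing over every sign assignment.
    """
    doubled_ranks = [int(r) for r in doubled_ranks]
    total = sum(doubled_ranks)
    pmf = np.zeros(total + 1, dtype=float)
    pmf[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def _pairs_to_differences(pairs: Iterable[PairedMetric]) -> np.ndarray:
    pairs = list(pairs)
    if not pairs:
        raise ComparisonError("need at least one pair")
    return np.array([p.value_a - p.value_b for p in pairs], dtype=float)


def wilcoxon_exact(pairs: Iterable[PairedMetric] | np.ndarray) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, exact by default.

    Accepts :class:`PairedMetric` pairs or a raw array of differences.
    Zero differences are dropped (Wilcoxon's original treatment); tied
    absolute differences receive midranks.  The reported statistic is
    W = min(W+, W-); the two-sided p-value is exact for n_used <= 25.
    """
    items = list(pairs) if not isinstance(pairs, np.ndarray) else pairs
    if len(items) == 0:
        raise ComparisonError("need at least one pair")
    if not isinstance(items, np.ndarray) and isinstance(items[0], PairedMetric):
        d = _pairs_to_differences(items)
    else:
        d = np.asarray(items, dtype=float)
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        raise ComparisonError(
            "all paired differences are zero; the signed-rank test is undefined"
        )
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= EXACT_ENUMERATION_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        pmf = signed_rank_null_distribution(doubled)
        cdf = np.cumsum(pmf)
        s = int(round(2 * w_plus))
        p_lo = float(cdf[s])
        p_hi = float(pmf[s:].sum())
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        method = "exact_enumeration"
    else:
        mean = n * (n + 1) / 4.0
        # tie-corrected variance of W+ under the null
        var = float(np.sum(ranks**2)) / 4.0
        z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * float(stats.norm.sf(z)))
        method = "normal_approx"
    return WilcoxonResult(
        n_used=n, w_plus=w_plus, w_minus=w_minus, w=w, p_two_sided=p, method=method
    )


def critical_value(n: int, alpha: float = 0.05) -> int:
    """Exact lower-tail two-sided critical value for the min rank-sum W.

    Returns the largest integer c such that 2 * P(W+ <= c) <= alpha under
    the exact tie-free null (ranks 1..n, all 2^n sign assignments).  The
    test rejects when W <= c.  Returns -1 when the rejection region is
    empty (e.g. alpha = 0).
    """
    if not (5 <= n <= EXACT_ENUMERATION_LIMIT):
        raise ComparisonError(
            f"critical_value supports 5 <= n <= {EXACT_ENUMERATION_LIMIT}, got {n}"
        )
    if not (0 <= alpha <= 1):
        raise ComparisonError("alpha must be in [0, 1]")
    pmf = signed_rank_null_distribution([2 * r for r in range(1, n + 1)])
    # tie-free: W+ takes integer values, pmf index = 2*W+
    cdf = np.cumsum(pmf)
    c = -1
    max_w = n * (n + 1) // 2
    for cand in range(0, max_w + 1):
        if 2.0 * cdf[2 * cand] <= alpha:
            c = cand
        else:
            break
    return c


def mechanism_concordance(
    fits_a: Mapping[tuple, DoseResponseFit | float],
    fits_b: Mapping[tuple, DoseResponseFit | float],
    tol_zero: float = 0.1,
    tol_one: float = 0.1,
    scheme: str = "sign",
) -> ConcordanceResult:
    """Count pairs whose two channels agree on drug-effect mechanism.

    ``scheme="sign"`` (default) applies the coarse sign-based grouping
    (cytotoxic vs anti-proliferative/cytostatic vs no-effect);
    ``scheme="four_class"`` applies the fine tolerance-based classifier.
    Key sets of the two mappings must match exactly.
    """
    keys_a, keys_b = set(fits_a), set(fits_b)
    if keys_a != keys_b:
        missing_a = sorted(keys_b - keys_a)
        missing_b = sorted(keys_a - keys_b)
        raise ComparisonError(
            f"mismatched key sets; missing from A: {missing_a}, "
            f"missing from B: {missing_b}"
        )
    if scheme == "sign":
        classify = lambda f: classify_effect_coarse(f, tol_one=tol_one)
    elif scheme == "four_class":
        classify = lambda f: classify_effect(f, tol_zero=tol_zero, tol_one=tol_one)
    else:
        raise ComparisonError(f"unknown scheme {scheme!r}")
    classes_a = {k: classify(fits_a[k]) for k in keys_a}
    classes_b = {k: classify(fits_b[k]) for k in keys_a}
    discordant = tuple(sorted(k for k in keys_a if classes_a[k] != classes_b[k]))
    return ConcordanceResult(
        n_pairs=len(keys_a),
        n_concordant=len(keys_a) - len(discordant),
        discordant_keys=discordant,
        classes_a=classes_a,
        classes_b=classes_b,
    )


# --- result-table pairing helpers -------------------------------------------

def _paired_column(
    table: pd.DataFrame,
    column: str,
    channel_a: str = "Lum",
    channel_b: str = "Direct",
    transform=None,
) -> list[PairedMetric]:
    sub = {}
    for channel in (channel_a, channel_b):
        part = table[table["data_type"] == channel]
        sub[channel] = part.set_index(["cell_line", "drug"])[column]
    keys = sorted(set(sub[channel_a].index) & set(sub[channel_b].index))
    if not keys:
        raise ComparisonError(
            f"no (cell_line, drug) keys shared between {channel_a} and {channel_b}"
        )
    out = []
    for k in keys:
        a, b = float(sub[channel_a][k]), float(sub[channel_b][k])
        if transform is not None:
            a, b = transform(a), transform(b)
        out.append(PairedMetric(key=k, value_a=a, value_b=b))
    return out


def paired_ln_ec50(
    table: pd.DataFrame, channel_a: str = "Lum", channel_b: str = "Direct"
) -> list[PairedMetric]:
    """ln(EC50) pairs per (cell_line, drug) shared by both channels."""
    return _paired_column(table, "ec50_M", channel_a, channel_b, transform=np.log)


def paired_max_resp(
    table: pd.DataFrame, channel_a: str = "Lum", channel_b: str = "Direct"
) -> list[PairedMetric]:
    """Maximal-response (Emax) pairs per (cell_line, drug)."""
    return _paired_column(table, "max_resp", channel_a, channel_b)
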