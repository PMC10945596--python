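"""Cross-stratum (nested) rhythm analysis.

Long calls carry two rhythmic strata: full pulses recurring near one tempo,
and sub-pulses recurring at faster, type-specific tempi *inside* each pulse.
The link between strata is the nested ratio

    nested_ratio = t_k(sub-pulse) / t_k(enclosing full pulse)

where the enclosing pulse's t_k is its onset-to-next-pulse-onset interval
(consistent with all IOIs being defined from begin times).  Sub-pulses inside
a call's final pulse have no enclosing interval and contribute nothing.

A unimodal concentration of nested ratios is quantified two ways: the peak of
their kernel density, and a paired test that the *central* quartiles of each
unit's nested-ratio distribution span less than the *peripheral* quartiles
(peakedness), assessed with a one-sided Wilcoxon signed-rank test across
units (long calls by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .rhythm import DensityPeak, IOISeries, _kde

log = logging.getLogger(__name__)

NESTED_COLUMNS = ("nested_ratio", "sub_type", "individual_id", "long_call_id",
                  "parent_pulse_id", "sub_t_k", "full_t_k")


@dataclass
class NestedRatioSeries:
    """Sub-pulse IOIs divided by their enclosing full-pulse IOI (tidy frame)."""

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def nested_ratio(self) -> np.ndarray:
        return self.data["nested_ratio"].to_numpy(float)


@dataclass
class QuartileExtentResult:
    """Paired central-vs-peripheral quartile spans and their Wilcoxon test."""

    units: int
    unit_ids: list[str]
    central_extents: np.ndarray
    peripheral_extents: np.ndarray
    W: float
    p_value: float
    method: str  # 'exact' or 'approx'


def pair_nested_iois(sub_series: IOISeries,
                     full_series: IOISeries) -> NestedRatioSeries:
    """Divide each sub-pulse IOI by the IOI of its enclosing full pulse.

    The full-pulse IOI is looked up by the enclosing pulse's event id (the
    pulse whose onset starts the interval).  Sub-pulse intervals whose parent
    pulse has no successor (final pulse of a call) or cannot be resolved are
    skipped and counted in a log message, never fatal.
    """
    full = full_series.data
    lookup: dict[tuple[str, str], float] = {
        (str(r.long_call_id), str(r.source_event_id)): float(r.t_k)
        for r in full.itertuples(index=False)
    }
    rows, skipped = [], 0
    for r in sub_series.data.itertuples(index=False):
        parent = r.parent_pulse_id
        if pd.isna(parent):
            skipped += 1
            continue
        full_t = lookup.get((str(r.long_call_id), str(parent)))
        if full_t is None:
            skipped += 1
            continue
        rows.append({
            "nested_ratio": float(r.t_k) / full_t,
            "sub_type": r.element_type,
            "individual_id": r.individual_id,
            "long_call_id": r.long_call_id,
            "parent_pulse_id": parent,
            "sub_t_k": float(r.t_k),
            "full_t_k": full_t,
        })
    if skipped:
        log.info("pair_nested_iois: skipped %d sub-pulse intervals without an "
                 "enclosing full-pulse interval", skipped)
    return NestedRatioSeries(pd.DataFrame(rows, columns=list(NESTED_COLUMNS)))


def nested_density_peak(series: NestedRatioSeries | np.ndarray,
                        bandwidth: float | str | None = None,
                        grid_size: int = 512) -> DensityPeak:
    """Gaussian KDE of nested ratios and its global peak.

    Same estimator conventions as :func:`longcall.rhythm.ratio_density`, but
    on a grid spanning [0, max ratio] (padded by one bandwidth so a peak at
    the edge is representable).  Requires at least 10 values.
    """
    values = series.nested_ratio if isinstance(series, NestedRatioSeries) \
        else np.asarray(series, dtype=float)
    if len(values) < 10:
        raise InsufficientDataError(
            f"nested density needs >= 10 values, got {len(values)}")
    hi = float(np.max(values))
    sd = float(np.std(values))
    pad = max(0.05 * hi, sd * len(values) ** -0.2, 1e-6)
    grid = np.linspace(0.0, hi + pad, grid_size)
    dens, bw = _kde(values, grid, bandwidth)
    i = int(np.argmax(dens))
    return DensityPeak(grid=grid, density=dens, bandwidth=bw,
                       peak_location=float(grid[i]),
                       peak_density=float(dens[i]))


def wilcoxon_signed_rank(differences: np.ndarray, alternative: str = "less",
                         exact_max_n: int = 25,
                         zero_atol: float = 0.0) -> tuple[float, float, str]:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Differences with magnitude <= ``zero_atol`` count as zero and are
    dropped (Wilcoxon convention).  With at most ``exact_max_n`` non-zero
    differences the exact null distribution is used; beyond that, the normal
    approximation with continuity correction.  Returns ``(W, p, method)``
    where W is the positive-rank sum.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.abs(d) > zero_atol]
    if len(d) == 0:
        return 0.0, 1.0, "degenerate"
    if len(d) <= exact_max_n and not _has_tied_ranks(d):
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method,
                         correction=(method == "approx"))
    # scipy's one-sided statistic is the positive-rank sum
    return float(res.statistic), float(res.pvalue), method


def _has_tied_ranks(d: np.ndarray) -> bool:
    return len(np.unique(np.abs(d))) < len(d)


def wilcoxon_exact_enumeration(differences: np.ndarray,
                               alternative: str = "less") -> tuple[float, float]:
    """Brute-force Wilcoxon signed-rank by enumerating all sign assignments.

    Independent oracle for :func:`wilcoxon_signed_rank`; O(2^n), intended for
    n <= 12.  Returns (W, p) with W the positive-rank sum of the observed
    signs and p the exact one-sided tail probability under random signs.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    if n > 16:
        raise ValueError("enumeration oracle limited to n <= 16")
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    count = 0
    total = 2 ** n
    for signs in itertools.product((0, 1), repeat=n):
        w = float(np.sum(ranks[np.array(signs, dtype=bool)]))
        if alternative == "less":
            count += w <= w_obs
        elif alternative == "greater":
            count += w >= w_obs
        else:  # two-sided: double the smaller tail, capped at 1
            raise ValueError("enumeration oracle supports one-sided only")
    return w_obs, count / total


def quartile_extent_test(series: NestedRatioSeries,
                         unit: str = "long_call_id",
                         min_units: int = 6,
                         min_obs: int = 8) -> QuartileExtentResult:
    """Test that central quartiles span less than peripheral quartiles.

    Per unit (default: long call) the nested ratios are sorted and split into
    four equal-count blocks.  The *central extent* is the span (max − min) of
    the pooled 2nd+3rd blocks; the *peripheral extent* is the summed span of
    the 1st and 4th blocks — the total length covered by the distribution's
    tails.  For a sharply peaked distribution the centre is much narrower than
    the tails; for a uniform one the two extents are equal in expectation.

    The paired extents are compared across units with a one-sided Wilcoxon
    signed-rank test (central < peripheral); exact null for few units, normal
    approximation with continuity correction otherwise.
    """
    df = series.data
    kept_ids, central, peripheral = [], [], []
    for uid, grp in df.groupby(unit, sort=False):
        vals = np.sort(grp["nested_ratio"].to_numpy(float))
        if len(vals) < min_obs:
            continue
        q1, q2, q3, q4 = np.array_split(vals, 4)
        kept_ids.append(str(uid))
        central.append(float(np.max(q3) - np.min(q2)))
        peripheral.append(float((np.max(q1) - np.min(q1))
                                + (np.max(q4) - np.min(q4))))
    if len(kept_ids) < min_units:
        raise InsufficientDataError(
            f"quartile extent test needs >= {min_units} units with >= "
            f"{min_obs} observations; got {len(kept_ids)}")
    central = np.asarray(central)
    peripheral = np.asarray(peripheral)
    # extents identical up to rounding noise carry no evidence either way
    atol = 1e-9 * float(np.max(np.abs(np.concatenate([central, peripheral])),
                               initial=1e-300))
    w, p, method = wilcoxon_signed_rank(central - peripheral,
                                        alternative="less", zero_atol=atol)
    return QuartileExtentResult(units=len(kept_ids), unit_ids=kept_ids,
                                central_extents=central,
                                peripheral_extents=peripheral,
                                W=w, p_value=p, method=method)
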