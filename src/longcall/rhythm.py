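"""Inter-onset-interval and rhythm-ratio statistics.

The rhythmic structure of a call sequence is summarized by inter-onset
intervals (IOIs) t_k — the time from one element's onset to the next onset of
a *same-type* element — and by the scale-free rhythm ratio

    r_k = t_k / (t_k + t_{k+1})

computed for temporally adjacent interval pairs.  A perfectly isochronous
(1:1) sequence has r_k = 0.5 for every pair; other small-integer rhythm
categories peak elsewhere (1:2 alternation gives 1/3 and 2/3).

Isochrony is operationalized by counting ratios inside an *on-isochrony* band
(0.440, 0.555) versus two flanking *off-isochrony* bands (0.400, 0.440) and
(0.555, 0.600); band membership uses strict inequalities, so values exactly on
a boundary fall in no band.  Distribution peaks are read off a Gaussian-kernel
density estimate on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .tables_io import ELEMENT_TYPES, FULL_PULSE, SUB_PULSE_TYPES, EventTable

ON_BAND = "on"
OFF_BAND = "off"
OUTSIDE_BAND = "outside"


@dataclass(frozen=True)
class IsochronyBands:
    """On/off-isochrony ratio bands (open intervals around r = 0.5).

    Defaults follow the standard protocol: on-isochrony (0.440, 0.555),
    off-isochrony (0.400, 0.440) ∪ (0.555, 0.600).  The on band contains 0.5;
    membership is strict, so boundary values belong to no band.
    """

    on: tuple[float, float] = (0.440, 0.555)
    off_low: tuple[float, float] = (0.400, 0.440)
    off_high: tuple[float, float] = (0.555, 0.600)

    def __post_init__(self) -> None:
        lo, hi = self.off_low, self.off_high
        on = self.on
        if not (lo[0] < lo[1] <= on[0] < on[1] <= hi[0] < hi[1]):
            raise ValueError("isochrony bands must be ordered and disjoint")
        if not (on[0] < 0.5 < on[1]):
            raise ValueError("on-isochrony band must contain 0.5")

    @property
    def on_width(self) -> float:
        return self.on[1] - self.on[0]

    @property
    def off_width(self) -> float:
        return (self.off_low[1] - self.off_low[0]) + (self.off_high[1] - self.off_high[0])

    @property
    def outside_width(self) -> float:
        return 1.0 - self.on_width - self.off_width

    def width(self, band: str) -> float:
        return {ON_BAND: self.on_width, OFF_BAND: self.off_width,
                OUTSIDE_BAND: self.outside_width}[band]

    def classify(self, r: np.ndarray) -> np.ndarray:
        """Label each ratio 'on', 'off' or 'outside' (strict boundaries)."""
        r = np.asarray(r, dtype=float)
        out = np.full(r.shape, OUTSIDE_BAND, dtype=object)
        out[(r > self.on[0]) & (r < self.on[1])] = ON_BAND
        off = ((r > self.off_low[0]) & (r < self.off_low[1])) | \
              ((r > self.off_high[0]) & (r < self.off_high[1]))
        out[off] = OFF_BAND
        return out


DEFAULT_BANDS = IsochronyBands()

#: Columns of the tidy IOI frame.
IOI_COLUMNS = ("t_k", "element_type", "long_call_id", "individual_id",
               "parent_pulse_id", "sequence_id", "source_event_id")
#: Columns of the tidy ratio frame.
RATIO_COLUMNS = ("r_k", "band", "element_type", "long_call_id",
                 "individual_id", "sequence_id")


@dataclass
class IOISeries:
    """Inter-onset intervals t_k as a tidy frame (one row per interval).

    ``sequence_id`` groups runs of temporally adjacent same-type intervals;
    ratios are only ever formed inside one sequence.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t_k(self) -> np.ndarray:
        return self.data["t_k"].to_numpy(float)

    @classmethod
    def from_values(cls, t_k: Sequence[float], element_type: str = FULL_PULSE,
                    long_call_id: str = "call_0", individual_id: str = "ind_0",
                    sequence_id: str = "seq_0") -> "IOISeries":
        """Build a single-sequence series from raw interval values."""
        t = np.asarray(list(t_k), dtype=float)
        df = pd.DataFrame({
            "t_k": t,
            "element_type": element_type,
            "long_call_id": long_call_id,
            "individual_id": individual_id,
            "parent_pulse_id": pd.NA,
            "sequence_id": sequence_id,
            "source_event_id": [f"{sequence_id}:{i}" for i in range(len(t))],
        })
        return cls(df)


@dataclass
class RatioSeries:
    """Rhythm ratios r_k with band labels, as a tidy frame."""

    data: pd.DataFrame
    bands: IsochronyBands = field(default_factory=IsochronyBands)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def r_k(self) -> np.ndarray:
        return self.data["r_k"].to_numpy(float)


@dataclass(frozen=True)
class TempoSummary:
    """Per-type tempo: moments of t_k and of the per-interval rate 1/t_k."""

    element_type: str
    n: int
    mean_t: float
    sd_t: float
    mean_rate: float
    sd_rate: float


@dataclass
class DensityPeak:
    """A kernel density estimate of a ratio distribution and its peaks.

    ``peak_location`` is the grid argmax over the whole support;
    ``restricted_peak_location`` the argmax inside ``restrict_interval``
    (the on/off-isochrony window by default), which is the headline
    isochrony peak.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peak_location: float
    peak_density: float
    restrict_interval: tuple[float, float] | None = None
    restricted_peak_location: float | None = None
    restricted_peak_density: float | None = None

    def local_maxima(self) -> np.ndarray:
        """Grid locations of interior local maxima of the density curve."""
        d = self.density
        idx = np.where((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:]))[0] + 1
        return self.grid[idx]


def compute_iois(table: EventTable, element_type: str,
                 within_parent: bool | None = None) -> IOISeries:
    """Extract same-type inter-onset intervals from an event table.

    t_k is the difference between the begin times of consecutive elements of
    ``element_type`` within one long call.  For sub-pulse types,
    ``within_parent`` (default True) additionally requires both elements to
    share their enclosing full pulse, so no interval spans a pulse boundary;
    full pulses ignore the flag.  Each maximal run of pairable elements gets
    its own ``sequence_id``.

    A table containing no such elements yields an empty series.
    """
    if element_type not in ELEMENT_TYPES:
        raise ValueError(
            f"unknown element_type '{element_type}'; expected one of {ELEMENT_TYPES}")
    if within_parent is None:
        within_parent = element_type in SUB_PULSE_TYPES
    df = table.data
    sel = df[df["element_type"] == element_type]
    rows: list[dict] = []
    if element_type in SUB_PULSE_TYPES and within_parent:
        group_cols = ["long_call_id", "parent_pulse_id"]
    else:
        group_cols = ["long_call_id"]
    for key, grp in sel.groupby(group_cols, sort=False, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        grp = grp.sort_values("begin_time", kind="stable")
        onsets = grp["begin_time"].to_numpy(float)
        if len(onsets) < 2:
            continue
        seq_id = "/".join("NA" if pd.isna(k) else str(k) for k in key) \
            + f"/{element_type}"
        ids = grp["event_id"].to_numpy(str)
        indiv = grp["individual_id"].iloc[0]
        parent = grp["parent_pulse_id"].iloc[0] if "parent_pulse_id" in group_cols \
            or element_type in SUB_PULSE_TYPES else pd.NA
        for i in range(len(onsets) - 1):
            rows.append({
                "t_k": onsets[i + 1] - onsets[i],
                "element_type": element_type,
                "long_call_id": key[0],
                "individual_id": indiv,
                "parent_pulse_id": parent,
                "sequence_id": seq_id,
                "source_event_id": ids[i],
            })
    return IOISeries(pd.DataFrame(rows, columns=list(IOI_COLUMNS)))


def filter_iois(series: IOISeries, min_t: float = 0.025,
                max_t: float = 5.0) -> IOISeries:
    """Keep intervals with ``min_t < t_k < max_t`` (strict bounds).

    Removing an interior interval splits its sequence: the retained runs on
    either side get distinct ``sequence_id`` values, so ratios never bridge a
    discarded interval.  Intact sequences keep their original id.
    """
    if not min_t < max_t:
        raise ValueError("min_t must be < max_t")
    df = series.data
    if df.empty:
        return IOISeries(df.copy())
    t = df["t_k"].to_numpy(float)
    keep = (t > min_t) & (t < max_t)
    parts = []
    for seq, grp in df.groupby("sequence_id", sort=False):
        kept_mask = keep[grp.index.to_numpy()]
        removed_before = np.cumsum(~kept_mask)
        sub = grp[kept_mask].copy()
        if len(sub) == 0:
            continue
        part_no = removed_before[kept_mask]
        sub["sequence_id"] = [seq if p == 0 else f"{seq}#{p}" for p in part_no]
        parts.append(sub)
    if not parts:
        return IOISeries(df.iloc[0:0].copy())
    return IOISeries(pd.concat(parts, axis=0))


def compute_ratios(series: IOISeries,
                   bands: IsochronyBands = DEFAULT_BANDS) -> RatioSeries:
    """Compute r_k = t_k / (t_k + t_{k+1}) for adjacent pairs of a sequence.

    One ratio per ordered pair of consecutive intervals within each
    ``sequence_id``; each ratio carries its isochrony-band label.
    """
    df = series.data
    rows = []
    for seq, grp in df.groupby("sequence_id", sort=False):
        t = grp["t_k"].to_numpy(float)
        if len(t) < 2:
            continue
        r = t[:-1] / (t[:-1] + t[1:])
        rows.append(pd.DataFrame({
            "r_k": r,
            "band": bands.classify(r),
            "element_type": grp["element_type"].iloc[0],
            "long_call_id": grp["long_call_id"].iloc[0],
            "individual_id": grp["individual_id"].iloc[0],
            "sequence_id": seq,
        }))
    if not rows:
        return RatioSeries(pd.DataFrame(columns=list(RATIO_COLUMNS)), bands)
    return RatioSeries(pd.concat(rows, ignore_index=True), bands)


def band_counts(ratios: RatioSeries,
                group_by: Sequence[str] = ("element_type", "individual_id"),
                bands: IsochronyBands | None = None) -> pd.DataFrame:
    """Count ratios per group and isochrony band.

    Returns a tidy frame with one row per group × band ('on', 'off',
    'outside'; zero-filled), a ``count`` column and the band's total ratio
    width ``band_width`` (0.115 on, 0.085 off by default) for use as a model
    offset.  Counts conserve: on + off + outside = total per group.
    """
    bands = bands or ratios.bands
    df = ratios.data
    group_by = list(group_by)
    if df.empty:
        return pd.DataFrame(columns=group_by + ["band", "count", "band_width"])
    counted = (df.groupby(group_by + ["band"], sort=False, dropna=False)
                 .size().rename("count").reset_index())
    groups = df[group_by].drop_duplicates()
    full = groups.merge(pd.DataFrame({"band": [ON_BAND, OFF_BAND, OUTSIDE_BAND]}),
                        how="cross")
    out = full.merge(counted, on=group_by + ["band"], how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    out["band_width"] = [bands.width(b) for b in out["band"]]
    return out.reset_index(drop=True)


def _kde(values: np.ndarray, grid: np.ndarray,
         bandwidth: float | str | None) -> tuple[np.ndarray, float]:
    """Gaussian KDE evaluated on a grid; degenerate samples get a narrow kernel."""
    sd = float(np.std(values))
    if sd == 0.0 or len(np.unique(values)) == 1:
        bw = 1e-3 if not isinstance(bandwidth, (int, float)) else float(bandwidth)
        dens = np.exp(-0.5 * ((grid - values[0]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
        return dens, bw
    bw_method = "silverman" if bandwidth is None else bandwidth
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    return kde(grid), float(kde.factor * sd)


def ratio_density(ratios: RatioSeries | np.ndarray,
                  bandwidth: float | str | None = None,
                  grid_size: int = 512,
                  restrict: tuple[float, float] = (0.400, 0.600)) -> DensityPeak:
    """Gaussian-kernel density of rhythm ratios on [0, 1] and its peaks.

    ``bandwidth`` follows :func:`scipy.stats.gaussian_kde` conventions
    (default: Silverman's rule).  Requires at least 10 ratio values.  Besides
    the global grid argmax, the argmax restricted to the open isochrony window
    ``restrict`` is reported — the headline on-isochrony peak.
    """
    values = ratios.r_k if isinstance(ratios, RatioSeries) else \
        np.asarray(ratios, dtype=float)
    if len(values) < 10:
        raise InsufficientDataError(
            f"ratio density needs >= 10 values, got {len(values)}")
    grid = np.linspace(0.0, 1.0, grid_size)
    dens, bw = _kde(values, grid, bandwidth)
    i_max = int(np.argmax(dens))
    peak = DensityPeak(grid=grid, density=dens, bandwidth=bw,
                       peak_location=float(grid[i_max]),
                       peak_density=float(dens[i_max]),
                       restrict_interval=restrict)
    inside = (grid > restrict[0]) & (grid < restrict[1])
    if inside.any():
        j = np.argmax(np.where(inside, dens, -np.inf))
        peak.restricted_peak_location = float(grid[j])
        peak.restricted_peak_density = float(dens[j])
    return peak


def tempo_summary(series: IOISeries) -> TempoSummary:
    """Mean/sd of t_k and of the per-interval rate 1/t_k.

    ``mean_rate`` is the mean of per-interval rates 1/t_k (not 1/mean(t_k));
    for pooled heterogeneous sequences the two differ substantially and the
    per-interval mean is the reported tempo.
    """
    if len(series) == 0:
        raise InsufficientDataError("tempo summary of an empty IOI series")
    t = series.t_k
    types = series.data["element_type"].unique()
    label = types[0] if len(types) == 1 else "pooled"
    rate = 1.0 / t
    ddof = 1 if len(t) > 1 else 0
    return TempoSummary(
        element_type=str(label),
        n=len(t),
        mean_t=float(np.mean(t)),
        sd_t=float(np.std(t, ddof=ddof)),
        mean_rate=float(np.mean(rate)),
        sd_rate=float(np.std(rate, ddof=ddof)),
    )
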