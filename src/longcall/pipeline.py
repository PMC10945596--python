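"""One-shot rhythm analysis of an event table.

Runs, per element type: IOI extraction → duration filter → rhythm ratios →
band counts → density peaks → tempo summary; then the nested (cross-stratum)
analysis, the band-count model and the binomial cross-check.  Returns a
JSON-serializable summary plus the tidy intermediate frames, mirroring the
quantities a rhythm study reports (per-type ratio peaks, on/off counts,
tempo means, nested peak, likelihood-ratio test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nested as nested_mod
from . import rhythm
from .band_models import binomial_band_check, fit_band_count_model
from .errors import InsufficientDataError, LongCallError
from .rhythm import IsochronyBands
from .tables_io import ELEMENT_TYPES, FULL_PULSE, SUB_PULSE_TYPES, EventTable

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Knobs of the one-shot analysis (filter bounds, bands, KDE settings)."""

    min_t: float = 0.025
    max_t: float = 5.0
    bands: IsochronyBands = field(default_factory=IsochronyBands)
    kde_bandwidth: float | str | None = None   # None = Silverman
    kde_grid_size: int = 512
    within_parent: bool = True
    quartile_unit: str = "long_call_id"


@dataclass
class AnalysisResult:
    summary: dict
    iois: pd.DataFrame
    ratios: pd.DataFrame
    band_counts: pd.DataFrame
    nested_ratios: pd.DataFrame
    densities: dict[str, pd.DataFrame]


def analyze_events(table: EventTable,
                   config: AnalysisConfig | None = None) -> AnalysisResult:
    config = config or AnalysisConfig()
    summary: dict = {"element_types": {}, "nested": {}, "band_model": None,
                     "binomial_check": []}
    ioi_frames, ratio_frames, densities = [], [], {}
    series_by_type: dict[str, rhythm.IOISeries] = {}

    for etype in ELEMENT_TYPES:
        raw = rhythm.compute_iois(table, etype,
                                  within_parent=config.within_parent
                                  if etype in SUB_PULSE_TYPES else False)
        filtered = rhythm.filter_iois(raw, config.min_t, config.max_t)
        log.info("%s: %d IOIs, %d after filtering (%g, %g)",
                 etype, len(raw), len(filtered), config.min_t, config.max_t)
        series_by_type[etype] = filtered
        entry: dict = {"n_iois": len(raw), "n_filtered": len(filtered)}
        if len(filtered) == 0:
            entry["status"] = "no intervals"
            summary["element_types"][etype] = entry
            continue
        ioi_frames.append(filtered.data)
        ts = rhythm.tempo_summary(filtered)
        entry.update(mean_t=ts.mean_t, sd_t=ts.sd_t,
                     mean_rate_hz=ts.mean_rate, sd_rate_hz=ts.sd_rate)
        ratios = rhythm.compute_ratios(filtered, config.bands)
        entry["n_ratios"] = len(ratios)
        if len(ratios):
            ratio_frames.append(ratios.data)
            bc = rhythm.band_counts(ratios, group_by=("element_type",),
                                    bands=config.bands)
            by_band = dict(zip(bc["band"], bc["count"]))
            entry["on_count"] = int(by_band.get("on", 0))
            entry["off_count"] = int(by_band.get("off", 0))
            entry["outside_count"] = int(by_band.get("outside", 0))
        try:
            peak = rhythm.ratio_density(ratios, bandwidth=config.kde_bandwidth,
                                        grid_size=config.kde_grid_size)
            entry["peak_rk"] = peak.restricted_peak_location
            entry["global_peak_rk"] = peak.peak_location
            densities[etype] = pd.DataFrame({"grid": peak.grid,
                                             "density": peak.density})
            entry["status"] = "ok"
        except InsufficientDataError:
            entry["status"] = "skipped: insufficient ratios for a density"
            log.warning("%s: %s", etype, entry["status"])
        summary["element_types"][etype] = entry

    iois = pd.concat(ioi_frames, ignore_index=True) if ioi_frames \
        else pd.DataFrame(columns=list(rhythm.IOI_COLUMNS))
    ratios_all = pd.concat(ratio_frames, ignore_index=True) if ratio_frames \
        else pd.DataFrame(columns=list(rhythm.RATIO_COLUMNS))

    # nested (cross-stratum) analysis, pooled and per sub type
    full = series_by_type.get(FULL_PULSE)
    nested_frames = []
    if full is not None and len(full):
        for stype in SUB_PULSE_TYPES:
            sub = series_by_type[stype]
            if len(sub) == 0:
                continue
            ns = nested_mod.pair_nested_iois(sub, full)
            if len(ns):
                nested_frames.append(ns.data)
    nested_df = pd.concat(nested_frames, ignore_index=True) if nested_frames \
        else pd.DataFrame(columns=list(nested_mod.NESTED_COLUMNS))
    if len(nested_df):
        pooled = nested_mod.NestedRatioSeries(nested_df)
        summary["nested"]["n"] = len(pooled)
        try:
            npk = nested_mod.nested_density_peak(pooled)
            summary["nested"]["peak"] = npk.peak_location
            densities["nested"] = pd.DataFrame({"grid": npk.grid,
                                                "density": npk.density})
        except InsufficientDataError:
            summary["nested"]["peak"] = None
        summary["nested"]["mean_ratio"] = float(np.mean(pooled.nested_ratio))
        per_type = {}
        for stype, grp in nested_df.groupby("sub_type", sort=False):
            if len(grp) >= 10:
                pk = nested_mod.nested_density_peak(
                    nested_mod.NestedRatioSeries(grp))
                per_type[stype] = pk.peak_location
        summary["nested"]["per_type_peak"] = per_type
        try:
            q = nested_mod.quartile_extent_test(pooled, unit=config.quartile_unit)
            summary["nested"]["quartile_test"] = {
                "units": q.units, "W": q.W, "p_value": q.p_value,
                "method": q.method}
        except InsufficientDataError as exc:
            summary["nested"]["quartile_test"] = {"status": str(exc)}

    counts = rhythm.band_counts(
        rhythm.RatioSeries(ratios_all, config.bands),
        group_by=("element_type", "individual_id"), bands=config.bands) \
        if len(ratios_all) else pd.DataFrame(
            columns=["element_type", "individual_id", "band", "count",
                     "band_width"])
    if len(counts):
        try:
            model = fit_band_count_model(counts)
            summary["band_model"] = model.to_dict()
        except LongCallError as exc:
            summary["band_model"] = {"status": f"not fitted: {exc}"}
        summary["binomial_check"] = binomial_band_check(counts) \
            .to_dict(orient="records")

    return AnalysisResult(summary=summary, iois=iois, ratios=ratios_all,
                          band_counts=counts, nested_ratios=nested_df,
                          densities=densities)
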