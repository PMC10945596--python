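"""Synthetic two-stratum long-call generator.

Emulates the statistical structure the rhythm pipeline assumes: long calls
composed of full pulses recurring near a single tempo; each pulse containing
sub-pulses of exactly one of three acoustically distinct staccato types
(grumble, transitory, bubble) recurring near faster type-specific tempi;
multiplicative log-normal timing jitter; per-individual tempo and acoustic
offsets; and a 7-dimensional Gaussian acoustic vector per sub-pulse with
type-specific means.

All timing variation is multiplicative log-normal (mean 1), so intervals
stay strictly positive and coefficients of variation are scale-free.  The
total marginal cv of an interval type (default 0.3, matching the field
tempo summaries) is decomposed into three components whose log-variances
add: a per-individual tempo factor, a per-call tempo factor shared by both
strata (slow calls are slow throughout), and small *local* per-interval
jitter (default cv 0.1).  Isochrony lives in the local component: adjacent
intervals share the individual and call factors, so rhythm ratios
concentrate tightly around 0.5 while pooled interval SDs remain large —
the signature of field recordings of isochronous sequences.

Pulse bodies are generated as single elements filling their pulse, so they
produce (almost) no same-type adjacent intervals — the degenerate element
type the analysis must tolerate.  Default tempi are the field values for
wild Bornean flanged-male long calls (full pulses 1.696 s; grumble 0.118 s,
transitory 0.239 s, bubble 0.186 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import GenerationError
from .rhythm import DEFAULT_BANDS, IsochronyBands
from .tables_io import ACOUSTIC_MEASURES, EventTable

#: Sub-pulse types that carry acoustic vectors and their own tempo.
STACCATO_TYPES = ("grumble_sub_pulse", "sub_pulse_transitory", "bubble_sub_pulse")

#: Feature scale (marginal within-type SD) of the seven acoustic measures.
DEFAULT_ACOUSTIC_SDS: dict[str, float] = {
    "duration": 0.03,        # s
    "peak_frequency": 120.0,  # Hz
    "peak_time": 0.08,       # relative position
    "pfc_avg_slope": 10.0,   # Hz
    "pfc_max_slope": 40.0,   # Hz
    "avg_entropy": 80.0,     # Hz
    "snr_nist_quick": 4.0,   # dB
}

_ACOUSTIC_BASE: dict[str, float] = {
    "duration": 0.10, "peak_frequency": 600.0, "peak_time": 0.45,
    "pfc_avg_slope": 15.0, "pfc_max_slope": 100.0, "avg_entropy": 400.0,
    "snr_nist_quick": 18.0,
}

# Positional layout of sub-pulse content along a call (fractions of pulses):
# grumbles in the build-up, transitory elements and isolated pulse bodies
# before the climax, uninterrupted (climax) pulses, bubbles in the tail-off.
_LAYOUT_BREAKS = (0.20, 0.35, 0.45, 0.60)
_LAYOUT_TYPES = ("grumble_sub_pulse", "sub_pulse_transitory", "pulse_body",
                 None, "bubble_sub_pulse")  # None = climax pulse, no subs


def _default_acoustic_means(separation: float) -> pd.DataFrame:
    """Type means at the vertices of an equilateral triangle (side
    ``separation`` in pooled-SD units) in the duration × peak-frequency
    plane, around a common base vector."""
    z = {
        "grumble_sub_pulse": (0.0, 0.0),
        "sub_pulse_transitory": (separation, 0.0),
        "bubble_sub_pulse": (separation / 2.0, separation * np.sqrt(3) / 2.0),
    }
    rows = {}
    for t, (z1, z2) in z.items():
        m = dict(_ACOUSTIC_BASE)
        m["duration"] += z1 * DEFAULT_ACOUSTIC_SDS["duration"]
        m["peak_frequency"] += z2 * DEFAULT_ACOUSTIC_SDS["peak_frequency"]
        rows[t] = m
    return pd.DataFrame(rows).T[list(ACOUSTIC_MEASURES)]


@dataclass
class SyntheticSpec:
    """Parameters of the two-stratum generator.

    Tempo means are seconds per interval.  ``full_tempo_cv`` and
    ``sub_tempo_cv`` are the *total* marginal coefficients of variation of
    the generated intervals (the quantity a pooled tempo summary reports);
    ``local_jitter_cv`` is the per-interval component of that variation, and
    the per-call tempo factor absorbs the remainder (log-variances add, so
    the split is exact).  ``individual_tempo_sd`` is the log-scale SD of a
    per-individual tempo factor multiplying both strata;
    ``individual_acoustic_sd`` scales a per-individual additive acoustic
    offset in units of each feature's SD.  ``anisochrony_ratio`` switches
    the pulse stratum to a short:long alternation (e.g. 2 for 1:2), keeping
    the mean interval fixed.
    """

    n_individuals: int = 10
    calls_per_individual: int | None = None   # None: ~66 calls in total
    total_calls: int = 66
    pulses_per_call: float = 25.0             # Poisson mean, floor 3
    full_tempo_mean: float = 1.696
    full_tempo_cv: float = 0.3
    sub_tempo_means: Mapping[str, float] = field(default_factory=lambda: {
        "grumble_sub_pulse": 0.118,
        "sub_pulse_transitory": 0.239,
        "bubble_sub_pulse": 0.186,
    })
    sub_tempo_cv: float = 0.3
    local_jitter_cv: float = 0.1              # per-interval jitter, both strata
    subpulses_per_pulse: float = 8.0          # Poisson mean, truncated to fit
    type_layout: str = "positional"           # or "uniform"
    acoustic_separation: float = 1.5          # pooled-SD distance between types
    acoustic_means: pd.DataFrame | None = None
    acoustic_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACOUSTIC_SDS))
    individual_tempo_sd: float = 0.1
    individual_acoustic_sd: float = 0.5
    anisochrony_ratio: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.full_tempo_mean <= 0 or any(v <= 0 for v in
                                            self.sub_tempo_means.values()):
            raise GenerationError("tempo means must be positive")
        if min(self.full_tempo_cv, self.sub_tempo_cv, self.local_jitter_cv) < 0:
            raise GenerationError("jitter cv must be >= 0")
        for t, v in self.sub_tempo_means.items():
            if 2.0 * v >= self.full_tempo_mean:
                raise GenerationError(
                    f"infeasible spec: two '{t}' intervals ({2 * v:.3f} s) do "
                    f"not fit inside one pulse interval "
                    f"({self.full_tempo_mean:.3f} s)")
        if self.type_layout not in ("positional", "uniform"):
            raise GenerationError(f"unknown type_layout '{self.type_layout}'")
        if self.acoustic_means is None:
            self.acoustic_means = _default_acoustic_means(self.acoustic_separation)

    # -- serialization -------------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        d["sub_tempo_means"] = dict(self.sub_tempo_means)
        d["acoustic_sds"] = dict(self.acoustic_sds)
        d["acoustic_means"] = {t: [float(v) for v in row]
                               for t, row in self.acoustic_means.iterrows()}
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        d = yaml.safe_load(text)
        means = d.pop("acoustic_means", None)
        spec = cls(**d)
        if means is not None:
            spec.acoustic_means = pd.DataFrame.from_dict(
                means, orient="index", columns=list(ACOUSTIC_MEASURES))
        return spec


def _log_var(cv: float) -> float:
    """Log-scale variance of a mean-one lognormal with the given cv."""
    return float(np.log1p(cv * cv))


def _unit_lognormal(rng: np.random.Generator, sigma2: float,
                    n: int | None = None):
    """Mean-one lognormal factor(s) with log-variance ``sigma2``."""
    if sigma2 <= 0:
        return 1.0 if n is None else np.ones(n)
    s = np.sqrt(sigma2)
    out = rng.lognormal(mean=-sigma2 / 2.0, sigma=s,
                        size=n if n is not None else None)
    return out


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative jitter with mean exactly 1 and the given cv."""
    return np.asarray(_unit_lognormal(rng, _log_var(cv), n))


def _calls_per_individual(spec: SyntheticSpec) -> list[int]:
    if spec.calls_per_individual is not None:
        return [spec.calls_per_individual] * spec.n_individuals
    base, extra = divmod(spec.total_calls, spec.n_individuals)
    return [base + (1 if i < extra else 0) for i in range(spec.n_individuals)]


def _pulse_content(rng: np.random.Generator, spec: SyntheticSpec,
                   n_pulses: int) -> list[str | None]:
    if spec.type_layout == "uniform":
        return list(rng.choice(STACCATO_TYPES, size=n_pulses))
    frac = (np.arange(n_pulses) + 0.5) / n_pulses
    idx = np.searchsorted(_LAYOUT_BREAKS, frac, side="right")
    return [_LAYOUT_TYPES[i] for i in idx]


def generate_dataset(spec: SyntheticSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[EventTable, pd.DataFrame]:
    """Generate an annotated event table plus an acoustic-measure table.

    Deterministic given ``spec.seed`` (or an explicit ``rng``).  The acoustic
    table has one row per staccato sub-pulse with the seven measures and the
    ``sub_type`` / ``individual_id`` factor columns consumed by the pDFA.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sds = np.array([spec.acoustic_sds[m] for m in ACOUSTIC_MEASURES])
    events: list[dict] = []
    acoustic: list[dict] = []

    # variance decomposition: individual + call + local log-variances add up
    # to the total marginal cv of each stratum
    sigma_ind = spec.individual_tempo_sd ** 2
    sigma_local = _log_var(spec.local_jitter_cv)
    sigma_call = max(0.0, _log_var(spec.full_tempo_cv) - sigma_ind - sigma_local)
    sigma_extra = {t: max(0.0, _log_var(spec.sub_tempo_cv) - sigma_ind
                          - sigma_call - sigma_local)
                   for t in spec.sub_tempo_means}

    for i, n_calls in enumerate(_calls_per_individual(spec)):
        indiv = f"ind{i + 1:02d}"
        indiv_factor = float(_unit_lognormal(rng, sigma_ind))
        indiv_acoustic = rng.normal(0.0, spec.individual_acoustic_sd, len(sds)) * sds

        for c in range(n_calls):
            call_id = f"{indiv}_lc{c + 1:02d}"
            tempo_factor = indiv_factor * float(_unit_lognormal(rng, sigma_call))
            n_pulses = max(3, int(rng.poisson(spec.pulses_per_call)))
            if spec.anisochrony_ratio is not None:
                r = float(spec.anisochrony_ratio)
                base = spec.full_tempo_mean * 2.0 / (1.0 + r)
                pattern = np.where(np.arange(n_pulses - 1) % 2 == 0, base, base * r)
            else:
                pattern = np.full(n_pulses - 1, spec.full_tempo_mean)
            iois = pattern * tempo_factor * np.asarray(
                _unit_lognormal(rng, sigma_local, n_pulses - 1))
            onsets = np.concatenate([[0.0], np.cumsum(iois)])
            # the final pulse has no successor; give it a nominal window
            windows = np.concatenate(
                [iois, [spec.full_tempo_mean * tempo_factor]])
            content = _pulse_content(rng, spec, n_pulses)

            for p in range(n_pulses):
                pulse_id = f"{call_id}_p{p + 1:03d}"
                onset, window = float(onsets[p]), float(windows[p])
                events.append({
                    "event_id": pulse_id, "individual_id": indiv,
                    "long_call_id": call_id, "element_type": "full_pulse",
                    "parent_pulse_id": pd.NA,
                    "begin_time": onset, "end_time": onset + 0.85 * window,
                })
                sub_type = content[p]
                if sub_type is None:
                    continue
                if sub_type == "pulse_body":
                    events.append({
                        "event_id": f"{pulse_id}_s001", "individual_id": indiv,
                        "long_call_id": call_id, "element_type": "pulse_body",
                        "parent_pulse_id": pulse_id,
                        "begin_time": onset + 0.05 * window,
                        "end_time": onset + 0.70 * window,
                    })
                    continue
                tempo = spec.sub_tempo_means[sub_type] * tempo_factor \
                    * float(_unit_lognormal(rng, sigma_extra[sub_type]))
                n_target = max(2, int(rng.poisson(spec.subpulses_per_pulse)))
                n_fit = int(0.9 * window / tempo)
                n_sub = max(1, min(n_target, n_fit))
                sub_iois = tempo * np.asarray(
                    _unit_lognormal(rng, sigma_local, max(0, n_sub - 1)))
                sub_onsets = onset + 0.02 * window + np.concatenate(
                    [[0.0], np.cumsum(sub_iois)])
                for s, s_on in enumerate(sub_onsets):
                    sub_id = f"{pulse_id}_s{s + 1:03d}"
                    events.append({
                        "event_id": sub_id, "individual_id": indiv,
                        "long_call_id": call_id, "element_type": sub_type,
                        "parent_pulse_id": pulse_id,
                        "begin_time": float(s_on),
                        "end_time": float(s_on + 0.6 * tempo),
                    })
                    mean_vec = spec.acoustic_means.loc[sub_type].to_numpy(float)
                    vec = mean_vec + indiv_acoustic + rng.normal(0, 1, len(sds)) * sds
                    row = {"event_id": sub_id, "individual_id": indiv,
                           "long_call_id": call_id, "sub_type": sub_type}
                    row.update({m: float(v) for m, v in
                                zip(ACOUSTIC_MEASURES, vec)})
                    acoustic.append(row)

    table = EventTable(pd.DataFrame(events), provenance="synthetic")
    acoustic_df = pd.DataFrame(
        acoustic, columns=["event_id", "individual_id", "long_call_id",
                           "sub_type", *ACOUSTIC_MEASURES])
    return table, acoustic_df


def generate_null_counts(rate_per_width: float = 1000.0,
                         bands: IsochronyBands = DEFAULT_BANDS,
                         n_individuals: int = 10,
                         element_types: tuple[str, ...] = (
                             "full_pulse", "grumble_sub_pulse",
                             "sub_pulse_transitory", "bubble_sub_pulse"),
                         dispersion: float = 0.05,
                         rng: np.random.Generator | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Band-count table with no band preference, for model calibration.

    Counts per individual × element type × band are negative-binomial with
    mean ``rate_per_width × band_width`` and gamma-Poisson ``dispersion``
    (variance = μ + dispersion·μ²; 0 gives Poisson) — the density of
    observations per unit ratio width is identical on and off isochrony by
    construction.
    """
    if rate_per_width <= 0:
        raise ValueError("rate_per_width must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_individuals):
        for t in element_types:
            for band in ("on", "off"):
                width = bands.width(band)
                mu = rate_per_width * width
                if dispersion > 0:
                    lam = rng.gamma(shape=1.0 / dispersion,
                                    scale=mu * dispersion)
                    count = int(rng.poisson(lam))
                else:
                    count = int(rng.poisson(mu))
                rows.append({"individual_id": f"ind{i + 1:02d}",
                             "element_type": t, "band": band,
                             "count": count, "band_width": width})
    return pd.DataFrame(rows)
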