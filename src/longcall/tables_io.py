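"""Reading, writing and validation of long-call event tables.

Annotated vocal events arrive either as Raven selection tables (tab-delimited,
one header row, times in decimal seconds) or as generic CSV/TSV exports of the
same information.  Internally an :class:`EventTable` is a thin wrapper around a
:class:`pandas.DataFrame` with one row per vocal element and a canonical set of
columns; extra annotation columns from the source file are preserved untouched.

Two strata of elements are distinguished: *full pulses* (the higher level of
organization of a long call) and four sub-pulse element types nested inside
them (grumble sub-pulses, sub-pulse transitory elements, pulse bodies and
bubble sub-pulses).  Sub-pulse events carry a ``parent_pulse_id`` linking them
to their enclosing full pulse; when the annotation file has no such column the
link is inferred from timing (see :func:`infer_parent_pulses`).

All times are absolute seconds within one recording; element intervals are
half-open ``[begin, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RowParseError, SchemaError, ValidationError

#: Closed vocabulary of long-call element types.
FULL_PULSE = "full_pulse"
ELEMENT_TYPES: tuple[str, ...] = (
    "full_pulse",
    "grumble_sub_pulse",
    "sub_pulse_transitory",
    "pulse_body",
    "bubble_sub_pulse",
)
#: The lower-stratum (sub-pulse) element types.
SUB_PULSE_TYPES: tuple[str, ...] = tuple(t for t in ELEMENT_TYPES if t != FULL_PULSE)

#: The seven per-element acoustic measures consumed by the discriminant analysis.
ACOUSTIC_MEASURES: tuple[str, ...] = (
    "duration",
    "peak_frequency",
    "peak_time",
    "pfc_avg_slope",
    "pfc_max_slope",
    "avg_entropy",
    "snr_nist_quick",
)

#: Canonical model fields, in on-disk column order.
CANONICAL_FIELDS: tuple[str, ...] = (
    "event_id",
    "individual_id",
    "long_call_id",
    "element_type",
    "parent_pulse_id",
    "begin_time",
    "end_time",
)

#: Canonical Raven-style header for each model field.
RAVEN_HEADERS: dict[str, str] = {
    "event_id": "Selection",
    "individual_id": "Individual ID",
    "long_call_id": "Long Call ID",
    "element_type": "Element Type",
    "parent_pulse_id": "Parent Pulse ID",
    "begin_time": "Begin Time (s)",
    "end_time": "End Time (s)",
}

# Header synonyms accepted without an explicit column_map.  Keys are
# normalized (lower case, alphanumeric only).
_HEADER_SYNONYMS: dict[str, str] = {
    "selection": "event_id",
    "eventid": "event_id",
    "individualid": "individual_id",
    "individual": "individual_id",
    "longcallid": "long_call_id",
    "longcall": "long_call_id",
    "elementtype": "element_type",
    "type": "element_type",
    "parentpulseid": "parent_pulse_id",
    "parentpulse": "parent_pulse_id",
    "begintimes": "begin_time",
    "begintime": "begin_time",
    "endtimes": "end_time",
    "endtime": "end_time",
}

# Element-type synonyms: free-form Raven annotations → canonical vocabulary.
_TYPE_SYNONYMS: dict[str, str] = {
    "fullpulse": "full_pulse",
    "pulse": "full_pulse",
    "grumblesubpulse": "grumble_sub_pulse",
    "grumble": "grumble_sub_pulse",
    "subpulsetransitory": "sub_pulse_transitory",
    "subpulsetransitoryelement": "sub_pulse_transitory",
    "transitory": "sub_pulse_transitory",
    "pulsebody": "pulse_body",
    "bubblesubpulse": "bubble_sub_pulse",
    "bubble": "bubble_sub_pulse",
}


def _norm(name: str) -> str:
    return "".join(ch for ch in str(name).lower() if ch.isalnum())


def normalize_element_type(value: str) -> str:
    """Map a free-form annotation string onto the canonical type vocabulary.

    Unknown strings are returned unchanged (validation reports them rather
    than parsing failing).
    """
    return _TYPE_SYNONYMS.get(_norm(value), str(value))


@dataclass(frozen=True)
class AcousticMeasures:
    """The seven spectrogram measures taken per element.

    ``duration`` is in seconds, frequency-domain measures in Hz, ``peak_time``
    as stored in the source table, and ``snr_nist_quick`` in dB.
    """

    duration: float
    peak_frequency: float
    peak_time: float
    pfc_avg_slope: float
    pfc_max_slope: float
    avg_entropy: float
    snr_nist_quick: float


@dataclass(frozen=True)
class LongCallEvent:
    """One annotated vocal element of a long call."""

    event_id: str
    individual_id: str
    long_call_id: str
    element_type: str
    begin_time: float
    end_time: float
    parent_pulse_id: str | None = None
    acoustic: AcousticMeasures | None = None


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_event_table`."""

    kind: str
    event_id: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def kinds(self) -> list[str]:
        return [v.kind for v in self.violations]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.violations)


class EventTable:
    """Time-ordered table of annotated long-call elements.

    Parameters
    ----------
    data
        Frame with at least ``begin_time`` and ``end_time``; missing canonical
        columns are filled with defaults (a single long call / individual,
        ``full_pulse`` element type, sequential event ids).
    provenance
        Source file name and dialect, for reporting only.
    """

    def __init__(self, data: pd.DataFrame, provenance: str = "<memory>"):
        df = data.copy()
        for col in ("begin_time", "end_time"):
            if col not in df.columns:
                raise SchemaError(f"event table is missing required column '{col}'")
        if "element_type" not in df.columns:
            df["element_type"] = FULL_PULSE
        if "long_call_id" not in df.columns:
            df["long_call_id"] = "call_0"
        if "individual_id" not in df.columns:
            df["individual_id"] = "ind_0"
        if "parent_pulse_id" not in df.columns:
            df["parent_pulse_id"] = pd.NA
        if "event_id" not in df.columns:
            df["event_id"] = [str(i + 1) for i in range(len(df))]
        df["event_id"] = df["event_id"].astype(str)
        df["element_type"] = df["element_type"].map(normalize_element_type)
        if df["event_id"].duplicated().any():
            dupes = df.loc[df["event_id"].duplicated(), "event_id"].unique()
            raise ValidationError(f"duplicate event_id values: {list(dupes)[:5]}")
        # stable sort: within each long call events are in time order
        df = df.sort_values(["long_call_id", "begin_time"], kind="stable")
        df = df.reset_index(drop=True)
        extra = [c for c in df.columns if c not in CANONICAL_FIELDS]
        self.data = df[list(CANONICAL_FIELDS) + extra]
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if col in ("begin_time", "end_time"):
                if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float),
                                   rtol=0, atol=5e-7, equal_nan=True):
                    return False
            else:
                av = a[col].fillna("").astype(str)
                bv = b[col].fillna("").astype(str)
                if not (av == bv).all():
                    return False
        return True

    def events(self) -> Iterator[LongCallEvent]:
        """Iterate over rows as :class:`LongCallEvent` records."""
        has_acoustic = all(m in self.data.columns for m in ACOUSTIC_MEASURES)
        for row in self.data.itertuples(index=False):
            parent = getattr(row, "parent_pulse_id")
            acoustic = None
            if has_acoustic:
                vals = [getattr(row, m) for m in ACOUSTIC_MEASURES]
                if all(isinstance(v, (int, float)) and math.isfinite(v) for v in vals):
                    acoustic = AcousticMeasures(*map(float, vals))
            yield LongCallEvent(
                event_id=str(row.event_id),
                individual_id=str(row.individual_id),
                long_call_id=str(row.long_call_id),
                element_type=str(row.element_type),
                begin_time=float(row.begin_time),
                end_time=float(row.end_time),
                parent_pulse_id=None if pd.isna(parent) else str(parent),
                acoustic=acoustic,
            )

    @classmethod
    def from_events(cls, events: Iterable[LongCallEvent],
                    provenance: str = "<memory>") -> "EventTable":
        rows = []
        for e in events:
            rows.append({
                "event_id": e.event_id,
                "individual_id": e.individual_id,
                "long_call_id": e.long_call_id,
                "element_type": e.element_type,
                "parent_pulse_id": e.parent_pulse_id,
                "begin_time": e.begin_time,
                "end_time": e.end_time,
            })
        return cls(pd.DataFrame(rows, columns=list(CANONICAL_FIELDS)), provenance)


def _resolve_columns(columns: Sequence[str],
                     column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map file columns onto model fields; explicit ``column_map`` wins."""
    resolved: dict[str, str] = {}
    explicit = {str(k): v for k, v in (column_map or {}).items()}
    for col in columns:
        if col in explicit:
            resolved[col] = explicit[col]
        elif _norm(col) in _HEADER_SYNONYMS:
            field_name = _HEADER_SYNONYMS[_norm(col)]
            if field_name not in resolved.values():
                resolved[col] = field_name
    return resolved


def read_selection_table(path: str | Path,
                         column_map: Mapping[str, str] | None = None,
                         sep: str | None = None) -> EventTable:
    """Read a Raven selection table (or CSV/TSV event table).

    Parameters
    ----------
    path
        Tab-delimited file with one header row.  ``.csv`` files are read
        comma-delimited; anything else tab-delimited unless ``sep`` is given.
    column_map
        Optional mapping ``{file column -> model field}`` overriding the
        built-in header synonyms (model fields: ``event_id``,
        ``individual_id``, ``long_call_id``, ``element_type``,
        ``parent_pulse_id``, ``begin_time``, ``end_time``).

    Raises
    ------
    SchemaError
        If a begin/end-time column cannot be located.
    RowParseError
        If a time cell is not a decimal number (row numbers reported,
        header = row 1).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      na_values=[""], encoding="utf-8")
    resolved = _resolve_columns(list(raw.columns), column_map)
    for required in ("begin_time", "end_time"):
        if required not in resolved.values():
            raise SchemaError(
                f"{path.name}: no column maps to '{required}' "
                f"(headers: {list(raw.columns)})")
    df = raw.rename(columns=resolved)
    for col in ("begin_time", "end_time"):
        # locale-independent: decimal point only, never comma
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise RowParseError(
                f"{path.name}: unparseable value in '{col}' at file row(s) "
                f"{[int(i) + 2 for i in bad[:10]]}", rows=[int(i) + 2 for i in bad])
        if parsed.isna().any():
            raise RowParseError(
                f"{path.name}: empty value in '{col}'",
                rows=[int(i) + 2 for i in df.index[parsed.isna()]])
        df[col] = parsed.astype(float)
    table = EventTable(df, provenance=f"{path.name} (sep={sep!r})")
    return infer_parent_pulses(table)


def write_selection_table(table: EventTable, path: str | Path) -> None:
    """Write an :class:`EventTable` as a Raven-style selection table.

    Tab-delimited, canonical headers, times as decimal seconds with six
    digits.  ``write → read → write`` is byte-identical.
    """
    path = Path(path)
    df = table.data.copy()
    out = pd.DataFrame()
    for field_name in CANONICAL_FIELDS:
        col = df[field_name]
        if field_name in ("begin_time", "end_time"):
            out[RAVEN_HEADERS[field_name]] = [f"{v:.6f}" for v in col]
        else:
            out[RAVEN_HEADERS[field_name]] = col.fillna("").astype(str)
    for extra in (c for c in df.columns if c not in CANONICAL_FIELDS):
        out[extra] = df[extra].fillna("").astype(str)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def infer_parent_pulses(table: EventTable) -> EventTable:
    """Fill missing ``parent_pulse_id`` links by temporal containment.

    A sub-pulse with no annotated parent is assigned to the full pulse of the
    same long call whose ``[begin, next-pulse-begin)`` interval (half-open on
    the right; the last pulse's interval extends to the end of the call)
    contains its onset.  Sub-pulses starting before the first pulse stay
    unlinked and are reported by validation.
    """
    df = table.data.copy()
    for call_id, idx in df.groupby("long_call_id", sort=False).groups.items():
        sub = df.loc[idx]
        pulses = sub[sub["element_type"] == FULL_PULSE].sort_values("begin_time")
        if pulses.empty:
            continue
        onsets = pulses["begin_time"].to_numpy(float)
        pulse_ids = pulses["event_id"].to_numpy(str)
        need = sub.index[(sub["element_type"] != FULL_PULSE)
                         & sub["parent_pulse_id"].isna()]
        if len(need) == 0:
            continue
        pos = np.searchsorted(onsets, df.loc[need, "begin_time"].to_numpy(float),
                              side="right") - 1
        assigned = np.where(pos >= 0, pulse_ids[np.clip(pos, 0, None)], None)
        df.loc[need, "parent_pulse_id"] = assigned
    out = EventTable.__new__(EventTable)
    out.data = df
    out.provenance = table.provenance
    return out


def validate_event_table(table: EventTable) -> ValidationReport:
    """Check every structural invariant; report rather than raise.

    Violation kinds: ``negative duration`` (end ≤ begin), ``negative begin``,
    ``unknown element_type``, ``orphan sub-pulse`` (parent missing or not a
    full pulse of the same long call), ``pulse with parent``.
    """
    df = table.data
    report = ValidationReport()

    def add(kind: str, event_id, message: str) -> None:
        report.violations.append(Violation(kind, str(event_id), message))

    pulses_by_call: dict[str, set[str]] = {
        str(call): set(grp.loc[grp["element_type"] == FULL_PULSE, "event_id"])
        for call, grp in df.groupby("long_call_id", sort=False)
    }
    for row in df.itertuples(index=False):
        if row.begin_time < 0:
            add("negative begin", row.event_id,
                f"begin_time {row.begin_time} < 0")
        if row.end_time <= row.begin_time:
            add("negative duration", row.event_id,
                f"end_time {row.end_time} <= begin_time {row.begin_time}")
        if row.element_type not in ELEMENT_TYPES:
            add("unknown element_type", row.event_id,
                f"'{row.element_type}' not in {ELEMENT_TYPES}")
        parent = row.parent_pulse_id
        if row.element_type in SUB_PULSE_TYPES:
            if pd.isna(parent):
                add("orphan sub-pulse", row.event_id,
                    "sub-pulse has no parent_pulse_id")
            elif str(parent) not in pulses_by_call.get(str(row.long_call_id), set()):
                add("orphan sub-pulse", row.event_id,
                    f"parent_pulse_id '{parent}' is not a full pulse of "
                    f"long call '{row.long_call_id}'")
        elif row.element_type == FULL_PULSE and not pd.isna(parent):
            add("pulse with parent", row.event_id,
                "full pulse must not have a parent_pulse_id")
    return report
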