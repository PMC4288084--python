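"""Extract-load-transform stages for coded observation streams.

The data model needs only four basic concepts to express any clinical fact:
target (the patient), feature (the coded variable), protocol, and value.
Patients are simply collections of time-stamped observations, each carrying
at least one concept annotation once transformed.

Loading keeps original codes verbatim ("the original data is never lost"):
transformation *adds* unified-concept annotations in a separate, repeatable
step, so annotations can be regenerated whenever the terminology updates.
Local (non-standard) codes are optionally rewritten to standard vocabulary
codes through a manually curated local-code map; the original fields are
retained so serialization is lossless.
"""
from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ObservationParseError
from .terminology import TerminologyGraph, lookup_code

logger = logging.getLogger(__name__)

OBSERVATION_COLUMNS = ("patient_id", "date", "source", "code", "value", "unit", "protocol")
_MANDATORY_COLUMNS = ("patient_id", "date", "source", "code", "value")

LOCAL_SOURCE = "LOCAL"


@dataclass(frozen=True)
class ObservationRecord:
    """One time-stamped coded clinical fact, exactly as loaded.

    ``original_source``/``original_code`` are set only when a local-code map
    rewrote the feature coding at parse time; they preserve the raw row.
    """

    patient_id: str
    timestamp: _dt.date
    feature_source: str
    feature_code: str
    value: str
    unit: str = ""
    protocol: str = ""
    original_source: str | None = None
    original_code: str | None = None


@dataclass(frozen=True)
class AnnotatedObservation:
    record: ObservationRecord
    cuis: frozenset[str]
    mapping_status: str  # "mapped" | "unmapped" | "local-mapped"


@dataclass(frozen=True)
class ValueSetMember:
    cui: str
    polarity: str  # "positive" | "negative"
    label: str = ""


@dataclass(frozen=True)
class ValueSet:
    """An explicit list of concepts jointly encoding one clinical variable."""

    name: str
    members: tuple[ValueSetMember, ...]
    source_standard: str = ""

    def cuis(self) -> set[str]:
        return {m.cui for m in self.members}

    def negatives(self) -> list[ValueSetMember]:
        return [m for m in self.members if m.polarity == "negative"]


@dataclass
class PatientProfile:
    """A patient as the set of its concept annotations with provenance."""

    patient_id: str
    annotations: set[tuple[str, str]] = field(default_factory=set)  # (cui, provenance)

    def cuis(self, provenance: str | None = None) -> set[str]:
        if provenance is None:
            return {cui for cui, _ in self.annotations}
        return {cui for cui, p in self.annotations if p == provenance}


class LocalCodeMap:
    """Manually curated map from (local code, value) to standard codes.

    Entries may be value-specific (e.g. ``("Smoker", "Y")``) or
    value-independent (``("Warfarin", None)``); value-specific entries win.
    """

    def __init__(self, entries: Iterable[tuple[str, str | None, str, str]] = ()):
        self._entries: dict[tuple[str, str | None], tuple[str, str]] = {}
        for local_code, value, source, code in entries:
            self._entries[(local_code, value)] = (source, code)

    def lookup(self, local_code: str, value: str) -> tuple[str, str] | None:
        hit = self._entries.get((local_code, value))
        if hit is None:
            hit = self._entries.get((local_code, None))
        return hit

    def items(self):
        return self._entries.items()

    def __len__(self):
        return len(self._entries)

    def to_json(self) -> str:
        rows = [
            {"local_code": lc, "value": v, "source": s, "code": c}
            for (lc, v), (s, c) in sorted(
                self._entries.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")
            )
        ]
        return json.dumps(rows, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LocalCodeMap":
        return cls(
            (row["local_code"], row.get("value"), row["source"], row["code"])
            for row in json.loads(text)
        )

    @classmethod
    def from_file(cls, path) -> "LocalCodeMap":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def load_value_sets(path) -> list[ValueSet]:
    """Read value sets from a JSON config file."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    sets = []
    for entry in raw:
        members = tuple(
            ValueSetMember(cui=m["cui"], polarity=m.get("polarity", "positive"), label=m.get("label", ""))
            for m in entry["members"]
        )
        sets.append(ValueSet(name=entry["name"], members=members, source_standard=entry.get("source_standard", "")))
    return sets


# ---------------------------------------------------------------------------
# Parse / serialize
# ---------------------------------------------------------------------------

def parse_observation_file(path, local_code_map: LocalCodeMap | None = None) -> list[ObservationRecord]:
    """Parse an observation TSV into records.

    The header must contain at least patient_id, date, source, code, value
    (unit and protocol are optional). Rows with unparseable timestamps are
    skipped and logged; structural problems raise
    :class:`ObservationParseError` with the offending line number.

    When a ``local_code_map`` is given, rows with source ``LOCAL`` whose
    (code, value) resolve in the map are rewritten to the standard coding;
    unresolved LOCAL rows are retained as-is.
    """
    records: list[ObservationRecord] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ObservationParseError(f"{path}: empty file, header row required")
        missing = [c for c in _MANDATORY_COLUMNS if c not in header]
        if missing:
            raise ObservationParseError(
                f"{path}:1: missing mandatory column(s) {', '.join(missing)}"
            )
        col = {name: header.index(name) for name in header}

        for line_number, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                raise ObservationParseError(
                    f"{path}:{line_number}: expected {len(header)} fields, got {len(row)}"
                )

            def get(name: str) -> str:
                idx = col.get(name)
                return row[idx] if idx is not None else ""

            patient_id, code = get("patient_id"), get("code")
            if not patient_id or not code:
                raise ObservationParseError(
                    f"{path}:{line_number}: patient_id and code must be non-empty"
                )
            try:
                timestamp = _dt.date.fromisoformat(get("date"))
            except ValueError:
                logger.warning(
                    "%s:%d: unparseable timestamp %r, row skipped", path, line_number, get("date")
                )
                continue

            source = get("source")
            record = ObservationRecord(
                patient_id=patient_id,
                timestamp=timestamp,
                feature_source=source,
                feature_code=code,
                value=get("value"),
                unit=get("unit"),
                protocol=get("protocol"),
            )
            if local_code_map is not None and source == LOCAL_SOURCE:
                hit = local_code_map.lookup(code, record.value)
                if hit is not None:
                    record = replace(
                        record,
                        feature_source=hit[0],
                        feature_code=hit[1],
                        original_source=source,
                        original_code=code,
                    )
            records.append(record)
    return records


def write_observation_file(records: Sequence[ObservationRecord], path) -> None:
    """Serialize records back to TSV, restoring pre-rewrite source/code."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(OBSERVATION_COLUMNS)
        for r in records:
            source = r.original_source if r.original_source is not None else r.feature_source
            code = r.original_code if r.original_code is not None else r.feature_code
            writer.writerow(
                [r.patient_id, r.timestamp.isoformat(), source, code, r.value, r.unit, r.protocol]
            )


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def transform_observations(
    records: Sequence[ObservationRecord], graph: TerminologyGraph
) -> list[AnnotatedObservation]:
    """Attach concept annotations to every record; originals are untouched.

    A record whose code does not resolve keeps status ``unmapped`` with an
    empty CUI set (never dropped); records that arrived through a local-code
    rewrite and resolve get status ``local-mapped``.
    """
    annotated = []
    for record in records:
        cuis = lookup_code(graph, record.feature_source, record.feature_code)
        if cuis:
            status = "local-mapped" if record.original_source is not None else "mapped"
        else:
            status = "unmapped"
        annotated.append(
            AnnotatedObservation(record=record, cuis=frozenset(cuis), mapping_status=status)
        )
    return annotated


def coverage_summary(annotated: Sequence[AnnotatedObservation]) -> dict:
    """Per-source mapped/unmapped counts, JSON-serializable."""
    per_source: dict[str, dict[str, int]] = {}
    mapped = unmapped = 0
    for obs in annotated:
        source = obs.record.feature_source
        bucket = per_source.setdefault(source, {"mapped": 0, "unmapped": 0})
        if obs.mapping_status == "unmapped":
            bucket["unmapped"] += 1
            unmapped += 1
        else:
            bucket["mapped"] += 1
            mapped += 1
    total = mapped + unmapped
    return {
        "total": total,
        "mapped": mapped,
        "unmapped": unmapped,
        "mapped_fraction": (mapped / total) if total else None,
        "per_source": {s: per_source[s] for s in sorted(per_source)},
    }


def build_profiles(annotated: Sequence[AnnotatedObservation]) -> list[PatientProfile]:
    """Collapse annotated observations into per-patient profiles.

    Every concept annotation enters with provenance ``direct``; duplicate
    observations of the same concept collapse by set semantics.
    """
    by_patient: dict[str, PatientProfile] = {}
    for obs in annotated:
        profile = by_patient.setdefault(
            obs.record.patient_id, PatientProfile(patient_id=obs.record.patient_id)
        )
        for cui in obs.cuis:
            profile.annotations.add((cui, "direct"))
    return [by_patient[pid] for pid in sorted(by_patient)]


def apply_value_sets(
    profiles: Sequence[PatientProfile],
    value_sets: Sequence[ValueSet],
    graph: TerminologyGraph | None = None,
) -> list[PatientProfile]:
    """Create complement annotations from positive/negative value-set pairs.

    For each value set carrying negative members: a patient annotated to
    *no* member of the set gains every negative member with provenance
    ``complement`` (e.g. a patient with no thrombosis annotation gains
    "No past history of venous thrombosis"). Patients already annotated to
    any member are untouched. Profiles are modified in place and returned.
    """
    for vs in value_sets:
        if graph is not None:
            for member in vs.members:
                if member.cui not in graph.concepts:
                    warnings.warn(
                        f"value set {vs.name!r}: member {member.cui} absent from graph",
                        stacklevel=2,
                    )
        negatives = vs.negatives()
        if not negatives:
            continue
        member_cuis = vs.cuis()
        for profile in profiles:
            if profile.cuis() & member_cuis:
                continue
            for member in negatives:
                profile.annotations.add((member.cui, "complement"))
    return list(profiles)
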