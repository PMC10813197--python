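"""Record schema, JSON-lines I/O and validation for four-modality EMR data.

One admission is one :class:`PatientRecord` holding the four raw
modalities (static tabular, static notes, temporal tabular, temporal
notes), the two binary outcome labels and the length of stay.  A
:class:`DatasetSchema` declares the feature vocabularies, reference
ranges for continuous static features, the temporal horizon and the
rolling-window length.

Conventions:

* day indices are 1-based (day 1 = first hospital day); day 0 is
  reserved downstream for the static fused representation;
* the long-stay label is 1 iff length_of_stay > 14 days;
* temporal notes carry at most one note per day (if raw input has more,
  keep the first of the day before building the record).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import yaml

LONG_STAY_THRESHOLD_DAYS = 14


class SchemaError(ValueError):
    """A record is structurally incompatible with the schema."""


class RecordValidationError(ValueError):
    """A record violates a dataset invariant."""


@dataclass
class ContinuousFeature:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise SchemaError(f"feature {self.name}: reference range requires low < high")


@dataclass
class CategoricalFeature:
    name: str
    categories: list[str]


@dataclass
class DatasetSchema:
    """Dataset-level vocabularies and windowing geometry."""

    static_continuous: list[ContinuousFeature] = field(default_factory=list)
    static_categorical: list[CategoricalFeature] = field(default_factory=list)
    temporal_features: list[str] = field(default_factory=list)
    note_vocab_size: int = 1000
    horizon_days: int = 30
    window_days: int = 3

    def __post_init__(self):
        if self.horizon_days % self.window_days != 0:
            raise SchemaError(
                f"horizon ({self.horizon_days} d) must be an exact multiple of "
                f"the window length ({self.window_days} d)"
            )

    @property
    def n_windows(self) -> int:
        return self.horizon_days // self.window_days

    @property
    def onehot_dim(self) -> int:
        return 3 * len(self.static_continuous) + sum(
            len(f.categories) + 1 for f in self.static_categorical
        )

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "static_continuous": [asdict(f) for f in self.static_continuous],
            "static_categorical": [asdict(f) for f in self.static_categorical],
            "temporal_features": list(self.temporal_features),
            "note_vocab_size": self.note_vocab_size,
            "horizon_days": self.horizon_days,
            "window_days": self.window_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSchema":
        return cls(
            static_continuous=[ContinuousFeature(**f) for f in d.get("static_continuous", [])],
            static_categorical=[CategoricalFeature(**f) for f in d.get("static_categorical", [])],
            temporal_features=list(d.get("temporal_features", [])),
            note_vocab_size=int(d.get("note_vocab_size", 1000)),
            horizon_days=int(d.get("horizon_days", 30)),
            window_days=int(d.get("window_days", 3)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TemporalObservation:
    day: int
    feature: str
    value: float


@dataclass
class PatientRecord:
    """One admission: four raw modalities, outcome labels, length of stay."""

    record_id: str
    static_tabular: dict[str, float | str]
    static_notes: list[tuple[str, list[str]]]
    temporal_tabular: list[TemporalObservation]
    temporal_notes: list[tuple[int, list[str]]]
    length_of_stay: int
    label_mortality: int
    label_long_stay: int

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "static_tabular": self.static_tabular,
            "static_notes": [[s, list(t)] for s, t in self.static_notes],
            "temporal_tabular": [[o.day, o.feature, o.value] for o in self.temporal_tabular],
            "temporal_notes": [[d, list(t)] for d, t in self.temporal_notes],
            "length_of_stay": self.length_of_stay,
            "label_mortality": self.label_mortality,
            "label_long_stay": self.label_long_stay,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientRecord":
        required = ["record_id", "static_tabular", "static_notes", "temporal_tabular",
                    "temporal_notes", "length_of_stay", "label_mortality", "label_long_stay"]
        missing = [k for k in required if k not in d]
        if missing:
            rid = d.get("record_id", "<unknown>")
            raise SchemaError(f"record {rid}: missing required field(s) {missing}")
        return cls(
            record_id=str(d["record_id"]),
            static_tabular=dict(d["static_tabular"]),
            static_notes=[(str(s), [str(x) for x in t]) for s, t in d["static_notes"]],
            temporal_tabular=[TemporalObservation(int(day), str(f), float(v))
                              for day, f, v in d["temporal_tabular"]],
            temporal_notes=[(int(day), [str(x) for x in t]) for day, t in d["temporal_notes"]],
            length_of_stay=int(d["length_of_stay"]),
            label_mortality=int(d["label_mortality"]),
            label_long_stay=int(d["label_long_stay"]),
        )


def validate_record(record: PatientRecord, schema: DatasetSchema) -> list[str]:
    """Return the list of invariant violations (empty iff the record is valid).

    Never raises on a structurally well-formed record.
    """
    v: list[str] = []
    if record.length_of_stay < 1:
        v.append(f"length_of_stay must be >= 1, got {record.length_of_stay}")
    if record.label_mortality not in (0, 1):
        v.append(f"label_mortality must be 0/1, got {record.label_mortality}")
    if record.label_long_stay not in (0, 1):
        v.append(f"label_long_stay must be 0/1, got {record.label_long_stay}")
    expected_long = int(record.length_of_stay > LONG_STAY_THRESHOLD_DAYS)
    if record.label_long_stay in (0, 1) and record.label_long_stay != expected_long:
        v.append(
            f"label_long_stay={record.label_long_stay} inconsistent with "
            f"length_of_stay={record.length_of_stay} under the "
            f"{LONG_STAY_THRESHOLD_DAYS}-day rule"
        )
    known = set(schema.temporal_features)
    for obs in record.temporal_tabular:
        if obs.day < 1:
            v.append(f"temporal_tabular day index must be >= 1, got {obs.day}")
        if obs.feature not in known:
            v.append(f"unknown feature '{obs.feature}' not in temporal vocabulary")
    seen_days: set[int] = set()
    for day, _tokens in record.temporal_notes:
        if day < 1:
            v.append(f"temporal_notes day index must be >= 1, got {day}")
        if day in seen_days:
            v.append(f"duplicate note day {day}")
        seen_days.add(day)
    return v


def read_records(path: str | Path, schema: DatasetSchema,
                 validate: bool = True) -> list[PatientRecord]:
    """Read a JSON-lines record file; one admission per line, file order kept.

    Malformed lines and invariant violations are reported with their line
    number and record id.
    """
    records: list[PatientRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
            try:
                rec = PatientRecord.from_dict(obj)
            except (SchemaError, KeyError, TypeError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            if validate:
                violations = validate_record(rec, schema)
                if violations:
                    raise RecordValidationError(
                        f"{path}:{lineno}: record {rec.record_id}: " + "; ".join(violations)
                    )
            records.append(rec)
    return records


def write_records(path: str | Path, records: Iterable[PatientRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")
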