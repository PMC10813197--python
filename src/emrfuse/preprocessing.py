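"""From irregular raw admissions to the canonical windowed representation.

Pipeline (per record): linear interpolation of the sparse day-indexed
laboratory/vital grid -> merge of post-horizon days into the horizon day
and forward-fill padding of short stays -> segmentation of the 30-day
grid into n equal non-overlapping windows (default 10 windows of 3
days) -> one-hot discretisation of static tabular features -> note
tokenisation.

Interpolation is linear in day index per feature, with
nearest-observation fill before the first and after the last
observation; a feature never observed for a patient falls back to the
training-cohort median.  Temporal values are z-scored with training
statistics computed over observed cells only.  Observation masks mark
original (non-imputed, non-padded) cells throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .data_model import DatasetSchema, PatientRecord, SchemaError

PAD_ID = 0
UNK_ID = 1
DEFAULT_MERGED_NOTE_BUDGET = 512


def tokenize(text: str | Sequence[str],
             tokenizer: Callable[[str], list[str]] | None = None) -> list[str]:
    """Tokenize text; pre-tokenized sequences pass through unchanged.

    The default tokenizer splits on whitespace; any callable
    ``str -> list[str]`` can be injected instead.
    """
    if not isinstance(text, str):
        return list(text)
    if tokenizer is not None:
        return list(tokenizer(text))
    return text.split()


@dataclass
class WindowedRecord:
    """One admission on the canonical grid: n windows of ``window_days`` days."""

    record_id: str
    subseq_tabular: np.ndarray        # (n, W, F) real values
    subseq_tabular_mask: np.ndarray   # (n, W, F) 1 where originally observed
    subseq_notes: list[list[str]]     # n token sequences
    static_onehot: np.ndarray         # (S,) binary
    static_note_tokens: list[str]
    length_of_stay: int = 0
    label_mortality: int = 0
    label_long_stay: int = 0


def _dense_grid(record: PatientRecord, schema: DatasetSchema,
                medians: dict[str, float] | None = None
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Impute the irregular observations to a dense (n_days, F) grid.

    Same-day duplicate measurements of a feature: the first in record
    order wins (mirroring the first-note-of-the-day rule).  Returns
    (values, mask, n_days) where n_days spans the observed stay.
    """
    medians = medians or {}
    feats = schema.temporal_features
    n_days = max([record.length_of_stay]
                 + [o.day for o in record.temporal_tabular]
                 + [d for d, _ in record.temporal_notes])
    values = np.zeros((n_days, len(feats)))
    mask = np.zeros((n_days, len(feats)))
    by_feature: dict[str, dict[int, float]] = {f: {} for f in feats}
    for obs in record.temporal_tabular:
        slot = by_feature[obs.feature]
        if obs.day not in slot:  # first observation of the day wins
            slot[obs.day] = obs.value
    days_axis = np.arange(1, n_days + 1)
    for j, f in enumerate(feats):
        slot = by_feature[f]
        if not slot:
            values[:, j] = medians.get(f, 0.0)
            continue
        obs_days = np.array(sorted(slot))
        obs_vals = np.array([slot[d] for d in obs_days])
        # np.interp is linear inside the hull and clamps to the first/last
        # observation outside it (the edge-fill rule)
        values[:, j] = np.interp(days_axis, obs_days, obs_vals)
        mask[obs_days - 1, j] = 1.0
    return values, mask, n_days


def impute_temporal_tabular(record: PatientRecord, schema: DatasetSchema,
                            medians: dict[str, float] | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Dense per-day values + observation mask over the observed stay."""
    values, mask, _ = _dense_grid(record, schema, medians)
    return values, mask


def merge_and_pad(values: np.ndarray, mask: np.ndarray,
                  notes_by_day: dict[int, list[str]], schema: DatasetSchema,
                  note_budget: int = DEFAULT_MERGED_NOTE_BUDGET
                  ) -> tuple[np.ndarray, np.ndarray, list[list[str]]]:
    """Bring an admission onto exactly ``horizon_days`` days.

    Stays beyond the horizon are merged into the horizon day: per
    tabular feature the last observation at day >= horizon wins (the
    cell keeps mask 1), and the horizon-day note is the concatenation of
    all notes from the horizon onward, truncated to ``note_budget``
    tokens.  Shorter stays are forward-filled with mask 0 and empty note
    slots.
    """
    H = schema.horizon_days
    n_days, F = values.shape
    if n_days >= H:
        out_v = values[:H].copy()
        out_m = mask[:H].copy()
        for j in range(F):
            tail = np.nonzero(mask[H - 1:, j])[0]
            if tail.size:
                out_v[H - 1, j] = values[H - 1 + tail[-1], j]
                out_m[H - 1, j] = 1.0
    else:
        out_v = np.vstack([values, np.repeat(values[-1:], H - n_days, axis=0)])
        out_m = np.vstack([mask, np.zeros((H - n_days, F))])
    daily_notes: list[list[str]] = []
    for day in range(1, H):
        daily_notes.append(list(notes_by_day.get(day, [])))
    merged: list[str] = []
    for day in sorted(d for d in notes_by_day if d >= H):
        merged.extend(notes_by_day[day])
    daily_notes.append(merged[:note_budget])
    return out_v, out_m, daily_notes


def segment_windows(values: np.ndarray, mask: np.ndarray,
                    daily_notes: list[list[str]], schema: DatasetSchema
                    ) -> tuple[np.ndarray, np.ndarray, list[list[str]]]:
    """Cut the horizon grid into n equal consecutive non-overlapping windows."""
    H, W = schema.horizon_days, schema.window_days
    if H % W != 0:
        raise SchemaError(f"horizon {H} d is not divisible by window {W} d")
    if values.shape[0] != H or len(daily_notes) != H:
        raise ValueError(f"expected a {H}-day grid, got {values.shape[0]} days")
    n = H // W
    F = values.shape[1]
    win_v = values.reshape(n, W, F)
    win_m = mask.reshape(n, W, F)
    win_notes = [sum(daily_notes[i * W:(i + 1) * W], []) for i in range(n)]
    return win_v, win_m, win_notes


def discretize_and_onehot_static(static: dict[str, float | str],
                                 schema: DatasetSchema) -> np.ndarray:
    """One-hot encode static tabular features, group by group in schema order.

    Continuous features are discretised against their reference range
    into low/normal/high (values exactly on a bound count as normal; a
    missing value counts as normal).  Categorical features get one slot
    per category plus a trailing UNK slot for unseen or missing values.
    """
    parts: list[np.ndarray] = []
    for feat in schema.static_continuous:
        block = np.zeros(3)
        raw = static.get(feat.name)
        if raw is None:
            block[1] = 1.0
        else:
            x = float(raw)
            block[0 if x < feat.low else (2 if x > feat.high else 1)] = 1.0
        parts.append(block)
    for feat in schema.static_categorical:
        block = np.zeros(len(feat.categories) + 1)
        raw = static.get(feat.name)
        try:
            block[feat.categories.index(raw)] = 1.0
        except ValueError:
            block[-1] = 1.0  # UNK
        parts.append(block)
    return np.concatenate(parts) if parts else np.zeros(0)


class Vocab:
    """Frequency-ranked token vocabulary with PAD=0 and UNK=1."""

    def __init__(self, tokens_to_ids: dict[str, int] | None = None):
        self._ids = tokens_to_ids or {}

    @classmethod
    def fit(cls, documents: Iterable[Sequence[str]], max_size: int) -> "Vocab":
        counts: dict[str, int] = {}
        for doc in documents:
            for tok in doc:
                counts[tok] = counts.get(tok, 0) + 1
        ranked = sorted(counts, key=lambda t: (-counts[t], t))[: max_size - 2]
        return cls({tok: i + 2 for i, tok in enumerate(ranked)})

    def __len__(self) -> int:
        return len(self._ids) + 2

    def encode(self, tokens: Sequence[str]) -> list[int]:
        return [self._ids.get(t, UNK_ID) for t in tokens]


@dataclass
class Preprocessor:
    """Fit training-cohort statistics, then map raw records to windowed ones.

    ``fit`` computes per-feature medians (never-observed fallback),
    z-scoring means/stds over observed cells, and the note vocabulary;
    ``transform`` applies imputation, merge/pad, windowing, one-hot
    encoding and tokenisation with those frozen statistics.
    """

    schema: DatasetSchema
    note_budget: int = DEFAULT_MERGED_NOTE_BUDGET
    tokenizer: Callable[[str], list[str]] | None = None
    medians: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)
    vocab: Vocab | None = None

    def fit(self, records: Sequence[PatientRecord]) -> "Preprocessor":
        per_feature: dict[str, list[float]] = {f: [] for f in self.schema.temporal_features}
        docs: list[list[str]] = []
        for rec in records:
            for obs in rec.temporal_tabular:
                per_feature[obs.feature].append(obs.value)
            for _section, toks in rec.static_notes:
                docs.append(tokenize(toks, self.tokenizer))
            for _day, toks in rec.temporal_notes:
                docs.append(tokenize(toks, self.tokenizer))
        for f, vals in per_feature.items():
            arr = np.asarray(vals, dtype=float)
            self.medians[f] = float(np.median(arr)) if arr.size else 0.0
            self.means[f] = float(arr.mean()) if arr.size else 0.0
            sd = float(arr.std()) if arr.size else 1.0
            self.stds[f] = sd if sd > 1e-8 else 1.0
        self.vocab = Vocab.fit(docs, self.schema.note_vocab_size)
        return self

    def transform(self, record: PatientRecord) -> WindowedRecord:
        values, mask = impute_temporal_tabular(record, self.schema, self.medians)
        notes_by_day = {d: tokenize(t, self.tokenizer) for d, t in record.temporal_notes}
        values, mask, daily_notes = merge_and_pad(
            values, mask, notes_by_day, self.schema, self.note_budget)
        if self.means:
            mu = np.array([self.means[f] for f in self.schema.temporal_features])
            sd = np.array([self.stds[f] for f in self.schema.temporal_features])
            values = (values - mu) / sd
        win_v, win_m, win_notes = segment_windows(values, mask, daily_notes, self.schema)
        static_note = sum((tokenize(t, self.tokenizer) for _s, t in record.static_notes), [])
        return WindowedRecord(
            record_id=record.record_id,
            subseq_tabular=win_v,
            subseq_tabular_mask=win_m,
            subseq_notes=win_notes,
            static_onehot=discretize_and_onehot_static(record.static_tabular, self.schema),
            static_note_tokens=static_note,
            length_of_stay=record.length_of_stay,
            label_mortality=record.label_mortality,
            label_long_stay=record.label_long_stay,
        )

    def transform_all(self, records: Sequence[PatientRecord]) -> list[WindowedRecord]:
        return [self.transform(r) for r in records]
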