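"""Data model and I/O for diagnostic record cohorts.

A cohort is a list of de-identified diagnostic records, each pairing one
disease label (the first-listed / primary diagnosis) with the set of symptoms
reported for the patient.  Symptoms are presence-only: a symptom not listed in
a record is treated as absent everywhere downstream (closed-world assumption),
which is what makes 2x2 presence/absence tables well defined.

Two interchange formats are supported:

* JSONL — one object per line:
  ``{"record_id": str, "disease": str, "symptoms": [str, ...], "extras": {...}}``
  (lossless; arbitrary JSON metadata survives a round trip).
* CSV — columns ``record_id``, ``disease``, ``symptoms`` (';'-joined), plus one
  ``extras_<key>`` column per metadata key.  CSV metadata is stringly typed;
  the reserved key ``other_diseases`` is ';'-joined on save and split on load.

If a source row lists several diseases (';'-delimited string or a JSON list),
only the first is kept as the record's label; the rest are preserved in
``extras["other_diseases"]``.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SymptomVector",
    "DiagnosticRecord",
    "Cohort",
    "load_cohort",
    "save_cohort",
    "normalize_symptom",
]


def normalize_symptom(name: str) -> str:
    """Unicode NFC normalization + whitespace stripping (case preserved)."""
    return unicodedata.normalize("NFC", str(name)).strip()


@dataclass(frozen=True)
class SymptomVector:
    """An ordered, duplicate-free set of symptom identifiers."""

    symptoms: tuple[str, ...]

    def __post_init__(self) -> None:
        seen = set()
        for s in self.symptoms:
            if not s:
                raise ValueError("empty symptom identifier after normalization")
            if s in seen:
                raise ValueError(f"duplicate symptom {s!r} in SymptomVector")
            seen.add(s)

    @classmethod
    def from_iterable(cls, symptoms: Iterable[str]) -> "SymptomVector":
        """Build a vector, normalizing identifiers and dropping duplicates
        while preserving first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for raw in symptoms:
            s = normalize_symptom(raw)
            if not s:
                raise ValueError(f"empty symptom identifier in {list(symptoms)!r}")
            if s not in seen:
                seen.add(s)
                out.append(s)
        return cls(tuple(out))

    @property
    def n(self) -> int:
        return len(self.symptoms)

    def __iter__(self):
        return iter(self.symptoms)

    def __len__(self) -> int:
        return len(self.symptoms)

    def __contains__(self, item: object) -> bool:
        return item in self.symptoms


@dataclass(frozen=True)
class DiagnosticRecord:
    record_id: str
    disease: str
    symptoms: SymptomVector
    extras: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.disease:
            raise ValueError(f"record {self.record_id!r}: empty disease")


class Cohort:
    """A validated collection of diagnostic records.

    Vocabularies are built in first-appearance order unless given explicitly
    (the synthetic generator passes its own, so unseen-but-possible symptoms
    still appear in the model).
    """

    def __init__(
        self,
        records: Sequence[DiagnosticRecord],
        disease_vocabulary: Sequence[str] | None = None,
        symptom_vocabulary: Sequence[str] | None = None,
    ) -> None:
        self.records: list[DiagnosticRecord] = list(records)
        ids: set[str] = set()
        for rec in self.records:
            if rec.record_id in ids:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            ids.add(rec.record_id)
        if disease_vocabulary is None:
            disease_vocabulary = _first_appearance(r.disease for r in self.records)
        if symptom_vocabulary is None:
            symptom_vocabulary = _first_appearance(
                s for r in self.records for s in r.symptoms
            )
        self.disease_vocabulary: tuple[str, ...] = tuple(disease_vocabulary)
        self.symptom_vocabulary: tuple[str, ...] = tuple(symptom_vocabulary)
        dset, sset = set(self.disease_vocabulary), set(self.symptom_vocabulary)
        for rec in self.records:
            if rec.disease not in dset:
                raise ValueError(
                    f"record {rec.record_id!r}: disease {rec.disease!r} "
                    "not in disease_vocabulary"
                )
            for s in rec.symptoms:
                if s not in sset:
                    raise ValueError(
                        f"record {rec.record_id!r}: symptom {s!r} "
                        "not in symptom_vocabulary"
                    )

    @property
    def m(self) -> int:
        return len(self.records)

    @property
    def k(self) -> int:
        return len(self.disease_vocabulary)

    def __len__(self) -> int:
        return self.m

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.records == other.records
            and self.disease_vocabulary == other.disease_vocabulary
            and self.symptom_vocabulary == other.symptom_vocabulary
        )


def _first_appearance(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for it in items:
        if it not in seen:
            seen.add(it)
            out.append(it)
    return out


def _split_disease_field(value: Any) -> tuple[str, list[str]]:
    """First-listed disease policy: keep the primary label, stash the rest."""
    if isinstance(value, (list, tuple)):
        labels = [normalize_symptom(v) for v in value]
    else:
        labels = [normalize_symptom(v) for v in str(value).split(";")]
    labels = [l for l in labels if l]
    if not labels:
        return "", []
    return labels[0], labels[1:]


def _record_from_fields(
    record_id: Any, disease: Any, symptoms: Any, extras: dict[str, Any], lineno: int
) -> DiagnosticRecord:
    rid = str(record_id).strip()
    if not rid:
        raise ValueError(f"line {lineno}: empty record_id")
    primary, rest = _split_disease_field(disease)
    if not primary:
        raise ValueError(f"line {lineno}: empty disease field")
    if rest:
        extras = dict(extras)
        extras["other_diseases"] = rest
    if isinstance(symptoms, str):
        parts = [p for p in symptoms.split(";") if p.strip()]
    elif symptoms is None:
        parts = []
    else:
        parts = list(symptoms)
    return DiagnosticRecord(
        record_id=rid,
        disease=primary,
        symptoms=SymptomVector.from_iterable(parts),
        extras=extras,
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unknown cohort format {fmt!r}")
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def load_cohort(path: str | Path, format: str | None = None) -> Cohort:
    """Load a cohort from JSONL or CSV (format inferred from the suffix
    unless given).  Raises ``ValueError`` with a line number on malformed
    rows and on duplicate record ids."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[DiagnosticRecord] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {lineno}: unparsable JSON ({exc})") from exc
                if not isinstance(obj, dict) or "record_id" not in obj or "disease" not in obj:
                    raise ValueError(
                        f"line {lineno}: expected object with record_id and disease"
                    )
                records.append(
                    _record_from_fields(
                        obj["record_id"],
                        obj["disease"],
                        obj.get("symptoms", []),
                        dict(obj.get("extras", {})),
                        lineno,
                    )
                )
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in ("record_id", "disease", "symptoms"):
            if col not in df.columns:
                raise ValueError(f"CSV missing required column {col!r}")
        extra_cols = [c for c in df.columns if c.startswith("extras_")]
        for i, row in enumerate(df.itertuples(index=False), start=2):
            d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
            extras: dict[str, Any] = {}
            for c in extra_cols:
                v = d[c]
                if v != "":
                    key = c[len("extras_"):]
                    extras[key] = v.split(";") if key == "other_diseases" else v
            rec = _record_from_fields(d["record_id"], d["disease"], d["symptoms"], extras, i)
            # other_diseases may arrive both via the column and via a multi-label
            # disease field; the column wins when present.
            records.append(rec)
    return Cohort(records)


def save_cohort(cohort: Cohort, path: str | Path, format: str | None = None) -> Path:
    """Write the cohort; ``load_cohort(save_cohort(c))`` reproduces records,
    order and vocabularies (see module docstring for CSV's typing caveat)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in cohort:
                obj = {
                    "record_id": rec.record_id,
                    "disease": rec.disease,
                    "symptoms": list(rec.symptoms),
                    "extras": dict(rec.extras),
                }
                fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")
    else:
        extra_keys = _first_appearance(
            k for rec in cohort for k in rec.extras
        )
        rows = []
        for rec in cohort:
            row: dict[str, Any] = {
                "record_id": rec.record_id,
                "disease": rec.disease,
                "symptoms": ";".join(rec.symptoms),
            }
            for k in extra_keys:
                v = rec.extras.get(k, "")
                if k == "other_diseases" and isinstance(v, (list, tuple)):
                    v = ";".join(v)
                row[f"extras_{k}"] = v
            rows.append(row)
        cols = ["record_id", "disease", "symptoms"] + [f"extras_{k}" for k in extra_keys]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path
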