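"""Volatile-compound catalog: data model, CSV reader/writer, class census.

The catalog is the master table of volatiles identified by GC-MS: one row per
compound with its chemical class, DB-WAX retention index, quantitative ion,
free-text aroma descriptors, and the odor detection threshold (µg/L) used for
odor-activity-value scoring.  A missing threshold is stored as ``None`` (never
0 or infinity): downstream OAVs for such compounds are undefined.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator

__all__ = [
    "CompoundClass",
    "CompoundRecord",
    "CompoundCatalog",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "class_census",
    "normalize_name",
]

#: cells holding these strings denote an absent value
MISSING_TOKENS = {"", "—", "-", "--", "na", "n/a", "none"}


class CatalogError(ValueError):
    """Raised when a catalog file violates the catalog contract."""


class CompoundClass(str, Enum):
    ESTER = "ester"
    ALDEHYDE = "aldehyde"
    ACID = "acid"
    ALCOHOL = "alcohol"
    KETONE = "ketone"
    PHENOL = "phenol"
    FURAN = "furan"
    PYRAZINE = "pyrazine"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "CompoundClass":
        norm = label.strip().lower()
        # table headers use the plural "Others" for the catch-all class
        if norm in {"other", "others"}:
            return cls.OTHER
        try:
            return cls(norm)
        except ValueError:
            allowed = ", ".join(c.value for c in cls)
            raise CatalogError(
                f"unknown compound class {label!r}; allowed: {allowed}"
            ) from None


def normalize_name(name: str) -> str:
    """Lowercase and collapse internal whitespace, for matching only."""
    return re.sub(r"\s+", " ", name.strip()).lower()


def _parse_number(cell: str) -> float | None:
    """Parse a numeric cell, accepting thousands separators; None if absent."""
    token = cell.strip()
    if token.lower() in MISSING_TOKENS:
        return None
    return float(token.replace(",", ""))


def _parse_descriptors(cell: str) -> list[str]:
    token = cell.strip()
    if token.lower() in MISSING_TOKENS:
        return []
    return [t.strip().lower() for t in token.split(",") if t.strip()]


@dataclass(frozen=True)
class CompoundRecord:
    """One volatile compound (a catalog row)."""

    compound_id: int
    name: str
    compound_class: CompoundClass
    retention_index: int | None = None
    quant_ion: int | None = None
    odor_threshold: float | None = None
    descriptors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.odor_threshold is not None and self.odor_threshold <= 0:
            raise CatalogError(
                f"nonpositive odor threshold for {self.name!r}: {self.odor_threshold}"
            )


@dataclass
class CompoundCatalog:
    """Ordered collection of compound records with unique normalized names."""

    records: list[CompoundRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise CatalogError("empty catalog")
        seen: dict[str, str] = {}
        for rec in self.records:
            key = normalize_name(rec.name)
            if key in seen:
                raise CatalogError(f"duplicate compound name: {rec.name!r}")
            seen[key] = rec.name
        ids = [r.compound_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CatalogError("duplicate compound_id in catalog")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, compound_id: int) -> CompoundRecord:
        return self.by_id()[compound_id]

    def by_id(self) -> dict[int, CompoundRecord]:
        return {r.compound_id: r for r in self.records}

    def by_name(self) -> dict[str, CompoundRecord]:
        return {normalize_name(r.name): r for r in self.records}

    def compound_ids(self) -> list[int]:
        return [r.compound_id for r in self.records]

    def thresholds(self) -> dict[int, float | None]:
        return {r.compound_id: r.odor_threshold for r in self.records}

    def with_thresholds(self, overrides: dict[int, float | None]) -> "CompoundCatalog":
        """Return a copy with some odor thresholds replaced (e.g. literature
        corrections)."""
        recs = [
            replace(r, odor_threshold=overrides.get(r.compound_id, r.odor_threshold))
            for r in self.records
        ]
        return CompoundCatalog(recs, provenance=self.provenance)


_COLUMN_ALIASES = {
    "compound_id": {"compound_id", "id", "no", "no."},
    "name": {"name", "compound"},
    "class": {"class", "compound_class"},
    "retention_index": {"retention_index", "ri"},
    "quant_ion": {"quant_ion", "quantitative_ion", "quantitative ion"},
    "odor_threshold": {"odor_threshold", "threshold", "odor threshold"},
    "descriptors": {"descriptors", "aroma_description", "aroma description"},
}


def _resolve_columns(header: list[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    lowered = {h.strip().lower(): h for h in header}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[canon] = lowered[alias]
                break
    for required in ("name", "class", "odor_threshold"):
        if required not in mapping:
            raise CatalogError(f"catalog file lacks a {required!r} column")
    return mapping


def load_catalog(
    path: str | Path,
    provenance: str | None = None,
    threshold_column: str | None = None,
) -> CompoundCatalog:
    """Read a compound catalog from a delimited text file.

    Parameters
    ----------
    path
        CSV file (comma, UTF-8, header row).  "—" or an empty cell denotes a
        missing value; thresholds may carry thousands separators.
    threshold_column
        Optional alternative column to read odor thresholds from (used by the
        packaged fixtures, which carry both the printed and the implied
        threshold values).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CatalogError("empty catalog")
        cols = _resolve_columns(list(reader.fieldnames))
        if threshold_column is not None:
            if threshold_column not in reader.fieldnames:
                raise CatalogError(f"no column {threshold_column!r} in {path.name}")
            cols["odor_threshold"] = threshold_column
        records: list[CompoundRecord] = []
        for i, row in enumerate(reader, start=1):
            name = row[cols["name"]].strip()
            if not name:
                raise CatalogError(f"row {i}: empty compound name")
            cid_cell = row.get(cols.get("compound_id", ""), "")
            cid = int(cid_cell) if cid_cell and cid_cell.strip() else i
            ri_cell = row.get(cols.get("retention_index", ""), "") or ""
            ion_cell = row.get(cols.get("quant_ion", ""), "") or ""
            ri = _parse_number(ri_cell)
            ion = _parse_number(ion_cell)
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    name=name,
                    compound_class=CompoundClass.parse(row[cols["class"]]),
                    retention_index=int(ri) if ri is not None else None,
                    quant_ion=int(ion) if ion is not None else None,
                    odor_threshold=_parse_number(row[cols["odor_threshold"]]),
                    descriptors=_parse_descriptors(
                        row.get(cols.get("descriptors", ""), "") or ""
                    ),
                )
            )
    if not records:
        raise CatalogError("empty catalog")
    return CompoundCatalog(records, provenance=provenance or str(path))


def write_catalog(catalog: CompoundCatalog, path: str | Path) -> None:
    """Write a catalog back to CSV (round-trips every field of load_catalog)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "compound_id",
                "name",
                "class",
                "retention_index",
                "quant_ion",
                "odor_threshold",
                "descriptors",
            ]
        )
        for r in catalog:
            writer.writerow(
                [
                    r.compound_id,
                    r.name,
                    r.compound_class.value,
                    r.retention_index if r.retention_index is not None else "",
                    r.quant_ion if r.quant_ion is not None else "",
                    repr(r.odor_threshold) if r.odor_threshold is not None else "",
                    ", ".join(r.descriptors),
                ]
            )


def class_census(catalog: CompoundCatalog) -> dict[CompoundClass, int]:
    """Count compounds per chemical class; absent classes map to 0."""
    counts = {c: 0 for c in CompoundClass}
    for rec in catalog:
        counts[rec.compound_class] += 1
    return counts
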