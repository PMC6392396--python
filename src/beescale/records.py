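"""Specimen tables: domain types, CSV I/O, and curation transforms.

A specimen is one measured insect: its taxonomy (species, genus, and a
grouping label -- bee family or hoverfly subfamily), sex, biogeographic
region of origin, intertegular distance (ITD, mm) and, when the specimen
has been dehydrated and weighed, dry weight (mg).  Dry weight is the
operational definition of body size throughout this package.

Curation transforms implemented here:

* pin-weight correction -- specimens weighed while mounted carry the pin's
  mass; the mean weight of the specimen's pin type is subtracted off;
* introduced-range exclusion -- records of a species collected outside its
  native range are removed before interspecific model fitting.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "REGIONS",
    "SEXES",
    "SpecimenRecord",
    "PinTable",
    "ExclusionRule",
    "DEFAULT_EXCLUSIONS",
    "SpecimenValidationError",
    "read_specimens",
    "write_specimens",
    "records_to_frame",
    "frame_to_records",
    "apply_pin_correction",
    "apply_exclusions",
]

REGIONS = ("Australia", "Europe", "North America", "South America")
SEXES = ("female", "male")

#: canonical column name -> canonical column name (identity default dialect)
DEFAULT_COLUMNS = {
    "specimen_id": "specimen_id",
    "species": "species",
    "genus": "genus",
    "group": "group",
    "sex": "sex",
    "region": "region",
    "itd_mm": "itd_mm",
    "dry_weight_mg": "dry_weight_mg",
    "body_length_mm": "body_length_mm",
    "pin_type": "pin_type",
    "latitude": "latitude",
    "longitude": "longitude",
}

_MANDATORY = ("specimen_id", "species", "genus", "group", "sex", "region", "itd_mm")

_SEX_ALIASES = {
    "f": "female", "female": "female", "♀": "female",
    "m": "male", "male": "male", "♂": "male",
}


@dataclass(frozen=True)
class SpecimenRecord:
    """One measured insect.

    ``group`` is the taxonomic grouping used as a fixed effect in the
    interspecific models: bee family (Michener's classification) or
    hoverfly subfamily.  ``pin_corrected`` guards against subtracting the
    pin weight twice; ``pin_mean_subtracted_mg`` is the audit trail of the
    correction that was applied.
    """

    specimen_id: str
    species: str
    genus: str
    group: str
    sex: str
    region: str
    itd_mm: float
    dry_weight_mg: float | None = None
    body_length_mm: float | None = None
    pin_type: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    pin_corrected: bool = False
    pin_mean_subtracted_mg: float | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.species or not self.species.strip():
            problems.append("species is empty")
        if self.sex not in SEXES:
            problems.append(f"unknown sex {self.sex!r} (expected one of {SEXES})")
        if self.region not in REGIONS:
            problems.append(f"unknown region {self.region!r} (expected one of {REGIONS})")
        if not (isinstance(self.itd_mm, (int, float)) and math.isfinite(self.itd_mm) and self.itd_mm > 0):
            problems.append(f"itd_mm must be a positive finite number, got {self.itd_mm!r}")
        for name in ("dry_weight_mg", "body_length_mm"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                problems.append(f"{name} must be positive when present, got {v!r}")
        return problems


class SpecimenValidationError(ValueError):
    """Raised after a full validation pass; carries every bad row.

    ``errors`` is a list of ``(row_number, message)`` pairs with 1-based
    row numbers counted over data rows (header excluded).  Validation is
    collect-then-report so a curator sees the whole damage at once.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors[:25])
        more = "" if len(self.errors) <= 25 else f" (+{len(self.errors) - 25} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


def _parse_float(token: str, column: str, optional: bool) -> float | None:
    token = token.strip()
    if token == "" or token.upper() in {"NA", "NAN", "NULL"}:
        if optional:
            return None
        raise ValueError(f"missing value for mandatory column {column!r}")
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"column {column!r}: cannot parse {token!r} as a number") from None


def read_specimens(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[SpecimenRecord]:
    """Read a UTF-8 CSV specimen table into validated records.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional mapping from canonical field names (``species``,
        ``itd_mm``, ...) to the column names actually present in the
        file.  Unmapped canonical names default to themselves.

    Raises
    ------
    SpecimenValidationError
        Listing every failing row (1-based, header excluded); valid rows
        are never silently dropped alongside invalid ones.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if dialect:
        colmap.update(dialect)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header row required")
        header = set(reader.fieldnames)
        missing = [colmap[k] for k in _MANDATORY if colmap[k] not in header]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")

        records: list[SpecimenRecord] = []
        errors: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=1):
            def get(key: str) -> str:
                col = colmap[key]
                return (row.get(col) or "").strip()

            try:
                sex_raw = get("sex")
                sex = _SEX_ALIASES.get(sex_raw.lower(), sex_raw)
                rec = SpecimenRecord(
                    specimen_id=get("specimen_id") or f"row{i}",
                    species=get("species"),
                    genus=get("genus"),
                    group=get("group"),
                    sex=sex,
                    region=get("region"),
                    itd_mm=_parse_float(get("itd_mm"), "itd_mm", optional=False),
                    dry_weight_mg=_parse_float(get("dry_weight_mg"), "dry_weight_mg", True),
                    body_length_mm=_parse_float(get("body_length_mm"), "body_length_mm", True),
                    pin_type=get("pin_type") or None,
                    latitude=_parse_float(get("latitude"), "latitude", True),
                    longitude=_parse_float(get("longitude"), "longitude", True),
                )
            except ValueError as exc:
                errors.append((i, str(exc)))
                continue
            problems = rec.validate()
            if problems:
                errors.extend((i, p) for p in problems)
            else:
                records.append(rec)

    # one species must not straddle genera within a table
    genus_of: dict[str, str] = {}
    for rec in records:
        prev = genus_of.setdefault(rec.species, rec.genus)
        if prev != rec.genus:
            errors.append((0, f"species {rec.species!r} mapped to two genera: {prev!r}, {rec.genus!r}"))
            break
    if errors:
        raise SpecimenValidationError(errors)
    return records


def write_specimens(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write records as CSV in the default dialect (full float precision)."""
    names = [f.name for f in fields(SpecimenRecord)]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(names)
        for rec in records:
            row = []
            for name in names:
                v = getattr(rec, name)
                if v is None:
                    row.append("")
                elif isinstance(v, bool):
                    row.append(str(v))
                elif isinstance(v, float):
                    row.append(repr(v))  # shortest round-trippable form
                else:
                    row.append(str(v))
            writer.writerow(row)


def records_to_frame(records: Sequence[SpecimenRecord]):
    """Records -> pandas DataFrame (the in-memory currency of the models)."""
    import pandas as pd

    names = [f.name for f in fields(SpecimenRecord)]
    return pd.DataFrame([{n: getattr(r, n) for n in names} for r in records])


def frame_to_records(frame) -> list[SpecimenRecord]:
    """DataFrame -> records; NaN becomes None for optional fields."""
    names = [f.name for f in fields(SpecimenRecord)]
    out = []
    for row in frame.to_dict("records"):
        kwargs = {}
        for n in names:
            if n not in row:
                continue
            v = row[n]
            if isinstance(v, float) and math.isnan(v):
                v = None
            kwargs[n] = v
        out.append(SpecimenRecord(**kwargs))
    return out


# ---------------------------------------------------------------------------
# pin correction


@dataclass
class PinTable:
    """Mean weight of each pin type, from weighing a sample of pins.

    ``entries`` maps pin_type -> (mean_weight_mg, se_mg, n_weighed).
    The standard error is recorded for bookkeeping but not propagated
    into downstream models.
    """

    entries: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pin, (mean, se, n) in self.entries.items():
            if mean < 0:
                raise ValueError(f"pin {pin!r}: mean weight must be >= 0, got {mean}")
            if n < 1:
                raise ValueError(f"pin {pin!r}: n_weighed must be >= 1, got {n}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PinTable":
        """Load a (pin_type, mean_mg, se_mg, n) CSV."""
        entries = {}
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries[row["pin_type"].strip()] = (
                    float(row["mean_mg"]), float(row["se_mg"]), int(row["n"]),
                )
        return cls(entries)


def apply_pin_correction(record: SpecimenRecord, pins: PinTable) -> SpecimenRecord:
    """Subtract the mean weight of the specimen's pin type from its dry weight.

    Returns a new record with ``pin_corrected=True`` and the subtracted
    mean recorded in ``pin_mean_subtracted_mg``; all other fields are
    unchanged.  Raises if the record has no weight or pin type, the pin
    type is unknown, the record was already corrected, or the corrected
    weight would be non-positive (which signals an implausible pin
    assignment, not a usable measurement).
    """
    if record.pin_corrected:
        raise ValueError(f"{record.specimen_id}: pin correction already applied")
    if record.dry_weight_mg is None:
        raise ValueError(f"{record.specimen_id}: no dry weight to correct")
    if record.pin_type is None:
        raise ValueError(f"{record.specimen_id}: no pin type recorded")
    if record.pin_type not in pins.entries:
        raise KeyError(f"{record.specimen_id}: unknown pin type {record.pin_type!r}")
    mean_mg = pins.entries[record.pin_type][0]
    corrected = record.dry_weight_mg - mean_mg
    if corrected <= 0:
        raise ValueError(
            f"{record.specimen_id}: corrected weight {corrected:.4g} mg <= 0 "
            f"(weight {record.dry_weight_mg} mg, pin mean {mean_mg} mg)"
        )
    return replace(
        record,
        dry_weight_mg=corrected,
        pin_corrected=True,
        pin_mean_subtracted_mg=mean_mg,
    )


# ---------------------------------------------------------------------------
# introduced-range exclusions


@dataclass(frozen=True)
class ExclusionRule:
    """Remove a species from one region (its introduced range)."""

    species: str
    excluded_region: str

    def __post_init__(self) -> None:
        if self.excluded_region not in REGIONS:
            raise ValueError(
                f"unknown region {self.excluded_region!r} (expected one of {REGIONS})"
            )


#: Bee species removed from their introduced ranges before interspecific fits.
DEFAULT_EXCLUSIONS: tuple[ExclusionRule, ...] = (
    ExclusionRule("Andrena wilkella", "North America"),
    ExclusionRule("Halictus rubicundus", "North America"),
    ExclusionRule("Lasioglossum leucozonium", "North America"),
    ExclusionRule("Anthidium manicatum", "North America"),
    ExclusionRule("Apis mellifera", "Australia"),
)


def apply_exclusions(
    records: Sequence[SpecimenRecord],
    rules: Iterable[ExclusionRule] = DEFAULT_EXCLUSIONS,
) -> tuple[list[SpecimenRecord], list[SpecimenRecord]]:
    """Partition records into (kept, removed) by (species, region) match.

    A record is removed iff some rule matches both its species and its
    region; order is preserved in both outputs and kept + removed is a
    permutation-free partition of the input.
    """
    banned = {(r.species, r.excluded_region) for r in rules}
    kept, removed = [], []
    for rec in records:
        (removed if (rec.species, rec.region) in banned else kept).append(rec)
    return kept, removed
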