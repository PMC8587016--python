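"""Domain types, units, ingestion, and toxicity-data screening rules.

Acute aquatic toxicity records (LC50/EC50) arrive from databases or from
model predictions in heterogeneous units and exposure durations.  This
module canonicalises them: concentrations are converted to mg/L once at
ingestion, records are filtered to the preferred exposure duration per
species class (48 h for invertebrates, 96 h otherwise), and replicate
values for the same species and endpoint are collapsed to their geometric
mean, yielding one sensitivity value per species ready for SSD fitting.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from fractions import Fraction
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._utils import geometric_mean, normalize_species
from .errors import FormatError, UnitError, ValidationError

#: The molecular-descriptor vocabulary: quantum-chemical (AM1) descriptors
#: plus molecular weight and the octanol-water partition coefficient.
DESCRIPTOR_SYMBOLS = (
    "HOF",    # heat of formation, kcal/mol
    "TE",     # total energy, eV
    "EE",     # electronic energy, eV
    "ECCR",   # core-core repulsion energy, eV
    "CA",     # COSMO area, A^2
    "CV",     # COSMO volume, A^3
    "GN",     # gradient norm
    "GNpA",   # gradient norm per atom
    "IP",     # ionization potential, eV
    "ELUMO",  # lowest unoccupied molecular orbital energy, eV
    "EHOMO",  # highest occupied molecular orbital energy, eV
    "MW",     # molecular weight
    "Kow",    # octanol-water partition coefficient
)

#: Power-of-ten exponent relative to mg/L.
_UNIT_EXP_MG_L = {"ng/L": -6, "µg/L": -3, "ug/L": -3, "mg/L": 0, "g/L": 3}

#: Preferred exposure duration (h) by species class.
PREFERRED_DURATION_H = {"invertebrate": 48.0, "fish": 96.0, "alga": 96.0, "other": 96.0}


class SpeciesClass(str, Enum):
    invertebrate = "invertebrate"
    fish = "fish"
    alga = "alga"
    other = "other"


class Endpoint(str, Enum):
    LC50 = "LC50"
    EC50 = "EC50"


class Provenance(str, Enum):
    """How a toxicity value was obtained; observed data outrank extrapolations."""

    measured = "measured"
    qsar = "qsar"
    ice = "ice"


@dataclass(frozen=True)
class ChemicalRecord:
    """A chemical identity plus its molecular-descriptor vector."""

    chem_id: str
    cas: str = ""
    name: str = ""
    chain_length: Optional[int] = None
    descriptors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.descriptors) - set(DESCRIPTOR_SYMBOLS)
        if unknown:
            raise ValidationError(
                f"unknown descriptor symbol(s) {sorted(unknown)} for chemical "
                f"{self.chem_id!r}; allowed: {DESCRIPTOR_SYMBOLS}"
            )
        mw = self.descriptors.get("MW")
        if mw is not None and mw <= 0:
            raise ValidationError(f"MW must be positive for chemical {self.chem_id!r}")
        if self.chain_length is not None and self.chain_length < 0:
            raise ValidationError(f"chain_length must be >= 0 for {self.chem_id!r}")


@dataclass(frozen=True)
class ToxicityRecord:
    """One acute endpoint observation (concentration in mg/L)."""

    chem_id: str
    species: str
    species_class: SpeciesClass
    endpoint: Endpoint
    duration_h: float
    concentration: float
    provenance: Provenance
    trophic_level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValidationError(
                f"concentration must be positive, got {self.concentration} "
                f"({self.chem_id!r}/{self.species!r})"
            )
        if self.duration_h <= 0:
            raise ValidationError(
                f"duration_h must be positive, got {self.duration_h} "
                f"({self.chem_id!r}/{self.species!r})"
            )
        if self.trophic_level is not None and not 1 <= self.trophic_level <= 3:
            raise ValidationError("trophic_level must be in 1..3 when given")


@dataclass(frozen=True)
class SpeciesToxicity:
    """Aggregated species-level sensitivity: geometric mean over source records."""

    species: str
    value: float  # mg/L
    n_source_records: int = 1
    provenance: Provenance = Provenance.measured
    endpoint: Optional[Endpoint] = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(f"species value must be positive ({self.species!r})")
        if self.n_source_records < 1:
            raise ValidationError("n_source_records must be >= 1")


def convert_concentration(value: float, from_unit: str, to_unit: str) -> float:
    """Power-of-ten conversion between ng/L, µg/L, mg/L and g/L.

    The decimal scaling is applied in exact rational arithmetic and rounded
    once to the nearest double, so each conversion is correctly rounded and
    a round trip returns the input to within one unit in the last place
    (bit-exact identity is impossible for decimal factors in binary floats).
    """
    try:
        f = _UNIT_EXP_MG_L[from_unit]
    except KeyError:
        raise UnitError(f"unknown unit {from_unit!r}; supported: ng/L, µg/L, mg/L, g/L")
    try:
        t = _UNIT_EXP_MG_L[to_unit]
    except KeyError:
        raise UnitError(f"unknown unit {to_unit!r}; supported: ng/L, µg/L, mg/L, g/L")
    e = f - t
    if e == 0 or value == 0 or not math.isfinite(value):
        return value
    scale = Fraction(10) ** e
    return float(Fraction(value) * scale)


_REQUIRED_TOX_COLUMNS = (
    "chem_id",
    "species",
    "species_class",
    "endpoint",
    "duration_h",
    "concentration",
    "unit",
    "provenance",
)


def load_toxicity_table(path: str | Path, format: str = "csv") -> list[ToxicityRecord]:
    """Read a toxicity CSV into records, converting concentrations to mg/L.

    The header must name the columns ``chem_id, species, species_class,
    endpoint, duration_h, concentration, unit, provenance`` (plus optional
    ``trophic_level``).  Rows are preserved in input order; validation
    failures raise with the 1-based data row number.
    """
    if format != "csv":
        raise FormatError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"toxicity table not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        return _parse_toxicity_csv(fh, str(path))


def _parse_toxicity_csv(fh: io.TextIOBase, source: str) -> list[ToxicityRecord]:
    reader = csv.DictReader(fh)
    header = reader.fieldnames or []
    missing = [c for c in _REQUIRED_TOX_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{source}: missing required column(s): {', '.join(missing)}")
    records: list[ToxicityRecord] = []
    for i, row in enumerate(reader, start=1):
        try:
            conc = convert_concentration(float(row["concentration"]), row["unit"], "mg/L")
            tl = row.get("trophic_level")
            records.append(
                ToxicityRecord(
                    chem_id=row["chem_id"].strip(),
                    species=row["species"].strip(),
                    species_class=SpeciesClass(row["species_class"].strip().lower()),
                    endpoint=Endpoint(row["endpoint"].strip().upper()),
                    duration_h=float(row["duration_h"]),
                    concentration=conc,
                    provenance=Provenance(row["provenance"].strip().lower()),
                    trophic_level=int(tl) if tl not in (None, "", "NA") else None,
                )
            )
        except (ValidationError, UnitError, ValueError) as exc:
            raise ValidationError(f"{source}, data row {i}: {exc}") from exc
    return records


def write_toxicity_table(records: Iterable[ToxicityRecord], path: str | Path) -> None:
    """Write records back to the same CSV schema (mg/L), round-trip safe."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_REQUIRED_TOX_COLUMNS + ("trophic_level",))
        for r in records:
            w.writerow(
                [
                    r.chem_id,
                    r.species,
                    r.species_class.value,
                    r.endpoint.value,
                    repr(float(r.duration_h)),
                    repr(float(r.concentration)),
                    "mg/L",
                    r.provenance.value,
                    "" if r.trophic_level is None else r.trophic_level,
                ]
            )


def load_chemical_table(path: str | Path) -> list[ChemicalRecord]:
    """Read chemicals.csv: identity columns followed by descriptor columns."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"chemical table not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if "chem_id" not in header:
            raise FormatError(f"{path}: missing required column(s): chem_id")
        chems: list[ChemicalRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=1):
            cid = row["chem_id"].strip()
            if cid in seen:
                raise ValidationError(f"{path}, data row {i}: duplicate chem_id {cid!r}")
            seen.add(cid)
            desc = {
                s: float(row[s])
                for s in DESCRIPTOR_SYMBOLS
                if s in row and row[s] not in (None, "", "NA")
            }
            cl = row.get("chain_length")
            try:
                chems.append(
                    ChemicalRecord(
                        chem_id=cid,
                        cas=row.get("cas", "").strip(),
                        name=row.get("name", "").strip(),
                        chain_length=int(cl) if cl not in (None, "", "NA") else None,
                        descriptors=desc,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}, data row {i}: {exc}") from exc
    return chems


def write_chemical_table(chems: Iterable[ChemicalRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(("chem_id", "cas", "name", "chain_length") + DESCRIPTOR_SYMBOLS)
        for c in chems:
            w.writerow(
                [c.chem_id, c.cas, c.name, "" if c.chain_length is None else c.chain_length]
                + [repr(float(c.descriptors[s])) if s in c.descriptors else "" for s in DESCRIPTOR_SYMBOLS]
            )


def select_preferred_records(records: Sequence[ToxicityRecord]) -> list[ToxicityRecord]:
    """Keep, per (chemical, species), records at the preferred exposure duration.

    Invertebrates prefer 48 h, all other classes 96 h.  When no record sits
    exactly at the preferred duration the nearest duration is used instead,
    with ties resolved toward the shorter exposure.  A species that had
    input records always keeps at least one.
    """
    groups: dict[tuple[str, str], list[ToxicityRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in records:
        key = (r.chem_id, normalize_species(r.species))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    kept: list[ToxicityRecord] = []
    for key in order:
        grp = groups[key]
        pref = PREFERRED_DURATION_H[grp[0].species_class.value]
        # nearest duration, tie -> shorter
        best = min(grp, key=lambda r: (abs(r.duration_h - pref), r.duration_h))
        target = best.duration_h
        kept.extend(r for r in grp if r.duration_h == target)
    return kept


def aggregate_species_toxicity(records: Sequence[ToxicityRecord]) -> list[SpeciesToxicity]:
    """Collapse records to one value per (species, endpoint): the geometric mean.

    All input records must share a chemical; concentrations are mg/L.  When
    a group mixes provenances, the observed (measured) label wins over model
    predictions, and QSAR over ICE.
    """
    chem_ids = {r.chem_id for r in records}
    if len(chem_ids) > 1:
        raise ValidationError(f"records span multiple chemicals: {sorted(chem_ids)}")
    groups: dict[tuple[str, Endpoint], list[ToxicityRecord]] = {}
    order: list[tuple[str, Endpoint]] = []
    for r in records:
        key = (normalize_species(r.species), r.endpoint)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    rank = {Provenance.measured: 0, Provenance.qsar: 1, Provenance.ice: 2}
    out: list[SpeciesToxicity] = []
    for key in order:
        grp = groups[key]
        out.append(
            SpeciesToxicity(
                species=grp[0].species,
                value=geometric_mean(r.concentration for r in grp),
                n_source_records=len(grp),
                provenance=min((r.provenance for r in grp), key=rank.__getitem__),
                endpoint=key[1],
            )
        )
    return out
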