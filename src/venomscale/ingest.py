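"""Curation of literature LD50 and morphology records into an analysis table.

The measure-level table this module produces is the input to the
phylogenetic mixed model: one row per published LD50 measurement, carrying
log10 LD50 (mg dried venom per kg of test subject), log10 total body
length (mm), the two mass-independent shape indices (chela length/width
and telson length/width), and the injection route.

Curation follows the conventions of comparative venom studies: only dried
venom assayed on a single configured model organism is retained, all doses
are normalized to mg/kg, and species whose morphology was never measured
may borrow the measurements of a morphologically indistinguishable donor
species (an explicit, audited proxy).
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import MissingMassError, ConfigurationError, UnitError, ValidationError

logger = logging.getLogger(__name__)

ROUTES = ("SC", "IV", "IP", "IM")

#: Multiplicative factors to mg/kg for per-mass dose units.
_PER_MASS_FACTORS = {
    "mg/kg": 1.0,
    "ug/g": 1.0,  # µg/g is the same mass ratio as mg/kg
    "mg/g": 1000.0,
    "ug/kg": 1e-3,
}

#: Per-animal dose units and their factor to mg (divide by subject mass in kg).
_PER_ANIMAL_FACTORS = {
    "ug/animal": 1e-3,
    "mg/animal": 1.0,
}


def normalize_species_name(name: str) -> str:
    """Canonicalize a species name for matching across tables and tree tips.

    Trims, collapses internal whitespace, replaces underscores with spaces,
    and case-folds. Tip labels and trait tables rarely agree byte-for-byte;
    anything beyond this normalization is treated as a genuine mismatch.
    """
    return re.sub(r"\s+", " ", name.replace("_", " ").strip()).casefold()


def normalize_unit_token(units: str) -> str:
    """Canonicalize a unit token: strip, lower-case, µ→u, remove spaces."""
    return units.strip().lower().replace("µ", "u").replace(" ", "")


@dataclass(frozen=True)
class PotencyRecord:
    """One literature LD50 measurement.

    ``ld50_value`` is in ``ld50_units``; ``subject_mass_kg`` is the body
    mass of the test animal (required for per-animal dose units).
    """

    species_name: str
    ld50_value: float
    ld50_units: str
    route: str
    venom_state: str
    test_model: str
    subject_mass_kg: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.species_name or not self.species_name.strip():
            raise ValidationError("PotencyRecord requires a species name")
        if not (self.ld50_value > 0) or not math.isfinite(self.ld50_value):
            raise ValidationError(
                f"LD50 must be a positive finite number, got {self.ld50_value!r} "
                f"for {self.species_name!r}"
            )
        if self.route not in ROUTES:
            raise ValidationError(
                f"route must be one of {ROUTES}, got {self.route!r} "
                f"for {self.species_name!r}"
            )
        if self.subject_mass_kg is not None and not (self.subject_mass_kg > 0):
            raise ValidationError(
                f"subject_mass_kg must be positive when present, got "
                f"{self.subject_mass_kg!r} for {self.species_name!r}"
            )
        if normalize_unit_token(self.ld50_units) in _PER_ANIMAL_FACTORS and self.subject_mass_kg is None:
            raise ValidationError(
                f"per-animal units {self.ld50_units!r} require subject_mass_kg "
                f"({self.species_name!r})"
            )


@dataclass(frozen=True)
class MorphologyRecord:
    """Per-species total body length and chela/telson length+width, all mm.

    A width larger than its length is allowed: a chela ratio below 1
    (short thick pincer) is biologically real.
    """

    species_name: str
    total_length_mm: float
    chela_length_mm: float
    chela_width_mm: float
    telson_length_mm: float
    telson_width_mm: float
    proxy_for: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        for fname in (
            "total_length_mm",
            "chela_length_mm",
            "chela_width_mm",
            "telson_length_mm",
            "telson_width_mm",
        ):
            v = getattr(self, fname)
            if not (v > 0) or not math.isfinite(v):
                raise ValidationError(
                    f"{fname} must be positive and finite, got {v!r} "
                    f"for {self.species_name!r}"
                )


@dataclass
class AnalysisTable:
    """Curated measure-level table consumed by the model.

    ``data`` has one row per LD50 measure with columns ``species``
    (display name), ``log10_ld50``, ``log10_body_length``, ``chela_ratio``,
    ``telson_ratio``, ``route``. ``species_names`` is the ordered unique
    species list (first-appearance order); ``species_index`` maps each row
    to its position in that list.
    """

    data: pd.DataFrame
    species_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {
            "species",
            "log10_ld50",
            "log10_body_length",
            "chela_ratio",
            "telson_ratio",
            "route",
        }
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"analysis table missing columns: {sorted(missing)}")
        if not self.species_names:
            self.species_names = list(dict.fromkeys(self.data["species"]))
        for col in ("log10_ld50", "log10_body_length", "chela_ratio", "telson_ratio"):
            if not self.data[col].map(math.isfinite).all():
                raise ValidationError(f"non-finite values in column {col!r}")
        if (self.data[["chela_ratio", "telson_ratio"]] <= 0).any().any():
            raise ValidationError("morphology ratios must be positive")

    @property
    def n_measures(self) -> int:
        return len(self.data)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def species_index(self) -> list[int]:
        """Row -> species position in ``species_names``."""
        pos = {s: i for i, s in enumerate(self.species_names)}
        return [pos[s] for s in self.data["species"]]

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def convert_ld50_units(
    value: float, units: str, subject_mass_kg: Optional[float] = None
) -> float:
    """Convert an LD50 dose to mg of dried venom per kg of test subject.

    Recognized tokens: mg/kg, ug/g, mg/g, ug/kg (per mass) and ug/animal,
    mg/animal (per animal, requiring ``subject_mass_kg``). Unknown tokens
    raise :class:`UnitError` rather than guessing — published units are
    chaotic and a silent misparse is worse than a failure.
    """
    if not (value > 0) or not math.isfinite(value):
        raise ValidationError(f"LD50 value must be positive and finite, got {value!r}")
    token = normalize_unit_token(units)
    if token in _PER_MASS_FACTORS:
        return value * _PER_MASS_FACTORS[token]
    if token in _PER_ANIMAL_FACTORS:
        if subject_mass_kg is None:
            raise MissingMassError(
                f"unit {units!r} is a per-animal dose; subject body mass is required"
            )
        if not (subject_mass_kg > 0):
            raise ValidationError(f"subject mass must be positive, got {subject_mass_kg!r}")
        return value * _PER_ANIMAL_FACTORS[token] / subject_mass_kg
    raise UnitError(
        f"unrecognized LD50 unit {units!r}; known units: "
        f"{sorted(_PER_MASS_FACTORS | _PER_ANIMAL_FACTORS)}"
    )


def apply_inclusion_criteria(
    records: Sequence[PotencyRecord], test_model: str = "Mus musculus"
) -> list[PotencyRecord]:
    """Filter potency records to those usable in the comparative analysis.

    Keeps records with dried venom, a dose convertible to mg/kg, and the
    configured test-model organism (default the house mouse, the standard
    mammalian LD50 model). Exclusions are logged with per-record reasons so
    the curation is auditable. Idempotent: filtering a filtered list is a
    no-op.
    """
    wanted_model = normalize_species_name(test_model)
    kept: list[PotencyRecord] = []
    for rec in records:
        reason = _exclusion_reason(rec, wanted_model)
        if reason is None:
            kept.append(rec)
        else:
            logger.info(
                "excluding LD50 record (%s, source=%s): %s",
                rec.species_name,
                rec.source_id or "?",
                reason,
            )
    return kept


def _exclusion_reason(rec: PotencyRecord, wanted_model: str) -> Optional[str]:
    if rec.venom_state.strip().lower() != "dried":
        return f"venom state {rec.venom_state!r} is not dried"
    token = normalize_unit_token(rec.ld50_units)
    if token not in _PER_MASS_FACTORS and token not in _PER_ANIMAL_FACTORS:
        return f"unrecognized unit {rec.ld50_units!r}"
    if token in _PER_ANIMAL_FACTORS and rec.subject_mass_kg is None:
        return "per-animal dose without subject body mass"
    if normalize_species_name(rec.test_model) != wanted_model:
        return f"test model {rec.test_model!r} is not the configured model"
    return None


def normalize_potency_records(records: Sequence[PotencyRecord]) -> list[PotencyRecord]:
    """Return records with ``ld50_value`` converted to mg/kg and units relabeled."""
    out = []
    for rec in records:
        mgkg = convert_ld50_units(rec.ld50_value, rec.ld50_units, rec.subject_mass_kg)
        out.append(replace(rec, ld50_value=mgkg, ld50_units="mg/kg"))
    return out


def compute_morphology_ratios(m: MorphologyRecord) -> tuple[float, float]:
    """Return (chela_ratio, telson_ratio) = length/width for each structure.

    High chela ratio = long slender pincers; low = short robust pincers.
    """
    return m.chela_length_mm / m.chela_width_mm, m.telson_length_mm / m.telson_width_mm


def resolve_morphology_proxy(
    records: Sequence[MorphologyRecord],
    proxy_table: Mapping[str, str],
    required_species: Optional[Iterable[str]] = None,
) -> list[MorphologyRecord]:
    """Fill morphology gaps by copying measurements from donor species.

    ``proxy_table`` maps a species lacking morphology to a donor species
    present in ``records`` (e.g. *Centruroides limpidus* borrowing from the
    morphologically indistinguishable *C. ruana*). The copied record has
    ``proxy_for`` set to the donor so provenance survives. If
    ``required_species`` is given, species with neither data nor proxy are
    reported with a warning (they will be dropped downstream).
    """
    by_name: dict[str, MorphologyRecord] = {}
    out = list(records)
    for rec in records:
        by_name.setdefault(normalize_species_name(rec.species_name), rec)
    for target, donor in proxy_table.items():
        t_norm = normalize_species_name(target)
        if t_norm in by_name:
            logger.info("species %r has its own morphology; proxy ignored", target)
            continue
        d_norm = normalize_species_name(donor)
        if d_norm not in by_name:
            raise ConfigurationError(
                f"proxy donor {donor!r} (for {target!r}) has no morphology record"
            )
        donor_rec = by_name[d_norm]
        proxied = replace(donor_rec, species_name=target, proxy_for=donor_rec.species_name)
        out.append(proxied)
        by_name[t_norm] = proxied
    if required_species is not None:
        for sp in required_species:
            if normalize_species_name(sp) not in by_name:
                logger.warning(
                    "species %r has no morphology record and no proxy; it will be dropped",
                    sp,
                )
    return out


def _species_morphology(records: Sequence[MorphologyRecord]) -> dict[str, tuple[float, float, float]]:
    """Collapse morphology to one (total_length, chela_ratio, telson_ratio)
    per normalized species name.

    Species with multiple records get the arithmetic mean of each raw
    measurement before the ratios are formed (mean lengths / mean widths).
    """
    groups: dict[str, list[MorphologyRecord]] = {}
    for rec in records:
        groups.setdefault(normalize_species_name(rec.species_name), []).append(rec)
    out = {}
    for norm, recs in groups.items():
        n = len(recs)
        mean = lambda f: sum(getattr(r, f) for r in recs) / n  # noqa: E731
        averaged = MorphologyRecord(
            species_name=recs[0].species_name,
            total_length_mm=mean("total_length_mm"),
            chela_length_mm=mean("chela_length_mm"),
            chela_width_mm=mean("chela_width_mm"),
            telson_length_mm=mean("telson_length_mm"),
            telson_width_mm=mean("telson_width_mm"),
        )
        chela, telson = compute_morphology_ratios(averaged)
        out[norm] = (averaged.total_length_mm, chela, telson)
    return out


def build_analysis_table(
    potency: Sequence[PotencyRecord], morphology: Sequence[MorphologyRecord]
) -> AnalysisTable:
    """Assemble the measure-level analysis table.

    Expects ``potency`` already filtered (:func:`apply_inclusion_criteria`)
    and unit-normalized (:func:`normalize_potency_records`), and
    ``morphology`` after proxy resolution. LD50 (mg/kg) and total length
    (mm) are log10-transformed; species are matched by normalized name.
    Potency species with no morphology are reported in one aggregate error.
    """
    if not potency:
        raise ValidationError("no potency records to tabulate")
    morph = _species_morphology(morphology)
    missing = sorted(
        {
            rec.species_name
            for rec in potency
            if normalize_species_name(rec.species_name) not in morph
        }
    )
    if missing:
        raise ValidationError(
            f"{len(missing)} potency species lack morphology: {missing}"
        )
    display: dict[str, str] = {}
    rows = []
    for rec in potency:
        norm = normalize_species_name(rec.species_name)
        display.setdefault(norm, rec.species_name)
        mgkg = convert_ld50_units(rec.ld50_value, rec.ld50_units, rec.subject_mass_kg)
        total_len, chela, telson = morph[norm]
        rows.append(
            {
                "species": display[norm],
                "log10_ld50": math.log10(mgkg),
                "log10_body_length": math.log10(total_len),
                "chela_ratio": chela,
                "telson_ratio": telson,
                "route": rec.route,
            }
        )
    return AnalysisTable(data=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Delimited-text interfaces

_POTENCY_COLUMNS = [
    "species",
    "ld50",
    "units",
    "subject_mass_kg",
    "route",
    "venom_state",
    "test_model",
    "source",
]

_MORPHOLOGY_COLUMNS = [
    "species",
    "total_length_mm",
    "chela_length_mm",
    "chela_width_mm",
    "telson_length_mm",
    "telson_width_mm",
    "source",
]


def read_potency_csv(path: str | Path) -> list[PotencyRecord]:
    """Read potency records from a UTF-8, comma-delimited, headered CSV."""
    df = pd.read_csv(path, dtype={"species": str}, float_precision="round_trip")
    missing = set(_POTENCY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"potency CSV {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        mass = getattr(row, "subject_mass_kg")
        mass = None if pd.isna(mass) else float(mass)
        records.append(
            PotencyRecord(
                species_name=row.species,
                ld50_value=float(row.ld50),
                ld50_units=str(row.units),
                subject_mass_kg=mass,
                route=str(row.route).strip().upper(),
                venom_state=str(row.venom_state),
                test_model=str(row.test_model),
                source_id=str(row.source),
            )
        )
    return records


def read_morphology_csv(path: str | Path) -> list[MorphologyRecord]:
    df = pd.read_csv(path, dtype={"species": str}, float_precision="round_trip")
    missing = set(_MORPHOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"morphology CSV {path} missing columns: {sorted(missing)}")
    return [
        MorphologyRecord(
            species_name=row.species,
            total_length_mm=float(row.total_length_mm),
            chela_length_mm=float(row.chela_length_mm),
            chela_width_mm=float(row.chela_width_mm),
            telson_length_mm=float(row.telson_length_mm),
            telson_width_mm=float(row.telson_width_mm),
            source_id=str(row.source),
        )
        for row in df.itertuples(index=False)
    ]


def write_potency_csv(records: Sequence[PotencyRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_POTENCY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.species_name,
                    repr(r.ld50_value),
                    r.ld50_units,
                    "" if r.subject_mass_kg is None else repr(r.subject_mass_kg),
                    r.route,
                    r.venom_state,
                    r.test_model,
                    r.source_id,
                ]
            )


def write_morphology_csv(records: Sequence[MorphologyRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MORPHOLOGY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.species_name,
                    repr(r.total_length_mm),
                    repr(r.chela_length_mm),
                    repr(r.chela_width_mm),
                    repr(r.telson_length_mm),
                    repr(r.telson_width_mm),
                    r.source_id,
                ]
            )


def curate(
    potency: Sequence[PotencyRecord],
    morphology: Sequence[MorphologyRecord],
    proxy_table: Optional[Mapping[str, str]] = None,
    test_model: str = "Mus musculus",
) -> AnalysisTable:
    """Full curation pipeline: filter, normalize units, resolve proxies, tabulate."""
    kept = apply_inclusion_criteria(potency, test_model=test_model)
    if not kept:
        raise ValidationError("no potency records survive the inclusion criteria")
    kept = normalize_potency_records(kept)
    needed = [r.species_name for r in kept]
    morph = resolve_morphology_proxy(morphology, proxy_table or {}, required_species=needed)
    have = {normalize_species_name(m.species_name) for m in morph}
    kept = [r for r in kept if normalize_species_name(r.species_name) in have]
    if not kept:
        raise ValidationError("no potency species has morphology after proxy resolution")
    return build_analysis_table(kept, morph)
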