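"""Reference library of Madeira-wine volatiles and the study's sensory data.

The packaged compound library transcribes the published identification table
for 82 volatile organic compounds (VOCs) found in Madeira wines: retention
time and Kovats index on a polyethylene-glycol column, the literature Kovats
index where one exists, identification evidence (mass spectrum, retention
index, authentic standard), odor threshold (OT, µg/L, determined in 10–12%
v/v ethanol), free-text odor descriptors, the subset of descriptors flagged
as Madeira aroma notes, and whether the compound was detected in every wine
of the study.  The sensory table records the aroma notes a trained panel
attributed to each grape variety for young (3–5 y) and old (10–20 y) wines.

Descriptor tokens are normalised through a small synonym map
(toasty→toast, flower→floral, ...).  The collective note "dried fruits" is
modelled as a configurable group expanding to
{almond, coconut, nutty, peanut, walnut}.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import io
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import LibraryParseError, ValidationError

__all__ = [
    "ChemicalFamily",
    "Variety",
    "AgeClass",
    "WineType",
    "CompoundRecord",
    "SensoryProfile",
    "SampleMeta",
    "Peak",
    "PeakTable",
    "DEFAULT_IS_CONC_UG_PER_L",
    "SYNONYMS",
    "NOTE_GROUPS",
    "normalize_token",
    "load_library",
    "write_library",
    "load_sensory",
    "default_sensory",
    "classify_wine_type",
    "age_class_of",
    "descriptor_vocabulary",
    "aroma_note_vocabulary",
    "library_checksum",
]

#: Internal standard (4-methyl-2-pentanol) spiking concentration, µg/L.
DEFAULT_IS_CONC_UG_PER_L = 250.0

#: sha256 of the packaged compound library, frozen when the transcription
#: was finalised; load_library verifies it for the packaged default.
PACKAGED_LIBRARY_SHA256 = (
    "b378a1e3886cad84d70d141d36321bcc2bb076776305a89789d70666257be767"
)


class ChemicalFamily(str, enum.Enum):
    TERPENIC = "terpenic"
    NORISOPRENOID = "norisoprenoid"
    HIGHER_ALCOHOL = "higher_alcohol"
    SULPHUR = "sulphur"
    ESTER = "ester"
    ACID = "acid"
    ACETAL = "acetal"
    FURANIC = "furanic"
    LACTONE = "lactone"
    VOLATILE_PHENOL = "volatile_phenol"


class Variety(str, enum.Enum):
    MALVASIA = "Malvasia"
    BUAL = "Bual"
    SERCIAL = "Sercial"
    VERDELHO = "Verdelho"
    TINTA_NEGRA = "Tinta Negra"


class AgeClass(str, enum.Enum):
    YOUNG = "young"  # 3-5 years
    OLD = "old"      # 10-20 years


class WineType(str, enum.Enum):
    DRY = "dry"
    MEDIUM_DRY = "medium_dry"
    MEDIUM_SWEET = "medium_sweet"
    SWEET = "sweet"


#: Descriptor synonym map applied by :func:`normalize_token`.
SYNONYMS = {
    "toasty": "toast",
    "flower": "floral",
    "fruity": "fruit",
    "woody": "wood",
    "spicy": "spice",
}

#: Collective-note groups: a group token expands to its member descriptors.
NOTE_GROUPS = {
    "dried fruits": frozenset({"almond", "coconut", "nutty", "peanut", "walnut"}),
}


def normalize_token(token: str, synonyms: dict[str, str] | None = None) -> str:
    """Lower-case, strip, and collapse a descriptor through the synonym map."""
    t = " ".join(token.strip().lower().split())
    syn = SYNONYMS if synonyms is None else synonyms
    return syn.get(t, t)


@dataclass(frozen=True)
class CompoundRecord:
    """One row of the reference library."""

    compound_id: str
    name: str
    family: ChemicalFamily
    rt_published_min: float
    ki_calc_published: float
    ki_lit: float | None
    id_evidence: frozenset[str]          # subset of {"MS", "RI", "Std"}
    odor_threshold_ug_per_L: float | None
    descriptors: tuple[str, ...]
    aroma_notes: frozenset[str]
    common_to_all: bool

    def __post_init__(self):
        if self.ki_calc_published <= 0:
            raise ValidationError(
                f"{self.compound_id}: ki_calc must be positive"
            )
        if not self.id_evidence <= {"MS", "RI", "Std"}:
            raise ValidationError(
                f"{self.compound_id}: evidence must be a subset of MS/RI/Std"
            )
        if not self.aroma_notes <= set(self.descriptors):
            raise ValidationError(
                f"{self.compound_id}: aroma_notes must be a subset of descriptors"
            )
        if self.odor_threshold_ug_per_L is not None and self.odor_threshold_ug_per_L <= 0:
            raise ValidationError(
                f"{self.compound_id}: odor threshold must be positive when present"
            )

    @property
    def delta_ki(self) -> float | None:
        """|KIcalc − KIlit|, None when no literature index exists."""
        if self.ki_lit is None:
            return None
        return abs(self.ki_calc_published - self.ki_lit)


@dataclass(frozen=True)
class SensoryProfile:
    """Aroma notes attributed to one (variety, age class) by the panel."""

    variety: Variety
    age_class: AgeClass
    notes: tuple[str, ...]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one wine sample."""

    sample_id: str
    variety: Variety
    age_years: int
    wine_type: WineType
    sugar_g_per_L: float
    ethanol_pct: float

    def __post_init__(self):
        if not 3 <= self.age_years <= 20:
            raise ValidationError(
                f"{self.sample_id}: age_years must be in [3, 20], got {self.age_years}"
            )
        declared = classify_wine_type(self.sugar_g_per_L)
        if declared is not None and declared != self.wine_type:
            raise ValidationError(
                f"{self.sample_id}: sugar {self.sugar_g_per_L} g/L implies "
                f"{declared.value}, not {self.wine_type.value}"
            )

    @property
    def age_class(self) -> AgeClass:
        return age_class_of(self.age_years)


@dataclass(frozen=True)
class Peak:
    """One detected chromatographic peak."""

    rt_min: float
    area: float
    candidate: str | None = None        # spectral-match candidate compound_id
    resemblance_pct: float | None = None

    def __post_init__(self):
        if self.area < 0:
            raise ValidationError(f"peak at {self.rt_min} min has negative area")
        if self.resemblance_pct is not None and not 0 <= self.resemblance_pct <= 100:
            raise ValidationError("resemblance_pct must be in [0, 100]")


@dataclass
class PeakTable:
    """One sample's peak list plus its internal-standard peak."""

    meta: SampleMeta
    peaks: list[Peak]
    is_peak: Peak
    is_conc_ug_per_L: float = DEFAULT_IS_CONC_UG_PER_L


# --------------------------------------------------------------------------
# wine-type classification (sugar g/L)

# Half-open [low, high) classes; the published ranges reuse their boundary
# values in adjacent classes, so the lower bound is inclusive and the top
# class is closed at 150.
_SUGAR_CLASSES = [
    (49.1, 64.8, WineType.DRY),
    (64.8, 80.4, WineType.MEDIUM_DRY),
    (80.4, 96.1, WineType.MEDIUM_SWEET),
    (96.1, 150.0, WineType.SWEET),
]


def classify_wine_type(sugar_g_per_L: float) -> WineType | None:
    """Map residual sugar to a wine type.

    Returns None for sugar outside [49.1, 150] g/L (out-of-range flag);
    raises :class:`ValidationError` for negative sugar.
    """
    if sugar_g_per_L < 0:
        raise ValidationError(f"sugar must be non-negative, got {sugar_g_per_L}")
    for low, high, wt in _SUGAR_CLASSES:
        if low <= sugar_g_per_L < high:
            return wt
    if sugar_g_per_L == 150.0:
        return WineType.SWEET
    return None


def age_class_of(age_years: int) -> AgeClass:
    """Young = 3–5 y, old = 10–20 y; ages in between are unclassifiable."""
    if 3 <= age_years <= 5:
        return AgeClass.YOUNG
    if 10 <= age_years <= 20:
        return AgeClass.OLD
    raise ValidationError(
        f"age {age_years} y is neither young (3-5) nor old (10-20)"
    )


# --------------------------------------------------------------------------
# library IO

_CSV_FIELDS = [
    "compound_id", "name", "family", "rt_min", "ki_calc", "ki_lit",
    "evidence", "ot_ug_per_L", "descriptors", "aroma_notes", "common_to_all",
]


def _packaged(name: str):
    return resources.files("aromaprofiler.data").joinpath(name)


def _parse_optional_float(raw: str, row: int, field_name: str) -> float | None:
    raw = raw.strip().replace(",", "")
    if raw in ("", "-"):
        return None
    try:
        return float(raw)
    except ValueError:
        raise LibraryParseError(
            f"cannot parse {raw!r} as a number", row=row, field=field_name
        ) from None


def _record_from_row(row: dict, rownum: int) -> CompoundRecord:
    missing = [f for f in _CSV_FIELDS if row.get(f) is None]
    if missing:
        raise LibraryParseError(f"missing columns {missing}", row=rownum)
    try:
        family = ChemicalFamily(row["family"].strip())
    except ValueError:
        raise LibraryParseError(
            f"unknown family {row['family']!r}", row=rownum, field="family"
        ) from None
    try:
        rt = float(row["rt_min"])
        ki_calc = float(row["ki_calc"])
    except ValueError as exc:
        raise LibraryParseError(str(exc), row=rownum, field="rt_min/ki_calc") from None
    descriptors = tuple(
        normalize_token(t) for t in row["descriptors"].split("|") if t.strip()
    )
    notes = frozenset(
        normalize_token(t) for t in row["aroma_notes"].split("|") if t.strip()
    )
    evidence = frozenset(t.strip() for t in row["evidence"].split("|") if t.strip())
    common = row["common_to_all"].strip().lower()
    if common not in ("true", "false"):
        raise LibraryParseError(
            f"common_to_all must be True/False, got {row['common_to_all']!r}",
            row=rownum, field="common_to_all",
        )
    try:
        return CompoundRecord(
            compound_id=row["compound_id"].strip(),
            name=row["name"].strip(),
            family=family,
            rt_published_min=rt,
            ki_calc_published=ki_calc,
            ki_lit=_parse_optional_float(row["ki_lit"], rownum, "ki_lit"),
            id_evidence=evidence,
            odor_threshold_ug_per_L=_parse_optional_float(
                row["ot_ug_per_L"], rownum, "ot_ug_per_L"
            ),
            descriptors=descriptors,
            aroma_notes=notes,
            common_to_all=(common == "true"),
        )
    except ValidationError as exc:
        raise LibraryParseError(str(exc), row=rownum) from None


def load_library(path_or_default: str | Path = "default") -> list[CompoundRecord]:
    """Load a compound library from CSV or JSON.

    ``"default"`` loads the packaged 82-compound transcription (checksum
    verified). Duplicate compound ids and schema violations raise
    :class:`LibraryParseError`.
    """
    if path_or_default == "default":
        text = _packaged("compounds.csv").read_text(encoding="utf-8")
        digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
        if PACKAGED_LIBRARY_SHA256 is not None and digest != PACKAGED_LIBRARY_SHA256:
            raise LibraryParseError(
                "packaged library checksum mismatch - fixture was modified"
            )
        return _load_library_text(text, fmt="csv")
    path = Path(path_or_default)
    text = path.read_text(encoding="utf-8")
    fmt = "json" if path.suffix.lower() == ".json" else "csv"
    return _load_library_text(text, fmt=fmt)


def _load_library_text(text: str, fmt: str) -> list[CompoundRecord]:
    if fmt == "json":
        try:
            rows = json.loads(text)
        except json.JSONDecodeError as exc:
            raise LibraryParseError(f"invalid JSON: {exc}") from None
        if not isinstance(rows, list):
            raise LibraryParseError("JSON library must be a list of objects")
        dict_rows = [{k: str(v) if v is not None else "" for k, v in r.items()}
                     for r in rows]
    else:
        reader = csv.DictReader(io.StringIO(text))
        if reader.fieldnames is None:
            raise LibraryParseError("empty library file")
        unknown = set(reader.fieldnames) - set(_CSV_FIELDS)
        if unknown or set(_CSV_FIELDS) - set(reader.fieldnames):
            raise LibraryParseError(
                f"header must be {_CSV_FIELDS}, got {reader.fieldnames}"
            )
        dict_rows = list(reader)
    if not dict_rows:
        raise LibraryParseError("library file contains no records")
    records = [_record_from_row(r, i + 1) for i, r in enumerate(dict_rows)]
    seen: set[str] = set()
    for i, rec in enumerate(records):
        if rec.compound_id in seen:
            raise LibraryParseError(
                f"duplicate compound_id {rec.compound_id!r}",
                row=i + 1, field="compound_id",
            )
        seen.add(rec.compound_id)
    return records


def write_library(records: list[CompoundRecord], path: str | Path) -> None:
    """Write records to CSV (or JSON when the path ends in .json)."""
    path = Path(path)

    def row_of(rec: CompoundRecord) -> dict:
        return {
            "compound_id": rec.compound_id,
            "name": rec.name,
            "family": rec.family.value,
            "rt_min": repr(rec.rt_published_min),
            "ki_calc": repr(rec.ki_calc_published),
            "ki_lit": "" if rec.ki_lit is None else repr(rec.ki_lit),
            "evidence": "|".join(sorted(rec.id_evidence)),
            "ot_ug_per_L": ""
            if rec.odor_threshold_ug_per_L is None
            else repr(rec.odor_threshold_ug_per_L),
            "descriptors": "|".join(rec.descriptors),
            "aroma_notes": "|".join(sorted(rec.aroma_notes)),
            "common_to_all": str(rec.common_to_all),
        }

    rows = [row_of(r) for r in records]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, ensure_ascii=False, indent=1),
                        encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        writer.writerows(rows)


def library_checksum(path_or_default: str | Path = "default") -> str:
    """sha256 hex digest of a library file's bytes."""
    if path_or_default == "default":
        text = _packaged("compounds.csv").read_text(encoding="utf-8")
    else:
        text = Path(path_or_default).read_text(encoding="utf-8")
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


# --------------------------------------------------------------------------
# sensory profiles

def load_sensory(path: str | Path) -> list[SensoryProfile]:
    """Read variety × age-class sensory notes from CSV (variety, age_class, notes)."""
    text = Path(path).read_text(encoding="utf-8")
    return _parse_sensory(text)


def default_sensory() -> list[SensoryProfile]:
    """The packaged panel table: 5 varieties × {young, old}."""
    text = _packaged("sensory.csv").read_text(encoding="utf-8")
    profiles = _parse_sensory(text)
    assert len(profiles) == 10
    return profiles


def _parse_sensory(text: str) -> list[SensoryProfile]:
    reader = csv.DictReader(io.StringIO(text))
    profiles = []
    for i, row in enumerate(reader):
        try:
            variety = Variety(row["variety"].strip())
            age_class = AgeClass(row["age_class"].strip())
        except (KeyError, ValueError) as exc:
            raise LibraryParseError(f"bad sensory row: {exc}", row=i + 1) from None
        notes = tuple(
            normalize_token(t) for t in row["notes"].split("|") if t.strip()
        )
        profiles.append(SensoryProfile(variety, age_class, notes))
    if not profiles:
        raise LibraryParseError("sensory file contains no profiles")
    return profiles


# --------------------------------------------------------------------------
# descriptor vocabulary

def descriptor_vocabulary(library: list[CompoundRecord]) -> set[str]:
    """Canonical descriptor tokens over the whole library (synonyms collapsed)."""
    vocab: set[str] = set()
    for rec in library:
        vocab.update(rec.descriptors)
    return vocab


def aroma_note_vocabulary(library: list[CompoundRecord]) -> set[str]:
    """Tokens flagged as Madeira aroma notes anywhere in the library."""
    notes: set[str] = set()
    for rec in library:
        notes.update(rec.aroma_notes)
    return notes
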