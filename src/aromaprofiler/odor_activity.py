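"""Odor-activity screening: which quantified volatiles can a nose perceive?

The odor activity value (OAV) of a compound is its relative concentration
divided by its odor threshold (OT, µg/L in 10–12% v/v ethanol).  A compound
is a *potential impact odorant* when its concentration strictly exceeds its
threshold (OAV > 1).  Compounds without a published OT get an undefined OAV
— never 0 or infinity — and can enter impact tables only on explicit
request.

``impact_table`` reconstructs a "note → wines → odorants" table: for each
aroma note the panel reported, it intersects the library compounds carrying
the note with the compounds that screened as impact odorants in the samples
of the varieties/age classes reporting the note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import UnknownCompoundError, UnknownNoteError
from .library import (
    NOTE_GROUPS,
    AgeClass,
    CompoundRecord,
    SampleMeta,
    SensoryProfile,
    Variety,
    normalize_token,
)
from .semiquant import Quantification

__all__ = [
    "OAVRecord",
    "ImpactTableRow",
    "compute_oav",
    "screen_impact_odorants",
    "impact_table",
]


@dataclass(frozen=True)
class OAVRecord:
    """Odor-activity screening result for one compound in one sample."""

    compound_id: str
    rel_conc_ug_per_L: float
    ot_ug_per_L: float | None
    oav: float | None          # None iff OT missing
    is_impact: bool | None     # None iff OT missing

    def __post_init__(self):
        if (self.oav is None) != (self.ot_ug_per_L is None):
            raise ValueError("oav must be present exactly when OT is present")


@dataclass(frozen=True)
class ImpactTableRow:
    """One aroma note with the wines reporting it and its candidate odorants."""

    note: str
    wines: tuple[Variety, ...]
    odorants: tuple[str, ...]
    unknown_ot_odorants: tuple[str, ...] = ()


def compute_oav(
    rel_conc_ug_per_L: float, ot_ug_per_L: float | None, compound_id: str = ""
) -> OAVRecord:
    """OAV = concentration / threshold; impact iff OAV strictly > 1.

    Equality at the threshold is *not* impact.  Missing OT yields an
    undefined-OAV record.
    """
    if ot_ug_per_L is None:
        return OAVRecord(compound_id, rel_conc_ug_per_L, None, None, None)
    if ot_ug_per_L <= 0:
        raise ValueError("odor threshold must be positive")
    oav = rel_conc_ug_per_L / ot_ug_per_L
    return OAVRecord(compound_id, rel_conc_ug_per_L, ot_ug_per_L, oav, oav > 1.0)


def screen_impact_odorants(
    quant: Quantification, library: list[CompoundRecord]
) -> list[OAVRecord]:
    """One OAV record per quantified compound, descending OAV, no-OT last."""
    by_id = {rec.compound_id: rec for rec in library}
    records = []
    for cid, conc in quant.entries.items():
        rec = by_id.get(cid)
        if rec is None:
            raise UnknownCompoundError(
                f"sample {quant.sample_id}: compound {cid!r} not in library"
            )
        records.append(compute_oav(conc, rec.odor_threshold_ug_per_L, cid))
    records.sort(
        key=lambda r: (r.oav is None, -(r.oav if r.oav is not None else math.nan)
                       if r.oav is not None else 0.0, r.compound_id)
    )
    return records


def _note_members(note: str, note_groups: dict[str, frozenset[str]]) -> set[str]:
    """Expand a (possibly collective) note into concrete descriptor tokens."""
    if note in note_groups:
        return set(note_groups[note])
    return {note}


def impact_table(
    screens_by_sample: dict[str, list[OAVRecord]],
    metas: list[SampleMeta],
    library: list[CompoundRecord],
    sensory: list[SensoryProfile],
    *,
    notes: list[str] | None = None,
    include_unknown_ot: bool = False,
    note_groups: dict[str, frozenset[str]] | None = None,
    merge_varieties: bool = True,
) -> list[ImpactTableRow]:
    """Reconstruct the potential-impact-odorant table, note by note.

    For each aroma note appearing in the sensory profiles (or the explicit
    ``notes`` list), the row lists the varieties whose profile contains the
    note and the library compounds that (a) carry the note among their
    flagged aroma notes and (b) screened as impact odorants in at least one
    sample of a reporting (variety, age class).  Compounds lacking an OT are
    reported separately and only when ``include_unknown_ot`` is set.

    With ``merge_varieties`` (default) evidence is pooled over all
    reporting varieties, the published table's convention; pass False to
    require the compound to be impact-flagged in every reporting variety.
    """
    groups = NOTE_GROUPS if note_groups is None else note_groups
    meta_of = {m.sample_id: m for m in metas}
    all_notes: set[str] = set()
    for profile in sensory:
        all_notes.update(profile.notes)
    if notes is None:
        wanted = sorted(all_notes)
    else:
        wanted = [normalize_token(n) for n in notes]
        for note in wanted:
            if note not in all_notes:
                raise UnknownNoteError(note, all_notes)

    # variety/age classes reporting each note
    reporters: dict[str, list[SensoryProfile]] = {}
    for profile in sensory:
        for note in profile.notes:
            reporters.setdefault(note, []).append(profile)

    # impact flags per (variety, age_class)
    impact_in: dict[tuple[Variety, AgeClass], set[str]] = {}
    for sample_id, screen in screens_by_sample.items():
        meta = meta_of.get(sample_id)
        if meta is None:
            raise UnknownCompoundError(f"no metadata for sample {sample_id!r}")
        key = (meta.variety, meta.age_class)
        bucket = impact_in.setdefault(key, set())
        bucket.update(r.compound_id for r in screen if r.is_impact)

    rows = []
    for note in wanted:
        profiles = reporters.get(note, [])
        if not profiles:
            continue
        members = _note_members(note, groups)
        carriers = [
            rec for rec in library if rec.aroma_notes & members
        ]
        per_variety: dict[Variety, set[str]] = {}
        for profile in profiles:
            flagged = impact_in.get((profile.variety, profile.age_class), set())
            per_variety.setdefault(profile.variety, set()).update(flagged)
        varieties = tuple(
            v for v in Variety if v in per_variety
        )
        if merge_varieties:
            pooled: set[str] = set()
            for flagged in per_variety.values():
                pooled.update(flagged)
            qualifier = lambda cid: cid in pooled  # noqa: E731
        else:
            qualifier = lambda cid: all(  # noqa: E731
                cid in flagged for flagged in per_variety.values()
            )
        odorants = tuple(
            rec.compound_id
            for rec in carriers
            if rec.odor_threshold_ug_per_L is not None and qualifier(rec.compound_id)
        )
        unknown = ()
        if include_unknown_ot:
            unknown = tuple(
                rec.compound_id
                for rec in carriers
                if rec.odor_threshold_ug_per_L is None
            )
        rows.append(
            ImpactTableRow(
                note=note,
                wines=varieties,
                odorants=odorants,
                unknown_ot_odorants=unknown,
            )
        )
    return rows
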