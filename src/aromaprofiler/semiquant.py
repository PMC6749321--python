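"""Internal-standard semi-quantification and family-level aggregation.

Concentrations are *relative*: each accepted peak's area is scaled by the
internal-standard peak (4-methyl-2-pentanol, spiked at a known µg/L)::

    rel_conc = (peak area / IS area) * IS concentration

No calibration curves or matrix-effect corrections are applied — the number
is proportional to the true concentration only insofar as response factors
are comparable, which is the standard semi-quantification caveat.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .errors import MissingInternalStandardError, UnknownCompoundError, ValidationError
from .kovats import IdentifiedVOC
from .library import AgeClass, ChemicalFamily, CompoundRecord, PeakTable, SampleMeta

__all__ = [
    "Quantification",
    "FamilyAggregate",
    "Trend",
    "semi_quantify",
    "replicate_rsd",
    "aggregate_families",
    "TREND_FLAT_BAND",
]

#: Relative old-vs-young change below which a family trend is called flat.
TREND_FLAT_BAND = 0.10


@dataclass(frozen=True)
class Quantification:
    """Relative concentrations (µg/L) for one sample."""

    sample_id: str
    entries: dict[str, float]  # compound_id -> rel conc, µg/L
    is_conc_ug_per_L: float


Trend = str  # "increase" | "decrease" | "flat" | "undefined"


@dataclass(frozen=True)
class FamilyAggregate:
    """Total relative concentration of one chemical family in one age class."""

    family: ChemicalFamily
    age_class: AgeClass
    total_rel_conc_ug_per_L: float
    n_samples: int
    trend: Trend  # old vs young; "undefined" when young class absent


def semi_quantify(
    peaks: PeakTable, identified: list[IdentifiedVOC]
) -> Quantification:
    """Convert accepted identifications into relative concentrations.

    Linear through the origin in peak area; compounds absent from the
    accepted identifications are absent from the result.
    """
    if peaks.is_peak is None or peaks.is_peak.area <= 0:
        raise MissingInternalStandardError(
            f"sample {peaks.meta.sample_id}: internal-standard area must be positive"
        )
    is_area = peaks.is_peak.area
    entries: dict[str, float] = {}
    for ident in identified:
        if not ident.accepted:
            continue
        entries[ident.compound_id] = (
            ident.area / is_area * peaks.is_conc_ug_per_L
        )
    return Quantification(
        sample_id=peaks.meta.sample_id,
        entries=entries,
        is_conc_ug_per_L=peaks.is_conc_ug_per_L,
    )


def replicate_rsd(quants: list[Quantification]) -> dict[str, float | None]:
    """Percent relative standard deviation per compound across replicates.

    RSD = 100 * sd / mean with the sample (n−1) standard deviation.
    Compounds whose replicate mean is zero map to None (undefined).
    A compound missing from a replicate contributes 0 µg/L for it.
    """
    if len(quants) < 2:
        raise ValidationError("replicate_rsd needs at least two replicates")
    compounds = sorted({c for q in quants for c in q.entries})
    out: dict[str, float | None] = {}
    for cid in compounds:
        values = [q.entries.get(cid, 0.0) for q in quants]
        mean = statistics.fmean(values)
        if mean == 0:
            out[cid] = None
            continue
        out[cid] = 100.0 * statistics.stdev(values) / mean
    return out


def aggregate_families(
    quants: list[Quantification],
    metas: list[SampleMeta],
    library: list[CompoundRecord],
) -> list[FamilyAggregate]:
    """Family totals per age class and their aging trends.

    The total for (family, age class) is the sum over member compounds of
    the compound's mean relative concentration across that class's samples
    (replicates included in the mean).  The trend flag compares old against
    young totals: a relative change beyond ±10% is an increase/decrease,
    else flat; undefined when the young class is absent.
    """
    by_id = {rec.compound_id: rec for rec in library}
    meta_of = {m.sample_id: m for m in metas}
    for q in quants:
        if q.sample_id not in meta_of:
            raise ValidationError(f"no metadata for sample {q.sample_id!r}")
        for cid in q.entries:
            if cid not in by_id:
                raise UnknownCompoundError(
                    f"sample {q.sample_id}: compound {cid!r} not in library"
                )

    # compound -> age class -> replicate values
    values: dict[str, dict[AgeClass, list[float]]] = {}
    n_samples: dict[AgeClass, set[str]] = {}
    for q in quants:
        age_class = meta_of[q.sample_id].age_class
        n_samples.setdefault(age_class, set()).add(q.sample_id)
        for cid, conc in q.entries.items():
            values.setdefault(cid, {}).setdefault(age_class, []).append(conc)

    totals: dict[tuple[ChemicalFamily, AgeClass], float] = {}
    for cid, per_class in values.items():
        family = by_id[cid].family
        for age_class, vals in per_class.items():
            key = (family, age_class)
            totals[key] = totals.get(key, 0.0) + statistics.fmean(vals)

    aggregates = []
    for (family, age_class), total in sorted(
        totals.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        if age_class is AgeClass.OLD:
            young = totals.get((family, AgeClass.YOUNG))
            if young is None or young == 0:
                trend = "undefined"
            else:
                change = (total - young) / young
                if change > TREND_FLAT_BAND:
                    trend = "increase"
                elif change < -TREND_FLAT_BAND:
                    trend = "decrease"
                else:
                    trend = "flat"
        else:
            trend = "undefined"
        aggregates.append(
            FamilyAggregate(
                family=family,
                age_class=age_class,
                total_rel_conc_ug_per_L=total,
                n_samples=len(n_samples[age_class]),
                trend=trend,
            )
        )
    return aggregates
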