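"""Readers and writers for the pipeline's file formats.

All formats are plain text: peak tables are CSV with a YAML metadata
sidecar, ladders and result tables are CSV, run summaries are JSON.
Floats are serialised with ``repr`` so that a write → read round trip is
bit-exact.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import yaml

from .errors import LibraryParseError
from .kovats import AlkaneLadder, IdentifiedVOC
from .library import (
    Peak,
    PeakTable,
    SampleMeta,
    Variety,
    WineType,
)
from .odor_activity import ImpactTableRow, OAVRecord
from .semiquant import FamilyAggregate, Quantification

__all__ = [
    "write_peak_table", "read_peak_table",
    "write_ladder", "read_ladder",
    "write_identified", "read_identified",
    "write_quantification", "read_quantification",
    "write_oav", "write_impact_table", "write_aggregates",
    "write_truth",
]


def _opt(value):
    return "" if value is None else repr(value) if isinstance(value, float) else str(value)


def _opt_float(raw: str) -> float | None:
    raw = raw.strip()
    return None if raw == "" else float(raw)


# -------------------------------------------------------------- peak tables

def write_peak_table(table: PeakTable, directory: str | Path) -> tuple[Path, Path]:
    """Write ``<sample>.peaks.csv`` and ``<sample>.meta.yaml``; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = table.meta.sample_id
    peaks_path = directory / f"{sid}.peaks.csv"
    meta_path = directory / f"{sid}.meta.yaml"
    with peaks_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "rt_min", "area", "candidate", "resemblance_pct"])
        for p in table.peaks:
            writer.writerow(
                [sid, repr(p.rt_min), repr(p.area), p.candidate or "",
                 _opt(p.resemblance_pct)]
            )
    meta = {
        "sample_id": sid,
        "variety": table.meta.variety.value,
        "age_years": table.meta.age_years,
        "wine_type": table.meta.wine_type.value,
        "sugar_g_per_L": table.meta.sugar_g_per_L,
        "ethanol_pct": table.meta.ethanol_pct,
        "internal_standard": {
            "rt_min": table.is_peak.rt_min,
            "area": table.is_peak.area,
            "conc_ug_per_L": table.is_conc_ug_per_L,
        },
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False), encoding="utf-8")
    return peaks_path, meta_path


def read_peak_table(peaks_path: str | Path, meta_path: str | Path | None = None) -> PeakTable:
    """Read a peak table; the sidecar defaults to ``<sample>.meta.yaml``."""
    peaks_path = Path(peaks_path)
    if meta_path is None:
        stem = peaks_path.name
        if stem.endswith(".peaks.csv"):
            stem = stem[: -len(".peaks.csv")]
        else:
            stem = peaks_path.stem
        meta_path = peaks_path.parent / f"{stem}.meta.yaml"
    meta_path = Path(meta_path)
    if not meta_path.exists():
        raise LibraryParseError(f"metadata sidecar {meta_path} not found")
    raw = yaml.safe_load(meta_path.read_text(encoding="utf-8"))
    try:
        meta = SampleMeta(
            sample_id=raw["sample_id"],
            variety=Variety(raw["variety"]),
            age_years=int(raw["age_years"]),
            wine_type=WineType(raw["wine_type"]),
            sugar_g_per_L=float(raw["sugar_g_per_L"]),
            ethanol_pct=float(raw["ethanol_pct"]),
        )
        is_raw = raw["internal_standard"]
        is_peak = Peak(rt_min=float(is_raw["rt_min"]), area=float(is_raw["area"]))
        is_conc = float(is_raw["conc_ug_per_L"])
    except (KeyError, ValueError) as exc:
        raise LibraryParseError(f"bad metadata in {meta_path}: {exc}") from None
    peaks = []
    with peaks_path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            peaks.append(
                Peak(
                    rt_min=float(row["rt_min"]),
                    area=float(row["area"]),
                    candidate=row["candidate"] or None,
                    resemblance_pct=_opt_float(row["resemblance_pct"]),
                )
            )
    return PeakTable(meta=meta, peaks=peaks, is_peak=is_peak, is_conc_ug_per_L=is_conc)


def read_peak_tables(directory: str | Path) -> list[PeakTable]:
    """All peak tables in a directory, sorted by sample id."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.peaks.csv"))
    if not paths:
        raise LibraryParseError(f"no *.peaks.csv files in {directory}")
    return [read_peak_table(p) for p in paths]


# -------------------------------------------------------------- ladders

def write_ladder(ladder: AlkaneLadder, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["carbon_number", "rt_min"])
        for carbon, rt in ladder.anchors:
            writer.writerow([carbon, repr(rt)])


def read_ladder(path: str | Path) -> AlkaneLadder:
    anchors = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            anchors.append((int(row["carbon_number"]), float(row["rt_min"])))
    return AlkaneLadder(anchors=tuple(anchors))


# -------------------------------------------------------------- results

def write_identified(
    rows: dict[str, list[IdentifiedVOC]], path: str | Path
) -> None:
    """Identification results for one or more samples, one CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "compound_id", "rt_min", "area", "ki_calc",
             "delta_ki", "resemblance_pct", "evidence", "accepted",
             "rejection_reason"]
        )
        for sid in sorted(rows):
            for r in rows[sid]:
                writer.writerow(
                    [sid, r.compound_id or "", repr(r.rt_min), repr(r.area),
                     repr(r.ki_calc), _opt(r.delta_ki), _opt(r.resemblance_pct),
                     "|".join(sorted(r.evidence_tier)), r.accepted,
                     r.rejection_reason or ""]
                )


def read_identified(path: str | Path) -> dict[str, list[IdentifiedVOC]]:
    out: dict[str, list[IdentifiedVOC]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["sample_id"], []).append(
                IdentifiedVOC(
                    compound_id=row["compound_id"] or None,
                    rt_min=float(row["rt_min"]),
                    area=float(row["area"]),
                    ki_calc=float(row["ki_calc"]),
                    delta_ki=_opt_float(row["delta_ki"]),
                    resemblance_pct=_opt_float(row["resemblance_pct"]),
                    evidence_tier=frozenset(
                        t for t in row["evidence"].split("|") if t
                    ),
                    accepted=row["accepted"] == "True",
                    rejection_reason=row["rejection_reason"] or None,
                )
            )
    return out


def write_quantification(quants: list[Quantification], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "compound_id", "rel_conc_ug_per_L",
                         "is_conc_ug_per_L"])
        for q in quants:
            for cid in sorted(q.entries):
                writer.writerow([q.sample_id, cid, repr(q.entries[cid]),
                                 repr(q.is_conc_ug_per_L)])


def read_quantification(path: str | Path) -> list[Quantification]:
    grouped: dict[str, dict[str, float]] = {}
    is_conc: dict[str, float] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            sid = row["sample_id"]
            grouped.setdefault(sid, {})[row["compound_id"]] = float(
                row["rel_conc_ug_per_L"]
            )
            is_conc[sid] = float(row["is_conc_ug_per_L"])
    return [
        Quantification(sample_id=sid, entries=entries, is_conc_ug_per_L=is_conc[sid])
        for sid, entries in sorted(grouped.items())
    ]


def write_oav(screens: dict[str, list[OAVRecord]], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "compound_id", "rel_conc_ug_per_L",
                         "ot_ug_per_L", "oav", "is_impact"])
        for sid in sorted(screens):
            for r in screens[sid]:
                writer.writerow(
                    [sid, r.compound_id, repr(r.rel_conc_ug_per_L),
                     _opt(r.ot_ug_per_L), _opt(r.oav),
                     "" if r.is_impact is None else r.is_impact]
                )


def write_impact_table(rows: list[ImpactTableRow], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note", "wines", "odorants", "unknown_ot_odorants"])
        for r in rows:
            writer.writerow(
                [r.note, "|".join(v.value for v in r.wines),
                 "|".join(r.odorants), "|".join(r.unknown_ot_odorants)]
            )


def write_aggregates(aggregates: list[FamilyAggregate], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["family", "age_class", "total_rel_conc_ug_per_L",
                         "n_samples", "trend"])
        for a in aggregates:
            writer.writerow([a.family.value, a.age_class.value,
                             repr(a.total_rel_conc_ug_per_L), a.n_samples,
                             a.trend])


def write_truth(truth, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "compound_id", "true_conc_ug_per_L",
                         "aging_sign"])
        for (sid, cid), conc in sorted(truth.concentrations.items()):
            writer.writerow([sid, cid, repr(conc), truth.aging_sign[cid]])


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
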