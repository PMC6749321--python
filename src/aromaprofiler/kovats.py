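"""Kovats retention-index computation and peak identification.

For a temperature-programmed GC run the Kovats index of a peak eluting at
retention time ``rt`` between the n-alkane anchors C_n and C_{n+1} is the
van den Dool–Kratz linear interpolation::

    KI = 100*n + 100 * (rt - rt_n) / (rt_{n+1} - rt_n)

Identification combines two lines of evidence, mirroring routine GC–qMS
practice on polyethylene-glycol columns:

* spectral resemblance — when a peak carries a library-search candidate, the
  match percentage must reach ``min_resemblance_pct`` (default 80);
* retention-index agreement — when the candidate has a literature index,
  |KIcalc − KIlit| must be within an absolute window (default 35 Kovats
  units) and within a relative window (default 5% of KIlit).

Peaks with no spectral candidate may still be identified from the retention
index alone; such hits are a lower evidence tier (RI without MS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    LadderError,
    LadderRangeError,
    MissingInternalStandardError,
)
from .library import CompoundRecord, PeakTable

__all__ = [
    "AlkaneLadder",
    "IdentifiedVOC",
    "compute_ki",
    "rt_for_ki",
    "match_compound",
    "identify_peaks",
    "ki_deviation_report",
    "DEFAULT_ABS_TOL",
    "DEFAULT_REL_TOL_PCT",
    "DEFAULT_MIN_RESEMBLANCE_PCT",
]

DEFAULT_ABS_TOL = 35.0
DEFAULT_REL_TOL_PCT = 5.0
DEFAULT_MIN_RESEMBLANCE_PCT = 80.0


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention-time anchors of a straight-chain alkane series.

    ``anchors`` maps carbon number (C8 ≡ KI 800) to retention time in
    minutes. Carbon numbers must be strictly increasing; gaps are allowed
    only when ``allow_gaps`` is set (interpolation then spans the gap).
    """

    anchors: tuple[tuple[int, float], ...]
    allow_gaps: bool = False

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise LadderError("ladder needs at least two anchors")
        carbons = [c for c, _ in self.anchors]
        rts = [rt for _, rt in self.anchors]
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise LadderError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise LadderError("anchor retention times must be strictly increasing")
        if not self.allow_gaps and any(
            b - a != 1 for a, b in zip(carbons, carbons[1:])
        ):
            raise LadderError(
                "carbon numbers must be contiguous (pass allow_gaps=True to accept)"
            )

    @property
    def carbons(self) -> np.ndarray:
        return np.array([c for c, _ in self.anchors])

    @property
    def rts(self) -> np.ndarray:
        return np.array([rt for _, rt in self.anchors])

    @property
    def span(self) -> tuple[float, float]:
        return self.anchors[0][1], self.anchors[-1][1]


@dataclass(frozen=True)
class IdentifiedVOC:
    """Outcome of identification for one peak."""

    compound_id: str | None
    rt_min: float
    area: float
    ki_calc: float
    delta_ki: float | None
    resemblance_pct: float | None
    evidence_tier: frozenset[str]
    accepted: bool
    rejection_reason: str | None = None


def compute_ki(
    ladder: AlkaneLadder, rt_min: float, *, extrapolate: bool = False
) -> float:
    """Kovats index of a retention time on an alkane ladder.

    Exactly 100*n at each anchor; piecewise linear, continuous and strictly
    increasing in between.  Outside the ladder span raises
    :class:`LadderRangeError` unless ``extrapolate`` is set, in which case
    the first/last segment's slope is continued.
    """
    lo, hi = ladder.span
    if not extrapolate and not lo <= rt_min <= hi:
        raise LadderRangeError(
            f"rt {rt_min} min outside ladder span [{lo}, {hi}] min"
        )
    rts = ladder.rts
    carbons = ladder.carbons
    # bracketing segment index (clipped for extrapolation)
    i = int(np.searchsorted(rts, rt_min, side="right")) - 1
    i = max(0, min(i, len(rts) - 2))
    n, rt_n = carbons[i], rts[i]
    n1, rt_n1 = carbons[i + 1], rts[i + 1]
    return float(
        100.0 * n + 100.0 * (n1 - n) * (rt_min - rt_n) / (rt_n1 - rt_n)
    )


def rt_for_ki(
    ladder: AlkaneLadder, ki: float, *, extrapolate: bool = False
) -> float:
    """Inverse of :func:`compute_ki` (exact within a segment)."""
    kis = 100.0 * ladder.carbons
    if not extrapolate and not kis[0] <= ki <= kis[-1]:
        raise LadderRangeError(
            f"KI {ki} outside ladder range [{kis[0]}, {kis[-1]}]"
        )
    rts = ladder.rts
    i = int(np.searchsorted(kis, ki, side="right")) - 1
    i = max(0, min(i, len(kis) - 2))
    frac = (ki - kis[i]) / (kis[i + 1] - kis[i])
    return float(rts[i] + frac * (rts[i + 1] - rts[i]))


def _ki_match_ok(
    ki_calc: float, ki_lit: float, abs_tol: float, rel_tol_pct: float
) -> bool:
    delta = abs(ki_calc - ki_lit)
    return delta <= abs_tol and 100.0 * delta / ki_lit <= rel_tol_pct


def match_compound(
    ki_calc: float,
    library: list[CompoundRecord],
    abs_tol: float = DEFAULT_ABS_TOL,
    rel_tol_pct: float = DEFAULT_REL_TOL_PCT,
) -> list[tuple[CompoundRecord, float]]:
    """Library records whose literature KI is compatible with ``ki_calc``.

    Returns (record, |ΔKI|) pairs sorted by ascending |ΔKI|, ties broken by
    compound_id. Records without a literature KI never match. An empty list
    is a valid result.
    """
    if abs_tol <= 0 or rel_tol_pct <= 0:
        raise ValueError("tolerances must be positive")
    hits = [
        (rec, abs(ki_calc - rec.ki_lit))
        for rec in library
        if rec.ki_lit is not None
        and _ki_match_ok(ki_calc, rec.ki_lit, abs_tol, rel_tol_pct)
    ]
    hits.sort(key=lambda h: (h[1], h[0].compound_id))
    return hits


def identify_peaks(
    peaks: PeakTable,
    ladder: AlkaneLadder,
    library: list[CompoundRecord],
    min_resemblance_pct: float = DEFAULT_MIN_RESEMBLANCE_PCT,
    abs_tol: float = DEFAULT_ABS_TOL,
    rel_tol_pct: float = DEFAULT_REL_TOL_PCT,
    *,
    extrapolate: bool = False,
) -> list[IdentifiedVOC]:
    """Identify the peaks of one sample against the reference library.

    Acceptance of a peak requires every applicable rule to pass:

    * a spectral candidate, when present, must reach the resemblance
      threshold (a failing candidate rejects the peak outright — it is a
      known non-match, not an unknown);
    * the (candidate's, or best-matching) literature KI must agree with the
      computed KI within the absolute and relative tolerances.

    Each library compound is assigned to at most one peak: the one with the
    smallest |ΔKI|, largest area on ties.  The returned list has one entry
    per input peak, in input order, with ``accepted`` flags; the internal
    standard peak must exist with positive area or a
    :class:`MissingInternalStandardError` is raised.
    """
    if peaks.is_peak is None or peaks.is_peak.area <= 0:
        raise MissingInternalStandardError(
            f"sample {peaks.meta.sample_id}: internal-standard peak missing "
            "or has non-positive area"
        )
    by_id = {rec.compound_id: rec for rec in library}

    # First pass: evaluate every peak independently.
    provisional: list[IdentifiedVOC] = []
    for peak in peaks.peaks:
        ki = compute_ki(ladder, peak.rt_min, extrapolate=extrapolate)
        record = None
        reason = None
        evidence: set[str] = set()
        if peak.candidate is not None:
            record = by_id.get(peak.candidate)
            if record is None:
                reason = f"candidate {peak.candidate!r} not in library"
            elif (
                peak.resemblance_pct is None
                or peak.resemblance_pct < min_resemblance_pct
            ):
                record, reason = None, (
                    f"resemblance {peak.resemblance_pct} below "
                    f"{min_resemblance_pct}%"
                )
            else:
                evidence.add("MS")
                if "Std" in record.id_evidence:
                    evidence.add("Std")
        else:
            hits = match_compound(ki, library, abs_tol, rel_tol_pct)
            if hits:
                record = hits[0][0]
            else:
                reason = "no library KI within tolerance"
        delta = None
        if record is not None:
            if record.ki_lit is not None:
                delta = abs(ki - record.ki_lit)
                if _ki_match_ok(ki, record.ki_lit, abs_tol, rel_tol_pct):
                    evidence.add("RI")
                else:
                    reason = (
                        f"|dKI| = {delta:.1f} vs {record.compound_id} "
                        f"outside tolerance"
                    )
                    record = None
        provisional.append(
            IdentifiedVOC(
                compound_id=record.compound_id if record else None,
                rt_min=peak.rt_min,
                area=peak.area,
                ki_calc=ki,
                delta_ki=delta,
                resemblance_pct=peak.resemblance_pct,
                evidence_tier=frozenset(evidence),
                accepted=record is not None,
                rejection_reason=reason,
            )
        )

    # Second pass: enforce one peak per library compound
    # (best |dKI|, then largest area, then earliest rt for determinism).
    best: dict[str, int] = {}
    for idx, ident in enumerate(provisional):
        if not ident.accepted:
            continue
        cid = ident.compound_id
        if cid not in best:
            best[cid] = idx
            continue
        cur = provisional[best[cid]]
        key_new = (
            np.inf if ident.delta_ki is None else ident.delta_ki,
            -ident.area,
            ident.rt_min,
        )
        key_cur = (
            np.inf if cur.delta_ki is None else cur.delta_ki,
            -cur.area,
            cur.rt_min,
        )
        if key_new < key_cur:
            best[cid] = idx
    out: list[IdentifiedVOC] = []
    for idx, ident in enumerate(provisional):
        if ident.accepted and best.get(ident.compound_id) != idx:
            ident = IdentifiedVOC(
                compound_id=ident.compound_id,
                rt_min=ident.rt_min,
                area=ident.area,
                ki_calc=ident.ki_calc,
                delta_ki=ident.delta_ki,
                resemblance_pct=ident.resemblance_pct,
                evidence_tier=ident.evidence_tier,
                accepted=False,
                rejection_reason="outranked by a better peak for this compound",
            )
        out.append(ident)
    return out


def ki_deviation_report(library: list[CompoundRecord]) -> dict:
    """Agreement statistics between calculated and literature Kovats indices.

    Returns ``min_abs``, ``max_abs``, ``max_rel_pct``, ``n`` and a
    ``per_compound`` table (compound_id, ki_calc, ki_lit, delta, rel_pct)
    sorted by descending |ΔKI|, over all records with a literature KI.
    """
    rows = []
    for rec in library:
        if rec.ki_lit is None:
            continue
        delta = abs(rec.ki_calc_published - rec.ki_lit)
        rows.append(
            {
                "compound_id": rec.compound_id,
                "ki_calc": rec.ki_calc_published,
                "ki_lit": rec.ki_lit,
                "delta": delta,
                "rel_pct": 100.0 * delta / rec.ki_lit,
            }
        )
    rows.sort(key=lambda r: (-r["delta"], r["compound_id"]))
    if not rows:
        return {"min_abs": None, "max_abs": None, "max_rel_pct": None,
                "n": 0, "per_compound": []}
    return {
        "min_abs": min(r["delta"] for r in rows),
        "max_abs": max(r["delta"] for r in rows),
        "max_rel_pct": max(r["rel_pct"] for r in rows),
        "n": len(rows),
        "per_compound": rows,
    }
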