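"""Ground-truthed synthetic study data.

The published study profiled 22 monovarietal fortified wines (5 grape
varieties, ages 3–20 y, four sweetness types) in triplicate, but its
per-sample concentration appendix is not public.  This module emulates the
study at the peak-table level so every pipeline stage can be tested against
known truth:

* a synthetic alkane ladder (C8–C28, a deliberate superset of the run's
  C8–C20 series, since several library compounds elute past KI 2000) whose
  anchors are threaded through the published (KI, retention-time) cloud;
* per-compound true concentrations anchored to odor thresholds, with
  age-class factors that realise the qualitative aging chemistry: varietal
  and fermentative compounds (terpenics, norisoprenoids, esters, alcohols)
  fall with age, Maillard/oak products (furanics, lactones, acetals,
  volatile phenols) rise;
* peak areas inverted through the internal-standard formula with
  multiplicative Gaussian noise, retention times from the exact inverse
  Kovats mapping, spectral-resemblance draws ≥ 80% for true compounds and
  configurable sub-threshold decoy peaks.

With zero noise and no decoys the identify → quantify → screen pipeline
reproduces the truth table exactly; this is the end-to-end identity the
test suite leans on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .kovats import AlkaneLadder, rt_for_ki
from .library import (
    DEFAULT_IS_CONC_UG_PER_L,
    AgeClass,
    ChemicalFamily,
    CompoundRecord,
    Peak,
    PeakTable,
    SampleMeta,
    Variety,
    WineType,
    load_library,
)

__all__ = [
    "StudyDesign",
    "TruthTable",
    "default_design",
    "generate_ladder",
    "generate_sample",
    "generate_study",
    "AGING_SIGN",
    "EXCEEDANCE_PROFILE",
]

#: Direction of the old-vs-young concentration change per chemical family.
AGING_SIGN: dict[ChemicalFamily, int] = {
    ChemicalFamily.TERPENIC: -1,
    ChemicalFamily.NORISOPRENOID: -1,
    ChemicalFamily.HIGHER_ALCOHOL: -1,
    ChemicalFamily.SULPHUR: -1,
    ChemicalFamily.ESTER: -1,
    ChemicalFamily.ACID: 0,
    ChemicalFamily.ACETAL: 1,
    ChemicalFamily.FURANIC: 1,
    ChemicalFamily.LACTONE: 1,
    ChemicalFamily.VOLATILE_PHENOL: 1,
}

# Odor-threshold exceedance profile per compound (compounds with an OT).
# The study's discussion pins down, note by note, which compounds sit above
# their threshold in young vs old wines; the generator realises exactly
# those statements.  Anything with an OT not listed here stays below it.
_YOUNG_ABOVE = {
    "beta_pinene", "limonene", "linalool", "citronellol", "geraniol",
    "beta_cyclocitral", "tdn", "beta_damascenone", "geranyl_acetone",
    "beta_ionone", "hexan_1_ol", "2_ethylhexan_1_ol",
    "ethyl_3_methylbutanoate", "isoamyl_acetate", "ethyl_octanoate",
    "ethyl_decanoate", "ethyl_3_hydroxyhexanoate",
}
_OLD_ABOVE = {
    "gamma_octalactone", "gamma_decalactone", "z_whiskylactone",
    "5_ethoxymethyl_2_furfural", "eugenol", "vanillin",
}
_ALWAYS_ABOVE = {"ethyl_butanoate", "hexyl_acetate", "2_phenylethyl_alcohol"}

EXCEEDANCE_PROFILE: dict[str, str] = {}
for _cid in _YOUNG_ABOVE:
    EXCEEDANCE_PROFILE[_cid] = "young_above"
for _cid in _OLD_ABOVE:
    EXCEEDANCE_PROFILE[_cid] = "old_above"
for _cid in _ALWAYS_ABOVE:
    EXCEEDANCE_PROFILE[_cid] = "always_above"

#: Typical relative-concentration scale (µg/L) for compounds without an OT.
_FAMILY_SCALE_UG_PER_L: dict[ChemicalFamily, float] = {
    ChemicalFamily.TERPENIC: 20.0,
    ChemicalFamily.NORISOPRENOID: 5.0,
    ChemicalFamily.HIGHER_ALCOHOL: 500.0,
    ChemicalFamily.SULPHUR: 5.0,
    ChemicalFamily.ESTER: 100.0,
    ChemicalFamily.ACID: 300.0,
    ChemicalFamily.ACETAL: 50.0,
    ChemicalFamily.FURANIC: 100.0,
    ChemicalFamily.LACTONE: 50.0,
    ChemicalFamily.VOLATILE_PHENOL: 20.0,
}

# Ethyl pyruvate has no OT; the study reports its mean relative
# concentration as 3.54 µg/L in Verdelho vs 1.49 µg/L elsewhere.
_ETHYL_PYRUVATE_BASE = 1.49
_ETHYL_PYRUVATE_VERDELHO = 3.54

# (young factor, old factor) applied to the compound's level (OT or family
# scale).  Impact requires factor > 1; the never-above band stays well under.
_CLASS_FACTORS = {
    "young_above": (2.5, 0.4),
    "old_above": (0.4, 2.5),
    "always_above": {-1: (3.0, 1.5), 0: (2.0, 2.0), 1: (1.5, 3.0)},
    "never_above": {-1: (0.4, 0.15), 0: (0.3, 0.3), 1: (0.15, 0.4)},
    "no_ot": {-1: (1.6, 0.64), 0: (1.0, 1.0), 1: (0.64, 1.6)},
}

#: Fixed internal-standard peak area (arbitrary detector counts).
IS_AREA = 1.0e6


@dataclass(frozen=True)
class StudyDesign:
    """Wine cohort to simulate."""

    wines: tuple[SampleMeta, ...]
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


@dataclass
class TruthTable:
    """Ground truth behind a synthetic study."""

    concentrations: dict[tuple[str, str], float]  # (sample_id, compound_id) -> µg/L
    aging_sign: dict[str, int]                    # compound_id -> -1/0/+1
    noise_cv: float
    clipped: list[tuple[str, str]] = field(default_factory=list)

    def conc(self, sample_id: str, compound_id: str) -> float:
        return self.concentrations[(sample_id, compound_id)]

    def sample_concs(self, sample_id: str) -> dict[str, float]:
        return {
            cid: c
            for (sid, cid), c in self.concentrations.items()
            if sid == sample_id
        }


def _sugar_for(wine_type: WineType) -> float:
    return {
        WineType.DRY: 57.0,
        WineType.MEDIUM_DRY: 72.5,
        WineType.MEDIUM_SWEET: 88.0,
        WineType.SWEET: 120.0,
    }[wine_type]


def default_design(seed: int = 0, replicates: int = 3) -> StudyDesign:
    """The 22-wine cohort: 5 varieties, ages 3–20 y, types per variety.

    Noble varieties keep their traditional type (Malvasia sweet, Bual medium
    sweet, Sercial dry, Verdelho medium dry) over four ages each; Tinta
    Negra, vinified in all four types, contributes the remaining six wines.
    Ages are drawn from {3, 5, 10, 15, 17, 18, 19, 20} so that every variety
    has both young (3–5 y) and old (10–20 y) wines.
    """
    spec = [
        (Variety.MALVASIA, WineType.SWEET, (3, 5, 15, 20)),
        (Variety.BUAL, WineType.MEDIUM_SWEET, (3, 5, 15, 19)),
        (Variety.SERCIAL, WineType.DRY, (3, 5, 10, 18)),
        (Variety.VERDELHO, WineType.MEDIUM_DRY, (3, 5, 10, 17)),
    ]
    wines: list[SampleMeta] = []
    for variety, wtype, ages in spec:
        for age in ages:
            slug = variety.value.lower().replace(" ", "_")
            wines.append(
                SampleMeta(
                    sample_id=f"{slug}_{age}y",
                    variety=variety,
                    age_years=age,
                    wine_type=wtype,
                    sugar_g_per_L=_sugar_for(wtype),
                    ethanol_pct=18.5,
                )
            )
    tn = [
        (WineType.DRY, 5), (WineType.MEDIUM_DRY, 3), (WineType.SWEET, 10),
        (WineType.MEDIUM_SWEET, 17), (WineType.DRY, 19), (WineType.SWEET, 20),
    ]
    for wtype, age in tn:
        wines.append(
            SampleMeta(
                sample_id=f"tinta_negra_{wtype.value}_{age}y",
                variety=Variety.TINTA_NEGRA,
                age_years=age,
                wine_type=wtype,
                sugar_g_per_L=_sugar_for(wtype),
                ethanol_pct=18.5,
            )
        )
    assert len(wines) == 22
    return StudyDesign(wines=tuple(wines), replicates=replicates, seed=seed)


# --------------------------------------------------------------------------
# alkane ladder

def generate_ladder(
    library: list[CompoundRecord] | None = None,
    rt_span: tuple[float, float] = (0.5, 86.0),
    carbons: tuple[int, int] = (8, 28),
    seed: int = 0,
) -> AlkaneLadder:
    """Alkane ladder consistent with the library's (KI, retention time) cloud.

    Anchor retention times at KI = 100·n are interpolated through the
    published (ki_calc, rt) pairs, with linear tails pinned to ``rt_span``.
    The extended C8–C28 range (vs the experimental C8–C20 series) covers
    library compounds with KI up to 2620.  Deterministic: the seed is
    accepted for interface symmetry but the default construction uses none
    of it.
    """
    if library is None:
        library = load_library("default")
    pairs = sorted(
        (rec.ki_calc_published, rec.rt_published_min) for rec in library
    )
    kis = np.array([p[0] for p in pairs])
    rts = np.array([p[1] for p in pairs])
    lo_c, hi_c = carbons
    if not (lo_c < hi_c):
        raise ValidationError("carbons must be an increasing pair")
    if not (rt_span[0] < rts.min() and rt_span[1] > rts.max()):
        raise ValidationError(
            f"rt_span {rt_span} cannot contain the library's retention times "
            f"[{rts.min()}, {rts.max()}]"
        )
    # virtual endpoints pin the extrapolation tails inside the run span
    kis_ext = np.concatenate(([100.0 * lo_c - 100.0], kis, [100.0 * hi_c + 100.0]))
    rts_ext = np.concatenate(([rt_span[0]], rts, [rt_span[1]]))
    anchor_kis = 100.0 * np.arange(lo_c, hi_c + 1)
    anchor_rts = np.interp(anchor_kis, kis_ext, rts_ext)
    anchors = tuple(
        (int(c), float(rt)) for c, rt in zip(range(lo_c, hi_c + 1), anchor_rts)
    )
    return AlkaneLadder(anchors=anchors)


# --------------------------------------------------------------------------
# truth construction

def _true_concentration(
    rec: CompoundRecord, meta: SampleMeta
) -> float:
    sign = AGING_SIGN[rec.family]
    age_class = meta.age_class
    if rec.compound_id == "ethyl_pyruvate":
        base = (
            _ETHYL_PYRUVATE_VERDELHO
            if meta.variety is Variety.VERDELHO
            else _ETHYL_PYRUVATE_BASE
        )
        return base
    ot = rec.odor_threshold_ug_per_L
    if ot is None:
        level = _FAMILY_SCALE_UG_PER_L[rec.family]
        young_f, old_f = _CLASS_FACTORS["no_ot"][sign]
    else:
        level = ot
        profile = EXCEEDANCE_PROFILE.get(rec.compound_id, "never_above")
        factors = _CLASS_FACTORS[profile]
        if isinstance(factors, dict):
            factors = factors[sign]
        young_f, old_f = factors
    factor = young_f if age_class is AgeClass.YOUNG else old_f
    # gentle within-class age slope in the family's direction, so aging
    # trends are monotone inside a class too (never crosses the OT band)
    if age_class is AgeClass.YOUNG:
        pos = (meta.age_years - 4.0) / 2.0      # [-0.5, 0.5] over 3-5 y
    else:
        pos = (meta.age_years - 15.0) / 10.0    # [-0.5, 0.5] over 10-20 y
    factor *= 1.0 + 0.08 * sign * pos
    return level * factor


def build_truth(
    design: StudyDesign,
    library: list[CompoundRecord] | None = None,
    noise_cv: float = 0.05,
) -> TruthTable:
    """True concentrations for every (wine, compound) of a design."""
    if library is None:
        library = load_library("default")
    concentrations: dict[tuple[str, str], float] = {}
    for meta in design.wines:
        for rec in library:
            concentrations[(meta.sample_id, rec.compound_id)] = _true_concentration(
                rec, meta
            )
    return TruthTable(
        concentrations=concentrations,
        aging_sign={
            rec.compound_id: AGING_SIGN[rec.family] for rec in library
        },
        noise_cv=noise_cv,
    )


# --------------------------------------------------------------------------
# peak-table synthesis

def _rng_for(seed: int, sample_id: str) -> np.random.Generator:
    # independent, regenerable per-sample stream
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode("utf-8"))])


def generate_sample(
    meta: SampleMeta,
    truth: TruthTable,
    ladder: AlkaneLadder,
    seed: int = 0,
    *,
    library: list[CompoundRecord] | None = None,
    sample_id: str | None = None,
    n_decoys: int = 0,
    rt_jitter_min: float | None = None,
    is_conc_ug_per_L: float = DEFAULT_IS_CONC_UG_PER_L,
) -> PeakTable:
    """Synthesise one sample's peak table from the truth.

    Areas follow ``area = conc / IS_conc * IS_area * (1 + eps)`` with
    ``eps ~ Normal(0, noise_cv)``; a draw producing a negative area is
    truncated to 0 and recorded in ``truth.clipped``.  Retention times are
    the exact inverse Kovats mapping plus Gaussian jitter (default: 0.01 min
    when noise_cv > 0, none otherwise).  True peaks carry their compound as
    spectral candidate with resemblance ≥ 80%; decoys carry a random
    candidate with resemblance < 80%.
    """
    if library is None:
        library = load_library("default")
    sid = sample_id or meta.sample_id
    rng = _rng_for(seed, sid)
    noise_cv = truth.noise_cv
    if rt_jitter_min is None:
        rt_jitter_min = 0.01 if noise_cv > 0 else 0.0
    peaks: list[Peak] = []
    for rec in library:
        conc = truth.conc(meta.sample_id, rec.compound_id)
        area = conc / is_conc_ug_per_L * IS_AREA
        if noise_cv > 0:
            area *= 1.0 + rng.normal(0.0, noise_cv)
        if area < 0:
            area = 0.0
            truth.clipped.append((sid, rec.compound_id))
        rt = rt_for_ki(ladder, rec.ki_calc_published)
        if rt_jitter_min > 0:
            rt += rng.normal(0.0, rt_jitter_min)
        resemblance = float(rng.uniform(85.0, 99.0))
        peaks.append(
            Peak(
                rt_min=rt,
                area=float(area),
                candidate=rec.compound_id,
                resemblance_pct=round(resemblance, 1),
            )
        )
    lo, hi = ladder.span
    for _ in range(n_decoys):
        decoy_target = library[int(rng.integers(len(library)))]
        peaks.append(
            Peak(
                rt_min=float(rng.uniform(lo, hi)),
                area=float(rng.uniform(0.01, 2.0) * IS_AREA),
                candidate=decoy_target.compound_id,
                resemblance_pct=round(float(rng.uniform(40.0, 79.4)), 1),
            )
        )
    peaks.sort(key=lambda p: p.rt_min)
    # IS: 4-methyl-2-pentanol elutes early on a wax column; place it at a
    # fixed low KI so it never collides with library peaks.
    is_rt = rt_for_ki(ladder, 990.0)
    replica_meta = SampleMeta(
        sample_id=sid,
        variety=meta.variety,
        age_years=meta.age_years,
        wine_type=meta.wine_type,
        sugar_g_per_L=meta.sugar_g_per_L,
        ethanol_pct=meta.ethanol_pct,
    )
    return PeakTable(
        meta=replica_meta,
        peaks=peaks,
        is_peak=Peak(rt_min=is_rt, area=IS_AREA),
        is_conc_ug_per_L=is_conc_ug_per_L,
    )


def generate_study(
    design: StudyDesign | None = None,
    *,
    library: list[CompoundRecord] | None = None,
    noise_cv: float = 0.05,
    n_decoys: int = 0,
    ladder: AlkaneLadder | None = None,
) -> tuple[list[PeakTable], TruthTable, AlkaneLadder]:
    """Simulate the full study: replicate peak tables + truth + ladder.

    The default design yields 22 wines × 3 replicates = 66 peak tables.
    Replicates share their wine's true concentrations and differ only by
    the multiplicative noise stream.
    """
    if design is None:
        design = default_design()
    if library is None:
        library = load_library("default")
    if ladder is None:
        ladder = generate_ladder(library)
    truth = build_truth(design, library, noise_cv=noise_cv)
    tables: list[PeakTable] = []
    for meta in design.wines:
        for rep in range(1, design.replicates + 1):
            rep_id = f"{meta.sample_id}_rep{rep}"
            tables.append(
                generate_sample(
                    meta,
                    truth,
                    ladder,
                    seed=design.seed,
                    library=library,
                    sample_id=rep_id,
                    n_decoys=n_decoys,
                )
            )
            # replicate truth rows, so downstream joins stay by sample_id
            for rec in library:
                truth.concentrations[(rep_id, rec.compound_id)] = truth.conc(
                    meta.sample_id, rec.compound_id
                )
    return tables, truth, ladder
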