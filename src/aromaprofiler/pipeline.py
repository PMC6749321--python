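"""End-to-end orchestration: simulate/load → identify → quantify → screen →
impact table → family aggregates → aroma networks → summary JSON.

``run_all`` is a plain composition of the module operations — it holds no
hidden state, so running the stages by hand gives identical results.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import io as aio
from .errors import AromaProfilerError
from .kovats import (
    DEFAULT_ABS_TOL,
    DEFAULT_MIN_RESEMBLANCE_PCT,
    DEFAULT_REL_TOL_PCT,
    AlkaneLadder,
    identify_peaks,
    ki_deviation_report,
)
from .library import (
    DEFAULT_IS_CONC_UG_PER_L,
    AgeClass,
    PeakTable,
    default_sensory,
    load_library,
    load_sensory,
)
from .network import build_bipartite, export_graph, project_notes, project_varieties
from .odor_activity import impact_table, screen_impact_odorants
from .semiquant import aggregate_families, semi_quantify
from .simulate import default_design, generate_study

log = logging.getLogger("aromaprofiler")

__all__ = ["RunConfig", "run_all", "StageError"]


class StageError(AromaProfilerError):
    """Wraps a stage failure with the stage name for CLI reporting."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run; round-trips through YAML."""

    library: str = "default"
    sensory: str = "default"
    abs_tol: float = DEFAULT_ABS_TOL
    rel_tol_pct: float = DEFAULT_REL_TOL_PCT
    min_resemblance_pct: float = DEFAULT_MIN_RESEMBLANCE_PCT
    is_conc_ug_per_L: float = DEFAULT_IS_CONC_UG_PER_L
    include_unknown_ot: bool = False
    seed: int = 0
    noise_cv: float = 0.05
    n_decoys: int = 0
    replicates: int = 3
    out_dir: str = "aromaprofiler_out"

    def __post_init__(self):
        for name in ("abs_tol", "rel_tol_pct", "min_resemblance_pct",
                     "is_conc_ug_per_L"):
            if getattr(self, name) <= 0:
                raise AromaProfilerError(f"config {name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                result = fn(*args, **kwargs)
            except AromaProfilerError as exc:
                raise StageError(name, exc) from exc
            return result
        return wrapped
    return deco


def run_all(
    config: RunConfig,
    peak_tables: list[PeakTable] | None = None,
    ladder: AlkaneLadder | None = None,
) -> dict:
    """Run every stage and emit the report bundle into ``config.out_dir``.

    Without explicit ``peak_tables`` the default synthetic study is
    simulated with the config's seed/noise settings. Returns the summary
    dictionary (also written as ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    library = load_library(config.library)
    sensory = (
        default_sensory() if config.sensory == "default"
        else load_sensory(config.sensory)
    )
    log.info("library: %d compounds; sensory: %d profiles",
             len(library), len(sensory))

    simulated = peak_tables is None
    if simulated:
        design = default_design(seed=config.seed, replicates=config.replicates)
        peak_tables, truth, ladder = generate_study(
            design, library=library, noise_cv=config.noise_cv,
            n_decoys=config.n_decoys,
        )
        aio.write_truth(truth, out / "truth.csv")
        for table in peak_tables:
            aio.write_peak_table(table, out / "samples")
    elif ladder is None:
        raise StageError("inputs", AromaProfilerError(
            "a ladder is required when peak tables are supplied"))
    aio.write_ladder(ladder, out / "ladder.csv")

    identify = _stage("identify")(identify_peaks)
    quantify = _stage("quantify")(semi_quantify)
    screen = _stage("screen")(screen_impact_odorants)

    identified = {}
    quants = []
    screens = {}
    metas = []
    for table in peak_tables:
        sid = table.meta.sample_id
        idents = identify(
            table, ladder, library,
            min_resemblance_pct=config.min_resemblance_pct,
            abs_tol=config.abs_tol, rel_tol_pct=config.rel_tol_pct,
        )
        identified[sid] = idents
        quant = quantify(table, idents)
        quants.append(quant)
        screens[sid] = screen(quant, library)
        metas.append(table.meta)
    log.info("identified %d samples", len(identified))
    aio.write_identified(identified, out / "identified.csv")
    aio.write_quantification(quants, out / "quant.csv")
    aio.write_oav(screens, out / "oav.csv")

    impact = _stage("impact-table")(impact_table)(
        screens, metas, library, sensory,
        include_unknown_ot=config.include_unknown_ot,
    )
    aio.write_impact_table(impact, out / "impact_table.csv")

    aggregates = _stage("aggregate")(aggregate_families)(quants, metas, library)
    aio.write_aggregates(aggregates, out / "family_aggregates.csv")

    bipartite = build_bipartite(library)
    export_graph(bipartite, out / "bipartite.graphml")
    note_proj = project_notes(bipartite)
    export_graph(note_proj, out / "notes_projection.csv", fmt="csv")
    projections = {}
    for age_class in AgeClass:
        proj = _stage("network")(project_varieties)(
            bipartite, sensory, age_class
        )
        export_graph(proj, out / f"varieties_{age_class.value}.graphml")
        weights = [d["weight"] for _, _, d in proj.edges(data=True)]
        projections[age_class.value] = {
            "n_edges": proj.number_of_edges(),
            "mean_edge_weight": (
                sum(weights) / len(weights) if weights else 0.0
            ),
        }

    deviation = ki_deviation_report(library)
    n_accepted = {
        sid: sum(1 for r in rows if r.accepted) for sid, rows in identified.items()
    }
    summary = {
        "n_library_compounds": len(library),
        "n_samples": len(peak_tables),
        "simulated": simulated,
        "seed": config.seed,
        "mean_accepted_per_sample": (
            sum(n_accepted.values()) / len(n_accepted) if n_accepted else 0
        ),
        "ki_deviation": {
            "min_abs": deviation["min_abs"],
            "max_abs": deviation["max_abs"],
            "max_rel_pct": deviation["max_rel_pct"],
            "n": deviation["n"],
        },
        "n_aroma_notes": sum(
            1 for _, d in bipartite.nodes(data=True) if d.get("kind") == "note"
        ),
        "variety_projections": projections,
        "family_trends": {
            a.family.value: a.trend
            for a in aggregates
            if a.age_class is AgeClass.OLD
        },
        "n_impact_rows": len(impact),
    }
    aio.write_json(summary, out / "summary.json")
    return summary
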