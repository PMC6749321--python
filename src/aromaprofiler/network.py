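"""Bipartite VOC↔aroma-note graph and its shared-VOC projections.

The relationship-based view of a wine's aroma links two node families: the
aroma notes a trained panel can name, and the volatile compounds whose
flagged descriptors include that note.  Two projections condense the
bipartite graph:

* note–note: two notes are linked when at least one compound carries both;
  the edge weight is the number of shared compounds;
* variety–variety (per age class): each grape variety is represented by the
  union of the compound neighborhoods of its reported notes; two varieties
  are linked by the size of the intersection of their compound sets.

Collective notes ("dried fruits") expand to their member descriptors before
any neighborhood computation.  All graphs are networkx objects; exports are
GraphML or a weighted edge-list CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx

from .errors import UnknownNoteError, ValidationError
from .library import (
    NOTE_GROUPS,
    AgeClass,
    CompoundRecord,
    SensoryProfile,
    Variety,
    normalize_token,
)

__all__ = [
    "build_bipartite",
    "shared_vocs",
    "project_notes",
    "project_varieties",
    "variety_voc_sets",
    "export_graph",
    "load_graph",
]


def build_bipartite(
    library: list[CompoundRecord], *, restrict_to: set[str] | None = None
) -> nx.Graph:
    """Bipartite graph of compounds (bipartite=0) and aroma notes (bipartite=1).

    One edge per (compound, flagged aroma note); the note set is the union
    of flags over the library.  Compounds with no flagged note are isolated
    VOC nodes.  ``restrict_to`` optionally limits VOC nodes to a compound-id
    subset (e.g. impact-flagged compounds only).
    """
    graph = nx.Graph()
    for rec in library:
        if restrict_to is not None and rec.compound_id not in restrict_to:
            continue
        graph.add_node(rec.compound_id, bipartite=0, kind="voc",
                       family=rec.family.value)
        for note in sorted(rec.aroma_notes):
            graph.add_node(note, bipartite=1, kind="note")
            graph.add_edge(rec.compound_id, note)
    return graph


def _note_nodes(bipartite: nx.Graph) -> set[str]:
    return {n for n, d in bipartite.nodes(data=True) if d.get("kind") == "note"}


def _neighborhood(
    bipartite: nx.Graph,
    note: str,
    note_groups: dict[str, frozenset[str]],
    *,
    strict: bool,
) -> set[str]:
    """VOC neighborhood of a note, expanding collective notes.

    Group members absent from the graph contribute nothing; a plain note
    absent from the graph raises (strict) or is empty (lenient — used for
    panel notes no library compound carries, e.g. mushroom).
    """
    known = _note_nodes(bipartite)
    members = note_groups.get(note, frozenset({note}))
    if strict and note not in note_groups and note not in known:
        raise UnknownNoteError(note, known)
    vocs: set[str] = set()
    for member in members:
        if member in known:
            vocs.update(bipartite.neighbors(member))
    return vocs


def shared_vocs(
    bipartite: nx.Graph,
    notes: set[str],
    *,
    note_groups: dict[str, frozenset[str]] | None = None,
) -> set[str]:
    """Compounds carrying *every* note in ``notes`` (intersection of
    neighborhoods); a single note returns its full neighborhood.  Unknown
    notes raise :class:`UnknownNoteError`.
    """
    if not notes:
        raise ValidationError("shared_vocs requires at least one note")
    groups = NOTE_GROUPS if note_groups is None else note_groups
    result: set[str] | None = None
    for note in sorted({normalize_token(n) for n in notes}):
        hood = _neighborhood(bipartite, note, groups, strict=True)
        result = hood if result is None else result & hood
    return result


def project_notes(bipartite: nx.Graph) -> nx.Graph:
    """Note–note projection weighted by shared-VOC counts (weight ≥ 1)."""
    notes = sorted(_note_nodes(bipartite))
    graph = nx.Graph()
    graph.add_nodes_from(notes, kind="note")
    for i, a in enumerate(notes):
        hood_a = set(bipartite.neighbors(a))
        for b in notes[i + 1:]:
            shared = hood_a & set(bipartite.neighbors(b))
            if shared:
                graph.add_edge(a, b, weight=len(shared),
                               shared="|".join(sorted(shared)))
    return graph


def variety_voc_sets(
    bipartite: nx.Graph,
    sensory: list[SensoryProfile],
    age_class: AgeClass,
    *,
    note_groups: dict[str, frozenset[str]] | None = None,
) -> dict[Variety, set[str]]:
    """Per-variety VOC sets: union of neighborhoods of the variety's notes."""
    groups = NOTE_GROUPS if note_groups is None else note_groups
    profiles = {
        p.variety: p for p in sensory if p.age_class == age_class
    }
    missing = [v.value for v in Variety if v not in profiles]
    if missing:
        raise ValidationError(
            f"missing {age_class.value} sensory profile(s) for: {', '.join(missing)}"
        )
    sets: dict[Variety, set[str]] = {}
    for variety, profile in profiles.items():
        vocs: set[str] = set()
        for note in profile.notes:
            vocs |= _neighborhood(bipartite, note, groups, strict=False)
        sets[variety] = vocs
    return sets


def project_varieties(
    bipartite: nx.Graph,
    sensory: list[SensoryProfile],
    age_class: AgeClass,
    *,
    note_groups: dict[str, frozenset[str]] | None = None,
) -> nx.Graph:
    """Variety–variety projection for one age class.

    Edge weight = number of compounds shared by the two varieties' VOC
    sets; zero-weight edges are omitted, so a variety with no notes (or
    only notes no compound carries) is an isolated node.
    """
    sets = variety_voc_sets(bipartite, sensory, age_class,
                            note_groups=note_groups)
    graph = nx.Graph()
    varieties = [v for v in Variety]
    for v in varieties:
        graph.add_node(v.value, kind="variety", age_class=age_class.value,
                       n_vocs=len(sets[v]))
    for i, a in enumerate(varieties):
        for b in varieties[i + 1:]:
            shared = sets[a] & sets[b]
            if shared:
                graph.add_edge(a.value, b.value, weight=len(shared),
                               shared="|".join(sorted(shared)))
    return graph


_FORMATS = ("graphml", "csv")


def export_graph(graph: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a graph as GraphML or a weighted edge-list CSV.

    The CSV has one row per unordered edge (source, target, weight); weights
    default to 1 for unweighted edges.
    """
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "csv"
    if fmt not in _FORMATS:
        raise ValidationError(
            f"unsupported graph format {fmt!r}; supported: {', '.join(_FORMATS)}"
        )
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for a, b, data in sorted(graph.edges(data=True)):
            writer.writerow([a, b, int(data.get("weight", 1))])


def load_graph(path: str | Path) -> nx.Graph:
    """Re-read a graph written by :func:`export_graph`."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        return nx.read_graphml(path)
    graph = nx.Graph()
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            graph.add_edge(row["source"], row["target"],
                           weight=int(row["weight"]))
    return graph
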