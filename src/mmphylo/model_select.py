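"""Nearest-model-organism inference relative to a reference species.

For each scoped MMP class (collagenases MMP-1/8/13 and gelatinases
MMP-2/9 by default), candidate model organisms are ranked by their
evolutionary proximity to the reference (Homo sapiens): the minimum
patristic distance between any of the organism's leaves and any reference
leaf within that class. A topological variant counts path edges instead of
branch lengths. Organisms without sequences in a class are reported as
absent, never silently dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy

from .phylo import leaf_distance_matrix, path_edge_count
from .seqio import ClassLabel

logger = logging.getLogger(__name__)

DEFAULT_CLASSES = ("MMP-1", "MMP-8", "MMP-13", "MMP-2", "MMP-9")
DEFAULT_ORGANISMS = ("Homo sapiens", "Bos taurus", "Mus musculus",
                     "Rattus norvegicus", "Canis lupus",
                     "Oryctolagus cuniculus", "Sus scrofa")


@dataclass(frozen=True)
class ScopeConfig:
    """Which classes, organisms, and reference the inference considers."""

    classes: tuple[str, ...] = DEFAULT_CLASSES
    organisms: tuple[str, ...] = DEFAULT_ORGANISMS
    reference: str = "Homo sapiens"

    def __post_init__(self) -> None:
        if not any(_binomial_match(self.reference, o) for o in self.organisms):
            raise ValueError(
                f"reference {self.reference!r} not among scoped organisms")


def _binomial(name: str) -> str:
    """First two name parts, lower-cased; subspecies epithets ignored."""
    return " ".join(name.strip().split()[:2]).lower()


def _binomial_match(a: str, b: str) -> bool:
    return _binomial(a) == _binomial(b)


def match_organism(name: str | None, scope: ScopeConfig) -> str | None:
    """Canonical scoped organism for a record's organism string, or None."""
    if not name:
        return None
    for org in scope.organisms:
        if _binomial_match(name, org):
            return org
    return None


@dataclass
class LeafInfo:
    seq_id: str
    label: ClassLabel
    organism: str | None


@dataclass
class ClassRanking:
    """Proximity ranking for one class."""

    cls: str
    rankings: list[tuple[str, float, int]]  # (organism, distance, rank)
    absent: list[str]
    reason: str | None = None  # set when the class is non-rankable


@dataclass
class ProximityReport:
    metric: str
    reference: str
    classes: dict[str, ClassRanking] = field(default_factory=dict)

    def table(self) -> list[dict]:
        rows = []
        for cls, ranking in self.classes.items():
            if ranking.reason:
                rows.append({"class": cls, "rank": "-", "organism": "-",
                             "distance": "-", "note": ranking.reason})
                continue
            if not ranking.rankings:
                rows.append({"class": cls, "rank": "-", "organism": "-",
                             "distance": "-", "note": "no candidate organisms"})
            for org, dist, rank in ranking.rankings:
                rows.append({"class": cls, "rank": rank, "organism": org,
                             "distance": dist, "note": ""})
            for org in ranking.absent:
                rows.append({"class": cls, "rank": "-", "organism": org,
                             "distance": "-", "note": "absent from class"})
        return rows


def restrict_scope(leaves: list[LeafInfo], scope: ScopeConfig,
                   ) -> dict[str, dict[str, list[str]]]:
    """Group scoped leaf ids as class -> canonical organism -> [seq_id].

    Organism strings are matched case-insensitively on the binomial, so
    subspecies such as "Canis lupus familiaris" fold into "Canis lupus".
    """
    scoped: dict[str, dict[str, list[str]]] = {c: {} for c in scope.classes}
    for leaf in leaves:
        if leaf.label.mmp not in scope.classes:
            continue
        org = match_organism(leaf.organism, scope)
        if org is None:
            continue
        scoped[leaf.label.mmp].setdefault(org, []).append(leaf.seq_id)
    for cls, orgs in scoped.items():
        for org in scope.organisms:
            logger.info("scope retention: %s / %s -> %d leaves", cls, org,
                        len(orgs.get(org, [])))
    return scoped


def _rank(distances: list[tuple[str, float]], rel_tol: float,
          ) -> list[tuple[str, float, int]]:
    """Sort ascending and assign shared ranks to near-tied distances."""
    ordered = sorted(distances, key=lambda t: (t[1], t[0]))
    out: list[tuple[str, float, int]] = []
    rank = 0
    prev: float | None = None
    for pos, (org, dist) in enumerate(ordered, start=1):
        tied = prev is not None and math.isclose(dist, prev, rel_tol=rel_tol,
                                                 abs_tol=rel_tol)
        if not tied:
            rank = pos
        out.append((org, dist, rank))
        prev = dist
    return out


def _proximity(tree: dendropy.Tree, leaves: list[LeafInfo],
               scope: ScopeConfig, metric: str,
               rel_tol: float) -> ProximityReport:
    scoped = restrict_scope(leaves, scope)
    report = ProximityReport(metric=metric, reference=scope.reference)
    if metric == "patristic":
        dm = leaf_distance_matrix(tree)
        dist_fn = dm.get
    else:
        dist_fn = lambda a, b: float(path_edge_count(tree, a, b))
    for cls in scope.classes:
        orgs = scoped[cls]
        ref_leaves = orgs.get(scope.reference, [])
        present = [o for o in scope.organisms
                   if o != scope.reference and orgs.get(o)]
        absent = [o for o in scope.organisms
                  if o != scope.reference and not orgs.get(o)]
        if not ref_leaves:
            report.classes[cls] = ClassRanking(
                cls=cls, rankings=[], absent=absent,
                reason=f"reference {scope.reference} absent from class")
            continue
        distances = []
        for org in present:
            d = min(dist_fn(a, b) for a in orgs[org] for b in ref_leaves)
            distances.append((org, d))
        report.classes[cls] = ClassRanking(
            cls=cls, rankings=_rank(distances, rel_tol), absent=absent)
    return report


def organism_proximity(tree: dendropy.Tree, leaves: list[LeafInfo],
                       scope: ScopeConfig | None = None,
                       rel_tol: float = 1e-9) -> ProximityReport:
    """Rank organisms by minimum patristic distance to the reference.

    Distances within ``rel_tol`` of each other share a tie-group rank
    (competition ranking: a two-way tie at the top leaves rank 3 next).
    """
    return _proximity(tree, leaves, scope or ScopeConfig(), "patristic",
                      rel_tol)


def topological_proximity(tree: dendropy.Tree, leaves: list[LeafInfo],
                          scope: ScopeConfig | None = None,
                          rel_tol: float = 1e-9) -> ProximityReport:
    """As :func:`organism_proximity` but counting path edges on the class
    subtree, ignoring branch lengths."""
    scope = scope or ScopeConfig()
    scoped = restrict_scope(leaves, scope)
    report = ProximityReport(metric="topological", reference=scope.reference)
    for cls in scope.classes:
        class_ids = [i for org in scoped[cls].values() for i in org]
        sub_leaves = [l for l in leaves if l.seq_id in set(class_ids)]
        if len(class_ids) >= 2:
            subtree = tree.extract_tree_with_taxa_labels(class_ids)
        else:
            subtree = tree
        part = _proximity(subtree, sub_leaves,
                          ScopeConfig(classes=(cls,),
                                      organisms=scope.organisms,
                                      reference=scope.reference),
                          "topological", rel_tol)
        report.classes[cls] = part.classes[cls]
    return report
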