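"""Phylogeny-guided class annotation and reannotation.

Sequences that sit inside a clade dominated by a different MMP class are
candidates for relabeling; sequences with only generic descriptions
("Zinc-dependent protein" and the like) can be assigned a concrete class
from their neighborhood. The manual color-inspection step this automates is
formalized as a k-nearest-ancestral-leaf vote: walk from the query leaf
toward the root, collect the first >=k concretely labeled leaves, and
relabel when a single class holds at least a fraction ``f`` of those votes.
Rare classes (<= min_class_size members) are protected from absorption and
only flagged.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import dendropy

from .seqio import (CONCRETE_CLASSES, GENERIC, GROUP_OF_MMP, UNASSIGNED,
                    ClassLabel, SequenceRecord)

#: case-insensitive keywords marking a generic (non-class-specific) label
GENERIC_KEYWORDS = ("zinc", "metalloproteinase", "metallopeptidase",
                    "matrix", "uncharacterized")

_MMP_TOKEN = re.compile(
    r"\b(?:MMP|matrix metalloproteinase|metalloproteinase|metallopeptidase)"
    r"[-\s]?(\d+)\b", re.IGNORECASE)


def label_from_description(description: str) -> ClassLabel:
    """Parse a class label from free description text.

    An explicit MMP-N token wins; numbers outside the recognised class set,
    or descriptions with only generic keywords, yield GENERIC; anything
    else is UNASSIGNED.
    """
    m = _MMP_TOKEN.search(description)
    if m:
        candidate = f"MMP-{int(m.group(1))}"
        if candidate in GROUP_OF_MMP:
            return ClassLabel(candidate)
    lowered = description.lower()
    if any(k in lowered for k in GENERIC_KEYWORDS):
        return ClassLabel(GENERIC)
    return ClassLabel(UNASSIGNED)


def labels_from_records(records: list[SequenceRecord]) -> dict[str, ClassLabel]:
    return {r.seq_id: label_from_description(r.description) for r in records}


@dataclass
class LeafAnnotation:
    """Outcome of the vote for one leaf."""

    seq_id: str
    prior_label: ClassLabel
    final_label: ClassLabel
    change_kind: str  # unchanged | class_annotation | reannotation | flagged
    vote_fraction: float
    votes_counted: int


@dataclass
class AnnotationReport:
    """Per-class totals in the shape of a class/annotation summary table."""

    per_class: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        out = {"total": 0, "class_annotation": 0, "reannotation": 0}
        for row in self.per_class.values():
            for k in out:
                out[k] += row[k]
        return out

    def table(self) -> list[dict]:
        rows = []
        for mmp in CONCRETE_CLASSES:
            if mmp not in self.per_class:
                continue
            row = self.per_class[mmp]
            rows.append({"group": GROUP_OF_MMP[mmp], "mmp": mmp,
                         "total": row["total"],
                         "class_annotation": row["class_annotation"],
                         "reannotation": row["reannotation"]})
        t = self.totals
        rows.append({"group": "", "mmp": "Total", "total": t["total"],
                     "class_annotation": t["class_annotation"],
                     "reannotation": t["reannotation"]})
        return rows


def neighbor_vote(tree: dendropy.Tree, labels: dict[str, ClassLabel],
                  leaf: str, k: int = 10, exclude: frozenset[str] = frozenset(),
                  ) -> tuple[ClassLabel | None, float, int]:
    """Modal concrete label among the first >=k ancestrally collected leaves.

    Walks from the leaf's parent toward the root; at each step all newly
    subtended concretely labeled leaves join the electorate (the query leaf,
    excluded leaves such as the outgroup, and GENERIC/UNASSIGNED leaves
    never vote). Stops once >=k votes are in or the root is reached. A tied
    vote returns ``(None, 0.0, count)``.
    """
    from .phylo import _find_leaf

    query = _find_leaf(tree, leaf)
    votes: list[str] = []
    seen = {query}
    node = query.parent_node
    while node is not None and len(votes) < k:
        for other in node.leaf_iter():
            if other in seen:
                continue
            seen.add(other)
            label = labels.get(other.taxon.label)
            if other.taxon.label in exclude or label is None:
                continue
            if label.is_concrete:
                votes.append(label.mmp)
        node = node.parent_node
    if not votes:
        return None, 0.0, 0
    counts = Counter(votes).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None, 0.0, len(votes)
    winner, n = counts[0]
    return ClassLabel(winner), n / len(votes), len(votes)


def annotate(tree: dendropy.Tree, labels: dict[str, ClassLabel],
             k: int = 10, f: float = 0.8, min_class_size: int = 3,
             outgroup: str | None = None,
             ) -> tuple[dict[str, ClassLabel], list[LeafAnnotation],
                        AnnotationReport]:
    """Single-pass clade-vote annotation against the prior labels.

    A GENERIC/UNASSIGNED leaf whose vote reaches fraction >= f gains the
    winning class (``class_annotation``). A concretely labeled leaf whose
    vote picks a different class at fraction >= f is relabeled
    (``reannotation``) unless its prior class has <= min_class_size members,
    in which case it is only ``flagged``. Votes are computed against the
    prior labels throughout, so the result is independent of leaf order.
    """
    exclude = frozenset({outgroup}) if outgroup else frozenset()
    class_sizes = Counter(l.mmp for l in labels.values() if l.is_concrete)
    annotations: list[LeafAnnotation] = []
    updated: dict[str, ClassLabel] = {}
    leaf_labels = [l.taxon.label for l in tree.leaf_node_iter()]
    for name in leaf_labels:
        prior = labels.get(name, ClassLabel(UNASSIGNED))
        if name in exclude:
            updated[name] = prior
            continue
        winner, frac, counted = neighbor_vote(tree, labels, name, k=k,
                                              exclude=exclude)
        final, kind = prior, "unchanged"
        if winner is not None and frac >= f:
            if not prior.is_concrete:
                final, kind = winner, "class_annotation"
            elif winner.mmp != prior.mmp:
                if class_sizes[prior.mmp] <= min_class_size:
                    kind = "flagged"
                else:
                    final, kind = winner, "reannotation"
        updated[name] = final
        annotations.append(LeafAnnotation(
            seq_id=name, prior_label=prior, final_label=final,
            change_kind=kind, vote_fraction=frac, votes_counted=counted))

    report = AnnotationReport()
    for ann in annotations:
        if not ann.final_label.is_concrete:
            continue
        row = report.per_class.setdefault(
            ann.final_label.mmp,
            {"total": 0, "class_annotation": 0, "reannotation": 0})
        row["total"] += 1
        if ann.change_kind in ("class_annotation", "reannotation"):
            row[ann.change_kind] += 1

    _check_flow_conservation(labels, updated, exclude)
    return updated, annotations, report


def _check_flow_conservation(prior: dict[str, ClassLabel],
                             final: dict[str, ClassLabel],
                             exclude: frozenset[str]) -> None:
    """total_final = total_prior + inflow - outflow, for every class."""
    for cls in CONCRETE_CLASSES:
        n_prior = sum(1 for s, l in prior.items()
                      if l.mmp == cls and s not in exclude)
        n_final = sum(1 for s, l in final.items()
                      if l.mmp == cls and s not in exclude)
        inflow = sum(1 for s in final
                     if s not in exclude and final[s].mmp == cls
                     and prior.get(s, ClassLabel(UNASSIGNED)).mmp != cls)
        outflow = sum(1 for s in prior
                      if s not in exclude and prior[s].mmp == cls
                      and final.get(s, prior[s]).mmp != cls)
        assert n_final == n_prior + inflow - outflow, (
            f"label flow not conserved for {cls}")


def clade_purity(tree: dendropy.Tree, labels: dict[str, ClassLabel],
                 cls: str) -> float:
    """Fraction of the class's MRCA clade occupied by the class itself."""
    from .phylo import clade_leaves, mrca

    members = [s for s, l in labels.items() if l.mmp == cls]
    if not members:
        raise ValueError(f"no leaves labeled {cls!r}")
    clade = clade_leaves(tree, mrca(tree, members))
    return len(set(members) & clade) / len(clade)


# --------------------------------------------------------------------------
# leaf-table and iTOL-style exports

GROUP_COLORS = {"collagenase": "#e41a1c", "gelatinase": "#377eb8",
                "stromelysin": "#4daf4a", "transmembrane": "#984ea3",
                "other": "#ff7f00", "none": "#999999"}


def write_leaf_table(annotations: list[LeafAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tprior_label\tfinal_label\tchange_kind\t"
                 "vote_fraction\tvotes_counted\n")
        for a in annotations:
            fh.write(f"{a.seq_id}\t{a.prior_label.mmp}\t{a.final_label.mmp}\t"
                     f"{a.change_kind}\t{a.vote_fraction:.4f}\t"
                     f"{a.votes_counted}\n")


def read_leaf_table(path) -> dict[str, ClassLabel]:
    """Final labels from a previously written leaf table."""
    labels: dict[str, ClassLabel] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = header.index("final_label")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            labels[cols[0]] = ClassLabel(cols[idx])
    return labels


def write_color_strip(labels: dict[str, ClassLabel], path) -> None:
    """iTOL-style color strip: one ``leaf<TAB>hex color`` line per leaf."""
    with open(path, "w") as fh:
        fh.write("DATASET_COLORSTRIP\nSEPARATOR TAB\nDATA\n")
        for seq_id, label in labels.items():
            fh.write(f"{seq_id}\t{GROUP_COLORS[label.group]}\n")
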