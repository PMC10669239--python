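"""Readers and writers for the external formats the pipeline touches.

Covers FASTA in the UniProt header dialect (``db|ACCESSION|ENTRY_NAME
description OS=... OX=... GN=...``), RPSBlast-style tab-separated
conserved-domain hit tables, newick trees (through dendropy), and the
tab-separated report tables the pipeline emits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

# 20 canonical amino acids plus ambiguity codes, selenocysteine and gap.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "XBZU-")

#: CDD identifiers of the four diagnostic MMP domain families.
DOMAIN_FAMILY_MAP: dict[str, frozenset[str]] = {
    "matrixin": frozenset({
        "CDD:395334", "CDD:239819", "CDD:239806", "CDD:239805", "CDD:239804",
        "CDD:239803", "CDD:239796", "CDD:238124", "CDD:214576",
    }),
    "hemopexin": frozenset({"CDD:395000", "CDD:238046"}),
    "pg_binding": frozenset({"CDD:396175"}),
    "fibronectin": frozenset({"CDD:128373"}),
}

DOMAIN_FAMILIES = tuple(DOMAIN_FAMILY_MAP)

# sanity of the constant map: disjoint sets of the documented sizes
_all_ids: list[str] = [i for s in DOMAIN_FAMILY_MAP.values() for i in s]
assert len(_all_ids) == len(set(_all_ids)) == 13, "CDD family sets overlap"
assert tuple(len(DOMAIN_FAMILY_MAP[f]) for f in DOMAIN_FAMILIES) == (9, 2, 1, 1)

_CDD_TO_FAMILY: dict[str, str] = {
    cdd: fam for fam, ids in DOMAIN_FAMILY_MAP.items() for cdd in ids
}


def family_of_cdd(cdd_id: str) -> str:
    """Domain family for a CDD identifier; unknown ids map to ``other``."""
    return _CDD_TO_FAMILY.get(cdd_id, "other")


# --------------------------------------------------------------------------
# class labels

#: The 21 concrete MMP classes recovered by the study, grouped by substrate
#: specificity (collagenases also cover the rare MMP-18).
GROUP_OF_MMP: dict[str, str] = {
    **{m: "collagenase" for m in ("MMP-1", "MMP-8", "MMP-13", "MMP-18")},
    **{m: "gelatinase" for m in ("MMP-2", "MMP-9")},
    **{m: "stromelysin" for m in ("MMP-3", "MMP-10", "MMP-11")},
    **{m: "transmembrane" for m in ("MMP-14", "MMP-15", "MMP-16", "MMP-17",
                                    "MMP-24", "MMP-25")},
    **{m: "other" for m in ("MMP-12", "MMP-19", "MMP-20", "MMP-21",
                            "MMP-27", "MMP-28")},
}

CONCRETE_CLASSES: tuple[str, ...] = tuple(sorted(
    GROUP_OF_MMP, key=lambda m: int(m.split("-")[1])))

GENERIC = "GENERIC"
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True, order=True)
class ClassLabel:
    """An MMP class assignment: a concrete class, GENERIC, or UNASSIGNED."""

    mmp: str

    def __post_init__(self) -> None:
        if self.mmp not in GROUP_OF_MMP and self.mmp not in (GENERIC, UNASSIGNED):
            raise ValueError(f"unknown MMP class label: {self.mmp!r}")

    @property
    def group(self) -> str:
        return GROUP_OF_MMP.get(self.mmp, "none")

    @property
    def is_concrete(self) -> bool:
        return self.mmp in GROUP_OF_MMP

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.mmp


# --------------------------------------------------------------------------
# sequence records

@dataclass
class SequenceRecord:
    """One protein sequence with parsed UniProt-dialect header metadata."""

    seq_id: str
    residues: str
    db_tag: str = "synthetic"
    accession: str = ""
    entry_name: str = ""
    description: str = ""
    organism: str | None = None
    taxid: int | None = None
    gene: str | None = None
    raw_header: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        for pos, ch in enumerate(self.residues):
            if ch not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"illegal residue {ch!r} at position {pos + 1} in {self.seq_id}")
        if not self.accession:
            self.accession = self.seq_id

    @property
    def length(self) -> int:
        """Number of residues, gap characters excluded."""
        return len(self.residues) - self.residues.count("-")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


_FIELD_TAG = re.compile(r"\b(OS|OX|GN|PE|SV)\s*=\s*")
_UNIPROT_ID = re.compile(r"^(sp|tr|synthetic)\|([^|\s]+)\|(\S+)")


def _parse_uniprot_header(header: str) -> dict:
    """Parse a UniProt-style header line (without the leading ``>``).

    Accepts both ``OS=value`` and the spaced ``OS = value`` form. Fields
    that do not parse are left absent rather than guessed.
    """
    first, _, rest = header.partition(" ")
    meta: dict = {"seq_id": first, "raw_header": header}
    m = _UNIPROT_ID.match(first)
    if m:
        meta["db_tag"], meta["accession"], meta["entry_name"] = m.groups()
    else:
        meta["db_tag"] = "synthetic"
        meta["accession"] = first
        meta["entry_name"] = first

    # split the free text into description + tagged fields
    tags = list(_FIELD_TAG.finditer(rest))
    meta["description"] = (rest[: tags[0].start()] if tags else rest).strip()
    for i, tag in enumerate(tags):
        value = rest[tag.end(): tags[i + 1].start() if i + 1 < len(tags) else None]
        value = value.strip()
        name = tag.group(1)
        if name == "OS":
            meta["organism"] = value or None
        elif name == "OX":
            try:
                meta["taxid"] = int(value)
            except ValueError:
                pass
        elif name == "GN":
            meta["gene"] = value or None
    return meta


def read_fasta(path: str | Path, dialect: str = "uniprot") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    path:
        FASTA file; must contain at least one record.
    dialect:
        ``uniprot`` parses ``db|ACC|ENTRY`` ids and OS/OX/GN fields;
        ``plain`` takes the whole first token as the id and attaches no
        metadata.
    """
    if dialect not in ("uniprot", "plain"):
        raise ValueError(f"unknown FASTA dialect: {dialect!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in _BioSeqIO.parse(str(path), "fasta"):
        header = bio.description
        if dialect == "uniprot":
            meta = _parse_uniprot_header(header)
        else:
            meta = {"seq_id": bio.id, "raw_header": header,
                    "db_tag": "synthetic", "accession": bio.id,
                    "entry_name": bio.id,
                    "description": header.partition(" ")[2].strip()}
        if meta["seq_id"] in seen:
            raise ValueError(f"duplicate sequence id: {meta['seq_id']!r}")
        seen.add(meta["seq_id"])
        records.append(SequenceRecord(residues=str(bio.seq), **meta))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records to FASTA, reproducing original headers when available."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.raw_header if rec.raw_header is not None else rec.seq_id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i: i + width] + "\n")


# --------------------------------------------------------------------------
# domain hits

@dataclass(frozen=True)
class DomainHit:
    """One RPSBlast match of a sequence against a CDD domain model."""

    seq_id: str
    cdd_id: str
    bitscore: float
    evalue: float
    qstart: int
    qend: int

    @property
    def family(self) -> str:
        return family_of_cdd(self.cdd_id)


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a BLAST-outfmt-6-like tab-separated domain hit table.

    Expected columns: seq_id, cdd_id, percent identity, alignment length,
    qstart, qend, evalue, bitscore. Additional columns are ignored.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected >=8 tab-separated columns, "
                    f"got {len(cols)}")
            seq_id, cdd_id = cols[0], cols[1]
            qstart, qend = int(cols[4]), int(cols[5])
            if qend < qstart or qstart < 1:
                raise ValueError(
                    f"{path}:{lineno}: malformed coordinates "
                    f"qstart={qstart} qend={qend}")
            hits.append(DomainHit(seq_id=seq_id, cdd_id=cdd_id,
                                  bitscore=float(cols[7]), evalue=float(cols[6]),
                                  qstart=qstart, qend=qend))
    if not hits:
        logger.warning("domain hit table %s is empty", path)
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            span = h.qend - h.qstart + 1
            fh.write(f"{h.seq_id}\t{h.cdd_id}\t100.0\t{span}\t{h.qstart}\t"
                     f"{h.qend}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n")


# --------------------------------------------------------------------------
# newick trees

def _check_parentheses(text: str, path: str | Path) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(
                    f"{path}: unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise ValueError(
            f"{path}: {depth} unclosed '(' (checked {len(text)} characters)")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single newick tree.

    Missing branch lengths default to 0 (with a warning); duplicate leaf
    names and unbalanced parentheses are rejected.
    """
    text = Path(path).read_text()
    _check_parentheses(text, path)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"{path}: duplicate leaf name: {exc}") from exc
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            edge.length = 0.0
            missing += 1
    if missing:
        logger.warning("%s: %d branch lengths absent, defaulted to 0",
                       path, missing)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as newick with branch lengths at 12 significant digits."""
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True,
               real_value_format_specifier=".12g")


# --------------------------------------------------------------------------
# report tables

def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    import math
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


REPORT_COLUMNS = {
    "stage_stats": ("stage", "n", "min", "max", "mean", "sd"),
    "annotation": ("group", "mmp", "total", "class_annotation", "reannotation"),
    "proximity": ("class", "rank", "organism", "distance", "note"),
}


def write_report(table: Sequence[dict], path: str | Path, kind: str) -> None:
    """Write a pipeline report as a fixed-column tab-separated table.

    ``stage_stats`` rows carry full-precision mean/sd and are rounded to
    integers (half away from zero) for display only. ``annotation`` rows
    follow the dash convention: zero change counts print as ``-``.
    """
    if kind not in REPORT_COLUMNS:
        raise ValueError(f"unknown report kind: {kind!r}")
    if not table:
        raise ValueError("report table is empty")
    cols = REPORT_COLUMNS[kind]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in table:
            out = []
            for c in cols:
                v = row.get(c, "")
                if kind == "stage_stats" and c in ("mean", "sd"):
                    v = _round_half_away(float(v))
                if kind == "annotation" and c in ("class_annotation", "reannotation") \
                        and isinstance(v, int) and v == 0:
                    v = "-"
                if kind == "proximity" and c == "distance" and isinstance(v, float):
                    v = f"{v:.6g}"
                out.append(str(v))
            fh.write("\t".join(out) + "\n")
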