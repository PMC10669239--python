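"""Simulator of class-structured MMP-like gene families with ground truth.

Stands in for a UniProt family download so every pipeline stage can be
exercised offline: sequences evolve along per-class gene trees derived from
a fixed mammalian species tree, carry UniProt-style synthetic headers and
per-class conserved-domain architectures, and are then corrupted the way
real downloads are (fragments, exact duplicates, mislabels, generic
labels). A manifest records every action, making survivor counts and label
recovery exactly predictable.

The gene tree for each class grafts a designated "planted nearest" species
as sister to the reference species on short branches, so the expected
closest model organism per class is controlled; a per-class rate multiplier
and per-branch log-normal jitter add realistic rate variation without
disturbing the planted ordering in expectation. Substitutions follow a
20-state Poisson model: a site hit by at least one substitution over branch
length t with rate mu ends up different with probability
p(t) = (19/20) * (1 - exp(-(20/19) * mu * t)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .seqio import (AMINO_ACIDS, CONCRETE_CLASSES, GROUP_OF_MMP, DomainHit,
                    SequenceRecord, write_domain_hits, write_fasta)

# ---------------------------------------------------------------------------
# the Archaeal outgroup: a complete interstitial-collagenase-like sequence
# from a Marine Group I thaumarchaeote, bundled verbatim and appended to
# every generated dataset so the phylogeny can be rooted.

OUTGROUP_HEADER = (
    "tr|A0A087RZB5|A0A087RZB5_9ARCH Matrix metalloproteinase-1 interstitial "
    "collagenase OS = Marine Group I thaumarchaeote SCGC AAA799-P11 "
    "OX = 1502295 GN = AAA799P11_00940 PE = 4 SV = 1")
OUTGROUP_SEQ = (
    "MLQKKSDEFEQLYEKYDKLKMKVKELSQENQIYSHMCKKIETNSKDLKKSQSNLKKQLDQKLHSQLESE"
    "QEKLLLEKQLERSESSSKKSQKKYYVALVMAALSIAIISGAYSIMFAELAGQQYKIEVTPKPTGYTIQN"
    "LRGDTINTFLSWRLVPGDTLRVNIINSDNYDPEKIEVIKKTILSEKQLEIDNSLMHKGPKGTTSILYEG"
    "WLGALNDASKTDTNLFVPTNIEVIESNNGEGDITIELTNRKNADGFAGWTNSIADDSQNQILKSRITIF"
    "AVDSLSLAELETIVRHEMGHALGLAHSTDPEDLMYPTIQTNFPYISECDVDAIESLYDGQNTSEVICEI")
OUTGROUP_ID = "tr|A0A087RZB5|A0A087RZB5_9ARCH"

TAXIDS = {"Homo sapiens": 9606, "Bos taurus": 9913, "Mus musculus": 10090,
          "Rattus norvegicus": 10116, "Canis lupus": 9612,
          "Oryctolagus cuniculus": 9986, "Sus scrofa": 9823}

#: clock-like species tree over the seven dentistry model organisms
#: (substitutions per site, order-of-magnitude mammalian divergence)
DEFAULT_SPECIES_NEWICK = (
    "((Homo_sapiens:0.10,(Oryctolagus_cuniculus:0.08,"
    "(Mus_musculus:0.04,Rattus_norvegicus:0.04):0.04):0.02):0.05,"
    "(Canis_lupus:0.07,(Bos_taurus:0.05,Sus_scrofa:0.05):0.02):0.05);")

#: matrilysin-like distractor classes: two-domain architecture, guaranteed
#: removal by the >=3-family rule
MATRILYSIN_CLASSES = ("MMP-7", "MMP-26")

_DEFAULT_CLASSES = CONCRETE_CLASSES + MATRILYSIN_CLASSES

#: per-class nearest model organism planted into the gene trees; scoped
#: classes follow the study's inference, the rest cycle deterministically
_SCOPED_PLANTS = {"MMP-1": "Oryctolagus cuniculus",
                  "MMP-8": "Oryctolagus cuniculus",
                  "MMP-13": "Canis lupus",
                  "MMP-2": "Rattus norvegicus",
                  "MMP-9": "Oryctolagus cuniculus"}


def _default_planted(classes: tuple[str, ...], reference: str) -> dict[str, str]:
    pool = [o for o in TAXIDS if o != reference]
    cycler = itertools.cycle(pool)
    out = {}
    for cls in classes:
        out[cls] = _SCOPED_PLANTS.get(cls) or next(cycler)
    return out


def _group_of(cls: str) -> str:
    if cls in MATRILYSIN_CLASSES:
        return "matrilysin"
    return GROUP_OF_MMP[cls]


@dataclass
class SimParams:
    """Generator settings; defaults define the standard study conditions."""

    species_newick: str = DEFAULT_SPECIES_NEWICK
    reference: str = "Homo sapiens"
    classes: tuple[str, ...] = _DEFAULT_CLASSES
    planted_nearest: dict[str, str] | None = None
    n_sites: int = 450
    mu: float = 1.0
    class_rate_multipliers: tuple[float, ...] = (0.8, 1.0, 1.25)
    class_divergence: float = 0.8
    branch_jitter_sigma: float = 0.1
    leaves_per: int = 3
    planted_attach: float = 0.02
    planted_pendant: float = 0.02
    duplication_eps: float = 0.02
    fragment_rate: float = 0.05
    duplicate_rate: float = 0.05
    mislabel_rate: float = 0.05
    generic_label_rate: float = 0.10

    def __post_init__(self) -> None:
        for name in ("fragment_rate", "duplicate_rate", "mislabel_rate",
                     "generic_label_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.planted_nearest is None:
            self.planted_nearest = _default_planted(self.classes,
                                                    self.reference)

    def multiplier(self, cls: str) -> float:
        idx = self.classes.index(cls)
        return self.class_rate_multipliers[idx % len(self.class_rate_multipliers)]


@dataclass
class RecordTruth:
    """Ground truth and corruption flags for one emitted record."""

    seq_id: str
    accession: str
    true_class: str
    group: str
    organism: str
    is_outgroup: bool = False
    fragment_span: tuple[int, int] | None = None
    duplicate_of: str | None = None
    mislabeled_as: str | None = None
    generic_labeled: bool = False


@dataclass
class SyntheticTruth:
    """Manifest covering every emitted record exactly once."""

    records: dict[str, RecordTruth] = field(default_factory=dict)
    planted_nearest: dict[str, str] = field(default_factory=dict)
    gene_trees: dict[str, str] = field(default_factory=dict)  # class -> newick

    def predicted_stage_counts(self) -> dict[str, int]:
        """Survivor counts the curation cascade must reproduce.

        Fragments fall below the length window by construction; records
        with fewer than three domain families (matrilysin-like) fail the
        domain filter; duplicate-flagged records fall at deduplication.
        """
        all_t = list(self.records.values())
        after_length = [t for t in all_t if t.fragment_span is None]
        after_domains = [t for t in after_length
                         if t.group != "matrilysin" or t.is_outgroup]
        after_dedup = [t for t in after_domains if t.duplicate_of is None]
        return {"input": len(all_t), "length_filter": len(after_length),
                "domain_filter": len(after_domains),
                "deduplicate": len(after_dedup)}


# ---------------------------------------------------------------------------
# sequence evolution

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}


def random_root_sequence(n_sites: int, rng: np.random.Generator) -> str:
    return bytes(_AA[rng.integers(0, 20, n_sites)]).decode()


def evolve_sequence(parent: str, t: float, mu: float,
                    rng: np.random.Generator) -> str:
    """Evolve a sequence along a branch under the 20-state Poisson model.

    Each site substitutes independently with probability
    p(t) = (19/20)(1 - exp(-(20/19) mu t)); the replacement residue is
    uniform over the 19 alternatives.
    """
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    if mu <= 0:
        raise ValueError(f"substitution rate must be positive, got {mu}")
    codes = np.array([_AA_INDEX[c] for c in parent], dtype=np.int64)
    p = (19 / 20) * (1 - np.exp(-(20 / 19) * mu * t))
    hit = rng.random(len(codes)) < p
    offsets = rng.integers(1, 20, size=int(hit.sum()))
    codes[hit] = (codes[hit] + offsets) % 20
    return bytes(_AA[codes]).decode()


# ---------------------------------------------------------------------------
# gene trees

def _species_tree(params: SimParams) -> dendropy.Tree:
    return dendropy.Tree.get(data=params.species_newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)


def build_gene_tree(params: SimParams, cls: str,
                    rng: np.random.Generator) -> dendropy.Tree:
    """Per-class gene tree: species tree + planted sister + duplications.

    The planted-nearest species is regrafted as sister to the reference on
    short branches; every branch is scaled by the class rate multiplier and
    log-normal jitter; each species leaf is finally expanded into
    ``leaves_per`` near-zero-length duplicate tips named for the eventual
    sequence records (``<Species>|<k>``).
    """
    tree = _species_tree(params)
    ref_label = params.reference.replace(" ", "_")
    planted = params.planted_nearest[cls].replace(" ", "_")

    if planted != ref_label:
        # detach the planted species, then regraft next to the reference
        leaf = [l for l in tree.leaf_node_iter()
                if l.taxon.label == planted][0]
        parent = leaf.parent_node
        parent.remove_child(leaf)
        tree.suppress_unifurcations()
        ref_leaf = [l for l in tree.leaf_node_iter()
                    if l.taxon.label == ref_label][0]
        stem = ref_leaf.parent_node
        joint = dendropy.Node()
        stem.remove_child(ref_leaf)
        stem.add_child(joint)
        joint.edge.length = max((ref_leaf.edge.length or 0.0)
                                - params.planted_attach, 0.0)
        joint.add_child(ref_leaf)
        ref_leaf.edge.length = params.planted_attach
        joint.add_child(leaf)
        leaf.edge.length = params.planted_pendant

    mult = params.multiplier(cls)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            jitter = float(np.exp(rng.normal(0.0, params.branch_jitter_sigma)))
            edge.length = edge.length * mult * jitter

    # within-species duplications: expand each species leaf into a small
    # caterpillar of leaves_per tips with eps-length branches
    eps = params.duplication_eps
    tns = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        species = leaf.taxon.label
        if params.leaves_per == 1:
            leaf.taxon = tns.new_taxon(f"{species}|1")
            continue
        leaf.taxon = None
        node = leaf
        for k in range(1, params.leaves_per):
            tip = dendropy.Node(taxon=tns.new_taxon(f"{species}|{k}"))
            tip.edge.length = eps
            node.add_child(tip)
            if k < params.leaves_per - 1:
                inner = dendropy.Node()
                inner.edge.length = eps
                node.add_child(inner)
                node = inner
            else:
                last = dendropy.Node(
                    taxon=tns.new_taxon(f"{species}|{params.leaves_per}"))
                last.edge.length = eps
                node.add_child(last)
    return tree


def simulate_family(params: SimParams, cls: str, class_root: str,
                    rng: np.random.Generator, counter: itertools.count,
                    ) -> tuple[list[SequenceRecord], dict[str, RecordTruth], str]:
    """Evolve one class family along its gene tree.

    Returns the records, their truth entries, and the gene tree newick with
    leaves renamed to the record seq_ids.
    """
    tree = build_gene_tree(params, cls, rng)
    seqs: dict[dendropy.Node, str] = {tree.seed_node: class_root}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        seqs[node] = evolve_sequence(seqs[node.parent_node],
                                     node.edge.length or 0.0, params.mu, rng)
    records: list[SequenceRecord] = []
    truth: dict[str, RecordTruth] = {}
    group = _group_of(cls)
    num = cls.split("-")[1]
    for leaf in tree.leaf_node_iter():
        species = leaf.taxon.label.split("|")[0].replace("_", " ")
        acc = f"SYN{next(counter):05d}"
        code = (species.split()[0][:3] + species.split()[1][:2]).upper()
        entry = f"{acc}_{code}"
        seq_id = f"synthetic|{acc}|{entry}"
        if group == "matrilysin":
            desc = f"Matrilysin protease {cls.replace('MMP-', 'MAT')}"
        else:
            desc = f"Matrix metalloproteinase-{num}"
        header = (f"{seq_id} {desc} OS={species} OX={TAXIDS[species]} "
                  f"GN=MMP{num}")
        records.append(SequenceRecord(
            seq_id=seq_id, residues=seqs[leaf], db_tag="synthetic",
            accession=acc, entry_name=entry, description=desc,
            organism=species, taxid=TAXIDS[species], gene=f"MMP{num}",
            raw_header=header))
        truth[seq_id] = RecordTruth(seq_id=seq_id, accession=acc,
                                    true_class=cls, group=group,
                                    organism=species)
        leaf.taxon.label = seq_id
    return records, truth, tree.as_string(schema="newick").strip()


# ---------------------------------------------------------------------------
# domain architectures

_BASE_ARCH = (("pg_binding", "CDD:396175", 10, 85),
              ("matrixin", "CDD:395334", 100, 265),
              ("hemopexin", "CDD:395000", 290, 445))
_FIBRONECTIN = (("fibronectin", "CDD:128373", 150, 185),
                ("fibronectin", "CDD:128373", 190, 225),
                ("fibronectin", "CDD:128373", 228, 262))
_MATRILYSIN_ARCH = _BASE_ARCH[:2]
_OUTGROUP_ARCH = (("pg_binding", "CDD:396175", 10, 85),
                  ("matrixin", "CDD:395334", 100, 265),
                  ("hemopexin", "CDD:395000", 270, 340))


def _architecture(t: RecordTruth) -> tuple[tuple[str, str, int, int], ...]:
    if t.is_outgroup:
        return _OUTGROUP_ARCH
    if t.group == "matrilysin":
        return _MATRILYSIN_ARCH
    if t.group == "gelatinase":
        return _BASE_ARCH + _FIBRONECTIN
    return _BASE_ARCH


def emit_domain_hits(records: list[SequenceRecord], truth: SyntheticTruth,
                     rng: np.random.Generator) -> list[DomainHit]:
    """Per-record domain hit tables following the class architecture.

    Gelatinases carry the three fibronectin type II repeats on top of the
    pro-domain/catalytic/hemopexin core; matrilysin-like distractors carry
    only two families. Fragments keep only hits fully inside the retained
    span, with coordinates rebased to the fragment.
    """
    hits: list[DomainHit] = []
    for rec in records:
        t = truth.records[rec.seq_id]
        for family, cdd, start, end in _architecture(t):
            if t.fragment_span is not None:
                fs, fe = t.fragment_span
                if not (fs <= start and end <= fe):
                    continue
                start, end = start - fs + 1, end - fs + 1
            hits.append(DomainHit(
                seq_id=rec.seq_id, cdd_id=cdd,
                bitscore=float(np.round(rng.uniform(80, 300), 1)),
                evalue=float(10.0 ** -rng.uniform(20, 60)),
                qstart=start, qend=end))
    return hits


def _ensure_unique_residues(records: list[SequenceRecord],
                            rng: np.random.Generator) -> None:
    """Guarantee residue-string uniqueness of independently evolved records.

    Short duplication branches can, rarely, leave two gene copies identical;
    the only intended 100%-identity pairs are the injected duplicates, so
    any accidental collision gets one extra substitution at a random site.
    """
    seen: dict[str, str] = {}
    for rec in records:
        while rec.residues in seen:
            pos = int(rng.integers(0, len(rec.residues)))
            old = _AA_INDEX[rec.residues[pos]]
            new = AMINO_ACIDS[(old + int(rng.integers(1, 20))) % 20]
            rec.residues = rec.residues[:pos] + new + rec.residues[pos + 1:]
        seen[rec.residues] = rec.seq_id


# ---------------------------------------------------------------------------
# corruption

GENERIC_PHRASES = ("Zinc-dependent protein", "Metalloproteinase",
                   "Matrix metallopeptidase", "Uncharacterized protein")


def inject_corruptions(records: list[SequenceRecord], truth: SyntheticTruth,
                       params: SimParams, rng: np.random.Generator,
                       ) -> list[SequenceRecord]:
    """Apply fragments, duplicates, mislabels and generic labels in place.

    Fragments truncate to a uniform 10-40% span (falling below the length
    window by construction); duplicates copy a non-fragment record under a
    fresh, lexicographically later accession; mislabels swap the class
    token in the description; generic labels replace the description with a
    non-specific phrase. Every action lands in the manifest.
    """
    base = [r for r in records
            if not truth.records[r.seq_id].is_outgroup]
    n = len(base)

    frag_mask = rng.random(n) < params.fragment_rate
    for rec, is_frag in zip(base, frag_mask):
        if not is_frag:
            continue
        length = rec.length
        span = max(int(length * rng.uniform(0.10, 0.40)), 10)
        start = int(rng.integers(1, length - span + 2))
        rec.residues = rec.residues[start - 1: start - 1 + span]
        rec.raw_header = None  # header rebuilt lazily on write
        truth.records[rec.seq_id].fragment_span = (start, start + span - 1)

    intact = [r for r, f in zip(base, frag_mask) if not f]
    mis_mask = rng.random(len(intact)) < params.mislabel_rate
    gen_mask = rng.random(len(intact)) < params.generic_label_rate
    for rec, mis, gen in zip(intact, mis_mask, gen_mask):
        t = truth.records[rec.seq_id]
        if mis and t.group != "matrilysin":
            others = [c for c in CONCRETE_CLASSES if c != t.true_class]
            wrong = others[int(rng.integers(0, len(others)))]
            rec.description = f"Matrix metalloproteinase-{wrong.split('-')[1]}"
            t.mislabeled_as = wrong
        elif gen:
            rec.description = GENERIC_PHRASES[
                int(rng.integers(0, len(GENERIC_PHRASES)))]
            t.generic_labeled = True
        else:
            continue
        rec.raw_header = (f"{rec.seq_id} {rec.description} OS={rec.organism} "
                          f"OX={rec.taxid} GN={rec.gene}")

    dup_mask = rng.random(len(intact)) < params.duplicate_rate
    duplicates: list[SequenceRecord] = []
    for rec, is_dup in zip(intact, dup_mask):
        if not is_dup:
            continue
        t = truth.records[rec.seq_id]
        acc = "SYND" + rec.accession[3:]
        entry = f"{acc}_{rec.entry_name.split('_')[-1]}"
        seq_id = f"synthetic|{acc}|{entry}"
        header = (f"{seq_id} {rec.description} OS={rec.organism} "
                  f"OX={rec.taxid} GN={rec.gene}")
        duplicates.append(SequenceRecord(
            seq_id=seq_id, residues=rec.residues, db_tag="synthetic",
            accession=acc, entry_name=entry, description=rec.description,
            organism=rec.organism, taxid=rec.taxid, gene=rec.gene,
            raw_header=header))
        truth.records[seq_id] = RecordTruth(
            seq_id=seq_id, accession=acc, true_class=t.true_class,
            group=t.group, organism=t.organism, duplicate_of=rec.accession,
            mislabeled_as=t.mislabeled_as, generic_labeled=t.generic_labeled)
    records.extend(duplicates)
    return records


# ---------------------------------------------------------------------------
# dataset assembly

def outgroup_record() -> SequenceRecord:
    from .seqio import _parse_uniprot_header
    meta = _parse_uniprot_header(OUTGROUP_HEADER)
    return SequenceRecord(residues=OUTGROUP_SEQ, **meta)


def generate_dataset(params: SimParams, seed: int, out_dir: str | Path | None = None,
                     ) -> tuple[list[SequenceRecord], list[DomainHit],
                                SyntheticTruth]:
    """Generate a full corrupted dataset; byte-identical under one seed.

    Writes ``sequences.fasta``, ``domain_hits.tsv``, ``alignment.fasta``,
    ``truth_manifest.tsv`` and ``planted_nearest.tsv`` when ``out_dir`` is
    given.
    """
    rng = np.random.default_rng(seed)
    counter = itertools.count(1)
    truth = SyntheticTruth(planted_nearest=dict(params.planted_nearest))
    family_root = random_root_sequence(params.n_sites, rng)
    records: list[SequenceRecord] = []
    full_length: dict[str, str] = {}
    for cls in params.classes:
        class_root = evolve_sequence(family_root, params.class_divergence,
                                     params.mu, rng)
        recs, rec_truth, newick = simulate_family(params, cls, class_root,
                                                  rng, counter)
        records.extend(recs)
        truth.records.update(rec_truth)
        truth.gene_trees[cls] = newick
    for rec in records:
        full_length[rec.seq_id] = rec.residues

    _ensure_unique_residues(records, rng)
    records = inject_corruptions(records, truth, params, rng)
    og = outgroup_record()
    records.append(og)
    truth.records[og.seq_id] = RecordTruth(
        seq_id=og.seq_id, accession=og.accession, true_class="OUTGROUP",
        group="outgroup", organism=og.organism or "", is_outgroup=True)
    hits = emit_domain_hits(records, truth, rng)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "sequences.fasta")
        write_domain_hits(hits, out / "domain_hits.tsv")
        write_alignment(records, truth, full_length, out / "alignment.fasta")
        write_truth(truth, out)
    return records, hits, truth


def aligned_rows(records: list[SequenceRecord], truth: SyntheticTruth,
                 full_length: dict[str, str] | None = None,
                 ) -> list[SequenceRecord]:
    """The true alignment of the emitted records.

    Indel-free simulation makes ingroup sequences mutually aligned at full
    length; fragments are padded with gaps outside their span and the
    (shorter) outgroup is right-padded. Duplicates inherit their source's
    row.
    """
    n_cols = max(len(r.residues) for r in records
                 if not truth.records[r.seq_id].is_outgroup
                 and truth.records[r.seq_id].fragment_span is None)
    rows = []
    for rec in records:
        t = truth.records[rec.seq_id]
        if t.fragment_span is not None:
            s, e = t.fragment_span
            row = "-" * (s - 1) + rec.residues + "-" * (n_cols - e)
        else:
            row = rec.residues + "-" * (n_cols - len(rec.residues))
        rows.append(SequenceRecord(seq_id=rec.seq_id, residues=row,
                                   db_tag=rec.db_tag, accession=rec.accession,
                                   entry_name=rec.entry_name,
                                   description=rec.description,
                                   organism=rec.organism, taxid=rec.taxid,
                                   gene=rec.gene, raw_header=rec.raw_header))
    return rows


def write_alignment(records, truth, full_length, path) -> None:
    write_fasta(aligned_rows(records, truth, full_length), path)


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    with open(out / "truth_manifest.tsv", "w") as fh:
        fh.write("seq_id\taccession\ttrue_class\tgroup\torganism\t"
                 "is_outgroup\tfragment_span\tduplicate_of\tmislabeled_as\t"
                 "generic_labeled\n")
        for t in truth.records.values():
            span = (f"{t.fragment_span[0]}-{t.fragment_span[1]}"
                    if t.fragment_span else "-")
            fh.write(f"{t.seq_id}\t{t.accession}\t{t.true_class}\t{t.group}\t"
                     f"{t.organism}\t{int(t.is_outgroup)}\t{span}\t"
                     f"{t.duplicate_of or '-'}\t{t.mislabeled_as or '-'}\t"
                     f"{int(t.generic_labeled)}\n")
    with open(out / "planted_nearest.tsv", "w") as fh:
        fh.write("class\tplanted_nearest\n")
        for cls, org in truth.planted_nearest.items():
            fh.write(f"{cls}\t{org}\n")


# ---------------------------------------------------------------------------
# direct labeled-tree simulation (annotation-recovery experiments)

def simulate_labeled_tree(rng: np.random.Generator, n_classes: int = 8,
                          leaves_per_class: int = 30,
                          intra_depth: float = 0.1,
                          separation_factor: float = 5.0,
                          mislabel_rate: float = 0.05,
                          generic_rate: float = 0.10):
    """A rooted tree of pure class clades with corrupted prior labels.

    Each class occupies one clade of random coalescent-like shape with
    intra-clade depth ``intra_depth``; clades hang off the root on stems
    ``separation_factor`` times deeper. Prior labels are the true class
    except for injected mislabels (a different concrete class) and generic
    labels; returns ``(tree, prior_labels, truth)`` where truth maps seq_id
    to ``(true_class, kind)`` with kind in {clean, mislabel, generic}.
    """
    from .seqio import GENERIC, ClassLabel

    classes = list(CONCRETE_CLASSES[:n_classes])
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    prior: dict[str, ClassLabel] = {}
    truth: dict[str, tuple[str, str]] = {}
    for cls in classes:
        nodes = []
        for k in range(leaves_per_class):
            name = f"{cls}_{k:03d}"
            node = dendropy.Node(taxon=tns.new_taxon(name))
            node.edge.length = float(rng.uniform(0.2, 1.0)) * intra_depth
            nodes.append(node)
            r = rng.random()
            if r < mislabel_rate:
                wrong = classes[(classes.index(cls)
                                 + 1 + int(rng.integers(0, n_classes - 1)))
                                % n_classes]
                prior[name] = ClassLabel(wrong)
                truth[name] = (cls, "mislabel")
            elif r < mislabel_rate + generic_rate:
                prior[name] = ClassLabel(GENERIC)
                truth[name] = (cls, "generic")
            else:
                prior[name] = ClassLabel(cls)
                truth[name] = (cls, "clean")
        while len(nodes) > 1:
            i = int(rng.integers(0, len(nodes)))
            a = nodes.pop(i)
            j = int(rng.integers(0, len(nodes)))
            b = nodes.pop(j)
            parent = dendropy.Node()
            parent.add_child(a)
            parent.add_child(b)
            parent.edge.length = float(rng.uniform(0.05, 0.3)) * intra_depth
            nodes.append(parent)
        clade = nodes[0]
        clade.edge.length = separation_factor * intra_depth
        root.add_child(clade)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return tree, prior, truth
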