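"""End-to-end orchestration: curate -> tree -> root -> annotate -> proximity.

Stages run in fixed order; external alignment/tree tools (Mafft, FastTree)
are never shelled out — their file outputs are imported instead, and the
bundled neighbor-joining builder covers the hermetic path. Every run writes
per-stage FASTA snapshots, the stage-statistics report, the annotated leaf
table, the annotation summary, both proximity reports, a run log and a
parameter/checksum manifest.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import classify, curation, model_select, phylo, seqio

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    fasta: str
    domain_hits: str
    out_dir: str
    outgroup: str
    alignment: str | None = None   # aligned FASTA (bundled NJ path)
    tree: str | None = None        # imported newick (external-tool path)
    curation: curation.CurationParams = field(
        default_factory=curation.CurationParams)
    vote_k: int = 10
    vote_f: float = 0.8
    min_class_size: int = 3
    scope: model_select.ScopeConfig = field(
        default_factory=model_select.ScopeConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.alignment is None) == (self.tree is None):
            raise ValueError("exactly one of an alignment (NJ path) or an "
                             "imported tree must be configured")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat INI-style config; sections mirror module names."""
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        inp = cp["inputs"]
        kwargs: dict = {
            "fasta": inp["fasta"], "domain_hits": inp["domain_hits"],
            "out_dir": inp["out_dir"], "outgroup": inp["outgroup"],
            "alignment": inp.get("alignment") or None,
            "tree": inp.get("tree") or None,
        }
        if cp.has_section("curation"):
            c = cp["curation"]
            kwargs["curation"] = curation.CurationParams(
                window=c.getfloat("window", 0.5),
                min_families=c.getint("min_families", 3),
                dedup_mode=c.get("dedup_mode", "exact"))
        if cp.has_section("classify"):
            c = cp["classify"]
            kwargs["vote_k"] = c.getint("k", 10)
            kwargs["vote_f"] = c.getfloat("f", 0.8)
            kwargs["min_class_size"] = c.getint("min_class_size", 3)
        if cp.has_section("scope"):
            c = cp["scope"]
            kwargs["scope"] = model_select.ScopeConfig(
                classes=tuple(c.get("classes",
                                    ",".join(model_select.DEFAULT_CLASSES)
                                    ).split(",")),
                organisms=tuple(c.get("organisms",
                                      ",".join(model_select.DEFAULT_ORGANISMS)
                                      ).split(",")),
                reference=c.get("reference", "Homo sapiens"))
        if cp.has_section("pipeline"):
            kwargs["seed"] = cp["pipeline"].getint("seed", 0)
            kwargs["log_level"] = cp["pipeline"].get("log_level", "INFO")
        return cls(**kwargs)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    survivors: list
    traces: list
    tree: object
    labels: dict
    annotations: list
    annotation_report: classify.AnnotationReport
    proximity: model_select.ProximityReport
    topological: model_select.ProximityReport
    out_dir: Path


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and persist every artifact.

    Any stage error aborts with the failing stage's name; artifacts already
    produced stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                           "%(name)s %(message)s"))
    root_logger = logging.getLogger("mmphylo")
    root_logger.addHandler(handler)
    root_logger.setLevel(config.log_level)

    stage = "read_inputs"
    try:
        records = seqio.read_fasta(config.fasta, dialect="uniprot")
        hits = seqio.read_domain_hits(config.domain_hits)
        logger.info("read %d records, %d domain hits", len(records), len(hits))

        stage = "curate"
        survivors, traces = curation.run_curation(records, hits,
                                                  config.curation)
        for trace, kept in _stage_snapshots(records, survivors, traces):
            seqio.write_fasta(kept, out / f"stage_{trace.stage}.fasta")
        seqio.write_report(curation.stage_stats_table(traces),
                           out / "stage_stats.tsv", kind="stage_stats")
        logger.info("curation: %s",
                    " -> ".join(str(t.n_out) for t in traces))

        stage = "tree"
        survivor_ids = [r.seq_id for r in survivors]
        if config.tree is not None:
            tree = seqio.read_newick(config.tree)
        else:
            aln_records = seqio.read_fasta(config.alignment, dialect="uniprot")
            aln = phylo.Alignment.from_records(aln_records).subset(survivor_ids)
            dm = phylo.p_distance(aln)
            tree = phylo.nj_tree(dm)
        seqio.write_newick(tree, out / "tree_unrooted.nwk")

        stage = "root"
        rooted = phylo.root_with_outgroup(tree, config.outgroup)
        seqio.write_newick(rooted, out / "tree_rooted.nwk")

        stage = "annotate"
        by_id = {r.seq_id: r for r in records}
        prior = {l.taxon.label: classify.label_from_description(
                     by_id[l.taxon.label].description
                     if l.taxon.label in by_id else "")
                 for l in rooted.leaf_node_iter()}
        labels, annotations, report = classify.annotate(
            rooted, prior, k=config.vote_k, f=config.vote_f,
            min_class_size=config.min_class_size, outgroup=config.outgroup)
        classify.write_leaf_table(annotations, out / "leaf_annotations.tsv")
        seqio.write_report(report.table(), out / "annotation_report.tsv",
                           kind="annotation")
        classify.write_color_strip(labels, out / "itol_color_strip.txt")

        stage = "proximity"
        leaves = [model_select.LeafInfo(
                      seq_id=s, label=l,
                      organism=by_id[s].organism if s in by_id else None)
                  for s, l in labels.items() if s != config.outgroup]
        prox = model_select.organism_proximity(rooted, leaves, config.scope)
        topo = model_select.topological_proximity(rooted, leaves, config.scope)
        seqio.write_report(prox.table(), out / "proximity_patristic.tsv",
                           kind="proximity")
        seqio.write_report(topo.table(), out / "proximity_topological.tsv",
                           kind="proximity")

        stage = "manifest"
        manifest = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": config.seed,
            "inputs": {k: {"path": str(v), "sha256": _sha256(v)}
                       for k, v in (("fasta", config.fasta),
                                    ("domain_hits", config.domain_hits),
                                    ("alignment", config.alignment),
                                    ("tree", config.tree)) if v},
            "curation": {"window": config.curation.window,
                         "min_families": config.curation.min_families,
                         "dedup_mode": config.curation.dedup_mode},
            "classify": {"k": config.vote_k, "f": config.vote_f,
                         "min_class_size": config.min_class_size},
            "scope": {"classes": list(config.scope.classes),
                      "organisms": list(config.scope.organisms),
                      "reference": config.scope.reference},
            "stage_counts": {t.stage: t.n_out for t in traces},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        logger.error("aborting at stage %r: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        root_logger.removeHandler(handler)
        handler.close()

    return PipelineResult(survivors=survivors, traces=traces, tree=rooted,
                          labels=labels, annotations=annotations,
                          annotation_report=report, proximity=prox,
                          topological=topo, out_dir=out)


def _stage_snapshots(records, survivors, traces):
    """Record subsets after each real curation stage, in trace order."""
    alive = {r.seq_id for r in records}
    for trace in traces:
        if trace.stage == "input":
            continue
        alive -= set(trace.removed)
        yield trace, [r for r in records if r.seq_id in alive]
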