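"""Three-step curation cascade: length window, domain architecture, dedup.

Protein-family downloads from UniProt mix full-length entries with
fragments, redundant records and mis-annotated sequences. The cascade keeps
sequences whose length lies within a window around the mean, whose
conserved-domain architecture shows at least ``min_families`` of the four
diagnostic MMP domain families, and which are not exact duplicates of a
retained sequence. Each stage emits a trace with summary statistics and
per-sequence removal reasons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqio import DOMAIN_FAMILIES, DomainHit, SequenceRecord

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    """Length summary of a record set (sample sd, n-1 denominator)."""

    n: int
    min_len: int
    max_len: int
    mean_len: float
    sd_len: float


@dataclass
class StageTrace:
    """Audit record of one curation stage."""

    stage: str
    n_in: int
    n_out: int
    stats: SummaryStats
    removed: dict[str, str] = field(default_factory=dict)  # seq_id -> reason

    def __post_init__(self) -> None:
        assert self.n_out <= self.n_in
        assert self.n_out + len(self.removed) == self.n_in, (
            f"{self.stage}: {self.n_out} survivors + {len(self.removed)} "
            f"removed != {self.n_in} inputs")


def compute_length_stats(records: list[SequenceRecord]) -> SummaryStats:
    """Min/max/mean/sd of ungapped sequence lengths at full precision."""
    if not records:
        raise ValueError("cannot summarise an empty record set")
    lengths = [r.length for r in records]
    n = len(lengths)
    mean = math.fsum(lengths) / n
    if n > 1:
        sd = math.sqrt(math.fsum((l - mean) ** 2 for l in lengths) / (n - 1))
    else:
        sd = 0.0
    return SummaryStats(n=n, min_len=min(lengths), max_len=max(lengths),
                        mean_len=mean, sd_len=sd)


def filter_by_length(records: list[SequenceRecord], window: float = 0.5,
                     ) -> tuple[list[SequenceRecord], StageTrace]:
    """Keep sequences with length within ``window`` of the mean length.

    The window is ``[(1-window)*mean, (1+window)*mean]``, bounds inclusive,
    with the mean computed on the full input at full precision.
    """
    if not records:
        raise ValueError("no records to filter")
    if not 0 < window < 1:
        raise ValueError(f"window must lie in (0, 1), got {window}")
    mean = compute_length_stats(records).mean_len
    lo, hi = (1 - window) * mean, (1 + window) * mean
    kept, removed = [], {}
    for rec in records:
        if lo <= rec.length <= hi:
            kept.append(rec)
        else:
            side = "below" if rec.length < lo else "above"
            removed[rec.seq_id] = (f"length {rec.length} {side} window "
                                   f"[{lo:.2f}, {hi:.2f}]")
    if not kept:
        raise ValueError(
            f"length filter removed all {len(records)} records "
            f"(window [{lo:.2f}, {hi:.2f}])")
    trace = StageTrace(stage="length_filter", n_in=len(records),
                       n_out=len(kept), stats=compute_length_stats(kept),
                       removed=removed)
    return kept, trace


def filter_by_domains(records: list[SequenceRecord], hits: list[DomainHit],
                      min_families: int = 3,
                      ) -> tuple[list[SequenceRecord], StageTrace]:
    """Keep sequences showing at least ``min_families`` distinct diagnostic
    domain families (matrixin, hemopexin, pg_binding, fibronectin).

    Hits against CDD models outside the family map (family ``other``) never
    count; hits whose seq_id matches no record are logged and ignored.
    """
    if min_families > len(DOMAIN_FAMILIES):
        raise ValueError(
            f"min_families={min_families} is unsatisfiable: only "
            f"{len(DOMAIN_FAMILIES)} diagnostic families exist")
    known = {r.seq_id for r in records}
    families: dict[str, set[str]] = {}
    dangling = 0
    for h in hits:
        if h.seq_id not in known:
            dangling += 1
            continue
        if h.family != "other":
            families.setdefault(h.seq_id, set()).add(h.family)
    if dangling:
        logger.warning("%d domain hits reference unknown sequences; ignored",
                       dangling)
    kept, removed = [], {}
    for rec in records:
        fams = families.get(rec.seq_id, set())
        if len(fams) >= min_families:
            kept.append(rec)
        else:
            removed[rec.seq_id] = (
                f"{len(fams)} distinct domain families "
                f"({', '.join(sorted(fams)) or 'none'}) < {min_families}")
    stats = compute_length_stats(kept) if kept else SummaryStats(0, 0, 0, 0.0, 0.0)
    trace = StageTrace(stage="domain_filter", n_in=len(records),
                       n_out=len(kept), stats=stats, removed=removed)
    return kept, trace


def deduplicate(records: list[SequenceRecord], mode: str = "exact",
                ) -> tuple[list[SequenceRecord], StageTrace]:
    """Remove 100%-identity duplicates.

    ``exact`` keeps, among records with identical residue strings
    (case-insensitive), the one with the lexicographically smallest
    accession. ``substring`` additionally removes records whose residues are
    a proper substring of a kept record's. Output order follows input order
    of the survivors, so the result is independent of input permutation.
    """
    if not records:
        raise ValueError("no records to deduplicate")
    if mode not in ("exact", "substring"):
        raise ValueError(f"unknown dedup mode: {mode!r}")
    groups: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        groups.setdefault(rec.ungapped.upper(), []).append(rec)
    removed: dict[str, str] = {}
    rep_of: dict[str, SequenceRecord] = {}
    for residues, members in groups.items():
        rep = min(members, key=lambda r: r.accession)
        rep_of[residues] = rep
        for m in members:
            if m is not rep:
                removed[m.seq_id] = f"duplicate of {rep.accession}"
    if mode == "substring":
        reps = sorted(rep_of.values(), key=lambda r: -len(r.ungapped))
        eliminated: set[str] = set()
        for rec in reps:
            if rec.seq_id in eliminated:
                continue
            for other in reps:
                if other is rec or other.seq_id in eliminated:
                    continue
                if len(other.ungapped) < len(rec.ungapped) and \
                        other.ungapped in rec.ungapped:
                    removed[other.seq_id] = f"substring of {rec.accession}"
                    eliminated.add(other.seq_id)
    kept = [r for r in records if r.seq_id not in removed]
    trace = StageTrace(stage="deduplicate", n_in=len(records),
                       n_out=len(kept), stats=compute_length_stats(kept),
                       removed=removed)
    return kept, trace


@dataclass
class CurationParams:
    window: float = 0.5
    min_families: int = 3
    dedup_mode: str = "exact"


def run_curation(records: list[SequenceRecord], hits: list[DomainHit],
                 params: CurationParams | None = None,
                 ) -> tuple[list[SequenceRecord], list[StageTrace]]:
    """Apply the cascade in fixed order: length -> domains -> dedup.

    Returns the surviving records and four traces (an input pseudo-stage
    plus one per filter), mirroring the four-row stage-statistics table.
    """
    params = params or CurationParams()
    traces = [StageTrace(stage="input", n_in=len(records), n_out=len(records),
                         stats=compute_length_stats(records))]
    kept, t1 = filter_by_length(records, window=params.window)
    traces.append(t1)
    kept, t2 = filter_by_domains(kept, hits, min_families=params.min_families)
    traces.append(t2)
    kept, t3 = deduplicate(kept, mode=params.dedup_mode)
    traces.append(t3)
    return kept, traces


def stage_stats_table(traces: list[StageTrace]) -> list[dict]:
    """Rows for :func:`mmphylo.seqio.write_report` with kind=stage_stats."""
    return [{"stage": t.stage, "n": t.stats.n, "min": t.stats.min_len,
             "max": t.stats.max_len, "mean": t.stats.mean_len,
             "sd": t.stats.sd_len} for t in traces]
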