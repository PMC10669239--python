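# Methods

This note documents the models, parameter choices and numerical
conventions behind `mmphylo`, and what the synthetic experiments do and do
not demonstrate about real data.

## Curation cascade

Three filters run in fixed order, each exactly once, with full audit
traces (survivors + per-sequence removal reasons; the two always sum to
the stage input, asserted on every run).

**Length window.** A sequence is kept iff
`(1−w)·mean ≤ length ≤ (1+w)·mean` with `w = 0.5` by default, bounds
inclusive, where the mean is computed over the *full input* at full
floating-point precision (never a rounded display value). Gaps are
excluded from lengths. Rationale for inclusivity: the filter is a window
around a continuous statistic; which convention the boundary cases follow
is immaterial in practice but must be fixed for reproducibility.

**Domain-architecture filter.** A sequence is kept iff its conserved-
domain hits cover ≥3 *distinct* families among {pg_binding, matrixin,
hemopexin, fibronectin}; repeated hits within a family count once, and
hits against CDD models outside the family map (`family = other`) never
count. Counting distinct families rather than raw hits is the reading
consistent with matrilysins (pro-domain + catalytic only, i.e. two
families) being excluded by the rule, which the field's domain literature
describes. The CDD identifier sets are frozen constants (9 matrixin + 2
hemopexin + 1 pg_binding + 1 fibronectin, pairwise disjoint, asserted at
import).

**Duplicate removal.** "100% identity" is implemented as exact
full-length residue equality, case-insensitive, gaps ignored. Among
identical records the lexicographically smallest accession is kept, so
output is independent of input order. A `substring` mode additionally
absorbs records that are proper substrings of a kept record (what
CD-HIT at threshold 1.0 would also remove); it is off by default because
exact mode is deterministic and auditable.

Summary statistics use the sample standard deviation (n−1 denominator;
0 when n = 1). Report tables display mean/sd rounded to the nearest
integer (half away from zero); full precision is retained internally.

## Distances and trees

* **p-distance** with pairwise deletion: mismatches over columns where
  both rows carry an unambiguous residue. `X`, `B`, `Z`, gaps and dots are
  treated as missing; `U` (selenocysteine) is folded into `C` so the
  20-state model stays closed. Pairwise deletion (rather than complete
  deletion) is robust to ragged fragments and is standard practice.
* **Distance correction** for the 20-state Poisson model:
  `d = −(19/20)·ln(1 − (20/19)·p)`, defined on `0 ≤ p < 19/20`, used in
  property tests to invert simulated divergences. The pipeline's NJ runs
  on raw p-distances; NJ only needs a monotone dissimilarity and raw
  p-distances avoid saturation blow-ups near the outgroup.
* **Neighbor joining**: Saitou–Nei agglomeration with the
  Studier–Keppler Q criterion. Determinism is part of the contract: the
  Q minimum is taken in row-major (row, column) order, and negative
  branch-length estimates are clamped to 0 without redistribution
  (simplicity; preserves the non-negativity invariant). NJ is provably
  consistent on additive matrices, which the test suite exercises over
  random binary trees; scikit-bio's independent NJ implementation serves
  as a cross-check oracle in the tests.
* **Rooting** places the root at the midpoint of the outgroup's pendant
  edge; patristic distances between leaves are unchanged by rooting
  (tested). Maximum-likelihood inference and bootstrap support are out of
  scope — imported newick trees carry their support values through
  unmodified, and the import path is the intended route for
  Mafft/FastTree results.

## Clade-vote annotation

The manual step of reading clade colors off a rendered tree is formalized
as a k-nearest-ancestral-leaf vote. For a query leaf, ancestors are walked
from the parent toward the root; at each step all newly subtended leaves
with *concrete* prior labels join the electorate (the query itself, the
outgroup, and GENERIC/UNASSIGNED leaves never vote) until ≥k votes are
collected or the root is reached. The modal class wins; exact ties win
nothing.

Rules applied in a single pass against prior labels only (no cascading,
so the outcome is independent of leaf iteration order, tested by
permutation):

* prior GENERIC/UNASSIGNED + vote fraction ≥ f → **class annotation**;
* prior concrete ≠ winner + fraction ≥ f → **reannotation**, unless the
  prior class has ≤ `min_class_size` members, in which case the leaf is
  only **flagged** (rare-class protection: a genuine singleton class such
  as MMP-18 must never be absorbed by its surrounding clade);
* otherwise unchanged.

Defaults `k = 10`, `f = 0.8`, `min_class_size = 3` are exposed in the
config. `f = 0.8` demands a clearly dominant class rather than a mere
plurality; raising `f` can only reduce the number of changes (monotone,
tested). Generic labels are recognized by an explicit MMP-N token parse
first, then a case-insensitive keyword list {zinc, metalloproteinase,
metallopeptidase, matrix, uncharacterized}.

Label-flow conservation (`total_final = total_prior + inflow − outflow`
per class) is asserted on every run.

## Model-organism proximity

Scope defaults to the collagenases (MMP-1/8/13) and gelatinases (MMP-2/9)
over the seven organisms used in dentistry research, with *Homo sapiens*
as reference. Organism strings are matched case-insensitively on the
binomial, folding subspecies epithets ("Canis lupus familiaris" → "Canis
lupus").

Per class, an organism's proximity is the **minimum** patristic distance
over all (organism leaf, reference leaf) pairs within the class — a single
closest ortholog pair is the natural reading of "closest organism";
average linkage is deliberately not the default. Distances within
`rel_tol = 1e-9` share a tie-group (competition) rank. Organisms with no
sequence in a class are listed as absent, never dropped; a class without
reference leaves is reported non-rankable rather than raising. A secondary
topological criterion counts path edges on the class subtree; when the two
criteria disagree the reports simply disagree — no reconciliation is
attempted. Rankings are invariant under uniform branch scaling and under
adding leaves of unscoped classes (both tested).

## Synthetic data generator

The generator emulates the statistical structure of a curated family
download, not its biology in full.

* **Species tree**: a fixed clock-like 7-taxon mammal tree
  (primate + Glires clade vs. Laurasiatheria) with depths of order 0.2
  substitutions/site. Per class, the designated *planted nearest* species
  is regrafted as sister to the reference on 0.02-length branches, so the
  expected closest organism per class is controlled and known. Branch
  lengths are scaled by a per-class rate multiplier (cycling 0.8/1.0/1.25
  by default) and per-branch log-normal jitter (σ = 0.1) — enough rate
  realism to perturb estimates without breaking the planted ordering in
  expectation.
* **Within-species duplication**: each species leaf expands into
  `leaves_per = 3` tips on 0.02-length branches. The branch is short but
  not negligible: it keeps independently evolved gene copies from
  colliding into accidental 100%-identity pairs, and any residual
  collision is resolved by a single forced substitution so that the
  manifest's duplicate list is exhaustive by construction.
* **Sequences**: 450 sites (the order of a curated MMP mean length minus
  signal peptide), evolved site-independently under the 20-state Poisson
  model from a family root, through class roots at divergence 0.8. No
  indels, no site-rate heterogeneity, no empirical exchangeability matrix
  (all deliberate non-goals) — hence the "true alignment" is the identity
  alignment, with gaps only from fragment corruption and outgroup
  padding.
* **Domain architectures**: pro-domain (residues 10–85), catalytic
  (100–265), hemopexin (290–445); gelatinases add three fibronectin
  repeats inside the catalytic domain; matrilysin-like distractor classes
  (MMP-7/26) carry only the first two families and are therefore removed
  by the ≥3-family rule — at full length, so it is the domain filter, not
  the length filter, that removes them.
* **Corruption**: fragments truncate to a uniform 10–40% span (always
  below the 50% length window given the near-constant full length);
  duplicates copy a non-fragment record under a lexicographically later
  accession (so the original is the retained representative); mislabels
  swap the description's class token; generic labels substitute a phrase
  from the generic-keyword family. All flags land in a manifest covering
  every record exactly once, from which the exact per-stage survivor
  counts follow.
* **Outgroup**: the complete Archaeal interstitial-collagenase-like
  sequence (tr|A0A087RZB5, 344 aa) ships verbatim and is appended to
  every dataset; it receives a three-family hit table so it survives
  curation and is available for rooting.

Everything is driven by one `numpy` Generator seeded explicitly;
regeneration under the same seed is byte-identical (tested).

## Validation experiments and problem sizes

The acceptance experiments (mirrored in `scripts/acceptance.py`) use these
sizes, chosen to give tight statistics at interactive runtimes on one CPU:

* curation accounting: one dataset at full defaults (21 classes + 2
  distractors × 7 organisms × 3 leaves ≈ 505 records + corruption);
* NJ consistency: 200 random binary trees, 5–12 leaves, branch lengths
  U[0.05, 2];
* patristic oracle: 100 random trees ≤ 20 leaves vs. a branch-weighted
  Dijkstra oracle (networkx), tolerance 1e-12;
* substitution closure: 10,000 sites at μt ∈ {0.1, 0.5, 1.0}, 3 binomial
  standard errors;
* mislabel recovery: 50 seeds of the direct labeled-tree simulator
  (8 classes × 30 leaves, clade separation 5× intra-clade depth, 5%
  mislabels, 10% generic);
* planted-organism recovery: 100 full simulate→curate→NJ→root→annotate→
  rank replicates over the five scoped classes plus the stromelysins and
  a matrilysin distractor (≈ 190 ingroup leaves per replicate).

## Known limitations

* The clade vote measures *local label consensus*. When corruption
  concentrates in one class by chance (e.g. 5 of 21 leaves of a small
  class mislabeled in one seed), clean neighbors may not reach the 0.8
  threshold and those mislabels are left unchanged — visibly, with their
  vote fractions in the leaf table. At realistic class sizes (hundreds of
  leaves, few-percent corruption) this concentration is rare.
* Passing recovery tests on simulator output demonstrates the machinery,
  not real-data performance: real downloads have indels, domain shuffling,
  alignment error and non-clock rate variation that the generator omits.
* The bundled tree is distance-based (NJ). For publication-grade trees an
  external ML tool should be used and its newick imported.
* Proximity rankings state tree distances only; they are not a claim of
  biological suitability of any animal model.
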