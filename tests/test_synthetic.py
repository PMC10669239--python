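"""The gene-family simulator: evolution model, architectures, corruption."""

import filecmp
import math

import dendropy
import numpy as np
import pytest

from mmphylo.phylo import Alignment, p_distance
from mmphylo.seqio import CONCRETE_CLASSES
from mmphylo.synthetic import (OUTGROUP_ID, SimParams, evolve_sequence,
                               generate_dataset, random_root_sequence,
                               simulate_labeled_tree)


class TestEvolveSequence:
    def test_zero_branch_is_identity(self):
        rng = np.random.default_rng(0)
        parent = random_root_sequence(200, rng)
        assert evolve_sequence(parent, 0.0, 1.0, rng) == parent

    def test_negative_branch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            evolve_sequence("MKL", -0.1, 1.0, rng)

    def test_mismatch_fraction_matches_model(self):
        # p(t) = 0.95 (1 - exp(-(20/19) mu t)) at mu*t = 0.5, 10k sites
        rng = np.random.default_rng(3)
        parent = random_root_sequence(10_000, rng)
        child = evolve_sequence(parent, 0.5, 1.0, rng)
        observed = sum(a != b for a, b in zip(parent, child)) / 10_000
        p = 0.95 * (1 - math.exp(-10 / 19))
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(observed - p) < 3 * se

    def test_saturation_limit(self):
        rng = np.random.default_rng(4)
        parent = random_root_sequence(10_000, rng)
        child = evolve_sequence(parent, 50.0, 1.0, rng)
        observed = sum(a != b for a, b in zip(parent, child)) / 10_000
        assert observed == pytest.approx(0.95, abs=0.01)


class TestGenerateDataset:
    def test_identical_seeds_identical_files(self, tmp_path):
        params = SimParams(classes=("MMP-1", "MMP-2"), leaves_per=2)
        generate_dataset(params, seed=9, out_dir=tmp_path / "a")
        generate_dataset(params, seed=9, out_dir=tmp_path / "b")
        for name in ("sequences.fasta", "domain_hits.tsv", "alignment.fasta",
                     "truth_manifest.tsv", "planted_nearest.tsv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_different_seeds_differ(self):
        params = SimParams(classes=("MMP-1",), leaves_per=1)
        r1, _, _ = generate_dataset(params, seed=1)
        r2, _, _ = generate_dataset(params, seed=2)
        assert r1[0].residues != r2[0].residues

    def test_default_dataset_covers_all_21_classes(self, default_dataset):
        records, _, truth = default_dataset
        present = {t.true_class for t in truth.records.values()}
        assert set(CONCRETE_CLASSES) <= present

    def test_outgroup_appended_verbatim(self, default_dataset):
        records, _, _ = default_dataset
        assert records[-1].seq_id == OUTGROUP_ID
        assert records[-1].taxid == 1502295

    def test_manifest_covers_every_record_exactly_once(self, default_dataset):
        records, _, truth = default_dataset
        assert {r.seq_id for r in records} == set(truth.records)
        assert len(records) == len(truth.records)


class TestDomainArchitectures:
    def test_gelatinases_carry_fibronectin_repeats(self, default_dataset):
        records, hits, truth = default_dataset
        by_seq = {}
        for h in hits:
            by_seq.setdefault(h.seq_id, []).append(h)
        for t in truth.records.values():
            if t.group == "gelatinase" and t.fragment_span is None:
                fams = {h.family for h in by_seq[t.seq_id]}
                assert fams == {"pg_binding", "matrixin", "hemopexin",
                                "fibronectin"}
                fib = [h for h in by_seq[t.seq_id]
                       if h.family == "fibronectin"]
                assert len(fib) == 3

    def test_matrilysin_distractors_have_two_families(self, default_dataset):
        records, hits, truth = default_dataset
        by_seq = {}
        for h in hits:
            by_seq.setdefault(h.seq_id, []).append(h)
        checked = 0
        for t in truth.records.values():
            if t.group == "matrilysin" and t.fragment_span is None:
                fams = {h.family for h in by_seq[t.seq_id]}
                assert fams == {"pg_binding", "matrixin"}
                checked += 1
        assert checked > 0

    def test_fragments_keep_only_contained_hits(self, default_dataset):
        records, hits, truth = default_dataset
        lengths = {r.seq_id: r.length for r in records}
        frag_ids = {t.seq_id for t in truth.records.values()
                    if t.fragment_span is not None}
        assert frag_ids
        for h in hits:
            if h.seq_id in frag_ids:
                assert 1 <= h.qstart <= h.qend <= lengths[h.seq_id]


class TestCorruption:
    def test_all_rates_zero_is_clean(self):
        params = SimParams(classes=("MMP-1", "MMP-2"), leaves_per=2,
                           fragment_rate=0, duplicate_rate=0,
                           mislabel_rate=0, generic_label_rate=0)
        records, _, truth = generate_dataset(params, seed=5)
        for t in truth.records.values():
            assert t.fragment_span is None and t.duplicate_of is None
            assert t.mislabeled_as is None and not t.generic_labeled

    def test_duplicate_rate_one_doubles_the_ingroup(self):
        params = SimParams(classes=("MMP-1",), leaves_per=2,
                           fragment_rate=0, duplicate_rate=1.0,
                           mislabel_rate=0, generic_label_rate=0)
        records, _, truth = generate_dataset(params, seed=5)
        n_base = 2 * 7  # leaves_per x organisms
        dups = [t for t in truth.records.values() if t.duplicate_of]
        assert len(records) == 2 * n_base + 1  # + outgroup
        assert len(dups) == n_base

    def test_fragments_fall_below_the_length_window(self, default_dataset):
        records, _, truth = default_dataset
        from mmphylo.curation import compute_length_stats
        mean = compute_length_stats(records).mean_len
        for r in records:
            if truth.records[r.seq_id].fragment_span is not None:
                assert r.length < 0.5 * mean

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            SimParams(fragment_rate=1.5)


class TestRateStructure:
    def test_faster_class_has_larger_intra_class_divergence(self):
        """Per-class rate multipliers show up as larger p-distances."""
        wins = 0
        for seed in range(20):
            params = SimParams(classes=("MMP-1", "MMP-2"), leaves_per=2,
                               class_rate_multipliers=(1.0, 3.0),
                               fragment_rate=0, duplicate_rate=0,
                               mislabel_rate=0, generic_label_rate=0)
            records, _, truth = generate_dataset(params, seed=100 + seed)
            aln = Alignment.from_records(
                [r for r in records if r.seq_id != OUTGROUP_ID])
            d = p_distance(aln)

            def mean_intra(cls):
                ids = [i for i, r in enumerate(aln.ids)
                       if truth.records[r].true_class == cls]
                vals = [d.values[i, j] for i in ids for j in ids if i < j]
                return float(np.mean(vals))

            if mean_intra("MMP-2") > mean_intra("MMP-1"):
                wins += 1
        assert wins >= 18

    def test_planted_species_nearest_in_true_gene_tree(self, default_dataset):
        from mmphylo.phylo import leaf_distance_matrix

        _, _, truth = default_dataset
        for cls in ("MMP-1", "MMP-13", "MMP-2"):
            tree = dendropy.Tree.get(data=truth.gene_trees[cls],
                                     schema="newick",
                                     preserve_underscores=True)
            dm = leaf_distance_matrix(tree)
            ref = [i for i in dm.ids
                   if truth.records[i].organism == "Homo sapiens"]
            best_org, best_d = None, np.inf
            for i in dm.ids:
                org = truth.records[i].organism
                if org == "Homo sapiens":
                    continue
                d = min(dm.get(i, r) for r in ref)
                if d < best_d:
                    best_org, best_d = org, d
            assert best_org == truth.planted_nearest[cls]


class TestLabeledTreeSimulator:
    def test_classes_form_separated_clades_with_known_truth(self):
        rng = np.random.default_rng(17)
        tree, prior, truth = simulate_labeled_tree(rng, n_classes=4,
                                                   leaves_per_class=10)
        assert len(prior) == 40
        kinds = {k for _, k in truth.values()}
        assert kinds <= {"clean", "mislabel", "generic"}
        for name, (cls, kind) in truth.items():
            if kind == "mislabel":
                assert prior[name].mmp != cls and prior[name].is_concrete
            elif kind == "generic":
                assert not prior[name].is_concrete
            else:
                assert prior[name].mmp == cls
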