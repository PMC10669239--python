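#!/usr/bin/env python
"""Build and root the family phylogeny for the curated sequences.

Bundled path: p-distances on the true alignment restricted to curation
survivors, neighbor joining, then rooting at the midpoint of the Archaeal
outgroup's pendant edge. (With real data, an externally computed
Mafft/FastTree newick can be imported here instead.) Writes the unrooted
and rooted trees under results/tree/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mmphylo import phylo, seqio
from mmphylo.synthetic import OUTGROUP_ID

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "tree"


def main() -> None:
    kept = seqio.read_fasta(ROOT / "curation" / "curated.fasta")
    aln_records = seqio.read_fasta(ROOT / "dataset" / "alignment.fasta")
    aln = phylo.Alignment.from_records(aln_records).subset(
        [r.seq_id for r in kept])
    dm = phylo.p_distance(aln)
    tree = phylo.nj_tree(dm)
    rooted = phylo.root_with_outgroup(tree, OUTGROUP_ID)
    OUT.mkdir(parents=True, exist_ok=True)
    seqio.write_newick(tree, OUT / "tree_unrooted.nwk")
    seqio.write_newick(rooted, OUT / "tree_rooted.nwk")
    print(f"neighbor-joining tree on {aln.n_rows} leaves "
          f"({aln.n_cols} alignment columns)")
    print(f"rooted on outgroup {OUTGROUP_ID}")
    print(f"trees -> {OUT}")


if __name__ == "__main__":
    main()
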