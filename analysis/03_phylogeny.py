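"""NJ tree over the 71 Arabidopsis + rice CC-TPR proteins with bootstrap.

Uses the concatenated three-motif alignment (102 columns) packaged with the
fixtures, so no alignment program is needed. 100 column-bootstrap replicates
keep this a desk-scale run; topology is exploratory (the original figure used
full-length Clustal X alignments) but known ortholog pairs such as
AtTPR1/Os10g34540 are expected to pair up.
"""
from pathlib import Path

from cctpr.phylo import bootstrap_support, concatenated_motif_alignment
from cctpr.seqio import load_arabidopsis_motifs, load_rice_motifs, \
    write_newick

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_REPLICATES = 100
SEED = 20100915


def main() -> None:
    rows = [r for r in load_arabidopsis_motifs() + load_rice_motifs()
            if not r.is_reference]
    alignment = concatenated_motif_alignment(rows)
    tree = bootstrap_support(alignment, n_replicates=N_REPLICATES, seed=SEED)
    write_newick(tree, OUT / "cctpr_tree.nwk")
    print(f"{len(tree.leaf_names())} leaves, {N_REPLICATES} bootstrap "
          f"replicates (seed {SEED}) -> results/cctpr_tree.nwk")
    parts = {frozenset(p) for p in tree.bipartitions()}
    pair = frozenset({"AtTPR1", "Os10g34540"})
    print("AtTPR1/Os10g34540 recovered as sisters:", pair in parts)


if __name__ == "__main__":
    main()
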