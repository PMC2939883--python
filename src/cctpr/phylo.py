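"""Distance-based phylogeny of CC-TPR proteins: NJ trees with bootstrap.

Distances are p-distances (proportion of differing aligned non-gap columns),
from pairwise global alignment of full-length sequences (BLOSUM62, affine
gaps) or directly from a supplied fixed-length alignment such as the
concatenated three-motif alignment (3 x 34 = 102 columns). Trees are built
with neighbor joining; internal-branch support comes from bootstrap
resampling of alignment columns, counting how often each bipartition of the
point-estimate tree recurs among replicate trees.

The source procedure aligned full-length proteins with Clustal X and drew an
NJ tree with 1000 bootstrap replicates; this module mirrors that procedure at
desk scale without claiming the original topology, which depends on the
progressive-alignment program.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import skbio
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    MatrixError,
    RaggedAlignmentError,
    UndefinedDistanceError,
)

GAP_CHARS = frozenset("-.")

#: Pairwise-alignment defaults (documented, not inferred from the source
#: procedure, which does not state its parameters).
ALIGN_DEFAULTS = {"matrix": "BLOSUM62", "open_gap": -10.0, "extend_gap": -0.5}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labeled proteins."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise MatrixError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise MatrixError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise MatrixError("matrix diagonal is not zero")
        if np.any(v < 0):
            raise MatrixError("matrix has negative entries")


@dataclass
class PhyloTree:
    """A tree with named leaves, branch lengths and optional supports.

    Wraps an skbio ``TreeNode``; internal node names hold integer bootstrap
    supports after :func:`bootstrap_support`.
    """

    tree: skbio.TreeNode
    n_replicates: int | None = None
    seed: int | None = None

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def tip_distances(self) -> DistanceMatrix:
        dm = self.tree.tip_tip_distances()
        return DistanceMatrix(labels=tuple(dm.ids),
                              values=np.asarray(dm.data, dtype=float))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        leaves = frozenset(self.leaf_names())
        anchor = min(leaves)
        parts: set[frozenset[str]] = set()
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(leaves - side) < 2:
                continue
            if anchor in side:
                side = leaves - side
            parts.add(side)
        return parts


def _aligner(params: Mapping | None = None) -> Align.PairwiseAligner:
    p = dict(ALIGN_DEFAULTS)
    if params:
        p.update(params)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(p["matrix"])
    aligner.open_gap_score = p["open_gap"]
    aligner.extend_gap_score = p["extend_gap"]
    return aligner


def pairwise_distance(a: str, b: str, params: Mapping | None = None) -> float:
    """p-distance from one global pairwise alignment.

    distance = 1 - identities / aligned non-gap columns.
    """
    if not a or not b:
        raise UndefinedDistanceError("empty sequence")
    if b < a:  # canonical orientation: co-optimal alignments can differ
        a, b = b, a  # between (a,b) and (b,a); this keeps d symmetric
    aligner = _aligner(params)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        raise UndefinedDistanceError("no aligned non-gap columns")
    return 1.0 - counts.identities / aligned


def distance_matrix_from_sequences(
    named_seqs: Sequence[tuple[str, str]], params: Mapping | None = None
) -> DistanceMatrix:
    """All-vs-all p-distances from pairwise global alignments."""
    labels = tuple(n for n, _ in named_seqs)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(named_seqs[i][1], named_seqs[j][1], params)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def _check_alignment(rows: Sequence[tuple[str, str]]) -> int:
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise RaggedAlignmentError(f"row lengths differ: {sorted(lengths)}")
    return lengths.pop()


def distance_matrix_from_alignment(
    rows: Sequence[tuple[str, str]],
    columns: np.ndarray | None = None,
) -> DistanceMatrix:
    """p-distances over alignment columns (optionally a resampled subset).

    Columns where either sequence has a gap or X are skipped pairwise; a pair
    with no comparable columns gets the maximal distance 1.
    """
    _check_alignment(rows)
    labels = tuple(n for n, _ in rows)
    mats = np.array([list(s) for _, s in rows])
    if columns is not None:
        mats = mats[:, columns]
    ok = ~(np.isin(mats, list(GAP_CHARS | {"X"})))
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                d = 1.0
            else:
                d = float((mats[i, both] != mats[j, both]).sum()) / m
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Standard neighbor joining; negative branch lengths clamped to zero."""
    n = len(d.labels)
    if n < 2:
        raise MatrixError("need at least 2 taxa")
    if n == 2:
        half = d.values[0, 1] / 2.0
        tree = skbio.TreeNode.read(
            io.StringIO(f"({d.labels[0]}:{half},{d.labels[1]}:{half});")
        )
        return PhyloTree(tree=tree)
    dm = skbio.DistanceMatrix(d.values, ids=list(d.labels))
    tree = skbio.tree.nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return PhyloTree(tree=tree)


def bootstrap_support(
    rows: Sequence[tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ point-estimate tree with column-bootstrap supports.

    Columns are resampled with replacement per replicate; the support of each
    internal bipartition of the point tree is the number of replicate trees
    containing it. Fully seeded and reproducible.

    Degenerate case: if all pairwise distances are zero (e.g. identical rows)
    the tree carries no information; the point tree is returned with every
    support set to ``n_replicates``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    length = _check_alignment(rows)
    point_dm = distance_matrix_from_alignment(rows)
    point = neighbor_joining(point_dm)
    point.n_replicates = n_replicates
    point.seed = seed
    degenerate = bool(np.all(point_dm.values == 0))
    support: dict[frozenset[str], int] = {p: 0 for p in point.bipartitions()}
    if degenerate:
        support = {p: n_replicates for p in support}
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_replicates):
            cols = rng.integers(0, length, size=length)
            rep_dm = distance_matrix_from_alignment(rows, columns=cols)
            rep = neighbor_joining(rep_dm)
            for part in rep.bipartitions():
                if part in support:
                    support[part] += 1
    leaves = frozenset(point.leaf_names())
    anchor = min(leaves)
    for node in point.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(leaves - side) < 2:
            continue
        if anchor in side:
            side = leaves - side
        node.name = str(support[side])
    return point


def concatenated_motif_alignment(rows) -> list[tuple[str, str]]:
    """Concatenate each protein's three excised motifs into one aligned row.

    Length-anomalous (33-residue) motifs are padded with a leading gap, which
    matches their register-shift reading (first residue not excised).
    """
    from .seqio import group_by_protein

    grouped = group_by_protein(rows)
    out = []
    for name, triplet in grouped.items():
        parts = []
        for row in triplet:
            seq = row.motif_seq
            if len(seq) < 34:
                seq = "-" * (34 - len(seq)) + seq
            parts.append(seq)
        out.append((name, "".join(parts)))
    return out
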