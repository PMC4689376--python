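"""Distance-based phylogeny: p-distances, neighbor joining, bootstrap.

The tree builder is the classic Saitou-Nei neighbor-joining agglomeration
on a pairwise distance matrix.  Distances default to the uncorrected
p-distance with pairwise deletion of gapped columns; a Poisson correction
is available.  Bootstrap support is the fraction of column-resampled
replicate trees containing each internal bipartition of the point-estimate
tree.  Trees are dendropy objects and serialize to Newick.

Determinism: when two joins have equal Q score the pair whose (sorted)
cluster labels are lexicographically smallest is joined; a cluster is
labelled by the smallest taxon name it contains.  Negative branch-length
estimates are clamped to zero and counted on the returned tree
(``tree.negative_branches_clamped``).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from Bio import AlignIO

from .errors import LeaSurveyError, ParseError

_GAP = ord("-")


@dataclass
class Alignment:
    """A multiple alignment: parallel lists of taxa and equal-length rows."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.rows:
            L = len(self.rows[0])
            if L < 1 or any(len(r) != L for r in self.rows):
                raise ValueError("alignment rows must share a positive length")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_matrix(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.n_columns)

    def resample_columns(self, cols: Sequence[int]) -> "Alignment":
        m = self.to_matrix()[:, list(cols)]
        rows = [bytes(r).decode("ascii") for r in m]
        return Alignment(list(self.taxa), rows)


def read_alignment(path: str) -> Alignment:
    """Read an aligned FASTA or Clustal file."""
    with open(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        fmt = "fasta" if head == ">" else "clustal"
        aln = AlignIO.read(fh, fmt)
    return Alignment([rec.id for rec in aln], [str(rec.seq).upper() for rec in aln])


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


def p_distance(aln: Alignment, poisson: bool = False) -> DistanceMatrix:
    """Pairwise mismatch fraction, comparing only mutually ungapped columns.

    With ``poisson=True`` the p-distance is corrected as -ln(1 - p).
    A pair with zero comparable columns is an error.
    """
    if aln.n_taxa < 2:
        raise LeaSurveyError("need at least 2 taxa for distances")
    m = aln.to_matrix()
    ungapped = m != _GAP
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        both = ungapped[i] & ungapped[i + 1:]
        comp = both.sum(axis=1)
        zero = np.nonzero(comp == 0)[0]
        if zero.size:
            j = int(zero[0]) + i + 1
            raise LeaSurveyError(
                f"no comparable columns between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
            )
        mism = ((m[i] != m[i + 1:]) & both).sum(axis=1)
        d[i, i + 1:] = mism / comp
    d = d + d.T
    if poisson:
        if np.any(d >= 1.0):
            raise LeaSurveyError("p-distance of 1.0 cannot be Poisson-corrected")
        with np.errstate(divide="ignore"):
            d = -np.log(1.0 - d)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(aln.taxa), d)


def _new_tree(taxa: Sequence[str]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    nodes = {}
    for name in taxa:
        node = dendropy.Node(taxon=ns.new_taxon(name))
        nodes[name] = node
    return tree, nodes


def nj_build(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix (>= 3 taxa, unrooted)."""
    n0 = len(dm.taxa)
    if n0 < 3:
        raise LeaSurveyError("neighbor joining requires at least 3 taxa")
    tree, leaf_nodes = _new_tree(dm.taxa)
    # active clusters: label -> (node, pending edge length applied at join)
    labels = list(dm.taxa)
    nodes = [leaf_nodes[t] for t in dm.taxa]
    d = dm.d.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(labels) > 3:
        n = len(labels)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in ties
            if i < j
        )
        _, i, j = best
        dij = d[i, j]
        li = clamp(0.5 * dij + (r[i] - r[j]) / (2 * (n - 2)))
        lj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (d[i] + d[j] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        new_label = min(labels[i], labels[j])
        labels = [labels[k] for k in keep] + [new_label]
        nodes = [nodes[k] for k in keep] + [parent]

    # connect the last three clusters to a central degree-3 node
    (d12, d13, d23) = (d[0, 1], d[0, 2], d[1, 2])
    lens = [
        clamp(0.5 * (d12 + d13 - d23)),
        clamp(0.5 * (d12 + d23 - d13)),
        clamp(0.5 * (d13 + d23 - d12)),
    ]
    center = dendropy.Node()
    for node, ln in zip(nodes, lens):
        center.add_child(node)
        node.edge.length = ln
    tree.seed_node = center
    tree.update_bipartitions(suppress_unifurcations=False)
    tree.negative_branches_clamped = clamped
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf names.

    Each split is represented by the side NOT containing the
    lexicographically smallest taxon, so representations are comparable
    across trees on the same leaf set.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    poisson: bool = False,
) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each internal
    edge of the point tree gets ``node.support`` in [0, 1], the fraction of
    replicate trees containing its bipartition.  The point tree itself does
    not depend on the seed.
    """
    if n_reps < 1:
        raise LeaSurveyError("n_reps must be >= 1")
    if aln.n_columns == 1:
        import warnings

        warnings.warn("alignment has a single column; all replicates identical")
    point = nj_build(p_distance(aln, poisson=poisson))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(point)}
    rng = np.random.default_rng(seed)
    L = aln.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = nj_build(p_distance(aln.resample_columns(cols), poisson=poisson))
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    leaves = {lf.taxon.label for lf in point.leaf_node_iter()}
    ref = min(leaves)
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves - side)
        if side in counts:
            node.support = counts[side] / n_reps
            node.label = f"{node.support:g}"
    return point


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialize to Newick; supports (if present) appear as internal labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def read_newick(source: str, is_path: bool = False) -> dendropy.Tree:
    """Parse a Newick string (or file when ``is_path``)."""
    try:
        if is_path:
            tree = dendropy.Tree.get(
                path=source, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
    except Exception as exc:  # dendropy raises several parse error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def patristic_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths keyed by sorted name pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = pdm.patristic_distance(t1, t2)
    return out


def topology_distance_fit(
    dm: DistanceMatrix, tree: dendropy.Tree
) -> float:
    """Least-squares residual of fitting branch lengths of ``tree``'s
    topology to the distances in ``dm``.  Used by tests as an oracle."""
    taxa = dm.taxa
    index = {t: i for i, t in enumerate(taxa)}
    tree = tree.clone(depth=1)
    tree.encode_bipartitions()
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    A = np.zeros((len(pairs), len(edges)))
    leafsets = []
    for e in edges:
        leafsets.append({lf.taxon.label for lf in e.head_node.leaf_iter()})
    for row, (i, j) in enumerate(pairs):
        for col, ls in enumerate(leafsets):
            if (taxa[i] in ls) != (taxa[j] in ls):
                A[row, col] = 1.0
    b = np.array([dm.d[index[taxa[i]], index[taxa[j]]] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(np.sum((A @ x - b) ** 2))
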