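"""Distance-based phylogenetics: Poisson correction, neighbor joining, bootstrap.

The pipeline mirrors the MEGA-style workflow for protein families: columns
containing gaps or ambiguous residues are removed in full (complete
deletion), pairwise p-distances are Poisson-corrected (d = −ln(1−p), the
equal-rates correction for multiple hits), an unrooted tree is built by
Saitou–Nei neighbor joining, and supports come from a column bootstrap whose
replicate bipartitions are mapped onto the full-data tree.

Determinism: Q-criterion ties are broken by the lexicographically smallest
(row, column) index pair, and negative NJ branch-length estimates are
clamped to zero with the total deficit recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .errors import AlignmentError, BootstrapError, DistanceError
from .seqio import CANONICAL_RESIDUES, ProteinRecord

_CANONICAL = frozenset(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned rows over residues and the gap character."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    @classmethod
    def from_records(cls, records: Sequence[ProteinRecord]) -> "Alignment":
        return cls(
            ids=tuple(r.id for r in records),
            rows=tuple(r.sequence for r in records),
        )


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (gap character '-')."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no records in {path}")
    return Alignment(ids=tuple(ids), rows=tuple(rows))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    p: np.ndarray  # proportion of differing retained sites
    d: np.ndarray  # distances of the stated kind
    kind: str  # p_distance | poisson

    def __post_init__(self):
        for name, mat in (("p", self.p), ("d", self.d)):
            arr = np.asarray(mat, dtype=float)
            n = len(self.ids)
            if arr.shape != (n, n):
                raise DistanceError(f"{name} matrix shape {arr.shape} != ({n},{n})")
            if not np.allclose(arr, arr.T):
                raise DistanceError(f"{name} matrix not symmetric")
            if not np.allclose(np.diag(arr), 0.0):
                raise DistanceError(f"{name} matrix diagonal not zero")
            if (arr < 0).any():
                raise DistanceError(f"{name} matrix has negative entries")
            object.__setattr__(self, name, arr)


@dataclass
class PhyloTree:
    """An unrooted tree (dendropy container) with optional bootstrap labels."""

    tree: dendropy.Tree
    negative_branch_deficit: float = 0.0

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions as unordered pairs of leaf-label sets."""
        return tree_bipartitions(self.tree)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    result = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - below
        if len(below) >= 2 and len(other) >= 2:
            result.add(frozenset({below, other}))
    return result


def complete_deletion(alignment: Alignment) -> Alignment:
    """Remove every column containing a gap or ambiguous residue in any row."""
    arr = alignment.to_array()
    keep = np.array(
        [all(ch in _CANONICAL for ch in arr[:, j]) for j in range(arr.shape[1])]
    )
    if not keep.any():
        raise AlignmentError("complete deletion removed every column")
    reduced = arr[:, keep]
    return Alignment(
        ids=alignment.ids,
        rows=tuple("".join(row) for row in reduced),
    )


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise proportion of differing sites (assumes complete deletion done)."""
    arr = alignment.to_array()
    n = alignment.n_rows
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = p[j, i] = np.mean(arr[i] != arr[j])
    return DistanceMatrix(ids=alignment.ids, p=p, d=p.copy(), kind="p_distance")


def poisson_distance(alignment: Alignment) -> DistanceMatrix:
    """Poisson-corrected distances d = −ln(1 − p).

    Raises :class:`DistanceError` if any pair is saturated (p = 1).
    """
    pd_ = p_distance(alignment)
    p = pd_.p
    if (p >= 1.0).any():
        i, j = np.argwhere(p >= 1.0)[0]
        raise DistanceError(
            f"p-distance 1 between {pd_.ids[i]!r} and {pd_.ids[j]!r}: "
            "Poisson correction undefined"
        )
    d = -np.log(1.0 - p)
    return DistanceMatrix(ids=pd_.ids, p=p, d=d, kind="poisson")


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining on a distance matrix.

    Iteratively joins the pair minimizing Q(i,j) = (n−2)·d(i,j) − r_i − r_j,
    with ties broken by the smallest (i, j) index pair; branch lengths use
    the standard NJ formulas and negative estimates are clamped to zero with
    the deficit accumulated on the returned tree.
    """
    n = len(dist.ids)
    if n < 3:
        raise DistanceError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace([str(label) for label in dist.ids])
    nodes: list[dendropy.Node] = []
    for label in dist.ids:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(str(label))
        nodes.append(node)

    d = dist.d.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        vi = clamp(0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2)))
        vj = clamp(sub[a, b] - (0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        # distances from the new node to every other active node
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    # join the remaining three nodes at a central (unrooted) vertex
    i, j, k = active
    root = dendropy.Node()
    vi = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    vj = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    vk = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    for idx, length in ((i, vi), (j, vj), (k, vk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = length

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, negative_branch_deficit=deficit)


@dataclass
class BootstrapResult:
    tree: PhyloTree  # full-data tree with supports as internal node labels
    supports: dict[frozenset[frozenset[str]], int]
    replicates_used: int
    replicates_skipped: int


def bootstrap(
    alignment: Alignment, replicates: int = 1000, seed: int | None = None
) -> BootstrapResult:
    """Column bootstrap with supports mapped onto the full-data tree.

    Each replicate resamples alignment columns with replacement, applies
    complete deletion, Poisson correction and NJ; the support of each
    internal bipartition of the full-data tree is the percentage of usable
    replicates containing it.  Replicates with a saturated pair or no
    retained columns are skipped and counted; more than 50% skipped raises
    :class:`BootstrapError`.
    """
    if replicates < 1:
        raise BootstrapError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    full = nj_tree(poisson_distance(complete_deletion(alignment)))
    target_bips = full.bipartitions()
    counts = {bip: 0 for bip in target_bips}
    arr = alignment.to_array()
    n_cols = arr.shape[1]
    skipped = 0
    used = 0
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = tuple("".join(row) for row in arr[:, cols])
        rep = Alignment(ids=alignment.ids, rows=rep_rows)
        try:
            rep_tree = nj_tree(poisson_distance(complete_deletion(rep)))
        except (AlignmentError, DistanceError):
            skipped += 1
            continue
        used += 1
        rep_bips = rep_tree.bipartitions()
        for bip in target_bips:
            if bip in rep_bips:
                counts[bip] += 1
    if skipped > replicates / 2:
        raise BootstrapError(
            f"{skipped}/{replicates} bootstrap replicates unusable"
        )
    supports = {
        bip: int(round(100.0 * c / used)) if used else 0 for bip, c in counts.items()
    }
    # attach supports as labels on the full-data tree's internal nodes
    all_leaves = full.leaf_labels
    for node in full.tree.preorder_node_iter():
        if node is full.tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        bip = frozenset({below, all_leaves - below})
        if bip in supports:
            node.label = str(supports[bip])
    return BootstrapResult(
        tree=full,
        supports=supports,
        replicates_used=used,
        replicates_skipped=skipped,
    )


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write Newick with branch lengths (6 significant digits) and supports."""
    text = tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )
    Path(path).write_text(text, encoding="utf-8")


def read_newick(path: str | Path) -> PhyloTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def write_phylip(dist: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{len(dist.ids)}\n")
        for label, row in zip(dist.ids, dist.d):
            cells = " ".join(f"{x:.6f}" for x in row)
            handle.write(f"{label}  {cells}\n")


def tree_path_distances(tree: PhyloTree) -> tuple[tuple[str, ...], np.ndarray]:
    """Leaf-to-leaf path-length (patristic) distance matrix."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    labels = tuple(sorted(l.taxon.label for l in tree.tree.leaf_node_iter()))
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return labels, out
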