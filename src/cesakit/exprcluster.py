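"""Expression normalization and heat-map clustering.

Counts are normalized to counts-per-million (CPM), log2-transformed with a
0.5 pseudocount, and row z-scored (population standard deviation) to give
the heat-map matrix.  Genes and samples are clustered agglomeratively with
Ward's linkage (the Ward.D2 squared-distance update, via scipy) on Pearson
correlation distances d = 1 − r; ties are broken deterministically by
index.  Items with zero variance are dropped from clustering with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import CountsFormatError
from .seqio import CountsMatrix


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples expression values at a tagged pipeline stage."""

    frame: pd.DataFrame
    stage: str  # cpm | log2_cpm | zscore
    constant_genes: tuple[str, ...] = ()

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result on one axis of the matrix."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix
    axis: str  # genes | samples

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> tuple[str, ...]:
        order = hierarchy.leaves_list(self.linkage)
        return tuple(self.labels[i] for i in order)

    def cut(self, k: int) -> dict[str, int]:
        """Assign each label to one of *k* flat clusters."""
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {label: int(c) for label, c in zip(self.labels, assignment)}

    def to_newick(self) -> str:
        """Render the dendrogram as a Newick string with merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"


def cpm(counts: CountsMatrix) -> ExpressionMatrix:
    """Counts-per-million: count / library size × 1e6 per sample."""
    frame = counts.to_frame().astype(float)
    library = frame.sum(axis=0)
    if (library <= 0).any():
        bad = library.index[int(np.argmin(library.to_numpy()))]
        raise CountsFormatError(f"sample {bad!r} has zero library size")
    return ExpressionMatrix(frame=frame / library * 1e6, stage="cpm")


def log2_cpm(expr: ExpressionMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    if expr.stage != "cpm":
        raise ValueError(f"expected a cpm-stage matrix, got {expr.stage!r}")
    return ExpressionMatrix(frame=np.log2(expr.frame + pseudocount), stage="log2_cpm")


def zscore_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores, (x − mean) / sd with the population (n) sd.

    Genes with zero variance are flagged (``constant_genes``) and dropped.
    """
    frame = expr.frame
    mean = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=0)
    constant = tuple(frame.index[sd == 0])
    if constant:
        warnings.warn(
            f"{len(constant)} constant gene(s) dropped from z-scoring: "
            f"{list(constant)[:5]}...",
            stacklevel=2,
        )
    keep = frame.index[sd > 0]
    z = frame.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return ExpressionMatrix(frame=z, stage="zscore", constant_genes=constant)


def pearson_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation distances d = 1 − r between rows."""
    corr = np.corrcoef(np.asarray(values, dtype=float))
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return dist


def pearson_ward(expr: ExpressionMatrix, axis: str = "genes") -> Dendrogram:
    """Ward's linkage on Pearson correlation distances (d = 1 − r)."""
    if axis not in {"genes", "samples"}:
        raise ValueError("axis must be 'genes' or 'samples'")
    frame = expr.frame if axis == "genes" else expr.frame.T
    values = frame.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    if (sd == 0).any():
        dropped = [str(l) for l in frame.index[sd == 0]]
        warnings.warn(
            f"{len(dropped)} zero-variance item(s) dropped from clustering",
            stacklevel=2,
        )
        frame = frame.loc[frame.index[sd > 0]]
        values = frame.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 items with nonzero variance")
    condensed = squareform(pearson_distances(values), checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(labels=tuple(str(l) for l in frame.index), linkage=linkage, axis=axis)


def heatmap_matrix(
    zscores: ExpressionMatrix,
    gene_dendrogram: Dendrogram,
    sample_dendrogram: Dendrogram,
) -> pd.DataFrame:
    """Z-score matrix reordered to the two dendrograms' leaf orders."""
    return zscores.frame.loc[
        list(gene_dendrogram.leaf_order), list(sample_dendrogram.leaf_order)
    ]


def heatmap_pipeline(
    counts: CountsMatrix,
) -> tuple[pd.DataFrame, Dendrogram, Dendrogram]:
    """counts → CPM → log2 → z-scores → Ward/Pearson ordered heat-map matrix."""
    z = zscore_rows(log2_cpm(cpm(counts)))
    genes = pearson_ward(z, axis="genes")
    samples = pearson_ward(z, axis="samples")
    return heatmap_matrix(z, genes, samples), genes, samples


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the ordered heat-map matrix to an image file (documentation aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, matrix.shape[1] * 0.3), max(4, matrix.shape[0] * 0.25))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="row z-score of log2 CPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
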