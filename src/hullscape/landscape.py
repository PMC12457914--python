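"""Topological colour landscapes: binary membership heatmaps and K-NN geometry.

Every confirmed major feature-category becomes a row and every nut a
column of a binary matrix; a nut's column vector is its *individual colour
landscape*.  Ward-D2 hierarchical clustering of the rows and of the
columns (plain Euclidean distance on the binary vectors) organizes the
matrix into a block heatmap, and per-nut ranked distances to the K nearest
other nuts summarize the local geometry of the resulting topological
space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from scipy.spatial.distance import cdist

from hullscape.ceda import CategoryVerdict
from hullscape.features import CategorizedFeature, FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class Landscape:
    """Binary category x nut matrix with dendrograms and K-NN profiles."""

    matrix: np.ndarray  # (n_categories, n_nuts) of {0, 1}
    category_names: list[str]
    nut_ids: list[str]
    labels: list[str] = field(default_factory=list)  # kernel status per nut
    ct_label: str = "unknown"
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("landscape matrix must be binary")
        if self.matrix.shape != (len(self.category_names), len(self.nut_ids)):
            raise ValueError("matrix shape must match category/nut axes")
        if self.labels and len(self.labels) != len(self.nut_ids):
            raise ValueError("labels must match nut axis")

    @property
    def n_nuts(self) -> int:
        return self.matrix.shape[1]

    def column(self, nut_id: str) -> np.ndarray:
        return self.matrix[:, self.nut_ids.index(nut_id)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.category_names,
                     columns=self.nut_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, labels=None, ct_label="unknown") -> "Landscape":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ls = cls(
            df.to_numpy(dtype=np.int64),
            category_names=[str(i) for i in df.index],
            nut_ids=[str(c) for c in df.columns],
            labels=list(labels) if labels is not None else [],
            ct_label=ct_label,
        )
        ls.row_linkage = _safe_linkage(ls.matrix)
        ls.col_linkage = _safe_linkage(ls.matrix.T)
        return ls


def _safe_linkage(vectors: np.ndarray) -> np.ndarray | None:
    if vectors.shape[0] < 2:
        return None
    # scipy's "ward" on raw observations follows the squared-Euclidean
    # (ward.D2) update convention
    return linkage(vectors.astype(float), method="ward")


def membership_matrix(
    majors: list[tuple[CategorizedFeature, CategoryVerdict]],
    table: FeatureTable,
) -> Landscape:
    """Binary nut-membership matrix over the major feature-categories.

    Each (categorized feature, major category) pair contributes one row;
    entry (i, j) is 1 iff nut j's code for that feature equals the major
    category.  Row and column dendrograms are Ward-D2 on Euclidean
    distance.
    """
    if not majors:
        raise ValueError(
            "no major categories: relax tau (larger overlap threshold) "
            "or provide more informative features"
        )
    nut_ids = [str(x) for x in table.data["nut_id"]]
    names, rows = [], []
    for cat, verdict in majors:
        names.append(f"{cat.name}={verdict.category}")
        rows.append((cat.codes == verdict.category).astype(np.int64))
    matrix = np.vstack(rows)
    ls = Landscape(
        matrix=matrix,
        category_names=names,
        nut_ids=nut_ids,
        labels=[str(s) for s in table.response],
        ct_label=str(table.data["ct"].iloc[0]) if len(table.data) else "unknown",
    )
    ls.row_linkage = _safe_linkage(matrix)
    ls.col_linkage = _safe_linkage(matrix.T)
    return ls


def knn_profile(landscape: Landscape, K: int = 10) -> pd.DataFrame:
    """Per-nut ranked distances to its K nearest other nuts.

    Distances are plain Euclidean between binary column vectors; ties are
    broken by nut position on the column axis so profiles are
    deterministic.  Returns a long-format frame (nut_id, rank,
    neighbour_id, distance) with distances ascending within each nut.
    """
    n = landscape.n_nuts
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the number of nuts ({n})")
    X = landscape.matrix.T.astype(float)
    D = cdist(X, X)
    rows = []
    for i in range(n):
        order = sorted((d, j) for j, d in enumerate(D[i]) if j != i)
        for rank, (d, j) in enumerate(order[:K], start=1):
            rows.append([landscape.nut_ids[i], rank, landscape.nut_ids[j], d])
    return pd.DataFrame(rows, columns=["nut_id", "rank", "neighbour_id", "distance"])


def branch_blank_rates(
    landscape: Landscape,
    n_branches: int | None = None,
    height: float | None = None,
) -> pd.DataFrame:
    """Blank fraction per dendrogram branch at a cut, plus the weighted total.

    Cut the column dendrogram either into ``n_branches`` clusters or at a
    merge ``height``.  For each branch the blank fraction and size are
    reported; the size-weighted overall rate equals the global blank
    fraction for any cut (a conservation identity used as a sanity check).
    The overall row has branch id 0.
    """
    if not landscape.labels:
        raise ValueError("landscape carries no kernel labels")
    if landscape.col_linkage is None:
        raise ValueError("landscape has no column dendrogram")
    if (n_branches is None) == (height is None):
        raise ValueError("specify exactly one of n_branches or height")
    if n_branches is not None:
        assign = fcluster(landscape.col_linkage, t=n_branches, criterion="maxclust")
    else:
        assign = fcluster(landscape.col_linkage, t=height, criterion="distance")
    blank = np.array([s == "blank" for s in landscape.labels], dtype=float)
    rows = []
    sizes = []
    for b in np.unique(assign):
        sel = assign == b
        rows.append([int(b), int(sel.sum()), float(blank[sel].mean())])
        sizes.append(int(sel.sum()))
    if max(sizes) == 1:
        logger.warning("cut produced singleton-only branches")
    df = pd.DataFrame(rows, columns=["branch", "size", "blank_rate"])
    overall = float((df["size"] / df["size"].sum() * df["blank_rate"]).sum())
    df.loc[len(df)] = [0, int(df["size"].sum()), overall]
    df.attrs["assignments"] = assign  # per-nut branch ids, column order
    return df


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage as a Newick string with merge-height branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def reordered_matrix(landscape: Landscape) -> pd.DataFrame:
    """The heatmap view: matrix with both axes in dendrogram leaf order."""
    ridx = leaves_list(landscape.row_linkage) if landscape.row_linkage is not None \
        else np.arange(landscape.matrix.shape[0])
    cidx = leaves_list(landscape.col_linkage) if landscape.col_linkage is not None \
        else np.arange(landscape.n_nuts)
    return pd.DataFrame(
        landscape.matrix[np.ix_(ridx, cidx)],
        index=[landscape.category_names[i] for i in ridx],
        columns=[landscape.nut_ids[j] for j in cidx],
    )
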