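"""Toroidal self-organizing map over the binary promoter binding matrix.

Promoters with similar regulator-binding patterns are mapped to nearby cells
of a wrap-around (toroidal) grid by online SOM training, each cell is
summarized by its binarized codebook vector (the cell's representative
regulator combination, or prototype), and the prototypes are grouped into
promoter clusters by Ward hierarchical clustering, the cluster count guided
by a homogeneity curve. Clusters are lettered "A", "B", ... in ascending
order of mean co-recruitment complexity (mean prototype sum).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class SOMGrid:
    """Trained toroidal map: codebook of shape (rows, cols, n_tfs)."""

    rows: int
    cols: int
    codebook: np.ndarray
    tf_names: list[str]
    toroidal: bool = True
    metadata: dict = field(default_factory=dict)

    def cell_index(self, row: int, col: int) -> int:
        return row * self.cols + col


def default_grid_shape(n_rows: int) -> tuple[int, int]:
    """Scale-adaptive square grid: side = ceil(sqrt(5 * sqrt(N)))."""
    side = int(np.ceil(np.sqrt(5.0 * np.sqrt(n_rows))))
    return max(side, 2), max(side, 2)


def toroidal_grid_distance(cell_a: tuple[int, int], cell_b: tuple[int, int],
                           rows: int, cols: int) -> float:
    """Euclidean distance on wrap-around grid coordinates."""
    for (r, c) in (cell_a, cell_b):
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"cell ({r}, {c}) outside {rows}x{cols} grid")
    dr = abs(cell_a[0] - cell_b[0])
    dc = abs(cell_a[1] - cell_b[1])
    dr = min(dr, rows - dr)
    dc = min(dc, cols - dc)
    return float(np.hypot(dr, dc))


def _grid_distance_matrix(rows: int, cols: int) -> np.ndarray:
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)])
    dr = np.abs(coords[:, None, 0] - coords[None, :, 0])
    dc = np.abs(coords[:, None, 1] - coords[None, :, 1])
    dr = np.minimum(dr, rows - dr)
    dc = np.minimum(dc, cols - dc)
    return np.sqrt(dr ** 2 + dc ** 2)


def train_som(matrix: pd.DataFrame, rows: int | None = None,
              cols: int | None = None, epochs: int = 100, seed: int = 0,
              alpha: tuple[float, float] = (0.05, 0.01)
              ) -> tuple[SOMGrid, pd.DataFrame]:
    """Online SOM training on binary rows with a toroidal neighborhood.

    One epoch presents every promoter once in random order. The learning
    rate decays linearly alpha0 -> alpha1 and the neighborhood radius decays
    linearly max(rows, cols)/2 -> 1 over all presentations; the update
    kernel is a Gaussian of the toroidal grid distance. Best-matching-unit
    ties break to the lowest (row, col), giving deterministic assignments.

    Returns the grid and a gene-indexed DataFrame with columns row/col.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty binding matrix")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X = matrix.to_numpy(dtype=float)
    n, n_tf = X.shape
    if rows is None or cols is None:
        rows, cols = default_grid_shape(n)
        while rows * cols > max(n, 4):  # grid must not exceed promoter count
            rows, cols = rows - 1, cols - 1
        rows, cols = max(rows, 2), max(cols, 2)
    if rows * cols > n:
        raise ValueError("grid has more cells than promoters")

    rng = np.random.default_rng(seed)
    n_cells = rows * cols
    codebook = rng.random((n_cells, n_tf))
    grid_dist = _grid_distance_matrix(rows, cols)

    total = epochs * n
    r0, r1 = max(rows, cols) / 2.0, 1.0
    a0, a1 = alpha
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = step / max(total - 1, 1)
            lr = a0 + (a1 - a0) * frac
            radius = r0 + (r1 - r0) * frac
            x = X[i]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            h = np.exp(-grid_dist[bmu] ** 2 / (2.0 * radius ** 2))
            codebook += (lr * h)[:, None] * (x - codebook)
            step += 1

    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    bmus = d2.argmin(axis=1)  # argmin -> lowest flat index -> lowest (r, c)
    assignment = pd.DataFrame(
        {"row": bmus // cols, "col": bmus % cols}, index=matrix.index
    )
    grid = SOMGrid(rows, cols, codebook.reshape(rows, cols, n_tf),
                   list(matrix.columns),
                   metadata={"epochs": epochs, "seed": seed,
                             "alpha": alpha, "radius": (r0, r1)})
    return grid, assignment


def binarize_prototypes(grid: SOMGrid, threshold: float = 0.5) -> pd.DataFrame:
    """Per-cell representative regulator combination (codebook >= threshold).

    At convergence a cell's codebook approaches the mean of its member rows,
    so thresholding at 0.5 is a majority vote of the members.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    flat = grid.codebook.reshape(-1, len(grid.tf_names))
    cells = [(r, c) for r in range(grid.rows) for c in range(grid.cols)]
    return pd.DataFrame((flat >= threshold).astype(int),
                        index=pd.MultiIndex.from_tuples(cells,
                                                        names=["row", "col"]),
                        columns=grid.tf_names)


def _cluster_letters(n: int) -> list[str]:
    letters = list(string.ascii_uppercase)
    while len(letters) < n:
        letters += [a + b for a in string.ascii_uppercase
                    for b in string.ascii_uppercase]
    return letters[:n]


def cluster_som_cells(prototypes: pd.DataFrame, k: int) -> pd.Series:
    """Ward cut of cell prototypes into k lettered clusters.

    Letters run "A", "B", ... by ascending mean prototype sum, so later
    letters mean more complex co-recruitment combinations.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = len(prototypes.drop_duplicates())
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct prototypes")
    Z = linkage(prototypes.to_numpy(dtype=float), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    sums = prototypes.sum(axis=1).to_numpy()
    order = sorted(np.unique(raw),
                   key=lambda lab: (sums[raw == lab].mean(), lab))
    letters = _cluster_letters(len(order))
    mapping = {lab: letters[i] for i, lab in enumerate(order)}
    return pd.Series([mapping[lab] for lab in raw], index=prototypes.index,
                     name="cluster")


def homogeneity_analysis(prototypes: pd.DataFrame,
                         k_range: range | list[int]
                         ) -> tuple[pd.Series, int]:
    """Homogeneity curve over k plus the elbow (max second difference).

    Homogeneity(k) = 1 - mean within-cluster squared distance to the cluster
    centroid / mean squared distance to the grand centroid. With nested Ward
    cuts this is non-decreasing in k and reaches 1 at k = n_cells.
    """
    X = prototypes.to_numpy(dtype=float)
    n = X.shape[0]
    ks = sorted(k_range)
    if any(k < 1 or k > n for k in ks):
        raise ValueError("k_range outside [1, n_cells]")
    global_ss = ((X - X.mean(axis=0)) ** 2).sum(axis=1).mean()
    Z = linkage(X, method="ward")
    scores = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        within = 0.0
        for lab in np.unique(labels):
            sub = X[labels == lab]
            within += ((sub - sub.mean(axis=0)) ** 2).sum()
        scores[k] = (1.0 if global_ss == 0
                     else 1.0 - (within / n) / global_ss)
    curve = pd.Series(scores, name="homogeneity")
    if len(ks) >= 3:
        second_diff = curve.diff().diff().shift(-1)  # d2 at interior ks
        elbow = int(second_diff.abs().idxmax())
    else:
        elbow = ks[-1]
    return curve, elbow


def cell_summary_map(assignment: pd.DataFrame,
                     gene_values: pd.Series,
                     rows: int, cols: int) -> pd.DataFrame:
    """Per-cell mean of a per-gene quantity; empty cells are NaN, not 0."""
    out = np.full((rows, cols), np.nan)
    joined = assignment.join(gene_values.rename("value"), how="inner")
    for (r, c), sub in joined.groupby(["row", "col"]):
        out[int(r), int(c)] = sub["value"].mean()
    return pd.DataFrame(out, index=range(rows), columns=range(cols))
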