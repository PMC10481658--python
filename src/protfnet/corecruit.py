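"""Co-recruitment structure within promoter clusters.

Tanimoto (Jaccard) distances between regulators' bound-promoter sets,
classical (Torgerson) multidimensional scaling of those distances,
levelwise frequent-itemset mining of the regulator combinations present at
cluster promoters (core co-recruitment nodes at >= 50% support), per-TF
occurrence in those nodes, and the Szekely distance correlation used to
compare binding profiles.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


def tanimoto_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - |intersection| / |union| of the TFs' bound-promoter sets.

    A TF binding nothing has distance 1 to every other TF and 0 to itself.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2 or X.sum() < 1:
        raise ValueError("need >= 2 TFs with >= 1 binding event")
    inter = X.T @ X
    sizes = X.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.divide(inter, union, out=np.zeros_like(union),
                               where=union > 0)
    dist[union == 0] = 1.0  # both empty: maximally distant
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


def mds_embedding(distances: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a symmetric distance matrix.

    Double-centers the squared distances, takes the top ``dims``
    eigenvectors scaled by sqrt(eigenvalue); negative eigenvalues are
    truncated at 0 (coordinates padded with zeros). Axis signs are fixed by
    making the first nonzero loading of each axis positive.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    D = distances.to_numpy(dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    coords = vecs[:, :dims] * np.sqrt(vals[:dims])
    for j in range(coords.shape[1]):  # deterministic sign convention
        nz = np.flatnonzero(np.abs(coords[:, j]) > 1e-12)
        if nz.size and coords[nz[0], j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(coords, index=distances.index,
                        columns=[f"dim{j+1}" for j in range(dims)])


def mine_frequent_itemsets(cluster_matrix: pd.DataFrame,
                           min_support: float = 0.5,
                           size_min: int = 2,
                           size_max: int | None = None) -> pd.DataFrame:
    """Levelwise (apriori) search for frequent regulator combinations.

    Transactions are promoters; an itemset's support is the fraction of the
    cluster's promoters where all its members are simultaneously bound.
    Returns a DataFrame with columns itemset (frozenset), support, count,
    sorted by descending support then lexicographic itemset.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must be in (0, 1]")
    if size_min < 2:
        raise ValueError("combinations start at 2 regulators")
    X = cluster_matrix.to_numpy(dtype=bool)
    n_prom, n_tf = X.shape
    if size_max is None or size_max > n_tf:
        size_max = n_tf
    min_count = int(np.ceil(min_support * n_prom - 1e-9))

    # level 1 candidates (singletons) seed the levelwise growth
    cols = {(j,): X[:, j] for j in range(n_tf)
            if X[:, j].sum() >= min_count}
    frequent: list[tuple[tuple[int, ...], int]] = []
    level = cols
    size = 1
    while level and size < size_max:
        next_level: dict[tuple[int, ...], np.ndarray] = {}
        keys = sorted(level)
        for a, b in combinations(keys, 2):
            if a[:-1] != b[:-1]:
                continue
            cand = a + (b[-1],)
            mask = level[a] & cols[(cand[-1],)] if size == 1 else \
                level[a] & level[b]
            cnt = int(mask.sum())
            if cnt >= min_count:
                next_level[cand] = mask
                if size + 1 >= size_min:
                    frequent.append((cand, cnt))
        level = next_level
        size += 1

    names = list(cluster_matrix.columns)
    rows = [(frozenset(names[j] for j in iset), cnt / n_prom, cnt)
            for iset, cnt in frequent]
    df = pd.DataFrame(rows, columns=["itemset", "support", "count"])
    if len(df):
        df["_key"] = df["itemset"].map(lambda s: tuple(sorted(s)))
        df = (df.sort_values(["support", "_key"],
                             ascending=[False, True], kind="stable")
              .drop(columns="_key").reset_index(drop=True))
    return df


def core_node_occurrence(itemsets: pd.DataFrame,
                         tf_universe: list[str]) -> pd.Series:
    """Percentage of core nodes each regulator participates in."""
    total = len(itemsets)
    occ = {tf: 0 for tf in tf_universe}
    for iset in (itemsets["itemset"] if total else []):
        for tf in iset:
            if tf in occ:
                occ[tf] += 1
    if total == 0:
        return pd.Series({tf: 0.0 for tf in tf_universe})
    return pd.Series({tf: 100.0 * c / total for tf, c in occ.items()})


def _center_distance_matrix(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True)
            + a.mean())


def distance_correlation(x, y, unbiased: bool = False) -> float:
    """Szekely sample distance correlation between two sample vectors.

    Accepts 1-D (n,) or 2-D (n, p) arrays; returns a value in [0, 1], 0 when
    either distance variance vanishes (e.g. a constant sample). The default
    is the biased V-statistic; ``unbiased`` switches to the U-statistic
    (which may be slightly negative; it is not clipped).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    y = np.atleast_2d(np.asarray(y, dtype=float).T).T
    if x.shape[0] != y.shape[0]:
        raise ValueError("sample counts differ")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 samples")
    a = cdist(x, x)
    b = cdist(y, y)
    if unbiased:
        def u_center(m):
            s_row = m.sum(axis=0, keepdims=True)
            s_col = m.sum(axis=1, keepdims=True)
            out = (m - s_row / (n - 2) - s_col / (n - 2)
                   + m.sum() / ((n - 1) * (n - 2)))
            np.fill_diagonal(out, 0.0)
            return out
        A, B = u_center(a), u_center(b)
        denom = n * (n - 3)
        dcov2 = (A * B).sum() / denom
        dvx = (A * A).sum() / denom
        dvy = (B * B).sum() / denom
    else:
        A, B = _center_distance_matrix(a), _center_distance_matrix(b)
        dcov2 = (A * B).mean()
        dvx = (A * A).mean()
        dvy = (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    r2 = dcov2 / np.sqrt(dvx * dvy)
    return float(np.sqrt(r2)) if not unbiased else float(np.sign(r2) *
                                                         np.sqrt(abs(r2)))
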