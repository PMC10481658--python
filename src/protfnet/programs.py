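"""Expression programs of TF-encoding genes.

Deciles of (tissue-specific) expression, the Tau tissue-specificity index,
multiple factor analysis (MFA) of a two-species expression atlas, Ward
clustering of the MFA scores into cell-type specific (CTS), cell-type
enriched (CTE) and ubiquitous (UBQ) programs, and the selection of
"connect"-type identity TFs by focal-cell expression rank and positive
fold-difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ks_2samp, rankdata

PSEUDOCOUNT = 0.01  # on the normalized-expression scale, for log-ratios


def expression_deciles(values: pd.Series) -> pd.Series:
    """Decile 1..10 of ascending expression; decile 10 = highest.

    Bins are equal-sized up to the remainder (the first ``n mod 10`` deciles
    get the extra gene); ties break by stable gene-id order.
    """
    n = len(values)
    if n < 10:
        raise ValueError("need >= 10 genes for deciles")
    order = values.sort_values(kind="stable").index
    sizes = [n // 10 + (1 if i < n % 10 else 0) for i in range(10)]
    labels = np.repeat(np.arange(1, 11), sizes)
    return pd.Series(labels, index=order).reindex(values.index)


def specificity_ratio(focal: float, others,
                      eps: float = PSEUDOCOUNT) -> float:
    """log2((focal + eps) / (mean(others) + eps))."""
    others = np.asarray(others, dtype=float)
    return float(np.log2((focal + eps) / (others.mean() + eps)))


def decile_distribution_test(subset_deciles, background_deciles):
    """Two-sided two-sample Kolmogorov-Smirnov test on decile values."""
    res = ks_2samp(np.asarray(subset_deciles), np.asarray(background_deciles),
                   alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compute_tau(expression) -> float:
    """Tau tissue-specificity index: sum(1 - x_i / x_max) / (n - 1).

    1 for single-tissue expression, 0 for a perfectly uniform profile.
    Returns NaN for an all-zero vector (undefined).
    """
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("Tau needs >= 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    mx = x.max()
    if mx == 0:
        return float("nan")
    return float((1.0 - x / mx).sum() / (x.size - 1))


@dataclass
class MFAResult:
    scores: pd.DataFrame            # TF x component row scores
    group_weights: dict[str, float]  # 1 / first PCA eigenvalue per group
    explained_variance: np.ndarray  # fractions, non-increasing
    loadings: pd.DataFrame          # weighted-variable loadings


def mfa(group_matrices: dict[str, pd.DataFrame] | list[pd.DataFrame],
        n_components: int = 5) -> MFAResult:
    """Multiple factor analysis of row-aligned variable groups.

    Each group's columns are centered and unit-scaled, the group is weighted
    by the inverse of its first PCA eigenvalue (so no single table dominates
    the compromise), and a global PCA (SVD) is run on the weighted
    concatenation. Row scores and explained-variance fractions follow the
    usual PCA conventions.
    """
    if not isinstance(group_matrices, dict):
        group_matrices = {f"group{i+1}": g
                          for i, g in enumerate(group_matrices)}
    names = list(group_matrices)
    if not names:
        raise ValueError("need >= 1 group")
    index = group_matrices[names[0]].index
    blocks, weights, cols = [], {}, []
    for name in names:
        g = group_matrices[name]
        if not g.index.equals(index):
            raise ValueError("groups must share the row (TF) universe")
        X = g.to_numpy(dtype=float)
        X = X - X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"constant column(s) in group '{name}': "
                f"{[g.columns[j] for j in bad]}")
        X = X / sd
        sv = np.linalg.svd(X, compute_uv=False)
        lam1 = sv[0] ** 2 / X.shape[0]
        weights[name] = 1.0 / lam1
        blocks.append(X / np.sqrt(lam1))
        cols.extend(f"{name}:{c}" for c in g.columns)
    Z = np.hstack(blocks)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = S ** 2
    n_components = min(n_components, len(eig))
    scores = U[:, :n_components] * S[:n_components]
    # deterministic sign: largest-|loading| entry of each axis positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
            Vt[j] = -Vt[j]
    comp_names = [f"comp{j+1}" for j in range(n_components)]
    return MFAResult(
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        group_weights=weights,
        explained_variance=eig[:n_components] / eig.sum(),
        loadings=pd.DataFrame(Vt[:n_components].T, index=cols,
                              columns=comp_names),
    )


def high_expression_counts(atlas: pd.DataFrame,
                           frac_of_max: float = 0.25) -> pd.Series:
    """Cell types where each TF exceeds ``frac_of_max`` of its own maximum."""
    X = atlas.to_numpy(dtype=float)
    mx = X.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        high = X > frac_of_max * mx
    return pd.Series(high.sum(axis=1), index=atlas.index)


def cluster_tf_programs(scores: pd.DataFrame,
                        high_counts: pd.Series,
                        k: int = 3) -> pd.Series:
    """Ward cut of MFA row scores into expression-program labels.

    The k clusters are labeled CTS, CTE, UBQ (then P4, P5, ... if k > 3) in
    ascending order of their members' mean number of high-expression cell
    types: the cluster expressed in fewest cell types is CTS, the broadest
    is UBQ.
    """
    if k > len(scores):
        raise ValueError("k exceeds number of TFs")
    Z = linkage(scores.to_numpy(dtype=float), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    hc = high_counts.reindex(scores.index).to_numpy()
    order = sorted(np.unique(raw), key=lambda lab: (hc[raw == lab].mean(),
                                                    lab))
    base = ["CTS", "CTE", "UBQ"]
    names = (base + [f"P{i+1}" for i in range(3, k)])[:len(order)]
    mapping = {lab: names[i] for i, lab in enumerate(order)}
    return pd.Series([mapping[lab] for lab in raw], index=scores.index,
                     name="program")


def select_connect_tfs(atlas: pd.DataFrame, focal_cell: str,
                       rank_threshold: int = 10,
                       eps: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Focal-cell rank and fold-difference selection of connect TFs.

    Per TF, cells are ranked by decreasing expression (rank 1 = highest;
    ties get the average rank, the focal cell's rank is then ceiled) and the
    fold-difference is log2((focal + eps) / (mean of other cells + eps)).
    A TF is selected iff rank <= rank_threshold and fold > 0.
    """
    if focal_cell not in atlas.columns:
        raise ValueError(f"focal cell '{focal_cell}' not in atlas")
    if rank_threshold < 1:
        raise ValueError("rank_threshold must be >= 1")
    others = [c for c in atlas.columns if c != focal_cell]
    out = []
    for tf, row in atlas.iterrows():
        ranks = rankdata(-row.to_numpy(dtype=float), method="average")
        rank = math.ceil(ranks[atlas.columns.get_loc(focal_cell)])
        fold = specificity_ratio(row[focal_cell], row[others], eps)
        out.append((tf, rank, fold, rank <= rank_threshold and fold > 0))
    return pd.DataFrame(out, columns=["tf", "rank", "log2_fold", "selected"]
                        ).set_index("tf")
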