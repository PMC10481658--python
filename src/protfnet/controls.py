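"""Activity-matched control gene sets and the group-level statistics.

Candidate genes are stratified into promoter-activity levels by Ward
clustering of log2-scaled accessibility, acetylation and expression
features. Control sets are drawn by stratified resampling so every control
set reproduces the identity set's per-stratum composition exactly; the
resampling is repeated many times (1,000 by default downstream) and a
representative set is picked at the mode of the per-set test p-value
distribution. The module also hosts the rank-based group tests, BH
correction, Fisher enrichment odds ratios, and Kruskal-Wallis with pairwise
follow-up used throughout the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import fisher_exact, kruskal, mannwhitneyu, wilcoxon
from statsmodels.stats.multitest import multipletests


@dataclass
class ActivityStrata:
    labels: pd.Series          # gene -> stratum 1..k (ascending activity)
    k: int
    features: pd.DataFrame    # scaled feature matrix used for clustering


@dataclass
class ControlSetEnsemble:
    identity_genes: list[str]
    sets: list[list[str]]
    p_values: np.ndarray | None = None
    representative: int | None = None
    extra: dict = field(default_factory=dict)


def activity_strata(features: pd.DataFrame, k: int = 4,
                    eps: float = 1.0) -> ActivityStrata:
    """Ward clustering of promoters into k activity strata.

    Features (accessibility, acetylation, expression) are log2(x + eps)
    transformed, then z-scaled per feature; the Ward tree is cut at k and
    strata are numbered 1..k by ascending mean scaled activity.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if features.isna().any().any():
        bad = features.index[features.isna().any(axis=1)][0]
        raise ValueError(f"missing feature for gene '{bad}'")
    X = np.log2(features.to_numpy(dtype=float) + eps)
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("degenerate input: all promoters identical")
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    means = {lab: X[raw == lab].mean() for lab in np.unique(raw)}
    order = sorted(means, key=lambda lab: (means[lab], lab))
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    labels = pd.Series([mapping[lab] for lab in raw], index=features.index,
                       name="stratum")
    scaled = pd.DataFrame(X, index=features.index, columns=features.columns)
    return ActivityStrata(labels=labels, k=k, features=scaled)


def sample_matched_controls(identity_genes: list[str],
                            candidate_pool: list[str],
                            strata: ActivityStrata,
                            n_iter: int = 1000,
                            seed: int = 0) -> ControlSetEnsemble:
    """Stratified resampling of control sets matching the identity set.

    Each iteration draws, within every stratum, exactly as many candidates
    (excluding identity genes) as the identity set has there, without
    replacement within the iteration. Iterations are independent given the
    seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    identity = [g for g in identity_genes]
    id_set = set(identity)
    labels = strata.labels
    pool_by_stratum: dict[int, np.ndarray] = {}
    need: dict[int, int] = {}
    for g in identity:
        if g not in labels.index:
            raise ValueError(f"identity gene '{g}' has no stratum")
        need[labels[g]] = need.get(labels[g], 0) + 1
    for s, n_need in need.items():
        pool = np.array([g for g in candidate_pool
                         if g not in id_set and labels.get(g) == s])
        if len(pool) < n_need:
            raise ValueError(f"stratum {s}: {len(pool)} candidates for "
                             f"{n_need} identity genes")
        pool_by_stratum[s] = pool
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_iter):
        chosen: list[str] = []
        for s in sorted(need):
            pick = rng.choice(pool_by_stratum[s], size=need[s],
                              replace=False)
            chosen.extend(pick.tolist())
        sets.append(chosen)
    return ControlSetEnsemble(identity_genes=identity, sets=sets)


def select_representative_set(ensemble: ControlSetEnsemble,
                              statistic_fn) -> ControlSetEnsemble:
    """Pick the control set at the mode of the p-value distribution.

    ``statistic_fn(identity_genes, control_genes) -> p``. P-values are
    histogrammed in fixed 0.01-wide bins on [0, 1]; the most populated bin
    (ties to the lower bin) defines the mode, and the representative is the
    set whose p lies closest to that bin's center (ties to the lowest
    index).
    """
    p = np.array([statistic_fn(ensemble.identity_genes, s)
                  for s in ensemble.sets], dtype=float)
    edges = np.linspace(0.0, 1.0, 101)
    counts, _ = np.histogram(p, bins=edges)
    modal = int(np.argmax(counts))  # argmax ties -> lowest bin
    center = (edges[modal] + edges[modal + 1]) / 2.0
    representative = int(np.argmin(np.abs(p - center)))  # ties -> lowest idx
    ensemble.p_values = p
    ensemble.representative = representative
    return ensemble


def group_shift_test(values_a, values_b, alternative: str = "two-sided",
                     paired: bool = False) -> float:
    """Wilcoxon rank test p-value for a location shift of a versus b.

    Unpaired: rank-sum (Mann-Whitney), exact when both samples are small
    (min n <= 10) and tie-free, otherwise the normal approximation with
    continuity correction. Paired: signed-rank test. Fully tied degenerate
    data returns p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if paired:
        if np.all(a == b):
            warnings.warn("all paired differences are zero; p = 1")
            return 1.0
        return float(wilcoxon(a, b, alternative=alternative).pvalue)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied; p = 1")
        return 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 10 and not ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method,
                       use_continuity=True)
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_odds_ratio(in_group_hits: int, in_group_misses: int,
                          out_group_hits: int, out_group_misses: int
                          ) -> tuple[float, float]:
    """log2 odds ratio (Haldane-Anscombe corrected) + two-sided Fisher p.

    The 0.5 correction applies only when some cell is zero, and only to the
    odds ratio; the Fisher test runs on the uncorrected table.
    """
    a, b, c, d = (in_group_hits, in_group_misses,
                  out_group_hits, out_group_misses)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), float("nan")
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        oa, ob, oc, od = a, b, c, d
    log2_or = float(np.log2((oa * od) / (ob * oc)))
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return log2_or, p


def kruskal_pairwise(groups: list, alternative: str = "two-sided"
                     ) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis omnibus p plus BH-adjusted pairwise rank-sum tests."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("every group must be non-empty")
    if np.unique(np.concatenate(arrays)).size == 1:
        omnibus = 1.0
    else:
        omnibus = float(kruskal(*arrays).pvalue)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append((i, j, group_shift_test(arrays[i], arrays[j],
                                                alternative=alternative)))
    pair = pd.DataFrame(rows, columns=["group_i", "group_j", "p"])
    pair["q"] = bh_adjust(pair["p"].to_numpy())
    return omnibus, pair
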