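"""Dedifferentiation scoring against a reference differentiation series.

Perturbed (injury) studies are batch-corrected against the reference by
anchor-referenced, mean-only location correction with parametric empirical-
Bayes shrinkage of the per-gene offsets: the anchors are the mature/control
samples shared in spirit between batches, the offset of each gene is the
difference of anchor means, offsets are shrunk toward their grand mean
under a normal prior, and variances are left untouched. A PCA fitted on the
(centered, unscaled) reference then defines the differentiation axis; its
first component, oriented so mature anchors score positive, is used to
project the corrected samples. Study-level effects are summarized as the
median log2 fold change per gene across studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def batch_correct_mean_only(reference_matrix: pd.DataFrame,
                            target_matrix: pd.DataFrame,
                            reference_anchors: list[str],
                            target_anchors: list[str]) -> pd.DataFrame:
    """Location-only batch correction of a target batch onto the reference.

    Matrices are genes x samples on a shared gene universe. Per gene, the
    batch offset is (target anchor mean - reference anchor mean); offsets
    are shrunk across genes toward their grand mean with a normal
    empirical-Bayes prior (method-of-moments hyperparameters) before being
    subtracted from every target sample. Variances are not rescaled.
    """
    if not reference_matrix.index.equals(target_matrix.index):
        missing = reference_matrix.index.symmetric_difference(
            target_matrix.index)
        raise ValueError(f"gene universes differ: {list(missing)[:5]} ...")
    for name, anchors, mat in (("reference", reference_anchors,
                                reference_matrix),
                               ("target", target_anchors, target_matrix)):
        if not anchors:
            raise ValueError(f"{name} batch has no anchor samples")
        absent = set(anchors) - set(mat.columns)
        if absent:
            raise ValueError(f"{name} anchors not in matrix: {absent}")

    ref_anchor = reference_matrix[reference_anchors].to_numpy(dtype=float)
    tgt_anchor = target_matrix[target_anchors].to_numpy(dtype=float)
    d = tgt_anchor.mean(axis=1) - ref_anchor.mean(axis=1)

    # sampling variance of each per-gene offset estimate
    n_r, n_t = ref_anchor.shape[1], tgt_anchor.shape[1]
    var_r = ref_anchor.var(axis=1, ddof=1) if n_r > 1 else np.zeros_like(d)
    var_t = tgt_anchor.var(axis=1, ddof=1) if n_t > 1 else np.zeros_like(d)
    s2 = var_r / max(n_r, 1) + var_t / max(n_t, 1)

    mu = d.mean()
    tau2 = max(d.var(ddof=1) - s2.mean(), 0.0) if d.size > 1 else 0.0
    denom = tau2 + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, tau2 / denom, 0.0)
    offsets = mu + shrink * (d - mu)
    corrected = target_matrix.to_numpy(dtype=float) - offsets[:, None]
    return pd.DataFrame(corrected, index=target_matrix.index,
                        columns=target_matrix.columns)


@dataclass
class ReferenceModel:
    gene_means: pd.Series
    loadings: pd.DataFrame          # genes x components, orthonormal
    explained_variance: np.ndarray  # fractions, non-increasing
    scores: pd.DataFrame            # reference samples x components
    mature_anchors: list[str]


def fit_differentiation_axis(reference_matrix: pd.DataFrame,
                             mature_anchors: list[str],
                             n_components: int = 5) -> ReferenceModel:
    """PCA of the reference series (gene-wise centering, no unit scaling).

    Component signs are oriented so the mature anchor group has a positive
    PC1 mean: higher scores mean more differentiated.
    """
    if reference_matrix.shape[1] < 3:
        raise ValueError("need >= 3 reference samples")
    X = reference_matrix.to_numpy(dtype=float).T  # samples x genes
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        import warnings
        warnings.warn(f"truncating to {max_comp} components")
        n_components = max_comp
    means = X.mean(axis=0)
    Xc = X - means
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    anchor_idx = [reference_matrix.columns.get_loc(a)
                  for a in mature_anchors]
    if not anchor_idx:
        raise ValueError("no mature anchor samples given")
    for j in range(n_components):
        if scores[anchor_idx, j].mean() < 0:
            scores[:, j] = -scores[:, j]
            loadings[:, j] = -loadings[:, j]
    ev = S ** 2
    comp = [f"PC{j+1}" for j in range(n_components)]
    return ReferenceModel(
        gene_means=pd.Series(means, index=reference_matrix.index),
        loadings=pd.DataFrame(loadings, index=reference_matrix.index,
                              columns=comp),
        explained_variance=ev[:n_components] / ev.sum(),
        scores=pd.DataFrame(scores, index=reference_matrix.columns,
                            columns=comp),
        mature_anchors=list(mature_anchors),
    )


def project_samples(model: ReferenceModel,
                    samples: pd.DataFrame) -> pd.Series:
    """First-component scores of new samples under the reference model."""
    missing = model.gene_means.index.difference(samples.index)
    if len(missing):
        raise ValueError(f"samples missing model genes: "
                         f"{list(missing)[:5]} ...")
    X = samples.loc[model.gene_means.index].to_numpy(dtype=float).T
    centered = X - model.gene_means.to_numpy()
    pc1 = centered @ model.loadings["PC1"].to_numpy()
    return pd.Series(pc1, index=samples.columns, name="PC1")


def meta_fold_change(per_study_fc: list[pd.Series],
                     min_studies: int = 1) -> pd.Series:
    """Median log2 fold change per gene across studies.

    Genes observed in fewer than ``min_studies`` studies are dropped.
    """
    if not per_study_fc:
        raise ValueError("need >= 1 study")
    df = pd.concat(per_study_fc, axis=1)
    present = df.notna().sum(axis=1)
    med = df.median(axis=1, skipna=True)
    return med[present >= min_studies]
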