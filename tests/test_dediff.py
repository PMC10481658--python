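"""Anchor-referenced batch correction, reference PCA and projection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from protfnet import dediff
from protfnet.synthetic import SyntheticConfig, generate_differentiation_series


def frame(arr, genes=None, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cols = [f"{prefix}{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=cols)


class TestBatchCorrection:
    def test_pure_constant_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(30, 4))
        ref = frame(base, prefix="r")
        tgt = frame(base + 7.5, prefix="t")
        out = dediff.batch_correct_mean_only(ref, tgt,
                                             list(ref.columns),
                                             list(tgt.columns))
        assert np.abs(out.to_numpy() - base).max() < 1e-9

    def test_variances_untouched(self):
        rng = np.random.default_rng(1)
        ref = frame(rng.normal(size=(20, 6)), prefix="r")
        tgt = frame(rng.normal(3.0, 2.0, size=(20, 6)), prefix="t")
        out = dediff.batch_correct_mean_only(ref, tgt,
                                             list(ref.columns),
                                             list(tgt.columns))
        assert np.allclose(out.var(axis=1, ddof=1),
                           tgt.var(axis=1, ddof=1))

    def test_shrinkage_beats_raw_offsets_in_mse(self):
        # true offset identical for all genes; per-gene anchor noise makes
        # the raw offset estimates scatter around it.  The EB-shrunk
        # offsets must recover the truth with lower mean squared error.
        rng = np.random.default_rng(2)
        n_genes, true_offset = 200, 4.0
        base = rng.normal(size=(n_genes, 3))
        ref = frame(base + rng.normal(0, 1.0, size=(n_genes, 3)),
                    prefix="r")
        tgt = frame(base + true_offset
                    + rng.normal(0, 1.0, size=(n_genes, 3)), prefix="t")
        raw_d = (tgt.mean(axis=1) - ref.mean(axis=1)).to_numpy()
        out = dediff.batch_correct_mean_only(ref, tgt,
                                             list(ref.columns),
                                             list(tgt.columns))
        applied = (tgt.to_numpy() - out.to_numpy())[:, 0]
        mse_raw = np.mean((raw_d - true_offset) ** 2)
        mse_eb = np.mean((applied - true_offset) ** 2)
        assert mse_eb < mse_raw

    def test_offsets_shrunk_toward_grand_mean(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(50, 4))
        noise = rng.normal(0, 0.5, size=(50, 4))
        ref = frame(base, prefix="r")
        tgt = frame(base + 2.0 + noise, prefix="t")
        raw_d = (tgt.mean(axis=1) - ref.mean(axis=1)).to_numpy()
        out = dediff.batch_correct_mean_only(ref, tgt,
                                             list(ref.columns),
                                             list(tgt.columns))
        applied = (tgt.to_numpy() - out.to_numpy())[:, 0]
        mu = raw_d.mean()
        # every applied offset lies between its raw estimate and the mean
        inside = ((applied - raw_d) * (mu - raw_d)) >= -1e-12
        assert inside.all()
        assert np.abs(applied - mu).sum() < np.abs(raw_d - mu).sum()

    def test_gene_universe_mismatch_rejected(self):
        ref = frame(np.zeros((3, 2)), genes=["a", "b", "c"], prefix="r")
        tgt = frame(np.zeros((3, 2)), genes=["a", "b", "d"], prefix="t")
        with pytest.raises(ValueError, match="gene universes"):
            dediff.batch_correct_mean_only(ref, tgt, ["r0"], ["t0"])

    def test_unknown_anchor_named(self):
        ref = frame(np.zeros((3, 2)), prefix="r")
        tgt = frame(np.zeros((3, 2)), prefix="t")
        with pytest.raises(ValueError, match="zz"):
            dediff.batch_correct_mean_only(ref, tgt, ["r0"], ["zz"])

    def test_empty_anchor_list_rejected(self):
        ref = frame(np.zeros((3, 2)), prefix="r")
        tgt = frame(np.zeros((3, 2)), prefix="t")
        with pytest.raises(ValueError, match="anchor"):
            dediff.batch_correct_mean_only(ref, tgt, [], ["t0"])


class TestReferenceModel:
    def planted(self, seed=0, n_genes=60, noise=0.0):
        rng = np.random.default_rng(seed)
        stages = np.repeat(np.arange(1.0, 7.0), 2)
        loading = rng.normal(size=n_genes)
        mu = rng.normal(5, 1, n_genes)
        X = mu[:, None] + loading[:, None] * stages[None, :]
        if noise:
            X = X + rng.normal(0, noise, X.shape)
        cols = [f"s{j}" for j in range(len(stages))]
        mat = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                           columns=cols)
        anchors = [c for c, st in zip(cols, stages) if st == 6.0]
        return mat, stages, anchors

    def test_pc1_recovers_planted_stage_axis(self):
        mat, stages, anchors = self.planted(noise=0.05)
        model = dediff.fit_differentiation_axis(mat, anchors, 3)
        r = np.corrcoef(model.scores["PC1"], stages)[0, 1]
        assert abs(r) > 0.99

    def test_mature_anchors_score_positive(self):
        for seed in range(5):
            mat, stages, anchors = self.planted(seed=seed, noise=0.1)
            model = dediff.fit_differentiation_axis(mat, anchors, 2)
            assert model.scores.loc[anchors, "PC1"].mean() > 0

    def test_matches_svd_oracle_up_to_sign(self):
        mat, _, anchors = self.planted(noise=0.3)
        model = dediff.fit_differentiation_axis(mat, anchors, 3)
        Xc = mat.to_numpy().T - mat.to_numpy().T.mean(axis=0)
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        for j in range(3):
            r = np.corrcoef(model.scores.iloc[:, j], U[:, j] * S[j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_fractions(self):
        mat, _, anchors = self.planted(noise=0.2)
        model = dediff.fit_differentiation_axis(mat, anchors, 4)
        ev = model.explained_variance
        assert (np.diff(ev) <= 1e-12).all() and ev.sum() <= 1 + 1e-12
        assert ev[0] > 0.9  # stage axis dominates

    def test_loadings_orthonormal(self):
        mat, _, anchors = self.planted(noise=0.2)
        model = dediff.fit_differentiation_axis(mat, anchors, 3)
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(3), atol=1e-9)

    def test_excess_components_warn_and_truncate(self):
        mat, _, anchors = self.planted()
        with pytest.warns(UserWarning, match="truncating"):
            model = dediff.fit_differentiation_axis(mat, anchors, 50)
        assert model.loadings.shape[1] == mat.shape[1] - 1

    def test_too_few_samples_rejected(self):
        mat, _, _ = self.planted()
        with pytest.raises(ValueError):
            dediff.fit_differentiation_axis(mat.iloc[:, :2], ["s0"], 1)


class TestProjection:
    def test_reference_samples_reproduce_their_own_scores(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(size=(30, 8)),
                           index=[f"g{i}" for i in range(30)],
                           columns=[f"s{j}" for j in range(8)])
        model = dediff.fit_differentiation_axis(mat, ["s7"], 2)
        proj = dediff.project_samples(model, mat)
        assert np.allclose(proj, model.scores["PC1"], atol=1e-9)

    def test_constant_gene_shift_moves_all_scores_equally(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(size=(25, 6)),
                           index=[f"g{i}" for i in range(25)],
                           columns=[f"s{j}" for j in range(6)])
        model = dediff.fit_differentiation_axis(mat, ["s5"], 2)
        shift = rng.normal(size=25)
        shifted = mat.add(shift, axis=0)
        p0 = dediff.project_samples(model, mat)
        p1 = dediff.project_samples(model, shifted)
        deltas = (p1 - p0).to_numpy()
        assert np.allclose(deltas, deltas[0], atol=1e-9)

    def test_extra_genes_ignored_missing_rejected(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.normal(size=(10, 4)),
                           index=[f"g{i}" for i in range(10)],
                           columns=[f"s{j}" for j in range(4)])
        model = dediff.fit_differentiation_axis(mat, ["s3"], 2)
        extra = pd.concat([mat, mat.iloc[:1].rename(index={"g0": "gX"})])
        assert np.allclose(dediff.project_samples(model, extra),
                           model.scores["PC1"], atol=1e-9)
        with pytest.raises(ValueError, match="g0"):
            dediff.project_samples(model, mat.drop(index="g0"))


class TestMetaFoldChange:
    def test_median_worked_example(self):
        fc = [pd.Series({"a": 1.0, "b": -1.0}),
              pd.Series({"a": 3.0, "b": -2.0}),
              pd.Series({"a": 2.0, "b": 6.0})]
        med = dediff.meta_fold_change(fc)
        assert med["a"] == 2.0 and med["b"] == -1.0

    def test_min_studies_filter(self):
        fc = [pd.Series({"a": 1.0, "b": 2.0}), pd.Series({"a": 3.0})]
        med = dediff.meta_fold_change(fc, min_studies=2)
        assert list(med.index) == ["a"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dediff.meta_fold_change([])


class TestEndToEndDediff:
    def test_injured_samples_score_below_controls_after_correction(self):
        cfg = SyntheticConfig(rng_seed=0)
        ref, injury, meta, truth = generate_differentiation_series(cfg)
        anchors = list(meta.index[meta["role"] == "adult_anchor"])
        model = dediff.fit_differentiation_axis(ref, anchors, 3)
        scores = list(model.scores["PC1"])
        stages = [truth.sample_stage[c] for c in ref.columns]
        for batch in sorted(meta.loc[injury.columns, "batch"].unique()):
            cols = meta.index[(meta["batch"] == batch)]
            ctrl = [c for c in cols if meta.loc[c, "role"] ==
                    "control_anchor"]
            corrected = dediff.batch_correct_mean_only(
                ref, injury[cols], anchors, ctrl)
            proj = dediff.project_samples(model, corrected)
            for c in cols:
                scores.append(proj[c])
                stages.append(truth.sample_stage[c])
        rho = spearmanr(scores, stages).statistic
        assert rho >= 0.95

    def test_correction_moves_controls_onto_reference_anchors(self):
        # the per-study batch offset separates the injury controls from
        # the reference adult anchors in gene space; mean-only correction
        # against the anchors must close that gap
        cfg = SyntheticConfig(rng_seed=0)
        ref, injury, meta, _ = generate_differentiation_series(cfg)
        anchors = list(meta.index[meta["role"] == "adult_anchor"])
        anchor_mean = ref[anchors].mean(axis=1)
        for batch in sorted(meta.loc[injury.columns, "batch"].unique()):
            cols = meta.index[meta["batch"] == batch]
            ctrl = [c for c in cols
                    if meta.loc[c, "role"] == "control_anchor"]
            corrected = dediff.batch_correct_mean_only(
                ref, injury[cols], anchors, ctrl)
            raw_gap = np.linalg.norm(
                injury[ctrl].mean(axis=1) - anchor_mean)
            fixed_gap = np.linalg.norm(
                corrected[ctrl].mean(axis=1) - anchor_mean)
            assert fixed_gap < 0.1 * raw_gap
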