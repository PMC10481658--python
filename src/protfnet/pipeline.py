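"""End-to-end orchestration of the analysis stages from one config.

Stages run in dependency order (synth -> binding -> som -> corecruit ->
programs -> controls -> dediff), write plain-text outputs atomically into
the run directory, and append to a tab-separated manifest recording, per
stage, the parameters, seed, output files with SHA-256 hashes, and wall
time. Reruns with an unchanged config and intact outputs are skipped, so an
interrupted run resumes from the last completed stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import binding, controls, corecruit, dediff, io, programs, som
from .synthetic import (GroundTruth, SyntheticConfig, generate_cistromes,
                        generate_differentiation_series,
                        generate_expression_atlas,
                        generate_perturbation_dataset, generate_signal_tracks,
                        generate_tss_annotation)

log = logging.getLogger("protfnet")

STAGES = ["synth", "binding", "som", "corecruit", "programs", "controls",
          "dediff"]


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys in the YAML are rejected."""

    seed: int = 0
    outdir: str = "protfnet_run"
    # synthetic-data conditions
    n_tfs: int = 20
    n_promoters: int = 300
    n_binding_clusters: int = 4
    binding_noise: float = 0.0
    n_celltypes_per_species: int = 30
    n_connect_planted: int = 5
    activity_levels: int = 4
    fc_effect_size: float = -1.0
    # SOM / clustering
    som_rows: int | None = None
    som_cols: int | None = None
    som_epochs: int = 30
    n_clusters: int = 0  # 0 -> homogeneity elbow
    # co-recruitment mining
    min_support: float = 0.5
    itemset_size_min: int = 2
    itemset_size_max: int | None = None
    # expression programs
    mfa_components: int = 5
    n_programs: int = 3
    rank_threshold: int = 10
    # matched controls
    strata_k: int = 4
    n_control_iter: int = 1000

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def synthetic(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_tfs=self.n_tfs, n_promoters=self.n_promoters,
            n_binding_clusters=self.n_binding_clusters,
            binding_noise=self.binding_noise,
            n_celltypes_per_species=self.n_celltypes_per_species,
            n_connect_planted=self.n_connect_planted,
            activity_levels=self.activity_levels,
            fc_effect_size=self.fc_effect_size, rng_seed=self.seed,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write(path: str, writer) -> None:
    tmp = path + ".tmp"
    writer(tmp)
    os.replace(tmp, path)


class Pipeline:
    """Stage runner bound to one RunConfig."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = config.outdir
        os.makedirs(self.outdir, exist_ok=True)
        self.manifest_path = os.path.join(self.outdir, "manifest.tsv")
        # per-run log file; delay=True so a dry run writes nothing
        log_path = os.path.abspath(os.path.join(self.outdir, "run.log"))
        for h in list(log.handlers):
            if isinstance(h, logging.FileHandler):
                log.removeHandler(h)
                h.close()
        handler = logging.FileHandler(log_path, delay=True)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)

    # -- manifest bookkeeping -------------------------------------------
    def _params_digest(self, stage: str) -> str:
        params = asdict(self.config)
        params.pop("outdir")  # storage location, not a parameter
        payload = json.dumps({"stage": stage, **params},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def _manifest(self) -> pd.DataFrame:
        cols = ["stage", "params_digest", "output", "sha256", "seed",
                "wall_time_s"]
        if os.path.exists(self.manifest_path):
            return pd.read_csv(self.manifest_path, sep="\t",
                               dtype={"params_digest": str, "sha256": str})
        return pd.DataFrame(columns=cols)

    def _stage_done(self, stage: str) -> bool:
        m = self._manifest()
        rows = m[(m["stage"] == stage)
                 & (m["params_digest"] == self._params_digest(stage))]
        if rows.empty:
            return False
        for _, r in rows.iterrows():
            path = os.path.join(self.outdir, r["output"])
            if not os.path.exists(path) or _sha256(path) != r["sha256"]:
                return False
        return True

    def _record(self, stage: str, outputs: list[str], wall: float) -> None:
        m = self._manifest()
        m = m[m["stage"] != stage]
        rows = [{
            "stage": stage, "params_digest": self._params_digest(stage),
            "output": os.path.relpath(p, self.outdir), "sha256": _sha256(p),
            "seed": self.config.seed, "wall_time_s": round(wall, 3),
        } for p in outputs]
        new = pd.DataFrame(rows)
        m = new if m.empty else pd.concat([m, new], ignore_index=True)
        _atomic_write(self.manifest_path,
                      lambda t: m.to_csv(t, sep="\t", index=False))

    def _path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    # -- stages ---------------------------------------------------------
    def run_stage(self, name: str, force: bool = False) -> list[str]:
        if name not in STAGES:
            raise ValueError(f"unknown stage '{name}'; valid: {STAGES}")
        if not force and self._stage_done(name):
            log.info("stage %s cached, skipping", name)
            return []
        upstream = STAGES[: STAGES.index(name)]
        for up in upstream:
            if not self._stage_done(up):
                raise RuntimeError(
                    f"stage '{name}' needs upstream stage '{up}' "
                    f"(run it first)")
        t0 = time.monotonic()
        log.info("stage %s starting (seed=%d, params=%s)", name,
                 self.config.seed, self._params_digest(name))
        outputs = getattr(self, f"_stage_{name}")()
        wall = time.monotonic() - t0
        self._record(name, outputs, wall)
        log.info("stage %s done in %.2fs (%d outputs)", name, wall,
                 len(outputs))
        return outputs

    def run_all(self, dry_run: bool = False) -> pd.DataFrame:
        if dry_run:
            for s in STAGES:
                state = "cached" if self._stage_done(s) else "pending"
                print(f"{s}\t{state}")
            return self._manifest()
        for s in STAGES:
            self.run_stage(s)
        return self._manifest()

    def _stage_synth(self) -> list[str]:
        cfg = self.config.synthetic()
        truth = GroundTruth()
        cistromes, truth = generate_cistromes(cfg, truth)
        tss, truth = generate_tss_annotation(cfg, truth, n_ambiguous=2)
        tracks, domains = generate_signal_tracks(cfg, truth)
        atlases, truth = generate_expression_atlas(cfg, truth)
        studies = generate_perturbation_dataset(cfg, truth)
        ref, injury, meta, truth = generate_differentiation_series(cfg, truth)
        out = []
        for tf, df in cistromes.items():
            p = self._path(f"cistrome_{tf}.bed")
            _atomic_write(p, lambda t, df=df: io.write_bed(df, t))
            out.append(p)
        for nm, obj in (("tss.bed", tss), ("h3k4me3_domains.bed", domains)):
            p = self._path(nm)
            _atomic_write(p, lambda t, o=obj: io.write_bed(o, t))
            out.append(p)
        for nm, tr in tracks.items():
            p = self._path(f"track_{nm}.bedgraph")
            _atomic_write(p, lambda t, tr=tr: io.write_bedgraph(tr, t))
            out.append(p)
        for sp, df in atlases.items():
            p = self._path(f"atlas_{sp}.tsv")
            _atomic_write(p, lambda t, df=df: io.write_matrix(df, t))
            out.append(p)
        fc = pd.DataFrame(studies)
        p = self._path("perturbation_fc.tsv")
        _atomic_write(p, lambda t: io.write_matrix(fc, t))
        out.append(p)
        for nm, df in (("reference_series.tsv", ref),
                       ("injury_samples.tsv", injury),
                       ("sample_metadata.tsv", meta)):
            p = self._path(nm)
            _atomic_write(p, lambda t, df=df: io.write_matrix(df, t))
            out.append(p)
        p = self._path("ground_truth.tsv")
        _atomic_write(p, truth.save)
        out.append(p)
        return out

    def _stage_binding(self) -> list[str]:
        cfg = self.config.synthetic()
        cistromes = {tf: io.read_bed(self._path(f"cistrome_{tf}.bed"))
                     if os.path.getsize(self._path(f"cistrome_{tf}.bed"))
                     else pd.DataFrame(columns=io.BED_COLUMNS)
                     for tf in cfg.tf_names}
        tss = io.read_bed(self._path("tss.bed"))
        crms = binding.merge_peaks_to_crms(cistromes)
        records = binding.map_crms_to_promoters(
            crms, tss, gene_filter=set(cfg.gene_ids))
        matrix = binding.build_binding_matrix(records,
                                              tf_universe=cfg.tf_names)
        track = io.read_bedgraph(self._path("track_h3k27ac.bedgraph"))
        signal = binding.extract_promoter_signal(track, records)
        out = []
        p = self._path("binding_matrix.tsv")
        _atomic_write(p, lambda t: io.write_matrix(matrix, t))
        out.append(p)
        p = self._path("promoter_signal.tsv")
        _atomic_write(p, lambda t: signal.rename("h3k27ac_max").to_csv(
            t, sep="\t"))
        out.append(p)
        return out

    def _stage_som(self) -> list[str]:
        matrix = io.read_matrix(self._path("binding_matrix.tsv"))
        grid, assignment = som.train_som(
            matrix, rows=self.config.som_rows, cols=self.config.som_cols,
            epochs=self.config.som_epochs, seed=self.config.seed)
        protos = som.binarize_prototypes(grid)
        n_distinct = len(protos.drop_duplicates())
        k = self.config.n_clusters
        if k <= 0:
            curve, k = som.homogeneity_analysis(
                protos, range(2, min(10, n_distinct) + 1))
        k = min(k, n_distinct)
        labels = som.cluster_som_cells(protos, max(k, 2))
        clusters = assignment.apply(
            lambda r: labels[(r["row"], r["col"])], axis=1)
        out = []
        p = self._path("som_prototypes.tsv")
        _atomic_write(p, lambda t: protos.reset_index().to_csv(
            t, sep="\t", index=False))
        out.append(p)
        p = self._path("som_clusters.tsv")
        df = assignment.copy()
        df["cluster"] = clusters
        _atomic_write(p, lambda t: df.to_csv(t, sep="\t"))
        out.append(p)
        return out

    def _stage_corecruit(self) -> list[str]:
        matrix = io.read_matrix(self._path("binding_matrix.tsv"))
        clusters = pd.read_csv(self._path("som_clusters.tsv"), sep="\t",
                               index_col=0)
        out = []
        occ_rows = []
        for label, sub in clusters.groupby("cluster"):
            cm = matrix.loc[sub.index]
            if cm.shape[0] < 2:
                continue
            isets = corecruit.mine_frequent_itemsets(
                cm, min_support=self.config.min_support,
                size_min=self.config.itemset_size_min,
                size_max=self.config.itemset_size_max)
            occ = corecruit.core_node_occurrence(isets, list(matrix.columns))
            occ_rows.append(occ.rename(label))
            p = self._path(f"core_itemsets_{label}.tsv")
            dump = isets.copy()
            dump["itemset"] = dump["itemset"].map(
                lambda s: ",".join(sorted(s)))
            _atomic_write(p, lambda t, d=dump: d.to_csv(t, sep="\t",
                                                        index=False))
            out.append(p)
        tan = corecruit.tanimoto_distance_matrix(matrix)
        emb = corecruit.mds_embedding(tan, dims=2)
        for nm, df in (("tanimoto.tsv", tan), ("mds.tsv", emb),
                       ("core_node_occurrence.tsv",
                        pd.DataFrame(occ_rows).T)):
            p = self._path(nm)
            _atomic_write(p, lambda t, df=df: io.write_matrix(df, t))
            out.append(p)
        return out

    def _stage_programs(self) -> list[str]:
        mouse = io.read_matrix(self._path("atlas_mouse.tsv"))
        human = io.read_matrix(self._path("atlas_human.tsv"))
        res = programs.mfa({"mouse": mouse, "human": human},
                           n_components=self.config.mfa_components)
        both = pd.concat([mouse, human], axis=1)
        hc = programs.high_expression_counts(both)
        calls = programs.cluster_tf_programs(res.scores, hc,
                                             k=self.config.n_programs)
        focal = [c for c in mouse.columns if "hepatocyte" in c][0]
        connect = programs.select_connect_tfs(
            mouse, focal, rank_threshold=self.config.rank_threshold)
        connect["program"] = calls
        connect.loc[connect["program"] == "CTS", "selected"] = False
        out = []
        for nm, df in (("mfa_scores.tsv", res.scores),
                       ("connect_calls.tsv", connect)):
            p = self._path(nm)
            _atomic_write(p, lambda t, df=df: io.write_matrix(df, t))
            out.append(p)
        p = self._path("program_calls.tsv")
        _atomic_write(p, lambda t: calls.to_csv(t, sep="\t"))
        out.append(p)
        return out

    def _stage_controls(self) -> list[str]:
        truth = GroundTruth.load(self._path("ground_truth.tsv"))
        signal = pd.read_csv(self._path("promoter_signal.tsv"), sep="\t",
                             index_col=0)["h3k27ac_max"]
        dhs = io.read_bedgraph(self._path("track_dhs.bedgraph"))
        tss = io.read_bed(self._path("tss.bed"))
        fc = io.read_matrix(self._path("perturbation_fc.tsv"))
        genes = [g for g in fc.index if g in truth.gene_group]
        # three activity features: accessibility, acetylation, expression
        pos = {r.name: (r.chrom, r.start) for r in tss.itertuples(False)}
        feats = pd.DataFrame({
            "dhs": [dhs.mean_over(pos[g][0], pos[g][1] - 500,
                                  pos[g][1] + 500) if g in pos else 0.0
                    for g in genes],
            "h3k27ac": signal.reindex(genes).fillna(0.0).to_numpy(),
            "expression": [2.0 ** truth.activity_stratum[g] for g in genes],
        }, index=genes)
        strata = controls.activity_strata(feats, k=self.config.strata_k)
        identity = [g for g in genes
                    if truth.gene_group.get(g) == "identity"]
        pool = [g for g in genes if truth.gene_group.get(g) != "identity"]
        ens = controls.sample_matched_controls(
            identity, pool, strata, n_iter=self.config.n_control_iter,
            seed=self.config.seed)
        study = fc.columns[0]

        def stat(id_genes, ctl_genes):
            return controls.group_shift_test(
                fc.loc[id_genes, study], fc.loc[ctl_genes, study],
                alternative="less")

        ens = controls.select_representative_set(ens, stat)
        rep = ens.sets[ens.representative]
        out = []
        p = self._path("control_pvalues.tsv")
        _atomic_write(p, lambda t: pd.Series(
            ens.p_values, name="p").to_csv(t, sep="\t", index_label="set"))
        out.append(p)
        p = self._path("representative_controls.tsv")
        _atomic_write(p, lambda t: pd.Series(
            rep, name="gene").to_csv(t, sep="\t", index=False))
        out.append(p)
        p = self._path("activity_strata.tsv")
        _atomic_write(p, lambda t: strata.labels.to_csv(t, sep="\t"))
        out.append(p)
        return out

    def _stage_dediff(self) -> list[str]:
        ref = io.read_matrix(self._path("reference_series.tsv"))
        injury = io.read_matrix(self._path("injury_samples.tsv"))
        meta = io.read_matrix(self._path("sample_metadata.tsv"))
        adult = meta.index[meta["role"] == "adult_anchor"].tolist()
        model = dediff.fit_differentiation_axis(ref, mature_anchors=adult)
        scores = {s: model.scores.loc[s, "PC1"] for s in ref.columns}
        fcs = []
        for batch, sub in meta[meta["batch"] != "reference"].groupby("batch"):
            cols = [c for c in sub.index if c in injury.columns]
            anchors = sub.index[sub["role"] == "control_anchor"].tolist()
            corrected = dediff.batch_correct_mean_only(
                ref, injury[cols], adult, anchors)
            proj = dediff.project_samples(model, corrected)
            scores.update(proj.to_dict())
            injured = sub.index[sub["role"] == "injured"].tolist()
            fcs.append((corrected[injured].mean(axis=1)
                        - corrected[anchors].mean(axis=1)).rename(batch))
        meta_fc = dediff.meta_fold_change(fcs)
        out = []
        p = self._path("dediff_scores.tsv")
        _atomic_write(p, lambda t: pd.Series(scores, name="PC1").to_csv(
            t, sep="\t", index_label="sample"))
        out.append(p)
        p = self._path("meta_fold_change.tsv")
        _atomic_write(p, lambda t: meta_fc.rename("median_log2fc").to_csv(
            t, sep="\t"))
        out.append(p)
        return out
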