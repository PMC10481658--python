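"""Synthetic cistrome / transcriptome generator with serialized ground truth.

Every generator is a pure function of its configuration: the root seed fans
out to one independent child seed per stage, so a stage regenerated with the
same config reproduces its output byte for byte regardless of what else ran.

The generated data emulate the statistical structure a promoter-centric TF
network analysis assumes: blocks of promoters co-bound by planted regulator
sets, promoter activity strata with correlated accessibility/acetylation/
expression, a two-species expression atlas with specific/enriched/ubiquitous
TF programs and a focal ("hepatocyte-like") cell type, perturbation
fold-change tables with planted group shifts, and a differentiation series
with batch-offset injury samples along a planted maturation axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SignalTrack, write_truth, read_truth

CHROM = "chrS"
PEAK_HALF_WIDTH = 100
PROMOTER_SPACING = 20_000  # >= 2x max peak width, avoids cross-promoter merges
FIRST_PROMOTER = 10_000

_STAGE_NAMES = (
    "cistromes", "tss", "signal", "atlas", "perturbation", "differentiation",
)


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generators.

    ``cluster_tf_sets`` plants one co-binding block per entry: every promoter
    assigned to that block carries peaks of exactly those TFs (before noise).
    ``binding_noise`` is the Bernoulli flip probability applied to each
    promoter x TF binding indicator. ``program_sizes`` gives the number of
    cell-type-specific, cell-type-enriched and ubiquitous TFs in the atlas.
    """

    n_tfs: int = 20
    n_promoters: int = 300
    n_binding_clusters: int = 4
    cluster_tf_sets: list[list[str]] | None = None
    binding_noise: float = 0.0
    n_celltypes_per_species: int = 30
    program_sizes: tuple[int, int, int] | None = None
    n_connect_planted: int | None = None  # default: min(5, n CTE+UBQ TFs)
    activity_levels: int = 4
    fc_effect_size: float = -1.0
    expression_noise: float = 0.3
    signal_noise: float = 0.2
    fc_noise: float = 0.3
    n_identity_genes: int = 10
    n_effector_genes: int = 20
    identity_breadth: int = 5000
    background_breadth: int = 1000
    rng_seed: int = 0

    tf_names: list[str] = field(init=False)
    gene_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        for name in ("n_tfs", "n_promoters", "n_binding_clusters",
                     "n_celltypes_per_species", "activity_levels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.binding_noise <= 1.0:
            raise ValueError("binding_noise must be a probability in [0, 1]")
        for name in ("expression_noise", "signal_noise", "fc_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.tf_names = [f"TF{i:02d}" for i in range(self.n_tfs)]
        self.gene_ids = [f"gene{i:04d}" for i in range(self.n_promoters)]
        if self.cluster_tf_sets is None:
            # default: disjoint equal splits of the TF universe, each >= 2 TFs
            splits = np.array_split(np.arange(self.n_tfs),
                                    self.n_binding_clusters)
            self.cluster_tf_sets = [
                [self.tf_names[i] for i in block] for block in splits
            ]
        if len(self.cluster_tf_sets) != self.n_binding_clusters:
            raise ValueError("cluster_tf_sets length != n_binding_clusters")
        universe = set(self.tf_names)
        for s in self.cluster_tf_sets:
            unknown = set(s) - universe
            if unknown:
                raise ValueError(f"cluster TF set references unknown TFs: "
                                 f"{sorted(unknown)}")
            if len(s) < 2:
                raise ValueError("each planted cluster needs >= 2 TFs")
        if self.program_sizes is None:
            third = self.n_tfs // 3
            self.program_sizes = (third, third, self.n_tfs - 2 * third)
        if self.n_celltypes_per_species < 6:
            raise ValueError("need >= 6 cell types per species (focal cell, "
                             "enriched block, and free specific cells)")
        if sum(self.program_sizes) > self.n_tfs:
            raise ValueError("program_sizes sum exceeds n_tfs")
        non_specific = self.program_sizes[1] + self.program_sizes[2]
        if self.n_connect_planted is None:
            self.n_connect_planted = min(5, non_specific)
        if self.n_connect_planted <= 0:
            raise ValueError("n_connect_planted must be > 0")
        if self.n_connect_planted > non_specific:
            raise ValueError("n_connect_planted exceeds CTE+UBQ TF count")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible generator for one pipeline stage."""
        idx = _STAGE_NAMES.index(stage)
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed).spawn(len(_STAGE_NAMES))[idx]
        )


@dataclass
class GroundTruth:
    """Planted structure, keyed by the entity identifiers the outputs use."""

    promoter_cluster: dict[str, int] = field(default_factory=dict)
    tf_program: dict[str, str] = field(default_factory=dict)
    activity_stratum: dict[str, int] = field(default_factory=dict)
    connect_flag: dict[str, bool] = field(default_factory=dict)
    gene_group: dict[str, str] = field(default_factory=dict)
    sample_stage: dict[str, float] = field(default_factory=dict)
    sample_batch: dict[str, float] = field(default_factory=dict)
    ambiguous_tss: dict[str, bool] = field(default_factory=dict)

    def save(self, path) -> None:
        write_truth({
            "promoter_cluster": self.promoter_cluster,
            "tf_program": self.tf_program,
            "activity_stratum": self.activity_stratum,
            "connect_flag": {k: int(v) for k, v in self.connect_flag.items()},
            "gene_group": self.gene_group,
            "sample_stage": self.sample_stage,
            "sample_batch": self.sample_batch,
            "ambiguous_tss": {k: int(v) for k, v in
                              self.ambiguous_tss.items()},
        }, path)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        raw = read_truth(path)
        t = cls()
        t.promoter_cluster = {k: int(v) for k, v in
                              raw.get("promoter_cluster", {}).items()}
        t.tf_program = dict(raw.get("tf_program", {}))
        t.activity_stratum = {k: int(v) for k, v in
                              raw.get("activity_stratum", {}).items()}
        t.connect_flag = {k: bool(int(v)) for k, v in
                          raw.get("connect_flag", {}).items()}
        t.gene_group = dict(raw.get("gene_group", {}))
        t.sample_stage = {k: float(v) for k, v in
                          raw.get("sample_stage", {}).items()}
        t.sample_batch = {k: float(v) for k, v in
                          raw.get("sample_batch", {}).items()}
        t.ambiguous_tss = {k: bool(int(v)) for k, v in
                           raw.get("ambiguous_tss", {}).items()}
        return t


def promoter_tss_position(i: int) -> int:
    return FIRST_PROMOTER + i * PROMOTER_SPACING


def generate_cistromes(config: SyntheticConfig,
                       truth: GroundTruth | None = None
                       ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-TF peak sets with planted co-binding blocks.

    Promoters are assigned round-robin to planted clusters; each promoter
    receives one peak per TF of its cluster's set, then each promoter x TF
    indicator is flipped with probability ``binding_noise``.
    Returns {tf_name: BED DataFrame} plus the (updated) ground truth.
    """
    rng = config.stage_rng("cistromes")
    truth = truth or GroundTruth()
    n_clusters = config.n_binding_clusters
    tf_index = {tf: j for j, tf in enumerate(config.tf_names)}

    bound = np.zeros((config.n_promoters, config.n_tfs), dtype=bool)
    for i, gene in enumerate(config.gene_ids):
        label = i % n_clusters
        truth.promoter_cluster[gene] = label
        for tf in config.cluster_tf_sets[label]:
            bound[i, tf_index[tf]] = True
    if config.binding_noise > 0:
        flips = rng.random(bound.shape) < config.binding_noise
        bound = bound ^ flips

    cistromes: dict[str, pd.DataFrame] = {}
    for j, tf in enumerate(config.tf_names):
        rows = []
        for i in np.flatnonzero(bound[:, j]):
            tss = promoter_tss_position(int(i))
            rows.append((CHROM, tss - PEAK_HALF_WIDTH, tss + PEAK_HALF_WIDTH,
                         f"{tf}_peak{i}"))
        cistromes[tf] = pd.DataFrame(rows,
                                     columns=["chrom", "start", "end", "name"])
    return cistromes, truth


def generate_tss_annotation(config: SyntheticConfig,
                            truth: GroundTruth | None = None,
                            n_ambiguous: int = 0
                            ) -> tuple[pd.DataFrame, GroundTruth]:
    """Active-TSS BED with gene ids, plus planted ambiguous associations.

    Each requested ambiguous unit plants one shared TSS claimed by two decoy
    genes and one decoy gene owning two TSSs, downstream of the real loci.
    """
    truth = truth or GroundTruth()
    rows = []
    for i, gene in enumerate(config.gene_ids):
        tss = promoter_tss_position(i)
        rows.append((CHROM, tss, tss + 1, gene))
        truth.ambiguous_tss[gene] = False
    base = promoter_tss_position(config.n_promoters) + PROMOTER_SPACING
    for a in range(n_ambiguous):
        pos = base + a * PROMOTER_SPACING
        if a % 2 == 0:  # one TSS claimed by two genes
            g1, g2 = f"ambig{a}a", f"ambig{a}b"
            rows.append((CHROM, pos, pos + 1, g1))
            rows.append((CHROM, pos, pos + 1, g2))
            truth.ambiguous_tss[g1] = True
            truth.ambiguous_tss[g2] = True
        else:  # one gene with two TSSs
            g = f"ambig{a}"
            rows.append((CHROM, pos, pos + 1, g))
            rows.append((CHROM, pos + 500, pos + 501, g))
            truth.ambiguous_tss[g] = True
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df = df.sort_values(["chrom", "start", "name"],
                        kind="stable").reset_index(drop=True)
    return df, truth


def _assign_strata_and_groups(config: SyntheticConfig,
                              truth: GroundTruth) -> None:
    if truth.activity_stratum:
        return
    k = config.activity_levels
    for i, gene in enumerate(config.gene_ids):
        truth.activity_stratum[gene] = (i % k) + 1
    n_id, n_eff = config.n_identity_genes, config.n_effector_genes
    for i, gene in enumerate(config.gene_ids):
        if i < n_id:
            truth.gene_group[gene] = "identity"
        elif i < n_id + n_eff:
            truth.gene_group[gene] = "effector"
        else:
            truth.gene_group[gene] = "control"


def generate_signal_tracks(config: SyntheticConfig, truth: GroundTruth
                           ) -> tuple[dict[str, SignalTrack], pd.DataFrame]:
    """DHS / H3K27ac / H3K4me3 bedGraph tracks plus H3K4me3 domain BED.

    Promoter signal means double with each planted activity stratum; genes in
    the planted identity group get broad H3K4me3 domains. Multiplicative
    lognormal noise of scale ``signal_noise`` is applied per promoter bin.
    """
    rng = config.stage_rng("signal")
    _assign_strata_and_groups(config, truth)
    tracks = {name: SignalTrack() for name in ("dhs", "h3k27ac", "h3k4me3")}
    base_level = {s: 2.0 ** s for s in range(1, config.activity_levels + 1)}

    starts, ends = [], []
    values = {name: [] for name in tracks}
    domain_rows = []
    for i, gene in enumerate(config.gene_ids):
        tss = promoter_tss_position(i)
        stratum = truth.activity_stratum[gene]
        level = base_level[stratum]
        starts.append(tss - 500)
        ends.append(tss + 500)
        for name in tracks:
            noise = (np.exp(rng.normal(0.0, config.signal_noise))
                     if config.signal_noise > 0 else 1.0)
            values[name].append(level * noise)
        breadth = (config.identity_breadth
                   if truth.gene_group.get(gene) == "identity"
                   else config.background_breadth)
        half = breadth // 2
        domain_rows.append((CHROM, max(tss - half, 0),
                            max(tss - half, 0) + breadth, gene))
    for name, track in tracks.items():
        track.add(CHROM, starts, ends, values[name])
    domains = pd.DataFrame(domain_rows,
                           columns=["chrom", "start", "end", "name"])
    return tracks, domains


def generate_expression_atlas(config: SyntheticConfig,
                              truth: GroundTruth | None = None
                              ) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Two TF x cell-type matrices sharing a TF universe, plus truth labels.

    Cell type 0 of each species is the focal ("hepatocyte_like") type.
    Specific TFs are expressed in one cell type only; enriched TFs in a small
    subset; ubiquitous TFs everywhere. Planted connect TFs (drawn from the
    enriched/ubiquitous programs) are built so the focal cell ranks first and
    the fold-difference versus the other cells' mean is positive.
    """
    rng = config.stage_rng("atlas")
    truth = truth or GroundTruth()
    n_spec, n_enr, n_ubq = config.program_sizes
    labels = (["CTS"] * n_spec + ["CTE"] * n_enr + ["UBQ"] * n_ubq)
    labels += ["UBQ"] * (config.n_tfs - len(labels))
    for tf, lab in zip(config.tf_names, labels):
        truth.tf_program[tf] = lab
        truth.connect_flag[tf] = False
    # interleave CTE and UBQ TFs so connect status spans both programs
    cte = [tf for tf in config.tf_names if truth.tf_program[tf] == "CTE"]
    ubq = [tf for tf in config.tf_names if truth.tf_program[tf] == "UBQ"]
    interleaved = [tf for pair in zip(cte, ubq) for tf in pair]
    interleaved += cte[len(ubq):] + ubq[len(cte):]
    for tf in interleaved[: config.n_connect_planted]:
        truth.connect_flag[tf] = True

    n_ct = config.n_celltypes_per_species
    atlases: dict[str, pd.DataFrame] = {}
    for species in ("mouse", "human"):
        cols = [f"{species}_ct{c:02d}" for c in range(n_ct)]
        cols[0] = f"{species}_hepatocyte_like"
        mat = np.zeros((config.n_tfs, n_ct))
        for r, tf in enumerate(config.tf_names):
            program = truth.tf_program[tf]
            connect = truth.connect_flag[tf]
            if program == "CTS":
                # one expressing cell type; never the focal cell (so the
                # focal-rank selection cannot pick a specific TF) and
                # never a cell of the shared enriched block below
                mat[r, 4 + r % (n_ct - 4)] = 10.0
            elif program == "CTE":
                # enriched TFs share one block of related cell types,
                # mirroring a lineage-correlated expression program
                subset = 1 + np.arange(3)
                mat[r, subset] = 8.0
                if connect:  # enriched subset contains the focal cell,
                    mat[r, 0] = 9.0  # which is strictly highest
            else:
                mat[r, :] = 5.0
                if connect:
                    mat[r, 0] = 6.5
        if config.expression_noise > 0:
            noise = rng.normal(0.0, config.expression_noise, mat.shape)
            mat = np.clip(mat + noise * (mat > 0), 0.0, None)
        atlases[species] = pd.DataFrame(mat, index=config.tf_names,
                                        columns=cols)
    return atlases, truth


def generate_perturbation_dataset(config: SyntheticConfig, truth: GroundTruth,
                                  target_group: str = "identity",
                                  n_studies: int = 3
                                  ) -> dict[str, pd.Series]:
    """Per-study log2 fold-change tables with a planted group shift.

    Genes of ``target_group`` get mean shift ``fc_effect_size`` (log2 units);
    all other genes have mean 0. I.i.d. Gaussian noise of SD ``fc_noise``.
    """
    rng = config.stage_rng("perturbation")
    _assign_strata_and_groups(config, truth)
    studies: dict[str, pd.Series] = {}
    for s in range(n_studies):
        shift = np.array([
            config.fc_effect_size
            if truth.gene_group.get(g) == target_group else 0.0
            for g in config.gene_ids
        ])
        noise = (rng.normal(0.0, config.fc_noise, len(shift))
                 if config.fc_noise > 0 else 0.0)
        studies[f"study{s}"] = pd.Series(shift + noise,
                                         index=config.gene_ids,
                                         name=f"study{s}")
    return studies


def generate_differentiation_series(config: SyntheticConfig,
                                    truth: GroundTruth | None = None,
                                    n_stages: int = 6,
                                    n_reps: int = 2,
                                    n_injury_studies: int = 3,
                                    injury_shift: float = -2.0,
                                    batch_scale: float = 3.0,
                                    noise_sd: float = 0.1
                                    ) -> tuple[pd.DataFrame, pd.DataFrame,
                                               pd.DataFrame, GroundTruth]:
    """Reference differentiation series and batch-offset injury samples.

    Expression of gene g in sample s is ``mu_g + loading_g * stage_s +
    batch_s + noise``; the loading vector makes the stage the dominant axis.
    Injury samples sit ``injury_shift`` stages below the adult anchors and
    carry a per-study constant batch offset. Returns (reference genes x
    samples, injury genes x samples, sample metadata, truth).
    """
    rng = config.stage_rng("differentiation")
    truth = truth or GroundTruth()
    genes = config.gene_ids
    mu = rng.normal(5.0, 1.0, len(genes))
    loading = rng.normal(0.0, 1.0, len(genes))

    ref_cols, ref_data, meta = [], [], []
    adult_stage = float(n_stages)
    for stage in range(1, n_stages + 1):
        for rep in range(n_reps):
            name = f"ref_stage{stage}_rep{rep}"
            ref_cols.append(name)
            ref_data.append(mu + loading * stage
                            + rng.normal(0.0, noise_sd, len(genes)))
            role = "adult_anchor" if stage == n_stages else "reference"
            meta.append((name, "reference", role))
            truth.sample_stage[name] = float(stage)
            truth.sample_batch[name] = 0.0
    reference = pd.DataFrame(np.column_stack(ref_data), index=genes,
                             columns=ref_cols)

    inj_cols, inj_data = [], []
    for s in range(n_injury_studies):
        offset = batch_scale * (s + 1)
        for role, stage in (("control_anchor", adult_stage),
                            ("injured", adult_stage + injury_shift)):
            for rep in range(n_reps):
                name = f"injury{s}_{role.split('_')[0]}_rep{rep}"
                inj_cols.append(name)
                inj_data.append(mu + loading * stage + offset
                                + rng.normal(0.0, noise_sd, len(genes)))
                meta.append((name, f"injury{s}", role))
                truth.sample_stage[name] = stage
                truth.sample_batch[name] = offset
    injury = pd.DataFrame(np.column_stack(inj_data), index=genes,
                          columns=inj_cols)
    metadata = pd.DataFrame(meta, columns=["sample", "batch", "role"]
                            ).set_index("sample")
    return reference, injury, metadata, truth
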