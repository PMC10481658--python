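"""From peak sets and TSS annotations to the promoter binding matrix.

A cis-regulatory module (CRM) is a merged genomic region bound by at least
two distinct transcriptional regulators: peaks from all cistromes are pooled
and merged by single-linkage overlap (>= 1 shared base, strand-ignored),
each merged region keeps the set of contributing TFs, and regions with fewer
than two distinct TFs are discarded. Promoters are genes whose active TSS
(a width-1 interval at the summit base) falls inside a CRM; the binary
promoter x regulator matrix built from those records is what the SOM,
itemset and Tanimoto analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SignalTrack


@dataclass(frozen=True)
class CisRegulatoryModule:
    chrom: str
    start: int
    end: int
    bound_tfs: frozenset[str]

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("degenerate CRM interval")
        if len(self.bound_tfs) < 2:
            raise ValueError("a CRM requires >= 2 distinct regulators")


@dataclass(frozen=True)
class PromoterRecord:
    gene_id: str
    chrom: str
    tss: int  # 0-based summit base; the TSS interval is [tss, tss+1)
    crm: CisRegulatoryModule


def merge_peaks_to_crms(cistromes: dict[str, pd.DataFrame]
                        ) -> list[CisRegulatoryModule]:
    """Merge all peaks into CRMs (single-linkage overlap, >= 2 TFs kept)."""
    if len(cistromes) < 2:
        raise ValueError("need peak sets for at least 2 regulators")
    frames = []
    for tf, df in cistromes.items():
        if len(df):
            frames.append(pd.DataFrame({
                "chrom": df["chrom"], "start": df["start"],
                "end": df["end"], "tf": tf,
            }))
    crms: list[CisRegulatoryModule] = []
    if not frames:
        return crms
    peaks = pd.concat(frames, ignore_index=True)
    for chrom, sub in peaks.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        tfs = sub["tf"].to_numpy()
        cur_start, cur_end = int(starts[0]), int(ends[0])
        cur_tfs = {tfs[0]}
        for s, e, t in zip(starts[1:], ends[1:], tfs[1:]):
            if s < cur_end:  # >= 1 bp shared under half-open coordinates
                cur_end = max(cur_end, int(e))
                cur_tfs.add(t)
            else:
                if len(cur_tfs) >= 2:
                    crms.append(CisRegulatoryModule(chrom, cur_start, cur_end,
                                                    frozenset(cur_tfs)))
                cur_start, cur_end, cur_tfs = int(s), int(e), {t}
        if len(cur_tfs) >= 2:
            crms.append(CisRegulatoryModule(chrom, cur_start, cur_end,
                                            frozenset(cur_tfs)))
    return crms


def drop_ambiguous_tss(tss: pd.DataFrame) -> pd.DataFrame:
    """Remove non-unique TSS-gene associations in both directions.

    A TSS position claimed by several genes is dropped, as is every gene
    annotated with more than one TSS record.
    """
    key = tss["chrom"].astype(str) + ":" + tss["start"].astype(str)
    pos_counts = key.map(key.value_counts())
    gene_counts = tss["name"].map(tss["name"].value_counts())
    return tss[(pos_counts == 1) & (gene_counts == 1)].reset_index(drop=True)


def map_crms_to_promoters(crms: list[CisRegulatoryModule],
                          tss_annotation: pd.DataFrame,
                          gene_filter: set[str] | None = None
                          ) -> list[PromoterRecord]:
    """Promoter records for genes whose unambiguous TSS overlaps a CRM.

    A TSS overlapping several CRMs (possible after ambiguity filtering of a
    multi-summit annotation) unions their bound-TF sets: the promoter is one
    binding locus.
    """
    tss = drop_ambiguous_tss(tss_annotation)
    if gene_filter is not None:
        tss = tss[tss["name"].isin(gene_filter)]
    by_chrom: dict[str, list[CisRegulatoryModule]] = {}
    for crm in crms:
        by_chrom.setdefault(crm.chrom, []).append(crm)
    for lst in by_chrom.values():
        lst.sort(key=lambda c: (c.start, c.end))

    records: list[PromoterRecord] = []
    for row in tss.itertuples(index=False):
        chrom_crms = by_chrom.get(row.chrom, [])
        starts = np.array([c.start for c in chrom_crms])
        ends = np.array([c.end for c in chrom_crms])
        if len(chrom_crms) == 0:
            continue
        hit_idx = np.flatnonzero((starts <= row.start) & (row.start < ends))
        if hit_idx.size == 0:
            continue
        hits = [chrom_crms[i] for i in hit_idx]
        merged = CisRegulatoryModule(
            row.chrom,
            min(c.start for c in hits),
            max(c.end for c in hits),
            frozenset().union(*(c.bound_tfs for c in hits)),
        )
        records.append(PromoterRecord(row.name, row.chrom, int(row.start),
                                      merged))
    return records


def build_binding_matrix(records: list[PromoterRecord],
                         tf_universe: list[str] | None = None
                         ) -> pd.DataFrame:
    """Binary gene x TF matrix; matrix[g, t] = 1 iff t bound at g's CRM."""
    if not records:
        raise ValueError("no promoter records")
    genes = [r.gene_id for r in records]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in promoter records")
    if tf_universe is None:
        tf_universe = sorted(set().union(*(r.crm.bound_tfs for r in records)))
    mat = np.zeros((len(records), len(tf_universe)), dtype=np.int8)
    col = {t: j for j, t in enumerate(tf_universe)}
    for i, r in enumerate(records):
        for t in r.crm.bound_tfs:
            if t in col:
                mat[i, col[t]] = 1
    return pd.DataFrame(mat, index=genes, columns=list(tf_universe))


def extract_promoter_signal(track: SignalTrack,
                            records: list[PromoterRecord]) -> pd.Series:
    """Per gene, the maximum track value over the promoter's CRM interval."""
    vals = {r.gene_id: track.max_over(r.chrom, r.crm.start, r.crm.end)
            for r in records}
    return pd.Series(vals, dtype=float)


def assign_h3k4me3_breadth(domains: pd.DataFrame,
                           tss_annotation: pd.DataFrame) -> pd.Series:
    """Breadth (bp) of the closest H3K4me3 domain when the TSS overlaps it.

    Mirrors nearest-feature assignment at distance 0: the gene is assigned
    only when its TSS base lies inside the closest domain; ties on distance
    go to the first domain in sorted order. Unassigned genes are absent.
    """
    out: dict[str, int] = {}
    for chrom, dom in domains.groupby("chrom", sort=True):
        dom = dom.sort_values(["start", "end"], kind="stable")
        starts = dom["start"].to_numpy()
        ends = dom["end"].to_numpy()
        sub = tss_annotation[tss_annotation["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            pos = row.start
            # distance 0 iff inside some domain; nearest tie -> first sorted
            dist = np.maximum(starts - (pos + 1) + 1, 0) + \
                np.maximum(pos - ends + 1, 0)
            i = int(np.argmin(dist))
            if dist[i] == 0:
                out[row.name] = int(ends[i] - starts[i])
    return pd.Series(out, dtype="int64")


def count_peaks_near_tss(cistrome: pd.DataFrame,
                         tss_annotation: pd.DataFrame,
                         window: int = 10_000) -> pd.Series:
    """Peaks overlapping [tss - window, tss + window) by >= 1 bp, per gene."""
    if window <= 0:
        raise ValueError("window must be > 0")
    counts: dict[str, int] = {}
    for row in tss_annotation.itertuples(index=False):
        sub = cistrome[cistrome["chrom"] == row.chrom]
        lo, hi = row.start - window, row.start + window
        n = int(((sub["start"] < hi) & (sub["end"] > lo)).sum())
        counts[row.name] = n
    return pd.Series(counts, dtype="int64")


def select_active_tss(tss_candidates: pd.DataFrame,
                      h3k27ac: SignalTrack,
                      control: SignalTrack,
                      window: int = 500,
                      fold: float = 2.0,
                      pseudocount: float = 0.1) -> pd.DataFrame:
    """Active-TSS filter: signal >= fold x control in a +/- window, best per gene.

    Window means get a pseudocount so an uncovered control track cannot
    divide by zero. Of the passing TSSs of a gene, only the one with the
    highest signal is retained.
    """
    keep_rows = []
    for idx, row in tss_candidates.iterrows():
        sig = h3k27ac.mean_over(row["chrom"], row["start"] - window,
                                row["start"] + window) + pseudocount
        ctl = control.mean_over(row["chrom"], row["start"] - window,
                                row["start"] + window) + pseudocount
        if sig >= fold * ctl:
            keep_rows.append((idx, sig))
    if not keep_rows:
        return tss_candidates.iloc[0:0]
    kept = tss_candidates.loc[[i for i, _ in keep_rows]].copy()
    kept["_signal"] = [s for _, s in keep_rows]
    kept = (kept.sort_values("_signal", ascending=False, kind="stable")
            .drop_duplicates("name", keep="first")
            .sort_values(["chrom", "start"], kind="stable")
            .drop(columns="_signal")
            .reset_index(drop=True))
    return kept
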