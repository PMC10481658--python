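"""Interval arithmetic agrees with brute-force oracles and the CRM rules."""

import numpy as np
import pandas as pd
import pytest

from protfnet import binding
from protfnet.io import SignalTrack

from conftest import brute_force_merge, cistromes_from_peaks, random_peaks


def make_cistromes(spec):
    return {tf: pd.DataFrame(iv, columns=["chrom", "start", "end"])
            for tf, iv in spec.items()}


class TestMergePeaksToCrms:
    def test_overlap_merges_and_singleton_dropped(self):
        cis = make_cistromes({
            "TF1": [("chr1", 100, 200)],
            "TF2": [("chr1", 150, 250)],
            "TF3": [("chr1", 300, 400)],
        })
        crms = binding.merge_peaks_to_crms(cis)
        assert len(crms) == 1
        crm = crms[0]
        assert (crm.start, crm.end) == (100, 250)
        assert crm.bound_tfs == frozenset({"TF1", "TF2"})

    def test_identical_peak_sets_give_peak_intervals(self):
        iv = [("chr1", 10, 60), ("chr1", 100, 130)]
        crms = binding.merge_peaks_to_crms(make_cistromes(
            {"A": iv, "B": iv}))
        assert [(c.start, c.end) for c in crms] == [(10, 60), (100, 130)]
        assert all(c.bound_tfs == frozenset({"A", "B"}) for c in crms)

    def test_adjacent_intervals_do_not_merge(self):
        crms = binding.merge_peaks_to_crms(make_cistromes({
            "A": [("chr1", 0, 100), ("chr1", 100, 200)],
            "B": [("chr1", 0, 100), ("chr1", 100, 200)],
        }))
        assert [(c.start, c.end) for c in crms] == [(0, 100), (100, 200)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_peaks(rng)
        crms = binding.merge_peaks_to_crms(cistromes_from_peaks(peaks))
        got = sorted((c.chrom, c.start, c.end, c.bound_tfs) for c in crms)
        assert got == brute_force_merge(peaks)

    def test_idempotent(self, rng):
        peaks = random_peaks(rng)
        crms = binding.merge_peaks_to_crms(cistromes_from_peaks(peaks))
        again = binding.merge_peaks_to_crms({
            tf: pd.DataFrame(
                [(c.chrom, c.start, c.end) for c in crms
                 if tf in c.bound_tfs], columns=["chrom", "start", "end"])
            for tf in {t for c in crms for t in c.bound_tfs}})
        assert sorted((c.chrom, c.start, c.end, c.bound_tfs)
                      for c in again) == \
            sorted((c.chrom, c.start, c.end, c.bound_tfs) for c in crms)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            binding.merge_peaks_to_crms({})


def tss_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestMapCrmsToPromoters:
    def crms(self):
        return binding.merge_peaks_to_crms(make_cistromes({
            "A": [("chr1", 100, 250)], "B": [("chr1", 100, 250)],
        }))

    def test_tss_inside_crm_emitted(self):
        recs = binding.map_crms_to_promoters(
            self.crms(), tss_frame([("chr1", 150, 151, "g1")]))
        assert len(recs) == 1 and recs[0].gene_id == "g1"
        assert recs[0].crm.bound_tfs == frozenset({"A", "B"})

    def test_shared_tss_drops_both_genes(self):
        recs = binding.map_crms_to_promoters(
            self.crms(), tss_frame([("chr1", 150, 151, "g1"),
                                    ("chr1", 150, 151, "g2")]))
        assert recs == []

    def test_gene_with_two_tss_dropped(self):
        recs = binding.map_crms_to_promoters(
            self.crms(), tss_frame([("chr1", 150, 151, "g1"),
                                    ("chr1", 200, 201, "g1")]))
        assert recs == []

    def test_gene_filter_applies(self):
        recs = binding.map_crms_to_promoters(
            self.crms(), tss_frame([("chr1", 150, 151, "g1")]),
            gene_filter={"other"})
        assert recs == []

    def test_multiple_crms_union_tf_sets(self):
        # overlapping CRMs can reach the mapper from pre-merged inputs;
        # a TSS inside both must see the union of the bound-TF sets
        crms = [
            binding.CisRegulatoryModule("chr1", 100, 160,
                                        frozenset({"A", "B"})),
            binding.CisRegulatoryModule("chr1", 150, 300,
                                        frozenset({"C", "D"})),
        ]
        recs = binding.map_crms_to_promoters(
            crms, tss_frame([("chr1", 155, 156, "g1")]))
        assert len(recs) == 1
        assert recs[0].crm.bound_tfs == frozenset({"A", "B", "C", "D"})


class TestBindingMatrix:
    def test_single_record_row(self):
        crm = binding.CisRegulatoryModule("chr1", 0, 10,
                                          frozenset({"A", "B"}))
        rec = binding.PromoterRecord("g1", "chr1", 5, crm)
        m = binding.build_binding_matrix([rec], ["A", "B", "C"])
        assert m.loc["g1"].tolist() == [1, 1, 0]

    def test_row_sums_equal_bound_tf_counts(self, binding_matrix):
        matrix, _ = binding_matrix
        assert (matrix.sum(axis=1) >= 2).all()

    def test_zero_noise_matrix_equals_planted_design(self, binding_matrix,
                                                     small_config):
        matrix, truth = binding_matrix
        for gene in matrix.index:
            planted = set(
                small_config.cluster_tf_sets[truth.promoter_cluster[gene]])
            bound = set(matrix.columns[matrix.loc[gene] == 1])
            assert bound == planted

    def test_column_marginals_match_interval_overlap_counts(
            self, binding_matrix, small_config):
        matrix, truth = binding_matrix
        for tf in matrix.columns:
            expected = sum(
                tf in small_config.cluster_tf_sets[truth.promoter_cluster[g]]
                for g in matrix.index)
            assert matrix[tf].sum() == expected

    def test_duplicate_gene_ids_rejected(self):
        crm = binding.CisRegulatoryModule("chr1", 0, 10,
                                          frozenset({"A", "B"}))
        rec = binding.PromoterRecord("g1", "chr1", 5, crm)
        with pytest.raises(ValueError):
            binding.build_binding_matrix([rec, rec])


class TestPromoterSignal:
    def record(self, start=100, end=200):
        crm = binding.CisRegulatoryModule("chr1", start, end,
                                          frozenset({"A", "B"}))
        return binding.PromoterRecord("g1", "chr1", start + 1, crm)

    def test_constant_and_spike(self):
        track = SignalTrack()
        track.add("chr1", [100], [200], [3.0])
        assert binding.extract_promoter_signal(track, [self.record()])[
            "g1"] == 3.0
        spike = SignalTrack()
        spike.add("chr1", [100, 150, 151], [150, 151, 200],
                  [1.0, 7.5, 1.0])
        assert binding.extract_promoter_signal(spike, [self.record()])[
            "g1"] == 7.5

    def test_matches_brute_force_per_base_maximum(self, rng):
        starts = np.arange(0, 300, 10)
        vals = rng.normal(size=len(starts))
        track = SignalTrack()
        track.add("chr1", starts, starts + 10, vals)
        per_base = np.repeat(vals, 10)
        rec = self.record(37, 251)
        got = binding.extract_promoter_signal(track, [rec])["g1"]
        assert got == pytest.approx(per_base[37:251].max())

    def test_uncovered_interval_reads_zero(self):
        track = SignalTrack()
        track.add("chr1", [0], [10], [-5.0])
        rec = self.record(100, 200)
        assert binding.extract_promoter_signal(track, [rec])["g1"] == 0.0


class TestH3K4me3Breadth:
    def test_tss_inside_domain_gets_breadth(self):
        domains = tss_frame([("chr1", 0, 5000, "d1")])
        tss = tss_frame([("chr1", 100, 101, "g1")])
        got = binding.assign_h3k4me3_breadth(domains, tss)
        assert got["g1"] == 5000

    def test_tss_outside_unassigned(self):
        domains = tss_frame([("chr1", 0, 5000, "d1")])
        tss = tss_frame([("chr1", 5000, 5001, "g1")])
        assert "g1" not in binding.assign_h3k4me3_breadth(domains, tss)

    def test_matches_brute_force_nearest_scan(self, rng):
        doms = []
        for _ in range(5):
            s = int(rng.integers(0, 5000))
            doms.append(("chr1", s, s + int(rng.integers(100, 1500)), "d"))
        tss_rows = [("chr1", int(rng.integers(0, 7000)),
                     0, f"g{i}") for i in range(8)]
        tss_rows = [(c, s, s + 1, n) for c, s, _, n in tss_rows]
        domains = tss_frame(doms).sort_values("start")
        got = binding.assign_h3k4me3_breadth(domains,
                                             tss_frame(tss_rows))
        for c, s, e, name in tss_rows:
            dists = [(max(row.start - s, 0) + max(s - row.end + 1, 0),
                      row.start, row.end)
                     for row in domains.itertuples(index=False)]
            dmin, ds, de = min(dists)
            if dmin == 0:
                assert got[name] == de - ds
            else:
                assert name not in got


class TestCountPeaksNearTss:
    def test_window_inclusion_and_exclusion(self):
        tss = tss_frame([("chr1", 20000, 20001, "g1")])
        near = pd.DataFrame([("chr1", 14800, 15200)],
                            columns=["chrom", "start", "end"])
        far = pd.DataFrame([("chr1", 30001, 30101)],
                           columns=["chrom", "start", "end"])
        assert binding.count_peaks_near_tss(near, tss, 10_000)["g1"] == 1
        assert binding.count_peaks_near_tss(far, tss, 10_000)["g1"] == 0

    def test_matches_brute_force_overlap_count(self, rng):
        peaks = pd.DataFrame(
            [("chr1", int(s), int(s) + 200) for s in
             rng.integers(0, 50_000, size=30)],
            columns=["chrom", "start", "end"])
        tss = tss_frame([("chr1", 25_000, 25_001, "g1")])
        w = 10_000
        expected = sum(1 for _, s, e in
                       peaks.itertuples(index=False, name=None)
                       if s < 25_000 + w and e > 25_000 - w)
        assert binding.count_peaks_near_tss(peaks, tss, w)["g1"] == expected


class TestSelectActiveTss:
    def tracks(self, sig_val, ctl_val=1.0):
        sig, ctl = SignalTrack(), SignalTrack()
        sig.add("chr1", [0], [2000], [sig_val])
        ctl.add("chr1", [0], [2000], [ctl_val])
        return sig, ctl

    def test_twofold_enrichment_kept_and_dropped(self):
        tss = tss_frame([("chr1", 1000, 1001, "g1")])
        sig, ctl = self.tracks(4.0)
        assert len(binding.select_active_tss(tss, sig, ctl)) == 1
        sig, ctl = self.tracks(1.9)
        assert len(binding.select_active_tss(tss, sig, ctl)) == 0

    def test_best_tss_per_gene_retained(self):
        tss = tss_frame([("chr1", 600, 601, "g1"),
                         ("chr1", 1400, 1401, "g1")])
        sig, ctl = SignalTrack(), SignalTrack()
        sig.add("chr1", [0, 1000], [1000, 2000], [5.0, 9.0])
        ctl.add("chr1", [0], [2000], [1.0])
        kept = binding.select_active_tss(tss, sig, ctl)
        assert len(kept) == 1 and kept.iloc[0]["start"] == 1400

    def test_zero_control_handled_by_pseudocount(self):
        tss = tss_frame([("chr1", 1000, 1001, "g1")])
        sig = SignalTrack()
        sig.add("chr1", [0], [2000], [4.0])
        kept = binding.select_active_tss(tss, sig, SignalTrack())
        assert len(kept) == 1
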