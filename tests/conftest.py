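import numpy as np
import pandas as pd
import pytest

from protfnet.synthetic import (GroundTruth, SyntheticConfig,
                                generate_cistromes, generate_tss_annotation)
from protfnet import binding


@pytest.fixture
def small_config():
    return SyntheticConfig(n_tfs=8, n_promoters=40, n_binding_clusters=2,
                           binding_noise=0.0, rng_seed=11)


@pytest.fixture
def binding_matrix(small_config):
    """Zero-noise binding matrix with two planted co-binding blocks."""
    cis, truth = generate_cistromes(small_config)
    tss, truth = generate_tss_annotation(small_config, truth)
    crms = binding.merge_peaks_to_crms(cis)
    recs = binding.map_crms_to_promoters(crms, tss,
                                         set(small_config.gene_ids))
    matrix = binding.build_binding_matrix(recs, small_config.tf_names)
    return matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def brute_force_merge(peaks):
    """O(n^2) single-linkage merge of labelled intervals via a graph walk.

    ``peaks`` is a list of (chrom, start, end, tf). Returns a sorted list of
    (chrom, start, end, frozenset_of_tfs) connected components, keeping only
    components with >= 2 distinct TFs.
    """
    n = len(peaks)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i], peaks[j]
            if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    out = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        tfs = frozenset(peaks[u][3] for u in comp)
        if len(tfs) >= 2:
            out.append((peaks[comp[0]][0],
                        min(peaks[u][1] for u in comp),
                        max(peaks[u][2] for u in comp), tfs))
    return sorted(out)


def random_peaks(rng, n_tfs=5, n_peaks=12, span=1000, max_width=80):
    peaks = []
    for t in range(n_tfs):
        for _ in range(n_peaks):
            s = int(rng.integers(0, span))
            w = int(rng.integers(1, max_width))
            peaks.append(("chr1", s, s + w, f"T{t}"))
    return peaks


def cistromes_from_peaks(peaks):
    out = {}
    for chrom, s, e, tf in peaks:
        out.setdefault(tf, []).append((chrom, s, e))
    return {tf: pd.DataFrame(v, columns=["chrom", "start", "end"])
            for tf, v in out.items()}
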