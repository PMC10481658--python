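"""Reading and writing the plain-text formats the pipeline exchanges.

All genomic records use BED conventions: 0-based, half-open intervals.
Signal tracks are bedGraph (chrom, start, end, value) with non-overlapping
sorted bins per chromosome. Matrices are tab-separated with a header row of
sample/cell names and the first column holding gene or TF identifiers.
Ground truth is a three-column key-value table (section, key, value).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name"]


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED file into a DataFrame (chrom, start, end, name, ...)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = BED_COLUMNS[: df.shape[1]] + [
        f"col{i}" for i in range(len(BED_COLUMNS), df.shape[1])
    ]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SignalTrack:
    """Binned numeric signal per chromosome.

    ``bins[chrom]`` holds three parallel arrays (starts, ends, values) with
    sorted, non-overlapping half-open bins. Bases not covered by any bin
    read as 0, matching enrichment-track semantics.
    """

    bins: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def add(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if np.any(ends <= starts):
            raise ValueError("degenerate bins (end <= start)")
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping bins on {chrom}")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite signal values")
        self.bins[chrom] = (starts, ends, values)

    def _overlapping(self, chrom: str, start: int, end: int):
        if chrom not in self.bins:
            return None
        starts, ends, values = self.bins[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return None
        return starts[lo:hi], ends[lo:hi], values[lo:hi]

    def max_over(self, chrom: str, start: int, end: int) -> float:
        """Maximum value over [start, end); uncovered bases count as 0."""
        hit = self._overlapping(chrom, start, end)
        if hit is None:
            return 0.0
        starts, ends, values = hit
        covered = np.minimum(ends, end) - np.maximum(starts, start)
        mx = float(values.max())
        if covered.sum() < end - start:  # gaps read as 0
            mx = max(mx, 0.0)
        return mx

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Base-weighted mean over [start, end); uncovered bases count as 0."""
        hit = self._overlapping(chrom, start, end)
        width = end - start
        if hit is None:
            return 0.0
        starts, ends, values = hit
        covered = np.minimum(ends, end) - np.maximum(starts, start)
        return float((values * covered).sum() / width)


def read_bedgraph(path: str | os.PathLike) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    track = SignalTrack()
    for chrom, sub in df.groupby("chrom", sort=False):
        track.add(str(chrom), sub["start"].values, sub["end"].values,
                  sub["value"].values)
    return track


def write_bedgraph(track: SignalTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.bins):
            starts, ends, values = track.bins[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV matrix: header row of column names, first column = index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t")


def write_truth(sections: dict[str, dict], path: str | os.PathLike) -> None:
    """Serialize ground truth as one (section, key, value) record per line."""
    with open(path, "w") as fh:
        for section in sorted(sections):
            for key in sections[section]:
                fh.write(f"{section}\t{key}\t{sections[section][key]}\n")


def read_truth(path: str | os.PathLike) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            section, key, value = line.split("\t", 2)
            out.setdefault(section, {})[key] = value
    return out
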