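"""Anchored coverage metaprofiles from bedGraph tracks.

A :class:`CoverageTrack` holds per-chromosome sorted, non-overlapping
scored intervals; positions not covered by any row read as signal 0.
Queries are exact integrals computed from cumulative sums, so profiles are
invariant to how the track happens to be split into rows.

:func:`anchor_matrix` bins a fixed window around each anchor (peak centre
or TSS) into a per-anchor profile row; minus-strand anchors are reversed so
every row runs 5' to 3'. This is the computation behind TSS/peak signal
metaplots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import PeakSet

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Sparse per-bp signal with exact interval-mean queries."""

    chrom_data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # chrom -> (starts, ends, values), sorted, non-overlapping
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, source: str = "") -> "CoverageTrack":
        data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start", kind="mergesort")
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            values = sub["value"].to_numpy(float)
            if (starts >= ends).any():
                raise ValueError(f"{source}: empty/inverted interval on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise ValueError(
                    f"{source}: overlapping rows on {chrom} near "
                    f"{starts[i + 1]} (previous row ends at {ends[i]})"
                )
            data[chrom] = (starts, ends, values)
        return cls(chrom_data=data)

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            starts, ends, values = self.chrom_data[chrom]
            seg = (ends - starts) * values
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(seg)])
        return self._cum[chrom]

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-bp signal over [start, end); uncovered bp contribute 0."""
        if chrom not in self.chrom_data:
            return 0.0
        starts, ends, values = self.chrom_data[chrom]
        cum = self._cumulative(chrom)
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        total = float(cum[hi] - cum[lo])
        # trim partial coverage of the first and last intersecting rows
        total -= max(0, start - starts[lo]) * values[lo]
        total -= max(0, ends[hi - 1] - end) * values[hi - 1]
        return total

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-bp signal over [start, end) with implicit zeros."""
        if end <= start:
            raise ValueError("end must exceed start")
        if chrom not in self.chrom_data:
            logger.warning("query on chromosome %r absent from track; mean = 0", chrom)
            return 0.0
        return self.integral(chrom, start, end) / (end - start)

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        widths = np.diff(edges)
        return np.array(
            [self.integral(chrom, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
        ) / widths


def load_track(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph. Unsorted input is sorted with a notice;
    overlapping rows are an error."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if df["value"].dtype == object:
        raise ValueError(f"{path}: non-numeric score column")
    sorted_df = df.sort_values(["chrom", "start"], kind="mergesort")
    if not sorted_df.index.equals(df.index):
        logger.info("load_track(%s): input not sorted; sorting", path)
    return CoverageTrack.from_dataframe(sorted_df, source=str(path))


def write_track(df: pd.DataFrame, path: str | Path) -> None:
    out = df.sort_values(["chrom", "start"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False,
               columns=["chrom", "start", "end", "value"], float_format="%g")


def _anchor_points(anchors, anchor_mode: str) -> pd.DataFrame:
    if isinstance(anchors, PeakSet):
        df = anchors.df
        if anchor_mode == "center":
            pos = (df["start"] + df["end"]) // 2
        elif anchor_mode == "tss":
            pos = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
        else:
            raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
        return pd.DataFrame(
            {"chrom": df["chrom"], "pos": pos, "strand": df["strand"]}
        ).reset_index(drop=True)
    df = anchors.copy()
    if "pos" not in df.columns:
        df = df.rename(columns={"tss": "pos"})
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df[["chrom", "pos", "strand"]].reset_index(drop=True)


def anchor_matrix(
    track: CoverageTrack,
    anchors,
    flank: int = 2000,
    n_bins: int = 40,
    anchor_mode: str = "center",
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor binned signal over [anchor - flank, anchor + flank).

    ``anchors`` is a PeakSet (anchor_mode 'center' or 'tss') or a DataFrame
    with columns chrom, pos (or tss), strand. Bin width = 2*flank // n_bins
    with any remainder assigned to the last bin. Minus-strand rows are
    reversed so bins run 5'->3'. Anchors whose window leaves the chromosome
    are dropped (logged).

    Returns (matrix anchors x bins, mean profile of length n_bins).
    """
    if flank <= 0 or n_bins < 1:
        raise ValueError("flank must be > 0 and n_bins >= 1")
    pts = _anchor_points(anchors, anchor_mode)
    width = 2 * flank
    bin_w = width // n_bins
    if bin_w < 1:
        raise ValueError("n_bins larger than window width")
    offsets = np.arange(n_bins + 1, dtype=np.int64) * bin_w
    offsets[-1] = width  # remainder bp go to the last bin

    rows = []
    dropped = 0
    for row in pts.itertuples(index=False):
        center = int(row.pos)
        start = center - flank
        end = center + flank
        size = (chrom_sizes or {}).get(row.chrom)
        if start < 0 or (size is not None and end > size):
            dropped += 1
            continue
        edges = start + offsets
        vals = track.binned_means(row.chrom, edges)
        if row.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    if dropped:
        logger.info("anchor_matrix: dropped %d off-chromosome anchors", dropped)
    if not rows:
        raise ValueError("no usable anchors (all off-chromosome or empty input)")
    mat = np.vstack(rows)
    return mat, mat.mean(axis=0)
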