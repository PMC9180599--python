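"""Genomic-interval engine.

0-based half-open intervals on named chromosomes, BED 3/6 I/O, merging,
peak-level overlap fractions, co-binding partitioning (the A+B+ / A+B- / A-B+
classification used to study cooperative transcription-factor binding),
multi-set union overlap, and strand-aware TSS windows.

A :class:`PeakSet` is a thin wrapper around a pandas DataFrame with columns
``chrom, start, end, name, score, strand`` kept in canonical sort order
(chromosome lexicographic, then start, then end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """One 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df = df[BED_COLUMNS]
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    return df.reset_index(drop=True)


@dataclass
class PeakSet:
    """Named collection of genomic intervals in canonical order."""

    name: str
    df: pd.DataFrame
    source: str = ""
    _trees: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        bad = self.df.index[~(self.df["start"] < self.df["end"])] if len(self.df) else []
        if len(bad):
            raise ValueError(f"{self.name}: {len(bad)} intervals with start >= end")
        if len(self.df) and (self.df["start"] < 0).any():
            raise ValueError(f"{self.name}: negative start coordinate")
        self.df = _canonical(self.df)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        name: str = "peaks",
        source: str = "",
    ) -> "PeakSet":
        """Build from (chrom, start, end[, name[, score[, strand]]]) tuples."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            row = dict(zip(BED_COLUMNS, rec))
            rows.append(row)
        df = pd.DataFrame(rows, columns=BED_COLUMNS[: max((len(r) for r in rows), default=3)])
        if "chrom" not in df.columns:
            df = pd.DataFrame(columns=BED_COLUMNS)
        return cls(name=name, df=df, source=source)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom, int(row.start), int(row.end),
                strand=row.strand, name=str(row.name), score=float(row.score),
            )

    def intervals_on(self, chrom: str) -> np.ndarray:
        sub = self.df[self.df["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique().tolist())

    def total_width(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees (built lazily, cached)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                trees[chrom] = IntervalTree.from_tuples(
                    (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
                )
            self._trees = trees
        return self._trees

    def max_overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Largest single-interval overlap (bp) of [start, end) with this set."""
        tree = self.trees().get(chrom)
        if tree is None:
            return 0
        best = 0
        for iv in tree.overlap(start, end):
            best = max(best, min(end, iv.end) - max(start, iv.begin))
        return best

    def replace(self, df: pd.DataFrame, name: str | None = None) -> "PeakSet":
        return PeakSet(name=name or self.name, df=df, source=self.source)


# ---------------------------------------------------------------------------
# BED I/O


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV chrom<TAB>length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            length = int(length)
            if length <= 0:
                raise ValueError(f"zero/negative chromosome length for {chrom}")
            sizes[chrom] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(
    path: str | Path,
    name: str | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> PeakSet:
    """Read a 3-6 column BED file as a PeakSet.

    If ``chrom_sizes`` is given, rows on chromosomes absent from it (e.g.
    unplaced scaffolds) are dropped and the count is logged — the standard
    "non-standard chromosomes removed" filter.
    """
    rows = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if chrom_sizes is not None and chrom not in chrom_sizes:
                dropped += 1
                continue
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "name": fields[3] if len(fields) > 3 else ".",
                "score": float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0,
                "strand": fields[5] if len(fields) > 5 else ".",
            }
            rows.append(row)
    if dropped:
        logger.info("read_bed(%s): dropped %d rows on chromosomes not in sizes file", path, dropped)
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    return PeakSet(name=name or Path(path).stem, df=df, source=str(path))


def write_bed(peaks: PeakSet, path: str | Path, columns: int = 6) -> None:
    """Write canonical-sorted BED with 3 or 6 columns."""
    df = peaks.df
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if columns >= 6:
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t{row.score:g}\t{row.strand}\n"
                )
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


# ---------------------------------------------------------------------------
# Core operations


def merge_intervals(peaks: PeakSet, name: str | None = None) -> PeakSet:
    """Merge overlapping and bookended (end == start) intervals.

    Output intervals are pairwise disjoint and non-touching; the union of
    covered bases is preserved.
    """
    if len(peaks) == 0:
        return peaks.replace(peaks.df, name=name or peaks.name)
    out = []
    for chrom, sub in peaks.df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(out, columns=["chrom", "start", "end"])
    return PeakSet(name=name or peaks.name, df=df, source=peaks.source)


def merged_arrays(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) of the merged set — for fast bulk queries."""
    merged = merge_intervals(peaks)
    out = {}
    for chrom, sub in merged.df.groupby("chrom", sort=False):
        out[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
        )
    return out


def overlaps_any(
    starts: np.ndarray,
    ends: np.ndarray,
    merged: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Vectorised: does each [start, end) overlap >= 1 merged interval?"""
    m_starts, m_ends = merged
    if len(m_starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(m_starts, ends, side="left")
    hit = idx > 0
    hit[hit] = m_ends[idx[hit] - 1] > starts[hit]
    return hit


def overlap_fraction(
    a: PeakSet,
    b: PeakSet,
    min_bp: int = 1,
) -> tuple[float, PeakSet, PeakSet]:
    """Fraction of a's peaks overlapping >= 1 peak of b by >= min_bp bases.

    Returns (fraction, overlapping subset of a, non-overlapping subset of a);
    the two subsets partition a exactly.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if len(a) == 0:
        raise ValueError(f"overlap fraction undefined: peak set {a.name!r} is empty")
    if min_bp == 1:
        merged = merged_arrays(b)
        mask = np.zeros(len(a), dtype=bool)
        for chrom, sub in a.df.groupby("chrom", sort=False):
            if chrom in merged:
                hit = overlaps_any(
                    sub["start"].to_numpy(np.int64),
                    sub["end"].to_numpy(np.int64),
                    merged[chrom],
                )
                mask[sub.index.to_numpy()] = hit
    else:
        mask = np.array(
            [
                b.max_overlap_bp(row.chrom, row.start, row.end) >= min_bp
                for row in a.df.itertuples(index=False)
            ],
            dtype=bool,
        )
    frac = float(mask.mean())
    over = a.replace(a.df[mask], name=f"{a.name}+{b.name}")
    nonover = a.replace(a.df[~mask], name=f"{a.name}-{b.name}")
    return frac, over, nonover


def classify_cobinding(a: PeakSet, b: PeakSet) -> dict[str, PeakSet]:
    """Partition peaks into co-binding classes.

    A+B+ = a peaks overlapping b; A+B- = remaining a peaks;
    A-B+ = b peaks overlapping no a peak. |A+B+| + |A+B-| == |a| always.
    """
    if len(a) == 0:
        return {
            "A+B+": a.replace(a.df, name=f"{a.name}+{b.name}+"),
            "A+B-": a.replace(a.df, name=f"{a.name}+{b.name}-"),
            "A-B+": b.replace(b.df, name=f"{a.name}-{b.name}+"),
        }
    if len(b) == 0:
        return {
            "A+B+": a.replace(a.df.iloc[0:0], name=f"{a.name}+{b.name}+"),
            "A+B-": a.replace(a.df, name=f"{a.name}+{b.name}-"),
            "A-B+": b.replace(b.df, name=f"{a.name}-{b.name}+"),
        }
    _, ab, a_not_b = overlap_fraction(a, b)
    _, _, b_not_a = overlap_fraction(b, a)
    return {
        "A+B+": ab.replace(ab.df, name=f"{a.name}+{b.name}+"),
        "A+B-": a_not_b.replace(a_not_b.df, name=f"{a.name}+{b.name}-"),
        "A-B+": b_not_a.replace(b_not_a.df, name=f"{a.name}-{b.name}+"),
    }


def multiway_union_overlap(
    query: PeakSet,
    others: Sequence[PeakSet],
) -> tuple[float, dict[str, int]]:
    """Fraction of query peaks hitting the union of several other sets.

    The other sets are merged into one union set first; per-set membership
    counts for the query peaks are reported alongside. Because the union is a
    merged set, membership bookkeeping can differ slightly from per-set
    pairwise counts.
    """
    if not others:
        raise ValueError("others must be nonempty")
    concat = pd.concat([o.df for o in others], ignore_index=True)
    union = merge_intervals(PeakSet(name="union", df=concat))
    frac, _, _ = overlap_fraction(query, union)
    counts: dict[str, int] = {}
    for o in others:
        f, over, _ = overlap_fraction(query, o)
        counts[o.name] = len(over)
    counts["union"] = int(round(frac * len(query)))
    return frac, counts


def tss_windows(
    genes: pd.DataFrame,
    upstream: int,
    downstream: int,
    chrom_sizes: Mapping[str, int] | None = None,
    name: str = "tss_windows",
) -> PeakSet:
    """Strand-aware windows around TSSs.

    + strand: [TSS-upstream, TSS+downstream); - strand mirrored. Unknown
    strands are treated as + with a logged warning. Windows are clipped to
    [0, chromosome length).

    ``genes`` needs columns gene, chrom, tss, strand.
    """
    rows = []
    n_unknown = 0
    for row in genes.itertuples(index=False):
        strand = getattr(row, "strand", "+")
        if strand not in ("+", "-"):
            n_unknown += 1
            strand = "+"
        tss = int(row.tss)
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        start = max(0, start)
        if chrom_sizes is not None and row.chrom in chrom_sizes:
            end = min(end, chrom_sizes[row.chrom])
        if start < end:
            rows.append((row.chrom, start, end, row.gene, 0.0, strand))
    if n_unknown:
        logger.warning("tss_windows: %d genes with unknown strand treated as +", n_unknown)
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    return PeakSet(name=name, df=df)
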