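"""Shuffle-based fold-enrichment of an annotation set over a target set.

The observed statistic is the number of annotation intervals (e.g.
super-enhancers, conserved elements) overlapping at least one target
interval (e.g. TF binding sites). The null is built by repeatedly
re-placing the annotation intervals uniformly at random across the genome
with lengths preserved (the bedtools-shuffle null) and recounting. Fold
enrichment = observed / mean(null); the empirical p uses the add-one
convention so it is never exactly zero. Two enrichment runs are compared by
a two-sided Welch t-test over their per-permutation fold values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import PeakSet, merged_arrays, overlaps_any

logger = logging.getLogger(__name__)

_ZERO_NULL_EPS = 0.5  # stand-in denominator when a permutation yields 0 overlaps


@dataclass
class EnrichmentResult:
    target_name: str
    annotation_name: str
    observed: int
    null_counts: np.ndarray
    fold: float
    empirical_p: float
    per_perm_folds: np.ndarray
    n_zero_null: int = 0

    @property
    def null_mean(self) -> float:
        return float(self.null_counts.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_counts.std(ddof=1)) if len(self.null_counts) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target": self.target_name,
                    "annotation": self.annotation_name,
                    "observed": self.observed,
                    "null_mean": self.null_mean,
                    "null_sd": self.null_sd,
                    "fold": self.fold,
                    "empirical_p": self.empirical_p,
                    "n_perm": len(self.null_counts),
                }
            ]
        )


def _chrom_layout(chrom_sizes: Mapping[str, int]) -> tuple[list[str], np.ndarray]:
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    return chroms, lengths


def shuffle_intervals(
    peaks: PeakSet,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator | int,
    within_chrom: bool = False,
) -> PeakSet:
    """Uniform random re-placement of intervals, lengths preserved.

    Genome-wide mode picks each interval's chromosome with probability
    proportional to the number of valid start positions
    (chrom_length - interval_length + 1); within_chrom keeps every interval
    on its own chromosome. Shuffled intervals may overlap each other.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chroms, lengths = _chrom_layout(chrom_sizes)
    df = peaks.df
    widths = (df["end"] - df["start"]).to_numpy(np.int64)

    if within_chrom:
        chrom_out = df["chrom"].to_numpy()
        caps = np.array([chrom_sizes[c] for c in chrom_out], dtype=np.int64)
        slots = caps - widths + 1
        if (slots <= 0).any():
            bad = df.loc[slots <= 0].iloc[0]
            raise ValueError(
                f"interval {bad['chrom']}:{bad['start']}-{bad['end']} longer "
                "than its chromosome"
            )
        starts = (rng.random(len(df)) * slots).astype(np.int64)
    else:
        # per-interval valid-start counts per chromosome
        slots = lengths[None, :] - widths[:, None] + 1  # (n, C)
        slots = np.maximum(slots, 0)
        totals = slots.sum(axis=1)
        if (totals == 0).any():
            bad = df.loc[totals == 0].iloc[0]
            raise ValueError(
                f"interval {bad['chrom']}:{bad['start']}-{bad['end']} longer "
                "than every chromosome"
            )
        cum = np.cumsum(slots, axis=1)
        draw = (rng.random(len(df)) * totals).astype(np.int64)
        ci = (cum <= draw[:, None]).sum(axis=1)
        offset_before = np.where(ci > 0, np.take_along_axis(cum, np.maximum(ci - 1, 0)[:, None], 1)[:, 0], 0)
        starts = draw - offset_before
        chrom_out = np.array(chroms, dtype=object)[ci]

    out = pd.DataFrame(
        {
            "chrom": chrom_out,
            "start": starts,
            "end": starts + widths,
            "name": df["name"].to_numpy(),
            "score": df["score"].to_numpy(),
            "strand": df["strand"].to_numpy(),
        }
    )
    return PeakSet(name=f"{peaks.name}_shuffled", df=out)


def _count_overlapping(
    ann_chrom: np.ndarray,
    ann_start: np.ndarray,
    ann_end: np.ndarray,
    merged_target: dict[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    """Number of annotation intervals overlapping >= 1 target interval."""
    total = 0
    for chrom in np.unique(ann_chrom):
        merged = merged_target.get(chrom)
        if merged is None:
            continue
        m = ann_chrom == chrom
        total += int(overlaps_any(ann_start[m], ann_end[m], merged).sum())
    return total


def count_annotation_overlaps(annotation: PeakSet, target: PeakSet) -> int:
    """Observed statistic: annotation intervals hitting >= 1 target interval."""
    merged = merged_arrays(target)
    df = annotation.df
    return _count_overlapping(
        df["chrom"].to_numpy(), df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64), merged,
    )


def fold_enrichment(
    target: PeakSet,
    annotation: PeakSet,
    chrom_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    within_chrom: bool = False,
    shuffle_target: bool = False,
    exclude: PeakSet | None = None,
) -> EnrichmentResult:
    """Permutation fold-enrichment of an annotation set at a target set.

    The annotation set is shuffled (length-preserving, uniform) n_perm
    times; the observed overlap count is divided by the mean null count.
    ``shuffle_target`` transposes which set is randomised. An optional
    ``exclude`` set rejects shuffled placements intersecting it.
    """
    if len(target) == 0 or len(annotation) == 0:
        raise ValueError("target and annotation must both be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    moving, fixed = (target, annotation) if shuffle_target else (annotation, target)
    merged_fixed = merged_arrays(fixed)
    mv = moving.df
    observed = _count_overlapping(
        mv["chrom"].to_numpy(), mv["start"].to_numpy(np.int64),
        mv["end"].to_numpy(np.int64), merged_fixed,
    )

    if exclude is None:
        null_counts = _null_counts_vectorized(
            moving, merged_fixed, chrom_sizes, rng, n_perm, within_chrom
        )
    else:
        excl = merged_arrays(exclude)
        null_counts = np.empty(n_perm, dtype=np.int64)
        for i in range(n_perm):
            shuf = shuffle_intervals(moving, chrom_sizes, rng, within_chrom=within_chrom)
            shuf = _reject_resample(shuf, excl, chrom_sizes, rng, within_chrom)
            sdf = shuf.df
            null_counts[i] = _count_overlapping(
                sdf["chrom"].to_numpy(), sdf["start"].to_numpy(np.int64),
                sdf["end"].to_numpy(np.int64), merged_fixed,
            )

    null_mean = null_counts.mean()
    fold = float(observed / null_mean) if null_mean > 0 else (0.0 if observed == 0 else float("inf"))
    zero = null_counts == 0
    denom = np.where(zero, _ZERO_NULL_EPS, null_counts)
    per_perm_folds = observed / denom
    n_zero = int(zero.sum())
    if n_zero > 0.05 * n_perm:
        warnings.warn(
            f"{n_zero}/{n_perm} permutations had zero null overlaps; "
            "per-permutation folds use a 0.5 denominator there",
            RuntimeWarning,
            stacklevel=2,
        )
    empirical_p = float((1 + (null_counts >= observed).sum()) / (n_perm + 1))
    return EnrichmentResult(
        target_name=target.name,
        annotation_name=annotation.name,
        observed=int(observed),
        null_counts=null_counts,
        fold=fold,
        empirical_p=empirical_p,
        per_perm_folds=per_perm_folds,
        n_zero_null=n_zero,
    )


def _null_counts_vectorized(
    moving: PeakSet,
    merged_fixed: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
    n_perm: int,
    within_chrom: bool,
) -> np.ndarray:
    """All permutations at once on a concatenated genome coordinate line."""
    chroms, lengths = _chrom_layout(chrom_sizes)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    off_by_chrom = dict(zip(chroms, offsets))

    df = moving.df
    n = len(df)
    widths = (df["end"] - df["start"]).to_numpy(np.int64)

    # merged fixed set mapped to global coordinates (stays sorted)
    g_starts, g_ends = [], []
    for c, off in zip(chroms, offsets):
        if c in merged_fixed:
            ms, me = merged_fixed[c]
            g_starts.append(ms + off)
            g_ends.append(me + off)
    if not g_starts:
        return np.zeros(n_perm, dtype=np.int64)
    m_starts = np.concatenate(g_starts)
    m_ends = np.concatenate(g_ends)

    if within_chrom:
        caps = np.array([chrom_sizes[c] for c in df["chrom"]], dtype=np.int64)
        slots = caps - widths + 1
        if (slots <= 0).any():
            bad = df.loc[slots <= 0].iloc[0]
            raise ValueError(
                f"interval {bad['chrom']}:{bad['start']}-{bad['end']} longer "
                "than its chromosome"
            )
        own_off = np.array([off_by_chrom[c] for c in df["chrom"]], dtype=np.int64)
        starts = own_off[None, :] + (rng.random((n_perm, n)) * slots[None, :]).astype(np.int64)
    else:
        slots = np.maximum(lengths[None, :] - widths[:, None] + 1, 0)  # (n, C)
        totals = slots.sum(axis=1)
        if (totals == 0).any():
            bad = df.loc[totals == 0].iloc[0]
            raise ValueError(
                f"interval {bad['chrom']}:{bad['start']}-{bad['end']} longer "
                "than every chromosome"
            )
        cum = np.cumsum(slots, axis=1)  # (n, C)
        draw = (rng.random((n_perm, n)) * totals[None, :]).astype(np.int64)
        ci = (cum[None, :, :] <= draw[:, :, None]).sum(axis=2)  # (n_perm, n)
        before = np.concatenate([np.zeros((n, 1), dtype=np.int64), cum[:, :-1]], axis=1)
        local = draw - np.take_along_axis(
            np.broadcast_to(before, (n_perm, n, before.shape[1])), ci[:, :, None], axis=2
        )[:, :, 0]
        starts = offsets[ci] + local

    ends = starts + widths[None, :]
    idx = np.searchsorted(m_starts, ends, side="left")
    hit = idx > 0
    hit &= m_ends[np.maximum(idx - 1, 0)] > starts
    return hit.sum(axis=1).astype(np.int64)


def _reject_resample(shuf, excl, chrom_sizes, rng, within_chrom, max_rounds: int = 50):
    """Re-place shuffled intervals that landed in the exclusion set."""
    from .intervals import PeakSet as _PS

    df = shuf.df
    for _ in range(max_rounds):
        bad = _overlap_mask(df, excl)
        if not bad.any():
            break
        redo = _PS(name="redo", df=df[bad])
        redone = shuffle_intervals(redo, chrom_sizes, rng, within_chrom=within_chrom)
        df = pd.concat([df[~bad], redone.df], ignore_index=True)
    return _PS(name=shuf.name, df=df)


def _overlap_mask(df: pd.DataFrame, merged: dict) -> np.ndarray:
    mask = np.zeros(len(df), dtype=bool)
    df = df.reset_index(drop=True)
    for chrom, sub in df.groupby("chrom", sort=False):
        m = merged.get(chrom)
        if m is None:
            continue
        mask[sub.index.to_numpy()] = overlaps_any(
            sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64), m
        )
    return mask


def compare_fold(res_a: EnrichmentResult, res_b: EnrichmentResult) -> tuple[float, float]:
    """Two-sided Welch t-test between two sets of per-permutation folds."""
    a, b = res_a.per_perm_folds, res_b.per_perm_folds
    if len(a) == 0 or len(b) == 0:
        raise ValueError("per-permutation folds must be nonempty")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            logger.warning("both fold samples constant and equal; p = 1 by convention")
            return 0.0, 1.0
        return float("inf") if a[0] > b[0] else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
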