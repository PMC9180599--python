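"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: K RNA-Seq
datasets contrasting an undifferentiated (MB) and a differentiated (MT)
state with dataset-specific batch shifts and a planted set of consistently
up/down-regulated genes; TF peak sets with designed pairwise overlap
fractions; annotation interval sets (super-enhancer-like, conserved-
element-like) with a designed fold enrichment over a TF set; peak
sequences with a motif consensus embedded at a designed rate; and a
coverage track elevated around chosen anchors.

Counts are negative-binomial with gene-wise log-normal means and a shared
dispersion (var = mu + dispersion * mu^2); the batch effect is a
per-dataset, per-gene multiplicative log2-normal shift. Every function is
a pure function of its inputs and the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet, merge_intervals, merged_arrays, overlaps_any
from .motifs import PWM, revcomp

DEFAULT_CHROMS = {"chr1": 10_000_000, "chr2": 8_000_000, "chr3": 6_000_000}


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs and platforms)."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults emulate a nine-dataset two-state design: ~3 replicates per
    state per dataset, planted |log2FC| = 2 for true DEGs, moderate NB
    dispersion, and a batch shift SD of 0.5 (in log2 units) large enough
    to make single-dataset DEG calls inconsistent.
    """

    seed: int = 0
    n_genes: int = 2000
    n_datasets: int = 9
    replicates_per_group: int = 3
    n_true_up: int = 100
    n_true_down: int = 100
    effect_log2fc: float = 2.0
    dispersion: float = 0.1
    batch_sd: float = 0.5
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    motif_embed_rate: float = 0.7
    se_enrichment_factor: float = 3.0
    peak_width_range: tuple[int, int] = (200, 600)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_datasets", "replicates_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_true_up + self.n_true_down > self.n_genes:
            raise ValueError("planted DEG count exceeds n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be nonempty")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            bad = [c for c, v in self.chrom_lengths.items() if v <= 0]
            raise ValueError(f"zero-length chromosome(s): {bad}")
        if not (0 <= self.motif_embed_rate <= 1):
            raise ValueError("motif_embed_rate must be in [0, 1]")
        if self.se_enrichment_factor < 0:
            raise ValueError("se_enrichment_factor must be >= 0")


@dataclass
class TruthSet:
    true_up: set[str] = field(default_factory=set)
    true_down: set[str] = field(default_factory=set)
    peak_overlap_design: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_fold: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_up & self.true_down:
            raise ValueError("true_up and true_down must be disjoint")


# ---------------------------------------------------------------------------
# Genome and expression


def simulate_genome(config: SimConfig) -> tuple[dict[str, int], pd.DataFrame]:
    """Gene table (gene, chrom, tss, strand) placed length-proportionally."""
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    ci = rng.choice(len(chroms), size=config.n_genes, p=probs)
    tss = (rng.random(config.n_genes) * lengths[ci]).astype(np.int64)
    strand = rng.choice(["+", "-"], size=config.n_genes)
    width = len(str(config.n_genes))
    genes = pd.DataFrame(
        {
            "gene": [f"gene{str(i).zfill(width)}" for i in range(config.n_genes)],
            "chrom": [chroms[i] for i in ci],
            "tss": tss,
            "strand": strand,
        }
    )
    return dict(config.chrom_lengths), genes


def simulate_count_datasets(
    genes: pd.DataFrame,
    config: SimConfig,
) -> tuple[list[tuple[pd.DataFrame, list[str]]], TruthSet]:
    """K NB count matrices (genes x samples) with planted DEGs.

    Returns a list of (counts, group labels) per dataset and the TruthSet.
    True up-genes have expected MT/MB mean ratio 2**effect_log2fc before
    batch noise; each dataset carries an independent per-gene batch shift.
    """
    if config.replicates_per_group < 2:
        raise ValueError("replicates_per_group must be >= 2")
    rng = np.random.default_rng(derive_seed(config.seed, "counts"))
    gene_ids = genes["gene"].tolist()
    n = len(gene_ids)

    order = rng.permutation(n)
    up_idx = order[: config.n_true_up]
    down_idx = order[config.n_true_up : config.n_true_up + config.n_true_down]
    truth = TruthSet(
        true_up={gene_ids[i] for i in up_idx},
        true_down={gene_ids[i] for i in down_idx},
    )

    base_mu = rng.lognormal(mean=4.0, sigma=1.0, size=n)
    effect = np.zeros(n)
    effect[up_idx] = config.effect_log2fc
    effect[down_idx] = -config.effect_log2fc

    r = 1.0 / config.dispersion  # NB size parameter
    reps = config.replicates_per_group
    datasets = []
    for _ in range(config.n_datasets):
        batch = rng.normal(0.0, config.batch_sd, size=n)
        mu_mb = base_mu * 2.0 ** (batch - effect / 2)
        mu_mt = base_mu * 2.0 ** (batch + effect / 2)
        cols = {}
        groups = []
        for j in range(reps):
            cols[f"MB_{j + 1}"] = rng.negative_binomial(r, r / (r + mu_mb))
            groups.append("MB")
        for j in range(reps):
            cols[f"MT_{j + 1}"] = rng.negative_binomial(r, r / (r + mu_mt))
            groups.append("MT")
        counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
        datasets.append((counts, groups))
    return datasets, truth


# ---------------------------------------------------------------------------
# Peak sets and annotations


def _draw_peaks(
    rng: np.random.Generator,
    n: int,
    chroms: list[str],
    lengths: np.ndarray,
    widths: np.ndarray,
) -> pd.DataFrame:
    """Uniform length-aware placement; never exceeds chromosome bounds."""
    slots = lengths[None, :] - widths[:, None] + 1
    slots = np.maximum(slots, 0)
    totals = slots.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("peak width exceeds every chromosome length")
    cum = np.cumsum(slots, axis=1)
    draw = (rng.random(n) * totals).astype(np.int64)
    ci = (cum <= draw[:, None]).sum(axis=1)
    before = np.where(
        ci > 0, np.take_along_axis(cum, np.maximum(ci - 1, 0)[:, None], 1)[:, 0], 0
    )
    starts = draw - before
    return pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[ci],
            "start": starts,
            "end": starts + widths,
        }
    )


def _uniform_overlap_probability(
    target: PeakSet, chrom_lengths: Mapping[str, int], interval_len: int
) -> float:
    """P(a uniformly placed interval of given length overlaps the target)."""
    merged = merge_intervals(target)
    total_slots = 0
    hit_slots = 0
    for chrom, length in chrom_lengths.items():
        slots = max(length - interval_len + 1, 0)
        total_slots += slots
        arr = merged.df[merged.df["chrom"] == chrom]
        for s, e in zip(arr["start"], arr["end"]):
            lo = max(0, s - interval_len + 1)
            hi = min(e - 1, length - interval_len)
            if hi >= lo:
                hit_slots += hi - lo + 1
    return hit_slots / total_slots if total_slots else 0.0


def simulate_peaksets(
    chrom_sizes: Mapping[str, int],
    design: Mapping[tuple[str, str], float],
    config: SimConfig,
    n_peaks: Mapping[str, int] | int = 1000,
    annotations: Mapping[str, tuple[str, int, int]] | None = None,
) -> tuple[dict[str, PeakSet], TruthSet]:
    """Peak sets with designed pairwise overlap, plus enriched annotations.

    ``design`` maps (query_set, reference_set) -> target fraction of the
    query set's peaks that overlap the reference set; reference sets must
    be built before queries that depend on them (insertion order).
    ``annotations`` maps name -> (target TF set, n intervals, interval
    length); each annotation set is placed so its expected fold enrichment
    over its target equals ``config.se_enrichment_factor`` (use a separate
    call with factor 1 for a null annotation).
    """
    for frac in design.values():
        if not (0 <= frac <= 1):
            raise ValueError("design fractions must lie in [0, 1]")
    rng = np.random.default_rng(derive_seed(config.seed, "peaks"))
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    lo_w, hi_w = config.peak_width_range

    set_names: list[str] = []
    for q, ref in design.keys():
        for s in (ref, q):
            if s not in set_names:
                set_names.append(s)
    if not set_names:
        set_names = ["peaks"]

    sets: dict[str, PeakSet] = {}
    truth = TruthSet(peak_overlap_design=dict(design))
    for s in set_names:
        n = n_peaks[s] if isinstance(n_peaks, Mapping) else int(n_peaks)
        widths = rng.integers(lo_w, hi_w + 1, size=n)
        refs = [(ref, frac) for (q, ref), frac in design.items() if q == s and ref in sets]
        if not refs:
            df = _draw_peaks(rng, n, chroms, lengths, widths)
        else:
            ref_name, frac = refs[0]  # one designed reference per query set
            ref_set = sets[ref_name]
            n_over = int(round(frac * n))
            df_over = _place_overlapping(rng, n_over, ref_set, chrom_sizes, widths[:n_over])
            df_free = _place_avoiding(
                rng, n - n_over, chroms, lengths, widths[n_over:], ref_set
            )
            df = pd.concat([df_over, df_free], ignore_index=True)
        df["name"] = [f"{s}_{i}" for i in range(len(df))]
        sets[s] = PeakSet(name=s, df=df)

    if annotations:
        for ann_name, (target_name, n_ann, ann_len) in annotations.items():
            target = sets[target_name]
            fold = config.se_enrichment_factor
            p = _uniform_overlap_probability(target, chrom_sizes, ann_len)
            if fold <= 1 or p >= 1:
                q = 0.0
            else:
                q = min(1.0, p * (fold - 1) / (1 - p))
            forced = int(round(q * n_ann))
            widths = np.full(n_ann, ann_len, dtype=np.int64)
            df_forced = _place_overlapping(rng, forced, target, chrom_sizes, widths[:forced])
            df_rest = _draw_peaks(rng, n_ann - forced, chroms, lengths, widths[forced:])
            df = pd.concat([df_forced, df_rest], ignore_index=True)
            df["name"] = [f"{ann_name}_{i}" for i in range(len(df))]
            sets[ann_name] = PeakSet(name=ann_name, df=df)
            truth.planted_fold[ann_name] = fold if fold > 1 else 1.0
    return sets, truth


def _place_overlapping(
    rng: np.random.Generator,
    n: int,
    ref: PeakSet,
    chrom_sizes: Mapping[str, int],
    widths: np.ndarray,
) -> pd.DataFrame:
    """Place each interval to overlap a randomly chosen reference peak by >= 1 bp."""
    rows = []
    ref_df = ref.df
    picks = rng.integers(0, len(ref_df), size=n)
    for w, k in zip(widths, picks):
        r = ref_df.iloc[int(k)]
        chrom_len = chrom_sizes[r["chrom"]]
        lo = max(0, int(r["start"]) - int(w) + 1)
        hi = min(int(r["end"]) - 1, chrom_len - int(w))
        if hi < lo:  # reference peak too close to the edge for this width
            hi = lo = max(0, min(int(r["start"]), chrom_len - int(w)))
        start = int(rng.integers(lo, hi + 1))
        rows.append((r["chrom"], start, start + int(w)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _place_avoiding(
    rng: np.random.Generator,
    n: int,
    chroms: list[str],
    lengths: np.ndarray,
    widths: np.ndarray,
    avoid: PeakSet,
    max_rounds: int = 100,
) -> pd.DataFrame:
    """Uniform placement rejecting overlaps with ``avoid`` (resampled, not clipped)."""
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    merged = merged_arrays(avoid)
    df = _draw_peaks(rng, n, chroms, lengths, widths)
    for _ in range(max_rounds):
        bad = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            m = merged.get(chrom)
            if m is None:
                continue
            bad[sub.index.to_numpy()] = overlaps_any(
                sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64), m
            )
        if not bad.any():
            break
        redo = _draw_peaks(
            rng, int(bad.sum()), chroms, lengths,
            (df.loc[bad, "end"] - df.loc[bad, "start"]).to_numpy(np.int64),
        )
        df = pd.concat([df.loc[~bad], redo], ignore_index=True)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sequences and coverage


def simulate_sequences(
    peaks: PeakSet,
    pwm: PWM,
    embed_rate: float,
    config: SimConfig,
    background: Sequence[float] | None = None,
) -> tuple[dict[str, str], set[str]]:
    """Per-peak sequences with the PWM consensus embedded at a designed rate.

    Exactly round(embed_rate * n_peaks) randomly chosen peaks carry one
    consensus insertion at a random offset and strand; the rest are pure
    background composition (uniform ACGT by default). Returns
    (record id -> sequence, set of embedded record ids); record ids are
    ``chrom:start-end``.
    """
    if not (0 <= embed_rate <= 1):
        raise ValueError("embed_rate must be in [0, 1]")
    widths = (peaks.df["end"] - peaks.df["start"]).to_numpy()
    if len(widths) and pwm.width > widths.min():
        raise ValueError("PWM wider than the narrowest peak")
    rng = np.random.default_rng(derive_seed(config.seed, "sequences"))
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    consensus = pwm.consensus

    n = len(peaks)
    n_embed = int(round(embed_rate * n))
    embed_mask = np.zeros(n, dtype=bool)
    embed_mask[rng.permutation(n)[:n_embed]] = True

    seqs: dict[str, str] = {}
    embedded: set[str] = set()
    bases = np.array(list("ACGT"))
    for i, row in enumerate(peaks.df.itertuples(index=False)):
        w = int(row.end - row.start)
        seq = "".join(bases[rng.choice(4, size=w, p=bg)])
        rec_id = f"{row.chrom}:{row.start}-{row.end}"
        if embed_mask[i]:
            motif = consensus if rng.random() < 0.5 else revcomp(consensus)
            off = int(rng.integers(0, w - pwm.width + 1))
            seq = seq[:off] + motif + seq[off + pwm.width :]
            embedded.add(rec_id)
        seqs[rec_id] = seq
    return seqs, embedded


def write_fasta(seqs: Mapping[str, str], path: str | Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def simulate_coverage(
    high_anchors: Sequence[tuple[str, int]],
    low_anchors: Sequence[tuple[str, int]],
    config: SimConfig,
    factor: float = 3.0,
    chrom_sizes: Mapping[str, int] | None = None,
    flank: int = 2000,
    bin_size: int = 50,
    base_amplitude: float = 1.0,
    background: float = 0.05,
    peak_sd: float = 600.0,
    depth: float = 50.0,
) -> pd.DataFrame:
    """bedGraph rows with signal bumps at anchors.

    The expected signal at distance d from an anchor centre is
    background + A * exp(-d^2 / (2 * peak_sd^2)); ``high`` anchors get an
    amplitude such that the expected centre signal is ``factor`` times the
    low-anchor centre signal. Values are Poisson-sampled at the given
    sequencing depth so profiles carry realistic counting noise. Rows are
    emitted on a fixed genome-aligned bin grid, so they never overlap.
    """
    chrom_sizes = dict(chrom_sizes or config.chrom_lengths)
    rng = np.random.default_rng(derive_seed(config.seed, "coverage"))
    amp_low = base_amplitude
    amp_high = factor * (background + amp_low) - background
    if amp_high < 0:
        raise ValueError("factor too small for the configured background")

    # lambda per genome-aligned bin, accumulated over all anchors
    lam: dict[str, dict[int, float]] = {}
    for anchors, amp in ((high_anchors, amp_high), (low_anchors, amp_low)):
        for chrom, center in anchors:
            size = chrom_sizes[chrom]
            if not (0 <= center < size):
                raise ValueError(f"anchor {chrom}:{center} outside genome")
            b0 = max(0, (center - flank) // bin_size)
            b1 = min((size - 1) // bin_size, (center + flank) // bin_size)
            chrom_bins = lam.setdefault(chrom, {})
            for b in range(b0, b1 + 1):
                mid = b * bin_size + bin_size / 2
                d = mid - center
                chrom_bins[b] = chrom_bins.get(b, 0.0) + amp * np.exp(
                    -(d * d) / (2 * peak_sd * peak_sd)
                )

    rows = []
    for chrom in sorted(lam):
        size = chrom_sizes[chrom]
        for b in sorted(lam[chrom]):
            expected = background + lam[chrom][b]
            value = rng.poisson(expected * depth) / depth
            start = b * bin_size
            end = min(start + bin_size, size)
            rows.append((chrom, start, end, float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# Auxiliary synthetic inputs for the annotation stage


def simulate_term_map(
    genes: pd.DataFrame,
    truth: TruthSet,
    config: SimConfig,
    n_terms: int = 20,
    genes_per_term: int = 50,
    enriched_terms: int = 3,
    enriched_fraction: float = 0.5,
) -> dict[str, set[str]]:
    """Random term-to-gene map with a few terms enriched for planted up-genes."""
    rng = np.random.default_rng(derive_seed(config.seed, "terms"))
    all_genes = genes["gene"].tolist()
    up = sorted(truth.true_up)
    terms: dict[str, set[str]] = {}
    for t in range(n_terms):
        name = f"TERM{t:03d}"
        if t < enriched_terms and up:
            n_up = min(int(genes_per_term * enriched_fraction), len(up))
            chosen = set(rng.choice(up, size=n_up, replace=False))
            rest = rng.choice(all_genes, size=genes_per_term - n_up, replace=False)
            terms[name] = chosen | set(rest)
        else:
            terms[name] = set(rng.choice(all_genes, size=genes_per_term, replace=False))
    return terms


def simulate_ppi_edges(
    nodes: Sequence[str],
    config: SimConfig,
    mean_degree: float = 4.0,
) -> pd.DataFrame:
    """Random PPI edge list (preferential-attachment flavour) over ``nodes``."""
    rng = np.random.default_rng(derive_seed(config.seed, "ppi"))
    nodes = list(nodes)
    m = max(1, int(round(mean_degree / 2)))
    edges = []
    attached: list[str] = list(nodes[: m + 1])
    for i in range(m + 1, len(nodes)):
        targets = rng.choice(attached, size=m, replace=False)
        for t in targets:
            edges.append((nodes[i], t))
        attached.extend([nodes[i]] * m)
        attached.extend(targets)
    return pd.DataFrame(edges, columns=["nodeA", "nodeB"])
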