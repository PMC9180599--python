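"""Robust rank aggregation of differential-expression results.

Each gene's evidence across K ranked lists is summarised by the beta
order-statistic score: with normalised ranks r_(1) <= ... <= r_(n) (rank
position divided by the universe size, 1.0 for genes absent from a list),

    p_k = P(Beta(k, n - k + 1) <= r_(k))
        = sum_{j=k}^{n} C(n, j) r_(k)^j (1 - r_(k))^(n-j)

is the probability that the k-th smallest of n independent Uniform(0,1)
ranks would be at most r_(k); the score is rho = min_k p_k.  Under the null
(independent uniform orderings) rho is conservative after multiplying by the
Bonferroni factor n, giving the corrected p-value reported per gene.

Aggregation is run separately for up-regulated lists (sorted by descending
log2 fold change) and down-regulated lists (ascending); a robust call
requires the corrected p below a cutoff AND the median across-dataset log2FC
beyond a fold-change cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedGeneList",
    "rank_normalize",
    "rho_score",
    "aggregate_lists",
]


@dataclass
class RankedGeneList:
    """One dataset's genes ordered best-first, with per-gene log2FC."""

    dataset_id: str
    ordered_genes: Sequence[str]
    log2fc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ordered_genes)) != len(self.ordered_genes):
            raise ValueError(f"{self.dataset_id}: duplicate genes in ranked list")

    @classmethod
    def from_deg_table(
        cls,
        table: pd.DataFrame,
        dataset_id: str,
        direction: Literal["up", "down"] = "up",
    ) -> "RankedGeneList":
        """Rank a DEG table (columns gene, log2fc) by effect size.

        direction='up': descending log2FC (strongest up-regulation first);
        'down': ascending. Ties broken by gene id for reproducibility.
        """
        ascending = direction == "down"
        ordered = table.sort_values(
            ["log2fc", "gene"], ascending=[ascending, True], kind="mergesort"
        )
        return cls(
            dataset_id=dataset_id,
            ordered_genes=ordered["gene"].tolist(),
            log2fc=dict(zip(table["gene"], table["log2fc"])),
        )


def rank_normalize(ranked: RankedGeneList, universe: Sequence[str]) -> dict[str, float]:
    """Normalised rank r in (0, 1] per universe gene.

    The gene at (1-based) position i gets r = i / N with N the universe
    size; universe genes absent from the list get r = 1.0 (conservative).
    """
    universe = list(universe)
    n = len(universe)
    if n == 0:
        raise ValueError("empty gene universe")
    extra = set(ranked.ordered_genes) - set(universe)
    if extra:
        raise ValueError(
            f"{ranked.dataset_id}: {len(extra)} ranked genes not in universe"
        )
    r = {g: 1.0 for g in universe}
    for i, g in enumerate(ranked.ordered_genes, start=1):
        r[g] = i / n
    return r


def rho_score(normalized_ranks: Sequence[float]) -> tuple[float, float]:
    """Beta order-statistic score of one gene's normalised ranks.

    Returns (rho, p_corrected) with rho = min_k P(Beta(k, n-k+1) <= r_(k))
    and p_corrected = min(1, n * rho).
    """
    r = np.asarray(normalized_ranks, dtype=float)
    if r.ndim != 1 or len(r) == 0:
        raise ValueError("need a nonempty 1-D rank vector")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalised ranks must lie in (0, 1]")
    n = len(r)
    rs = np.sort(r)
    k = np.arange(1, n + 1)
    p = stats.beta.cdf(rs, k, n - k + 1)
    rho = float(p.min())
    return rho, min(1.0, n * rho)


def _rho_matrix(rank_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised rho over rows of a (genes x lists) rank matrix."""
    n = rank_matrix.shape[1]
    rs = np.sort(rank_matrix, axis=1)
    k = np.arange(1, n + 1)
    p = stats.beta.cdf(rs, k[None, :], (n - k + 1)[None, :])
    rho = p.min(axis=1)
    return rho, np.minimum(1.0, n * rho)


def aggregate_lists(
    lists: Sequence[RankedGeneList],
    universe: Sequence[str],
    direction: Literal["up", "down"],
    padj_max: float = 0.01,
    abs_log2fc_min: float = 1.0,
    correction: Literal["bonferroni_n", "bh_over_genes"] = "bonferroni_n",
    drop_absent: bool = False,
) -> pd.DataFrame:
    """Score every universe gene across ranked lists and call robust DEGs.

    Parameters
    ----------
    lists
        Per-dataset ranked lists, already ordered for the requested
        direction (use :meth:`RankedGeneList.from_deg_table`).
    universe
        All genes eligible for scoring.
    direction
        'up' or 'down'; determines the sign required of the summary log2FC.
    padj_max, abs_log2fc_min
        Joint robust-call thresholds (corrected p strictly below,
        |median log2FC| strictly above).
    correction
        'bonferroni_n': p_corrected = min(1, n_lists * rho) per the RRA
        method. 'bh_over_genes': Benjamini-Hochberg over the per-gene rho
        values instead.
    drop_absent
        If True, a gene absent from a list is scored over the lists that
        contain it rather than receiving r = 1.0 there.

    Returns a DataFrame (gene, rho, p_corrected, summary_log2fc,
    n_lists_present, direction, robust) sorted by rho ascending.
    """
    if not lists:
        raise ValueError("need at least one ranked list")
    universe = list(dict.fromkeys(universe))
    n_genes = len(universe)
    if n_genes == 0:
        raise ValueError("empty gene universe")
    gene_idx = {g: i for i, g in enumerate(universe)}
    n_lists = len(lists)

    rmat = np.ones((n_genes, n_lists))
    present = np.zeros((n_genes, n_lists), dtype=bool)
    fc = np.full((n_genes, n_lists), np.nan)
    for j, rl in enumerate(lists):
        rj = rank_normalize(rl, universe)
        for g, val in rj.items():
            rmat[gene_idx[g], j] = val
        for g in rl.ordered_genes:
            i = gene_idx[g]
            present[i, j] = True
            fc[i, j] = rl.log2fc.get(g, np.nan)

    if drop_absent:
        rho = np.ones(n_genes)
        p_corr = np.ones(n_genes)
        for i in range(n_genes):
            cols = present[i]
            if cols.any():
                rho[i], p_corr[i] = rho_score(rmat[i, cols])
    else:
        rho, p_corr = _rho_matrix(rmat)

    if correction == "bh_over_genes":
        p_corr = multipletests(rho, method="fdr_bh")[1]
    elif correction != "bonferroni_n":
        raise ValueError(f"unknown correction {correction!r}")

    with np.errstate(all="ignore"):
        summary_fc = np.nanmedian(np.where(present, fc, np.nan), axis=1)
    summary_fc = np.where(present.any(axis=1), summary_fc, 0.0)
    n_present = present.sum(axis=1)

    if direction == "up":
        fc_pass = summary_fc > abs_log2fc_min
    elif direction == "down":
        fc_pass = summary_fc < -abs_log2fc_min
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    robust = (p_corr < padj_max) & fc_pass

    out = pd.DataFrame(
        {
            "gene": universe,
            "rho": rho,
            "p_corrected": p_corr,
            "summary_log2fc": summary_fc,
            "n_lists_present": n_present,
            "direction": direction,
            "robust": robust,
        }
    )
    return out.sort_values(["rho", "gene"], kind="mergesort").reset_index(drop=True)


def overlap_report(query: set[str], reference: set[str]) -> dict:
    """Cross-platform validation report: what share of one robust-DEG set
    is recovered by another.

    Returns counts and the percentage rounded to the nearest integer, e.g.
    418 of 452 -> 92%.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    k = len(query & set(reference))
    pct = 100.0 * k / len(query)
    return {
        "n_query": len(query),
        "n_overlap": k,
        "fraction": k / len(query),
        "percent_rounded": int(round(pct)),
    }
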