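"""Region-to-gene association and gene-set enrichment.

Regulatory domains follow the GREAT "basal plus extension" scheme: every
gene gets a basal domain (default 5 kb upstream / 1 kb downstream of its
TSS, strand-aware) and each side is then extended to the nearer of the
adjacent gene's basal boundary, a distance cap (default 1 Mb), or the
chromosome end — never crossing into another gene's basal domain. A
binding site is associated with every gene whose extended domain it
overlaps, so one site may annotate several neighbouring genes.

Term enrichment on the associated (or any) gene set is the hypergeometric
upper tail with Benjamini-Hochberg adjustment; candidate regulators are
ranked by their degree in a protein-protein interaction edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, PeakSet

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryDomain:
    gene: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if self.basal.chrom != self.extended.chrom:
            raise ValueError(f"{self.gene}: basal and extended on different chromosomes")
        if not (self.extended.start <= self.basal.start and self.basal.end <= self.extended.end):
            raise ValueError(f"{self.gene}: basal domain not contained in extended domain")


def basal_domains(
    genes: pd.DataFrame,
    upstream: int = 5000,
    downstream: int = 1000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Strand-aware basal domain per gene (extended == basal until extended).

    ``genes`` needs columns gene, chrom, tss, strand; strand is required
    here (the upstream/downstream asymmetry is meaningless without it).
    """
    domains = []
    for row in genes.itertuples(index=False):
        strand = getattr(row, "strand", None)
        if strand not in ("+", "-"):
            raise ValueError(f"gene {row.gene}: strand must be '+' or '-', got {strand!r}")
        tss = int(row.tss)
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        start = max(0, start)
        if chrom_sizes is not None and row.chrom in chrom_sizes:
            end = min(end, chrom_sizes[row.chrom])
        iv = GenomicInterval(row.chrom, start, end, strand=strand, name=str(row.gene))
        domains.append(RegulatoryDomain(gene=str(row.gene), basal=iv, extended=iv))
    return domains


def extend_domains(
    domains: Sequence[RegulatoryDomain],
    cap: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
    stop_at_sites: PeakSet | None = None,
) -> list[RegulatoryDomain]:
    """Extend basal domains toward neighbours, up to ``cap`` bp per side.

    Each side stops at the nearest of: the adjacent gene's basal boundary,
    cap bp beyond the gene's own basal boundary, or the chromosome end.
    Extensions never enter another gene's basal domain. If
    ``stop_at_sites`` is given, the extension additionally stops at the
    first binding site encountered on that side (the literal
    stop-at-first-site reading of region extension).
    """
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.basal.chrom, []).append(d)

    out: list[RegulatoryDomain] = []
    for chrom, ds in by_chrom.items():
        ds = sorted(ds, key=lambda d: (d.basal.start, d.basal.end, d.gene))
        starts = np.array([d.basal.start for d in ds])
        ends = np.array([d.basal.end for d in ds])
        n = len(ds)
        # running extrema over neighbours on each side (basal domains may overlap)
        prefix_max_end = np.full(n, -1)
        running = -1
        for i in range(n):
            prefix_max_end[i] = running
            running = max(running, ends[i])
        suffix_min_start = np.full(n, np.iinfo(np.int64).max)
        running = np.iinfo(np.int64).max
        for i in range(n - 1, -1, -1):
            suffix_min_start[i] = running
            running = min(running, starts[i])

        chrom_len = (chrom_sizes or {}).get(chrom)
        for i, d in enumerate(ds):
            s, e = int(starts[i]), int(ends[i])
            left_limit = 0
            if prefix_max_end[i] >= 0:
                left_limit = min(int(prefix_max_end[i]), s)
            right_limit = chrom_len if chrom_len is not None else None
            if suffix_min_start[i] < np.iinfo(np.int64).max:
                neigh = max(int(suffix_min_start[i]), e)
                right_limit = neigh if right_limit is None else min(right_limit, neigh)
            # a neighbour's basal may contain this one entirely
            if prefix_max_end[i] > e:
                right_limit = e
            ext_start = max(s - cap, left_limit, 0)
            ext_end = e + cap if right_limit is None else min(e + cap, right_limit)
            if chrom_len is not None:
                ext_end = min(ext_end, chrom_len)
            ext_end = max(ext_end, e)
            if stop_at_sites is not None:
                ext_start, ext_end = _clip_to_sites(
                    chrom, s, e, ext_start, ext_end, stop_at_sites
                )
            out.append(
                RegulatoryDomain(
                    gene=d.gene,
                    basal=d.basal,
                    extended=GenomicInterval(
                        chrom, ext_start, ext_end, strand=d.basal.strand, name=d.gene
                    ),
                )
            )
    return out


def _clip_to_sites(chrom, basal_s, basal_e, ext_s, ext_e, sites: PeakSet):
    """Stop each extension at the first binding site beyond the basal domain."""
    arr = sites.intervals_on(chrom)
    if len(arr) == 0:
        return ext_s, ext_e
    left_ends = arr[arr[:, 1] <= basal_s, 1]
    if len(left_ends):
        ext_s = max(ext_s, int(left_ends.max()) - 1)  # include the site itself
        ext_s = min(ext_s, basal_s)
    right_starts = arr[arr[:, 0] >= basal_e, 0]
    if len(right_starts):
        ext_e = min(ext_e, int(right_starts.min()) + 1)
        ext_e = max(ext_e, basal_e)
    return ext_s, ext_e


def associate_regions(
    sites: PeakSet,
    domains: Sequence[RegulatoryDomain],
) -> tuple[dict[str, list[int]], dict[int, list[str]]]:
    """Associate each site with every gene whose extended domain it overlaps.

    Returns (gene -> list of site row indices, site row index -> gene
    list). Genes with no sites appear with empty lists; sites hitting no
    domain get empty gene lists (counted in the log).
    """
    trees: dict[str, IntervalTree] = {}
    for d in domains:
        trees.setdefault(d.extended.chrom, IntervalTree()).addi(
            d.extended.start, d.extended.end, d.gene
        )
    gene2sites: dict[str, list[int]] = {d.gene: [] for d in domains}
    site2genes: dict[int, list[str]] = {}
    n_orphan = 0
    for i, row in enumerate(sites.df.itertuples(index=False)):
        tree = trees.get(row.chrom)
        genes = sorted(iv.data for iv in tree.overlap(row.start, row.end)) if tree else []
        site2genes[i] = genes
        if not genes:
            n_orphan += 1
        for g in genes:
            gene2sites[g].append(i)
    if n_orphan:
        logger.info("associate_regions: %d sites hit no regulatory domain", n_orphan)
    return gene2sites, site2genes


def hypergeom_enrich(
    query: Iterable[str],
    universe: Iterable[str],
    term2genes: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail term enrichment with BH adjustment.

    For each term with K genes in the universe, query size n and overlap k:
    p = P(X >= k) for X ~ Hypergeometric(N, K, n). Terms with k = 0 are
    skipped; terms are intersected with the universe first.

    Returns a DataFrame (term, k, K, n, N, p, padj) sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query) & universe
    n, N = len(query), len(universe)
    rows = []
    for term, genes in term2genes.items():
        tg = set(genes) & universe
        K = len(tg)
        k = len(query & tg)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(out):
        out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["padj"] = pd.Series(dtype=float)
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def ppi_degree_rank(
    edges: pd.DataFrame | Sequence[tuple],
    nodes_of_interest: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Rank nodes by distinct-neighbour degree in a PPI edge list.

    Self-loops are ignored and duplicate edges count once. Sort: degree
    descending, ties by node id ascending. If ``nodes_of_interest`` is
    given only those nodes are reported (absent ones with degree 0).
    """
    if isinstance(edges, pd.DataFrame):
        pairs = edges.iloc[:, :2].itertuples(index=False)
    else:
        pairs = ((a, b) for a, b, *_ in edges)
    g = nx.Graph()
    for a, b in pairs:
        if a != b:
            g.add_edge(str(a), str(b))
    if nodes_of_interest is None:
        nodes = list(g.nodes)
    else:
        nodes = [str(x) for x in nodes_of_interest]
    rows = [{"node": v, "degree": g.degree(v) if v in g else 0} for v in nodes]
    out = pd.DataFrame(rows, columns=["node", "degree"])
    return (
        out.sort_values(["degree", "node"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# I/O


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, chrom, tss, strand."""
    genes = pd.read_csv(path, sep="\t")
    missing = {"gene", "chrom", "tss", "strand"} - set(genes.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    return genes


def read_term2genes(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], comment="#")
    if df.iloc[0]["term"] == "term":  # tolerate a header row
        df = df.iloc[1:]
    out: dict[str, set[str]] = {}
    for term, sub in df.groupby("term"):
        out[str(term)] = set(sub["gene"].astype(str))
    return out


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if str(df.iloc[0, 0]).lower() in ("nodea", "node_a", "protein1", "source"):
        df = df.iloc[1:].reset_index(drop=True)
    return df
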