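"""Per-dataset differential expression.

A deliberately small, transparent DE test producing the (gene, log2fc,
pvalue, padj) tables the rank-aggregation step consumes: median-of-ratios
size factors (or CPM), log2(normalised count + 0.5), a two-sided Welch t
per gene, and Benjamini-Hochberg adjustment. Externally produced DEG tables
(e.g. from DESeq2 or limma) can be dropped in instead — the downstream
aggregation only needs the table columns.

Fold-change sign convention: positive log2FC = higher in the second group
(MT, differentiated) relative to the first (MB, undifferentiated).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "log2fc", "pvalue", "padj"]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors.

    Per-gene geometric mean over samples (genes with any zero excluded from
    the reference), then per-sample median of count/reference ratios.
    Falls back to library-size scaling if no gene is all-positive.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        logger.warning("no all-positive genes; falling back to library-size factors")
        libs = mat.sum(axis=0)
        return pd.Series(libs / np.exp(np.mean(np.log(libs))), index=counts.columns)
    logmat = np.log(mat[positive])
    ref = logmat.mean(axis=1)
    sf = np.exp(np.median(logmat - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def normalize_counts(
    counts: pd.DataFrame,
    method: Literal["median-of-ratios", "cpm"] = "median-of-ratios",
) -> pd.DataFrame:
    if method == "median-of-ratios":
        sf = size_factors_median_of_ratios(counts)
        return counts / sf
    if method == "cpm":
        libs = counts.sum(axis=0)
        return counts * 1e6 / libs
    raise ValueError(f"unknown normalisation {method!r}")


def differential_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    norm: Literal["median-of-ratios", "cpm"] = "median-of-ratios",
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-group DE test on a genes x samples count matrix.

    ``groups`` labels each column; the log2FC is (second group) - (first
    group) of mean log2(normalised count + 0.5). With labels {MB, MT} the
    contrast is MT over MB. All-zero genes are excluded from testing and
    from the BH denominator (logged).

    Returns a DataFrame with columns gene, log2fc, pvalue, padj.
    """
    groups = np.asarray(groups)
    if len(groups) != counts.shape[1]:
        raise ValueError("groups length must equal number of samples")
    labels = group_order or tuple(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    g0, g1 = labels  # contrast = g1 - g0
    if group_order is None and (g0, g1) == ("MT", "MB"):
        g0, g1 = g1, g0  # MB is the baseline state unless told otherwise
    for g in (g0, g1):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")

    all_zero = (counts.sum(axis=1) == 0).to_numpy()
    if all_zero.any():
        logger.info("excluding %d all-zero genes from testing", int(all_zero.sum()))
    tested = counts.loc[~all_zero]

    normed = normalize_counts(tested, method=norm)
    logn = np.log2(normed.to_numpy(dtype=float) + 0.5)
    x0 = logn[:, groups == g0]
    x1 = logn[:, groups == g1]

    log2fc = x1.mean(axis=1) - x0.mean(axis=1)
    with np.errstate(all="ignore"):
        t, p = stats.ttest_ind(x1, x0, axis=1, equal_var=False)
    # constant genes in both groups -> nan p; no evidence against the null
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {"gene": tested.index, "log2fc": log2fc, "pvalue": p, "padj": padj}
    ).reset_index(drop=True)


def threshold_degs(
    table: pd.DataFrame,
    abs_log2fc_min: float = 1.0,
    padj_max: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Call up/down DEGs with strict inequalities.

    up = {log2fc > abs_log2fc_min and padj < padj_max}; down mirrored.
    The default thresholds are |FC| > 2 (|log2FC| > 1) at adjusted p < 0.05.
    """
    if abs_log2fc_min <= 0 or padj_max <= 0:
        raise ValueError("thresholds must be positive")
    sig = table["padj"] < padj_max
    up = set(table.loc[sig & (table["log2fc"] > abs_log2fc_min), "gene"])
    down = set(table.loc[sig & (table["log2fc"] < -abs_log2fc_min), "gene"])
    return up, down


# ---------------------------------------------------------------------------
# I/O


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV count matrix; first column = gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (sample, group)."""
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(sheet.columns):
        raise ValueError("sample sheet needs columns 'sample' and 'group'")
    return sheet


def read_deg_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(DEG_COLUMNS[:2]) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing DEG columns {sorted(missing)}")
    return table


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
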