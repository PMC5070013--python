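"""RNA-seq downstream statistics: RPKM, X:A medians, chromosome shift tests,
quadrant concordance and top-percentile gene sets.

The X:A expression ratio — median expression of X-linked genes over median
expression of autosomal genes among expressed genes (RPKM > 1) — is the
chromosome-level summary of dosage compensation: 0.5 would mean a single
uncompensated X transcribed at autosomal per-copy rates, 1.0 full parity.
Condition contrasts are per-gene log2 ratios of library-size-normalized
replicate means, compared between chromosomes by one-sided Wilcoxon rank-sum
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .karyotype import Karyotype
from .stats import TestResult, rank_sum_test


def compute_rpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
    chroms: pd.Series | None = None,
) -> pd.DataFrame:
    """Reads per kilobase per million: count x 1e9 / (length_bp x library_size).

    ``counts`` is genes x replicates; ``lengths`` the exonic length per gene.
    ``library_sizes`` defaults to the column sums.  Returns a table with the
    per-replicate RPKM columns, their mean, and optional chromosome labels.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        bad = counts.index[(lengths <= 0) | lengths.isna()][:5].tolist()
        raise ValueError(f"non-positive or missing gene lengths, e.g. {bad}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm = counts * 1e9
    rpkm = rpkm.div(library_sizes, axis=1).div(lengths, axis=0)
    out = pd.DataFrame(index=counts.index)
    if chroms is not None:
        out["chrom"] = chroms.reindex(counts.index)
    out["length"] = lengths
    for col in counts.columns:
        out[f"count_{col}"] = counts[col]
    for col in rpkm.columns:
        out[f"rpkm_{col}"] = rpkm[col]
    out["mean_rpkm"] = rpkm.mean(axis=1)
    return out


@dataclass
class XARatio:
    ratio: float
    per_chrom_median: pd.Series
    n_x: int
    n_autosomal: int
    min_rpkm: float


def median_xa_ratio(table: pd.DataFrame, karyotype: Karyotype, min_rpkm: float = 1.0) -> XARatio:
    """Median X / median autosomal mean RPKM among genes above ``min_rpkm``.

    Requires ``chrom`` and ``mean_rpkm`` columns (see :func:`compute_rpkm`).
    """
    expressed = table[table["mean_rpkm"] > min_rpkm]
    x_mask = expressed["chrom"] == karyotype.x_chrom
    a_mask = expressed["chrom"].isin(karyotype.autosomes)
    n_x, n_a = int(x_mask.sum()), int(a_mask.sum())
    if n_x == 0:
        raise ValueError("no expressed X-linked genes")
    if n_a == 0:
        raise ValueError("no expressed autosomal genes")
    x_med = float(expressed.loc[x_mask, "mean_rpkm"].median())
    a_med = float(expressed.loc[a_mask, "mean_rpkm"].median())
    per_chrom = expressed.groupby("chrom")["mean_rpkm"].median()
    return XARatio(
        ratio=x_med / a_med, per_chrom_median=per_chrom, n_x=n_x, n_autosomal=n_a,
        min_rpkm=min_rpkm,
    )


def contrast_log2(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    chroms: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 ratio of condition A over condition B.

    Each replicate is scaled by its library size (column sum) to the geometric
    mean library of both conditions, replicate means are taken per condition,
    and the ratio is log2((meanA + pc) / (meanB + pc)) with the pseudocount on
    the normalized-count scale.  Swapping A and B negates every ratio.
    """
    genes = counts_a.index.intersection(counts_b.index)
    a = counts_a.loc[genes]
    b = counts_b.loc[genes]
    libs = np.concatenate([a.sum(axis=0).to_numpy(), b.sum(axis=0).to_numpy()]).astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    target = float(np.exp(np.mean(np.log(libs))))
    mean_a = a.div(a.sum(axis=0), axis=1).mean(axis=1) * target
    mean_b = b.div(b.sum(axis=0), axis=1).mean(axis=1) * target
    ratio = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {"chrom": chroms.reindex(genes), "log2_ratio": ratio}, index=genes
    )


def chromosome_shift_test(
    contrast: pd.DataFrame, karyotype: Karyotype, direction: str = "greater"
) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum of X-gene ratios against autosomal ratios.

    ``direction='greater'`` tests X shifted up relative to autosomes.  Tests X
    against the pooled autosomes and against each autosome individually.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    x_vals = contrast.loc[contrast["chrom"] == karyotype.x_chrom, "log2_ratio"].to_numpy()
    rows = []
    comparisons = [("autosomes", karyotype.autosomes)] + [
        (c, [c]) for c in karyotype.autosomes
    ]
    for label, chroms in comparisons:
        a_vals = contrast.loc[contrast["chrom"].isin(chroms), "log2_ratio"].to_numpy()
        if len(x_vals) < 5 or len(a_vals) < 5:
            raise ValueError("need >= 5 genes per group for the shift test")
        res: TestResult = rank_sum_test(x_vals, a_vals, alternative=direction)
        rows.append(
            {
                "comparison": f"X_vs_{label}",
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "n_x": res.n1,
                "n_other": res.n2,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


QUADRANTS = ("up_up", "up_down", "down_up", "down_down")


@dataclass
class QuadrantTable:
    """Percent of genes per sign-quadrant (plus unclassified), X vs autosomes.

    A gene is in a quadrant only if |log2 ratio| exceeds the threshold on both
    axes; quadrant names are '<A-direction>_<B-direction>'.  Percentages use
    all genes of the class as denominator and sum to 100.
    """

    percent: pd.DataFrame  # index X/autosomes, columns QUADRANTS + unclassified
    counts: pd.DataFrame
    threshold: float


def quadrant_classify(
    contrast_a: pd.DataFrame,
    contrast_b: pd.DataFrame,
    karyotype: Karyotype,
    thresh: float = 0.1,
) -> QuadrantTable:
    genes = contrast_a.index.intersection(contrast_b.index)
    a = contrast_a.loc[genes, "log2_ratio"].to_numpy()
    b = contrast_b.loc[genes, "log2_ratio"].to_numpy()
    chrom = contrast_a.loc[genes, "chrom"]
    classified = (np.abs(a) > thresh) & (np.abs(b) > thresh)
    quadrant = np.where(
        ~classified,
        "unclassified",
        np.where(a > 0, "up", "down") + "_" + np.where(b > 0, "up", "down"),
    )
    klass = np.where(chrom == karyotype.x_chrom, "X",
                     np.where(chrom.isin(karyotype.autosomes), "autosomes", "other"))
    df = pd.DataFrame({"class": klass, "quadrant": quadrant})
    df = df[df["class"] != "other"]
    counts = (
        df.value_counts().unstack(fill_value=0)
        .reindex(index=["X", "autosomes"], columns=list(QUADRANTS) + ["unclassified"], fill_value=0)
    )
    percent = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return QuadrantTable(percent=percent, counts=counts, threshold=thresh)


@dataclass
class TopPercentSets:
    """Top-percentile X gene sets of a reference contrast and the companion
    distribution of those same genes in a second contrast."""

    summary: pd.DataFrame
    sets: dict[int, list]


def top_percent_sets(
    reference: pd.DataFrame,
    companion: pd.DataFrame,
    pcts: tuple[int, ...] = (5, 10, 15),
    chrom: str = "X",
) -> TopPercentSets:
    """Rank X genes by descending reference log2 ratio and summarize the same
    genes' companion ratios for each top percentage (ties broken by gene id)."""
    x_ref = reference[reference["chrom"] == chrom]
    if len(x_ref) < 20:
        raise ValueError("need >= 20 X-linked genes in the reference contrast")
    ranked = (
        x_ref.assign(_gid=x_ref.index.astype(str))
        .sort_values(["log2_ratio", "_gid"], ascending=[False, True], kind="mergesort")
    )
    comp = companion["log2_ratio"]
    rows = []
    sets: dict[int, list] = {}
    for pct in pcts:
        k = max(1, int(len(ranked) * pct / 100))
        top = ranked.index[:k].tolist()
        sets[pct] = top
        vals = comp.reindex(top).dropna()
        rows.append(
            {
                "top_pct": pct,
                "n_genes": len(top),
                "companion_median": float(vals.median()),
                "companion_q1": float(vals.quantile(0.25)),
                "companion_q3": float(vals.quantile(0.75)),
            }
        )
    all_vals = comp.reindex(x_ref.index).dropna()
    rows.append(
        {
            "top_pct": 100,
            "n_genes": len(x_ref),
            "companion_median": float(all_vals.median()),
            "companion_q1": float(all_vals.quantile(0.25)),
            "companion_q3": float(all_vals.quantile(0.75)),
        }
    )
    return TopPercentSets(summary=pd.DataFrame(rows), sets=sets)
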