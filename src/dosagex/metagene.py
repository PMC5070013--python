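"""Gene-anchored signal profiles from z-scored coverage tracks.

A metagene profile resamples each gene body to a fixed number of bins
(length-weighted averaging of the underlying per-bp signal) and adds fixed
width flanks upstream of the TSS and downstream of the TTS.  Minus-strand
genes are reversed so the TSS is always on the left.  Genes are averaged
unweighted within a stratum.

The length-weighted average over an arbitrary interval is computed exactly
from the cumulative integral of the piecewise-constant binned track, which is
piecewise linear and therefore evaluable by ``np.interp`` — no per-bp arrays
are ever materialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip import CoverageTrack

log = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    """Mean signal on the flank / scaled-body / flank axis for one stratum."""

    values: np.ndarray
    n_genes: int
    label: str
    flank_bins: int
    body_bins: int
    flank_bp: int

    @property
    def axis_len(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def body_mean(self) -> float:
        return float(np.nanmean(self.values[self.flank_bins: self.flank_bins + self.body_bins]))


class _ChromIntegral:
    """Exact cumulative integral of a binned track on one chromosome."""

    def __init__(self, values: np.ndarray, bin_size: int, length: int | None = None):
        n = len(values)
        edges = np.arange(n + 1, dtype=float) * bin_size
        if length is not None:
            edges[-1] = min(edges[-1], float(length))
        widths = np.diff(edges)
        self.length = edges[-1]
        self.edges = edges
        self.cum = np.concatenate([[0.0], np.cumsum(values * widths)])

    def segment_means(self, seg_edges: np.ndarray) -> np.ndarray:
        """Mean signal over segments given by consecutive edge columns.

        seg_edges: (n_genes, n_segments+1) physical coordinates; edges are
        clipped to the chromosome, zero-width segments yield NaN.
        """
        clipped = np.clip(seg_edges, 0.0, self.length)
        s = np.interp(clipped, self.edges, self.cum)
        widths = np.diff(clipped, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.diff(s, axis=1) / widths
        means[widths <= 0] = np.nan
        return means


def _gene_matrix(
    track: CoverageTrack,
    genes: pd.DataFrame,
    chrom_lengths: dict[str, int],
    flank_bp: int,
    body_bins: int,
    flank_bins: int,
) -> tuple[np.ndarray, pd.Index]:
    """(n_genes, axis) matrix of per-gene profiles, TSS on the left."""
    mats = []
    idx = []
    skipped = 0
    for chrom, sub in genes.groupby("chrom", sort=False):
        if chrom not in track.values:
            continue
        integral = _ChromIntegral(track.values[chrom], track.bin_size, chrom_lengths.get(chrom))
        starts = sub["start"].to_numpy(dtype=float)
        ends = sub["end"].to_numpy(dtype=float)
        ok = (ends - starts) >= body_bins  # need >= 1 bp per body bin
        if (~ok).any():
            skipped += int((~ok).sum())
        sub = sub[ok]
        starts, ends = starts[ok], ends[ok]
        if len(sub) == 0:
            continue
        up = starts[:, None] - flank_bp + np.arange(flank_bins + 1) * (flank_bp / flank_bins)
        body = starts[:, None] + (ends - starts)[:, None] * np.linspace(0, 1, body_bins + 1)
        down = ends[:, None] + np.arange(flank_bins + 1) * (flank_bp / flank_bins)
        m = np.concatenate(
            [
                integral.segment_means(up),
                integral.segment_means(body),
                integral.segment_means(down),
            ],
            axis=1,
        )
        minus = (sub["strand"] == "-").to_numpy()
        m[minus] = m[minus, ::-1]
        mats.append(m)
        idx.extend(sub["gene_id"].tolist())
    if skipped:
        log.info("metagene: skipped %d genes shorter than %d bp", skipped, body_bins)
    if not mats:
        return np.empty((0, 2 * flank_bins + body_bins)), pd.Index([])
    return np.concatenate(mats, axis=0), pd.Index(idx)


def metagene_profile(
    track: CoverageTrack,
    genes: pd.DataFrame,
    strata: dict[str, list] | None = None,
    flank_bp: int = 1000,
    body_bins: int = 100,
    flank_bins: int = 20,
    chrom_lengths: dict[str, int] | None = None,
) -> list[MetageneProfile]:
    """Stratified metagene profiles of a (z-scored) track.

    ``genes`` needs gene_id / chrom / start / end / strand columns.  ``strata``
    maps a label to a list of gene ids (default: one stratum with every gene).
    Genes shorter than one bp per body bin are skipped and logged.
    """
    if "strand" not in genes.columns:
        raise ValueError("genes need a strand column")
    mat, idx = _gene_matrix(
        track, genes, chrom_lengths or {}, flank_bp, body_bins, flank_bins
    )
    if strata is None:
        strata = {"all": list(idx)}
    lookup = pd.Series(np.arange(len(idx)), index=idx)
    profiles = []
    for label, gene_ids in strata.items():
        pos = lookup.reindex(gene_ids).dropna().astype(int).to_numpy()
        if len(pos) == 0:
            raise ValueError(f"stratum {label!r} has no usable genes")
        profiles.append(
            MetageneProfile(
                values=np.nanmean(mat[pos], axis=0),
                n_genes=len(pos),
                label=label,
                flank_bins=flank_bins,
                body_bins=body_bins,
                flank_bp=flank_bp,
            )
        )
    return profiles


def quartile_profiles(
    track: CoverageTrack,
    genes: pd.DataFrame,
    expression: pd.Series,
    chrom_sets: dict[str, list[str]],
    **kwargs,
) -> dict[str, list[MetageneProfile]]:
    """Metagene profiles split by expression quartile within each chromosome set.

    ``expression`` is indexed by gene_id (e.g. mean RPKM).  Quartile boundaries
    are computed within each chromosome set; ties at a boundary go to the lower
    quartile.  Fewer than 4 genes in a set is an error.
    """
    out: dict[str, list[MetageneProfile]] = {}
    for set_label, chroms in chrom_sets.items():
        sub = genes[genes["chrom"].isin(chroms)]
        expr = expression.reindex(sub["gene_id"]).dropna()
        if len(expr) < 4:
            raise ValueError(f"chromosome set {set_label!r} has <4 genes with expression")
        bounds = np.quantile(expr.to_numpy(), [0.25, 0.5, 0.75])
        q = np.searchsorted(bounds, expr.to_numpy(), side="left")  # ties -> lower
        strata = {
            f"{set_label}_Q{i + 1}": expr.index[q == i].tolist() for i in range(4)
        }
        out[set_label] = metagene_profile(track, sub, strata=strata, **kwargs)
    return out


def tss_upstream_score(
    track: CoverageTrack,
    genes: pd.DataFrame,
    window: int = 500,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean track value over the ``window`` bp upstream of each TSS.

    Strand-aware: [TSS - w, TSS) for '+' genes, [TSS, TSS + w) for '-' genes
    (with the '-' TSS at the gene end).  Windows truncated by a chromosome
    edge are averaged over the available bp and flagged ``clipped``.
    """
    rows = []
    chrom_lengths = chrom_lengths or {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        if chrom not in track.values:
            continue
        integral = _ChromIntegral(track.values[chrom], track.bin_size, chrom_lengths.get(chrom))
        plus = sub["strand"] == "+"
        tss = sub["start"].where(plus, sub["end"]).to_numpy(dtype=float)
        lo = np.where(plus, tss - window, tss)
        hi = np.where(plus, tss, tss + window)
        edges = np.stack([lo, hi], axis=1)
        means = integral.segment_means(edges)[:, 0]
        clipped = (lo < 0) | (hi > integral.length)
        for gid, score, cl in zip(sub["gene_id"], means, clipped):
            rows.append({"gene_id": gid, "score": float(score), "clipped": bool(cl)})
    return pd.DataFrame(rows)
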