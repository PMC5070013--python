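"""ChIP-seq downstream pipeline: binned coverage, ploidy-aware normalization,
z-score standardization, broad-peak calling, read-fraction ratios, peak
density and genomic-category annotation.

The normalization follows the dosage-compensation-aware rule: coverage is
divided by the genome-wide median bin coverage (mitochondrial bins excluded);
in XO samples, where the single X contributes half the reads of a diploid
chromosome, autosomal bins are divided by the autosomal median while X bins
are divided by *half* that median, putting X and autosomes on the same
per-copy scale.  Enrichment is normalized ChIP minus normalized input, then
standardized by a z-score against a presumed-background estimate.

Coordinates are 0-based half-open; bins tile each chromosome with a possibly
short last bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CATEGORIES, CATEGORY_CODES, GenomeAnnotation
from .karyotype import Karyotype

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "mean_z"]


@dataclass
class ReadSet:
    """Aligned single-end reads, one sorted start array per chromosome."""

    starts: dict[str, np.ndarray]
    read_length: int = 50

    @property
    def n_reads(self) -> int:
        return int(sum(len(v) for v in self.starts.values()))

    def n_on(self, chrom: str) -> int:
        return int(len(self.starts.get(chrom, ())))

    def midpoints(self, chrom: str) -> np.ndarray:
        return self.starts.get(chrom, np.empty(0, dtype=np.int64)) + self.read_length // 2

    # -- BED IO ------------------------------------------------------------

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.starts):
                for s in self.starts[chrom]:
                    fh.write(f"{chrom}\t{s}\t{s + self.read_length}\n")

    @classmethod
    def read_bed(cls, path) -> "ReadSet":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"],
                         usecols=[0, 1, 2])
        read_length = int((df["end"] - df["start"]).mode().iloc[0]) if len(df) else 50
        starts = {
            str(chrom): np.sort(sub["start"].to_numpy(dtype=np.int64))
            for chrom, sub in df.groupby("chrom")
        }
        return cls(starts=starts, read_length=read_length)


@dataclass
class CoverageTrack:
    """Per-chromosome binned values with a semantics tag.

    kind is one of raw | normalized | enrichment | zscore.
    """

    values: dict[str, np.ndarray]
    bin_size: int
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def with_values(self, values: dict[str, np.ndarray], kind: str, **meta) -> "CoverageTrack":
        return CoverageTrack(values=values, bin_size=self.bin_size, kind=kind,
                             meta={**self.meta, **meta})

    def write_bedgraph(self, path, karyotype: Karyotype) -> None:
        with open(path, "w") as fh:
            for chrom, vals in self.values.items():
                length = karyotype.lengths[chrom]
                edges = np.minimum(np.arange(len(vals) + 1) * self.bin_size, length)
                for i, v in enumerate(vals):
                    fh.write(f"{chrom}\t{edges[i]}\t{edges[i + 1]}\t{v:.6g}\n")


def bin_coverage(reads: ReadSet, karyotype: Karyotype, bin_size: int = 50) -> CoverageTrack:
    """Raw coverage: count of read midpoints per bin.

    Bins tile each chromosome of the karyotype; reads on chromosomes unknown
    to the karyotype raise an error naming the offenders.
    """
    if bin_size < 10:
        raise ValueError("bin_size must be >= 10 bp")
    unknown = sorted(set(reads.starts) - set(karyotype.lengths))
    if unknown:
        raise ValueError(f"reads on chromosomes not in karyotype: {unknown}")
    values: dict[str, np.ndarray] = {}
    for chrom in karyotype.chromosomes:
        length = karyotype.lengths[chrom]
        n_bins = -(-length // bin_size)
        mids = reads.midpoints(chrom)
        idx = np.clip(mids // bin_size, 0, n_bins - 1)
        values[chrom] = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return CoverageTrack(values=values, bin_size=bin_size, kind="raw")


def normalize_coverage(track: CoverageTrack, karyotype: Karyotype) -> CoverageTrack:
    """Median-normalize a raw coverage track, ploidy-aware.

    XX: every bin divided by the genome-wide median bin coverage (mito
    excluded from the median).  XO: autosomal bins divided by the autosomal
    median, X bins by half that median — the single X contributes half the
    reads of a diploid chromosome, so halving the divisor restores per-copy
    comparability.  The divisor is recorded in ``meta['median']``.
    """
    xo = karyotype.copy_number[karyotype.x_chrom] == 1
    x = karyotype.x_chrom
    if xo:
        pool = np.concatenate([track.values[c] for c in karyotype.autosomes])
    else:
        pool = np.concatenate([track.values[c] for c in karyotype.nuclear])
    med = float(np.median(pool))
    if med == 0:
        raise ValueError("genome-wide median coverage is zero; cannot normalize")
    out: dict[str, np.ndarray] = {}
    for chrom, vals in track.values.items():
        if xo and chrom == x:
            out[chrom] = vals / (med / 2.0)
        else:
            out[chrom] = vals / med
    return track.with_values(out, kind="normalized", median=med,
                             mode="XO" if xo else "XX")


def normalize_ploidy_aware(
    chip: CoverageTrack, inp: CoverageTrack, karyotype: Karyotype
) -> CoverageTrack:
    """Ploidy-aware normalized ChIP minus normalized input, per bin.

    XX: every bin divided by the genome-wide median bin coverage (mito
    excluded).  XO: autosomal bins divided by the autosomal median, X bins by
    half that median.  The same rule is applied to ChIP and input before the
    subtraction; the medians used are recorded in ``meta``.
    """
    if chip.bin_size != inp.bin_size:
        raise ValueError("ChIP and input tracks must share a bin size")
    if set(chip.values) != set(inp.values):
        raise ValueError("ChIP and input tracks must cover the same chromosomes")
    chip_n = normalize_coverage(chip, karyotype)
    inp_n = normalize_coverage(inp, karyotype)
    values = {c: chip_n.values[c] - inp_n.values[c] for c in chip.values}
    return chip.with_values(values, kind="enrichment",
                            chip_median=chip_n.meta["median"],
                            input_median=inp_n.meta["median"],
                            mode=chip_n.meta["mode"])


def zscore_standardize(
    track: CoverageTrack,
    background: str = "all_bins_robust",
    karyotype: Karyotype | None = None,
) -> CoverageTrack:
    """Standardize enrichment values against a presumed background.

    all_bins_robust: median / MAD over all (non-mito) bins — robust to the
    minority of enriched bins.  nonpositive_bins: background sd estimated
    from the mirrored distribution of bins <= 0 (mean fixed at 0).
    """
    if karyotype is not None:
        pool = np.concatenate([track.values[c] for c in karyotype.nuclear])
    else:
        pool = np.concatenate(list(track.values.values()))
    if background == "all_bins_robust":
        if pool.size < 100:
            raise ValueError("need >= 100 background bins")
        mu = float(np.median(pool))
        sigma = 1.4826 * float(np.median(np.abs(pool - mu)))
    elif background == "nonpositive_bins":
        neg = pool[pool <= 0]
        if neg.size < 100:
            raise ValueError("need >= 100 non-positive background bins")
        mu = 0.0
        sigma = float(np.sqrt(np.mean(neg**2)))
    else:
        raise ValueError(f"unknown background definition {background!r}")
    if sigma == 0:
        raise ValueError("background sd is zero; cannot standardize")
    log.info("zscore_standardize: background %s mu=%.4g sigma=%.4g", background, mu, sigma)
    values = {c: (v - mu) / sigma for c, v in track.values.items()}
    return track.with_values(values, kind="zscore", bg_mu=mu, bg_sigma=sigma,
                             background=background)


def call_broad_peaks(
    ztrack: CoverageTrack, z_min: float = 3.0, merge_gap: int = 500, min_len: int = 200
) -> pd.DataFrame:
    """Simplified broad-peak caller on a z-scored track.

    Maximal runs of bins with z >= z_min; runs separated by < merge_gap bp are
    merged; peaks shorter than min_len bp are dropped.  Returns a sorted,
    non-overlapping interval table with each peak's mean z.
    """
    if z_min <= 0:
        raise ValueError("z_min must be positive")
    rows = []
    bs = ztrack.bin_size
    for chrom, vals in ztrack.values.items():
        above = vals >= z_min
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]]).astype(np.int8)
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive, in bins
        starts = run_starts * bs
        ends = run_ends * bs
        merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] < merge_gap:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s < min_len:
                continue
            b0, b1 = s // bs, -(-e // bs)
            rows.append({"chrom": chrom, "start": s, "end": e,
                         "mean_z": float(vals[b0:b1].mean())})
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def read_fraction_ratio(reads: ReadSet, karyotype: Karyotype) -> pd.Series:
    """Per-chromosome (read fraction) / (copy-weighted genome fraction).

    Mitochondrial reads and length are excluded from both numerator and
    denominator.  Under uniform per-copy read placement the ratio is 1 for
    every chromosome.
    """
    chroms = karyotype.nuclear
    counts = np.array([reads.n_on(c) for c in chroms], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("read set is empty")
    fractions = counts / total
    genome = karyotype.copy_weighted_fractions()
    return pd.Series(
        {c: fractions[i] / genome[c] for i, c in enumerate(chroms)}, name="read_fraction_ratio"
    )


@dataclass
class PeakDensity:
    per_chrom: pd.Series  # peaks per Mb
    x_density: float
    autosome_density: float  # pooled: total autosomal peaks / total autosomal Mb


def peak_density(peaks: pd.DataFrame, karyotype: Karyotype) -> PeakDensity:
    """Peaks per Mb per chromosome, plus X and pooled-autosome densities."""
    counts = peaks.groupby("chrom").size() if len(peaks) else pd.Series(dtype=int)
    per_chrom = pd.Series(
        {
            c: counts.get(c, 0) / (karyotype.lengths[c] / 1e6)
            for c in karyotype.nuclear
        },
        name="peaks_per_mb",
    )
    auto = karyotype.autosomes
    auto_mb = sum(karyotype.lengths[c] for c in auto) / 1e6
    auto_peaks = sum(counts.get(c, 0) for c in auto)
    return PeakDensity(
        per_chrom=per_chrom,
        x_density=float(per_chrom[karyotype.x_chrom]),
        autosome_density=float(auto_peaks / auto_mb) if auto_mb else 0.0,
    )


@dataclass
class CategoryBreakdown:
    """Fractions of peak bp and of genome bp per genomic category,
    for the X and the pooled autosomes."""

    peak_fractions: pd.DataFrame  # index: X / autosomes, columns: categories
    genome_fractions: pd.DataFrame
    peak_bp: pd.DataFrame


def annotate_peaks(peaks: pd.DataFrame, annotation: GenomeAnnotation) -> CategoryBreakdown:
    """Assign peak bp to promoter/exon/intron/intergenic by partition overlap.

    Precedence promoter > exon > intron > intergenic is inherent in the
    partition raster.  Peaks extending beyond a chromosome end are clipped
    (logged).  Reports the genome's own category fractions alongside.
    """
    kt = annotation.karyotype
    groups = {"X": [kt.x_chrom], "autosomes": kt.autosomes}
    bp = {g: np.zeros(4, dtype=np.int64) for g in groups}
    chrom_to_group = {kt.x_chrom: "X", **{c: "autosomes" for c in kt.autosomes}}
    for row in peaks.itertuples(index=False):
        group = chrom_to_group.get(row.chrom)
        if group is None:
            continue
        length = kt.lengths[row.chrom]
        s, e = max(row.start, 0), min(row.end, length)
        if e != row.end or s != row.start:
            log.info("annotate_peaks: clipped peak %s:%d-%d to chromosome end", row.chrom, row.start, row.end)
        if e <= s:
            continue
        raster = annotation.partition_raster(row.chrom)
        bp[group] += np.bincount(raster[s:e], minlength=4)
    inv = {v: k for k, v in CATEGORY_CODES.items()}
    peak_bp = pd.DataFrame(
        {inv[i]: {g: bp[g][i] for g in groups} for i in range(4)}
    )[list(CATEGORIES)]
    totals = peak_bp.sum(axis=1)
    peak_fractions = peak_bp.div(totals.where(totals > 0, np.nan), axis=0)
    genome_fractions = pd.DataFrame(
        {
            "X": annotation.category_fractions([kt.x_chrom]),
            "autosomes": annotation.category_fractions(kt.autosomes),
        }
    ).T[list(CATEGORIES)]
    return CategoryBreakdown(
        peak_fractions=peak_fractions, genome_fractions=genome_fractions, peak_bp=peak_bp
    )


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED6 with score = mean z x 100 capped at 1000."""
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.itertuples(index=False)):
            score = int(min(max(row.mean_z * 100, 0), 1000))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tpeak_{i}\t{score}\t.\n")
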