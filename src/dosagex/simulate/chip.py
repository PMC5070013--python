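"""Synthetic ChIP-seq read generator with planted enrichment islands.

Reads are drawn per chromosome with expected count proportional to

    copy_number x length x per-copy acetylation density

modulated inside planted enrichment islands (density x island_fold).  Input
(whole-cell extract) reads follow copy_number x length only, which encodes
the copy-number law: doubling a chromosome's copies doubles its expected
input reads.  Islands are placed on a jittered grid, so the realized island
count equals round(density x Mb) exactly and islands never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..chip import ReadSet
from ..karyotype import Karyotype


@dataclass
class ChipSimParams:
    """Generator settings for ChIP + input read sets.

    per_copy_density: relative acetylation density per copy per chromosome
    (scalar, or dict by chromosome; units arbitrary, only ratios matter).
    island_density_per_mb: planted enrichment islands per Mb per chromosome
    (dict; chromosomes absent from the dict get none).
    """

    n_reads: int = 1_000_000
    n_input_reads: int = 1_000_000
    read_length: int = 50
    per_copy_density: float | dict[str, float] = 1.0
    island_density_per_mb: dict[str, float] = field(default_factory=dict)
    island_width_bp: tuple[int, int] = (600, 1400)
    island_fold: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads <= 0 or self.n_input_reads <= 0:
            raise ValueError("read counts must be positive")
        densities = (
            self.per_copy_density.values()
            if isinstance(self.per_copy_density, dict)
            else [self.per_copy_density]
        )
        if any(d < 0 for d in densities):
            raise ValueError("per-copy densities must be >= 0")
        if self.island_fold < 1:
            raise ValueError("island_fold must be >= 1")
        if self.island_width_bp[0] <= 0 or self.island_width_bp[1] < self.island_width_bp[0]:
            raise ValueError(f"bad island width range {self.island_width_bp}")


def _density(params: ChipSimParams, chrom: str) -> float:
    if isinstance(params.per_copy_density, dict):
        return params.per_copy_density.get(chrom, 0.0)
    return params.per_copy_density


def _plant_islands(params: ChipSimParams, karyotype: Karyotype, rng) -> pd.DataFrame:
    rows = []
    for chrom in karyotype.nuclear:
        per_mb = params.island_density_per_mb.get(chrom, 0.0)
        if per_mb <= 0:
            continue
        length = karyotype.lengths[chrom]
        n = int(round(per_mb * length / 1e6))
        if n == 0:
            continue
        slot = length / n
        if slot < params.island_width_bp[1] * 2:
            raise ValueError(f"island density {per_mb}/Mb too high for widths {params.island_width_bp}")
        centers = (np.arange(n) + 0.5) * slot + rng.uniform(-0.2, 0.2, size=n) * slot
        widths = rng.integers(params.island_width_bp[0], params.island_width_bp[1] + 1, size=n)
        starts = np.clip((centers - widths / 2).astype(np.int64), 0, length - 1)
        ends = np.clip(starts + widths, 1, length)
        for s, e in zip(starts, ends):
            rows.append({"chrom": chrom, "start": int(s), "end": int(e), "fold": params.island_fold})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fold"])


def _sample_positions(length: int, n: int, islands: pd.DataFrame, fold: float, rng) -> np.ndarray:
    """Sample n read midpoints on [0, length) with island-weighted density."""
    if islands.empty or fold == 1.0:
        return rng.integers(0, length, size=n)
    starts = islands["start"].to_numpy()
    ends = islands["end"].to_numpy()
    widths = ends - starts
    island_bp = int(widths.sum())
    bg_bp = length - island_bp
    p_island = fold * island_bp / (bg_bp + fold * island_bp)
    n_isl = rng.binomial(n, p_island)
    # island reads: pick island by width, then uniform within
    cum_w = np.cumsum(widths)
    pick = np.searchsorted(cum_w, rng.integers(0, cum_w[-1], size=n_isl), side="right")
    pos_isl = starts[pick] + (rng.random(n_isl) * widths[pick]).astype(np.int64)
    # background reads: uniform over the complement, via the gap cumsum
    gap_starts = np.concatenate([[0], ends])
    gap_ends = np.concatenate([starts, [length]])
    gap_w = gap_ends - gap_starts
    keep = gap_w > 0
    gap_starts, gap_w = gap_starts[keep], gap_w[keep]
    cum_g = np.cumsum(gap_w)
    u = rng.integers(0, cum_g[-1], size=n - n_isl)
    g = np.searchsorted(cum_g, u, side="right")
    offset = u - np.concatenate([[0], cum_g[:-1]])[g]
    pos_bg = gap_starts[g] + offset
    return np.concatenate([pos_isl, pos_bg])


def gen_chip_reads(
    params: ChipSimParams, karyotype: Karyotype, seed: int | None = None
) -> tuple[ReadSet, ReadSet, pd.DataFrame]:
    """Generate (chip_reads, input_reads, truth_islands).

    Expected per-chromosome ChIP read counts are proportional to
    copy x density x (length + (fold-1) x island bp); input counts to
    copy x length.  Mitochondrial chromosomes receive no reads.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    islands = _plant_islands(params, karyotype, rng)

    chroms = karyotype.nuclear
    weights = []
    for chrom in chroms:
        isl = islands[islands["chrom"] == chrom]
        island_bp = int((isl["end"] - isl["start"]).sum())
        length = karyotype.lengths[chrom]
        d = _density(params, chrom)
        mass = karyotype.copy_number[chrom] * d * (
            (length - island_bp) + params.island_fold * island_bp
        )
        weights.append(mass)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("total read density is zero; nothing to sample")
    counts = rng.multinomial(params.n_reads, weights / weights.sum())

    chip_starts: dict[str, np.ndarray] = {}
    half = params.read_length // 2
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        length = karyotype.lengths[chrom]
        mids = _sample_positions(length, int(n), islands[islands["chrom"] == chrom], params.island_fold, rng)
        starts = np.clip(mids - half, 0, max(length - params.read_length, 0))
        chip_starts[chrom] = np.sort(starts).astype(np.int64)

    in_weights = np.asarray(
        [karyotype.copy_number[c] * karyotype.lengths[c] for c in chroms], dtype=float
    )
    in_counts = rng.multinomial(params.n_input_reads, in_weights / in_weights.sum())
    input_starts: dict[str, np.ndarray] = {}
    for chrom, n in zip(chroms, in_counts):
        if n == 0:
            continue
        length = karyotype.lengths[chrom]
        mids = rng.integers(0, length, size=int(n))
        starts = np.clip(mids - half, 0, max(length - params.read_length, 0))
        input_starts[chrom] = np.sort(starts).astype(np.int64)

    return (
        ReadSet(starts=chip_starts, read_length=params.read_length),
        ReadSet(starts=input_starts, read_length=params.read_length),
        islands,
    )


def solve_x_density_for_ratio(karyotype: Karyotype, target_ratio: float) -> float:
    """Per-copy X density factor (autosomes = 1) giving an expected
    read-fraction / copy-weighted-genome-fraction ratio of ``target_ratio``."""
    if target_ratio <= 0:
        raise ValueError("target ratio must be positive")
    x = karyotype.x_chrom
    wx = karyotype.copy_number[x] * karyotype.lengths[x]
    wa = sum(karyotype.copy_number[c] * karyotype.lengths[c] for c in karyotype.autosomes)
    g = wx / (wx + wa)  # copy-weighted X genome fraction
    p = target_ratio * g  # required X read fraction
    if p >= 1:
        raise ValueError("target ratio unreachable")
    return (p / (1 - p)) * (wa / wx)
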