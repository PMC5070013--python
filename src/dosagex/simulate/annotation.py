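"""Synthetic gene-annotation generator.

Places non-overlapping gene models (promoter + exon/intron body) along each
chromosome so that the promoter/exon/intron/intergenic partition tiles the
chromosome exactly.  Gene density and, optionally, the intergenic bp fraction
are configurable per chromosome — the latter matters because the real X
chromosome carries proportionally more intergenic sequence than the autosomes.
"""

from __future__ import annotations

import numpy as np

import pandas as pd

from ..annotation import GenomeAnnotation
from ..karyotype import Karyotype

_MIN_EXON = 50
_MIN_INTRON = 50


def _largest_remainder(total: int, weights: np.ndarray, minimum: int) -> np.ndarray:
    """Integer allocation of `total` over parts proportional to `weights`,
    each part >= minimum.  Exact: the parts sum to `total`."""
    n = len(weights)
    if total < n * minimum:
        raise ValueError(f"cannot allocate {total} bp over {n} parts with minimum {minimum}")
    spare = total - n * minimum
    raw = spare * weights / weights.sum()
    base = np.floor(raw).astype(np.int64)
    short = int(spare - base.sum())
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base + minimum


def _per_chrom(value, chrom, default=None):
    if isinstance(value, dict):
        return value.get(chrom, default)
    return value


def gen_genome_annotation(
    karyotype: Karyotype,
    genes_per_mb: float | dict[str, float] = 180.0,
    seed: int = 0,
    intergenic_fraction: float | dict[str, float] | None = None,
    promoter_bp: int = 1000,
    mean_exons: float = 4.0,
    body_range: tuple[int, int] = (800, 2500),
    min_body: int = 300,
) -> GenomeAnnotation:
    """Generate a deterministic synthetic :class:`GenomeAnnotation`.

    Parameters
    ----------
    genes_per_mb
        Gene density (scalar, or per-chromosome dict).
    intergenic_fraction
        If given (scalar or per-chromosome dict), gene-body lengths are scaled
        so that the intergenic category occupies this fraction of the
        chromosome, up to integer rounding.  Otherwise bodies are drawn
        uniformly from ``body_range``.

    Raises
    ------
    ValueError
        If a chromosome is too short to host a single gene with its promoter
        and flanking margins.
    """
    rng = np.random.default_rng(seed)
    gene_rows = []
    exon_rows = []
    # every inter-gene gap must fit two promoters (divergent neighbours)
    min_gap = 2 * promoter_bp + 100

    for chrom in karyotype.chromosomes:
        if chrom in karyotype.mito:
            continue
        length = karyotype.lengths[chrom]
        density = _per_chrom(genes_per_mb, chrom)
        n = int(round(density * length / 1e6))
        if n < 1 or length < min_body + 2 * min_gap:
            raise ValueError(
                f"chromosome {chrom!r} ({length} bp) too short to host one gene "
                f"at {density} genes/Mb"
            )
        target_f = _per_chrom(intergenic_fraction, chrom)
        if target_f is not None:
            if not 0.0 < target_f < 1.0:
                raise ValueError(f"intergenic_fraction must be in (0,1), got {target_f}")
            body_total = int(round((1.0 - target_f) * length)) - n * promoter_bp
            if body_total < n * min_body:
                raise ValueError(
                    f"chromosome {chrom!r}: intergenic fraction {target_f} leaves "
                    f"too little genic space for {n} genes"
                )
            bodies = _largest_remainder(body_total, rng.dirichlet(np.ones(n)) + 1e-9, min_body)
        else:
            bodies = rng.integers(body_range[0], body_range[1] + 1, size=n)
        gap_total = length - int(bodies.sum())
        if gap_total < (n + 1) * min_gap:
            raise ValueError(
                f"chromosome {chrom!r} too short for {n} genes with their promoters"
            )
        gaps = _largest_remainder(gap_total, rng.dirichlet(np.ones(n + 1)) + 1e-9, min_gap)
        strands = np.where(rng.integers(0, 2, size=n) == 1, "+", "-")

        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = start + int(bodies[i])
            pos = end
            gid = f"{chrom}_g{i:05d}"
            body = end - start
            max_exons = max(1, body // (2 * max(_MIN_EXON, _MIN_INTRON)))
            k = int(min(1 + rng.poisson(max(mean_exons - 1.0, 0.0)), max_exons))
            nseg = 2 * k - 1  # exon, intron, exon, ... exon
            segs = _largest_remainder(
                body, rng.dirichlet(np.ones(nseg)) + 1e-9, min(_MIN_EXON, _MIN_INTRON)
            )
            s = start
            exonic = 0
            for j, seg in enumerate(segs):
                if j % 2 == 0:  # exon
                    exon_rows.append((gid, chrom, s, s + int(seg)))
                    exonic += int(seg)
                s += int(seg)
            gene_rows.append((gid, chrom, start, end, strands[i], exonic))

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "exonic_length"]
    )
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    return GenomeAnnotation(
        genes=genes, exons=exons, karyotype=karyotype, promoter_bp=promoter_bp
    )
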