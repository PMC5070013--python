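"""Gene annotation container and the promoter/exon/intron/intergenic partition.

The genomic-category partition assigns every base pair of a chromosome to
exactly one of four categories with precedence

    promoter > exon > intron > intergenic

where the promoter is a fixed window (default 1 kb) upstream of the TSS on the
gene's strand.  The partition is materialized lazily as a per-chromosome uint8
raster, which makes bp-overlap bookkeeping (peak annotation, genome category
fractions) a ``numpy.bincount``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .karyotype import Karyotype

CATEGORY_CODES = {"intergenic": 0, "promoter": 1, "exon": 2, "intron": 3}
CATEGORIES = ("promoter", "exon", "intron", "intergenic")


@dataclass
class GenomeAnnotation:
    """Gene models plus the karyotype they live on.

    ``genes`` columns: gene_id, chrom, start, end (0-based half-open), strand
    ('+'/'-'), exonic_length.  ``exons`` columns: gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    karyotype: Karyotype
    promoter_bp: int = 1000
    _rasters: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"genes table missing columns: {sorted(missing)}")
        if "exonic_length" not in self.genes.columns:
            lens = (self.exons["end"] - self.exons["start"]).groupby(self.exons["gene_id"]).sum()
            self.genes = self.genes.assign(
                exonic_length=self.genes["gene_id"].map(lens).fillna(0).astype(int)
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def tss(self) -> pd.Series:
        """Transcription start coordinate per gene (strand-aware).

        '+' genes start at ``start``; '-' genes start at ``end`` (the promoter
        window is [end, end + promoter_bp) in genomic coordinates).
        """
        plus = self.genes["strand"] == "+"
        return self.genes["start"].where(plus, self.genes["end"]).rename("tss")

    def tts(self) -> pd.Series:
        plus = self.genes["strand"] == "+"
        return self.genes["end"].where(plus, self.genes["start"]).rename("tts")

    # -- partition ---------------------------------------------------------

    def partition_raster(self, chrom: str) -> np.ndarray:
        """uint8 per-bp category raster for one chromosome (see CATEGORY_CODES)."""
        if chrom in self._rasters:
            return self._rasters[chrom]
        length = self.karyotype.lengths[chrom]
        arr = np.zeros(length, dtype=np.uint8)
        genes = self.genes[self.genes["chrom"] == chrom]
        # precedence is enforced by paint order: intron < exon < promoter
        for s, e in zip(genes["start"].to_numpy(), genes["end"].to_numpy()):
            arr[max(s, 0): min(e, length)] = CATEGORY_CODES["intron"]
        exons = self.exons[self.exons["chrom"] == chrom]
        for s, e in zip(exons["start"].to_numpy(), exons["end"].to_numpy()):
            arr[max(s, 0): min(e, length)] = CATEGORY_CODES["exon"]
        for s, e, strand in zip(
            genes["start"].to_numpy(), genes["end"].to_numpy(), genes["strand"].to_numpy()
        ):
            if strand == "+":
                p0, p1 = s - self.promoter_bp, s
            else:
                p0, p1 = e, e + self.promoter_bp
            arr[max(p0, 0): min(p1, length)] = CATEGORY_CODES["promoter"]
        self._rasters[chrom] = arr
        return arr

    def category_bp(self, chroms: list[str] | None = None) -> pd.Series:
        """Total bp per category over the given chromosomes (default: all nuclear)."""
        if chroms is None:
            chroms = self.karyotype.nuclear
        counts = np.zeros(4, dtype=np.int64)
        for c in chroms:
            counts += np.bincount(self.partition_raster(c), minlength=4)
        inv = {v: k for k, v in CATEGORY_CODES.items()}
        ser = pd.Series({inv[i]: counts[i] for i in range(4)})
        return ser.reindex(list(CATEGORIES))

    def category_fractions(self, chroms: list[str] | None = None) -> pd.Series:
        bp = self.category_bp(chroms)
        return bp / bp.sum()

    # -- IO ----------------------------------------------------------------

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.genes.itertuples(index=False):
                attrs = f'gene_id "{row.gene_id}";'
                fh.write(
                    f"{row.chrom}\tdosagex\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )
            for row in self.exons.itertuples(index=False):
                attrs = f'gene_id "{row.gene_id}";'
                strand = "."
                fh.write(
                    f"{row.chrom}\tdosagex\texon\t{row.start + 1}\t{row.end}\t.\t"
                    f"{strand}\t.\t{attrs}\n"
                )

    @classmethod
    def read_gtf(cls, path, karyotype: Karyotype, promoter_bp: int = 1000) -> "GenomeAnnotation":
        import pyranges as pr

        df = pr.read_gtf(str(path)).df
        genes = df[df["Feature"] == "gene"]
        genes = pd.DataFrame(
            {
                "gene_id": genes["gene_id"].to_numpy(),
                "chrom": genes["Chromosome"].astype(str).to_numpy(),
                "start": genes["Start"].to_numpy(),
                "end": genes["End"].to_numpy(),
                "strand": genes["Strand"].astype(str).to_numpy(),
            }
        )
        ex = df[df["Feature"] == "exon"]
        exons = pd.DataFrame(
            {
                "gene_id": ex["gene_id"].to_numpy(),
                "chrom": ex["Chromosome"].astype(str).to_numpy(),
                "start": ex["Start"].to_numpy(),
                "end": ex["End"].to_numpy(),
            }
        )
        return cls(genes=genes, exons=exons, karyotype=karyotype, promoter_bp=promoter_bp)
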