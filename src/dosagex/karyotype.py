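"""Chromosome-level genome description.

A :class:`Karyotype` carries chromosome lengths, somatic copy numbers, and the
X / mitochondrial flags that every downstream normalization depends on.  The
two configurations of interest for nematode dosage compensation are XX
(hermaphrodite: two X, two of each autosome) and XO (male or masculinized
hermaphrodite: one X, two of each autosome).

Copy-weighted genome fractions (length x copy number over the copy-weighted
total, mitochondrial DNA excluded) are the denominators used for read-fraction
ratios: with one X against diploid autosomes, the X holds ~10% of the DNA of an
XO nucleus even though it is ~18% of the reference assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# WS235-like chromosome sizes in bp.  Supplied as data, not hard-coded into the
# analyses, because genome fractions depend on the assembly.
ELEGANS_LENGTHS: dict[str, int] = {
    "I": 15_072_434,
    "II": 15_279_421,
    "III": 13_783_801,
    "IV": 17_493_829,
    "V": 20_924_180,
    "X": 17_718_942,
}
ELEGANS_MITO = ("MtDNA", 13_794)


@dataclass(frozen=True)
class Karyotype:
    """Chromosome names, lengths (bp), copy numbers and flags.

    Parameters
    ----------
    lengths
        Mapping chromosome name -> length in bp (all > 0).
    copy_number
        Mapping chromosome name -> somatic copy number (1 or 2).
    x_chrom
        Name of the X chromosome (must be present in ``lengths``).
    mito
        Names of mitochondrial "chromosomes"; excluded from all genome-fraction
        and normalization computations.
    """

    lengths: dict[str, int]
    copy_number: dict[str, int]
    x_chrom: str = "X"
    mito: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("karyotype needs at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if set(self.copy_number) != set(self.lengths):
            raise ValueError("copy_number must cover exactly the chromosomes in lengths")
        for name, cn in self.copy_number.items():
            if cn not in (1, 2):
                raise ValueError(f"copy number of {name!r} must be 1 or 2, got {cn}")
        if self.x_chrom not in self.lengths:
            raise ValueError(f"X chromosome {self.x_chrom!r} not in karyotype")
        if self.x_chrom in self.mito:
            raise ValueError("the X chromosome cannot be flagged mitochondrial")
        object.__setattr__(self, "mito", frozenset(self.mito))
        unknown_mito = self.mito - set(self.lengths)
        if unknown_mito:
            raise ValueError(f"mitochondrial chromosomes not in karyotype: {sorted(unknown_mito)}")

    # -- accessors ---------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def nuclear(self) -> list[str]:
        """All chromosomes except mitochondrial ones."""
        return [c for c in self.lengths if c not in self.mito]

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.nuclear if c != self.x_chrom]

    @property
    def sex(self) -> str:
        return "XO" if self.copy_number[self.x_chrom] == 1 else "XX"

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    # -- derived fractions -------------------------------------------------

    def copy_weighted_fractions(self) -> dict[str, float]:
        """Per-chromosome (copies x length) / total, mito excluded."""
        weights = {c: self.copy_number[c] * self.lengths[c] for c in self.nuclear}
        total = sum(weights.values())
        return {c: w / total for c, w in weights.items()}

    def length_fractions(self) -> dict[str, float]:
        total = sum(self.lengths[c] for c in self.nuclear)
        return {c: self.lengths[c] / total for c in self.nuclear}

    def with_copy_number(self, chrom: str, copies: int) -> "Karyotype":
        cn = dict(self.copy_number)
        cn[chrom] = copies
        return replace(self, copy_number=cn)

    # -- constructors ------------------------------------------------------

    @classmethod
    def elegans(cls, sex: str = "XX", include_mito: bool = False) -> "Karyotype":
        """WS235-like C. elegans karyotype for the given sex ('XX' or 'XO')."""
        if sex not in ("XX", "XO"):
            raise ValueError(f"sex must be 'XX' or 'XO', got {sex!r}")
        lengths = dict(ELEGANS_LENGTHS)
        mito: frozenset[str] = frozenset()
        if include_mito:
            lengths[ELEGANS_MITO[0]] = ELEGANS_MITO[1]
            mito = frozenset({ELEGANS_MITO[0]})
        copy_number = {c: 2 for c in lengths}
        if sex == "XO":
            copy_number["X"] = 1
        if include_mito:
            # treat mito as single-copy for bookkeeping; it never enters fractions
            copy_number[ELEGANS_MITO[0]] = 1
        return cls(lengths=lengths, copy_number=copy_number, x_chrom="X", mito=mito)


# Alias used in configuration-facing code.
KaryotypeConfig = Karyotype
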