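"""ChIP pipeline: binning, ploidy-aware normalization, z-scores, peak calling,
read-fraction ratios, densities and genomic-category annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dosagex.chip import (
    CoverageTrack,
    ReadSet,
    annotate_peaks,
    bin_coverage,
    call_broad_peaks,
    normalize_coverage,
    normalize_ploidy_aware,
    peak_density,
    read_fraction_ratio,
    zscore_standardize,
)
from dosagex.karyotype import Karyotype


def _track(values_by_chrom, bin_size=50, kind="zscore"):
    return CoverageTrack(
        values={c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()},
        bin_size=bin_size,
        kind=kind,
    )


# -- binning ---------------------------------------------------------------


def test_bin_coverage_midpoint_assignment_and_conservation(rng):
    kt = Karyotype(lengths={"I": 1000, "X": 1000}, copy_number={"I": 2, "X": 2})
    reads = ReadSet(starts={"I": np.array([0])}, read_length=10)  # midpoint at 5
    track = bin_coverage(reads, kt, bin_size=50)
    assert track.values["I"][0] == 1
    starts = np.sort(rng.integers(0, 990, size=250))
    track = bin_coverage(ReadSet(starts={"I": starts}, read_length=10), kt, bin_size=100)
    assert track.total() == 250  # conservation


def test_bin_coverage_unknown_chromosome_errors():
    kt = Karyotype(lengths={"I": 1000, "X": 1000}, copy_number={"I": 2, "X": 2})
    reads = ReadSet(starts={"I": np.array([1]), "chrUn": np.array([5])})
    with pytest.raises(ValueError, match="chrUn"):
        bin_coverage(reads, kt)


# -- normalization ---------------------------------------------------------


def test_xx_normalized_median_is_one(rng):
    kt = Karyotype(lengths={"I": 100_000, "X": 100_000}, copy_number={"I": 2, "X": 2})
    track = _track({"I": rng.poisson(20, 2000), "X": rng.poisson(20, 2000)}, kind="raw")
    norm = normalize_coverage(track, kt)
    pooled = np.concatenate([norm.values["I"], norm.values["X"]])
    assert np.median(pooled) == pytest.approx(1.0, abs=1e-9)


def test_xo_x_bins_divided_by_half_autosomal_median():
    kt = Karyotype(lengths={"I": 5000, "X": 5000}, copy_number={"I": 2, "X": 1})
    track = _track({"I": np.full(100, 100.0), "X": np.full(100, 50.0)}, kind="raw")
    norm = normalize_coverage(track, kt)
    assert np.allclose(norm.values["X"], 1.0)  # 50 / (100 / 2)
    assert np.allclose(norm.values["I"], 1.0)


def test_self_subtraction_gives_zero_enrichment():
    kt = Karyotype(lengths={"I": 5000, "X": 5000}, copy_number={"I": 2, "X": 2})
    track = _track({"I": np.full(100, 7.0), "X": np.full(100, 3.0)}, kind="raw")
    enrich = normalize_ploidy_aware(track, track, kt)
    assert np.allclose(enrich.values["I"], 0.0)
    assert np.allclose(enrich.values["X"], 0.0)


def test_xo_parity_simulation_equalizes_x_and_autosome_means():
    from dosagex.simulate import ChipSimParams, gen_chip_reads

    kt = Karyotype(lengths={"I": 2_000_000, "X": 2_000_000},
                   copy_number={"I": 2, "X": 1})
    reads, inp, _ = gen_chip_reads(
        ChipSimParams(n_reads=2_000_000, n_input_reads=2_000_000, seed=4), kt
    )
    chip_n = normalize_coverage(bin_coverage(reads, kt, 200), kt)
    assert chip_n.values["X"].mean() == pytest.approx(chip_n.values["I"].mean(), rel=0.02)


def test_zero_median_raises():
    kt = Karyotype(lengths={"X": 5000}, copy_number={"X": 2}, x_chrom="X")
    track = _track({"X": np.zeros(100)}, kind="raw")
    with pytest.raises(ValueError, match="median"):
        normalize_coverage(track, kt)


# -- z-score ---------------------------------------------------------------


def test_zscore_standardizes_gaussian_background(rng):
    track = _track({"I": rng.normal(0, 1, 5000)}, kind="enrichment")
    z = zscore_standardize(track)
    assert np.mean(z.values["I"]) == pytest.approx(0.0, abs=0.05)
    assert np.std(z.values["I"]) == pytest.approx(1.0, abs=0.05)


def test_zscore_robust_is_shift_invariant(rng):
    vals = rng.normal(0, 1, 3000)
    z1 = zscore_standardize(_track({"I": vals}), background="all_bins_robust")
    z2 = zscore_standardize(_track({"I": vals + 42.0}), background="all_bins_robust")
    assert np.allclose(z1.values["I"], z2.values["I"], atol=1e-9)


def test_zscore_nonpositive_background_definition(rng):
    vals = np.concatenate([rng.normal(0, 2, 4000), np.full(200, 30.0)])
    z = zscore_standardize(_track({"I": vals}), background="nonpositive_bins")
    assert z.meta["bg_mu"] == 0.0
    assert z.meta["bg_sigma"] == pytest.approx(2.0, rel=0.1)


def test_zscore_islands_raise_mean_z(rng):
    background = rng.normal(0, 1, 4000)
    island = background.copy()
    island[1000:1100] += 8.0
    z = zscore_standardize(_track({"I": island}))
    assert z.values["I"][1000:1100].mean() > z.values["I"][:1000].mean() + 3


# -- peak calling ----------------------------------------------------------


def test_peak_caller_hand_trace_merge_and_minlen():
    vals = np.zeros(40)
    vals[5:15] = 5.0   # 10-bin run
    vals[16:21] = 5.0  # 5-bin run, 1 bin gap
    track = _track({"I": vals}, bin_size=50)
    peaks = call_broad_peaks(track, z_min=2.5, merge_gap=100, min_len=200)
    assert len(peaks) == 1
    assert peaks.iloc[0]["start"] == 250
    assert peaks.iloc[0]["end"] == 1050
    none = call_broad_peaks(_track({"I": np.zeros(40)}), z_min=2.5)
    assert none.empty


def _runlength_oracle(vals, bin_size, z_min, merge_gap, min_len):
    """Plain scan over bins: runs, then merge, then length filter."""
    runs = []
    in_run = False
    for i, v in enumerate(vals):
        if v >= z_min and not in_run:
            runs.append([i, i + 1])
            in_run = True
        elif v >= z_min:
            runs[-1][1] = i + 1
        else:
            in_run = False
    intervals = [[s * bin_size, e * bin_size] for s, e in runs]
    merged = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_len]


@given(st.integers(0, 10_000))
def test_peak_caller_matches_runlength_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 1000))
    vals = rng.normal(0, 1.5, n)
    z_min = float(rng.uniform(0.5, 3.0))
    merge_gap = int(rng.integers(0, 500))
    min_len = int(rng.integers(0, 400))
    track = _track({"I": vals}, bin_size=50)
    got = call_broad_peaks(track, z_min=z_min, merge_gap=merge_gap, min_len=min_len)
    expected = _runlength_oracle(vals, 50, z_min, merge_gap, min_len)
    assert [(r.start, r.end) for r in got.itertuples()] == expected


@given(st.integers(0, 10_000))
def test_raising_zmin_keeps_peaks_nested(seed):
    """Peaks at a stricter threshold always lie inside laxer-threshold peaks
    (a single peak may split, so the raw count is not monotone)."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 2, 400)
    track = _track({"I": vals}, bin_size=50)
    lax = call_broad_peaks(track, z_min=0.8, merge_gap=100, min_len=0)
    strict = call_broad_peaks(track, z_min=2.2, merge_gap=100, min_len=0)
    covered_bp = sum(r.end - r.start for r in lax.itertuples())
    strict_bp = sum(r.end - r.start for r in strict.itertuples())
    assert strict_bp <= covered_bp
    for r in strict.itertuples():
        assert any(p.start <= r.start and r.end <= p.end for p in lax.itertuples())


# -- ratios and density ----------------------------------------------------


def test_read_fraction_ratio_uniform_per_copy_is_one():
    kt = Karyotype.elegans(sex="XO")
    weights = {c: kt.copy_number[c] * kt.lengths[c] for c in kt.nuclear}
    total = sum(weights.values())
    n = 100_000
    starts = {c: np.zeros(int(round(n * w / total)), dtype=int) for c, w in weights.items()}
    ratios = read_fraction_ratio(ReadSet(starts=starts), kt)
    assert np.allclose(ratios, 1.0, atol=0.001)


def test_read_fraction_ratio_empty_errors():
    kt = Karyotype.elegans()
    with pytest.raises(ValueError, match="empty"):
        read_fraction_ratio(ReadSet(starts={}), kt)


def test_peak_density_trivial_and_empty():
    kt = Karyotype(lengths={"I": 17_000_000, "X": 1_000_000},
                   copy_number={"I": 2, "X": 2})
    peaks = pd.DataFrame(
        {"chrom": ["I"] * 17, "start": range(0, 17_000_000, 1_000_000),
         "end": range(100, 17_000_100, 1_000_000), "mean_z": 3.0}
    )
    dens = peak_density(peaks, kt)
    assert dens.per_chrom["I"] == pytest.approx(1.0)
    assert dens.autosome_density == pytest.approx(1.0)
    assert dens.x_density == 0.0
    empty = peak_density(pd.DataFrame(columns=["chrom", "start", "end", "mean_z"]), kt)
    assert (empty.per_chrom == 0).all()


# -- annotation of peaks ---------------------------------------------------


@pytest.fixture(scope="module")
def toy_annotation():
    from dosagex.annotation import GenomeAnnotation

    kt = Karyotype(lengths={"X": 10_000, "I": 10_000}, copy_number={"X": 2, "I": 2})
    genes = pd.DataFrame(
        {
            "gene_id": ["gx", "gi"],
            "chrom": ["X", "I"],
            "start": [2000, 3000],
            "end": [4000, 5000],
            "strand": ["+", "+"],
        }
    )
    exons = pd.DataFrame(
        {"gene_id": ["gx", "gx", "gi"], "chrom": ["X", "X", "I"],
         "start": [2000, 3500, 3000], "end": [2500, 4000, 5000]}
    )
    return GenomeAnnotation(genes=genes, exons=exons, karyotype=kt, promoter_bp=1000)


def test_peak_inside_exon_is_pure_exon(toy_annotation):
    peaks = pd.DataFrame([{"chrom": "X", "start": 2100, "end": 2300, "mean_z": 3.0}])
    cb = annotate_peaks(peaks, toy_annotation)
    assert cb.peak_fractions.loc["X", "exon"] == 1.0


def test_peak_split_between_promoter_and_exon(toy_annotation):
    peaks = pd.DataFrame([{"chrom": "X", "start": 1900, "end": 2100, "mean_z": 3.0}])
    cb = annotate_peaks(peaks, toy_annotation)
    assert cb.peak_fractions.loc["X", "promoter"] == pytest.approx(0.5)
    assert cb.peak_fractions.loc["X", "exon"] == pytest.approx(0.5)


def test_category_fractions_sum_to_one(toy_annotation):
    peaks = pd.DataFrame(
        [{"chrom": "X", "start": 0, "end": 8000, "mean_z": 2.0},
         {"chrom": "I", "start": 1000, "end": 9000, "mean_z": 2.0}]
    )
    cb = annotate_peaks(peaks, toy_annotation)
    assert cb.peak_fractions.sum(axis=1).round(9).eq(1.0).all()
    assert cb.genome_fractions.sum(axis=1).round(9).eq(1.0).all()
    # genome partition accounts for every bp
    assert toy_annotation.category_bp(["X"]).sum() == 10_000


def test_intergenic_rich_x_shows_in_uniform_peaks():
    from dosagex.simulate import gen_genome_annotation

    kt = Karyotype(lengths={"I": 1_000_000, "X": 1_000_000},
                   copy_number={"I": 2, "X": 2})
    ann = gen_genome_annotation(kt, genes_per_mb=60, seed=2,
                                intergenic_fraction={"I": 0.35, "X": 0.6})
    rng = np.random.default_rng(0)
    starts = np.sort(rng.integers(0, 999_000, size=400))
    peaks = pd.concat([
        pd.DataFrame({"chrom": c, "start": starts, "end": starts + 500, "mean_z": 2.0})
        for c in ("I", "X")
    ])
    cb = annotate_peaks(peaks, ann)
    assert cb.peak_fractions.loc["X", "intergenic"] > cb.peak_fractions.loc["autosomes", "intergenic"]
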