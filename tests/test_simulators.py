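"""Construction fidelity and determinism of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from dosagex.karyotype import Karyotype
from dosagex.simulate import (
    ChipSimParams,
    ConditionEffect,
    ExprSimParams,
    NucleusSimParams,
    ProbeSimParams,
    gen_chip_reads,
    gen_expression_counts,
    gen_genome_annotation,
    gen_nucleus_stack,
    gen_probe_stack,
)

# -- genome annotation -----------------------------------------------------


class TestGenomeAnnotation:
    def test_gene_count_and_partition_tiles_chromosome(self):
        kt = Karyotype(lengths={"X": 1_000_000}, copy_number={"X": 2})
        ann = gen_genome_annotation(kt, genes_per_mb=10, seed=7)
        assert len(ann.genes) == 10
        bp = ann.category_bp(["X"])
        assert bp.sum() == 1_000_000  # partition covers every bp exactly once
        assert (bp > 0).all()

    def test_gene_models_do_not_overlap_and_promoters_fit(self):
        kt = Karyotype(lengths={"X": 1_000_000}, copy_number={"X": 2})
        ann = gen_genome_annotation(kt, genes_per_mb=40, seed=7)
        g = ann.genes.sort_values("start")
        # footprint = gene body plus its strand-aware promoter window
        starts = np.where(g["strand"] == "+", g["start"] - ann.promoter_bp, g["start"])
        ends = np.where(g["strand"] == "+", g["end"], g["end"] + ann.promoter_bp)
        assert (starts >= 0).all() and (ends <= 1_000_000).all()
        assert (starts[1:] >= ends[:-1]).all()
        # exons tile each gene body
        widths = (ann.exons["end"] - ann.exons["start"]).groupby(ann.exons["gene_id"]).sum()
        spans = (g["end"] - g["start"]).to_numpy()
        exonic = g["exonic_length"].to_numpy()
        assert (exonic <= spans).all() and (exonic > 0).all()
        assert (widths.reindex(g["gene_id"]).to_numpy() == exonic).all()

    def test_determinism_byte_identical(self, small_karyotype):
        a = gen_genome_annotation(small_karyotype, genes_per_mb=25, seed=5)
        b = gen_genome_annotation(small_karyotype, genes_per_mb=25, seed=5)
        assert a.genes.to_csv() == b.genes.to_csv()
        assert a.exons.to_csv() == b.exons.to_csv()

    def test_configured_x_intergenic_excess_is_realized(self):
        kt = Karyotype(
            lengths={"I": 2_000_000, "X": 2_000_000}, copy_number={"I": 2, "X": 2}
        )
        ann = gen_genome_annotation(
            kt, genes_per_mb=50, seed=1, intergenic_fraction={"I": 0.35, "X": 0.50}
        )
        fx = ann.category_fractions(["X"])["intergenic"]
        fa = ann.category_fractions(["I"])["intergenic"]
        assert fx == pytest.approx(0.50, abs=0.01)
        assert fa == pytest.approx(0.35, abs=0.01)
        assert fx > fa

    def test_chromosome_too_short_raises(self):
        kt = Karyotype(lengths={"X": 3_000}, copy_number={"X": 2})
        with pytest.raises(ValueError, match="too short"):
            gen_genome_annotation(kt, genes_per_mb=300, seed=0)

    def test_gtf_roundtrip(self, small_karyotype, small_annotation, tmp_path):
        from dosagex.annotation import GenomeAnnotation

        path = tmp_path / "ann.gtf"
        small_annotation.write_gtf(path)
        back = GenomeAnnotation.read_gtf(path, small_karyotype)
        orig = small_annotation.genes.sort_values("gene_id").reset_index(drop=True)
        got = back.genes.sort_values("gene_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            got[["gene_id", "chrom", "start", "end", "strand"]],
            orig[["gene_id", "chrom", "start", "end", "strand"]],
        )


# -- nuclei ----------------------------------------------------------------


class TestNucleusGenerator:
    def test_realized_occupancy_within_discretization(self):
        params = NucleusSimParams(occupancy=0.10, n_nuclei=20, seed=1)
        _, truth = gen_nucleus_stack(params)
        assert truth["realized_pct"].between(9.5, 10.5).all()

    def test_determinism_byte_identical(self):
        params = NucleusSimParams(occupancy=0.12, n_nuclei=3, seed=9)
        stacks_a, truth_a = gen_nucleus_stack(params)
        stacks_b, truth_b = gen_nucleus_stack(params)
        for sa, sb in zip(stacks_a, stacks_b):
            assert sa.data.tobytes() == sb.data.tobytes()
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_unrealizable_occupancy_raises(self):
        params = NucleusSimParams(occupancy=1e-4, n_nuclei=1, radii_vox=(4, 4, 4), seed=0)
        with pytest.raises(ValueError, match="unrealizable"):
            gen_nucleus_stack(params)

    def test_territory_is_connected(self):
        from scipy import ndimage

        params = NucleusSimParams(occupancy=0.15, n_nuclei=3, noise_sd=0.0, seed=2)
        stacks, _ = gen_nucleus_stack(params)
        for stack in stacks:
            paint = stack.channel("paint")
            mask = paint > paint.min() + 1
            _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
            assert n == 1


# -- probes ----------------------------------------------------------------


class TestProbeGenerator:
    def test_truth_separations_exact_and_spot_counts(self):
        params = ProbeSimParams(separation_um=1.06, n_nuclei=4, pairs_per_probe=2, seed=1)
        _, truth = gen_probe_stack(params)
        for (_, _), grp in truth.groupby(["nucleus_id", "pair"]):
            a = grp[grp["channel"] == "probeA"][["z_um", "y_um", "x_um"]].to_numpy()
            b = grp[grp["channel"] == "probeB"][["z_um", "y_um", "x_um"]].to_numpy()
            assert np.linalg.norm(a - b) == pytest.approx(1.06, abs=1e-9)
        counts = truth.groupby(["nucleus_id", "channel"]).size()
        assert (counts == 2).all()

    def test_zero_separation_detected_below_localization_error(self):
        from dosagex.imaging import detect_spots, pair_spot_distances

        params = ProbeSimParams(separation_um=0.0, n_nuclei=3, pairs_per_probe=1,
                                noise_sd=2.0, seed=4)
        stacks, _ = gen_probe_stack(params)
        for stack in stacks:
            a = detect_spots(stack, "probeA", ("fraction_of_max", 0.3))
            b = detect_spots(stack, "probeB", ("fraction_of_max", 0.3))
            d = pair_spot_distances(a, b)["distance_um"]
            assert (d < 0.05).all()

    def test_anisotropic_voxels_preserve_physical_distances(self):
        from dosagex.imaging import detect_spots, pair_spot_distances

        params = ProbeSimParams(
            separation_um=0.9, n_nuclei=6, pairs_per_probe=1, noise_sd=0.0,
            voxel_size=(0.2, 0.1, 0.1), shape_vox=(40, 96, 96), seed=6,
        )
        stacks, truth = gen_probe_stack(params)
        dists = []
        for stack in stacks:
            a = detect_spots(stack, "probeA", ("fraction_of_max", 0.3))
            b = detect_spots(stack, "probeB", ("fraction_of_max", 0.3))
            dists.extend(pair_spot_distances(a, b)["distance_um"])
        assert np.median(dists) == pytest.approx(0.9, abs=0.03)

    def test_determinism(self):
        params = ProbeSimParams(separation_um=0.5, n_nuclei=2, seed=3)
        (sa, *_), ta = gen_probe_stack(params)
        (sb, *_), tb = gen_probe_stack(params)
        assert sa.data.tobytes() == sb.data.tobytes()
        pd.testing.assert_frame_equal(ta, tb)


# -- ChIP reads ------------------------------------------------------------


class TestChipGenerator:
    def test_uniform_density_gives_unit_ratio_any_karyotype(self):
        from dosagex.chip import read_fraction_ratio

        for sex in ("XX", "XO"):
            kt = Karyotype.elegans(sex=sex)
            reads, _, _ = gen_chip_reads(ChipSimParams(n_reads=400_000, seed=2), kt)
            ratios = read_fraction_ratio(reads, kt)
            assert np.allclose(ratios, 1.0, atol=0.02)

    def test_copy_number_law_for_input_reads(self):
        """Halving X copy number halves its expected input read share."""
        xx = Karyotype.elegans(sex="XX")
        xo = Karyotype.elegans(sex="XO")
        params = ChipSimParams(n_reads=10_000, n_input_reads=500_000, seed=5)
        _, inp_xx, _ = gen_chip_reads(params, xx)
        _, inp_xo, _ = gen_chip_reads(params, xo)
        def x_share(rs, kt):
            return rs.n_on("X") / rs.n_reads
        expected_xx = 2 * xx.lengths["X"] / sum(2 * l for l in xx.lengths.values())
        wsum = sum(xo.copy_number[c] * xo.lengths[c] for c in xo.nuclear)
        expected_xo = xo.lengths["X"] / wsum
        assert x_share(inp_xx, xx) == pytest.approx(expected_xx, rel=0.03)
        assert x_share(inp_xo, xo) == pytest.approx(expected_xo, rel=0.03)
        assert expected_xo < 0.6 * expected_xx

    def test_islands_planted_at_requested_density(self):
        kt = Karyotype(lengths={"X": 2_000_000, "I": 1_000_000},
                       copy_number={"X": 2, "I": 2})
        params = ChipSimParams(
            n_reads=10_000, island_density_per_mb={"X": 52.0}, seed=3
        )
        _, _, islands = gen_chip_reads(params, kt)
        on_x = islands[islands["chrom"] == "X"]
        assert len(on_x) == 104
        assert (on_x["end"] - on_x["start"]).between(*params.island_width_bp).all()
        # non-overlapping
        s = on_x.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_zero_total_density_raises(self):
        kt = Karyotype(lengths={"X": 1_000_000}, copy_number={"X": 2})
        with pytest.raises(ValueError, match="density"):
            gen_chip_reads(ChipSimParams(n_reads=100, per_copy_density=0.0), kt)

    def test_determinism(self, small_karyotype):
        params = ChipSimParams(n_reads=50_000, seed=8)
        a = gen_chip_reads(params, small_karyotype)
        b = gen_chip_reads(params, small_karyotype)
        for chrom in a[0].starts:
            assert np.array_equal(a[0].starts[chrom], b[0].starts[chrom])
            assert np.array_equal(a[1].starts[chrom], b[1].starts[chrom])


# -- expression counts -----------------------------------------------------


class TestExpressionGenerator:
    def test_null_truth_medians_are_parity(self, small_annotation):
        params = ExprSimParams(xa_ratio=1.0, seed=1)
        _, truth = gen_expression_counts(params, small_annotation)
        x_med = truth.loc[truth["is_x"], "base_mean"].median()
        a_med = truth.loc[~truth["is_x"], "base_mean"].median()
        assert x_med / a_med == pytest.approx(1.0, abs=0.02)

    def test_planted_xa_ratio_in_truth(self, small_annotation):
        params = ExprSimParams(xa_ratio=0.88, seed=1)
        _, truth = gen_expression_counts(params, small_annotation)
        x_med = truth.loc[truth["is_x"], "base_mean"].median()
        a_med = truth.loc[~truth["is_x"], "base_mean"].median()
        assert x_med / a_med == pytest.approx(0.88, abs=0.02)

    def test_planted_effect_medians_preserved_after_balancing(self):
        # realistic X share of transcriptome mass (~15%), unlike the tiny fixture
        kt = Karyotype(lengths={"I": 8_000_000, "X": 1_500_000},
                       copy_number={"I": 2, "X": 2})
        annotation = gen_genome_annotation(kt, genes_per_mb=60.0, seed=11)
        params = ExprSimParams(
            conditions={"up": ConditionEffect(x_median=0.447, x_sd=0.25,
                                              a_median=-0.08, a_sd=0.25)},
            seed=2,
        )
        counts, truth = gen_expression_counts(params, annotation)
        raw_params = ExprSimParams(
            conditions={"up": ConditionEffect(x_median=0.447, x_sd=0.25,
                                              a_median=-0.08, a_sd=0.25,
                                              balance_mass=False)},
            seed=2,
        )
        _, raw_truth = gen_expression_counts(raw_params, annotation)
        eff = truth["log2_effect_up"]
        raw = raw_truth["log2_effect_up"]
        is_x = truth["is_x"]
        # X effects never modified; autosomal sample median preserved exactly
        assert np.array_equal(eff[is_x], raw[is_x])
        assert eff[~is_x].median() == raw[~is_x].median()
        assert eff[~is_x].median() == pytest.approx(-0.08, abs=0.05)
        # mass balance: expected transcriptome output matches control
        mass = (truth["base_mean"] * np.exp2(eff)).sum()
        assert mass == pytest.approx(truth["base_mean"].sum(), rel=1e-9)
        # without balancing the mass is visibly off
        raw_mass = (raw_truth["base_mean"] * np.exp2(raw)).sum()
        assert abs(raw_mass / raw_truth["base_mean"].sum() - 1.0) > 0.005
        assert set(counts) == {"control", "up"}

    def test_nb_dispersion_controls_replicate_noise(self, small_annotation):
        tight = ExprSimParams(dispersion=0.0, n_replicates=20, lib_jitter=0.0, seed=3)
        loose = ExprSimParams(dispersion=0.3, n_replicates=20, lib_jitter=0.0, seed=3)
        ct, tt = gen_expression_counts(tight, small_annotation)
        cl, _ = gen_expression_counts(loose, small_annotation)
        mu = tt["base_mean"].to_numpy()
        big = mu > 500
        cv_t = (ct["control"].std(axis=1) / ct["control"].mean(axis=1))[big].median()
        cv_l = (cl["control"].std(axis=1) / cl["control"].mean(axis=1))[big].median()
        assert cv_l > 3 * cv_t  # alpha=0.3 => cv ~ 0.55 vs Poisson ~ 0.03

    def test_determinism(self, small_annotation):
        params = ExprSimParams(seed=4)
        a, ta = gen_expression_counts(params, small_annotation)
        b, tb = gen_expression_counts(params, small_annotation)
        pd.testing.assert_frame_equal(a["control"], b["control"])
        pd.testing.assert_frame_equal(ta, tb)
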