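"""End-to-end scenarios: simulate -> analyze -> report.

A :class:`ScenarioConfig` is schema-validated (unknown keys rejected) before
any computation; :func:`run_scenario` executes the configured generator +
analysis chain deterministically under the config seed and returns a
:class:`RunReport` whose summary values/tables can also be written to disk.

The packaged scenarios plant the effect sizes of the study this pipeline
models (territory occupancies, probe separations, X acetylation depletion,
X:A expression skews), so each headline quantity is one ``run_scenario``
call away.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import chip as chip_mod
from . import expression as expr_mod
from . import imaging
from .karyotype import Karyotype
from .simulate import (
    ChipSimParams,
    ConditionEffect,
    ExprSimParams,
    NucleusSimParams,
    ProbeSimParams,
    QuadrantScheme,
    gen_chip_reads,
    gen_expression_counts,
    gen_genome_annotation,
    gen_nucleus_stack,
    gen_probe_stack,
    solve_x_density_for_ratio,
)
from .stats import chisq_proportions

log = logging.getLogger(__name__)


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FishVolumeParams(_Params):
    occupancy_pct: float = Field(gt=0, lt=100)
    n_nuclei: int = Field(ge=1)
    occupancy_sd_pct: float = Field(default=0.0, ge=0)
    snr: float = Field(default=8.0, gt=1)
    noise_sd: float = Field(default=25.0, ge=0)
    radii_vox: tuple[float, float, float] = (14.0, 22.0, 22.0)
    voxel_size: tuple[float, float, float] = (0.25, 0.13, 0.13)


class FishDistanceParams(_Params):
    separation_um: float = Field(ge=0)
    n_nuclei: int = Field(ge=1)
    pairs_per_probe: int = Field(default=2, ge=1)
    spot_sigma_um: float = Field(default=0.12, gt=0)
    noise_sd: float = Field(default=8.0, ge=0)


class ChipRatioParams(_Params):
    n_reads: int = Field(default=1_000_000, gt=0)
    target_x_ratio: Optional[float] = Field(default=None, gt=0)  # None = per-copy parity


class ChipPeaksParams(_Params):
    x_mb: float = Field(default=15.0, ge=15.0)
    autosome_mb: float = Field(default=10.0, gt=0)
    x_islands_per_mb: float = Field(default=52.0, gt=0)
    autosome_islands_per_mb: float = Field(default=95.0, gt=0)
    island_fold: float = Field(default=8.0, gt=1)
    reads_per_bp: float = Field(default=0.3, gt=0)
    bin_size: int = Field(default=50, ge=10)
    z_min: float = Field(default=3.0, gt=0)
    merge_gap: int = Field(default=500, ge=0)
    min_len: int = Field(default=200, ge=0)


class ConditionModel(_Params):
    x_median: float = 0.0
    x_sd: float = 0.0
    a_median: float = 0.0
    a_sd: float = 0.0
    direction: Literal["greater", "less"] = "greater"
    balance_mass: bool = True


class QuadrantModel(_Params):
    condition_a: str
    condition_b: str
    x_fractions: dict[str, float]
    a_fractions: dict[str, float]
    magnitude_lo: float = 0.25
    magnitude_hi: float = 0.8


class ExpressionParams(_Params):
    xa_ratio: float = Field(default=1.0, gt=0)
    median_count: float = Field(default=1000.0, gt=0)
    log2_sd: float = Field(default=1.5, gt=0)
    dispersion: float = Field(default=0.01, ge=0)
    n_replicates: int = Field(default=3, ge=1)
    genes_per_mb: float = Field(default=180.0, gt=0)
    min_rpkm: float = Field(default=1.0, ge=0)
    pseudocount: float = Field(default=1.0, ge=0)
    conditions: dict[str, ConditionModel] = Field(default_factory=dict)
    quadrants: Optional[QuadrantModel] = None


class SurvivalParams(_Params):
    rate_control: float = Field(gt=0, lt=1)
    n_control: int = Field(gt=0)
    rate_treated: float = Field(gt=0, lt=1)
    n_treated: int = Field(gt=0)


_PARAM_MODELS = {
    "fish_volume": FishVolumeParams,
    "fish_distance": FishDistanceParams,
    "chip_ratio": ChipRatioParams,
    "chip_peaks": ChipPeaksParams,
    "expression": ExpressionParams,
    "survival": SurvivalParams,
}


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    kind: Literal[
        "fish_volume", "fish_distance", "chip_ratio", "chip_peaks", "expression", "survival"
    ]
    sex: Literal["XX", "XO"] = "XX"
    seed: int = 1
    params: Any

    @model_validator(mode="after")
    def _parse_params(self):
        model = _PARAM_MODELS[self.kind]
        if isinstance(self.params, dict):
            object.__setattr__(self, "params", model(**self.params))
        elif not isinstance(self.params, model):
            raise ValueError(f"params of kind {self.kind} must be {model.__name__}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class RunReport:
    """Stage-by-stage scenario output: headline values, tables, provenance."""

    scenario: str
    kind: str
    seed: int
    values: dict[str, float]
    tables: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.values, sort_keys=True, default=float).encode())
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=True).encode())
        return h.hexdigest()

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=True)
        payload = {
            "scenario": self.scenario,
            "kind": self.kind,
            "seed": self.seed,
            "values": self.values,
            "provenance": self.provenance,
            "checksum": self.checksum(),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, default=float))


# ---------------------------------------------------------------------------
# scenario runners


def _run_fish_volume(cfg: ScenarioConfig) -> RunReport:
    p: FishVolumeParams = cfg.params
    sim = NucleusSimParams(
        occupancy=p.occupancy_pct / 100.0,
        occupancy_sd=p.occupancy_sd_pct / 100.0,
        n_nuclei=p.n_nuclei,
        snr=p.snr,
        noise_sd=p.noise_sd,
        radii_vox=p.radii_vox,
        voxel_size=p.voxel_size,
        seed=cfg.seed,
    )
    stacks, truth = gen_nucleus_stack(sim)
    rows = []
    for i, stack in enumerate(stacks):
        dapi = imaging.threshold_mask(stack, "dna", "otsu")
        terr = imaging.threshold_mask(stack, "paint", "otsu", within=dapi)
        rows.append(
            {"nucleus_id": i, "group": cfg.name, "percent": imaging.percent_volume(terr, dapi)}
        )
    measurements = pd.DataFrame(rows)
    summary = imaging.summarize_volumes(measurements, group_by="group")
    values = {
        "mean_percent": float(summary["mean"].iloc[0]),
        "sd_percent": float(summary["sd"].iloc[0]),
        "n_nuclei": int(summary["n"].iloc[0]),
    }
    return RunReport(cfg.name, cfg.kind, cfg.seed, values,
                     {"measurements": measurements, "volume_summary": summary, "truth": truth})


def _run_fish_distance(cfg: ScenarioConfig) -> RunReport:
    p: FishDistanceParams = cfg.params
    sim = ProbeSimParams(
        separation_um=p.separation_um,
        n_nuclei=p.n_nuclei,
        pairs_per_probe=p.pairs_per_probe,
        spot_sigma_um=p.spot_sigma_um,
        noise_sd=p.noise_sd,
        seed=cfg.seed,
    )
    stacks, truth = gen_probe_stack(sim)
    all_pairs = []
    for i, stack in enumerate(stacks):
        spots_a = imaging.detect_spots(stack, "probeA", ("fraction_of_max", 0.25))
        spots_b = imaging.detect_spots(stack, "probeB", ("fraction_of_max", 0.25))
        if len(spots_a) == 0 or len(spots_b) == 0:
            log.warning("no spots detected in nucleus %d", i)
            continue
        all_pairs.append(imaging.pair_spot_distances(spots_a, spots_b, nucleus_id=i))
    distances = pd.concat(all_pairs, ignore_index=True)
    values = {
        "median_distance_um": float(distances["distance_um"].median()),
        "n_nuclei": int(p.n_nuclei),
        "n_pairs": int(len(distances)),
    }
    return RunReport(cfg.name, cfg.kind, cfg.seed, values,
                     {"distances": distances, "truth": truth})


def _run_chip_ratio(cfg: ScenarioConfig) -> RunReport:
    p: ChipRatioParams = cfg.params
    kt = Karyotype.elegans(sex=cfg.sex)
    density: float | dict[str, float]
    if p.target_x_ratio is None:
        density = 1.0
    else:
        f = solve_x_density_for_ratio(kt, p.target_x_ratio)
        density = {c: (f if c == kt.x_chrom else 1.0) for c in kt.nuclear}
    sim = ChipSimParams(
        n_reads=p.n_reads, n_input_reads=p.n_reads, per_copy_density=density, seed=cfg.seed
    )
    reads, _inp, _islands = gen_chip_reads(sim, kt)
    ratios = chip_mod.read_fraction_ratio(reads, kt)
    values = {"x_ratio": float(ratios[kt.x_chrom]), "n_reads": int(reads.n_reads)}
    return RunReport(cfg.name, cfg.kind, cfg.seed, values,
                     {"read_fraction_ratios": ratios.rename_axis("chrom").to_frame()})


def _run_chip_peaks(cfg: ScenarioConfig) -> RunReport:
    p: ChipPeaksParams = cfg.params
    x_len = int(p.x_mb * 1e6)
    a_len = int(p.autosome_mb * 1e6)
    kt = Karyotype(
        lengths={"X": x_len, "I": a_len},
        copy_number={"X": 2 if cfg.sex == "XX" else 1, "I": 2},
    )
    n_reads = int(p.reads_per_bp * (x_len + a_len))
    sim = ChipSimParams(
        n_reads=n_reads,
        n_input_reads=n_reads,
        island_density_per_mb={"X": p.x_islands_per_mb, "I": p.autosome_islands_per_mb},
        island_fold=p.island_fold,
        seed=cfg.seed,
    )
    reads, inp, islands = gen_chip_reads(sim, kt)
    raw_chip = chip_mod.bin_coverage(reads, kt, bin_size=p.bin_size)
    raw_inp = chip_mod.bin_coverage(inp, kt, bin_size=p.bin_size)
    enrich = chip_mod.normalize_ploidy_aware(raw_chip, raw_inp, kt)
    ztrack = chip_mod.zscore_standardize(enrich, karyotype=kt)
    peaks = chip_mod.call_broad_peaks(ztrack, z_min=p.z_min, merge_gap=p.merge_gap, min_len=p.min_len)
    dens = chip_mod.peak_density(peaks, kt)
    values = {
        "x_peaks_per_mb": dens.x_density,
        "autosome_peaks_per_mb": dens.autosome_density,
        "n_peaks": int(len(peaks)),
        "planted_x_islands_per_mb": float(
            (islands["chrom"] == "X").sum() / (x_len / 1e6)
        ),
    }
    return RunReport(cfg.name, cfg.kind, cfg.seed, values,
                     {"peaks": peaks, "peak_density": dens.per_chrom.to_frame(), "islands": islands})


def _run_expression(cfg: ScenarioConfig) -> RunReport:
    p: ExpressionParams = cfg.params
    kt = Karyotype.elegans(sex=cfg.sex)
    annotation = gen_genome_annotation(kt, genes_per_mb=p.genes_per_mb, seed=cfg.seed)
    conditions = {
        name: ConditionEffect(
            x_median=c.x_median, x_sd=c.x_sd, a_median=c.a_median, a_sd=c.a_sd,
            direction=c.direction, balance_mass=c.balance_mass,
        )
        for name, c in p.conditions.items()
    }
    quad = None
    if p.quadrants is not None:
        q = p.quadrants
        quad = QuadrantScheme(
            condition_a=q.condition_a, condition_b=q.condition_b,
            x_fractions=q.x_fractions, a_fractions=q.a_fractions,
            magnitude_lo=q.magnitude_lo, magnitude_hi=q.magnitude_hi,
        )
    sim = ExprSimParams(
        median_count=p.median_count, log2_sd=p.log2_sd, dispersion=p.dispersion,
        xa_ratio=p.xa_ratio, conditions=conditions, quadrants=quad,
        n_replicates=p.n_replicates, seed=cfg.seed,
    )
    counts, truth = gen_expression_counts(sim, annotation)
    lengths = annotation.genes.set_index("gene_id")["exonic_length"]
    chroms = annotation.genes.set_index("gene_id")["chrom"]

    tables: dict[str, pd.DataFrame] = {"truth": truth}
    rpkm = {
        name: expr_mod.compute_rpkm(df, lengths, chroms=chroms) for name, df in counts.items()
    }
    xa = expr_mod.median_xa_ratio(rpkm["control"], kt, min_rpkm=p.min_rpkm)
    values: dict[str, float] = {
        "xa_ratio": xa.ratio,
        "n_x_expressed": xa.n_x,
        "n_autosomal_expressed": xa.n_autosomal,
    }
    tables["xa_per_chrom_median"] = xa.per_chrom_median.to_frame()

    directions = {name: c.direction for name, c in p.conditions.items()}
    contrasts: dict[str, pd.DataFrame] = {}
    condition_names = [n for n in counts if n != "control"]
    for name in condition_names:
        expressed = (rpkm[name]["mean_rpkm"] > p.min_rpkm) & (
            rpkm["control"]["mean_rpkm"] > p.min_rpkm
        )
        universe = rpkm[name].index[expressed]
        contrast = expr_mod.contrast_log2(
            counts[name].loc[universe], counts["control"].loc[universe],
            chroms, pseudocount=p.pseudocount,
        )
        contrasts[name] = contrast
        tables[f"contrast_{name}"] = contrast
        x_vals = contrast.loc[contrast["chrom"] == kt.x_chrom, "log2_ratio"]
        a_vals = contrast.loc[contrast["chrom"].isin(kt.autosomes), "log2_ratio"]
        values[f"{name}_x_median"] = float(x_vals.median())
        values[f"{name}_autosome_median"] = float(a_vals.median())
        direction = directions.get(name)
        if direction is None:
            direction = "greater" if x_vals.median() >= a_vals.median() else "less"
        shift = expr_mod.chromosome_shift_test(contrast, kt, direction=direction)
        tables[f"shift_{name}"] = shift
        values[f"{name}_shift_p"] = float(shift["pvalue"].iloc[0])

    if quad is not None:
        qt = expr_mod.quadrant_classify(
            contrasts[quad.condition_a], contrasts[quad.condition_b], kt, thresh=0.1
        )
        tables["quadrants_percent"] = qt.percent
        values["x_concordant_pct"] = float(qt.percent.loc["X", "up_down"])
        tops = expr_mod.top_percent_sets(contrasts[quad.condition_a], contrasts[quad.condition_b])
        tables["top_percent_summary"] = tops.summary
    return RunReport(cfg.name, cfg.kind, cfg.seed, values, tables)


def _run_survival(cfg: ScenarioConfig) -> RunReport:
    p: SurvivalParams = cfg.params
    rng = np.random.default_rng(cfg.seed)
    surv_c = int(rng.binomial(p.n_control, p.rate_control))
    surv_t = int(rng.binomial(p.n_treated, p.rate_treated))
    table = np.array(
        [[surv_c, p.n_control - surv_c], [surv_t, p.n_treated - surv_t]]
    )
    res = chisq_proportions(table)
    values = {
        "chi_square": res.statistic,
        "p_value": res.pvalue,
        "control_survival_pct": 100.0 * surv_c / p.n_control,
        "treated_survival_pct": 100.0 * surv_t / p.n_treated,
    }
    counts = pd.DataFrame(table, index=["control", "treated"], columns=["survived", "died"])
    return RunReport(cfg.name, cfg.kind, cfg.seed, values, {"survival_counts": counts})


_RUNNERS = {
    "fish_volume": _run_fish_volume,
    "fish_distance": _run_fish_distance,
    "chip_ratio": _run_chip_ratio,
    "chip_peaks": _run_chip_peaks,
    "expression": _run_expression,
    "survival": _run_survival,
}


def run_scenario(config: ScenarioConfig, out_dir=None) -> RunReport:
    """Validate, execute and (optionally) persist one scenario."""
    t0 = time.time()
    report = _RUNNERS[config.kind](config)
    report.provenance = {
        "params": config.params.model_dump(),
        "sex": config.sex,
        "elapsed_s": round(time.time() - t0, 3),
    }
    if out_dir is not None:
        report.write(out_dir)
    log.info("scenario %s done in %.1fs", config.name, time.time() - t0)
    return report


# ---------------------------------------------------------------------------
# packaged scenarios: the study's printed effect sizes as configs

_PACKAGED: dict[str, dict] = {
    # territory percent nuclear volume (paint FISH)
    "wt-male-fish": dict(kind="fish_volume", sex="XO",
                         params=dict(occupancy_pct=15.74, n_nuclei=27)),
    "mys1-male-fish": dict(kind="fish_volume", sex="XO",
                           params=dict(occupancy_pct=9.87, n_nuclei=20)),
    "control-herm-fish": dict(kind="fish_volume", sex="XX",
                              params=dict(occupancy_pct=9.41, n_nuclei=40)),
    "mys1-herm-fish": dict(kind="fish_volume", sex="XX",
                           params=dict(occupancy_pct=17.11, n_nuclei=36)),
    # 1.2 Mb probe-pair 3D distances (tetraploid nuclei: 2 pairs per probe)
    "control-male-distance": dict(kind="fish_distance", sex="XO",
                                  params=dict(separation_um=1.06, n_nuclei=20)),
    "mys1-male-distance": dict(kind="fish_distance", sex="XO",
                               params=dict(separation_um=0.67, n_nuclei=16)),
    # H4K16ac read-fraction ratios
    "xx-chip": dict(kind="chip_ratio", sex="XX",
                    params=dict(n_reads=1_000_000, target_x_ratio=0.33)),
    "xo-chip": dict(kind="chip_ratio", sex="XO",
                    params=dict(n_reads=1_000_000, target_x_ratio=None)),
    # planted enrichment islands through the full peak-calling chain
    "xx-chip-peaks": dict(kind="chip_peaks", sex="XX", params=dict()),
    # expression skews
    "xx-wt-expr": dict(kind="expression", sex="XX",
                       params=dict(xa_ratio=0.88, median_count=2000.0, dispersion=0.005)),
    "dpy21-expr": dict(
        kind="expression", sex="XX",
        params=dict(conditions={"dpy21": dict(x_median=0.447, x_sd=0.25,
                                              a_median=-0.080, a_sd=0.25,
                                              direction="greater")})),
    "mys1-expr": dict(
        kind="expression", sex="XO",
        params=dict(conditions={"mys1": dict(x_median=-0.021, x_sd=0.05,
                                             a_median=-0.008, a_sd=0.05,
                                             direction="less")})),
    "quadrant-expr": dict(
        kind="expression", sex="XX",
        params=dict(
            median_count=2000.0, dispersion=0.002,
            quadrants=dict(
                condition_a="dpy21", condition_b="mys1",
                x_fractions={"up_down": 0.24, "up_up": 0.08,
                             "down_up": 0.08, "down_down": 0.08},
                a_fractions={"up_down": 0.02, "up_up": 0.02,
                             "down_up": 0.02, "down_down": 0.02},
            ),
        )),
    # him-8 brood survival chi-square
    "him8-survival": dict(
        kind="survival", sex="XX",
        params=dict(rate_control=0.98, n_control=2090, rate_treated=0.54, n_treated=1071)),
}


def packaged_scenario(name: str, seed: int = 1) -> ScenarioConfig:
    """One of the packaged study scenarios, with the given seed."""
    if name not in _PACKAGED:
        raise KeyError(f"unknown scenario {name!r}; see list_scenarios()")
    spec = _PACKAGED[name]
    return ScenarioConfig(name=name, seed=seed, **spec)


def list_scenarios() -> list[str]:
    return sorted(_PACKAGED)
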