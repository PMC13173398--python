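"""End-to-end runner: simulate -> design -> normalize -> fit -> optimize -> score.

A single :class:`PipelineConfig` (loadable from YAML) drives every stage; one
root seed fans out to fixed per-stage seeds so a re-run with an identical
config reproduces identical artifacts. Each stage's outputs are written to
the output directory and remain consumable standalone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .design import (
    DEFAULT_B_MM,
    Composition,
    FactorBounds,
    build_ccd,
    concat_designs,
    confirmation_design,
    randomize_runs,
)
from .errors import ConfigError
from .normalize import (
    ExpressionMatrix,
    average_replicates,
    depth_normalize_transform,
    filter_genes,
    reference_normalize,
    select_reference_gene,
)
from .optimize import ObjectiveSpec, optimize_composition, select_control
from .simulate import SimulationConfig, simulate_counts, simulate_ground_truth
from .surface import fit_all_genes, run_weights, validate_confirmation

# fixed per-stage seed offsets fanned out from the root seed
_OFFSETS = {
    "design": 11,
    "confirmation": 23,
    "truth": 37,
    "counts": 53,
    "optimizer": 71,
    "control": 89,
}


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    seed: int = 0
    bounds: dict = field(
        default_factory=lambda: {"C": (0.75, 1.5), "F": (0.15, 0.375), "L": (0.15, 0.375)}
    )
    b_mm: float = DEFAULT_B_MM
    n_center: int = 9
    n_confirmation: int = 5
    n_genes: int = 500
    n_reps: int = 3
    n_donors: int = 3
    depth_range: tuple[float, float] = (0.7, 1.4)
    noise: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # normalization
    filter_min_count: int = 10
    filter_min_samples: int = 6
    filter_mode: str = "per_sample"
    reference_gene: str | None = None  # data-driven minimum-CV pick when None
    # fitting
    coded: bool = True
    hierarchy: str = "marginality"
    # optimizer
    pop_size: int | None = None
    n_gen: int = 200
    asf_convention: str = "multiply"
    min_r2_filter: float | None = None
    reliability_floor: float = 0.05
    # control selection
    control_front_gap: float = 0.12
    control_cheb_range: tuple[float, float] = (0.2, 0.6)
    out_dir: str | None = None

    def factor_bounds(self) -> list[FactorBounds]:
        return [FactorBounds(name, lo, hi) for name, (lo, hi) in self.bounds.items()]

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) * 101 + _OFFSETS[stage]) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **{k: v for k, v in raw.items()})
        if isinstance(cfg.bounds, dict):
            cfg.bounds = {k: tuple(v) for k, v in cfg.bounds.items()}
        cfg.depth_range = tuple(cfg.depth_range)
        cfg.control_cheb_range = tuple(cfg.control_cheb_range)
        return cfg

    def validate(self):
        if self.n_confirmation < 0 or self.n_center < 0:
            raise ConfigError("n_confirmation and n_center must be >= 0")
        if self.n_donors < 1 or self.n_reps < 1:
            raise ConfigError("n_donors and n_reps must be >= 1")


def _composition_dict(comp: Composition) -> dict:
    return {"C_mM": comp.c, "F_mM": comp.f, "L_mM": comp.l, "B_mM": comp.b}


def recovery_distance(found: Composition, truth: Composition, bounds) -> float:
    """Max over factors of |found - planted| as a fraction of the factor range."""
    gaps = [
        abs(a - b) / (fb.high - fb.low)
        for a, b, fb in zip(found.as_array(), truth.as_array(), bounds)
    ]
    return float(max(gaps))


@dataclass
class RunReport:
    """Headline outputs and per-stage provenance of one pipeline run."""

    config: dict
    reference_gene: str
    reference_cv: float
    n_genes_kept: int
    adjusted_r2_summary: dict
    donors: dict  # donor -> {asf_composition, control_composition, validation, recovery}
    planted_optimum: dict | None
    stage_seeds: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow on a synthetic experiment.

    Stages, in order: build and randomize the CCD, draw confirmation
    compositions, simulate ground truth and counts, filter/normalize/average
    expression, fit per-gene response surfaces per donor, optimize the
    planted EMT program with NSGA-II + ASF, select a control composition,
    validate on confirmation runs and score recovery of the planted optimum.
    Writes intermediate artifacts when ``config.out_dir`` is set.
    """
    config.validate()
    bounds = config.factor_bounds()
    design = randomize_runs(
        build_ccd(bounds, config.n_center, b_mm=config.b_mm),
        seed=config.stage_seed("design"),
    )
    conf = confirmation_design(
        bounds, config.n_confirmation, seed=config.stage_seed("confirmation"),
        b_mm=config.b_mm,
    )
    full_design = concat_designs(design, conf)

    truth = simulate_ground_truth(
        config.n_genes, bounds, config.sim, seed=config.stage_seed("truth")
    )

    if config.noise:
        experiment = simulate_counts(
            truth, full_design, n_reps=config.n_reps, n_donors=config.n_donors,
            depth_range=config.depth_range, seed=config.stage_seed("counts"),
            noise=True,
        )
        raw = ExpressionMatrix(experiment.counts, "raw")
        kept = filter_genes(
            raw, config.filter_min_count, config.filter_min_samples, config.filter_mode
        )
        vst = depth_normalize_transform(raw).subset_genes(kept)
        samples = experiment.samples.set_index("sample")
    else:
        # noiseless limit: expression taken directly from the exact surfaces
        eta = truth.expected_log2_expression(full_design)
        cols, rows = {}, []
        for donor in [f"donor{d+1}" for d in range(config.n_donors)]:
            for rid in full_design.runs["run_id"]:
                for rep in range(1, config.n_reps + 1):
                    name = f"{donor}_{rid}_r{rep}"
                    cols[name] = eta[rid]
                    rows.append((name, rid, donor, rep, 1.0))
        vst = ExpressionMatrix(pd.DataFrame(cols, index=truth.genes), "depth_transformed")
        kept = truth.genes
        samples = pd.DataFrame(
            rows, columns=["sample", "run_id", "donor", "replicate", "depth_factor"]
        ).set_index("sample")

    if config.reference_gene is not None:
        ref_gene = config.reference_gene
        mean = vst.data.loc[ref_gene].mean()
        ref_cv = float(vst.data.loc[ref_gene].std(ddof=1) / mean) if mean > 0 else float("nan")
    else:
        ref_gene, ref_cv = select_reference_gene(vst)
    normed = reference_normalize(vst, ref_gene)

    emt_up = [g for g in truth.program_genes("emt_up") if g in normed.data.index]
    emt_down = [g for g in truth.program_genes("emt_down") if g in normed.data.index]
    fit_run_ids = list(design.runs["run_id"])
    conf_run_ids = list(conf.runs["run_id"])
    weights = run_weights(design)

    donors_out: dict[str, dict] = {}
    r2_all: list[float] = []
    for donor in sorted(samples["donor"].unique()):
        donor_samples = samples.index[samples["donor"] == donor]
        donor_expr = ExpressionMatrix(normed.data[list(donor_samples)], normed.stage)
        groups = samples.loc[donor_samples, "run_id"]
        averaged = average_replicates(donor_expr, groups)
        fit_expr = ExpressionMatrix(averaged.data[fit_run_ids], "condition_averaged")
        models = fit_all_genes(
            fit_expr, design, weights=weights, coded=config.coded,
            hierarchy=config.hierarchy,
        )
        ok_r2 = [m.adjusted_r2 for m in models.values() if m.status == "ok"]
        r2_all.extend(ok_r2)

        conf_expr = averaged.data[conf_run_ids]
        _, summary = validate_confirmation(models, conf_expr, conf, coded=config.coded)

        obj_genes = emt_up + emt_down
        if config.min_r2_filter is not None:
            obj_genes = [
                g for g in obj_genes if models[g].adjusted_r2 >= config.min_r2_filter
            ]
        directions = ["up" if g in emt_up else "down" for g in obj_genes]
        rel = np.array(
            [np.clip(models[g].adjusted_r2, config.reliability_floor, 1.0) for g in obj_genes]
        )
        spec = ObjectiveSpec(
            genes=obj_genes, directions=directions, weights=rel,
            models=[models[g] for g in obj_genes], bounds=bounds,
        )
        result = optimize_composition(
            spec, pop_size=config.pop_size, n_gen=config.n_gen,
            seed=config.stage_seed("optimizer"), asf_convention=config.asf_convention,
        )
        try:
            control, control_info = select_control(
                result, spec, front_gap_max=config.control_front_gap,
                cheb_range=config.control_cheb_range,
                seed=config.stage_seed("control"),
                asf_convention=config.asf_convention,
            )
            control_dict = _composition_dict(control)
        except Exception as exc:  # empty selection stays reported, not fatal
            control_dict, control_info = None, {"error": str(exc)}

        donors_out[donor] = {
            "asf_composition": _composition_dict(result.asf_solution),
            "control_composition": control_dict,
            "control_info": control_info,
            "validation": summary,
            "n_front": int(result.X.shape[0]),
            "recovery_fraction_of_range": recovery_distance(
                result.asf_solution, truth.planted_optimum, bounds
            ),
        }

    r2_arr = np.array(r2_all)
    report = RunReport(
        config=_config_dict(config),
        reference_gene=ref_gene,
        reference_cv=ref_cv,
        n_genes_kept=len(kept),
        adjusted_r2_summary={
            "median": float(np.median(r2_arr)),
            "q25": float(np.quantile(r2_arr, 0.25)),
            "q75": float(np.quantile(r2_arr, 0.75)),
            "n_models": int(r2_arr.size),
        },
        donors=donors_out,
        planted_optimum=_composition_dict(truth.planted_optimum),
        stage_seeds={k: config.stage_seed(k) for k in _OFFSETS},
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_design(full_design, out / "design.csv")
        eio.write_matrix(normed, out / "expression_reference_normalized.tsv")
        eio.write_gmt(
            {"EMT_UP": emt_up, "EMT_DOWN": emt_down,
             "BASAL": truth.program_genes("basal"),
             "CLASSICAL": truth.program_genes("classical")},
            out / "programs.gmt",
        )
        (out / "report.json").write_text(report.to_json())
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["bounds"] = {k: list(v) for k, v in d["bounds"].items()}
    return d
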