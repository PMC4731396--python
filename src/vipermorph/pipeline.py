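"""End-to-end orchestration of the shape-analysis workflow.

The stages, in order: fixed-angle mandible correction (lateral view);
per-view GPA with sliding semilandmarks; the two-block PLS integration
gate; separate-subsets combination into one shape vector; model
screening; RRPP MANOVA on the retained model; pairwise LS-mean distance
tests; allometry-free shapes; Bayesian classification under equal and
phylogenetically informed priors with IQR distinctness; squared-change
parsimony on group means; disparity through time.  Every random stage
consumes its own child of the master seed, logged in the run record.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    DistinctnessReport,
    PosteriorTable,
    iqr_distinctness,
    phylo_priors,
    posterior_classify,
)
from .integrate import PlsResult, combine_subsets, two_block_pls
from .io import (
    CurveSpec,
    SpecimenRecord,
    assemble_dataset,
    read_curve_spec,
    read_metadata,
    read_tps,
)
from .phylo import AncestralStates, DTTResult, PhyloTree, dtt, read_newick, squared_change_parsimony
from .shapestats import (
    PairwiseDistanceTable,
    RrppFitTable,
    ShapeDataset,
    allometry_free_shapes,
    fit_rrpp_manova,
    pairwise_group_distances,
    select_model,
)
from .simulate import SimulationConfig, SyntheticStudy, generate_study
from .superimpose import ArticulationSpec, fixed_angle_align, gpa

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = (
    "gpa",
    "pls",
    "manova",
    "pairwise",
    "classify",
    "ancestors",
    "dtt",
)

_STAGE_SEEDS = ("pls", "model_selection", "manova", "pairwise", "dtt")


@dataclass
class PipelineConfig:
    """Inputs, analysis settings and output directory for one run.

    Exactly one of ``inputs`` (paths to dorsal/lateral TPS, metadata CSV,
    Newick tree and curve spec) or ``simulate`` must be given.  Defaults
    follow the study conventions: 40-degree articulation target, 10,000
    permutations/simulations, alpha = 0.05; ``fast`` profiles scale the
    resampling down (999 permutations, 200 simulations).
    """

    simulate: SimulationConfig | None = None
    dorsal_tps: str | Path | None = None
    lateral_tps: str | Path | None = None
    metadata_csv: str | Path | None = None
    newick: str | Path | None = None
    curve_spec: str | Path | None = None
    articulation: ArticulationSpec | None = None
    target_angle_deg: float = 40.0
    n_perm: int = 10_000
    n_sim: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | Path | None = None
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        has_inputs = self.dorsal_tps is not None
        if has_inputs == (self.simulate is not None):
            raise ValueError("exactly one of input paths or a simulation config is required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def fast(cls, **kwargs) -> "PipelineConfig":
        kwargs.setdefault("n_perm", 999)
        kwargs.setdefault("n_sim", 200)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the run log."""

    records: list[SpecimenRecord]
    gpa_dorsal: object = None
    gpa_lateral: object = None
    pls: PlsResult | None = None
    dataset: ShapeDataset | None = None
    model_formula: list[str] | None = None
    model_report: pd.DataFrame | None = None
    manova: RrppFitTable | None = None
    pairwise: PairwiseDistanceTable | None = None
    allometry_free: np.ndarray | None = None
    posterior_equal: PosteriorTable | None = None
    posterior_phylo: PosteriorTable | None = None
    distinct_equal: DistinctnessReport | None = None
    distinct_phylo: DistinctnessReport | None = None
    ancestral: AncestralStates | None = None
    dtt_result: DTTResult | None = None
    warnings_log: list[str] = field(default_factory=list)
    run_log: dict = field(default_factory=dict)


def _load_records(config: PipelineConfig):
    if config.simulate is not None:
        study: SyntheticStudy = generate_study(config.simulate, out_dir=None)
        records, dropped = assemble_dataset(study.dorsal, study.lateral, study.metadata)
        return records, study.tree, study.curve_specs, study.articulation, dropped
    specs = read_curve_spec(config.curve_spec)
    dorsal = read_tps(config.dorsal_tps, "dorsal", specs["dorsal"])
    lateral = read_tps(config.lateral_tps, "lateral", specs["lateral"])
    metadata = read_metadata(config.metadata_csv)
    records, dropped = assemble_dataset(dorsal, lateral, metadata)
    tree = read_newick(config.newick) if config.newick is not None else None
    return records, tree, specs, config.articulation, dropped


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the analysis chain; any stage failure aborts naming the stage.

    Outputs (CSV tables, posterior matrices, the DTT curve and a JSON
    run log) are written to ``config.out_dir`` when given; partial
    outputs of completed stages are retained on failure.  Reruns with
    the same seed produce identical numeric outputs.
    """
    out = Path(config.out_dir) if config.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: np.random.SeedSequence(config.seed, spawn_key=(i,))
        for i, name in enumerate(_STAGE_SEEDS)
    }
    result = PipelineResult(records=[])
    log: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "master_seed": config.seed,
        "stage_seeds": {k: list(v.spawn_key) for k, v in seeds.items()},
        "n_perm": config.n_perm,
        "n_sim": config.n_sim,
        "alpha": config.alpha,
        "stages_run": [],
    }
    result.run_log = log
    stage = "load"
    try:
        records, tree, specs, articulation, dropped = _load_records(config)
        result.records = records
        log["n_specimens"] = len(records)
        log["dropped"] = dropped

        stage = "gpa"
        if articulation is not None:
            laterals = [
                fixed_angle_align(r.lateral, articulation, config.target_angle_deg)
                for r in records
            ]
        else:
            warnings.warn(
                "no articulation specification: mandible angle left uncorrected",
                RuntimeWarning,
                stacklevel=2,
            )
            result.warnings_log.append("no articulation specification")
            laterals = [r.lateral for r in records]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res_d = gpa([r.dorsal for r in records], tol=1e-10, max_iter=30)
            res_l = gpa(laterals, tol=1e-10, max_iter=30)
        result.warnings_log.extend(str(w.message) for w in caught)
        result.gpa_dorsal, result.gpa_lateral = res_d, res_l
        log["stages_run"].append("gpa")

        n = len(records)
        block_d = res_d.aligned.reshape(n, -1)
        block_l = res_l.aligned.reshape(n, -1)

        if "pls" in config.stages:
            stage = "pls"
            result.pls = two_block_pls(
                res_d.residual_matrix,
                res_l.residual_matrix,
                n_perm=min(config.n_perm, 999),
                seed=np.random.default_rng(seeds["pls"]),
            )
            log["r_pls"] = result.pls.r_pls
            log["pls_p"] = result.pls.p_value
            if result.pls.p_value >= config.alpha:
                msg = (
                    "integration not supported by the PLS test "
                    f"(P = {result.pls.p_value:.4f}); proceeding with the "
                    "combined analysis regardless — interpret with caution"
                )
                warnings.warn(msg, RuntimeWarning, stacklevel=2)
                result.warnings_log.append(msg)
            if out is not None:
                (out / "pls.json").write_text(
                    json.dumps(
                        {
                            "r_pls": result.pls.r_pls,
                            "p_value": result.pls.p_value,
                            "n_permutations": result.pls.n_permutations,
                        },
                        indent=2,
                    )
                    + "\n"
                )
            log["stages_run"].append("pls")

        stage = "combine"
        combined = np.vstack(
            [
                combine_subsets(
                    block_d[i],
                    block_l[i],
                    res_d.centroid_sizes[i],
                    res_l.centroid_sizes[i],
                ).y_total
                for i in range(n)
            ]
        )
        mean_combined = combined.mean(axis=0)
        mean_combined /= np.linalg.norm(mean_combined)
        y_total = combined + np.outer(1.0 - combined @ mean_combined, mean_combined)
        covariates = pd.DataFrame(
            {
                # head size is the log centroid size of the dorsal configuration
                "log_cs": np.log(res_d.centroid_sizes),
                "group": [r.group for r in records],
                "sex": [r.sex for r in records],
                "stage": [r.stage for r in records],
            }
        )
        dataset = ShapeDataset(y_total, covariates)
        result.dataset = dataset

        if "manova" in config.stages:
            stage = "model selection"
            formula, report = select_model(
                dataset,
                n_perm=min(config.n_perm, 999),
                seed=np.random.default_rng(seeds["model_selection"]),
                alpha=config.alpha,
            )
            if not formula:
                formula = ["log_cs", "group"]
                result.warnings_log.append(
                    "model selection retained no terms; falling back to log_cs + group"
                )
            if "group" not in formula:
                formula = formula + ["group"]
            result.model_formula, result.model_report = formula, report
            if out is not None:
                report.to_csv(out / "model_selection.csv", float_format="%.10g")

            stage = "manova"
            result.manova = fit_rrpp_manova(
                dataset,
                formula,
                n_perm=config.n_perm,
                seed=np.random.default_rng(seeds["manova"]),
            )
            if out is not None:
                result.manova.to_csv(out / "manova.csv")
            log["stages_run"].append("manova")

        if "pairwise" in config.stages:
            stage = "pairwise distances"
            formula = result.model_formula or ["log_cs", "group"]
            result.pairwise = pairwise_group_distances(
                dataset,
                formula,
                n_perm=config.n_perm,
                seed=np.random.default_rng(seeds["pairwise"]),
            )
            if out is not None:
                result.pairwise.to_csv(out / "pairwise.csv")
            log["stages_run"].append("pairwise")

        stage = "allometry-free shapes"
        result.allometry_free = allometry_free_shapes(dataset)

        if "classify" in config.stages:
            stage = "classification"
            groups_series = covariates["group"]
            result.posterior_equal = posterior_classify(dataset.Y, groups_series)
            result.distinct_equal = iqr_distinctness(result.posterior_equal)
            if tree is not None:
                present = sorted(groups_series.unique())
                ptree = tree.prune([t for t in tree.tip_labels if t in present])
                prior_by_group = {g: phylo_priors(ptree, g) for g in present}
                result.posterior_phylo = posterior_classify(
                    dataset.Y, groups_series, priors=prior_by_group
                )
                result.distinct_phylo = iqr_distinctness(result.posterior_phylo)
            if out is not None:
                result.posterior_equal.to_csv(
                    out / "posteriors_equal.csv", out / "quartiles_equal.csv"
                )
                result.distinct_equal.to_csv(out / "distinctness_equal.csv")
                if result.posterior_phylo is not None:
                    result.posterior_phylo.to_csv(
                        out / "posteriors_phylo.csv", out / "quartiles_phylo.csv"
                    )
                    result.distinct_phylo.to_csv(out / "distinctness_phylo.csv")
            log["stages_run"].append("classify")

        group_means = None
        if tree is not None and ("ancestors" in config.stages or "dtt" in config.stages):
            stage = "group means"
            af = pd.DataFrame(result.allometry_free)
            af["group"] = covariates["group"].to_numpy()
            group_means = af.groupby("group").mean()
            ptree = tree.prune([t for t in tree.tip_labels if t in group_means.index])

        if group_means is not None and "ancestors" in config.stages:
            stage = "ancestral states"
            result.ancestral = squared_change_parsimony(ptree, group_means)
            if out is not None:
                result.ancestral.to_csv(
                    out / "ancestral_states.csv", out / "ancestral_distances.csv"
                )
            log["stages_run"].append("ancestors")

        if group_means is not None and "dtt" in config.stages:
            stage = "dtt"
            result.dtt_result = dtt(
                ptree,
                group_means,
                n_sim=config.n_sim,
                seed=np.random.default_rng(seeds["dtt"]),
            )
            log["mdi"] = result.dtt_result.mdi
            log["mdi_area"] = result.dtt_result.mdi_area
            if out is not None:
                result.dtt_result.to_csv(out / "dtt.csv")
            log["stages_run"].append("dtt")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log["warnings"] = result.warnings_log
        if out is not None:
            (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return result
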