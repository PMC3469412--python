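"""Full-workflow orchestration from a single YAML configuration.

Stages run in a fixed order -- filter, cluster, infer, optimize, nulltest,
validate, consensus -- each reading its inputs from files written by the
previous stage, so a run can resume from any completed stage.  An optional
``synthetic`` block generates the complete input bundle first.  Every
source of randomness derives from the single global seed, and a manifest
records the SHA-256 of every artifact so reruns can be compared
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annealing import DynamicCalibration, SAConfig
from .consensus import compare_groups, ensemble_summary, group_consensus
from .discovery import (
    ClusterAssignment,
    build_tree_and_cut,
    coherence_curve,
    read_annotations,
)
from .dynamics import InfluenceModel, TimeCourse
from .expression import (
    cluster_mean_profiles,
    filter_probes,
    read_expression_table,
    read_probe_stats,
    write_expression_table,
)
from .significance import significance_test
from .steady_state import DEFAULT_PENALTY_GRID, SteadyStateInfluence
from .validation import read_interaction_set, rewire_pvalues, validation_accuracy

__all__ = ["ConfigError", "DependencyError", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("filter", "cluster", "infer", "optimize", "nulltest", "validate", "consensus")

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "synthetic", "stages", "inputs",
         "filter", "cluster", "infer", "optimize", "nulltest", "validate", "consensus"},
    "synthetic": {"n_clusters", "edge_density", "sigma_obs", "sigma_gene",
                  "purity", "concordance", "cluster_size_range", "treatments", "times"},
    "stages": set(STAGES),
    "inputs": {"expression", "metadata", "stats", "annotations", "interactions"},
    "filter": {"p_max", "fc_min"},
    "cluster": {"divisions", "thresholds"},
    "infer": {"min_support", "weight_floor", "penalty_grid", "tau_default"},
    "optimize": {"treatments", "n_runs", "steps_stage1", "steps_stage2",
                 "p_accept0_stage1", "p_accept0_stage2", "cooling",
                 "perturb_range", "p_add", "p_remove"},
    "nulltest": {"treatment", "modes", "reps"},
    "validate": {"treatment", "reps", "alpha"},
    "consensus": {"groups"},
}


class ConfigError(ValueError):
    """Configuration violates the schema; nothing has been written."""


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


def load_config(path_or_dict) -> dict:
    """Load and validate a run configuration (unknown keys are errors)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            config = yaml.safe_load(fh)
    else:
        config = dict(path_or_dict)
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(config, "")
    for section, keys in _SCHEMA.items():
        if section and section in config and isinstance(config[section], dict):
            _check_keys(config[section], section)
    if "seed" in config and not isinstance(config["seed"], int):
        raise ConfigError("seed must be an integer")
    if "out_dir" not in config:
        raise ConfigError("out_dir is required")
    return config


def _check_keys(section: dict, name: str) -> None:
    unknown = set(section) - _SCHEMA[name]
    if unknown:
        where = name or "top level"
        raise ConfigError(f"unknown configuration keys at {where}: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} needs missing artifact {path}")
    return path


def run_pipeline(config, log_level: int = logging.INFO) -> dict:
    """Execute all enabled stages and return the artifact manifest."""
    logging.basicConfig(level=log_level, format="%(levelname)s %(name)s: %(message)s")
    config = load_config(config)
    seed = int(config.get("seed", 0))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    toggles = {s: bool(config.get("stages", {}).get(s, True)) for s in STAGES}
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
    }

    inputs_dir = out / "inputs"
    paths = {
        "expression": inputs_dir / "expression.tsv",
        "metadata": inputs_dir / "metadata.tsv",
        "stats": inputs_dir / "probe_stats.tsv",
        "annotations": inputs_dir / "annotations.tsv",
        "interactions": [],
    }
    if "synthetic" in config:
        _generate_inputs(config, seed, inputs_dir, paths, manifest)
    else:
        declared = config.get("inputs", {})
        for key in ("expression", "metadata", "stats", "annotations"):
            if key in declared:
                paths[key] = Path(declared[key])
        paths["interactions"] = [Path(p) for p in declared.get("interactions", [])]

    for stage in STAGES:
        if not toggles[stage]:
            logger.info("stage %s disabled", stage)
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](config, seed, out, paths)
        manifest["stages"][stage] = {
            "outputs": {str(p): _sha256(Path(p)) for p in outputs}
        }
        logger.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _generate_inputs(config, seed, inputs_dir: Path, paths, manifest) -> None:
    from .synthetic import (
        generate_expression_dataset,
        generate_probe_stats,
        generate_validation_data,
        make_truth,
    )

    syn = dict(config["synthetic"])
    if "cluster_size_range" in syn:
        syn["cluster_size_range"] = tuple(syn["cluster_size_range"])
    if "treatments" in syn:
        syn["treatments"] = tuple(syn["treatments"])
    if "times" in syn:
        syn["times"] = tuple(float(t) for t in syn["times"])
    truth = make_truth(seed=_stage_seed(seed, "synthetic"), **syn)
    inputs_dir.mkdir(parents=True, exist_ok=True)
    table, _, assign, _ = generate_expression_dataset(truth)
    write_expression_table(table, paths["expression"], paths["metadata"])
    stats = generate_probe_stats(truth, table)
    pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in stats],
            "p_value": [s.p_value for s in stats],
            "max_abs_fc": [s.max_abs_fc for s in stats],
        }
    ).to_csv(paths["stats"], sep="\t", index=False)
    annot, isets = generate_validation_data(truth)
    pd.DataFrame(
        [(g, t) for g, terms in sorted(annot.items()) for t in sorted(terms)],
        columns=["gene_id", "term_id"],
    ).to_csv(paths["annotations"], sep="\t", index=False)
    for iset in isets:
        p = inputs_dir / f"{iset.name}.tsv"
        with open(p, "w") as fh:
            fh.write(f"#directed={'true' if iset.directed else 'false'}\n")
            fh.write("gene_a\tgene_b\n")
            for a, b in iset.edges:
                fh.write(f"{a}\t{b}\n")
        paths["interactions"].append(p)
    truth.model.to_tsv(inputs_dir / "truth_model.tsv")
    assign.to_tsv(inputs_dir / "truth_clusters.tsv")
    manifest["stages"]["synthesize"] = {
        "outputs": {
            str(p): _sha256(p) for p in sorted(inputs_dir.glob("*.tsv"))
        }
    }


def _stage_filter(config, seed, out: Path, paths) -> list[Path]:
    opts = config.get("filter", {})
    stats = read_probe_stats(_require(paths["stats"], "filter"))
    kept = filter_probes(
        stats, float(opts.get("p_max", 0.05)), float(opts.get("fc_min", 2.0))
    )
    table = read_expression_table(
        _require(paths["expression"], "filter"), _require(paths["metadata"], "filter")
    )
    kept = [g for g in table.gene_ids if g in set(kept)]
    filtered = table.subset(kept)
    out_expr = out / "filtered_expression.tsv"
    out_meta = out / "filtered_metadata.tsv"
    write_expression_table(filtered, out_expr, out_meta)
    kept_path = out / "kept_genes.txt"
    kept_path.write_text("\n".join(kept) + "\n")
    logger.info("filter kept %d of %d genes", len(kept), table.n_genes)
    return [out_expr, out_meta, kept_path]


def _stage_cluster(config, seed, out: Path, paths) -> list[Path]:
    opts = config.get("cluster", {})
    table = read_expression_table(
        _require(out / "filtered_expression.tsv", "cluster"),
        _require(out / "filtered_metadata.tsv", "cluster"),
    )
    divisions = [int(k) for k in opts.get("divisions", range(5, 51, 5))]
    divisions = [k for k in divisions if k <= table.n_genes]
    thresholds = [float(t) for t in opts.get("thresholds", (0.05, 0.01, 0.001))]
    annot = read_annotations(_require(paths["annotations"], "cluster"))
    assignments = build_tree_and_cut(table, divisions)
    curve = coherence_curve(assignments, annot, thresholds)
    best_k = curve.best_division[thresholds[0]]
    best = assignments[best_k]
    clusters_path = out / "clusters.tsv"
    best.to_tsv(clusters_path)
    curve_path = out / "coherence.tsv"
    curve.to_frame().to_csv(curve_path, sep="\t")
    profiles = cluster_mean_profiles(table, best)
    profiles_path = out / "cluster_profiles.tsv"
    frame = profiles.to_frame()
    frame.to_csv(profiles_path, sep="\t", float_format="%.10g")
    counts_path = out / "cluster_gene_counts.tsv"
    pd.DataFrame(
        {"cluster": profiles.cluster_ids, "gene_count": profiles.gene_counts}
    ).to_csv(counts_path, sep="\t", index=False)
    logger.info("selected %d clusters (coherence over %s)", best_k, divisions)
    return [clusters_path, curve_path, profiles_path, counts_path]


def _read_profiles(out: Path, stage: str):
    from .expression import ClusterProfileMatrix, read_expression_table

    table = read_expression_table(
        _require(out / "filtered_expression.tsv", stage),
        _require(out / "filtered_metadata.tsv", stage),
    )
    assign = ClusterAssignment.from_tsv(_require(out / "clusters.tsv", stage))
    return cluster_mean_profiles(table, assign), assign


def _stage_infer(config, seed, out: Path, paths) -> list[Path]:
    opts = config.get("infer", {})
    profiles, _ = _read_profiles(out, "infer")
    result = SteadyStateInfluence(profiles).fit(
        penalty_grid=opts.get("penalty_grid", DEFAULT_PENALTY_GRID),
        min_support=int(opts.get("min_support", 3)),
        weight_floor=float(opts.get("weight_floor", 0.1)),
    )
    tau = float(opts.get("tau_default", 24.0))
    model = result.influence_model(np.full(profiles.n_clusters, tau))
    model_path = out / "model0.tsv"
    model.to_tsv(model_path)
    info_path = out / "model0_info.json"
    info_path.write_text(
        json.dumps(
            {
                "mean_performance": result.report.mean_performance,
                "per_treatment": result.report.per_treatment_performance,
                "penalties": {
                    f.held_out_treatment: f.penalties.tolist() for f in result.folds
                },
                "support_counts": result.report.support_counts.tolist(),
            },
            indent=1,
        )
    )
    logger.info("%s", result.summary())
    return [model_path, Path(str(model_path) + ".json"), info_path]


def _sa_config(config, seed: int) -> SAConfig:
    opts = dict(config.get("optimize", {}))
    opts.pop("treatments", None)
    return SAConfig(seed=_stage_seed(seed, "optimize"), **opts)


def _stage_optimize(config, seed, out: Path, paths) -> list[Path]:
    profiles, _ = _read_profiles(out, "optimize")
    start = InfluenceModel.from_tsv(_require(out / "model0.tsv", "optimize"))
    start.gene_counts = profiles.gene_counts
    treatments = config.get("optimize", {}).get(
        "treatments", [s.treatment for s in profiles.samples]
    )
    treatments = list(dict.fromkeys(treatments))
    base = _sa_config(config, seed)
    outputs = []
    for i, treatment in enumerate(treatments):
        course = TimeCourse.from_profiles(profiles, treatment)
        cfg = SAConfig(**{**base.__dict__, "seed": base.seed + i})
        result = DynamicCalibration(start, course).fit(cfg)
        run_dir = out / "runs" / treatment
        run_dir.mkdir(parents=True, exist_ok=True)
        best_path = run_dir / "best_model.tsv"
        result.best_model.to_tsv(best_path)
        outputs += [best_path, Path(str(best_path) + ".json")]
        for ensemble in (result.stage1, result.stage2):
            for run in ensemble.runs:
                trace_path = run_dir / f"stage{ensemble.stage}_run{run.index}.tsv"
                run.trace_frame().to_csv(
                    trace_path, sep="\t", index=False, float_format="%.8g"
                )
                outputs.append(trace_path)
        meta_path = run_dir / "metadata.json"
        meta_path.write_text(
            json.dumps(
                {
                    "treatment": treatment,
                    "seed": cfg.seed,
                    "config": cfg.__dict__,
                    "initial_fitness": result.initial_fitness,
                    "stage1_best": result.stage1.best_run.best_fitness,
                    "best_fitness": result.best_fitness,
                },
                indent=1,
            )
        )
        outputs.append(meta_path)
        logger.info(
            "optimized %s: %.3f -> %.3f",
            treatment, result.initial_fitness, result.best_fitness,
        )
    return outputs


def _stage_nulltest(config, seed, out: Path, paths) -> list[Path]:
    opts = config.get("nulltest", {})
    profiles, _ = _read_profiles(out, "nulltest")
    treatment = opts.get("treatment") or profiles.samples[0].treatment
    course = TimeCourse.from_profiles(profiles, treatment)
    model_path = out / "runs" / treatment / "best_model.tsv"
    if not model_path.exists():
        model_path = out / "model0.tsv"
    model = InfluenceModel.from_tsv(_require(model_path, "nulltest"))
    model.gene_counts = profiles.gene_counts
    rng = np.random.default_rng(_stage_seed(seed, "nulltest"))
    results = {}
    for mode in opts.get("modes", ("resample", "uniform", "scramble")):
        res = significance_test(
            model, course, mode, n_reps=int(opts.get("reps", 100)), rng=rng
        )
        results[mode] = res.to_dict()
        logger.info(
            "null %s: observed %.3f vs %.3f +- %.3f (empirical p %.4f)",
            mode, res.observed, res.null_mean, res.null_sd, res.empirical_p,
        )
    null_path = out / "nulltest.json"
    null_path.write_text(json.dumps({"treatment": treatment, "results": results}, indent=1))
    return [null_path]


def _stage_validate(config, seed, out: Path, paths) -> list[Path]:
    opts = config.get("validate", {})
    profiles, assign = _read_profiles(out, "validate")
    treatment = opts.get("treatment") or profiles.samples[0].treatment
    model_path = out / "runs" / treatment / "best_model.tsv"
    if not model_path.exists():
        model_path = out / "model0.tsv"
    model = InfluenceModel.from_tsv(_require(model_path, "validate"))
    model.gene_counts = profiles.gene_counts
    if not paths["interactions"]:
        raise DependencyError("stage 'validate' needs at least one interaction file")
    rng = np.random.default_rng(_stage_seed(seed, "validate"))
    pvals = {}
    for p in paths["interactions"]:
        iset = read_interaction_set(_require(Path(p), "validate"), name=Path(p).stem)
        pvals[iset.name] = rewire_pvalues(
            assign, iset, n_reps=int(opts.get("reps", 1000)), rng=rng
        )
    table = validation_accuracy(model, pvals, alpha=float(opts.get("alpha", 0.05)))
    table_path = out / "validation.tsv"
    table.table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
    within_path = out / "validation_within_cluster.tsv"
    table.within_cluster.to_csv(within_path, sep="\t", index=False, float_format="%.6g")
    acc_path = out / "validation_accuracy.json"
    acc_path.write_text(
        json.dumps(
            {
                "per_dataset": table.per_dataset_accuracy,
                "any": table.combined_accuracy,
                "alpha": table.alpha,
            },
            indent=1,
        )
    )
    logger.info(
        "validation accuracies %s; any %.3f",
        table.per_dataset_accuracy, table.combined_accuracy,
    )
    return [table_path, within_path, acc_path]


def _stage_consensus(config, seed, out: Path, paths) -> list[Path]:
    opts = config.get("consensus", {})
    groups = opts.get("groups")
    if not groups:
        logger.info("consensus stage: no groups configured, skipping")
        return []
    models = {}
    loaded = {}
    for label, members in groups.items():
        for treatment in members:
            path = out / "runs" / treatment / "best_model.tsv"
            loaded[treatment] = InfluenceModel.from_tsv(_require(path, "consensus"))
        models[label] = group_consensus(
            [loaded[t] for t in members], label=label
        )
    outputs = []
    for label, gcm in models.items():
        path = out / f"consensus_{label}.tsv"
        k = gcm.n_clusters
        frame = pd.DataFrame(gcm.matrix, index=range(1, k + 1), columns=range(1, k + 1))
        frame.index.name = "target"
        frame.to_csv(path, sep="\t", float_format="%.10g")
        outputs.append(path)
    summary = ensemble_summary(list(loaded.values()))
    summary_path = out / "ensemble_summary.tsv"
    summary.to_frame().to_csv(summary_path, sep="\t", index=False, float_format="%.6g")
    outputs.append(summary_path)
    labels = list(models)
    if len(labels) >= 2:
        comparison = compare_groups(models[labels[0]], models[labels[1]])
        comp_path = out / "edge_status.tsv"
        comparison.to_csv(comp_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(comp_path)
        logger.info(
            "edge comparison %s vs %s: %s",
            labels[0], labels[1],
            comparison["status"].value_counts().to_dict() if len(comparison) else {},
        )
    return outputs


_STAGE_FUNCS = {
    "filter": _stage_filter,
    "cluster": _stage_cluster,
    "infer": _stage_infer,
    "optimize": _stage_optimize,
    "nulltest": _stage_nulltest,
    "validate": _stage_validate,
    "consensus": _stage_consensus,
}
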