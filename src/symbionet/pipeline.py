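"""Full-analysis orchestration: one config in, one reproducible report out.

Stage order: structural metrics -> swap-null significance -> probability
matrices -> randomization prediction -> multinomial AIC selection ->
phylogenetic signal.  Stages whose inputs are absent from the config are
skipped with a logged notice; any stage failure halts with a stage-named
error.  All randomness derives deterministically from one master seed, so
identical config + seed gives a byte-identical serialized report.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import InteractionMatrix, load_inputs
from .errors import SymbionetError, ValidationError
from .model_selection import ModelComparisonTable, NetworkAssemblyModel
from .network_metrics import (
    MetricSet,
    compute_all_metrics,
    species_degree,
    species_strength,
)
from .network_prediction import DEFAULT_METRICS, predict_metric_distribution
from .null_models import NullDistribution, significance, swap_null
from .phylogenetic_signal import (
    TraitVector,
    blomberg_k,
    mantel,
    pagel_lambda,
    partner_dissimilarity,
    phylo_distance,
)
from .probability_models import build_ab, build_absp, build_null, build_obs, build_sp
from .synthetic_data import CommunityScenario, simulate_network, simulate_tree_and_trait

logger = logging.getLogger("symbionet")

__all__ = ["AnalysisReport", "run_full_analysis", "load_config"]


@dataclass
class AnalysisReport:
    """Aggregated outputs of the full analysis, serializable to a directory."""

    metrics: MetricSet | None = None
    degree: dict | None = None
    strength: dict | None = None
    null_tests: dict[str, NullDistribution] = field(default_factory=dict)
    predictions: dict[str, dict[str, NullDistribution]] = field(default_factory=dict)
    comparison: ModelComparisonTable | None = None
    signal: list[dict] = field(default_factory=list)
    mantel_results: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        out: dict[str, Any] = {"metadata": self.metadata}
        if self.metrics is not None:
            out["metrics"] = self.metrics.as_dict()
        if self.null_tests:
            out["null_tests"] = {
                k: {
                    "observed": d.observed,
                    "ci95": list(d.ci95),
                    "p_value": d.p_value,
                    "n_reps": d.n_reps,
                }
                for k, d in self.null_tests.items()
            }
        if self.predictions:
            out["predictions"] = {
                model: {
                    k: {
                        "observed": d.observed,
                        "ci95": list(d.ci95),
                        "inside_ci": bool(d.inside_ci),
                        "n_failed": d.n_failed,
                    }
                    for k, d in dists.items()
                }
                for model, dists in self.predictions.items()
            }
        if self.comparison is not None:
            out["model_selection"] = self.comparison.to_frame().to_dict(orient="records")
        if self.signal:
            out["phylogenetic_signal"] = self.signal
        if self.mantel_results:
            out["mantel"] = self.mantel_results
        return out

    def to_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary = self.summary_dict()
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=_jsonable) + "\n"
        )
        if self.metrics is not None:
            pd.DataFrame([self.metrics.as_dict()]).to_csv(
                out_dir / "metrics.tsv", sep="\t", index=False
            )
        if self.degree is not None:
            for guild in ("plants", "fungi"):
                pd.DataFrame(
                    {
                        "species": list(self.degree[guild]),
                        "degree": list(self.degree[guild].values()),
                        "strength": [self.strength[guild][s] for s in self.degree[guild]],
                    }
                ).to_csv(out_dir / f"species_{guild}.tsv", sep="\t", index=False)
        if self.comparison is not None:
            self.comparison.to_frame().to_csv(out_dir / "model_selection.tsv", sep="\t", index=False)
        if self.predictions:
            rows = []
            for model, dists in self.predictions.items():
                for metric, d in dists.items():
                    rows.append(
                        {
                            "model": model,
                            "metric": metric,
                            "observed": d.observed,
                            "ci_low": d.ci95[0],
                            "ci_high": d.ci95[1],
                            "inside_ci": d.inside_ci,
                        }
                    )
            pd.DataFrame(rows).to_csv(out_dir / "predicted_metrics.tsv", sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return config


def _stage_seed(master: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=master, spawn_key=(100 + stage,)))


def run_full_analysis(config: dict | str | Path) -> AnalysisReport:
    """Execute every configured stage and return the aggregated report."""
    if not isinstance(config, dict):
        config = load_config(config)
    master = int(config.get("seed", 0))
    stages = config.get("stages", {}) or {}
    report = AnalysisReport()
    canon = json.dumps(config, sort_keys=True, default=str)
    report.metadata = {
        "seed": master,
        "package_version": __version__,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
    }

    # ---- inputs ----------------------------------------------------------
    data: dict[str, Any] = {}
    if "simulate" in config:
        scenario = CommunityScenario(**{**(config["simulate"] or {}), "seed": master})
        sim = simulate_network(scenario)
        data = {
            "interaction_matrix": sim.network,
            "plant_abundance": sim.plant_abundance,
            "fungus_abundance": sim.fungus_abundance,
            "plant_occurrence": sim.plant_occurrence,
            "fungus_occurrence": sim.fungus_occurrence,
        }
        tree_cfg = config.get("simulate_trees")
        if tree_cfg:
            for guild, n in (("plant", scenario.n_plants), ("fungus", scenario.n_fungi)):
                tree, _ = simulate_tree_and_trait(
                    n_tips=n,
                    lambda_true=scenario.lambda_true,
                    sigma2=scenario.sigma2,
                    seed=master + (0 if guild == "plant" else 1),
                    prefix=guild,
                )
                data[f"{guild}_tree"] = tree
        report.metadata["true_model"] = sim.true_model
    elif "inputs" in config:
        data = load_inputs(config["inputs"], base_dir=config.get("base_dir", "."))
    else:
        raise ValidationError("config needs either an 'inputs' or a 'simulate' section")

    matrix: InteractionMatrix = data["interaction_matrix"]

    # ---- stage 1: structural metrics ------------------------------------
    try:
        opts = stages.get("metrics", {}) or {}
        report.metrics = compute_all_metrics(
            matrix,
            evenness_denominator=opts.get("evenness_denominator", "grand_total"),
            modularity_restarts=int(opts.get("modularity_restarts", 20)),
            seed=_stage_seed(master, 1),
        )
        report.degree = species_degree(matrix)
        report.strength = species_strength(matrix)
    except SymbionetError as exc:
        raise type(exc)(f"[metrics] {exc}") from exc

    # ---- stage 2: null-model significance --------------------------------
    opts = stages.get("nulltest", {}) or {}
    if opts.get("enabled", True):
        try:
            n_reps = int(opts.get("n_reps", 1000))
            which = tuple(opts.get("metrics", ("wnodf", "modularity")))
            rng = _stage_seed(master, 2)
            replicates = swap_null(matrix, n_reps=n_reps, seed=rng)
            from .network_prediction import _metric_value

            for name in which:
                obs = getattr(report.metrics, name)
                reps = np.array([_metric_value(r, name, rng) for r in replicates])
                report.null_tests[name] = significance(obs, reps, tail="two_sided", metric=name)
        except SymbionetError as exc:
            raise type(exc)(f"[nulltest] {exc}") from exc

    # ---- stage 3: probability matrices -----------------------------------
    hypotheses = {}
    try:
        hypotheses["Null"] = build_null(
            matrix.I, matrix.J, row_labels=matrix.row_labels, col_labels=matrix.col_labels
        )
        if "plant_abundance" in data and "fungus_abundance" in data:
            hypotheses["Ab"] = build_ab(data["plant_abundance"], data["fungus_abundance"])
        if "plant_occurrence" in data and "fungus_occurrence" in data:
            hypotheses["Sp"] = build_sp(data["plant_occurrence"], data["fungus_occurrence"])
        if "Ab" in hypotheses and "Sp" in hypotheses:
            hypotheses["AbSp"] = build_absp(hypotheses["Ab"], hypotheses["Sp"])
    except SymbionetError as exc:
        raise type(exc)(f"[probability_models] {exc}") from exc

    # ---- stage 4: randomization prediction -------------------------------
    opts = stages.get("predict", {}) or {}
    if opts.get("enabled", True) and len(hypotheses) >= 1:
        try:
            n_reps = int(opts.get("n_reps", 1000))
            metric_names = tuple(opts.get("metrics", DEFAULT_METRICS))
            observed = report.metrics.as_dict()
            for i, (name, p) in enumerate(sorted(hypotheses.items())):
                report.predictions[name] = predict_metric_distribution(
                    p, matrix.F, n_reps=n_reps, metrics=metric_names,
                    seed=_stage_seed(master, 40 + i), observed=observed,
                )
        except SymbionetError as exc:
            raise type(exc)(f"[predict] {exc}") from exc

    # ---- stage 5: model selection -----------------------------------------
    opts = stages.get("select", {}) or {}
    if opts.get("enabled", True) and len(hypotheses) >= 2:
        try:
            model = NetworkAssemblyModel(matrix, hypotheses)
            results = model.fit(zero_policy=opts.get("zero_policy", "strict"))
            report.comparison = results.comparison
        except SymbionetError as exc:
            raise type(exc)(f"[select] {exc}") from exc

    # ---- stage 6: phylogenetic signal -------------------------------------
    opts = stages.get("physignal", {}) or {}
    if opts.get("enabled", True):
        degree = species_degree(matrix)
        strength = species_strength(matrix)
        for guild, tree_key, dis_guild in (
            ("plants", "plant_tree", "rows"),
            ("fungi", "fungus_tree", "columns"),
        ):
            if tree_key not in data:
                logger.info("physignal: no %s in config, skipping %s", tree_key, guild)
                continue
            try:
                tree = data[tree_key]
                tips = set(tree.tip_labels)
                labels, bc = partner_dissimilarity(matrix, guild=dis_guild)
                keep = [i for i, l in enumerate(labels) if l in tips]
                kept_labels = tuple(labels[i] for i in keep)
                if len(keep) >= 4:
                    _, pd_mat = phylo_distance(tree, kept_labels)
                    bc_sub = bc[np.ix_(keep, keep)]
                    rng = _stage_seed(master, 60 + (0 if guild == "plants" else 1))
                    n_perm = int(opts.get("n_perm", 999))
                    # paper orientation: phylogenetic distance vs partner similarity
                    r, p = mantel(pd_mat, 1.0 - bc_sub, tail="less", n_perm=n_perm, seed=rng)
                    report.mantel_results.append(
                        {
                            "guild": guild,
                            "r": r,
                            "p_value": p,
                            "tail": "less",
                            "n_perm": n_perm,
                            "orientation": "phylogenetic distance vs partner similarity (1 - Bray-Curtis)",
                        }
                    )
                for trait_name, table in (("degree", degree), ("strength", strength)):
                    x = TraitVector.from_dict(
                        {l: float(table[guild][l]) for l in kept_labels}
                    )
                    if len(x.labels) < 4 or np.allclose(x.values, x.values[0]):
                        logger.info("physignal: %s %s degenerate, skipped", guild, trait_name)
                        continue
                    rng = _stage_seed(master, 70 + (0 if guild == "plants" else 1))
                    kres = blomberg_k(tree, x, n_rand=int(opts.get("n_rand", 999)), seed=rng)
                    lres = pagel_lambda(tree, x)
                    report.signal.append(
                        {
                            "guild": guild,
                            "trait": trait_name,
                            "K": kres.estimate,
                            "p_K": kres.p_value,
                            "lambda": lres.estimate,
                            "p_lambda": lres.p_value,
                            "n_tips": kres.n_tips,
                        }
                    )
            except SymbionetError as exc:
                raise type(exc)(f"[physignal] {exc}") from exc

    return report
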