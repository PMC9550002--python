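"""End-to-end orchestration: load or simulate, describe, stratify, estimate.

``run_pipeline`` executes the full two-stage analysis and writes every
artifact (characteristics table, three candidate trees, strata, effect table,
logistic sensitivity column, stepwise trace) plus a manifest recording seeds,
the configuration hash and every file produced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import descriptive, effects, logistic, synth, tree as tree_mod
from .errors import SchemaError
from .schema import (
    CohortTable,
    default_specs,
    discretize,
    impute_missing,
    load_cohort,
    load_variable_specs,
    PUTATIVE_RISK,
)


def render_tree(tree) -> str:
    """Indented-text rendering: one line per node with split, n, events,
    incidence."""
    return tree.render_text()


@dataclass
class RunConfig:
    """Configuration for one pipeline run. Exactly one of ``input_path`` /
    ``simulate`` must be set."""

    input_path: str | None = None
    simulate: bool = False
    spec_path: str | None = None
    n_simulated: int = 7302
    folds: int = 10
    seed: int = tree_mod.DEFAULT_SEED
    out_dir: str = "treestrat_out"
    measure: str = "or"
    cv_metric: str = "mse"
    model_defs: dict[str, list[str]] | None = None
    lr_interactions: bool = True
    stepwise: bool = True

    def validate(self) -> None:
        if bool(self.input_path) == bool(self.simulate):
            raise SchemaError("set exactly one of input_path / simulate")
        if self.measure not in ("or", "rr"):
            raise SchemaError("measure must be 'or' or 'rr'")


def _load_or_simulate(config: RunConfig) -> tuple[CohortTable, dict | None]:
    specs = (
        load_variable_specs(config.spec_path) if config.spec_path else default_specs()
    )
    if config.simulate:
        gen = synth.default_config(n=config.n_simulated, seed=config.seed)
        cohort, truth = synth.generate_cohort(gen)
        return cohort, truth
    raw = load_cohort(config.input_path, specs)
    raw = impute_missing(raw, specs)
    return discretize(raw, specs), None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        files.append(name)

    cohort, truth = _load_or_simulate(config)
    cohort.require_estimable()
    if config.simulate:
        emit("cohort.csv", cohort.write)

    table1 = descriptive.characteristics_table(cohort)
    emit("characteristics.tsv", lambda p: descriptive.write_characteristics(table1, p))

    model_defs = config.model_defs or tree_mod.default_model_defs(cohort)
    candidates = tree_mod.fit_candidate_models(
        cohort, model_defs, folds=config.folds, seed=config.seed, metric=config.cv_metric
    )
    strata_by_model = {}
    for cand in candidates:
        emit(f"tree_{cand.model_id}.txt",
             lambda p, c=cand: Path(p).write_text(render_tree(c.tree) + "\n"))
        emit(f"tree_{cand.model_id}.json",
             lambda p, c=cand: Path(p).write_text(c.tree.to_json() + "\n"))
        emit(f"tree_{cand.model_id}.dot",
             lambda p, c=cand: Path(p).write_text(c.tree.to_dot() + "\n"))
        strata_by_model[cand.model_id] = tree_mod.assign_strata(cand.tree, cohort)
    best = tree_mod.select_model(candidates)

    node_effects = tree_mod.pairwise_node_effects(best.tree)
    emit("pairwise_nodes.tsv",
         lambda p: effects.effect_frame(node_effects).to_csv(p, sep="\t", index=False))

    exposures = [s.name for s in cohort.specs.values() if s.role == PUTATIVE_RISK]
    lr_map = {}
    flagged_pairs = []
    if config.lr_interactions and len(best.confounders) >= 2:
        screened = logistic.screen_interactions(
            cohort, _tree_confounders(best), alpha=0.05
        )
        flagged_pairs = [r["pair"] for r in screened if r["flagged"]]
        (out / "interactions.json").write_text(
            json.dumps(
                [
                    {"pair": list(r["pair"]), "p_value": r["p_value"],
                     "flagged": r["flagged"], "untestable": r["untestable"]}
                    for r in screened
                ],
                indent=2,
            )
        )
        files.append("interactions.json")
    for name in exposures:
        for est in logistic.adjusted_or_lr(cohort, name, _tree_confounders(best), flagged_pairs):
            lr_map[(est.exposure, est.exposed_level)] = est

    rows = effects.effect_table(cohort, exposures, strata_by_model,
                                measure=config.measure, lr_estimates=lr_map)
    emit("effect_table.tsv", lambda p: effects.write_effect_table(rows, p))
    emit("effect_estimates.tsv",
         lambda p: effects.effect_frame(rows).to_csv(p, sep="\t", index=False, float_format="%.10g"))

    if config.stepwise:
        trace = logistic.forward_stepwise(cohort, exposures, _tree_confounders(best))
        (out / "stepwise.json").write_text(
            json.dumps({"selected": trace.selected, "aic_path": trace.aic_path}, indent=2)
        )
        files.append("stepwise.json")

    manifest = {
        "seed": config.seed,
        "folds": config.folds,
        "cv_metric": config.cv_metric,
        "measure": config.measure,
        "n_subjects": cohort.n_subjects,
        "outcome_prevalence": cohort.prevalence,
        "models": {
            c.model_id: {"aic": c.aic, "n_leaves": c.tree.n_leaves,
                         "alpha": c.tree.alpha, "confounders": c.confounders}
            for c in candidates
        },
        "selected_model": best.model_id,
        "flagged_interactions": [list(p) for p in flagged_pairs],
        "config_hash": _run_hash(config),
        "simulated": bool(config.simulate),
        "files": files,
    }
    if truth is not None:
        manifest["generator"] = {"config_hash": truth["config_hash"], "seed": truth["seed"]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _tree_confounders(candidate) -> list[str]:
    """Confounders actually used as splitters by the selected tree."""
    used = []
    for node in candidate.tree.root.internal_nodes():
        var = candidate.tree.feature_names[node.feature].split("=", 1)[0]
        if var not in used:
            used.append(var)
    return used


def _run_hash(config: RunConfig) -> str:
    doc = {k: v for k, v in vars(config).items()}
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:16]
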