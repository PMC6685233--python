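"""End-to-end orchestration: simulate -> filter -> score -> fit -> export
-> validate, with a reproducibility manifest.

Development runs apply the Goldberg plausibility filter before fitting;
external validation never filters (it only annotates reporting status),
mirroring the asymmetric design of screening-tool studies. Every run
writes a manifest recording the configuration, derived seeds and SHA-256
hashes of each artifact; identical configurations and seeds reproduce all
artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ahei, cart, ffq, metrics, plausibility, questionnaire, synth

logger = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 1

# spawn keys for seeds derived from the run seed
_SEED_SIMULATION = 0
_SEED_CV = 1
_SEED_BOOTSTRAP = 2


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class RunConfig:
    seed: int = 0
    preset: str = "development"
    n: int | None = None  # override the preset sample size
    catalog_path: str | None = None  # None -> bundled demo catalog
    cohort_path: str | None = None  # None -> simulate from the preset
    plausibility_mode: str = "filter"  # filter | annotate | off
    ahei_threshold: float = ahei.DEFAULT_THRESHOLD
    min_node_size: int = 20
    min_leaf_size: int = 7
    max_depth: int = 6
    cv_method: str = "mc"  # mc | kfold
    n_repeats: int = 10
    holdout_fraction: float = 0.1
    one_se: bool = False
    bootstrap_n: int = 2000
    outdir: str = "results"

    def growth_params(self) -> cart.GrowthParams:
        return cart.GrowthParams(
            min_node_size=self.min_node_size,
            min_leaf_size=self.min_leaf_size,
            max_depth=self.max_depth,
        )


def _derived_seed(seed: int, key: int) -> int:
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,)).generate_state(1)[0]
        % (2**31)
    )


def _load_inputs(config: RunConfig):
    catalog = (
        ffq.load_catalog(config.catalog_path)
        if config.catalog_path
        else ffq.load_demo_catalog()
    )
    if config.cohort_path:
        cohort = ffq.load_cohort(config.cohort_path, catalog)
    else:
        spec = synth.presets()[config.preset]
        spec = dataclasses.replace(
            spec,
            seed=_derived_seed(config.seed, _SEED_SIMULATION),
            n=config.n or spec.n,
            ahei_threshold=config.ahei_threshold,
        )
        cohort = synth.generate_cohort(spec, catalog).cohort
    return catalog, cohort


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> Path:
    artifacts = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "derived_seeds": {
            "simulation": _derived_seed(config.seed, _SEED_SIMULATION),
            "cv": _derived_seed(config.seed, _SEED_CV),
            "bootstrap": _derived_seed(config.seed, _SEED_BOOTSTRAP),
        },
        "artifacts": artifacts,
        **extra,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _report_frame(report: metrics.AccuracyReport) -> pd.DataFrame:
    rows = []
    for name, est in report.as_dict().items():
        if name == "n" or est is None:
            continue
        rows.append(
            {
                "metric": name,
                "value": est["value"],
                "ci_low": est["ci_low"],
                "ci_high": est["ci_high"],
            }
        )
    return pd.DataFrame(rows)


def _evaluate(
    tree: cart.Tree,
    cohort: pd.DataFrame,
    catalog: ffq.ItemCatalog,
    scores: pd.DataFrame,
    config: RunConfig,
) -> metrics.AccuracyReport:
    predictors = cart.build_predictor_matrix(cohort, catalog)
    predicted, p_low = cart.predict(tree, predictors)
    cm = metrics.confusion(predicted, scores["quality_class"].to_numpy())
    return metrics.accuracy_report(
        cm,
        scores=p_low,
        truth=scores["quality_class"].to_numpy(),
        n_boot=config.bootstrap_n,
        seed=_derived_seed(config.seed, _SEED_BOOTSTRAP),
    )


def run_development(config: RunConfig) -> dict:
    """Full development run: returns the fitted objects and writes
    ``cohort.csv``, ``exclusions.csv``, ``ahei_scores.csv``, ``tree.json``,
    ``questionnaire.json``, ``report.json|csv`` and ``manifest.json``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        catalog, cohort = _load_inputs(config)
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc

    n_input = len(cohort)
    try:
        if config.plausibility_mode == "off":
            retained, log = cohort.copy(), pd.DataFrame()
        else:
            retained, log = plausibility.filter_plausible(
                cohort, catalog, apply=config.plausibility_mode == "filter"
            )
    except Exception as exc:
        raise PipelineError(f"plausibility stage failed: {exc}") from exc

    try:
        scores = ahei.score_cohort(retained, catalog, threshold=config.ahei_threshold)
    except Exception as exc:
        raise PipelineError(f"scoring stage failed: {exc}") from exc

    try:
        predictors = cart.build_predictor_matrix(retained, catalog)
        tree = cart.fit_classification_tree(
            predictors,
            scores["quality_class"].to_numpy(),
            params=config.growth_params(),
            seed=_derived_seed(config.seed, _SEED_CV),
            cv_method=config.cv_method,
            n_repeats=config.n_repeats,
            holdout_fraction=config.holdout_fraction,
            one_se=config.one_se,
        )
    except Exception as exc:
        raise PipelineError(f"tree development stage failed: {exc}") from exc

    try:
        quest = questionnaire.tree_to_questionnaire(tree, catalog)
    except Exception as exc:
        raise PipelineError(f"questionnaire export stage failed: {exc}") from exc

    try:
        report = _evaluate(tree, retained, catalog, scores, config)
    except Exception as exc:
        raise PipelineError(f"evaluation stage failed: {exc}") from exc

    ffq.save_cohort(retained, outdir / "cohort.csv")
    log.to_csv(outdir / "exclusions.csv", index=False)
    scored = retained[["respondent_id"]].join(scores)
    scored.to_csv(outdir / "ahei_scores.csv", index=False)
    cart.save_tree(tree, outdir / "tree.json")
    questionnaire.save_questionnaire(quest, outdir / "questionnaire.json")
    (outdir / "report.json").write_text(
        json.dumps(report.as_dict(), indent=2, sort_keys=True)
    )
    _report_frame(report).to_csv(outdir / "report.csv", index=False)
    manifest_path = _write_manifest(
        outdir,
        config,
        {"stage": "development", "n_input": n_input, "n_retained": len(retained)},
    )
    logger.info(
        "development run complete: n_input=%d n_retained=%d leaves=%d",
        n_input,
        len(retained),
        tree.n_leaves,
    )
    return {
        "catalog": catalog,
        "cohort": retained,
        "exclusions": log,
        "scores": scores,
        "tree": tree,
        "questionnaire": quest,
        "report": report,
        "manifest_path": manifest_path,
    }


def run_external_validation(config: RunConfig, tree: cart.Tree) -> dict:
    """Validate a fitted tree on an external cohort (annotate-only
    plausibility); writes ``external_report.json|csv`` and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        catalog, cohort = _load_inputs(config)
        cohort, status_log = plausibility.filter_plausible(
            cohort, catalog, apply=False
        )
        scores = ahei.score_cohort(cohort, catalog, threshold=config.ahei_threshold)
        report = _evaluate(tree, cohort, catalog, scores, config)
    except cart.TreeError as exc:
        raise PipelineError(f"external validation failed: {exc}") from exc
    except Exception as exc:
        raise PipelineError(f"external validation failed: {exc}") from exc
    (outdir / "external_report.json").write_text(
        json.dumps(report.as_dict(), indent=2, sort_keys=True)
    )
    _report_frame(report).to_csv(outdir / "external_report.csv", index=False)
    status_log.to_csv(outdir / "external_plausibility.csv", index=False)
    _write_manifest(
        outdir, config, {"stage": "external_validation", "n_input": len(cohort)}
    )
    return {"report": report, "cohort": cohort, "scores": scores}
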