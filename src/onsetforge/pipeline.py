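"""End-to-end reproducible pipeline: simulate/read -> filter -> split ->
features -> selection -> fit -> evaluate -> explain.

A single global seed is split deterministically into per-stage seeds, every
intermediate artifact is written to the output directory, and a manifest
records the configuration hash, stage seeds and artifact list — identical
configurations produce identical manifests and byte-identical text artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as ofio
from . import models as model_zoo
from .cohort import (
    DEFAULT_AAO_MODEL,
    DEFAULT_GENE_SPECS,
    AAOModelSpec,
    Cohort,
    GeneAlleleSpec,
    SimConfig,
    filter_cagexp,
    simulate_cohort,
)
from .evaluate import ScreenConfig, SplitSpec, run_comparison, split_cohort
from .explain import attribute, dependence_curve, fit_changepoint
from .features import METHODS, derive_features, cross_features
from .models import ALGORITHMS, ModelConfig
from .selection import RFEConfig, StepSVMConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExplainConfig:
    n_permutations: int = 32
    background_size: int = 100
    max_samples: int = 100
    dependence_feature: str = "ATXN3-A2"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-serializable."""

    input_path: str | None = None  # cohort CSV; None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    filter_low: int = 60
    filter_high: int = 80
    split: SplitSpec = field(default_factory=SplitSpec)
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHMS))
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    stepsvm: StepSVMConfig = field(default_factory=StepSVMConfig)
    rfe: RFEConfig = field(default_factory=RFEConfig)
    model_grids: dict[str, dict] = field(default_factory=dict)
    cv_folds: int = 10
    explain: ExplainConfig = field(default_factory=ExplainConfig)
    seed: int = 0

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; valid: {METHODS}")
        unknown = [a for a in self.algorithms if a not in ALGORITHMS]
        if unknown:
            raise ValueError(f"unknown algorithms {unknown}; valid: {ALGORITHMS}")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return convert(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            sim = dict(data["sim"])
            if "gene_specs" in sim:
                sim["gene_specs"] = tuple(
                    GeneAlleleSpec(
                        gene=g["gene"],
                        a1_mean=g["a1_mean"], a1_sd=g["a1_sd"],
                        a1_range=tuple(g["a1_range"]),
                        a2_mean=g["a2_mean"], a2_sd=g["a2_sd"],
                        a2_range=tuple(g["a2_range"]),
                    )
                    for g in sim["gene_specs"]
                )
            if "aao_model" in sim and isinstance(sim["aao_model"], dict):
                am = dict(sim["aao_model"])
                if "interaction_terms" in am:
                    am["interaction_terms"] = tuple(
                        ((tuple(pair)), coef)
                        for pair, coef in (tuple(t) for t in am["interaction_terms"])
                    )
                if "aao_bounds" in am:
                    am["aao_bounds"] = tuple(am["aao_bounds"])
                sim["aao_model"] = AAOModelSpec(**am)
            data["sim"] = SimConfig(**sim)
        for key, cls_ in (("split", SplitSpec), ("screen", ScreenConfig),
                          ("stepsvm", StepSVMConfig), ("rfe", RFEConfig),
                          ("explain", ExplainConfig)):
            if key in data and isinstance(data[key], dict):
                payload = dict(data[key])
                if key == "stepsvm" and isinstance(payload.get("base_learner"), dict):
                    from .selection import SVRParams
                    payload["base_learner"] = SVRParams(**payload["base_learner"])
                if key == "rfe" and isinstance(payload.get("base_learner"), dict):
                    from .selection import SVRParams
                    payload["base_learner"] = SVRParams(**payload["base_learner"])
                data[key] = cls_(**payload)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written as JSON).

    Any stage failure aborts with the stage name attached; artifacts written
    before the failure are preserved.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["simulate", "split", "model", "explain"])
    manifest: dict = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "artifacts": [],
        "counts": {},
        "status": "running",
    }

    def add_artifact(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    stage = "setup"
    try:
        stage = "cohort"
        if config.input_path is not None:
            cohort = ofio.read_cohort(config.input_path)
        else:
            sim = dataclasses.replace(config.sim, seed=seeds["simulate"])
            cohort = simulate_cohort(sim)
        n_before = len(cohort)
        cohort = filter_cagexp(cohort, config.filter_low, config.filter_high)
        manifest["counts"]["subjects_total"] = n_before
        manifest["counts"]["subjects_filtered_out"] = n_before - len(cohort)
        cohort_path = out / "cohort.csv"
        ofio.write_cohort(cohort, cohort_path)
        add_artifact(cohort_path)

        stage = "split"
        split = dataclasses.replace(config.split, seed=seeds["split"])
        train, test = split_cohort(cohort, split)
        manifest["counts"]["n_train"] = len(train)
        manifest["counts"]["n_test"] = len(test)
        for name, part in (("train.csv", train), ("test.csv", test)):
            p = out / name
            ofio.write_cohort(part, p)
            add_artifact(p)

        stage = "comparison"
        model_configs = {
            a: ModelConfig(algorithm=a,
                           grid=config.model_grids.get(a),
                           cv_folds=config.cv_folds,
                           seed=seeds["model"])
            for a in config.algorithms
        }
        result = run_comparison(
            train, test, config.methods, config.algorithms,
            screen=config.screen,
            stepsvm_config=config.stepsvm, rfe_config=config.rfe,
            model_configs=model_configs,
            piecewise_threshold=config.split.piecewise_threshold,
            seed=seeds["model"],
        )
        for method, sel in result.selections.items():
            p = out / f"selection_{method}.json"
            ofio.write_selection(sel, p)
            add_artifact(p)
            manifest["counts"][f"selected_{method}"] = len(sel.selected)
        report_path = out / "evaluation.tsv"
        ofio.write_report(result.report, report_path)
        add_artifact(report_path)
        manifest["best"] = list(result.report.best) if result.report.best else None

        stage = "explain"
        if result.report.best is not None:
            best_alg, best_method = result.report.best
            model = result.fitted[(best_alg, best_method)]
            train_fm = derive_features(train)
            if best_method != "correlation":
                train_fm = cross_features(train_fm)
            ex = config.explain
            rng = np.random.default_rng(seeds["explain"])
            n = train_fm.n_subjects
            bg_idx = rng.choice(n, size=min(ex.background_size, n), replace=False)
            background = _take_rows(train_fm, np.sort(bg_idx))
            n_explain = min(ex.max_samples, n)
            sample_idx = np.sort(rng.choice(n, size=n_explain, replace=False))
            samples = _take_rows(train_fm, sample_idx)
            attr = attribute(model, samples, background,
                             n_permutations=ex.n_permutations,
                             seed=seeds["explain"])
            attr_path = out / "attributions.tsv"
            ofio.write_attribution(attr, attr_path)
            add_artifact(attr_path)
            dep_feature = ex.dependence_feature
            if dep_feature in model.feature_names:
                raw = samples.column(dep_feature)
                pairs = dependence_curve(attr, dep_feature, raw)
                dep_path = out / "dependence.tsv"
                ofio.write_dependence_tsv(pairs, dep_path)
                add_artifact(dep_path)
                try:
                    cp = fit_changepoint(pairs)
                    manifest["changepoint"] = {
                        "feature": dep_feature,
                        "breakpoint": cp.breakpoint,
                        "sse": cp.sse,
                        "sse_linear": cp.sse_linear,
                    }
                except ValueError:
                    logger.info("too few distinct values for a changepoint fit")

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _take_rows(matrix, idx):
    from .features import FeatureMatrix

    return FeatureMatrix(
        subject_ids=[matrix.subject_ids[i] for i in idx],
        descriptors=list(matrix.descriptors),
        values=matrix.values[idx].copy(),
        target=matrix.target[idx].copy(),
    )
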