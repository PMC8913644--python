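"""End-to-end orchestration: simulate/load -> features -> train -> evaluate.

One :class:`RunConfig` drives a full run: a synthetic study (or flat
files), single-response models for each (construct, format), combined
"all-responses" models, a discriminant difference-score model, model
comparisons, per-scale reliability, and per-response-set diversity and
word-count summaries. A fixed configuration plus seed reproduces the
report bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .datatypes import CONSTRUCTS, FORMATS, PredictionResult, TrainingConfig
from .embeddings import combine_feature_sets, tokenize
from .errors import InvalidInputError
from .evaluation import (
    ComparisonResult,
    compare_bootstrap,
    compare_same_outcome,
    diversity_index,
    interpret_r,
    reliability_report,
    word_count_stats,
)
from .io import StudyBundle, load_study
from .prediction import cross_validated_predict, difference_target
from .synthetic import SyntheticConfig, generate_study
from .utils import derive_seed

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("lba")

_SCALE_NAME = {"hil": "HILS", "swl": "SWLS"}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    Either ``synthetic`` is set (the study is simulated) or the three input
    paths are. The global ``seed`` is propagated to every stochastic stage
    through named substreams.
    """

    synthetic: SyntheticConfig | None = None
    responses_path: str | None = None
    items_hil_path: str | None = None
    items_swl_path: str | None = None
    embedding_paths: dict = field(default_factory=dict)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    compare_models: bool = True
    n_boot: int = 1000
    ceiling_convention: str = "paper"
    seed: int = 0

    def to_dict(self) -> dict:
        cfg = {
            "seed": self.seed,
            "compare_models": self.compare_models,
            "n_boot": self.n_boot,
            "ceiling_convention": self.ceiling_convention,
            "training": {
                "n_folds": self.training.n_folds,
                "n_strat_bins": self.training.n_strat_bins,
                "inner_analysis_fraction": self.training.inner_analysis_fraction,
                "penalty_grid": list(self.training.penalty_grid),
                "standardize_features": self.training.standardize_features,
                "seed": self.training.seed,
            },
        }
        if self.synthetic is not None:
            s = self.synthetic
            cfg["synthetic"] = {
                "n_participants": s.n_participants,
                "rho_latent": s.rho_latent,
                "n_items": s.n_items,
                "item_loading": s.loadings,
                "scale_range": list(s.scale_range),
                "embed_dim": s.embed_dim,
                "embed_signal": s.signals,
                "n_tokens_word_response": s.n_tokens_word_response,
                "n_tokens_text_response": s.n_tokens_text_response,
                "tilt": s.tilt,
                "seed": s.seed,
            }
        else:
            cfg["paths"] = {
                "responses": self.responses_path,
                "items_hil": self.items_hil_path,
                "items_swl": self.items_swl_path,
                "embeddings": dict(self.embedding_paths),
            }
        return cfg

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        training = TrainingConfig(**d.get("training", {})) if "training" in d else TrainingConfig()
        synthetic = None
        if "synthetic" in d:
            s = dict(d["synthetic"])
            if "scale_range" in s:
                s["scale_range"] = tuple(s["scale_range"])
            synthetic = SyntheticConfig(**s)
        paths = d.get("paths", {})
        return cls(
            synthetic=synthetic,
            responses_path=paths.get("responses"),
            items_hil_path=paths.get("items_hil"),
            items_swl_path=paths.get("items_swl"),
            embedding_paths=dict(paths.get("embeddings", {})),
            training=training,
            compare_models=d.get("compare_models", True),
            n_boot=d.get("n_boot", 1000),
            ceiling_convention=d.get("ceiling_convention", "paper"),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunReport:
    """Canonical result bundle of one pipeline run."""

    models: dict  # name -> PredictionResult
    comparisons: list  # ComparisonResult
    reliability: dict  # construct -> ReliabilityReport
    diversity: dict  # "construct_format" -> DiversityReport
    word_counts: dict  # "construct_format" -> (mean, sd)
    excluded: list
    config: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "excluded": list(self.excluded),
            "models": {
                name: {
                    "outcome": res.outcome_name,
                    "accuracy_r": res.accuracy_r,
                    "accuracy_p": res.accuracy_p,
                    "interpretation": interpret_r(res.accuracy_r),
                    "fold_penalties": list(res.fold_penalties),
                    "n": res.n,
                }
                for name, res in self.models.items()
            },
            "comparisons": [
                {
                    "method": c.method,
                    "models": list(c.model_names),
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "n_boot": c.n_boot,
                }
                for c in self.comparisons
            ],
            "reliability": {k: v.to_dict() for k, v in self.reliability.items()},
            "diversity": {k: v.to_dict() for k, v in self.diversity.items()},
            "word_counts": {
                k: {"mean": m, "sd": s} for k, (m, s) in self.word_counts.items()
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def summary_frame(self) -> pd.DataFrame:
        """Flat per-model summary for spreadsheet use."""
        rows = [
            {
                "model": name,
                "outcome": res.outcome_name,
                "accuracy_r": res.accuracy_r,
                "accuracy_p": res.accuracy_p,
                "interpretation": interpret_r(res.accuracy_r),
                "n": res.n,
            }
            for name, res in self.models.items()
        ]
        return pd.DataFrame(rows)


def _bundle_from_config(config: RunConfig) -> StudyBundle:
    if config.synthetic is not None:
        study = generate_study(config.synthetic)
        return StudyBundle(
            responses=study.responses,
            items_hil=study.items_hil,
            items_swl=study.items_swl,
            embeddings={
                f"{c}_{f}": m.reorder(study.participant_ids)
                for (c, f, _mode), m in study.embeddings.items()
            },
            excluded=[],
        )
    if not (config.responses_path and config.items_hil_path and config.items_swl_path):
        raise InvalidInputError("config needs either a synthetic spec or all three input paths")
    return load_study(
        config.responses_path,
        config.items_hil_path,
        config.items_swl_path,
        embedding_paths=config.embedding_paths,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured study end to end and assemble the report.

    Models fitted: one per (construct, format) feature set predicting its
    own scale total; a combined all-responses model per scale; and a
    combined model for the discriminant difference score (centred HILS
    total minus centred SWLS total). With ``compare_models`` the combined
    model is tested against each single-response model via the paired
    error t-test, and the two combined models against each other via the
    paired bootstrap.
    """
    log.info("stage=load seed=%d", config.seed)
    bundle = _bundle_from_config(config)
    ids = bundle.participant_ids
    feature_names = [f"{c}_{f}" for c in CONSTRUCTS for f in FORMATS]
    missing = [n for n in feature_names if n not in bundle.embeddings]
    if missing:
        raise InvalidInputError(f"missing feature sets: {missing}")
    features = {n: bundle.embeddings[n].reorder(ids) for n in feature_names}
    features["all"] = combine_feature_sets([features[n] for n in feature_names])

    totals = {c: bundle.items(c).total for c in CONSTRUCTS}
    outcomes = dict(totals)
    outcomes["diff"] = difference_target(totals["hil"], totals["swl"])

    models: dict[str, PredictionResult] = {}

    def _train(model_name: str, feat: str, outcome: str) -> None:
        tc = replace(config.training, seed=derive_seed(config.seed, f"train-{model_name}"))
        log.info("stage=train model=%s features=%s outcome=%s", model_name, feat, outcome)
        models[model_name] = cross_validated_predict(
            features[feat].values,
            outcomes[outcome],
            tc,
            outcome_name={"hil": "HILS", "swl": "SWLS", "diff": "HILS-SWLS"}[outcome],
            model_name=model_name,
        )

    for construct in CONSTRUCTS:
        for fmt in FORMATS:
            _train(f"{construct}_{fmt}", f"{construct}_{fmt}", construct)
    for construct in CONSTRUCTS:
        _train(f"all_{construct}", "all", construct)
    _train("all_diff", "all", "diff")

    comparisons: list[ComparisonResult] = []
    if config.compare_models:
        for construct in CONSTRUCTS:
            for fmt in FORMATS:
                comparisons.append(
                    compare_same_outcome(models[f"all_{construct}"], models[f"{construct}_{fmt}"])
                )
        comparisons.append(
            compare_bootstrap(
                models["all_hil"],
                models["all_swl"],
                n_boot=config.n_boot,
                seed=derive_seed(config.seed, "bootstrap-all"),
            )
        )

    reliability = {
        construct: reliability_report(
            bundle.items(construct), convention=config.ceiling_convention
        )
        for construct in CONSTRUCTS
    }

    diversity, word_counts = {}, {}
    for construct, fmt, block in bundle.responses.blocks():
        token_lists = [tokenize(t) for t in block.texts]
        diversity[f"{construct}_{fmt}"] = diversity_index(token_lists)
        word_counts[f"{construct}_{fmt}"] = word_count_stats(token_lists)

    return RunReport(
        models=models,
        comparisons=comparisons,
        reliability=reliability,
        diversity=diversity,
        word_counts=word_counts,
        excluded=bundle.excluded,
        config=config.to_dict(),
    )
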