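"""End-to-end experiment orchestration.

An :class:`ExperimentConfig` names a synthetic cohort, a binary outcome
(the FA-phenotype contrasts of the study design), and a resampling protocol:

* ``plain_cv`` — stratified five-fold CV, used for the high-signal
  CNV-vs-none outcomes;
* ``holdout_tuned`` — 15% stratified holdout with two-stage non-nested
  tuning on the 85% development split, for the subtype contrasts;
* ``external_transfer`` — the tuned model is applied unchanged to a second
  cohort generated on a different scanner geometry.

``run_experiment`` executes simulate → segment → features → train →
evaluate → explain and returns a JSON-serializable report with AUROC and
CI, Youden operating point, contingency table, optional RFE curve and
attribution summary, and the config snapshot. One global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence`` spawn keys, so the
report is reproducible byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .anatomy import GEOMETRY_PRESETS, VoxelGeometry
from .attribution import population_summary, shapley_attribution
from .classify import (
    LabeledDataset,
    ModelConfig,
    TrainedModel,
    cross_validate,
    recursive_feature_elimination,
    tune_with_holdout,
)
from .etdrs import default_registry, feature_table
from .evaluate import bootstrap_ci, contingency, roc_curve, sens_spec, youden_cutoff
from .synthetic import DEFAULT_EFFECTS, CohortSpec, iter_cohort
from .anatomy import rule_based_segment

logger = logging.getLogger("cnvpheno")

__all__ = ["OUTCOMES", "ExperimentConfig", "run_experiment", "cohort_features"]

#: Binary outcome definitions: (positive classes, negative classes).
OUTCOMES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "any_cnv_vs_none": (
        ("occult", "minimally_classic", "predominantly_classic"),
        ("none",),
    ),
    "occult_vs_none": (("occult",), ("none",)),
    "minimally_classic_vs_none": (("minimally_classic",), ("none",)),
    "predominantly_classic_vs_none": (("predominantly_classic",), ("none",)),
    "classic_vs_occult": (
        ("minimally_classic", "predominantly_classic"),
        ("occult",),
    ),
    "predominantly_classic_vs_minimally_classic": (
        ("predominantly_classic",),
        ("minimally_classic",),
    ),
    "occult_vs_minimally_classic": (("occult",), ("minimally_classic",)),
    "occult_vs_predominantly_classic": (("occult",), ("predominantly_classic",)),
}

#: Outcomes for which plain CV (no tuning, no holdout) is the protocol.
PLAIN_CV_OUTCOMES = frozenset(
    o for o in OUTCOMES if o.endswith("_vs_none") or o == "any_cnv_vs_none"
)


def _stage_seed(seed: int, stage: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full recipe for one experiment run."""

    outcome: str = "occult_vs_predominantly_classic"
    protocol: str = "holdout_tuned"  # plain_cv | holdout_tuned | external_transfer
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"occult": 60, "predominantly_classic": 60}
    )
    geometry: str = "small"
    transfer_geometry: str = "tiny"  # cohort B geometry for external_transfer
    noise_sd: float = 0.05
    use_rule_based_segmentation: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    k_folds: int = 5
    holdout_fraction: float = 0.15
    include_rfe_curve: bool = False
    include_attribution: bool = False
    attribution_samples: int = 256
    attribution_max_eyes: int = 40
    ci_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.protocol not in ("plain_cv", "holdout_tuned", "external_transfer"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        pos, neg = OUTCOMES[self.outcome]
        if self.protocol == "plain_cv" and self.outcome not in PLAIN_CV_OUTCOMES:
            raise ValueError(
                "plain_cv is reserved for the high-signal vs-none outcomes; "
                f"use holdout_tuned for {self.outcome!r}"
            )

    def snapshot(self) -> dict:
        d = asdict(self)
        d["model"] = {
            "family": self.model.family,
            "fixed_params": dict(self.model.fixed_params),
            "grid": {k: list(v) for k, v in self.model.grid.items()},
        }
        return d


def cohort_features(
    spec: CohortSpec, *, segment: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a cohort and extract its feature table, one eye at a time.

    When ``segment`` is true each rendered volume is passed through the
    rule-based segmenter (the full pipeline); otherwise the planted
    ground-truth masks are used directly.
    """
    registry = default_registry()
    segmenter = rule_based_segment if segment else None
    return feature_table(iter_cohort(spec), registry, segmenter=segmenter)


def _evaluate_scores(scores, y, seed: int, ci_boot: int) -> dict:
    roc = roc_curve(scores, y)
    cutoff, se, sp = youden_cutoff(roc)
    table = contingency(scores, y, cutoff if np.isfinite(cutoff) else np.max(scores))
    lo, hi = bootstrap_ci(scores, y, n_boot=ci_boot, seed=seed)
    return {
        "auroc": roc.auroc,
        "ci95": [lo, hi],
        "youden": {"cutoff": cutoff, "sensitivity": se, "specificity": sp},
        "contingency": table.to_dict(),
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the configured experiment end to end and return the report."""
    geom = GEOMETRY_PRESETS[config.geometry]
    spec = CohortSpec(
        n_per_class=dict(config.n_per_class),
        geometry=geom,
        noise_sd=config.noise_sd,
        seed=_stage_seed(config.seed, 0),
    )
    logger.info(
        "simulate+features: %d eyes on %s geometry (segment=%s)",
        spec.n_total,
        config.geometry,
        config.use_rule_based_segmentation,
    )
    X, labels = cohort_features(spec, segment=config.use_rule_based_segmentation)
    pos, neg = OUTCOMES[config.outcome]
    dataset = LabeledDataset.from_labels(X, labels, pos, neg)
    train_seed = _stage_seed(config.seed, 1)

    report: dict = {
        "config": config.snapshot(),
        "n_eyes": dataset.n,
        "n_positive": int(dataset.y.sum()),
        "n_negative": int((1 - dataset.y).sum()),
        "outcome": config.outcome,
        "protocol": config.protocol,
    }

    model: TrainedModel | None = None
    if config.protocol == "plain_cv":
        logger.info("train: plain %d-fold CV", config.k_folds)
        cv = cross_validate(dataset, config.model, k=config.k_folds, seed=train_seed)
        report["evaluation"] = _evaluate_scores(
            cv.oof_scores, cv.y, _stage_seed(config.seed, 2), config.ci_boot
        )
        report["per_fold"] = cv.per_fold_table().to_dict(orient="records")
        est = config.model.build(train_seed)
        est.fit(dataset.X.to_numpy(), dataset.y)
        model = TrainedModel(
            est, list(dataset.X.columns), config.model.family, {}, train_seed,
            config.k_folds,
        )
    else:
        logger.info("train: 15%% holdout, two-stage tuning")
        model, roc = tune_with_holdout(
            dataset,
            config.model,
            holdout_fraction=config.holdout_fraction,
            k=config.k_folds,
            seed=train_seed,
            ci_boot=config.ci_boot,
        )
        cutoff, se, sp = roc.operating_point
        report["evaluation"] = {
            "auroc": roc.auroc,
            "ci95": list(roc.ci),
            "youden": {"cutoff": cutoff, "sensitivity": se, "specificity": sp},
        }
        report["selected_features"] = model.feature_names
        report["hyperparameters"] = {
            k: (v if v is None or isinstance(v, (int, float, str)) else str(v))
            for k, v in model.hyperparameters.items()
        }

    if config.protocol == "external_transfer":
        spec_b = CohortSpec(
            n_per_class=dict(config.n_per_class),
            geometry=GEOMETRY_PRESETS[config.transfer_geometry],
            noise_sd=config.noise_sd,
            seed=_stage_seed(config.seed, 3),
        )
        logger.info("external transfer: scoring cohort B (%s)", config.transfer_geometry)
        Xb, labels_b = cohort_features(
            spec_b, segment=config.use_rule_based_segmentation
        )
        ds_b = LabeledDataset.from_labels(Xb, labels_b, pos, neg)
        scores_b = model.predict_proba(ds_b.X)
        report["external"] = _evaluate_scores(
            scores_b, ds_b.y, _stage_seed(config.seed, 4), config.ci_boot
        )

    if config.include_rfe_curve:
        logger.info("rfe: elimination curve")
        curve = recursive_feature_elimination(
            dataset, config.model, k=config.k_folds, seed=train_seed
        )
        report["rfe"] = {
            "n_features": curve.n_features,
            "auroc": curve.aurocs,
            "top_features": curve.top_features(20),
        }

    if config.include_attribution:
        logger.info("explain: permutation Shapley attributions")
        rng = np.random.default_rng(_stage_seed(config.seed, 5))
        n_eyes = min(config.attribution_max_eyes, dataset.n)
        pick = rng.choice(dataset.n, size=n_eyes, replace=False)
        background = dataset.X.iloc[
            rng.choice(dataset.n, size=min(50, dataset.n), replace=False)
        ]
        attrs = [
            shapley_attribution(
                model,
                dataset.X.iloc[i],
                background,
                n_samples=config.attribution_samples,
                seed=_stage_seed(config.seed, 100 + int(i)),
                eye_id=str(dataset.X.index[i]),
            )
            for i in pick
        ]
        summary = population_summary(attrs)
        report["attribution"] = {
            "top_features": summary.head(20).reset_index().to_dict(orient="records")
        }

    return report
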