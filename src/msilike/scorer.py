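"""MSI-H scoring: seed ensembles of gradient-boosted trees over a lattice
of feature combinations, trimmed-mean aggregation, and missing-input
dispatch.

Each feature combination gets its own ensemble of ``n_seeds`` XGBoost
classifiers differing only in random seed; a patient's MSI-H score is the
trimmed mean of the submodel probabilities (for 10 seeds: the mean of the
middle 6, dropping the 2 lowest and 2 highest). A registry of ensembles,
ordered from most to least feature-complete, lets records with whole
missing blocks (an assay never run) fall back to a model that does not
need them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from xgboost import Booster, XGBClassifier

from .core_data import (
    Cohort,
    GeneClassMap,
    GeneFrequencyTable,
    PatientRecord,
    ValidationError,
)
from .features import (
    CLINICAL_BLOCK,
    GENE_CLASSES_S1_BLOCK,
    GENE_CLASSES_S2_BLOCK,
    MUTATION_POSTERIOR_BLOCK,
    TIL_BLOCK_PREFIX,
    FeatureMatrix,
    FeatureSpec,
    build_feature_matrix,
    record_features,
)

DEFAULT_THRESHOLD = 0.3

#: conservative defaults for the base learner; fully overridable
DEFAULT_XGB_PARAMS: dict = {
    "max_depth": 3,
    "n_estimators": 60,
    "learning_rate": 0.1,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "min_child_weight": 1,
    "tree_method": "hist",
    "n_jobs": 1,
}


class UnscorableError(ValueError):
    """No registry model's required blocks are available for the record."""


class DispatchError(ValueError):
    """A model was asked to score a record missing required features."""


@dataclass(frozen=True)
class TrainingConfig:
    """Seed-ensemble training configuration.

    ``seed_list`` gives one seed per submodel; the class-imbalance weight
    (XGBoost's ``scale_pos_weight``) is always the negative/positive count
    ratio of the training data.
    """

    n_seeds: int = 10
    seed_list: tuple[int, ...] = tuple(range(10))
    xgb_params: dict = field(default_factory=dict)
    imbalance_weight_mode: str = "class_ratio"

    def __post_init__(self) -> None:
        if self.n_seeds < 3:
            raise ValidationError(f"n_seeds must be >= 3, got {self.n_seeds}")
        if len(self.seed_list) != self.n_seeds:
            raise ValidationError(
                f"seed_list length {len(self.seed_list)} != n_seeds {self.n_seeds}"
            )
        if self.imbalance_weight_mode != "class_ratio":
            raise ValidationError(
                f"unknown imbalance_weight_mode {self.imbalance_weight_mode!r}"
            )

    def params(self) -> dict:
        p = dict(DEFAULT_XGB_PARAMS)
        p.update(self.xgb_params)
        return p

    @classmethod
    def from_base_seed(cls, base_seed: int, n_seeds: int = 10, **kw) -> "TrainingConfig":
        return cls(
            n_seeds=n_seeds,
            seed_list=tuple(int(base_seed) + i for i in range(n_seeds)),
            **kw,
        )


@dataclass
class EnsembleModel:
    """One feature combination's fitted seed ensemble."""

    spec: FeatureSpec
    submodels: list  # XGBClassifier when trained in-session, Booster when loaded
    columns: list[str]
    seeds: tuple[int, ...]
    n_positive: int
    n_negative: int

    @property
    def imbalance_weight(self) -> float:
        return self.n_negative / self.n_positive


def trimmed_mean(values: Sequence[float]) -> float:
    """Mean of the sorted values after dropping floor(0.2 n) per tail.

    For a 10-member ensemble this is the mean of sorted positions 3-8,
    i.e. the middle 6, excluding the 2 extremes on each side.
    """
    v = np.sort(np.asarray(values, dtype=float))
    k = int(np.floor(0.2 * len(v)))
    core = v[k: len(v) - k] if k else v
    return float(core.mean())


def train_ensemble(matrix: FeatureMatrix, config: TrainingConfig) -> EnsembleModel:
    """Fit one seed ensemble on a labeled feature matrix.

    Each submodel shares hyperparameters and the class-ratio positive
    weight but uses its own seed for row/column subsampling, so the
    ensemble averages over initialization noise. Deterministic given
    (matrix, config).
    """
    if matrix.y is None:
        raise ValidationError("training requires a labeled matrix")
    if len(matrix) == 0:
        raise ValidationError("training matrix is empty")
    n_pos = int(matrix.y.sum())
    n_neg = int(len(matrix.y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"training data must contain both classes (pos={n_pos}, neg={n_neg})"
        )
    weight = n_neg / n_pos
    X = matrix.X.to_numpy(dtype=float)
    submodels = []
    for seed in config.seed_list:
        clf = XGBClassifier(
            **config.params(),
            scale_pos_weight=weight,
            random_state=int(seed),
        )
        clf.fit(X, matrix.y)
        submodels.append(clf)
    return EnsembleModel(
        spec=matrix.spec,
        submodels=submodels,
        columns=list(matrix.X.columns),
        seeds=tuple(config.seed_list),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def _as_row(model: EnsembleModel, features: dict) -> np.ndarray:
    missing = [c for c in model.columns if c not in features]
    if missing:
        raise DispatchError(
            f"model {model.spec.name!r} missing required feature(s): {missing[:5]}"
        )
    return np.array(
        [[np.nan if features[c] is None else float(features[c])
          for c in model.columns]],
        dtype=float,
    )


def _proba_positive(submodel, arr: np.ndarray) -> np.ndarray:
    # submodels are sklearn-style after training but raw Boosters after
    # loading from disk; both consume NaN as missing
    if isinstance(submodel, Booster):
        return np.asarray(submodel.inplace_predict(arr), dtype=float)
    return submodel.predict_proba(arr)[:, 1]


def predict_score(model: EnsembleModel, features: dict) -> float:
    """Trimmed-mean MSI-H score for one named feature vector."""
    row = _as_row(model, features)
    probs = [float(_proba_positive(m, row)[0]) for m in model.submodels]
    return trimmed_mean(probs)


def predict_scores(model: EnsembleModel, X: pd.DataFrame) -> np.ndarray:
    """Vectorized trimmed-mean scores for a feature matrix."""
    arr = X[model.columns].to_numpy(dtype=float)
    probs = np.column_stack(
        [_proba_positive(m, arr) for m in model.submodels]
    )
    probs.sort(axis=1)
    k = int(np.floor(0.2 * probs.shape[1]))
    core = probs[:, k: probs.shape[1] - k] if k else probs
    return core.mean(axis=1)


def classify(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Call MSI-H-like iff score >= threshold (inclusive boundary)."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score must be in [0, 1], got {score}")
    return "MSI-H-like" if score >= threshold else "other"


def calibrate_threshold(
    scores: Sequence[float], target_prevalence: float
) -> float:
    """Threshold whose predicted-positive fraction best matches a target.

    Candidates are the observed scores themselves (each achievable
    predicted-positive fraction under the >= rule) plus a just-above-max
    cutoff for the all-negative case; ties break toward the lower
    (more inclusive) threshold.
    """
    s = np.asarray(list(scores), dtype=float)
    if s.size == 0:
        raise ValidationError("calibrate_threshold needs at least one score")
    if not (0.0 < target_prevalence <= 1.0):
        raise ValidationError(
            f"target_prevalence must be in (0, 1], got {target_prevalence}"
        )
    candidates = np.unique(s)
    above = min(1.0, float(candidates[-1]) + 1e-9)
    cand = np.append(candidates, above)
    best_t, best_err = None, np.inf
    for t in cand:
        frac = float((s >= t).mean())
        err = abs(frac - target_prevalence)
        # strictly-better or (tie and lower threshold); iterate ascending
        if err < best_err - 1e-15:
            best_t, best_err = float(t), err
    return best_t


def block_available(record: PatientRecord, block: str) -> bool:
    """Whether a record carries any data for a feature block.

    A block counts as available when its assay was performed at all:
    clinical if any clinical field is present, mutation blocks if the
    panel was run (even with zero hits), TIL blocks per measured
    (cell type, region). Within-block missing values are tolerated by the
    learners; whole-block absence is what dispatch routes around.
    """
    if block == CLINICAL_BLOCK:
        return not record.clinical.is_fully_missing()
    if block in (MUTATION_POSTERIOR_BLOCK, GENE_CLASSES_S1_BLOCK, GENE_CLASSES_S2_BLOCK):
        return not record.mutations.is_missing
    if block.startswith(TIL_BLOCK_PREFIX):
        col = block[len(TIL_BLOCK_PREFIX):]
        cell, _, region = col.rpartition("__")
        return record.til.get(cell, region) is not None
    raise ValidationError(f"unknown block {block!r}")


@dataclass
class ModelRegistry:
    """Ordered ensemble collection (most feature-complete first) with the
    deployment decision threshold."""

    models: list[EnsembleModel]
    threshold: float = DEFAULT_THRESHOLD
    table: Optional[GeneFrequencyTable] = None
    class_map: Optional[GeneClassMap] = None

    def __post_init__(self) -> None:
        names = [m.spec.name for m in self.models]
        if len(set(names)) != len(names):
            raise ValidationError("registry specs must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.models)

    def get(self, name: str) -> EnsembleModel:
        for m in self.models:
            if m.spec.name == name:
                return m
        raise KeyError(name)


def dispatch_and_score(
    registry: ModelRegistry, record: PatientRecord
) -> tuple[float, str]:
    """Score a record with the most complete model its data can feed.

    Walks the registry in completeness order and uses the first ensemble
    whose required blocks are all available. Returns (score, model name).
    Raises :class:`UnscorableError` if nothing fits — never a silent
    default score.
    """
    if not registry.models:
        raise UnscorableError("registry is empty")
    for model in registry.models:
        if all(block_available(record, b) for b in model.spec.blocks):
            feats = record_features(
                record, model.spec, registry.table, registry.class_map
            )
            return predict_score(model, feats), model.spec.name
    raise UnscorableError(
        f"record {record.patient_id!r}: no model's required blocks are "
        "all available"
    )


def train_lattice(
    cohort: Cohort,
    specs: Sequence[FeatureSpec],
    config: TrainingConfig,
    table: Optional[GeneFrequencyTable] = None,
    class_map: Optional[GeneClassMap] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> ModelRegistry:
    """Train one ensemble per feature combination and assemble a registry.

    Registry order is most-to-least feature-complete: descending block
    count, ties broken by spec name for determinism.
    """
    models = []
    for spec in specs:
        try:
            matrix = build_feature_matrix(cohort, spec, table, class_map)
            models.append(train_ensemble(matrix, config))
        except (ValidationError, KeyError) as exc:
            raise ValidationError(f"spec {spec.name!r}: {exc}") from exc
    models.sort(key=lambda m: (-len(m.spec.blocks), m.spec.name))
    return ModelRegistry(
        models=models, threshold=threshold, table=table, class_map=class_map
    )


# ---------------------------------------------------------------------------
# Default 44-combination lattice (reconstruction; the deployed combination
# list is configurable and this default is documented in docs/methods.md)

_TIL_MARKERS = ("CD8+", "CD163+", "PD-L1+")


def default_lattice_specs() -> list[FeatureSpec]:
    """44 feature combinations over clinical, mutation, and TIL blocks.

    Bases: clinical alone, and clinical + mutation-derived features
    (posterior + both gene-class stringencies). Each base is optionally
    augmented with a non-empty subset of the CD8+/CD163+/PD-L1+ percent
    cellularity markers measured in a single region (tumor, stromal or
    whole): 2 x (1 + 3 x 7) = 44 combinations.
    """
    mutation_blocks = (
        MUTATION_POSTERIOR_BLOCK,
        GENE_CLASSES_S1_BLOCK,
        GENE_CLASSES_S2_BLOCK,
    )
    bases = [
        ("clin", (CLINICAL_BLOCK,)),
        ("clin+mut", (CLINICAL_BLOCK,) + mutation_blocks),
    ]
    subsets = []
    for mask in range(1, 8):
        subsets.append(tuple(
            m for i, m in enumerate(_TIL_MARKERS) if mask >> i & 1
        ))
    specs = []
    for base_name, base_blocks in bases:
        specs.append(FeatureSpec(name=base_name, blocks=base_blocks))
        for region in ("tumor", "stromal", "whole"):
            for markers in subsets:
                til = tuple(
                    f"{TIL_BLOCK_PREFIX}{m}__{region}" for m in markers
                )
                tag = "+".join(m.rstrip("+") for m in markers)
                specs.append(FeatureSpec(
                    name=f"{base_name}+{region}:{tag}",
                    blocks=base_blocks + til,
                ))
    assert len(specs) == 44
    return specs


# ---------------------------------------------------------------------------
# Persistence: registry.yaml + one model file per (spec, seed)


def save_registry(registry: ModelRegistry, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "threshold": registry.threshold,
        "models": [],
    }
    for i, m in enumerate(registry.models):
        entry = {
            "spec": m.spec.to_dict(),
            "columns": m.columns,
            "seeds": list(m.seeds),
            "n_positive": m.n_positive,
            "n_negative": m.n_negative,
            "files": [],
        }
        for j, clf in enumerate(m.submodels):
            fname = f"model_{i:03d}_seed{m.seeds[j]}.json"
            booster = clf.get_booster() if isinstance(clf, XGBClassifier) else clf
            booster.save_model(d / fname)
            entry["files"].append(fname)
        meta["models"].append(entry)
    if registry.table is not None:
        from .core_data import write_frequency_table

        write_frequency_table(registry.table, d / "gene_frequencies.csv")
        meta["priors"] = {
            "prior_msi": registry.table.prior_msi,
            "prior_mss": registry.table.prior_mss,
        }
    if registry.class_map is not None:
        meta["class_map"] = {
            str(s): dict(m)
            for s, m in registry.class_map.stringency_maps.items()
        }
    with open(d / "registry.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_registry(directory: str | Path) -> ModelRegistry:
    d = Path(directory)
    with open(d / "registry.yaml") as fh:
        meta = yaml.safe_load(fh)
    table = None
    if (d / "gene_frequencies.csv").exists():
        from .core_data import read_frequency_table

        table = read_frequency_table(d / "gene_frequencies.csv")
        if "priors" in meta:
            table = GeneFrequencyTable(
                rows=table.rows,
                prior_msi=meta["priors"]["prior_msi"],
                prior_mss=meta["priors"]["prior_mss"],
            )
    class_map = None
    if "class_map" in meta:
        class_map = GeneClassMap(
            {int(s): m for s, m in meta["class_map"].items()}
        )
    models = []
    for entry in meta["models"]:
        submodels = []
        for fname in entry["files"]:
            fpath = d / fname
            if not fpath.exists():
                raise FileNotFoundError(
                    f"registry references missing model file: {fpath}"
                )
            submodels.append(Booster(model_file=str(fpath)))
        models.append(EnsembleModel(
            spec=FeatureSpec.from_dict(entry["spec"]),
            submodels=submodels,
            columns=list(entry["columns"]),
            seeds=tuple(entry["seeds"]),
            n_positive=entry["n_positive"],
            n_negative=entry["n_negative"],
        ))
    return ModelRegistry(
        models=models,
        threshold=float(meta["threshold"]),
        table=table,
        class_map=class_map,
    )
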