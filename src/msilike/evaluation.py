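"""Model evaluation: repeated stratified cross-validated Cohen kappa and
dual feature-importance reporting.

Generalization is measured the way the scorer is deployed: within each
hold-out fold the seed ensemble is retrained on the remaining folds (with
the in-fold class-ratio weight), patients are scored with the trimmed
mean, called at the decision threshold, and agreement with the true MSI
status is summarized by Cohen's kappa. Five folds per repeat, ten repeats
with fresh split and ensemble seeds, reported as mean and SD across
repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core_data import Cohort, GeneClassMap, GeneFrequencyTable, ValidationError
from .features import FeatureSpec, build_feature_matrix
from .scorer import (
    DEFAULT_THRESHOLD,
    EnsembleModel,
    FeatureMatrix,
    TrainingConfig,
    predict_scores,
    train_ensemble,
)


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Assign each index to one of ``k`` class-stratified folds.

    Per fold, the positive count deviates from perfect proportionality by
    at most one; the assignment is an exhaustive disjoint partition and is
    deterministic for a given seed.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValidationError(
                f"class {cls} has fewer than k={k} members"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def cohen_kappa(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Observed agreement p_o and chance agreement p_e come from the marginal
    label frequencies. Degenerate case: when p_e = 1 (both raters constant
    and identical marginals), kappa is 1 if agreement is perfect, else 0.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.size == 0:
        raise ValidationError(
            f"label vectors must be equal-length and non-empty "
            f"({t.shape} vs {p.shape})"
        )
    n = t.size
    p_o = float((t == p).mean())
    classes = np.union1d(t, p)
    p_e = float(sum(
        (t == c).mean() * (p == c).mean() for c in classes
    ))
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class EvaluationReport:
    """Per-repeat fold kappas plus cross-repeat aggregation."""

    fold_kappas: list[list[Optional[float]]]  # [repeat][fold], None = degenerate
    repeat_means: list[float]
    mean_kappa: float
    sd_kappa: Optional[float]
    k: int
    repeats: int
    seeds: list[int]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "fold_kappas": self.fold_kappas,
            "repeat_means": self.repeat_means,
            "mean_kappa": self.mean_kappa,
            "sd_kappa": self.sd_kappa,
            "k": self.k,
            "repeats": self.repeats,
            "seeds": self.seeds,
            "threshold": self.threshold,
        }

    def fold_table(self) -> pd.DataFrame:
        rows = [
            {"repeat": i, "fold": j, "kappa": kap}
            for i, folds in enumerate(self.fold_kappas)
            for j, kap in enumerate(folds)
        ]
        return pd.DataFrame(rows)


def cross_validate(
    cohort: Cohort,
    spec: FeatureSpec,
    config: Optional[TrainingConfig] = None,
    k: int = 5,
    repeats: int = 10,
    seeds: Optional[Sequence[int]] = None,
    threshold: float = DEFAULT_THRESHOLD,
    table: Optional[GeneFrequencyTable] = None,
    class_map: Optional[GeneClassMap] = None,
) -> EvaluationReport:
    """Repeated stratified k-fold kappa for one feature combination.

    Each repeat draws a fresh stratified split from its seed and fresh
    ensemble seeds (derived from the repeat seed; split and submodel seeds
    are independent streams). A hold-out fold whose truth is single-class
    leaves kappa undefined: it is recorded as missing, excluded from the
    repeat mean, and warned about.
    """
    if seeds is None:
        seeds = list(range(repeats))
    if len(seeds) != repeats:
        raise ValidationError(f"need {repeats} seeds, got {len(seeds)}")
    base_config = config or TrainingConfig()
    matrix = build_feature_matrix(cohort, spec, table, class_map)
    if matrix.y is None:
        raise ValidationError("cross-validation requires a fully labeled cohort")
    X, y = matrix.X, matrix.y

    fold_kappas: list[list[Optional[float]]] = []
    repeat_means: list[float] = []
    for seed in seeds:
        assignment = stratified_folds(y, k, seed)
        # fresh submodel seeds per repeat, decoupled from the split seed
        rep_config = TrainingConfig(
            n_seeds=base_config.n_seeds,
            seed_list=tuple(
                (int(seed) * 1000 + 1 + i) % (2**31 - 1)
                for i in range(base_config.n_seeds)
            ),
            xgb_params=base_config.xgb_params,
        )
        kappas: list[Optional[float]] = []
        for fold in range(k):
            test = assignment == fold
            train = ~test
            sub = FeatureMatrix(
                X=X.iloc[train], spec=spec, y=y[train]
            )
            model = train_ensemble(sub, rep_config)
            scores = predict_scores(model, X.iloc[test])
            pred = (scores >= threshold).astype(int)
            truth = y[test]
            if truth.min() == truth.max():
                warnings.warn(
                    f"repeat seed {seed} fold {fold}: single-class hold-out, "
                    "kappa undefined and excluded",
                    stacklevel=2,
                )
                kappas.append(None)
            else:
                kappas.append(cohen_kappa(truth, pred))
        fold_kappas.append(kappas)
        defined = [x for x in kappas if x is not None]
        repeat_means.append(float(np.mean(defined)))
    mean_kappa = float(np.mean(repeat_means))
    sd_kappa = (
        float(np.std(repeat_means, ddof=1)) if repeats > 1 else None
    )
    return EvaluationReport(
        fold_kappas=fold_kappas,
        repeat_means=repeat_means,
        mean_kappa=mean_kappa,
        sd_kappa=sd_kappa,
        k=k,
        repeats=repeats,
        seeds=[int(s) for s in seeds],
        threshold=threshold,
    )


@dataclass
class ImportanceReport:
    """Gain-based and permutation-based feature importance, each normalized
    to sum to one, with rank orders under both."""

    table: pd.DataFrame  # columns: feature, gain, permutation, gain_rank, perm_rank


def importance_report(
    model: EnsembleModel,
    matrix: FeatureMatrix,
    n_permutations: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Dual feature importance for one ensemble.

    Gain importance is XGBoost's native total-gain metric averaged across
    submodels. Attribution importance is permutation-based: the mean
    absolute change in the trimmed-mean score when one feature column is
    shuffled, averaged over ``n_permutations`` seeded shuffles. Both are
    normalized to sum to 1 (all-zero vectors are left at zero).
    """
    if n_permutations < 1:
        raise ValidationError(
            f"n_permutations must be >= 1, got {n_permutations}"
        )
    cols = model.columns
    gains = np.zeros(len(cols))
    for clf in model.submodels:
        booster = clf.get_booster() if hasattr(clf, "get_booster") else clf
        score_map = booster.get_score(importance_type="total_gain")
        # booster names features f0, f1, ... in column order
        for i in range(len(cols)):
            gains[i] += score_map.get(f"f{i}", 0.0)
    gains /= len(model.submodels)

    rng = np.random.default_rng(int(seed))
    base = predict_scores(model, matrix.X)
    perm = np.zeros(len(cols))
    for i, col in enumerate(cols):
        deltas = []
        for _ in range(n_permutations):
            Xp = matrix.X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            deltas.append(np.abs(predict_scores(model, Xp) - base).mean())
        perm[i] = float(np.mean(deltas))

    def _norm(v: np.ndarray) -> np.ndarray:
        s = v.sum()
        return v / s if s > 0 else v

    gains_n, perm_n = _norm(gains), _norm(perm)
    df = pd.DataFrame({
        "feature": cols,
        "gain": gains_n,
        "permutation": perm_n,
    })
    df["gain_rank"] = df["gain"].rank(ascending=False, method="min").astype(int)
    df["perm_rank"] = df["permutation"].rank(ascending=False, method="min").astype(int)
    return ImportanceReport(table=df)
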