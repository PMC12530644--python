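"""Feature engineering: one-hot clinical encoding, gene-class indicators,
and the naive-Bayes mutation posterior.

The mutation posterior treats the set of mutated genes M = {g_i} as
conditionally independent evidence for MSI-H status:

    P(MSI-H | M) = P(MSI-H) prod_i P(g_i | MSI-H)
                   / [ P(MSI-H) prod_i P(g_i | MSI-H)
                       + P(MSS) prod_i P(g_i | MSS) ]

evaluated in log space with a configurable per-gene frequency floor so a
zero-frequency gene cannot collapse the posterior to exactly 0 or 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import (
    CATEGORICAL_LEVELS,
    Cohort,
    ClinicalFeatures,
    GeneClassMap,
    GeneFrequencyTable,
    MutationProfile,
    MSI_H,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: block name for clinical metainformation
CLINICAL_BLOCK = "clinical"
MUTATION_POSTERIOR_BLOCK = "mutation_posterior"
GENE_CLASSES_S1_BLOCK = "gene_classes_s1"
GENE_CLASSES_S2_BLOCK = "gene_classes_s2"
TIL_BLOCK_PREFIX = "til:"

UNCLASSIFIED = "unclassified"


def clinical_columns() -> list[str]:
    """Column names of the one-hot clinical encoding, in fixed order."""
    cols: list[str] = []
    cols.append("age_years")
    for name, levels in CATEGORICAL_LEVELS.items():
        cols.extend(f"{name}={lvl}" for lvl in levels)
    cols.extend(["cea_ng_ml", "cea_ge_5"])
    return cols


def one_hot_clinical(clinical: ClinicalFeatures) -> dict[str, Optional[float]]:
    """Expand clinical features into a fixed-width named numeric vector.

    Each k-level categorical becomes k indicators (no reference level is
    dropped; tree ensembles are insensitive to the redundancy). Age and CEA
    pass through numerically, plus the CEA>=5 ng/ml indicator used
    clinically. A missing field yields missing values for all its columns.
    """
    out: dict[str, Optional[float]] = {"age_years": clinical.age_years}
    for name, levels in CATEGORICAL_LEVELS.items():
        value = getattr(clinical, name)
        for lvl in levels:
            out[f"{name}={lvl}"] = (
                None if value is None else float(value == lvl)
            )
    cea = clinical.cea_ng_ml
    out["cea_ng_ml"] = cea
    out["cea_ge_5"] = None if cea is None else float(cea >= 5.0)
    return out


def gene_class_columns(class_map: GeneClassMap, stringency: int) -> list[str]:
    return [
        f"class_s{stringency}={c}" for c in class_map.classes(stringency)
    ] + [f"class_s{stringency}={UNCLASSIFIED}"]


def encode_gene_classes(
    mutations: MutationProfile,
    class_map: GeneClassMap,
    stringency: int,
) -> dict[str, Optional[float]]:
    """Indicator per functional class: 1 iff any mutated gene falls in it.

    Mutated genes absent from the map light up a catch-all ``unclassified``
    indicator. A missing mutation profile yields an all-missing vector.
    """
    cols = gene_class_columns(class_map, stringency)
    if mutations.is_missing:
        return {c: None for c in cols}
    hit: set[str] = set()
    for g in mutations.genes:
        cls = class_map.class_of(g, stringency)
        hit.add(UNCLASSIFIED if cls is None else cls)
    return {
        c: float(c.split("=", 1)[1] in hit) for c in cols
    }


def mutation_posterior(
    mutations: MutationProfile,
    table: GeneFrequencyTable,
    epsilon: float = 1e-4,
) -> Optional[float]:
    """Posterior probability of MSI-H given the mutated gene set.

    Computed in log space; per-gene frequencies below ``epsilon`` are
    floored at ``epsilon`` before use. Genes absent from the frequency
    table are skipped (uninformative) with a logged warning. An empty gene
    set returns the MSI-H prior; a missing profile returns ``None``.
    """
    if not (0.0 < epsilon <= 0.01):
        raise ValidationError(f"epsilon must be in (0, 0.01], got {epsilon}")
    if mutations.is_missing:
        return None
    log_msi = math.log(table.prior_msi) if table.prior_msi > 0 else -math.inf
    log_mss = math.log(table.prior_mss) if table.prior_mss > 0 else -math.inf
    skipped = 0
    for gene in sorted(mutations.genes):
        if gene not in table.rows:
            skipped += 1
            continue
        f_msi = max(table.freq_msi(gene), epsilon)
        f_mss = max(table.freq_mss(gene), epsilon)
        log_msi += math.log(f_msi)
        log_mss += math.log(f_mss)
    if skipped:
        logger.warning(
            "mutation_posterior: %d gene(s) absent from frequency table, skipped",
            skipped,
        )
    # posterior = logistic(log_msi - log_mss), stable for large |log odds|
    if log_msi == -math.inf and log_mss == -math.inf:
        return 0.5
    d = log_mss - log_msi
    if d > 0:
        e = math.exp(-d)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(d))


@dataclass(frozen=True)
class FeatureSpec:
    """A named feature combination: which blocks it uses, in which order."""

    name: str
    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError(f"spec {self.name!r} has no blocks")
        if len(set(self.blocks)) != len(self.blocks):
            raise ValidationError(f"spec {self.name!r} repeats a block")

    @property
    def til_keys(self) -> list[tuple[str, str]]:
        keys = []
        for b in self.blocks:
            if b.startswith(TIL_BLOCK_PREFIX):
                col = b[len(TIL_BLOCK_PREFIX):]
                cell, _, region = col.rpartition("__")
                keys.append((cell, region))
        return keys

    def columns(
        self,
        class_map: Optional[GeneClassMap] = None,
    ) -> list[str]:
        cols: list[str] = []
        for b in self.blocks:
            if b == CLINICAL_BLOCK:
                cols.extend(clinical_columns())
            elif b == MUTATION_POSTERIOR_BLOCK:
                cols.append("mutation_posterior")
            elif b in (GENE_CLASSES_S1_BLOCK, GENE_CLASSES_S2_BLOCK):
                if class_map is None:
                    raise ValidationError(
                        f"spec {self.name!r} needs a gene class map"
                    )
                s = 1 if b == GENE_CLASSES_S1_BLOCK else 2
                cols.extend(gene_class_columns(class_map, s))
            elif b.startswith(TIL_BLOCK_PREFIX):
                cols.append(b[len(TIL_BLOCK_PREFIX):])
            else:
                raise ValidationError(f"unknown block {b!r} in spec {self.name!r}")
        return cols

    def to_dict(self) -> dict:
        return {"name": self.name, "blocks": list(self.blocks)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(name=d["name"], blocks=tuple(d["blocks"]))


def save_specs(specs: Sequence[FeatureSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([s.to_dict() for s in specs], fh, sort_keys=False)


def load_specs(path) -> list[FeatureSpec]:
    with open(path) as fh:
        return [FeatureSpec.from_dict(d) for d in yaml.safe_load(fh)]


@dataclass
class FeatureMatrix:
    """Model-ready numeric matrix aligned to a cohort and a FeatureSpec.

    Missing values stay NaN — no silent imputation; the gradient-boosted
    learners consume NaN natively.
    """

    X: pd.DataFrame
    spec: FeatureSpec
    y: Optional[np.ndarray] = None  # MSI-H = 1, MSS = 0

    @property
    def patient_ids(self) -> list[str]:
        return list(self.X.index)

    def __len__(self) -> int:
        return len(self.X)


def record_features(
    record,
    spec: FeatureSpec,
    table: Optional[GeneFrequencyTable] = None,
    class_map: Optional[GeneClassMap] = None,
    epsilon: float = 1e-4,
) -> dict[str, Optional[float]]:
    """One patient's named feature vector under ``spec``."""
    out: dict[str, Optional[float]] = {}
    for b in spec.blocks:
        if b == CLINICAL_BLOCK:
            out.update(one_hot_clinical(record.clinical))
        elif b == MUTATION_POSTERIOR_BLOCK:
            if table is None:
                raise ValidationError("mutation_posterior block needs a frequency table")
            out["mutation_posterior"] = mutation_posterior(
                record.mutations, table, epsilon
            )
        elif b in (GENE_CLASSES_S1_BLOCK, GENE_CLASSES_S2_BLOCK):
            s = 1 if b == GENE_CLASSES_S1_BLOCK else 2
            if class_map is None:
                raise ValidationError("gene class block needs a class map")
            out.update(encode_gene_classes(record.mutations, class_map, s))
        elif b.startswith(TIL_BLOCK_PREFIX):
            col = b[len(TIL_BLOCK_PREFIX):]
            cell, _, region = col.rpartition("__")
            out[col] = record.til.get(cell, region)
        else:
            raise ValidationError(f"unknown block {b!r}")
    return out


def build_feature_matrix(
    cohort: Cohort,
    spec: FeatureSpec,
    table: Optional[GeneFrequencyTable] = None,
    class_map: Optional[GeneClassMap] = None,
    epsilon: float = 1e-4,
) -> FeatureMatrix:
    """Assemble the cohort-level matrix for one feature combination.

    Columns follow the spec's declared order exactly; the result is
    deterministic given its inputs. TIL blocks naming a (cell type, region)
    no patient has measured raise a schema error.
    """
    available = set(cohort.til_columns())
    for cell, region in spec.til_keys:
        if f"{cell}__{region}" not in available:
            raise SchemaError(
                f"spec {spec.name!r} requires TIL column "
                f"'{cell}__{region}' absent from the cohort"
            )
    cols = spec.columns(class_map)
    rows = []
    for r in cohort:
        vec = record_features(r, spec, table, class_map, epsilon)
        rows.append([np.nan if vec[c] is None else float(vec[c]) for c in cols])
    X = pd.DataFrame(rows, index=cohort.patient_ids, columns=cols, dtype=float)
    labels = cohort.labels
    y = None
    if all(lab is not None for lab in labels):
        y = np.array([1 if lab == MSI_H else 0 for lab in labels], dtype=int)
    return FeatureMatrix(X=X, spec=spec, y=y)
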