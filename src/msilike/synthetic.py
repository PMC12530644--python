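"""Synthetic cohort generation.

Emulates a 188-patient stage-II colorectal cohort with 24 MSI-H cases:
clinical categoricals drawn from per-stratum marginals matching the
published cohort's proportions, TIL percent cellularity drawn from
logit-normal distributions with stratum- and region-specific locations
(stromal > tumor, MSI-H enriched for macrophage/Treg compartments), and
per-gene Bernoulli mutation draws from a status-conditioned frequency
table. An optional fraction of MSS records is generated from the MSI-H
TIL/mutation parameters while keeping the MSS label — the MSI-H-like MSS
subpopulation the scorer is meant to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy.special import expit

from .core_data import (
    CELL_TYPES,
    MSI_H,
    MSS,
    REGIONS,
    ClinicalFeatures,
    Cohort,
    GeneFrequencyTable,
    MutationProfile,
    PatientRecord,
    TILProfile,
    ValidationError,
)
from .data import load_default_frequency_table

# Per-stratum clinical marginals mirroring the published cohort's
# proportions (MSS: n=164, MSI-H: n=24); probabilities are the printed
# count ratios. Right-sided disease and mucinous histology are enriched in
# MSI-H (67% vs 22%, 42% vs 16%).
DEFAULT_CLINICAL_MARGINALS: dict[str, dict[str, dict[str, float]]] = {
    "sex": {
        MSS: {"male": 93 / 164, "female": 71 / 164},
        MSI_H: {"male": 13 / 24, "female": 11 / 24},
    },
    "mucinous": {
        MSS: {"no": 138 / 164, "yes": 26 / 164},
        MSI_H: {"no": 14 / 24, "yes": 10 / 24},
    },
    "differentiation": {
        MSS: {"poor": 29 / 158, "moderate_to_well": 129 / 158},
        MSI_H: {"poor": 11 / 22, "moderate_to_well": 11 / 22},
    },
    "t_stage": {
        MSS: {"T3": 78 / 164, "T4": 86 / 164},
        MSI_H: {"T3": 10 / 24, "T4": 14 / 24},
    },
    "tumor_site": {
        MSS: {"right": 36 / 163, "left": 49 / 163, "rectum": 78 / 163},
        MSI_H: {"right": 16 / 24, "left": 3 / 24, "rectum": 5 / 24},
    },
    "lymphovascular_invasion": {
        MSS: {"no": 128 / 164, "yes": 36 / 164},
        MSI_H: {"no": 21 / 24, "yes": 3 / 24},
    },
    "perineural_invasion": {
        MSS: {"no": 119 / 164, "yes": 45 / 164},
        MSI_H: {"no": 17 / 24, "yes": 7 / 24},
    },
    "chemotherapy": {
        MSS: {"no": 68 / 164, "yes": 96 / 164},
        MSI_H: {"no": 8 / 24, "yes": 16 / 24},
    },
    "radiotherapy": {
        MSS: {"no": 142 / 155, "yes": 13 / 155},
        MSI_H: {"no": 21 / 23, "yes": 2 / 23},
    },
}

#: probability that age >= 65 / CEA >= 5, per stratum
DEFAULT_AGE_GE65 = {MSS: 68 / 164, MSI_H: 9 / 24}
DEFAULT_CEA_GE5 = {MSS: 56 / 164, MSI_H: 8 / 24}

#: cell types whose infiltration is shifted upward in MSI-H tumors
#: (macrophage/Treg compartments, strongest in the stromal region)
MSI_SHIFTED_CELLS = (
    "macrophage",
    "M1 macrophage",
    "M2 macrophage",
    "CD163+",
    "Treg",
    "FOXP3+",
    "PD-L1+",
    "PD-L1+ macrophage",
    "PD-L1+ M2 macrophage",
)

#: baseline logit-scale abundance per cell type (tumor region, MSS);
#: roughly 1-20% cellularity
_BASE_MU = {
    "CD3+": -1.6,
    "CD8+": -2.0,
    "memory T": -2.2,
    "CD8+ memory T": -2.8,
    "CD3+PD-1+": -3.0,
    "CD8+PD-1+": -3.4,
    "CD4+": -2.4,
    "Treg": -3.2,
    "FOXP3+": -3.0,
    "macrophage": -2.2,
    "M1 macrophage": -3.0,
    "M2 macrophage": -2.8,
    "CD163+": -2.6,
    "PD-L1+": -2.9,
    "PD-L1+ macrophage": -3.3,
    "PD-L1+ M2 macrophage": -3.6,
}

#: stromal regions are more infiltrated than tumor regions
_REGION_OFFSET = {"tumor": 0.0, "stromal": 0.8, "whole": 0.4}

#: MSI-H logit shift by region for the shifted cell types
_MSI_SHIFT = {"tumor": 0.8, "stromal": 1.4, "whole": 1.1}
#: mild global MSI-H shift for the remaining cell types
_MSI_SHIFT_OTHER = 0.3

_SIGMA = 0.6


def default_til_params() -> dict[tuple[str, str, str], tuple[float, float]]:
    """(cell_type, region, stratum) -> (mu, sigma) on the logit scale."""
    params = {}
    for cell in CELL_TYPES:
        for region in REGIONS:
            mu = _BASE_MU[cell] + _REGION_OFFSET[region]
            params[(cell, region, MSS)] = (mu, _SIGMA)
            shift = (
                _MSI_SHIFT[region]
                if cell in MSI_SHIFTED_CELLS
                else _MSI_SHIFT_OTHER
            )
            params[(cell, region, MSI_H)] = (mu + shift, _SIGMA)
    return params


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for cohort generation.

    Defaults encode the emulated cohort: 188 patients with exactly 24
    MSI-H, clinical marginals matching the published per-stratum
    proportions, logit-normal TIL distributions with MSI-H enrichment of
    macrophage/Treg compartments, Bernoulli mutations from the packaged
    status-conditioned frequency table, and 15% of MSS records generated
    from MSI-H TIL/mutation parameters (the MSI-H-like subpopulation).
    """

    n_patients: int = 188
    n_positive: int = 24
    clinical_marginals: Mapping = field(
        default_factory=lambda: DEFAULT_CLINICAL_MARGINALS
    )
    age_ge65: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_GE65)
    )
    cea_ge5: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CEA_GE5)
    )
    til_params: Mapping[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=default_til_params
    )
    frequency_table: Optional[GeneFrequencyTable] = None
    msi_like_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_positive < self.n_patients):
            raise ValidationError(
                f"need 0 < n_positive < n_patients, got "
                f"{self.n_positive}/{self.n_patients}"
            )
        if not (0.0 <= self.msi_like_fraction <= 1.0):
            raise ValidationError(
                f"msi_like_fraction out of [0,1]: {self.msi_like_fraction}"
            )

    def table(self) -> GeneFrequencyTable:
        return self.frequency_table or load_default_frequency_table()


def _draw_level(rng: np.random.Generator, probs: dict[str, float]) -> str:
    levels = list(probs)
    p = np.array([probs[lvl] for lvl in levels], dtype=float)
    p = p / p.sum()
    return levels[rng.choice(len(levels), p=p)]


def _simulate_record(
    rng: np.random.Generator,
    pid: str,
    label: str,
    param_stratum: str,
    config: SimulationConfig,
    table: GeneFrequencyTable,
) -> PatientRecord:
    # clinical features follow the *labelled* stratum's marginals; the
    # MSI-H-like swap applies to the TIL/mutation axes only
    clin_kwargs: dict = {}
    for name, per_stratum in config.clinical_marginals.items():
        clin_kwargs[name] = _draw_level(rng, per_stratum[label])
    ge65 = rng.random() < config.age_ge65[label]
    clin_kwargs["age_years"] = float(
        rng.integers(65, 86) if ge65 else rng.integers(40, 65)
    )
    ge5 = rng.random() < config.cea_ge5[label]
    clin_kwargs["cea_ng_ml"] = float(
        np.round(rng.uniform(5.0, 30.0) if ge5 else rng.uniform(0.5, 4.9), 2)
    )

    # tumor and stromal are drawn from their logit-normal parameters; the
    # whole-region value is a random convex mix of the two, so it always
    # respects the tumor/stromal envelope
    til_values = {}
    for cell in CELL_TYPES:
        for region in ("tumor", "stromal"):
            key = (cell, region, param_stratum)
            if key not in config.til_params:
                continue
            mu, sigma = config.til_params[key]
            v = 100.0 * expit(rng.normal(mu, sigma))
            til_values[(cell, region)] = float(np.clip(v, 0.0, 100.0))
        t = til_values.get((cell, "tumor"))
        s = til_values.get((cell, "stromal"))
        if t is not None and s is not None:
            w = rng.uniform(0.3, 0.7)
            til_values[(cell, "whole")] = float(w * t + (1 - w) * s)

    genes = set()
    for gene in table.genes:
        f = table.freq_msi(gene) if param_stratum == MSI_H else table.freq_mss(gene)
        if rng.random() < f:
            genes.add(gene)

    return PatientRecord(
        patient_id=pid,
        clinical=ClinicalFeatures(**clin_kwargs),
        til=TILProfile(til_values),
        mutations=MutationProfile(frozenset(genes)),
        msi_label=label,
        msi_like=(label == MSS and param_stratum == MSI_H) or None,
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a labeled cohort under the configured study conditions.

    Label counts are exact (stratified draw): ``n_positive`` MSI-H records
    and the rest MSS, of which a ``msi_like_fraction`` share (rounded)
    draws its TIL and mutation data from the MSI-H parameters while
    keeping the MSS label; those records carry ``msi_like=True``.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    table = config.table()
    n_mss = config.n_patients - config.n_positive
    n_like = int(round(config.msi_like_fraction * n_mss))
    like_idx = set(
        rng.choice(n_mss, size=n_like, replace=False).tolist()
    ) if n_like else set()

    records = []
    for i in range(config.n_positive):
        records.append(_simulate_record(
            rng, f"P{i + 1:04d}", MSI_H, MSI_H, config, table
        ))
    for j in range(n_mss):
        stratum = MSI_H if j in like_idx else MSS
        records.append(_simulate_record(
            rng, f"P{config.n_positive + j + 1:04d}", MSS, stratum, config, table
        ))
    return Cohort(
        records,
        provenance=(
            f"simulated: n={config.n_patients}, positives={config.n_positive}, "
            f"msi_like_fraction={config.msi_like_fraction}, seed={config.seed}"
        ),
    )


def simulate_null_cohort(config: SimulationConfig) -> Cohort:
    """Cohort whose labels are re-assigned independently of all features.

    Generates a clean two-stratum cohort, then permutes the MSI labels
    with the config seed, severing every feature-label association. Used
    for kappa null calibration and type-I error checks.
    """
    base = simulate_cohort(replace(config, msi_like_fraction=0.0))
    rng = np.random.default_rng(config.seed + 1)
    labels = [r.msi_label for r in base]
    perm = rng.permutation(len(labels))
    records = [
        replace(r, msi_label=labels[perm[i]], msi_like=None)
        for i, r in enumerate(base.records)
    ]
    return Cohort(records, provenance=base.provenance + "; labels permuted")


def recovery_config(seed: int = 0) -> SimulationConfig:
    """The clean strongly-signaled configuration used for parameter
    recovery: two clean strata (no MSI-H-like admixture), default signal
    sizes."""
    return SimulationConfig(msi_like_fraction=0.0, seed=seed)
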