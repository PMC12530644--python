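"""Domain types, cohort I/O, validation, and Table-1-style summarization.

The central object is a :class:`Cohort` of :class:`PatientRecord`, each
holding clinical/pathological categoricals, regional tumor-infiltrating
lymphocyte (TIL) measurements as percent cellularity, an optional mutated
gene set, and an optional microsatellite-status label (MSI-H vs MSS).

Missingness is first-class: an absent assay (``None``) is distinct from a
measured zero everywhere, because downstream model dispatch keys on which
whole feature blocks a patient actually has.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

MSI_H = "MSI-H"
MSS = "MSS"

#: canonical cell-type vocabulary for TIL measurements
CELL_TYPES = (
    "CD3+",
    "CD8+",
    "memory T",
    "CD8+ memory T",
    "CD3+PD-1+",
    "CD8+PD-1+",
    "CD4+",
    "Treg",
    "FOXP3+",
    "macrophage",
    "M1 macrophage",
    "M2 macrophage",
    "CD163+",
    "PD-L1+",
    "PD-L1+ macrophage",
    "PD-L1+ M2 macrophage",
)

REGIONS = ("tumor", "stromal", "whole")

CATEGORICAL_LEVELS = {
    "sex": ("male", "female"),
    "mucinous": ("no", "yes"),
    "differentiation": ("poor", "moderate_to_well"),
    "t_stage": ("T3", "T4"),
    "tumor_site": ("right", "left", "rectum"),
    "lymphovascular_invasion": ("no", "yes"),
    "perineural_invasion": ("no", "yes"),
    "chemotherapy": ("no", "yes"),
    "radiotherapy": ("no", "yes"),
}

#: columns summarize_cohort reports on, in Table-1 order
SUMMARY_VARIABLES = (
    "sex",
    "age_group",
    "mucinous",
    "differentiation",
    "t_stage",
    "tumor_site",
    "lymphovascular_invasion",
    "perineural_invasion",
    "cea_group",
    "chemotherapy",
    "radiotherapy",
)


class SchemaError(ValueError):
    """A file header or column layout does not match the cohort schema."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, enumeration, uniqueness)."""


def _check_level(name: str, value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    levels = CATEGORICAL_LEVELS[name]
    if value not in levels:
        raise ValidationError(
            f"unknown level {value!r} for {name}; expected one of {levels}"
        )
    return value


@dataclass(frozen=True)
class ClinicalFeatures:
    """Clinical/pathological record; every field may be None (missing).

    Boolean-like fields are stored as 'yes'/'no' strings so they share the
    categorical machinery; CEA is kept on its ng/ml scale and dichotomized
    at 5 only at encoding time.
    """

    sex: Optional[str] = None
    age_years: Optional[float] = None
    mucinous: Optional[str] = None
    differentiation: Optional[str] = None
    t_stage: Optional[str] = None
    tumor_site: Optional[str] = None
    lymphovascular_invasion: Optional[str] = None
    perineural_invasion: Optional[str] = None
    cea_ng_ml: Optional[float] = None
    chemotherapy: Optional[str] = None
    radiotherapy: Optional[str] = None

    def __post_init__(self) -> None:
        for name in CATEGORICAL_LEVELS:
            _check_level(name, getattr(self, name))
        for name in ("age_years", "cea_ng_ml"):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")

    def is_fully_missing(self) -> bool:
        return all(
            getattr(self, f) is None
            for f in list(CATEGORICAL_LEVELS) + ["age_years", "cea_ng_ml"]
        )


@dataclass(frozen=True)
class TILProfile:
    """Percent-cellularity measurements keyed by (cell_type, region).

    Values live on the 0-100 scale. Absent keys are missing measurements.
    """

    values: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = dict(self.values)
        for (cell, region), v in vals.items():
            if region not in REGIONS:
                raise ValidationError(f"unknown region {region!r} for {cell!r}")
            if cell not in CELL_TYPES:
                raise ValidationError(f"unknown cell type {cell!r}")
            if not math.isfinite(v) or not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"percent cellularity for ({cell}, {region}) out of [0, 100]: {v}"
                )
        object.__setattr__(self, "values", vals)
        self._soft_check_whole()

    def _soft_check_whole(self) -> None:
        # whole-region values should fall between tumor and stromal when all
        # three are measured; warn only (both acquisition modes are accepted)
        for cell in {c for c, _ in self.values}:
            t = self.values.get((cell, "tumor"))
            s = self.values.get((cell, "stromal"))
            w = self.values.get((cell, "whole"))
            if t is None or s is None or w is None:
                continue
            lo, hi = min(t, s), max(t, s)
            if not (lo - 1e-9 <= w <= hi + 1e-9):
                warnings.warn(
                    f"whole-region value {w} for {cell!r} outside "
                    f"[min, max] of tumor/stromal ({lo}, {hi})",
                    stacklevel=3,
                )

    def get(self, cell_type: str, region: str) -> Optional[float]:
        return self.values.get((cell_type, region))


@dataclass(frozen=True)
class MutationProfile:
    """Set of detected mutated gene symbols.

    ``genes=None`` means the assay was not run (a missing block); an empty
    set means the assay ran and found no mutation in the panel.
    """

    genes: Optional[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        if self.genes is not None:
            object.__setattr__(
                self, "genes", frozenset(g.upper() for g in self.genes)
            )

    @property
    def is_missing(self) -> bool:
        return self.genes is None


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    clinical: ClinicalFeatures = field(default_factory=ClinicalFeatures)
    til: TILProfile = field(default_factory=TILProfile)
    mutations: MutationProfile = field(default_factory=MutationProfile)
    msi_label: Optional[str] = None
    msi_like: Optional[bool] = None  # simulation truth flag, never a feature

    def __post_init__(self) -> None:
        if self.msi_label is not None and self.msi_label not in (MSI_H, MSS):
            raise ValidationError(
                f"msi_label must be {MSI_H!r} or {MSS!r}, got {self.msi_label!r}"
            )


@dataclass
class Cohort:
    """Ordered collection of patient records with unique patient ids."""

    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> list[Optional[str]]:
        return [r.msi_label for r in self.records]

    def msi_like_ids(self) -> list[str]:
        """Patient ids flagged as MSI-H-like at simulation time."""
        return [r.patient_id for r in self.records if r.msi_like]

    def til_columns(self) -> list[str]:
        cols: set[str] = set()
        for r in self.records:
            cols.update(f"{c}__{reg}" for c, reg in r.til.values)
        return sorted(cols)


@dataclass(frozen=True)
class GeneFrequencyTable:
    """Per-gene mutation frequencies conditioned on MSI status, plus priors.

    Houses P(g|MSI-H), P(g|MSS) per gene and the class priors
    P(MSI-H)/P(MSS) used by the naive-Bayes mutation posterior.
    """

    rows: Mapping[str, tuple[float, float]]
    prior_msi: float = 0.83
    prior_mss: float = 0.17

    def __post_init__(self) -> None:
        if abs(self.prior_msi + self.prior_mss - 1.0) > 1e-9:
            raise ValidationError(
                f"priors must sum to 1: {self.prior_msi} + {self.prior_mss}"
            )
        if not (0.0 <= self.prior_msi <= 1.0):
            raise ValidationError(f"prior_msi out of [0,1]: {self.prior_msi}")
        rows = {}
        for gene, (f_msi, f_mss) in dict(self.rows).items():
            g = gene.upper()
            if g in rows:
                raise ValidationError(f"duplicate gene in frequency table: {g}")
            for v in (f_msi, f_mss):
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(
                        f"frequency for {g} out of [0,1]: {v}"
                    )
            rows[g] = (float(f_msi), float(f_mss))
        object.__setattr__(self, "rows", rows)

    @property
    def genes(self) -> list[str]:
        return list(self.rows)

    def freq_msi(self, gene: str) -> float:
        return self.rows[gene][0]

    def freq_mss(self, gene: str) -> float:
        return self.rows[gene][1]


@dataclass(frozen=True)
class GeneClassMap:
    """Gene -> functional-class maps at two classification stringencies."""

    stringency_maps: Mapping[int, Mapping[str, str]]

    def __post_init__(self) -> None:
        maps = {}
        for s, m in dict(self.stringency_maps).items():
            if s not in (1, 2):
                raise ValidationError(f"stringency must be 1 or 2, got {s}")
            maps[s] = {g.upper(): c for g, c in dict(m).items()}
        object.__setattr__(self, "stringency_maps", maps)

    def classes(self, stringency: int) -> list[str]:
        if stringency not in self.stringency_maps:
            raise ValidationError(f"stringency {stringency} not defined")
        return sorted(set(self.stringency_maps[stringency].values()))

    def class_of(self, gene: str, stringency: int) -> Optional[str]:
        return self.stringency_maps[stringency].get(gene.upper())


# ---------------------------------------------------------------------------
# I/O

_CLINICAL_COLUMNS = list(CATEGORICAL_LEVELS) + ["age_years", "cea_ng_ml"]


def _parse_til_column(col: str) -> Optional[tuple[str, str]]:
    if "__" not in col:
        return None
    cell, _, region = col.rpartition("__")
    if cell in CELL_TYPES and region in REGIONS:
        return cell, region
    return None


def read_cohort(
    path: str | Path,
    *,
    sep: str = ",",
    percent_scale: str = "0-100",
    mutations_path: str | Path | None = None,
) -> Cohort:
    """Read a cohort from delimited text.

    The header must name ``patient_id``; clinical columns use the canonical
    field names; TIL columns are ``<cell_type>__<region>``; mutations are a
    ``mutations`` column with ``;``-separated gene symbols or a companion
    long-format file (patient_id, gene) given as ``mutations_path``. Empty
    cells become explicit missing values, never zeros.

    ``percent_scale='0-1'`` rescales TIL columns from proportions.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    if "patient_id" not in df.columns:
        raise SchemaError("header must contain a 'patient_id' column")

    til_cols: dict[str, tuple[str, str]] = {}
    known = {"patient_id", "mutations", "msi_label", "msi_like"}
    for col in df.columns:
        if col in known or col in _CLINICAL_COLUMNS:
            continue
        parsed = _parse_til_column(col)
        if parsed is None:
            raise SchemaError(
                f"unrecognized column {col!r}: not clinical, not "
                "'<cell_type>__<region>', not 'mutations'/'msi_label'"
            )
        til_cols[col] = parsed

    long_mut: dict[str, set[str]] = {}
    if mutations_path is not None:
        mdf = pd.read_csv(mutations_path, sep=sep, dtype=str)
        if not {"patient_id", "gene"} <= set(mdf.columns):
            raise SchemaError(
                "long-format mutation file must have columns patient_id, gene"
            )
        for pid, gene in zip(mdf["patient_id"], mdf["gene"]):
            long_mut.setdefault(str(pid), set()).add(str(gene))

    records = []
    scale = 100.0 if percent_scale == "0-1" else 1.0
    for idx, row in df.iterrows():
        pid = row["patient_id"]
        clin_kwargs: dict = {}
        for name in _CLINICAL_COLUMNS:
            if name not in df.columns:
                continue
            raw = row[name]
            if pd.isna(raw) or str(raw).strip() == "":
                continue
            if name in ("age_years", "cea_ng_ml"):
                clin_kwargs[name] = float(raw)
            else:
                clin_kwargs[name] = str(raw)
        til_values = {}
        for col, key in til_cols.items():
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() == "":
                continue
            v = float(raw) * scale
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"row {idx} ({pid}): TIL value {v} for {col!r} "
                    "outside [0, 100]"
                )
            til_values[key] = v

        if "mutations" in df.columns:
            raw = row["mutations"]
            # empty cell = assay not run; "-" = assay run, nothing detected
            if pd.isna(raw) or str(raw).strip() == "":
                mut = MutationProfile(genes=None)
            elif str(raw).strip() == "-":
                mut = MutationProfile(genes=frozenset())
            else:
                genes = {g.strip() for g in str(raw).split(";") if g.strip()}
                mut = MutationProfile(genes=frozenset(genes))
        elif mutations_path is not None:
            mut = MutationProfile(genes=frozenset(long_mut.get(str(pid), set())))
        else:
            mut = MutationProfile(genes=None)

        label = None
        if "msi_label" in df.columns and not pd.isna(row["msi_label"]):
            label = str(row["msi_label"])
        msi_like = None
        if "msi_like" in df.columns and not pd.isna(row["msi_like"]):
            msi_like = str(row["msi_like"]).lower() in ("1", "true", "yes")

        try:
            records.append(
                PatientRecord(
                    patient_id=str(pid),
                    clinical=ClinicalFeatures(**clin_kwargs),
                    til=TILProfile(til_values),
                    mutations=mut,
                    msi_label=label,
                    msi_like=msi_like,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx} ({pid}): {exc}") from exc
    return Cohort(records, provenance=f"read from {path}")


def write_cohort(cohort: Cohort, path: str | Path, *, sep: str = ",") -> None:
    """Write a cohort back to delimited text (inverse of :func:`read_cohort`)."""
    til_cols = cohort.til_columns()
    rows = []
    any_mut = any(not r.mutations.is_missing for r in cohort)
    any_like = any(r.msi_like is not None for r in cohort)
    for r in cohort:
        row: dict = {"patient_id": r.patient_id}
        for name in _CLINICAL_COLUMNS:
            row[name] = getattr(r.clinical, name)
        for col in til_cols:
            cell, _, region = col.rpartition("__")
            row[col] = r.til.get(cell, region)
        if any_mut:
            if r.mutations.is_missing:
                row["mutations"] = None
            elif not r.mutations.genes:
                row["mutations"] = "-"
            else:
                row["mutations"] = ";".join(sorted(r.mutations.genes))
        row["msi_label"] = r.msi_label
        if any_like:
            row["msi_like"] = r.msi_like
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_frequency_table(
    path: str | Path, *, priors_path: str | Path | None = None
) -> GeneFrequencyTable:
    """Read a gene-frequency table (CSV: gene, freq_msi, freq_mss).

    Priors come from a YAML/JSON sidecar (keys ``prior_msi``/``prior_mss``)
    or default to (0.83, 0.17), the MSI-H/MSS priors used by the posterior.
    """
    df = pd.read_csv(path)
    required = {"gene", "freq_msi", "freq_mss"}
    if not required <= set(df.columns):
        raise SchemaError(
            f"frequency table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    prior_msi, prior_mss = 0.83, 0.17
    if priors_path is not None:
        with open(priors_path) as fh:
            blob = yaml.safe_load(fh)
        prior_msi = float(blob["prior_msi"])
        prior_mss = float(blob["prior_mss"])
    rows = {
        str(g): (float(a), float(b))
        for g, a, b in zip(df["gene"], df["freq_msi"], df["freq_mss"])
    }
    if len(rows) != len(df):
        seen: set[str] = set()
        dupes = sorted(
            {str(g).upper() for g in df["gene"]
             if str(g).upper() in seen or seen.add(str(g).upper())}
        )
        raise ValidationError(f"duplicate gene(s) in frequency table: {dupes}")
    return GeneFrequencyTable(rows=rows, prior_msi=prior_msi, prior_mss=prior_mss)


def write_frequency_table(table: GeneFrequencyTable, path: str | Path) -> None:
    pd.DataFrame(
        [(g, f_msi, f_mss) for g, (f_msi, f_mss) in table.rows.items()],
        columns=["gene", "freq_msi", "freq_mss"],
    ).to_csv(path, index=False)


def read_gene_class_map(
    paths: Mapping[int, str | Path]
) -> GeneClassMap:
    """Read per-stringency two-column CSVs (gene, class)."""
    maps = {}
    for stringency, p in paths.items():
        df = pd.read_csv(p)
        if not {"gene", "class"} <= set(df.columns):
            raise SchemaError(
                f"class map {p} must have columns gene, class"
            )
        m: dict[str, str] = {}
        for g, c in zip(df["gene"], df["class"]):
            g = str(g).upper()
            if g in m and m[g] != str(c):
                raise ValidationError(
                    f"gene {g} maps to multiple classes at stringency {stringency}"
                )
            m[g] = str(c)
        maps[int(stringency)] = m
    return GeneClassMap(stringency_maps=maps)


# ---------------------------------------------------------------------------
# Table-1-style summarization


def _round_half_away(x: float) -> int:
    # Table-1 convention: 16/24 prints as 67, 12.5% prints as 13
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def _summary_level(record: PatientRecord, variable: str) -> Optional[str]:
    c = record.clinical
    if variable == "age_group":
        return None if c.age_years is None else ("<65" if c.age_years < 65 else ">=65")
    if variable == "cea_group":
        return None if c.cea_ng_ml is None else ("<5" if c.cea_ng_ml < 5 else ">=5")
    return getattr(c, variable)


def summary_levels(variable: str) -> tuple[str, ...]:
    if variable == "age_group":
        return ("<65", ">=65")
    if variable == "cea_group":
        return ("<5", ">=5")
    return CATEGORICAL_LEVELS[variable]


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-variable counts and integer column percentages per MSI stratum.

    Reproduces the layout of a clinical characteristics table: one row per
    (variable, level), columns for overall count and per-stratum
    ``n (percent)``, with percentages over the stratum's non-missing count
    for that variable, rounded half away from zero.
    """
    for r in cohort:
        if r.msi_label is None:
            raise ValidationError(
                f"record {r.patient_id!r} has no msi_label; summarization "
                "requires labeled records"
            )
    strata = {MSS: [r for r in cohort if r.msi_label == MSS],
              MSI_H: [r for r in cohort if r.msi_label == MSI_H]}
    out = []
    for variable in SUMMARY_VARIABLES:
        levels = summary_levels(variable)
        counts = {
            s: {lvl: 0 for lvl in levels} for s in strata
        }
        for s, recs in strata.items():
            for r in recs:
                lvl = _summary_level(r, variable)
                if lvl is not None:
                    counts[s][lvl] += 1
        denom = {s: sum(counts[s].values()) for s in strata}
        for lvl in levels:
            row = {
                "variable": variable,
                "level": lvl,
                "n_total": counts[MSS][lvl] + counts[MSI_H][lvl],
            }
            for s, key in ((MSS, "mss"), (MSI_H, "msi_h")):
                n = counts[s][lvl]
                row[f"n_{key}"] = n
                row[f"pct_{key}"] = (
                    _round_half_away(100.0 * n / denom[s]) if denom[s] else None
                )
            out.append(row)
    return pd.DataFrame(out)
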