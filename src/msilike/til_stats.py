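"""Tumor-infiltrating lymphocyte analytics: region contrasts, four-group
comparisons, the signed similarity statistic, 4D latent projection of cell
types, and complete-linkage hierarchical clustering.

Group contrasts are two-sided unpaired Mann-Whitney U tests with
family-wise (Bonferroni) or false-discovery-rate (Benjamini-Hochberg)
adjustment, depending on the analysis. Each cell type's four adjusted
group comparisons are mapped into a 4D latent space by

    similarity(former, latter) = p_adj / (median_f - median_l)   if medians differ
                                 p_adj                           otherwise

(the printed form p_adj * d / d^2 reduces algebraically to p_adj / d), and
cell types are clustered by Euclidean distance with complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .core_data import MSI_H, MSS, Cohort, ValidationError

#: the four ordered (former, latter) group comparisons, fixed order
FOUR_COMPARISONS = (
    ("all MSS", "MSI-H"),
    ("other MSS", "MSI-H"),
    ("other MSS", "MSI-H-like MSS"),
    ("MSI-H-like MSS", "MSI-H"),
)


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided unpaired Mann-Whitney U test.

    Returns (U for sample_a, two-sided p). Exact null enumeration when
    both samples have <= 8 observations and no ties; otherwise the normal
    approximation with midrank tie correction and continuity correction.
    If every value in both samples is identical the test is degenerate and
    p = 1.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size <= 8 and b.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Family-wise adjustment: min(1, m * p) elementwise."""
    p = _checked(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = _checked(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _checked(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    return p


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass(frozen=True)
class GroupComparison:
    """One cell type x one ordered group pair, with adjusted significance."""

    cell_type: str
    region: Optional[str]
    former_group: str
    latter_group: str
    median_former: float
    median_latter: float
    u_statistic: float
    p_raw: float
    p_adj: float

    @property
    def direction(self) -> int:
        if self.median_former > self.median_latter:
            return 1
        if self.median_former < self.median_latter:
            return -1
        return 0


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cell_type": c.cell_type,
            "region": c.region,
            "former": c.former_group,
            "latter": c.latter_group,
            "median_former": c.median_former,
            "median_latter": c.median_latter,
            "U": c.u_statistic,
            "p_raw": c.p_raw,
            "p_adj": c.p_adj,
            "direction": c.direction,
            "stars": significance_stars(c.p_adj),
        }
        for c in comparisons
    ])


def region_contrast(
    cohort: Cohort, cell_types: Sequence[str]
) -> list[GroupComparison]:
    """Stromal-vs-tumor contrast per cell type, Bonferroni-adjusted.

    For each cell type, all patients' stromal percent-cellularity values
    are compared with all tumor values by an unpaired two-sided U test;
    the Bonferroni family is the set of cell types tested. Cell types
    lacking values in either region are skipped with a warning.
    """
    tested: list[tuple[str, np.ndarray, np.ndarray]] = []
    for cell in cell_types:
        stromal = np.array([
            v for r in cohort
            if (v := r.til.get(cell, "stromal")) is not None
        ])
        tumor = np.array([
            v for r in cohort
            if (v := r.til.get(cell, "tumor")) is not None
        ])
        if stromal.size == 0 or tumor.size == 0:
            warnings.warn(
                f"region_contrast: {cell!r} lacks values in one region, skipped",
                stacklevel=2,
            )
            continue
        tested.append((cell, stromal, tumor))
    raw = []
    stats_u = []
    for cell, stromal, tumor in tested:
        u, p = mann_whitney_u(stromal, tumor)
        stats_u.append(u)
        raw.append(p)
    adj = bonferroni_adjust(raw)
    out = []
    for (cell, stromal, tumor), u, p, pa in zip(tested, stats_u, raw, adj):
        out.append(GroupComparison(
            cell_type=cell,
            region="stromal vs tumor",
            former_group="stromal",
            latter_group="tumor",
            median_former=float(np.median(stromal)),
            median_latter=float(np.median(tumor)),
            u_statistic=u,
            p_raw=p,
            p_adj=float(pa),
        ))
    return out


def _til_key(key: str) -> tuple[str, str]:
    cell, _, region = key.rpartition("__")
    return cell, region


def four_group_comparison(
    cohort: Cohort,
    calls: dict[str, bool],
    til_keys: Sequence[str],
    adjust_within: str = "comparison",
) -> list[GroupComparison]:
    """The four-group contrast battery for each ``<cell_type>__<region>``.

    Groups: MSI-H (by label), all MSS, MSI-H-like MSS (MSS records whose
    ``calls[patient_id]`` is true), other MSS. For each TIL key the four
    ordered comparisons are tested; BH adjustment runs within each
    comparison family across TIL keys (``adjust_within='comparison'``,
    matching a per-column heat-map reading) or over the whole battery
    (``adjust_within='all'``). Comparisons with an empty group are marked
    missing (NaN p values).
    """
    if adjust_within not in ("comparison", "all"):
        raise ValidationError(
            f"adjust_within must be 'comparison' or 'all', got {adjust_within!r}"
        )
    for r in cohort:
        if r.msi_label == MSS and r.patient_id not in calls:
            raise ValidationError(
                f"MSS record {r.patient_id!r} has no MSI-H-like call"
            )
    groups: dict[str, list] = {
        "MSI-H": [r for r in cohort if r.msi_label == MSI_H],
        "all MSS": [r for r in cohort if r.msi_label == MSS],
    }
    groups["MSI-H-like MSS"] = [
        r for r in groups["all MSS"] if calls[r.patient_id]
    ]
    groups["other MSS"] = [
        r for r in groups["all MSS"] if not calls[r.patient_id]
    ]

    records = []  # (cell, region, former, latter, median_f, median_l, U, p) or missing
    for key in til_keys:
        cell, region = _til_key(key)
        for former, latter in FOUR_COMPARISONS:
            fvals = np.array([
                v for r in groups[former]
                if (v := r.til.get(cell, region)) is not None
            ])
            lvals = np.array([
                v for r in groups[latter]
                if (v := r.til.get(cell, region)) is not None
            ])
            if fvals.size == 0 or lvals.size == 0:
                records.append((cell, region, former, latter,
                                np.nan, np.nan, np.nan, np.nan))
                continue
            u, p = mann_whitney_u(fvals, lvals)
            records.append((cell, region, former, latter,
                            float(np.median(fvals)), float(np.median(lvals)),
                            u, p))

    p_adj = np.full(len(records), np.nan)
    if adjust_within == "comparison":
        for former, latter in FOUR_COMPARISONS:
            idx = [
                i for i, rec in enumerate(records)
                if rec[2] == former and rec[3] == latter
                and not np.isnan(rec[7])
            ]
            if idx:
                p_adj[idx] = bh_adjust([records[i][7] for i in idx])
    else:
        idx = [i for i, rec in enumerate(records) if not np.isnan(rec[7])]
        if idx:
            p_adj[idx] = bh_adjust([records[i][7] for i in idx])

    return [
        GroupComparison(
            cell_type=cell, region=region,
            former_group=former, latter_group=latter,
            median_former=mf, median_latter=ml,
            u_statistic=u, p_raw=p, p_adj=float(pa),
        )
        for (cell, region, former, latter, mf, ml, u, p), pa
        in zip(records, p_adj)
    ]


def similarity(p_adj: float, median_former: float, median_latter: float) -> float:
    """Signed similarity coordinate for one group comparison.

    Equal medians return ``p_adj`` itself; otherwise the value is
    ``p_adj / (median_former - median_latter)`` — small when the groups are
    confidently different, large when they are indistinguishable, signed by
    which group sits higher. The blow-up as the median difference shrinks
    toward (but not to) zero is a property of the formula itself and is
    deliberately not smoothed.
    """
    if not (0.0 <= p_adj <= 1.0):
        raise ValidationError(f"p_adj must be in [0, 1], got {p_adj}")
    d = median_former - median_latter
    if d == 0.0:
        return p_adj
    return p_adj * d / (d * d)


@dataclass
class LatentVector:
    cell_type: str
    region: Optional[str]
    coordinates: np.ndarray  # one per FOUR_COMPARISONS entry, fixed order


@dataclass
class LinkageTable:
    """Agglomerative merge history plus deterministic leaf order."""

    merges: pd.DataFrame  # step, cluster_a, cluster_b, height, size
    leaf_order: list[str]
    scipy_linkage: np.ndarray
    labels: list[str]


def project_and_cluster(
    comparisons: Sequence[GroupComparison],
) -> tuple[list[LatentVector], LinkageTable]:
    """Project each cell type into 4D similarity space and cluster.

    Coordinates follow the fixed comparison order of
    :data:`FOUR_COMPARISONS`. Cell types missing any of the four
    comparisons (or with non-finite coordinates) are dropped with a
    warning. Clustering is agglomerative with Euclidean distance and
    complete linkage; leaves are pre-sorted lexicographically by
    ``cell_type__region`` so equal-distance merges resolve
    deterministically.
    """
    by_key: dict[tuple[str, str], dict[tuple[str, str], GroupComparison]] = {}
    for c in comparisons:
        by_key.setdefault((c.cell_type, c.region), {})[
            (c.former_group, c.latter_group)
        ] = c
    vectors = []
    for (cell, region) in sorted(by_key, key=lambda k: f"{k[0]}__{k[1]}"):
        comps = by_key[(cell, region)]
        if any(pair not in comps for pair in FOUR_COMPARISONS):
            warnings.warn(
                f"{cell!r}/{region!r}: incomplete comparison set, dropped",
                stacklevel=2,
            )
            continue
        coords = np.array([
            similarity(
                comps[pair].p_adj,
                comps[pair].median_former,
                comps[pair].median_latter,
            )
            for pair in FOUR_COMPARISONS
        ])
        if not np.all(np.isfinite(coords)):
            warnings.warn(
                f"{cell!r}/{region!r}: non-finite latent coordinates, dropped",
                stacklevel=2,
            )
            continue
        vectors.append(LatentVector(cell, region, coords))
    if len(vectors) < 2:
        raise ValidationError(
            f"clustering needs >= 2 cell types with complete comparisons, "
            f"got {len(vectors)}"
        )
    labels = [
        f"{v.cell_type}__{v.region}" if v.region else v.cell_type
        for v in vectors
    ]
    Z = linkage(
        np.vstack([v.coordinates for v in vectors]),
        method="complete", metric="euclidean",
    )
    merges = pd.DataFrame({
        "step": np.arange(len(Z)),
        "cluster_a": Z[:, 0].astype(int),
        "cluster_b": Z[:, 1].astype(int),
        "height": Z[:, 2],
        "size": Z[:, 3].astype(int),
    })
    leaf_order = [labels[i] for i in leaves_list(Z)]
    return vectors, LinkageTable(
        merges=merges, leaf_order=leaf_order, scipy_linkage=Z, labels=labels
    )
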