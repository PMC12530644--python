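import itertools
import math

import numpy as np
import pytest

import msilike as m
from msilike.core_data import (
    ClinicalFeatures,
    MutationProfile,
    PatientRecord,
    TILProfile,
)
from msilike.til_stats import (
    GroupComparison,
    bh_adjust,
    bonferroni_adjust,
    mann_whitney_u,
    region_contrast,
    similarity,
)


def exact_two_sided_p(a, b):
    """Brute-force enumeration oracle: distribution of U over all
    C(n+m, n) assignments of the pooled (tie-free) values to group a."""
    pooled = sorted(a) + sorted(b)
    pooled = np.asarray(sorted(pooled), dtype=float)
    n, mm = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    total = 0
    extreme = 0
    center = n * mm / 2.0
    for idx in itertools.combinations(range(n + mm), n):
        sel = set(idx)
        av = pooled[list(idx)]
        bv = pooled[[i for i in range(n + mm) if i not in sel]]
        u = sum(1 for x in av for y in bv if x > y)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_identical_samples_are_null(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(4.5)
        assert p > 0.9

    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_swap_mirrors_u_same_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(6), rng.random(4)
        ua, pa = mann_whitney_u(a, b)
        ub, pb = mann_whitney_u(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))
        assert pa == pytest.approx(pb)

    def test_degenerate_all_identical(self):
        u, p = mann_whitney_u([5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0
        assert u == pytest.approx(3.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(m.ValidationError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("na,nb", [(na, nb) for na in range(1, 6)
                                       for nb in range(1, 6)])
    def test_exact_agrees_with_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 7 + nb)
        a = rng.random(na).tolist()
        b = rng.random(nb).tolist()
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(exact_two_sided_p(a, b), abs=1e-12)


class TestAdjustments:
    def test_single_p_unchanged(self):
        assert bonferroni_adjust([0.03])[0] == pytest.approx(0.03)
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_bonferroni_hand_values(self):
        np.testing.assert_allclose(
            bonferroni_adjust([0.01, 0.4]), [0.02, 0.8])
        np.testing.assert_allclose(bonferroni_adjust([0.6, 0.7]), [1.0, 1.0])

    def test_bh_step_up_hand_values(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        # hand computation: sorted p*(m/rank) = .03, .045, .04, then
        # running minimum from the largest rank down -> .03, .04, .04
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_bh_preserves_input_order(self):
        p = [0.04, 0.01, 0.5, 0.02]
        adj = bh_adjust(p)
        perm = [1, 3, 0, 2]
        adj_perm = bh_adjust([p[i] for i in perm])
        for j, i in enumerate(perm):
            assert adj_perm[j] == pytest.approx(adj[i])

    def test_bonferroni_dominates_bh(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        assert np.all(bonferroni_adjust(p) >= bh_adjust(p) - 1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.random(15)
        assert np.all(bh_adjust(p) >= p - 1e-12)
        assert np.all(bonferroni_adjust(p) >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(m.ValidationError):
            bh_adjust([0.5, 1.2])


def _region_cohort(shift, n=40, seed=0):
    """Cohort where stromal = tumor + shift for two cell types."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        t1, t2 = rng.uniform(5, 20), rng.uniform(5, 20)
        records.append(PatientRecord(
            f"R{i:03d}",
            ClinicalFeatures(),
            TILProfile({
                ("CD8+", "tumor"): t1, ("CD8+", "stromal"): min(t1 + shift, 100),
                ("Treg", "tumor"): t2, ("Treg", "stromal"): min(t2 + shift, 100),
            }),
            MutationProfile(genes=None),
            msi_label="MSS",
        ))
    return m.Cohort(records)


class TestRegionContrast:
    def test_large_shift_all_significant(self):
        cohort = _region_cohort(shift=30.0)
        comps = region_contrast(cohort, ["CD8+", "Treg"])
        assert len(comps) == 2
        for c in comps:
            assert c.p_adj < 0.001
            assert c.direction == 1  # stromal above tumor

    def test_null_shift_not_significant(self):
        cohort = _region_cohort(shift=0.0)
        comps = region_contrast(cohort, ["CD8+", "Treg"])
        for c in comps:
            assert c.p_adj > 0.05

    def test_single_cell_type_bonferroni_identity(self):
        cohort = _region_cohort(shift=30.0)
        comps = region_contrast(cohort, ["CD8+"])
        assert comps[0].p_adj == pytest.approx(comps[0].p_raw)

    def test_absent_cell_type_skipped_with_warning(self):
        cohort = _region_cohort(shift=10.0)
        with pytest.warns(UserWarning, match="CD163"):
            comps = region_contrast(cohort, ["CD8+", "CD163+"])
        assert [c.cell_type for c in comps] == ["CD8+"]


class TestSimilarity:
    def test_equal_medians_return_p(self):
        assert similarity(0.07, 3.0, 3.0) == pytest.approx(0.07)

    def test_hand_values_and_sign(self):
        assert similarity(0.05, 3.0, 1.0) == pytest.approx(0.025)
        assert similarity(0.05, 1.0, 3.0) == pytest.approx(-0.025)

    def test_antisymmetry_on_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.random()
            m1, m2 = rng.uniform(0, 50, 2)
            if m1 == m2:
                continue
            assert similarity(p, m1, m2) == pytest.approx(
                -similarity(p, m2, m1), rel=1e-12)
            assert similarity(p, m1, m2) == pytest.approx(
                p / (m1 - m2), rel=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(m.ValidationError):
            similarity(1.5, 1.0, 2.0)


def _comparison(cell, region, former, latter, p_adj, mf, ml):
    return GroupComparison(
        cell_type=cell, region=region, former_group=former,
        latter_group=latter, median_former=mf, median_latter=ml,
        u_statistic=0.0, p_raw=p_adj, p_adj=p_adj)


def _full_set(cell, coords):
    out = []
    for (former, latter), c in zip(m.FOUR_COMPARISONS, coords):
        # encode coordinate c as p_adj = c with equal medians
        out.append(_comparison(cell, "stromal", former, latter, c, 1.0, 1.0))
    return out


class TestProjectAndCluster:
    def test_identical_cell_types_merge_at_zero(self):
        comps = _full_set("CD8+", [0.1, 0.2, 0.3, 0.4]) + \
            _full_set("Treg", [0.1, 0.2, 0.3, 0.4])
        vectors, link = m.project_and_cluster(comps)
        assert link.merges.height.iloc[0] == pytest.approx(0.0)

    def test_hand_traced_complete_linkage(self):
        # 1D coordinates 0, 0.3, 0.9 in the first axis: pairwise distances
        # 0.3, 0.6, 0.9 -> merge the closest pair at height 0.3, then
        # complete linkage puts the final merge at the max distance 0.9
        comps = (_full_set("CD3+", [0.0, 0.0, 0.0, 0.0])
                 + _full_set("CD8+", [0.3, 0.0, 0.0, 0.0])
                 + _full_set("Treg", [0.9, 0.0, 0.0, 0.0]))
        _, link = m.project_and_cluster(comps)
        assert link.merges.height.tolist() == pytest.approx([0.3, 0.9])
        assert np.all(np.diff(link.merges.height) >= -1e-12)

    def test_row_order_invariant(self):
        comps = (_full_set("CD3+", [0.2, 0.1, 0.5, 0.3])
                 + _full_set("CD8+", [0.9, 0.4, 0.2, 0.1])
                 + _full_set("Treg", [0.5, 0.5, 0.5, 0.5]))
        _, link_a = m.project_and_cluster(comps)
        _, link_b = m.project_and_cluster(list(reversed(comps)))
        assert link_a.leaf_order == link_b.leaf_order
        assert link_a.merges.equals(link_b.merges)

    def test_incomplete_cell_type_dropped(self):
        comps = (_full_set("CD3+", [0.2, 0.1, 0.5, 0.3])
                 + _full_set("CD8+", [0.9, 0.4, 0.2, 0.1])
                 + [_comparison("Treg", "stromal", "all MSS", "MSI-H",
                                0.5, 1.0, 1.0)])
        with pytest.warns(UserWarning, match="incomplete"):
            vectors, _ = m.project_and_cluster(comps)
        assert {v.cell_type for v in vectors} == {"CD3+", "CD8+"}

    def test_fewer_than_two_rejected(self):
        with pytest.raises(m.ValidationError):
            m.project_and_cluster(_full_set("CD8+", [0.1, 0.2, 0.3, 0.4]))


class TestFourGroup:
    def test_mss_record_without_call_rejected(self, recovery_cohort):
        with pytest.raises(m.ValidationError, match="call"):
            m.four_group_comparison(recovery_cohort, {}, ["CD8+__stromal"])

    def test_empty_group_marked_missing(self, recovery_cohort):
        calls = {r.patient_id: False
                 for r in recovery_cohort if r.msi_label == "MSS"}
        comps = m.four_group_comparison(
            recovery_cohort, calls, ["CD8+__stromal"])
        by_pair = {(c.former_group, c.latter_group): c for c in comps}
        assert math.isnan(
            by_pair[("MSI-H-like MSS", "MSI-H")].p_raw)
        assert not math.isnan(by_pair[("all MSS", "MSI-H")].p_raw)
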