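import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from blebpoint import (
    build_center_contingency,
    fisher_exact_2x2,
    mann_whitney_u,
    summarize,
    summarize_counts,
)
from blebpoint.exceptions import BlebpointError
from blebpoint.mesh_io import BLEB, NONBLEB
from blebpoint.region_stats import contingency_from_counts
from blebpoint.sampling import SamplePointSet
from blebpoint.synthetic_data import TABLE1_COUNTS


def fisher_oracle(table):
    """Exhaustive two-sided Fisher p by factorial enumeration (independent
    of the hypergeometric-pmf implementation path)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    denom = math.comb(n, c1)
    probs = []
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        probs.append((k, math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom))
    p_obs = dict(probs)[a]
    return min(1.0, sum(p for _, p in probs if p <= p_obs * (1 + 1e-7)))


def mwu_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p via midrank re-enumeration."""
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    mu = n_a * (n - n_a) / 2.0
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2.0

    u_obs = u_of(range(n_a))
    hits = total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_separated_groups_enumeration(self):
        """A={1,2,3} vs B={4,5,6}: U=0 and exact p=2/20."""
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5], mode="exact")
        assert p == 1.0

    def test_all_ties_u_is_half_product(self):
        u, p = mann_whitney_u([3.0] * 4, [3.0] * 6, mode="exact")
        assert u == 4 * 6 / 2
        assert p == 1.0
        u2, p2 = mann_whitney_u([3.0] * 4, [3.0] * 6, mode="normal_approx")
        assert u2 == u and p2 == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(BlebpointError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 7)
        u, p = mann_whitney_u(a, b, mode="exact")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.integers(0, 4, size=4).astype(float)
        b = rng.integers(0, 4, size=5).astype(float)
        _, p = mann_whitney_u(a, b, mode="exact")
        assert p == pytest.approx(mwu_exact_oracle(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_modes_agree_near_feasibility_boundary(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 10), rng.normal(0.3, 1, 12)
        _, p_exact = mann_whitney_u(a, b, mode="exact")
        _, p_approx = mann_whitney_u(a, b, mode="normal_approx")
        assert abs(p_exact - p_approx) < 0.01


class TestFisher:
    def test_published_tables(self):
        """The as_printed tables reproduce the published p-values."""
        assert fisher_exact_2x2([[2, 19], [2, 279]]) == pytest.approx(
            0.025, abs=5e-4
        )
        assert fisher_exact_2x2([[1, 11], [1, 135]]) == pytest.approx(
            0.156, abs=5e-4
        )
        assert fisher_exact_2x2([[1, 8], [1, 144]]) == pytest.approx(
            0.114, abs=5e-4
        )

    def test_conventional_pooled_table(self):
        assert fisher_exact_2x2([[2, 17], [2, 277]]) == pytest.approx(
            0.021, abs=5e-4
        )

    def test_degenerate_margin(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(BlebpointError):
            fisher_exact_2x2([[1, -2], [3, 4]])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.integers(0, 40), st.integers(0, 40),
            st.integers(0, 40), st.integers(0, 40),
        )
    )
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_oracle(table), abs=1e-10
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.integers(0, 30), st.integers(0, 30),
            st.integers(0, 30), st.integers(0, 30),
        )
    )
    def test_invariant_under_row_and_column_swap(self, cells):
        a, b, c, d = cells
        p1 = fisher_exact_2x2([[a, b], [c, d]])
        p2 = fisher_exact_2x2([[d, c], [b, a]])  # both rows and columns swapped
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestContingency:
    def _point_set(self, n_bleb, n_nonbleb, centers_bleb, centers_nonbleb):
        n = n_bleb + n_nonbleb
        pts = SamplePointSet(
            points=np.zeros((n, 3)),
            anchor_faces=np.zeros(n, dtype=int),
            anchor_bary=np.tile([1.0, 0, 0], (n, 1)),
            spacing_d=0.5,
            region=np.array([BLEB] * n_bleb + [NONBLEB] * n_nonbleb),
        )
        for i in range(centers_bleb):
            pts.records[i].is_center = True
        for i in range(centers_nonbleb):
            pts.records[n_bleb + i].is_center = True
        return pts

    def test_as_printed_reproduces_pooled_published_table(self):
        pts = self._point_set(19, 279, 2, 2)
        table = build_center_contingency(pts, mode="as_printed")
        np.testing.assert_array_equal(table, [[2, 19], [2, 279]])

    def test_conventional_subtracts_centers(self):
        pts = self._point_set(19, 279, 2, 2)
        table = build_center_contingency(pts, mode="conventional")
        np.testing.assert_array_equal(table, [[2, 17], [2, 277]])

    def test_zero_centers(self):
        pts = self._point_set(5, 7, 0, 0)
        table = build_center_contingency(pts, mode="as_printed")
        np.testing.assert_array_equal(table[:, 0], [0, 0])

    def test_summarize_counts_pooled_matches_published(self):
        report = summarize_counts(TABLE1_COUNTS)
        pooled = report.pooled.centers
        assert pooled.centers_bleb == 2 and pooled.n_bleb == 19
        assert pooled.centers_nonbleb == 2 and pooled.n_nonbleb == 279
        assert pooled.p_value == pytest.approx(0.025, abs=5e-4)
        assert pooled.prevalence_bleb_pct == pytest.approx(10.5, abs=0.05)
        assert report.cases["case1"].centers.p_value == pytest.approx(
            0.156, abs=5e-4
        )
        assert report.cases["case2"].centers.p_value == pytest.approx(
            0.114, abs=5e-4
        )


class TestSummarize:
    def _measured_points(self, rng, shift=0.0):
        n_b, n_n = 12, 60
        pts = SamplePointSet(
            points=np.zeros((n_b + n_n, 3)),
            anchor_faces=np.zeros(n_b + n_n, dtype=int),
            anchor_bary=np.tile([1.0, 0, 0], (n_b + n_n, 1)),
            spacing_d=0.5,
            region=np.array([BLEB] * n_b + [NONBLEB] * n_n),
        )
        for i, rec in enumerate(pts.records):
            base = shift if i < n_b else 0.0
            rec.normalized_pressure = base + rng.normal(1.0, 0.05)
            rec.normalized_wss = abs(rng.normal(1.0, 0.3))
            rec.tawss = abs(rng.normal(8.0, 2.0))
            rec.osi = float(np.clip(rng.normal(0.01, 0.01), 0, 0.5))
        return pts

    def test_planted_pressure_shift_detected(self):
        rng = np.random.default_rng(0)
        pts = self._measured_points(rng, shift=0.15)  # 3 SD shift
        rep = summarize(pts)
        p = {x.parameter: x for x in rep.pooled.parameters}["normalized_pressure"]
        assert p.mean_bleb > p.mean_nonbleb
        assert p.p_value < 0.001

    def test_identical_groups_give_p_one(self):
        vals = np.arange(10.0)
        pts = SamplePointSet(
            points=np.zeros((20, 3)),
            anchor_faces=np.zeros(20, dtype=int),
            anchor_bary=np.tile([1.0, 0, 0], (20, 1)),
            spacing_d=0.5,
            region=np.array([BLEB] * 10 + [NONBLEB] * 10),
        )
        for i, rec in enumerate(pts.records):
            v = float(vals[i % 10])
            rec.normalized_pressure = v
            rec.normalized_wss = v
            rec.tawss = v
            rec.osi = 0.01
        rep = summarize(pts, mwu_mode="exact")
        for p in rep.pooled.parameters:
            assert p.p_value == 1.0

    def test_missing_osi_excluded_with_count(self):
        rng = np.random.default_rng(1)
        pts = self._measured_points(rng)
        pts.records[0].osi = float("nan")
        pts.records[20].osi = float("nan")
        rep = summarize(pts)
        p = {x.parameter: x for x in rep.pooled.parameters}["osi"]
        assert p.n_excluded == 2
        assert p.n_bleb + p.n_nonbleb == len(pts) - 2

    def test_group_counts_add_up(self):
        rng = np.random.default_rng(2)
        pts = self._measured_points(rng)
        rep = summarize(pts)
        assert rep.pooled.n_bleb + rep.pooled.n_nonbleb == len(pts)

    def test_per_case_blocks_present(self):
        rng = np.random.default_rng(3)
        pts = self._measured_points(rng)
        ids = np.array(["case1"] * 36 + ["case2"] * 36)
        rep = summarize(pts, per_case_ids=ids)
        assert set(rep.cases) == {"case1", "case2", "total"}

    def test_contingency_mode_choice_changes_fisher_table(self):
        pts = TestContingency()._point_set(19, 279, 2, 2)
        for rec in pts.records:
            rec.normalized_pressure = 1.0
            rec.normalized_wss = 1.0
            rec.tawss = 1.0
            rec.osi = 0.0
        rep_printed = summarize(pts, contingency_mode="as_printed")
        rep_conv = summarize(pts, contingency_mode="conventional")
        assert rep_printed.pooled.centers.p_value == pytest.approx(0.025, abs=5e-4)
        assert rep_conv.pooled.centers.p_value == pytest.approx(0.021, abs=5e-4)


def test_contingency_from_counts_modes():
    np.testing.assert_array_equal(
        contingency_from_counts(1, 11, 1, 135, "as_printed"), [[1, 11], [1, 135]]
    )
    np.testing.assert_array_equal(
        contingency_from_counts(1, 11, 1, 135, "conventional"),
        [[1, 10], [1, 134]],
    )
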