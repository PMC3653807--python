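"""AUC, thresholding, consensus and the three map-agreement statistics."""

import itertools

import numpy as np
import pytest

from sdmeval.map_eval import (BinaryMap, ScaleSettings, binarize,
                              cohens_kappa, compute_auc, consensus_map,
                              fuzzy_global_matching, fuzzy_kappa,
                              fuzzy_membership, pairwise_similarity,
                              select_threshold, theoretical_max_auc)


def bmap(arr, **kw) -> BinaryMap:
    return BinaryMap(grid=np.asarray(arr), **kw)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def auc_by_pair_enumeration(sp, sa) -> float:
    wins = sum(1.0 if p > a else 0.5 if p == a else 0.0
               for p in sp for a in sa)
    return wins / (len(sp) * len(sa))


def fgm_brute_force(a, b, radius, halving) -> float:
    """Exhaustive per-cell evaluation of the two-way fuzzy similarity."""
    a = np.asarray(a)
    b = np.asarray(b)
    nr, nc = a.shape

    def membership(grid, cat, i, j):
        best = 0.0
        for r in range(nr):
            for c in range(nc):
                d = np.hypot(r - i, c - j)
                if d <= radius and grid[r, c] == cat:
                    best = max(best, 2.0 ** (-d / halving))
        return best

    sims = []
    for i in range(nr):
        for j in range(nc):
            s_ab = membership(b, a[i, j], i, j)
            s_ba = membership(a, b[i, j], i, j)
            sims.append(min(s_ab, s_ba))
    return float(np.mean(sims))


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

class TestAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_multisets(self):
        assert compute_auc([0.3, 0.7], [0.7, 0.3]) == 0.5

    def test_partial_overlap_matches_enumeration(self):
        sp, sa = [0.8, 0.4], [0.6, 0.2]
        assert compute_auc(sp, sa) == 0.75 == auc_by_pair_enumeration(sp, sa)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        sp = rng.choice([0.1, 0.3, 0.5, 0.9], 17)
        sa = rng.choice([0.1, 0.3, 0.5, 0.9], 23)
        assert compute_auc(sp, sa) == pytest.approx(
            auc_by_pair_enumeration(sp, sa))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        sp, sa = rng.uniform(size=30), rng.uniform(size=40)
        base = compute_auc(sp, sa)
        for f in (np.exp, np.sqrt, lambda x: 3 * x + 1):
            assert compute_auc(f(sp), f(sa)) == pytest.approx(base)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([], [0.5])


class TestTheoreticalMaxAuc:
    @pytest.mark.parametrize("a,expected", [(0.0, 1.0), (1.0, 0.5),
                                            (0.4, 0.8)])
    def test_values(self, a, expected):
        assert theoretical_max_auc(a) == pytest.approx(expected)

    def test_monotone_decreasing(self):
        grid = np.linspace(0, 1, 11)
        vals = [theoretical_max_auc(a) for a in grid]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            theoretical_max_auc(1.2)


class TestSelectThreshold:
    def test_separable_midpoint(self):
        t, se, sp = select_threshold([0.9, 0.1], [1, 0])
        assert t == pytest.approx(0.5)
        assert se == sp == 1.0

    def test_matches_exhaustive_scan(self):
        scores = [0.9, 0.6, 0.4, 0.5, 0.3, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        t, se, sp = select_threshold(scores, labels)
        s = np.array(scores)
        y = np.array(labels)
        best_gap = min(
            abs(((s >= c) & (y == 1)).sum() / 3 - (~(s >= c) & (y == 0)).sum() / 3)
            for c in np.linspace(0, 1, 2001))
        assert abs(se - sp) == pytest.approx(best_gap, abs=1e-9)

    def test_inverted_labels_still_minimal(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=40)
        labels = (scores + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        _, se1, sp1 = select_threshold(scores, labels)
        _, se2, sp2 = select_threshold(scores, 1 - labels)
        for c in np.linspace(0, 1, 501):
            pred = scores >= c
            y = 1 - labels
            se = (pred & (y == 1)).sum() / (y == 1).sum()
            sp = (~pred & (y == 0)).sum() / (y == 0).sum()
            assert abs(se2 - sp2) <= abs(se - sp) + 1e-9

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_threshold([0.5, 0.5, 0.5], [1, 0, 1])


class TestBinarize:
    grid = np.array([[0.1, 0.5], [0.9, 0.3]])

    def test_extreme_thresholds(self):
        assert binarize(self.grid, 1.1).grid.sum() == 0
        assert binarize(self.grid, 0.05).grid.sum() == 4

    def test_threshold_inclusive(self):
        assert binarize(self.grid, 0.5).grid.tolist() == [[0, 1], [1, 0]]

    def test_idempotent_as_scores(self):
        b = binarize(self.grid, 0.5)
        again = binarize(b.grid.astype(float), 0.5)
        assert np.array_equal(b.grid, again.grid)


class TestConsensus:
    def test_strict_majority_of_fifty(self):
        base = np.zeros((1, 1))
        members26 = [bmap(np.ones((1, 1)))] * 26 + [bmap(base)] * 24
        members25 = [bmap(np.ones((1, 1)))] * 25 + [bmap(base)] * 25
        assert consensus_map(members26).grid[0, 0] == 1
        assert consensus_map(members25).grid[0, 0] == 0  # exact half -> absence

    def test_identical_members_idempotent(self):
        m = bmap(np.eye(4, dtype=int))
        assert np.array_equal(consensus_map([m, m, m]).grid, m.grid)

    def test_three_member_vote_matches_enumeration(self):
        rng = np.random.default_rng(3)
        members = [bmap(rng.integers(0, 2, (6, 6))) for _ in range(3)]
        out = consensus_map(members).grid
        for i, j in itertools.product(range(6), range(6)):
            votes = sum(m.grid[i, j] for m in members)
            assert out[i, j] == (1 if votes > 1.5 else 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            consensus_map([bmap(np.zeros((2, 2))), bmap(np.zeros((3, 3)))])


class TestCohensKappa:
    def test_identical_maps(self):
        m = bmap(np.array([[1, 0], [0, 1]]))
        assert cohens_kappa(m, m) == 1.0

    def test_independence_construction(self):
        a = bmap(np.array([[1, 1, 0, 0]]))
        b = bmap(np.array([[1, 0, 1, 0]]))
        assert cohens_kappa(a, b) == pytest.approx(0.0)

    def test_hand_computed_table(self):
        a = bmap(np.array([[1, 1, 1, 0]]))
        b = bmap(np.array([[1, 1, 0, 0]]))
        # Po = 0.75, Pe = 0.5 -> kappa = 0.5
        assert cohens_kappa(a, b) == pytest.approx(0.5)

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        a = bmap(rng.integers(0, 2, (20, 20)))
        b = bmap(rng.integers(0, 2, (20, 20)))
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))


class TestFuzzyMembership:
    def test_crisp_limit_radius_zero(self):
        g = np.array([[1, 0], [0, 1]])
        mp, ma = fuzzy_membership(g, radius_cells=0)
        assert np.array_equal(mp, g)
        assert np.array_equal(ma, 1 - g)

    def test_adjacent_cell_decay(self):
        # single presence in an absence field: absence membership at the
        # presence cell comes from distance-1 neighbours: 2**(-1/2)
        g = np.zeros((5, 5))
        g[2, 2] = 1
        mp, ma = fuzzy_membership(g, radius_cells=4, halving_distance_cells=2)
        assert ma[2, 2] == pytest.approx(2 ** (-0.5))
        assert mp[2, 2] == 1.0
        # presence membership decays with distance from (2, 2)
        assert mp[2, 3] == pytest.approx(2 ** (-0.5))
        assert mp[2, 4] == pytest.approx(2 ** (-1.0))

    def test_bounded_and_own_category_one(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 2, (15, 15))
        mp, ma = fuzzy_membership(g, radius_cells=3)
        assert (mp <= 1).all() and (ma <= 1).all()
        assert np.array_equal(np.where(g == 1, mp, ma), np.ones((15, 15)))


class TestFuzzyGlobalMatching:
    def test_identical_maps(self):
        rng = np.random.default_rng(6)
        m = bmap(rng.integers(0, 2, (12, 12)))
        assert fuzzy_global_matching(m, m) == 1.0

    def test_opposite_constant_maps(self):
        a = bmap(np.ones((10, 10)))
        b = bmap(np.zeros((10, 10)))
        assert fuzzy_global_matching(a, b, radius_cells=4) == 0.0

    def test_single_cell_shift_matches_brute_force(self):
        a = np.zeros((9, 9), dtype=int)
        b = np.zeros((9, 9), dtype=int)
        a[4, 4] = 1
        b[5, 5] = 1  # one-cell diagonal shift
        got = fuzzy_global_matching(bmap(a), bmap(b), 4, 2)
        want = fgm_brute_force(a, b, 4, 2)
        assert got == pytest.approx(want)

    def test_random_maps_match_brute_force(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, (8, 8))
        b = rng.integers(0, 2, (8, 8))
        got = fuzzy_global_matching(bmap(a), bmap(b), 3, 2)
        assert got == pytest.approx(fgm_brute_force(a, b, 3, 2))

    def test_fuzzy_credit_never_below_raw_agreement(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, (20, 20))
        b = rng.integers(0, 2, (20, 20))
        raw = (a == b).mean()
        assert fuzzy_global_matching(bmap(a), bmap(b)) >= raw - 1e-12

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        a, b = bmap(rng.integers(0, 2, (15, 15))), bmap(rng.integers(0, 2, (15, 15)))
        assert fuzzy_global_matching(a, b) == pytest.approx(
            fuzzy_global_matching(b, a))


class TestFuzzyKappa:
    def test_identical_maps(self):
        rng = np.random.default_rng(10)
        m = bmap(rng.integers(0, 2, (20, 20)))
        assert fuzzy_kappa(m, m, n_null=10, seed=0) == 1.0

    def test_crisp_limit_equals_cohens_kappa(self):
        rng = np.random.default_rng(11)
        a = bmap(rng.integers(0, 2, (50, 50)))
        b = bmap((rng.uniform(size=(50, 50)) < 0.4).astype(int))
        kf = fuzzy_kappa(a, b, radius_cells=0, n_null=2000, seed=1)
        assert kf == pytest.approx(cohens_kappa(a, b), abs=0.02)

    def test_independent_maps_score_near_zero(self):
        vals = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            a = bmap(rng.integers(0, 2, (30, 30)))
            b = bmap(rng.integers(0, 2, (30, 30)))
            vals.append(fuzzy_kappa(a, b, radius_cells=4, n_null=100,
                                    seed=s))
        assert abs(np.mean(vals)) < 0.05


class TestPairwiseSimilarity:
    settings = ScaleSettings(n_null=20, seed=0)

    def _maps(self, k, seed=12):
        rng = np.random.default_rng(seed)
        return [bmap(rng.integers(0, 2, (10, 10)), species_id="s",
                     algorithm_id="RF", replicate=i) for i in range(k)]

    def test_ten_maps_give_45_comparisons_per_scale(self):
        recs = pairwise_similarity(self._maps(10), self.settings)
        assert len(recs) == 3 * 45
        for scale in ("cell", "neighborhood", "global"):
            assert sum(r.scale == scale for r in recs) == 45

    def test_two_maps_give_one_per_scale(self):
        recs = pairwise_similarity(self._maps(2), self.settings)
        assert len(recs) == 3

    def test_statistics_symmetric_in_map_order(self):
        maps = self._maps(3)
        fwd = pairwise_similarity(maps, self.settings)
        rev = pairwise_similarity(maps[::-1], self.settings)
        fwd_vals = sorted((r.scale, round(r.statistic_value, 6)) for r in fwd
                          if r.scale != "neighborhood")
        rev_vals = sorted((r.scale, round(r.statistic_value, 6)) for r in rev
                          if r.scale != "neighborhood")
        # Kappa and FGM are exactly symmetric; fuzzy Kappa only up to MC
        # noise in the null, checked separately
        assert fwd_vals == rev_vals
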