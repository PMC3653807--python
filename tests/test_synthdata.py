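"""Synthetic environments, virtual species, sampling and classification."""

import numpy as np
import pytest

from sdmeval import synthdata
from sdmeval.synthdata import (ClassThresholds, build_target_group_background,
                               classify_species, generate_env_stack,
                               make_virtual_species, q3_distance,
                               sample_presences, sample_pseudo_absences)


def morans_i_rook(z: np.ndarray) -> float:
    """Independent Moran's I oracle with rook (4-neighbour) weights."""
    z = z - z.mean()
    num = 0.0
    w = 0
    num += (z[:-1, :] * z[1:, :]).sum() * 2
    w += 2 * z[:-1, :].size
    num += (z[:, :-1] * z[:, 1:]).sum() * 2
    w += 2 * z[:, :-1].size
    return float((z.size / w) * num / (z**2).sum())


class TestGenerateEnvStack:
    def test_deterministic_given_seed(self):
        a = generate_env_stack(3, (30, 30), 2.0, seed=5)
        b = generate_env_stack(3, (30, 30), 2.0, seed=5)
        c = generate_env_stack(3, (30, 30), 2.0, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_standardized(self):
        stack = generate_env_stack(4, (50, 50), 3.0, seed=1)
        for layer in stack.values:
            assert abs(layer.mean()) < 1e-9
            assert layer.std() == pytest.approx(1.0)

    def test_white_noise_has_no_autocorrelation(self):
        stack = generate_env_stack(2, (100, 100), 0.0, seed=2)
        assert abs(morans_i_rook(stack.values[0])) < 0.05

    def test_smoothing_induces_autocorrelation(self):
        stack = generate_env_stack(2, (100, 100), 4.0, seed=2)
        assert morans_i_rook(stack.values[0]) > 0.5

    @pytest.mark.parametrize("bad", [dict(n_layers=1, shape=(30, 30)),
                                     dict(n_layers=3, shape=(10, 30)),
                                     dict(n_layers=3, shape=(30, 30),
                                          autocorr_range_cells=-1.0)])
    def test_invalid_arguments(self, bad):
        kw = dict(n_layers=3, shape=(30, 30), autocorr_range_cells=1.0, seed=0)
        kw.update(bad)
        with pytest.raises(ValueError):
            generate_env_stack(**kw)


class TestMakeVirtualSpecies:
    def test_optimum_cell_has_suitability_one(self, small_stack):
        v = small_stack.layer("env01")[10, 10]
        vs = make_virtual_species(small_stack, ["env01"], {"env01": (v, 0.5)})
        assert vs.truth_suitability[10, 10] == pytest.approx(1.0)
        assert vs.truth_suitability.max() == pytest.approx(1.0)

    def test_range_mask_zeroes_outside(self, small_stack):
        mask = np.zeros(small_stack.shape, dtype=bool)
        mask[:20, :20] = True
        vs = make_virtual_species(small_stack, ["env01"],
                                  {"env01": (0.0, 1.0)}, range_mask=mask)
        assert (vs.truth_suitability[20:, :] == 0).all()
        assert vs.truth_suitability[:20, :20].max() == pytest.approx(1.0)

    def test_product_bound_for_two_drivers(self, small_stack):
        p1 = {"env01": (0.0, 1.0)}
        p2 = {"env02": (0.0, 1.0)}
        s1 = make_virtual_species(small_stack, ["env01"], p1).truth_suitability
        s2 = make_virtual_species(small_stack, ["env02"], p2).truth_suitability
        both = make_virtual_species(small_stack, ["env01", "env02"],
                                    {**p1, **p2}).truth_suitability
        # suitability surfaces are each rescaled to max 1, so compare the
        # un-rescaled product bound through the raw Gaussian responses
        raw1 = np.exp(-small_stack.layer("env01")**2 / 2)
        raw2 = np.exp(-small_stack.layer("env02")**2 / 2)
        raw_both = raw1 * raw2
        assert (raw_both <= raw1 + 1e-12).all()
        assert (raw_both <= raw2 + 1e-12).all()
        assert both.max() == pytest.approx(1.0)
        assert s1.max() == s2.max() == pytest.approx(1.0)

    def test_empty_driver_set_rejected(self, small_stack):
        with pytest.raises(ValueError, match="driver"):
            make_virtual_species(small_stack, [], {})


class TestSamplePresences:
    def test_exact_count_distinct(self, small_stack):
        vs = make_virtual_species(small_stack, ["env01"], {"env01": (0.0, 1.0)})
        cells = sample_presences(vs, 6, seed=3)
        assert len(cells) == 6
        assert len({tuple(c) for c in cells}) == 6

    def test_degenerate_mass_on_one_cell(self, small_stack):
        mask = np.zeros(small_stack.shape, dtype=bool)
        mask[7, 9] = True
        vs = make_virtual_species(small_stack, ["env01"],
                                  {"env01": (0.0, 1.0)}, range_mask=mask)
        assert sample_presences(vs, 1, seed=0).tolist() == [[7, 9]]

    def test_sampling_proportional_to_suitability(self, small_stack):
        # two-cell support with weights 0.75 / 0.25
        mask = np.zeros(small_stack.shape, dtype=bool)
        mask[0, 0] = mask[0, 1] = True
        vs = make_virtual_species(small_stack, ["env01"],
                                  {"env01": (0.0, 1.0)}, range_mask=mask)
        vs.truth_suitability[0, 0] = 0.75
        vs.truth_suitability[0, 1] = 0.25
        hits = sum(sample_presences(vs, 1, seed=s)[0][1] == 0
                   for s in range(2000))
        assert hits / 2000 == pytest.approx(0.75, abs=0.03)

    def test_reproducible_and_seed_sensitive(self, small_stack):
        vs = make_virtual_species(small_stack, ["env01"], {"env01": (0.0, 1.0)})
        a = sample_presences(vs, 20, seed=4)
        b = sample_presences(vs, 20, seed=4)
        c = sample_presences(vs, 20, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_many_requested(self, small_stack):
        mask = np.zeros(small_stack.shape, dtype=bool)
        mask[0, :3] = True
        vs = make_virtual_species(small_stack, ["env01"],
                                  {"env01": (0.0, 1.0)}, range_mask=mask)
        with pytest.raises(ValueError, match="3"):
            sample_presences(vs, 4, seed=0)


class TestQ3Distance:
    def test_single_pair(self):
        assert q3_distance(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0

    def test_collinear_points(self):
        pts = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [3.0, 0]])
        # pairwise distances {1,1,1,2,2,3}; Q3 by linear interpolation = 2
        assert q3_distance(pts) == pytest.approx(2.0)

    def test_identical_points(self):
        assert q3_distance(np.zeros((5, 2))) == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            q3_distance(np.array([[1.0, 1.0]]))


class TestClassifySpecies:
    T = ClassThresholds(rare_max=100, common_min=130, narrow_max_km=30,
                        wide_min_km=40)

    @pytest.mark.parametrize("occ,q3,label", [
        (50, 10.0, "NR"), (500, 100.0, "WC"), (50, 100.0, "WR"),
        (500, 10.0, "NC"), (115, 10.0, "unclear"), (50, 35.0, "unclear"),
    ])
    def test_labels(self, occ, q3, label):
        assert classify_species(occ, q3, self.T).label == label

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassThresholds(rare_max=200, common_min=100)


class TestTargetGroupBackground:
    def test_disjoint_union(self):
        a = np.array([[i, 0] for i in range(10)])
        b = np.array([[i, 1] for i in range(15)])
        assert len(build_target_group_background({"a": a, "b": b})) == 25

    def test_full_overlap(self):
        a = np.array([[1, 1], [2, 2]])
        assert len(build_target_group_background({"a": a, "b": a.copy()})) == 2

    def test_matches_set_union_oracle(self):
        rng = np.random.default_rng(6)
        pool = {f"s{i}": rng.integers(0, 30, size=(rng.integers(5, 50), 2))
                for i in range(16)}
        oracle = set()
        for arr in pool.values():
            oracle |= {tuple(c) for c in arr}
        bg = build_target_group_background(pool)
        assert {tuple(c) for c in bg} == oracle

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            build_target_group_background({"a": np.array([[1, 1]])})


class TestSamplePseudoAbsences:
    bg = np.array([[i, j] for i in range(5) for j in range(5)])

    def test_background_equals_presences_rejected(self):
        with pytest.raises(ValueError):
            sample_pseudo_absences(self.bg, self.bg, 1, seed=0)

    def test_exhaustive_draw_returns_complement(self):
        pres = self.bg[:5]
        out = sample_pseudo_absences(self.bg, pres, 20, seed=0)
        assert {tuple(c) for c in out} == {tuple(c) for c in self.bg[5:]}

    def test_never_returns_focal_presence(self):
        pres = self.bg[::3]
        pres_set = {tuple(c) for c in pres}
        for s in range(100):
            out = sample_pseudo_absences(self.bg, pres, 10, seed=s)
            assert not ({tuple(c) for c in out} & pres_set)

    def test_oversized_request_reports_maximum(self):
        with pytest.raises(ValueError, match="20"):
            sample_pseudo_absences(self.bg, self.bg[:5], 21, seed=0)


class TestSpeciesPool:
    def test_parameter_to_class_recovery(self):
        """Small range + few records -> NR; full grid + many -> WC."""
        stack = synthdata.generate_env_stack(6, (100, 100), 4.0, seed=21)
        pool = synthdata.generate_species_pool(
            stack, seed=22, record_counts=(6, 8, 13, 19, 29, 42, 62, 92, 136,
                                           202, 298, 440, 650, 961, 1419,
                                           2094))
        labels = [pool.classes[s].label for s in pool.species_ids]
        n_rec = [pool.occurrences[s].n_records for s in pool.species_ids]
        # the rarest narrow-masked species is NR, the most common
        # full-grid species is WC
        nr_candidates = [l for l, n in zip(labels, n_rec) if n <= 19]
        wc_candidates = [l for l, n in zip(labels, n_rec) if n >= 961]
        assert "NR" in nr_candidates
        assert "WC" in wc_candidates
        assert all(l in {"NR", "NC", "WR", "WC", "unclear"} for l in labels)

    def test_background_is_union_of_presences(self, small_pool):
        union = set()
        for occ in small_pool.occurrences.values():
            union |= {tuple(c) for c in occ.presence_cells}
        assert {tuple(c) for c in small_pool.background_cells} == union

    def test_pool_reproducible(self, small_stack):
        p1 = synthdata.generate_species_pool(small_stack, seed=7,
                                             record_counts=(6, 15, 40, 120))
        p2 = synthdata.generate_species_pool(small_stack, seed=7,
                                             record_counts=(6, 15, 40, 120))
        for a, b in zip(p1.species, p2.species):
            assert np.array_equal(a.truth_suitability, b.truth_suitability)
        for sid in p1.occurrences:
            assert np.array_equal(p1.occurrences[sid].presence_cells,
                                  p2.occurrences[sid].presence_cells)
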