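import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micdeg.mic_core import (
    PairedSample,
    characteristic_matrix,
    grid_budget,
    mic,
    mic_scores,
    mutual_information,
    optimize_partition,
)

from .oracle import best_mi_exhaustive, mic_exhaustive


class TestMutualInformation:
    @pytest.mark.parametrize("table,expected", [
        ([[3, 0], [0, 3]], 1.0),                    # perfect association
        ([[2, 2], [2, 2]], 0.0),                    # independence
        ([[2, 1], [1, 2]], 0.08170416594551044),    # hand-computed plug-in value
    ])
    def test_analytic_examples(self, table, expected):
        assert mutual_information(table) == pytest.approx(expected, abs=1e-12)

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros((0, 2)))
        with pytest.raises(ValueError):
            mutual_information([[2, -1], [1, 2]])

    @given(st.lists(st.lists(st.integers(0, 20), min_size=2, max_size=5),
                    min_size=2, max_size=5).filter(
        lambda t: len({len(r) for r in t}) == 1 and sum(map(sum, t)) > 0))
    @settings(max_examples=60, deadline=None)
    def test_bounded_by_log_min_dim(self, table):
        mi = mutual_information(table)
        a = np.asarray(table)
        assert -1e-12 <= mi <= np.log2(min(a.shape)) + 1e-12


class TestMic:
    def test_perfect_separation_is_one(self):
        x = np.r_[np.ones(6), np.zeros(6)]
        y = np.r_[np.full(6, 10.0), np.full(6, 1.0)]
        assert mic(PairedSample(x, y)) == pytest.approx(1.0, abs=1e-12)

    def test_constant_expression_is_zero(self):
        x = np.r_[np.ones(6), np.zeros(6)]
        assert mic(PairedSample(x, np.full(12, 3.0))) == 0.0

    def test_rejects_small_samples(self):
        with pytest.raises(ValueError):
            PairedSample(np.array([0, 1, 0]), np.array([1.0, 2.0, 3.0]))

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError):
            PairedSample(np.array([0, 1, 0, 1.0]), np.array([1.0, np.nan, 3.0, 4.0]))

    def test_symmetry_in_axes(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert mic(PairedSample(x, y)) == pytest.approx(
                mic(PairedSample(y, x)), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.integers(0, 2, 12).astype(float)
        x[:2] = [0, 1]  # ensure both classes
        y = rng.normal(size=12)
        base = mic(PairedSample(x, y))
        for f in (np.exp, lambda v: 3.0 * v + 7.0, lambda v: v ** 3):
            assert mic(PairedSample(x, f(y))) == pytest.approx(base, abs=1e-12)

    def test_within_unit_interval(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 20))
            s = PairedSample(rng.normal(size=n), rng.normal(size=n))
            assert 0.0 <= mic(s) <= 1.0

    def test_matches_oracle_on_continuous_pairs(self, rng):
        # both axes continuous (not just the binary-phenotype case)
        for _ in range(15):
            n = int(rng.integers(4, 11))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert mic(PairedSample(x, y)) == pytest.approx(
                mic_exhaustive(list(x), list(y)), abs=1e-12)


class TestCharacteristicMatrix:
    def test_perfectly_separated_2x2_entry(self):
        x = np.r_[np.ones(6), np.zeros(6)]
        y = np.r_[np.arange(6) + 10.0, np.arange(6)]
        cm = characteristic_matrix(PairedSample(x, y))
        assert cm.entries[(2, 2)] == pytest.approx(1.0, abs=1e-12)

    def test_constant_y_all_zero(self):
        x = np.r_[np.ones(6), np.zeros(6)]
        cm = characteristic_matrix(PairedSample(x, np.full(12, 5.0)))
        assert all(v == 0.0 for v in cm.entries.values())

    def test_entries_match_exhaustive_oracle(self, rng):
        for _ in range(5):
            x, y = rng.normal(size=10), rng.normal(size=10)
            cm = characteristic_matrix(PairedSample(x, y))
            for (nx, ny), val in cm.entries.items():
                want = best_mi_exhaustive(list(x), list(y), nx, ny) / np.log2(min(nx, ny))
                assert val == pytest.approx(want, abs=1e-12)

    def test_entries_in_unit_interval(self, rng):
        # larger n with a bigger budget exercises the DP path
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        cm = characteristic_matrix(PairedSample(x, y))
        assert cm.entries
        assert all(0.0 <= v <= 1.0 for v in cm.entries.values())


class TestOptimizePartition:
    @staticmethod
    def _dp_inputs(x_binary, y):
        order = np.argsort(y, kind="stable")
        return x_binary[order].astype(int), np.asarray(y)[order]

    def test_matches_bruteforce_fixed_binary_axis(self, rng):
        # free-axis optimum per bin count == exhaustive search over all cuts
        for _ in range(10):
            x = rng.integers(0, 2, 8).astype(float)
            x[:2] = [0, 1]
            y = rng.normal(size=8)
            rows, free = self._dp_inputs(x, y)
            got = optimize_partition(rows, free, 2, 4)
            for k in (2, 3, 4):
                want = best_mi_exhaustive(list(y), list(x), k, 2)
                assert got[k - 2] == pytest.approx(want, abs=1e-12)

    def test_constant_free_axis_gives_zero(self):
        rows = np.array([0, 1, 0, 1, 0, 1])
        free = np.full(6, 2.0)
        assert np.allclose(optimize_partition(rows, free, 2, 4), 0.0)

    def test_perfect_separation_two_bins(self):
        rows = np.array([0, 0, 0, 1, 1, 1])
        free = np.arange(6, dtype=float)
        got = optimize_partition(rows, free, 2, 2)
        assert got[0] == pytest.approx(1.0, abs=1e-12)

    def test_rejects_max_bins_below_two(self):
        with pytest.raises(ValueError):
            optimize_partition(np.array([0, 1, 0, 1]), np.arange(4.0), 2, 1)


class TestMicScores:
    def test_toy_dataset_scores(self):
        pheno = np.r_[np.ones(6, int), np.zeros(6, int)]
        mat = np.full((10, 12), 4.0)
        mat[1] = np.r_[np.full(6, 9.0), np.full(6, 2.0)]
        scores = mic_scores(mat, pheno)
        assert scores[1] == pytest.approx(1.0, abs=1e-12)
        others = np.delete(scores, 1)
        assert np.allclose(others, 0.0)

    def test_sample_order_invariance(self, rng):
        pheno = np.r_[np.ones(6, int), np.zeros(6, int)]
        mat = rng.normal(size=(20, 12))
        perm = rng.permutation(12)
        assert np.allclose(mic_scores(mat, pheno),
                           mic_scores(mat[:, perm], pheno[perm]), atol=1e-12)

    def test_rejects_single_class_phenotype(self, rng):
        with pytest.raises(ValueError):
            mic_scores(rng.normal(size=(5, 8)), np.zeros(8, int))

    def test_fast_path_equals_generic_exhaustive(self, rng):
        pheno = np.r_[np.ones(6, int), np.zeros(6, int)]
        mat = rng.normal(size=(40, 12))
        fast = mic_scores(mat, pheno)
        generic = np.array([mic(PairedSample(pheno.astype(float), row))
                            for row in mat])
        assert np.allclose(fast, generic, atol=1e-12)

    def test_de_genes_score_above_nonde(self, lognormal_group_1):
        from micdeg.simulate import DatasetSpec, generate_dataset
        ds = generate_dataset(lognormal_group_1,
                              DatasetSpec(n_genes=2000), rng=3)
        scores = mic_scores(ds.matrix, ds.phenotype)
        assert np.median(scores[ds.de_mask]) > np.median(scores[~ds.de_mask])

    def test_budget_floor_keeps_minimum_grid(self):
        assert grid_budget(4) == 4.0
        assert grid_budget(12) == pytest.approx(12 ** 0.6)
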