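import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthoset.infometrics import (
    BinaryProfilePair,
    OrthologMap,
    joint_entropy,
    mutual_information,
    pairwise_mi_screen,
    permutation_pvalue,
    shannon_entropy,
    state_probabilities,
)

from .conftest import make_activation

# ---------------------------------------------------------------------------
# independent oracles: direct evaluation over the 2x2 table
# ---------------------------------------------------------------------------


def oracle_entropy(counts):
    n = sum(counts)
    return -sum(c / n * np.log2(c / n) for c in counts if c > 0)


def oracle_mi(n00, n01, n10, n11):
    n = n00 + n01 + n10 + n11
    px = [(n00 + n01) / n, (n10 + n11) / n]  # x = 0, 1
    py = [(n00 + n10) / n, (n01 + n11) / n]  # y = 0, 1
    total = 0.0
    for (i, j), c in zip(itertools.product(range(2), range(2)), (n00, n01, n10, n11)):
        if c > 0:
            p = c / n
            total += p * np.log2(p / (px[i] * py[j]))
    return total


def vectors_from_counts(n00, n01, n10, n11):
    x = np.array([0] * n00 + [0] * n01 + [1] * n10 + [1] * n11, dtype=bool)
    y = np.array([0] * n00 + [1] * n01 + [0] * n10 + [1] * n11, dtype=bool)
    return x, y


binary_vec = st.lists(st.booleans(), min_size=2, max_size=30).map(np.array)


class TestEntropy:
    def test_half_on_probability_and_one_bit(self):
        x = np.array([True] * 13 + [False] * 13)
        p_off, p_on = state_probabilities(x)
        assert p_on == 0.5
        assert shannon_entropy(x) == pytest.approx(1.0)

    def test_degenerate_all_on(self):
        assert shannon_entropy(np.ones(10, dtype=bool)) == 0.0

    def test_two_of_eight(self):
        expected = -0.25 * np.log2(0.25) - 0.75 * np.log2(0.75)
        assert shannon_entropy(np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(0.8112781244591328)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([], dtype=bool))


class TestJointEntropy:
    def test_identical_profiles_degenerate_joint(self):
        x = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert joint_entropy(x, x) == pytest.approx(shannon_entropy(x))

    def test_uniform_2x2_is_two_bits(self):
        x, y = vectors_from_counts(1, 1, 1, 1)
        assert joint_entropy(x, y) == pytest.approx(2.0)

    def test_oracle_on_10_3_3_10(self):
        x, y = vectors_from_counts(10, 3, 3, 10)
        assert joint_entropy(x, y) == pytest.approx(oracle_entropy([10, 3, 3, 10]), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_entropy(np.array([True, False]), np.array([True, False, True]))


class TestMutualInformation:
    def test_complement_of_balanced_profile_is_one_bit(self):
        x = np.array([True, False] * 13)
        assert mutual_information(x, ~x) == pytest.approx(1.0)

    def test_independent_balanced_is_zero(self):
        x, y = vectors_from_counts(1, 1, 1, 1)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_oracle_all_tables_n_le_26(self):
        # every 2x2 contingency table with n <= 26
        for n in range(2, 27):
            for n00 in range(n + 1):
                for n01 in range(n - n00 + 1):
                    for n10 in range(n - n00 - n01 + 1):
                        n11 = n - n00 - n01 - n10
                        x, y = vectors_from_counts(n00, n01, n10, n11)
                        assert mutual_information(x, y) == pytest.approx(
                            max(oracle_mi(n00, n01, n10, n11), 0.0), abs=1e-12
                        )

    @settings(max_examples=200, deadline=None)
    @given(binary_vec, binary_vec)
    def test_symmetry_complement_and_bounds(self, x, y):
        m = min(len(x), len(y))
        x, y = x[:m], y[:m]
        if m < 2:
            return
        mi = mutual_information(x, y)
        assert mi == mutual_information(y, x)
        assert mi == pytest.approx(mutual_information(x, ~y), abs=1e-12)
        assert mi == pytest.approx(mutual_information(~x, y), abs=1e-12)
        assert -1e-12 <= mi <= min(shannon_entropy(x), shannon_entropy(y)) + 1e-12
        assert joint_entropy(x, y) <= shannon_entropy(x) + shannon_entropy(y) + 1e-12


class TestPermutationPvalue:
    def test_identical_nondegenerate_profiles_minimum_p(self):
        x = np.array([True, False] * 13)
        res = permutation_pvalue(x, x.copy(), n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.mi == pytest.approx(1.0)

    def test_constant_profile_gives_p_one(self):
        x = np.zeros(26, dtype=bool)
        y = np.array([True, False] * 13)
        res = permutation_pvalue(x, y, n_perm=200, seed=1)
        assert res.mi == 0.0
        assert res.p_value == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(26) < 0.5, rng.random(26) < 0.5
        a = permutation_pvalue(x, y, n_perm=500, seed=11)
        b = permutation_pvalue(x, y, n_perm=500, seed=11)
        assert a.p_value == b.p_value

    def test_null_pvalues_are_valid(self):
        # the discrete MI statistic ties heavily, so permutation p-values are
        # superuniform (conservative), not uniform: check P(p <= a) <= a
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(400):
            x, y = rng.random(26) < 0.5, rng.random(26) < 0.5
            ps.append(permutation_pvalue(x, y, n_perm=200, rng=rng).p_value)
        ps = np.asarray(ps)
        for a in (0.01, 0.05, 0.1, 0.25):
            assert ps[ps <= a].size / ps.size <= a + 3 * np.sqrt(a * (1 - a) / ps.size)

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.array([True, False]), np.array([False, True]), n_perm=10)


class TestPairwiseMIScreen:
    def test_identical_matrices_reach_marginal_maximum(self):
        rng = np.random.default_rng(2)
        on = rng.random((5, 12)) < 0.5
        a = make_activation(on)
        b = make_activation(on)
        omap = OrthologMap(pairs=[(f"GS{i}", f"GS{i}") for i in range(5)])
        table, _ = pairwise_mi_screen(a, b, omap, n_perm=100, seed=0)
        for _, row in table.iterrows():
            x = on[int(row.id_a[2:])]
            assert row.mi_bits == pytest.approx(shannon_entropy(x), abs=1e-12)

    def test_unmapped_ids_reported(self):
        a = make_activation(np.zeros((2, 4), dtype=bool))
        b = make_activation(np.zeros((2, 4), dtype=bool))
        omap = OrthologMap(pairs=[("GS0", "GS0"), ("missing", "GS1")])
        with pytest.raises(KeyError, match="missing"):
            pairwise_mi_screen(a, b, omap, n_perm=100, seed=0)

    def test_multiplicity_preserved(self):
        rng = np.random.default_rng(4)
        on = rng.random((3, 10)) < 0.5
        a = make_activation(on)
        b = make_activation(on)
        omap = OrthologMap(pairs=[("GS0", "GS0"), ("GS0", "GS1"), ("GS0", "GS2"), ("GS1", "GS0")])
        table, _ = pairwise_mi_screen(a, b, omap, n_perm=100, seed=0)
        assert len(table) == 4

    def test_planted_anticorrelated_pairs_rank_top(self):
        from orthoset.diffexpr import binarize_genesets
        from orthoset.synthetic import SyntheticTranslationConfig, generate_translation_dataset

        cfg = SyntheticTranslationConfig(
            n_genesets=100, seed=8, frac_anticorrelated=0.05, human_label_noise=0.0,
            rat_activation_rate=0.5, human_activation_rate=0.5,
        )
        ds = generate_translation_dataset(cfg)
        rat_on = binarize_genesets(ds.rat)
        rat_train = make_activation(
            rat_on.on[ds.train_stimulus_ids].to_numpy(),
            ids=list(rat_on.on.index),
            cols=ds.train_stimulus_ids,
        )
        table, _ = pairwise_mi_screen(
            rat_train, ds.human_labels_train, ds.ortholog_map, n_perm=100, seed=0
        )
        anti_ids = {f"r_GS{i:04d}" for i in np.flatnonzero(ds.anticorrelated)}
        top_half = set(table.iloc[: len(table) // 2].id_a)
        # anticorrelated pairs carry as much MI as correlated ones
        assert len(anti_ids & top_half) >= len(anti_ids) / 2
        anti_rows = table[table.id_a.isin(anti_ids)]
        assert (anti_rows.pearson < 0).mean() > 0.8

    def test_null_tail_self_consistency(self):
        # independent matrices: the fraction of observed MI >= 0.15 bits
        # should match the permutation null's own tail estimate
        rng = np.random.default_rng(6)
        G, S = 246, 26
        a = make_activation(rng.random((G, S)) < 0.5)
        b = make_activation(rng.random((G, S)) < 0.5)
        omap = OrthologMap(pairs=[(f"GS{i}", f"GS{i}") for i in range(G)])
        bins = np.linspace(0, 1, 41)
        table, hist = pairwise_mi_screen(a, b, omap, n_perm=200, seed=0, hist_bins=bins)
        obs_tail = (table.mi_bits >= 0.15).mean()
        null_tail = hist.null_mean_count[hist.bin_left >= 0.15].sum() / G
        assert obs_tail == pytest.approx(null_tail, abs=0.05)
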