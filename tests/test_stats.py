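"""Agreement scores, permutation tests, entropy and correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rhythmcat import (CategoryLabel, EXCLUDED, agreement, permutation_test,
                       relative_entropy, snr_entropy_correlation)
from rhythmcat.categorize import Categorization
from rhythmcat.errors import (UndefinedCorrelationError, ValidationError)
from rhythmcat.stimuli import NO_METER

LABELS = [CategoryLabel((1, 1, k + 1)) for k in range(12)]


def _cat(labels, ids=None):
    ids = ids or [f"r{i}" for i in range(len(labels))]
    return Categorization(dict(zip(ids, labels)), NO_METER)


class TestAgreement:
    def test_identical_categorizations(self):
        a = _cat([LABELS[i % 3] for i in range(10)])
        res = agreement(a, a)
        assert res.n_compared == 10 and res.fraction == 1.0

    def test_disjoint_labelings(self):
        a = _cat([LABELS[0]] * 6)
        b = _cat([LABELS[1]] * 6)
        assert agreement(a, b).fraction == 0.0

    def test_exclusions_drop_before_counting(self):
        # 66 rhythms, 3 excluded, 42 of the rest agreeing -> 42/63
        ids = [f"r{i}" for i in range(66)]
        a = _cat([LABELS[0]] * 66, ids)
        b_labels = [LABELS[0]] * 42 + [LABELS[1]] * 21 + [EXCLUDED] * 3
        b = _cat(b_labels, ids)
        res = agreement(a, b)
        assert (res.n_compared, res.n_agree) == (63, 42)
        assert res.fraction == pytest.approx(42 / 63)

    @given(st.lists(st.integers(0, 5), min_size=2, max_size=40))
    def test_symmetry(self, codes):
        rng = np.random.default_rng(len(codes))
        a = _cat([LABELS[c] for c in codes])
        b = _cat([LABELS[int(rng.integers(6))] for _ in codes])
        assert agreement(a, b) == agreement(b, a)

    def test_disjoint_id_sets_rejected(self):
        a = _cat([LABELS[0]], ids=["x"])
        b = _cat([LABELS[0]], ids=["y"])
        with pytest.raises(ValidationError):
            agreement(a, b)


class TestPermutationTest:
    def test_self_agreement_is_highly_significant(self):
        rng = np.random.default_rng(3)
        a = _cat([LABELS[int(rng.integers(12))] for _ in range(66)])
        res = permutation_test(a, a, n=10_000, tail="one", seed=11)
        assert res.observed == 66
        assert res.p_value <= 0.001

    def test_constant_labels_give_p_one(self):
        rng = np.random.default_rng(4)
        a = _cat([LABELS[int(rng.integers(12))] for _ in range(20)])
        b = _cat([LABELS[0]] * 20)
        for tail in ("one", "two"):
            assert permutation_test(a, b, n=500, tail=tail, seed=1).p_value == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        a = _cat([LABELS[int(rng.integers(12))] for _ in range(30)])
        b = _cat([LABELS[int(rng.integers(12))] for _ in range(30)])
        r1 = permutation_test(a, b, n=2000, seed=42)
        r2 = permutation_test(a, b, n=2000, seed=42)
        assert r1 == r2

    def test_invariance_under_consistent_relabeling(self):
        rng = np.random.default_rng(6)
        codes_a = [int(rng.integers(4)) for _ in range(30)]
        codes_b = [int(rng.integers(4)) for _ in range(30)]
        a1, b1 = _cat([LABELS[c] for c in codes_a]), _cat([LABELS[c] for c in codes_b])
        # map every label k -> k+4 in both categorizations
        a2 = _cat([LABELS[c + 4] for c in codes_a])
        b2 = _cat([LABELS[c + 4] for c in codes_b])
        p1 = permutation_test(a1, b1, n=1000, seed=9).p_value
        p2 = permutation_test(a2, b2, n=1000, seed=9).p_value
        assert p1 == p2

    def test_degenerate_input_rejected(self):
        a = _cat([LABELS[0]], ids=["x"])
        with pytest.raises(ValidationError):
            permutation_test(a, a, n=10)

    def test_two_tailed_variants_agree_on_extremes(self):
        rng = np.random.default_rng(7)
        a = _cat([LABELS[int(rng.integers(12))] for _ in range(66)])
        double = permutation_test(a, a, n=2000, tail="two", seed=1,
                                  tail_method="double")
        extreme = permutation_test(a, a, n=2000, tail="two", seed=1,
                                   tail_method="extreme_count")
        assert double.p_value <= 0.01 and extreme.p_value <= 0.01


class TestRelativeEntropy:
    def test_point_mass_is_zero(self):
        assert relative_entropy([7, 0, 0]) == 0.0

    @pytest.mark.parametrize("k", [2, 5, 12])
    def test_uniform_is_one(self, k):
        assert relative_entropy(np.ones(k)) == pytest.approx(1.0)

    def test_two_equal_counts(self):
        assert relative_entropy([3, 3]) == pytest.approx(1.0)

    def test_available_category_denominator(self):
        # uniform over 3 observed of 12 available: log 3 / log 12
        got = relative_entropy([1, 1, 1], k=12)
        assert got == pytest.approx(np.log(3) / np.log(12))

    @given(st.permutations(list(range(1, 7))))
    def test_invariant_under_permutation(self, counts):
        assert relative_entropy(counts) == pytest.approx(
            relative_entropy(sorted(counts)))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            relative_entropy([0, 0])


class TestCorrelation:
    @staticmethod
    def _tables(snr_values, entropy_values):
        base = {"k1": range(len(snr_values)), "k2": 0, "k3": 0}
        return (pd.DataFrame({**base, "snr": snr_values}),
                pd.DataFrame({**base, "rel_entropy": entropy_values}))

    def test_perfect_anticorrelation(self):
        snr_t, ent_t = self._tables([1, 2, 3, 4.0], [4, 3, 2, 1.0])
        r, p = snr_entropy_correlation(snr_t, ent_t)
        assert r == pytest.approx(-1.0)

    def test_constant_entropy_undefined(self):
        snr_t, ent_t = self._tables([1, 2, 3.0], [1, 1, 1.0])
        with pytest.raises(UndefinedCorrelationError):
            snr_entropy_correlation(snr_t, ent_t)

    def test_too_few_pairs_rejected(self):
        snr_t, ent_t = self._tables([1, 2.0], [2, 1.0])
        with pytest.raises(ValidationError):
            snr_entropy_correlation(snr_t, ent_t)
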