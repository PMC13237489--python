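import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from cglkit.labelcheck import (PermutationScheme, composition_first_pc,
                               equal_frequency_bins, pair_agreement_analysis,
                               pair_label_permutation, permutation_stress_test,
                               permute_labels)
from cglkit.model import ActivityLabel
from cglkit.seqio import SequenceRecord


class TestPermuteLabels:
    @given(st.lists(st.integers(0, 2), min_size=2, max_size=60))
    @settings(max_examples=25, deadline=None)
    def test_global_scheme_preserves_label_multiset(self, labels):
        rng = np.random.default_rng(0)
        out = permute_labels(labels, PermutationScheme("global"), rng)
        assert sorted(out) == sorted(labels)

    def test_length_binned_preserves_per_bin_multisets(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(50, 400, size=80)
        labels = rng.integers(0, 2, size=80)
        scheme = PermutationScheme("length_binned", length_bins=10)
        out = permute_labels(labels, scheme, rng, lengths=lengths)
        bins = equal_frequency_bins(lengths, 10)
        for b in np.unique(bins):
            assert sorted(out[bins == b]) == sorted(labels[bins == b])

    def test_dual_scheme_partitions_into_25_strata(self):
        rng = np.random.default_rng(2)
        lengths = rng.integers(50, 400, size=200)
        pc = rng.standard_normal(200)
        lb = equal_frequency_bins(lengths, 5)
        cb = equal_frequency_bins(pc, 5)
        strata = lb * 5 + cb
        assert len(np.unique(strata)) == 25
        scheme = PermutationScheme("dual_restricted")
        out = permute_labels(rng.integers(0, 2, 200), scheme, rng,
                             lengths=lengths, composition_pc=pc)
        assert len(out) == 200

    def test_missing_covariate_is_an_error(self):
        with pytest.raises(ValueError):
            permute_labels([0, 1], PermutationScheme("length_binned"),
                           np.random.default_rng(0))


class TestEqualFrequencyBins:
    def test_equal_counts_without_ties(self):
        bins = equal_frequency_bins(np.arange(100), 10)
        assert all((bins == b).sum() == 10 for b in range(10))

    def test_tied_values_share_a_bin(self):
        bins = equal_frequency_bins([1, 1, 1, 1, 5, 6, 7, 8], 2)
        assert len(set(bins[:4])) == 1


class TestCompositionPC:
    def test_identical_sequences_identical_scores(self):
        scores = composition_first_pc(["MKTAY", "MKTAY", "ACDE"])
        assert scores[0] == scores[1] != scores[2]

    def test_two_letter_reduction_matches_analytic_eigenvector(self):
        # sequences over {A, C}: composition lives on a line, and the first
        # PC of a 2x2 covariance with equal variances is (1, -1)/sqrt(2)
        seqs = ["AAAA", "AACC", "CCCC", "ACCC"]
        scores = composition_first_pc(seqs)
        freq_a = np.array([s.count("A") / len(s) for s in seqs])
        centered = freq_a - freq_a.mean()
        expected = centered * np.sqrt(2)
        ratio = scores / expected
        np.testing.assert_allclose(abs(ratio), abs(ratio[0]), atol=1e-12)
        np.testing.assert_allclose(abs(scores), abs(expected), atol=1e-12)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            composition_first_pc(["ACD", ""])


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((120, 8))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    lengths = rng.integers(50, 300, 120)
    return X, y, lengths


class TestStressTest:

    def test_planted_signal_beats_all_nulls(self, planted):
        X, y, lengths = planted
        est = LogisticRegression(max_iter=500)
        nd = permutation_stress_test(
            X, y, est, PermutationScheme("global"), B=50,
            rng=np.random.default_rng(0), lengths=lengths)
        assert nd.b == 0
        assert nd.p == pytest.approx(1 / 51)
        assert nd.observed.macro_f1 > max(nd.null_scores)

    def test_observed_below_every_null_gives_p_one(self, planted):
        X, y, lengths = planted

        class WorseThanChance:
            """Predicts the planted rule inverted on true labels only."""
            def get_params(self, deep=True):
                return {}
            def set_params(self, **kw):
                return self
            def fit(self, X, y):
                self._flip = (y == (X[:, 0] + 0.5 * X[:, 1] > 0)).mean() > 0.9
                return self
            def predict(self, X):
                pred = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
                return 1 - pred if self._flip else pred

        nd = permutation_stress_test(
            X, y, WorseThanChance(), PermutationScheme("global"), B=30,
            rng=np.random.default_rng(1), lengths=lengths)
        assert nd.p == 1.0

    def test_b_must_be_positive(self, planted):
        X, y, lengths = planted
        with pytest.raises(ValueError):
            permutation_stress_test(X, y, LogisticRegression(),
                                    PermutationScheme("global"), B=0)


def _pair_records(n, seed):
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    recs = [SequenceRecord(f"r{i}", "".join(rng.choice(aa, 15)))
            for i in range(n)]
    labels = [ActivityLabel.HIGH if i < n // 3 else ActivityLabel.LOW
              for i in range(n)]
    return recs, labels


class TestPairAnalysis:
    def test_auc_matches_mann_whitney_pair_counting(self):
        recs, labels = _pair_records(12, seed=4)
        stats = pair_agreement_analysis(recs, labels, n_pairs=50,
                                        rng=np.random.default_rng(4),
                                        n_boot=10)
        t = stats.table
        y = t.record_labels
        same = y[t.idx_a] == y[t.idx_b]
        pos = t.identity[same]
        neg = t.identity[~same]
        wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        assert stats.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_rank_biserial_identity(self):
        recs, labels = _pair_records(12, seed=5)
        stats = pair_agreement_analysis(recs, labels, n_pairs=40,
                                        rng=np.random.default_rng(5),
                                        n_boot=10)
        assert stats.rank_biserial == pytest.approx(2 * stats.auc - 1,
                                                    abs=1e-12)

    def test_pair_count_capped_at_n_choose_2(self):
        recs, labels = _pair_records(6, seed=6)
        stats = pair_agreement_analysis(recs, labels, n_pairs=10**6,
                                        rng=np.random.default_rng(6),
                                        n_boot=5)
        assert stats.n_pairs == 15

    def test_pair_types_partition_all_pairs(self):
        recs, labels = _pair_records(10, seed=7)
        stats = pair_agreement_analysis(recs, labels, n_pairs=30,
                                        rng=np.random.default_rng(7),
                                        n_boot=5)
        assert sum(stats.pair_types.values()) == stats.n_pairs

    def test_none_labels_rejected(self):
        recs, _ = _pair_records(4, seed=8)
        with pytest.raises(ValueError):
            pair_agreement_analysis(recs, [ActivityLabel.NONE] * 4,
                                    n_pairs=3)


class TestPairPermutation:
    def test_degenerate_statistic_gives_p_one(self):
        # all identities equal: AUC is 0.5 under every labeling
        recs, labels = _pair_records(8, seed=9)
        recs = [SequenceRecord(r.record_id, "ACDEACDE") for r in recs]
        stats = pair_agreement_analysis(recs, labels, n_pairs=20,
                                        rng=np.random.default_rng(9),
                                        n_boot=5)
        pv = pair_label_permutation(stats.table, R=50,
                                    rng=np.random.default_rng(9))
        assert pv["auc"] == 1.0
        assert stats.auc == 0.5
        assert stats.rank_biserial == 0.0

    def test_identities_cached_not_recomputed(self):
        recs, labels = _pair_records(10, seed=10)
        stats = pair_agreement_analysis(recs, labels, n_pairs=20,
                                        rng=np.random.default_rng(10),
                                        n_boot=5)
        before = stats.table.identity.copy()
        pair_label_permutation(stats.table, R=20,
                               rng=np.random.default_rng(0))
        np.testing.assert_array_equal(stats.table.identity, before)

    def test_null_calibration_p_roughly_uniform(self):
        # random labels: fraction of p < 0.2 should be near 0.2
        rng = np.random.default_rng(11)
        recs, _ = _pair_records(14, seed=11)
        hits = 0
        runs = 40
        for _ in range(runs):
            labels = [ActivityLabel.HIGH if rng.random() < 0.4
                      else ActivityLabel.LOW for _ in recs]
            if sum(int(l) == 0 for l in labels) in (0, len(recs)):
                labels[0] = ActivityLabel.HIGH
                labels[1] = ActivityLabel.LOW
            stats = pair_agreement_analysis(recs, labels, n_pairs=40,
                                            rng=rng, n_boot=2)
            pv = pair_label_permutation(stats.table, R=49, rng=rng)
            hits += pv["auc"] <= 0.2
        assert 0.02 <= hits / runs <= 0.45
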