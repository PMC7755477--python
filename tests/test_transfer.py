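"""Fisher scoring and transfer-filter selection tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transfercsp import (ConfigurationError, DataError, FilterBank,
                         csp_filters, covariance_pair, fisher_scores,
                         select_transfer_filters)
from transfercsp.transfer import select_filters_from_features


def naive_fisher(x, y):
    """Direct summation oracle for the Fisher ratio."""
    x, y = np.asarray(x, float), np.asarray(y)
    classes = np.unique(y)
    n = len(x)
    out = np.empty(x.shape[1])
    for k in range(x.shape[1]):
        m = x[:, k].mean()
        sb = sum((y == c).sum() / n * (x[y == c, k].mean() - m) ** 2
                 for c in classes)
        sw = sum(((x[y == c, k] - x[y == c, k].mean()) ** 2).sum()
                 for c in classes) / n
        out[k] = sb / sw if sw > 0 else (np.inf if sb > 0 else 0.0)
    return out


def toy_bank(n_filters, eigenvalues=None):
    if eigenvalues is None:
        eigenvalues = np.linspace(0.9, 0.1, n_filters)
    half = n_filters // 2
    group = np.array(["high"] * half + (["mid"] if n_filters % 2 else [])
                     + ["low"] * half)
    return FilterBank(np.eye(n_filters), np.asarray(eigenvalues), group,
                      ("a", "b"))


class TestFisherScores:
    def test_worked_example(self):
        j = fisher_scores(np.array([[1], [2], [3], [4], [5], [6]], float),
                          ["a"] * 3 + ["b"] * 3)
        # S_between = 2.25, S_within = 2/3
        assert j[0] == pytest.approx(3.375, abs=1e-12)

    def test_identical_class_means_score_zero(self):
        j = fisher_scores(np.array([[1.], [3.], [1.], [3.]]), list("aabb"))
        assert j[0] == 0.0

    def test_perfect_separation_scores_infinite(self):
        j = fisher_scores(np.array([[1.], [1.], [2.], [2.]]), list("aabb"))
        assert np.isinf(j[0])

    def test_all_constant_scores_zero(self):
        j = fisher_scores(np.ones((4, 2)), list("aabb"))
        assert np.array_equal(j, [0.0, 0.0])

    def test_matches_naive_oracle_on_random_tables(self, rng):
        for _ in range(50):
            n = rng.integers(4, 12)
            d = rng.integers(1, 6)
            x = rng.standard_normal((n, d))
            y = rng.choice(["a", "b"], n)
            while len(np.unique(y)) < 2 or min((y == "a").sum(),
                                               (y == "b").sum()) < 2:
                y = rng.choice(["a", "b"], n)
            assert np.allclose(fisher_scores(x, y), naive_fisher(x, y),
                               atol=1e-10, rtol=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8), st.integers(1, 5))
    def test_fisher_matches_oracle_property(self, table_seed, per_class, dims):
        """Fisher ratio equals the direct-summation definition on arbitrary
        balanced two-class tables."""
        r = np.random.default_rng(table_seed)
        x = r.normal(scale=r.uniform(0.1, 10), size=(2 * per_class, dims))
        y = np.array(["a"] * per_class + ["b"] * per_class)
        assert np.allclose(fisher_scores(x, y), naive_fisher(x, y),
                           atol=1e-10, rtol=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            fisher_scores(np.ones((3, 1)), ["a"] * 3)

    def test_duplication_leaves_scores_unchanged(self, rng):
        x = rng.standard_normal((8, 3))
        y = np.array(list("aabbaabb"))
        doubled = fisher_scores(np.vstack([x, x]), np.concatenate([y, y]))
        assert np.allclose(fisher_scores(x, y), doubled, atol=1e-12)


class TestSelection:
    def _features(self, rng, n_trials, informative, n_filters=8, gap=3.0):
        """Random features where `informative` columns separate the classes."""
        x = rng.standard_normal((2 * n_trials, n_filters))
        y = np.array(["a"] * n_trials + ["b"] * n_trials)
        for col in informative:
            x[:n_trials, col] += gap
        return x, y

    def test_group_balance_and_monotonicity(self, rng):
        bank = toy_bank(8)
        x, y = self._features(rng, 10, informative=[1, 6])
        tbank, report = select_filters_from_features(bank, x, y, 2)
        sel = report.source_indices
        groups = bank.group[sel]
        assert (groups == "high").sum() == 2 and (groups == "low").sum() == 2
        j = report.scores
        for g in ("high", "low"):
            pool = np.flatnonzero(bank.group == g)
            picked = [i for i in sel if bank.group[i] == g]
            rejected = [i for i in pool if i not in picked]
            assert min(j[p] for p in picked) >= max(j[r] for r in rejected)

    def test_informative_filters_selected(self, rng):
        bank = toy_bank(8)
        x, y = self._features(rng, 20, informative=[1, 6], gap=5.0)
        _, report = select_filters_from_features(bank, x, y, 1)
        assert set(report.source_indices) == {1, 6}

    def test_full_selection_is_identity(self, rng):
        bank = toy_bank(8)
        x, y = self._features(rng, 6, informative=[0])
        tbank, _ = select_filters_from_features(bank, x, y, 4)
        assert np.array_equal(np.sort(tbank.source_indices), np.arange(8))
        assert np.array_equal(tbank.filters, bank.filters)

    def test_ties_broken_by_eigenvalue_extremity(self, rng):
        bank = toy_bank(8)
        x, y = self._features(rng, 10, informative=[], gap=0.0)
        x[:, 1] = x[:, 0]  # columns 0 and 1 tie exactly
        x[:10, 0] += 2.0
        x[:10, 1] += 2.0
        _, report = select_filters_from_features(bank, x, y, 1)
        high_pick = [i for i in report.source_indices
                     if bank.group[i] == "high"]
        assert high_pick == [0]  # more extreme eigenvalue wins the tie

    def test_middle_filter_of_odd_bank_never_selected(self, rng):
        bank = toy_bank(9)
        x, y = self._features(rng, 10, informative=[4], gap=10.0, n_filters=9)
        _, report = select_filters_from_features(bank, x, y, 2)
        assert 4 not in report.source_indices
        assert len(report.source_indices) == 4

    def test_output_sorted_by_source_eigenvalue(self, rng):
        bank = toy_bank(8)
        x, y = self._features(rng, 10, informative=[2, 5])
        tbank, _ = select_filters_from_features(bank, x, y, 2)
        assert np.all(np.diff(tbank.eigenvalues) <= 0)

    def test_too_few_target_trials_rejected(self, rng):
        bank = toy_bank(8)
        x = rng.standard_normal((3, 8))
        with pytest.raises(DataError):
            select_filters_from_features(bank, x, ["a", "a", "b"], 2)

    def test_k_out_of_range_rejected(self, rng):
        bank = toy_bank(8)
        x, y = self._features(rng, 5, informative=[0])
        with pytest.raises(ConfigurationError):
            select_filters_from_features(bank, x, y, 5)

    def test_overall_mode_may_unbalance_groups(self, rng):
        bank = toy_bank(8)
        x, y = self._features(rng, 20, informative=[0, 1, 2], gap=5.0)
        _, rep = select_filters_from_features(bank, x, y, 2,
                                              selection="overall")
        assert (bank.group[rep.source_indices] == "high").sum() == 3


class TestSelfTransfer:
    def test_self_transfer_selects_extreme_filters(self, quick_session):
        # source data = target data on a clean session: Fisher ranking agrees
        # with eigenvalue extremity, so transfer reduces to plain CSP
        epochs, _ = quick_session
        bank = csp_filters(covariance_pair(epochs, "LH", "RH"))
        tbank, rep = select_transfer_filters(bank, epochs, k_per_group=2,
                                             window_s=(0.0, 1.0))
        n = bank.n_filters
        assert set(rep.source_indices) == {0, 1, n - 2, n - 1}
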