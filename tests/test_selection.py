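"""Feature-selection contracts: information-theoretic primitives against
brute-force oracles, the closed-form Spearman identity, greedy pruning
soundness, and the two grid searches."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

import libspect as ls
from libspect.selection import (
    _greedy_prune,
    default_bins,
    discretize,
    mutual_information,
    spearman_matrix,
)


# ------------------------------------------------------------------ oracles


def brute_force_entropy(values) -> float:
    """Plain -sum p log2 p over explicit symbol counts."""
    values = list(values)
    total = len(values)
    h = 0.0
    for symbol in set(values):
        p = values.count(symbol) / total
        h -= p * np.log2(p)
    return h


def brute_force_mi(x, y) -> float:
    """I(X;Y) from the explicit joint count table, double loop."""
    x, y = list(x), list(y)
    n = len(x)
    mi = 0.0
    for a in set(x):
        for b in set(y):
            pab = sum(1 for i in range(n) if x[i] == a and y[i] == b) / n
            if pab == 0:
                continue
            pa = x.count(a) / n
            pb = y.count(b) / n
            mi += pab * np.log2(pab / (pa * pb))
    return mi


def spearman_closed_form(x, y) -> float:
    """Eq-style 1 - 6 sum d_i^2 / (n (n^2 - 1)); valid only without ties."""
    x, y = np.asarray(x), np.asarray(y)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    d = rx - ry
    n = len(x)
    return 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))


# ------------------------------------------------------------------ entropy


class TestEntropy:
    def test_degenerate_distribution_zero_bits(self):
        assert ls.entropy(["a"] * 10) == 0.0

    def test_fair_coin_one_bit(self):
        assert ls.entropy([0, 1, 0, 1]) == pytest.approx(1.0)

    def test_counts_1_1_2_is_1p5_bits(self):
        assert ls.entropy(["a", "b", "c", "c"]) == pytest.approx(1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ls.entropy([])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            v = rng.integers(0, 5, size=rng.integers(1, 40))
            assert ls.entropy(v) == pytest.approx(brute_force_entropy(list(v)))


# ---------------------------------------------------------------- mic_score


class TestMicScore:
    def test_injective_recoding_scores_one(self):
        labels = np.array(["A", "B", "C"] * 7)
        channel = np.array([1.0, 5.0, 9.0] * 7)
        assert ls.mic_score(channel, labels, bins=3) == pytest.approx(1.0)

    def test_independent_channel_scores_low(self, rng):
        labels = np.repeat(["A", "B"], 2500)
        channel = rng.standard_normal(5000)
        score = ls.mic_score(channel, labels)
        assert score < 0.05
        # cross-check against the brute-force contingency computation
        x = discretize(channel, default_bins(5000))
        denom = np.sqrt(brute_force_entropy(list(x)) * 1.0)
        assert score == pytest.approx(brute_force_mi(list(x), list(labels)) / denom, abs=1e-12)

    def test_twenty_sample_input_equals_contingency_oracle(self, rng):
        channel = rng.standard_normal(20)
        labels = rng.choice(["A", "B", "C"], size=20)
        while np.unique(labels).size < 2:
            labels = rng.choice(["A", "B", "C"], size=20)
        bins = 4
        x = discretize(channel, bins)
        expected = brute_force_mi(list(x), list(labels)) / np.sqrt(
            brute_force_entropy(list(x)) * brute_force_entropy(list(labels))
        )
        assert ls.mic_score(channel, labels, bins=bins) == pytest.approx(
            np.clip(expected, 0, 1)
        )

    def test_matches_oracle_on_many_small_instances(self, rng):
        # mirrors the exhaustive small-n oracle-equivalence property
        for _ in range(200):
            n = int(rng.integers(4, 51))
            channel = rng.standard_normal(n)
            labels = rng.integers(0, 3, size=n)
            if np.unique(labels).size < 2:
                continue
            bins = int(rng.integers(2, 8))
            x = discretize(channel, bins)
            hx, hy = brute_force_entropy(list(x)), brute_force_entropy(list(labels))
            expected = 0.0 if hx == 0 else np.clip(
                brute_force_mi(list(x), list(labels)) / np.sqrt(hx * hy), 0, 1
            )
            assert ls.mic_score(channel, labels, bins=bins) == pytest.approx(
                expected, abs=1e-12
            )

    def test_product_denominator_flag(self):
        labels = np.array(["A", "B"] * 10)
        channel = np.arange(20.0)
        s_sqrt = ls.mic_score(channel, labels, bins=2, denominator="sqrt")
        s_prod = ls.mic_score(channel, labels, bins=2, denominator="product")
        assert s_prod == pytest.approx(s_sqrt * s_sqrt)  # H(X)=H(Y)=1 bit here

    def test_errors(self):
        with pytest.raises(ValueError):
            ls.mic_score([1.0, 2.0], ["A", "B", "B"])
        with pytest.raises(ValueError):
            ls.mic_score([1.0, 2.0, 3.0], ["A", "A", "A"])


# ----------------------------------------------------------------- spearman


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.standard_normal(30)
        assert ls.spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        assert ls.spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_hand_worked_example_0p6(self):
        # ranks (1..5) vs (3,1,2,5,4): sum d^2 = 8 -> 1 - 48/120 = 0.6
        assert ls.spearman([1, 2, 3, 4, 5], [3, 1, 2, 5, 4]) == pytest.approx(0.6)

    def test_constant_vector_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert ls.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0

    def test_closed_form_on_all_tie_free_permutations_up_to_n6(self):
        for n in (3, 4, 5, 6):
            x = np.arange(n, dtype=float)
            for perm in itertools.permutations(range(n)):
                y = np.array(perm, dtype=float)
                assert ls.spearman(x, y) == pytest.approx(
                    spearman_closed_form(x, y), abs=1e-12
                )

    def test_matrix_agrees_with_pairwise_scipy(self, rng):
        X = rng.standard_normal((25, 6))
        X[:, 3] = np.round(X[:, 3])  # introduce ties
        M = spearman_matrix(X)
        for i in range(6):
            for j in range(6):
                assert M[i, j] == pytest.approx(
                    stats.spearmanr(X[:, i], X[:, j]).statistic, abs=1e-10
                )


# ------------------------------------------------------------ rank_channels


class TestRankChannels:
    def test_informative_channels_outrank_noise(self):
        cfg = ls.default_config(
            n_classes=3, spectra_per_class=40, n_channels=1200, seed=2,
            noise_sd=20.0, shot_noise_scale=0.05,
        )
        ds = ls.simulate_dataset(cfg)
        from libspect.simulate import informative_channels

        res = ls.rank_channels(ds)
        core = set(informative_channels(cfg, n_widths=1.0).tolist())
        line_adjacent = set(informative_channels(cfg, n_widths=5.0).tolist())
        noise_scores = [
            s for j, s in enumerate(res.mic_scores) if j not in line_adjacent
        ]
        core_top = sorted(
            (res.mic_scores[j] for j in core), reverse=True
        )[: len(core) // 2]
        # the strongest line-core channels clearly beat every far-from-line one
        assert min(core_top) > max(noise_scores)

    def test_tied_scores_rank_lower_index_first(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [1.0, 1.0], [2.0, 2.0]] * 3)
        ds = ls.SpectralDataset(
            wavelengths=[1.0, 2.0], intensities=x, labels=np.array(["A", "B"] * 6)
        )
        res = ls.rank_channels(ds, bins=2)
        assert res.mic_scores[0] == res.mic_scores[1]
        assert list(res.rank_order) == [0, 1]

    def test_shuffled_labels_concentrate_in_extremely_weak(self, small_dataset, rng):
        shuffled = ls.SpectralDataset(
            wavelengths=small_dataset.wavelengths,
            intensities=small_dataset.intensities,
            labels=rng.permutation(small_dataset.labels),
        )
        res = ls.rank_channels(shuffled)
        counts = res.category_counts()
        assert counts["extremely_weak"] > 0.9 * small_dataset.n_channels

    def test_single_class_rejected(self, small_dataset):
        mono = small_dataset.subset(small_dataset.labels == small_dataset.labels[0])
        with pytest.raises(ValueError):
            ls.rank_channels(mono)


# ------------------------------------------------------------------ pruning


class TestPruneRedundant:
    def _dataset(self, X):
        return ls.SpectralDataset(
            wavelengths=np.arange(X.shape[1], dtype=float),
            intensities=X,
            labels=np.array(["A", "B"] * (X.shape[0] // 2)),
        )

    def test_duplicated_channel_collapses(self, rng):
        base = rng.standard_normal(20)
        X = np.column_stack([base, base, rng.standard_normal(20)])
        ds = self._dataset(X)
        res = ls.rank_channels(ds, bins=4)
        pruned = ls.prune_redundant(ds, res, 0.9)
        assert 0 in pruned.selected or 1 in pruned.selected
        assert not (0 in pruned.selected and 1 in pruned.selected)

    def test_uncorrelated_channels_all_survive(self, rng):
        X = rng.standard_normal((40, 6))
        ds = self._dataset(X)
        res = ls.rank_channels(ds, bins=4)
        rho = np.abs(spearman_matrix(X))
        np.fill_diagonal(rho, 0)
        tau = rho.max() + 1e-6
        pruned = ls.prune_redundant(ds, res, min(tau, 1.0))
        assert pruned.selected.size == 6

    def test_greedy_result_satisfies_pairwise_constraint(self, rng):
        for _ in range(20):
            X = rng.standard_normal((30, 10))
            X[:, 5] = X[:, 0] + 0.01 * rng.standard_normal(30)
            X[:, 7] = -X[:, 1]
            kept = _greedy_prune(X, 0.8)
            rho = np.abs(spearman_matrix(X[:, kept]))
            np.fill_diagonal(rho, 0)
            assert np.all(rho <= 0.8 + 1e-12)
            assert kept[0] == 0  # first-ranked channel always kept

    def test_invalid_tau_rejected(self, small_dataset):
        res = ls.rank_channels(small_dataset)
        for tau in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                ls.prune_redundant(small_dataset, res, tau)


# ------------------------------------------------------------- grid search


@pytest.fixture(scope="module")
def separable_split():
    cfg = ls.noiseless_config(n_classes=3, spectra_per_class=20, n_channels=600, seed=9)
    return ls.split_dataset(ls.simulate_dataset(cfg), seed=9)


class TestGridSearch:
    def test_noiseless_accuracy_one_on_every_grid_point(self, separable_split):
        res = ls.grid_search_k(separable_split, "svm", 40, 120, 40)
        assert np.all(res.table["accuracy"].to_numpy() == 1.0)
        assert res.best == 40  # ties resolved to the smallest k

    def test_single_point_grid(self, small_split):
        res = ls.grid_search_k(small_split, "knn", 50, 50, 10)
        assert len(res.table) == 1
        assert res.best == 50

    def test_accuracies_within_unit_interval(self, small_split):
        res = ls.grid_search_k(small_split, "rf", 20, 100, 40)
        acc = res.table["accuracy"].to_numpy()
        assert np.all((acc >= 0) & (acc <= 1))

    def test_oversized_grid_truncated_with_warning(self, small_split):
        with pytest.warns(RuntimeWarning, match="truncated"):
            ls.grid_search_k(small_split, "knn", 50, 10_000, 500)

    def test_surviving_count_nondecreasing_in_tau(self, small_split):
        res = ls.grid_search_threshold(
            small_split, "knn", k=80, tau_min=0.5, tau_max=1.0, step=0.1
        )
        counts = res.table.sort_values("tau")["n_features"].to_numpy()
        assert np.all(np.diff(counts) >= 0)

    def test_tau_one_keeps_all_but_exact_duplicates(self, rng):
        base = rng.standard_normal(30)
        X = np.column_stack(
            [base, base.copy(), rng.standard_normal(30), rng.standard_normal(30)]
        )
        ds = ls.SpectralDataset(
            wavelengths=np.arange(4.0),
            intensities=X,
            labels=np.array(["A", "B"] * 15),
            split=np.array((["train"] * 20) + (["validation"] * 10), dtype=object),
        )
        res = ls.grid_search_threshold(ds, "knn", k=4, tau_min=1.0, tau_max=1.0, step=0.01)
        # at tau = 1 only the perfect duplicate is pruned
        assert res.table.iloc[0]["n_features"] == 3

    def test_duplicate_collapse_row_matches_hand_count(self, rng):
        base = rng.standard_normal(40)
        X = np.column_stack([base, base + 1e-9, rng.standard_normal(40)])
        ds = ls.SpectralDataset(
            wavelengths=np.arange(3.0),
            intensities=X,
            labels=np.array(["A", "B"] * 20),
            split=np.array((["train"] * 26) + (["validation"] * 14), dtype=object),
        )
        res = ls.grid_search_threshold(ds, "knn", k=3, tau_min=0.9, tau_max=0.99, step=0.09)
        # duplicated pair has |rho| = 1 > tau on every row -> 2 survivors
        assert set(res.table["n_features"]) == {2}
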