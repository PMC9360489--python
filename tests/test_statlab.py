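"""Spearman bands, empirical ROC/Youden, DeLong tests, bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from coreattn import (
    band_label,
    bootstrap_auc_ci,
    delong_test,
    delong_variance,
    roc_auc,
    spearman,
    youden_cutoff,
    youden_index,
)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(0, 1, 40)
        res = spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)
        assert spearman(x, -np.exp(x)).rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson(self, rng):
        x = rng.integers(0, 5, 50).astype(float)  # heavy ties
        y = rng.integers(0, 5, 50).astype(float)
        res = spearman(x, y)
        rho_oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(rho_oracle, abs=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(10), np.arange(10.0))

    def test_exact_permutation_p_for_tiny_n(self):
        x = np.arange(5.0)
        res = spearman(x, x * 2.0, method="exact")
        # only the 2 perfectly monotone pairings reach |rho| = 1
        assert res.p == pytest.approx(2 / 120)

    def test_band_attached(self, rng):
        x = rng.normal(0, 1, 30)
        res = spearman(x, x + rng.normal(0, 2.5, 30))
        assert res.band == band_label(res.rho)


@pytest.mark.parametrize(
    "rho, label",
    [
        (0.0, "slight"), (0.19, "slight"), (0.2, "fair"), (0.39, "fair"),
        (0.4, "moderate"), (0.596, "moderate"),
        (0.6, "substantial"), (0.637, "substantial"), (0.79, "substantial"),
        (0.8, "almost perfect"), (1.0, "almost perfect"),
        (-0.45, "moderate"),
    ],
)
def test_band_labels(rho, label):
    assert band_label(rho) == label


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _pair_count_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: concordant + half-tied pairs."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array([False] * 5 + [True] * 5)
        assert roc_auc(np.arange(10.0), labels) == 1.0

    def test_pure_ties_give_half(self):
        labels = np.array([False, True] * 5)
        assert roc_auc(np.ones(10), labels) == 0.5

    def test_label_flip_complements_auc(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = rng.random(30) < 0.5
        labels[:2] = [True, False]
        assert roc_auc(scores, ~labels) == pytest.approx(1 - roc_auc(scores, labels), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_pair_counting(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 30))
        scores = r.integers(0, 6, n).astype(float)  # force ties
        labels = r.random(n) < 0.5
        labels[0], labels[1] = True, False
        assert roc_auc(scores, labels) == pytest.approx(
            _pair_count_auc(scores, labels), abs=1e-10
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc(np.arange(4.0), np.array([True] * 4))


class TestYouden:
    def test_printed_youden_identities(self):
        """Se/Sp pairs reproduce their published Youden indices at 3 dp."""
        printed = [
            (93.75, 81.58, 0.753), (62.5, 84.21, 0.467),
            (72.22, 87.8, 0.600), (66.67, 95.12, 0.618),
            (81.82, 80.39, 0.622), (68.18, 88.24, 0.564),
        ]
        for se, sp, j in printed:
            assert round(youden_index(se, sp), 3) == j

    def test_perfect_separation_reaches_unit_j(self):
        labels = np.array([False] * 4 + [True] * 4)
        res = youden_cutoff(np.arange(8.0), labels)
        assert res.j == pytest.approx(1.0)
        assert res.sensitivity == 100.0 and res.specificity == 100.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_threshold_search(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 40))
        scores = r.integers(0, 8, n).astype(float)
        labels = r.random(n) < 0.4
        labels[0], labels[1] = True, False
        res = youden_cutoff(scores, labels)
        pos, neg = scores[labels], scores[~labels]
        best = -np.inf
        for c in np.concatenate(([-np.inf, np.inf], np.unique(scores))):
            j = (pos > c).mean() + (neg <= c).mean() - 1.0
            best = max(best, j)
        assert res.j == pytest.approx(best, abs=1e-10)
        # the returned operating point is self-consistent
        assert res.j == pytest.approx(
            res.sensitivity / 100 + res.specificity / 100 - 1, abs=1e-12
        )


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

# Frozen fixture cross-checked against an independent R implementation
# (pROC roc.test, method="delong", paired): z and p to 12 decimals.
DELONG_A = np.array([0.0012, 1.2987, -0.2741, 0.1094, -0.4547, 0.0084, 0.0601,
                     2.3402, -0.4922, 0.3795, 0.4898, 1.3569, 0.1054, 0.0695,
                     -0.0293, 1.6953, -1.3442, 0.5424, -1.9012, -0.2895])
DELONG_B = np.array([-1.4727, 0.5911, -1.1784, 0.2827, -0.1474, -0.1445, -1.9773,
                     0.9732, -0.3341, 0.3183, -0.9302, 0.4319, -0.7196, -0.6054,
                     0.8311, 0.3712, -0.8325, 1.033, -1.6076, -0.2631])
DELONG_LABELS = np.array([0, 1] * 10, dtype=bool)


class TestDelong:
    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(0, 1, 24)
        labels = rng.random(24) < 0.5
        labels[:2] = [True, False]
        res = delong_test(scores, scores, labels)
        assert res.z == 0.0 and res.p == 1.0

    def test_monotone_transform_is_null(self, rng):
        scores = rng.normal(0, 1, 24)
        labels = rng.random(24) < 0.5
        labels[:2] = [True, False]
        res = delong_test(scores, np.exp(scores) + 3.0, labels)
        assert res.auc_diff == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_against_independent_reference(self):
        res = delong_test(DELONG_A, DELONG_B, DELONG_LABELS)
        assert res.auc_a == pytest.approx(0.87, abs=1e-12)
        assert res.auc_b == pytest.approx(0.89, abs=1e-12)
        assert res.z == pytest.approx(-0.175261871351096, abs=1e-10)
        assert res.p == pytest.approx(0.860873870264063, abs=1e-10)

    def test_placement_value_oracle(self):
        """Structural components recomputed by brute force reproduce z and p."""
        a, b, labels = DELONG_A, DELONG_B, DELONG_LABELS
        pos_idx = np.flatnonzero(labels)
        neg_idx = np.flatnonzero(~labels)

        def components(s):
            v10 = [np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
                            for j in neg_idx]) for i in pos_idx]
            v01 = [np.mean([1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
                            for i in pos_idx]) for j in neg_idx]
            return np.array(v10), np.array(v01)

        v10a, v01a = components(a)
        v10b, v01b = components(b)
        m, n = len(pos_idx), len(neg_idx)
        auc_a, auc_b = v10a.mean(), v10b.mean()
        var = (np.var(v10a, ddof=1) + np.var(v10b, ddof=1)
               - 2 * np.cov(v10a, v10b, ddof=1)[0, 1]) / m \
            + (np.var(v01a, ddof=1) + np.var(v01b, ddof=1)
               - 2 * np.cov(v01a, v01b, ddof=1)[0, 1]) / n
        z = (auc_a - auc_b) / np.sqrt(var)
        res = delong_test(a, b, labels)
        assert res.z == pytest.approx(z, abs=1e-10)
        assert res.p == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-10)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            delong_test(np.arange(5.0), np.arange(6.0), np.array([True, False] * 3))

    def test_variance_matches_hanley_mcneil_for_exponential_scores(self):
        """Exponential special case: mean DeLong variance approaches the
        Hanley-McNeil closed form (AUC 0.75, 30 + 30 subjects)."""
        A, m, n = 0.75, 30, 30
        q1, q2 = A / (2 - A), 2 * A * A / (1 + A)
        hm = (A * (1 - A) + (m - 1) * (q1 - A * A) + (n - 1) * (q2 - A * A)) / (m * n)
        r = np.random.default_rng(2024)
        estimates = []
        for _ in range(400):
            s = np.concatenate([r.exponential(1.0, n), r.exponential(3.0, m)])
            lab = np.concatenate([np.zeros(n, bool), np.ones(m, bool)])
            estimates.append(delong_variance(s, lab)[1])
        assert np.mean(estimates) == pytest.approx(hm, rel=0.10)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_degenerate_perfect_marker(self):
        labels = np.array([False] * 6 + [True] * 6)
        lo, hi = bootstrap_auc_ci(np.arange(12.0), labels, n_boot=100, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_fixed_seed_reproducible(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        a = bootstrap_auc_ci(scores, labels, n_boot=200, seed=42)
        b = bootstrap_auc_ci(scores, labels, n_boot=200, seed=42)
        assert a == b

    def test_interval_brackets_point_estimate(self, rng):
        scores = rng.normal(0, 1, 60) + rng.random(60)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=300, seed=7)
        assert lo <= hi

    def test_too_few_samples_rejected(self):
        labels = np.array([False, True] * 4)
        with pytest.raises(ValueError, match="bootstrap"):
            bootstrap_auc_ci(np.arange(8.0), labels, n_boot=1, seed=0)
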