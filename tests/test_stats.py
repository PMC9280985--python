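"""Signed-rank test against enumeration oracles, Holm step-down, and the
exponential EMG-impulse fit."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as spstats

from neckcore.signal_model import ValidationError
from neckcore.stats import (
    fit_exponential,
    holm_bonferroni,
    ratio_table,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(diffs: np.ndarray, direction: str = "greater") -> float:
    """Exhaustive 2^n enumeration oracle for the one-tailed signed-rank p.

    Enumerates every sign assignment of the ranked absolute differences
    and counts assignments at least as extreme as the observed statistic.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = spstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if direction == "greater":
            count += w >= w_obs - 1e-9
        else:
            count += w <= w_obs + 1e-9
        total += 1
    return count / total


class TestWilcoxon:
    def test_all_positive_differences_extreme_p(self):
        pairs = [(0.0, 1.0), (0.0, 2.0), (0.0, 0.5), (0.0, 3.0), (0.0, 1.5)]
        res = wilcoxon_signed_rank(pairs, direction="greater")
        assert res.method == "exact"
        assert res.p_one_tailed == pytest.approx(1 / 32)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([(1.0, 1.0)] * 6)
        assert res.p_one_tailed == 1.0
        assert res.n_effective == 0
        assert res.method == "degenerate"

    def test_random_n8_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        d = rng.normal(size=8)
        pairs = np.column_stack([np.zeros(8), d])
        res = wilcoxon_signed_rank(pairs, direction="greater")
        assert res.p_one_tailed == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    @given(
        n=st.integers(min_value=2, max_value=12),
        seed=st.integers(min_value=0, max_value=10_000),
        direction=st.sampled_from(["greater", "less"]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_p_matches_oracle_up_to_n12(self, n, seed, direction):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=n)
        pairs = np.column_stack([np.zeros(n), d])
        res = wilcoxon_signed_rank(pairs, direction=direction)
        expected = brute_force_signed_rank_p(d, direction)
        assert res.p_one_tailed == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        control = rng.normal(size=14)
        manip = control + rng.normal(0.3, 1.0, size=14)
        res = wilcoxon_signed_rank(np.column_stack([control, manip]), "greater")
        ref = spstats.wilcoxon(manip, control, alternative="greater", method="exact")
        assert res.p_one_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_fall_back_to_corrected_normal(self):
        control = np.zeros(10)
        manip = np.array([1.0, 1.0, 1.0, -1.0, 2.0, 2.0, -2.0, 3.0, 3.0, 3.0])
        res = wilcoxon_signed_rank(np.column_stack([control, manip]), "greater")
        assert res.method == "normal_approx"
        ref = spstats.wilcoxon(
            manip, control, alternative="greater", method="approx", correction=True
        )
        assert res.p_one_tailed == pytest.approx(ref.pvalue, rel=1e-6)

    def test_direction_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=9), rng.normal(size=9)
        p_greater = wilcoxon_signed_rank(np.column_stack([a, b]), "greater").p_one_tailed
        p_less = wilcoxon_signed_rank(np.column_stack([b, a]), "less").p_one_tailed
        assert p_greater == pytest.approx(p_less, abs=1e-12)

    def test_statistic_bounds(self):
        rng = np.random.default_rng(11)
        d = rng.normal(size=20)
        res = wilcoxon_signed_rank(np.column_stack([np.zeros(20), d]))
        assert 0 <= res.w_plus <= 20 * 21 / 2


class TestHolm:
    def test_single_p_unchanged(self):
        fam = holm_bonferroni([0.02])
        assert fam.adjusted_p[0] == pytest.approx(0.02)

    def test_hand_computed_step_down(self):
        fam = holm_bonferroni([0.01, 0.04, 0.03])
        np.testing.assert_allclose(fam.adjusted_p, [0.03, 0.06, 0.06])

    def test_family_of_eight_smallest_p(self):
        raw = [0.0009] + [0.5] * 7
        fam = holm_bonferroni(raw, alpha=0.05)
        assert fam.adjusted_p[0] == pytest.approx(0.0072)
        assert fam.adjusted_p[0] < 0.008
        assert fam.reject[0] and not fam.reject[1:].any()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        raw = rng.uniform(0.001, 0.8, size=8)
        fam = holm_bonferroni(raw)
        _, ref, _, _ = multipletests(raw, method="holm")
        np.testing.assert_allclose(fam.adjusted_p, ref, rtol=1e-12)

    @given(seed=st.integers(min_value=0, max_value=9999))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_permutation_invariance_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(1e-4, 1.0, size=6)
        perm = rng.permutation(6)
        fam = holm_bonferroni(raw)
        fam_perm = holm_bonferroni(raw[perm])
        np.testing.assert_allclose(fam.adjusted_p[perm], fam_perm.adjusted_p, rtol=1e-12)
        assert np.all(fam.adjusted_p >= fam.raw_p - 1e-15)
        assert np.all(fam.adjusted_p <= 1.0)
        order = np.argsort(fam.raw_p)
        assert np.all(np.diff(fam.adjusted_p[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            holm_bonferroni([0.0, 0.5])
        with pytest.raises(ValidationError):
            holm_bonferroni([1.5])


class TestRatioTable:
    def test_identical_conditions_unit_ratio(self):
        per_subject = {
            "sternohyoid": {f"S{i}": (2.0 + i, 2.0 + i) for i in range(6)},
        }
        frame = ratio_table(per_subject)
        row = frame.iloc[0]
        assert row["mean_ratio"] == pytest.approx(1.0)
        assert row["raw_p"] == 1.0  # degenerate: all differences zero

    def test_nonpositive_baseline_excluded(self):
        per_subject = {"m": {"S1": (0.0, 1.0), "S2": (1.0, 2.0), "S3": (1.0, 3.0)}}
        frame = ratio_table(per_subject)
        assert frame.iloc[0]["n"] == 2
        assert frame.iloc[0]["n_excluded"] == 1

    def test_small_family_flagged_untested(self):
        frame = ratio_table({"m": {"S1": (1.0, 2.0)}})
        assert not frame.iloc[0]["tested"]
        assert np.isnan(frame.iloc[0]["raw_p"])

    def test_holm_applied_across_family(self):
        rng = np.random.default_rng(0)
        per_subject = {}
        for k, muscle in enumerate(["a", "b", "c"]):
            base = rng.uniform(1, 2, size=10)
            shift = 1.5 if muscle == "a" else 0.0
            per_subject[muscle] = {
                f"S{i}": (b, b + shift + 0.01 * rng.normal()) for i, b in enumerate(base)
            }
        frame = ratio_table(per_subject, direction="greater").set_index("muscle")
        assert frame.loc["a", "adjusted_p"] >= frame.loc["a", "raw_p"]
        assert frame.loc["a", "adjusted_p"] < 0.05
        assert frame.loc["a", "reject"]


class TestExponentialFit:
    def test_exact_model_recovery(self):
        x = np.linspace(0, 5, 10)
        y = 2.0 * np.exp(0.5 * x)
        fit = fit_exponential(x, y)
        assert fit.a == pytest.approx(2.0, abs=1e-4)
        assert fit.b == pytest.approx(0.5, abs=1e-4)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_degenerate_exponent(self):
        x = np.linspace(0, 10, 12)
        y = np.full(12, 3.7)
        fit = fit_exponential(x, y)
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        assert fit.a == pytest.approx(3.7, rel=1e-6)

    def test_noisy_recovery_within_10_percent(self):
        rng = np.random.default_rng(8)
        x = np.linspace(20, 200, 40)
        y = 1.5 * np.exp(0.012 * x)
        fits = []
        for seed in range(5):
            noisy = y * (1 + 0.05 * np.random.default_rng(seed).standard_normal(40))
            fits.append(fit_exponential(x, noisy))
        assert np.mean([f.a for f in fits]) == pytest.approx(1.5, rel=0.10)
        assert np.mean([f.b for f in fits]) == pytest.approx(0.012, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_exponential(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
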