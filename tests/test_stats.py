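"""Wilcoxon signed-rank, Mann-Kendall tau-b, cohort tables, bubble energy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from qpmorph import (
    CavitationParams,
    generate_cohort,
    mann_kendall_tau_b,
    rayleigh_bubble_energy,
    summarize_pairwise,
    trend_over_time,
    wilcoxon_signed_rank,
)
from qpmorph.synthetic import EffectModel


def brute_force_wilcoxon_p(x, y):
    """Exhaustive 2^n enumeration over sign assignments of |d| ranks."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    totals = np.array([
        sum(r for s, r in zip(signs, ranks) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    return min(1.0, 2.0 * min((totals <= w_obs).mean(), (totals >= w_obs).mean()))


def brute_force_tau_b(series):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    x = np.asarray(series, float)
    n = len(x)
    S = sum(np.sign(x[j] - x[i]) for i in range(n) for j in range(i + 1, n))
    D = n * (n - 1) / 2
    _, counts = np.unique(x, return_counts=True)
    Tx = sum(t * (t - 1) / 2 for t in counts)
    return S, S / np.sqrt((D - Tx) * D)


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        x = np.arange(8.0)
        with pytest.warns(UserWarning, match="all differences zero"):
            res = wilcoxon_signed_rank(x, x)
        assert res.p_value == 1.0 and not res.significant and res.degenerate

    def test_six_pair_example_matches_enumeration(self):
        y = np.zeros(6)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -6.0])
        res = wilcoxon_signed_rank(x, y)
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(x, y), abs=1e-12)
        assert res.statistic == 15.0  # ranks 1..5 positive

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        if seed % 3 == 0:  # force ties in |d| and some zeros
            x[: n // 2] = y[: n // 2] + rng.integers(0, 3)
        res = wilcoxon_signed_rank(x, y)
        if res.degenerate:
            return
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(x, y), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            res = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_power_against_unit_shift(self):
        """200 pairs with differences ~ N(1,1): overwhelmingly significant."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            y = rng.normal(0, 1, 200)
            x = y + rng.normal(1, 1, 200)
            if wilcoxon_signed_rank(x, y).p_value < 0.001:
                hits += 1
        assert hits >= 20 * 0.99

    def test_normal_approx_close_to_exact_at_threshold(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0.3, 1, 25)
        y = rng.normal(0, 1, 25)
        exact = wilcoxon_signed_rank(x, y, exact_threshold=25)
        approx = wilcoxon_signed_rank(x, y, exact_threshold=0)
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.15, abs=0.01)

    def test_pratt_zero_handling_differs_sanely(self):
        x = np.array([1.0, 2.0, 3.0, 3.0, 5.0, 7.0])
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        w = wilcoxon_signed_rank(x, y, zero_method="wilcox")
        p = wilcoxon_signed_rank(x, y, zero_method="pratt")
        assert w.n_zero_dropped == p.n_zero_dropped == 1
        assert 0 < p.p_value <= 1

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestMannKendall:
    def test_strictly_increasing(self):
        res = mann_kendall_tau_b(np.arange(8.0))
        assert res.tau_b == 1.0
        assert res.S_statistic == 28

    def test_strictly_decreasing(self):
        assert mann_kendall_tau_b(np.arange(8.0)[::-1]).tau_b == -1.0

    def test_ties_match_pair_counting_oracle(self):
        series = [1.0, 2.0, 2.0, 3.0, 1.0]
        res = mann_kendall_tau_b(series)
        S, tau = brute_force_tau_b(series)
        assert res.S_statistic == S
        assert res.tau_b == pytest.approx(tau, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_series_match_scipy_tau_b(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(5, 30)).astype(float)
        if np.unique(x).size < 2:
            return
        res = mann_kendall_tau_b(x)
        ref = sps.kendalltau(np.arange(len(x)), x)
        assert res.tau_b == pytest.approx(ref.statistic, abs=1e-12)

    def test_all_equal_flagged(self):
        with pytest.warns(UserWarning):
            res = mann_kendall_tau_b([2.0, 2.0, 2.0, 2.0])
        assert res.degenerate and np.isnan(res.tau_b)

    @given(st.lists(st.floats(min_value=-100, max_value=100, allow_nan=False),
                    min_size=3, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, values):
        if len(set(values)) < 2:
            return
        fwd = mann_kendall_tau_b(values)
        rev = mann_kendall_tau_b(values[::-1])
        assert fwd.tau_b == pytest.approx(-rev.tau_b, abs=1e-12)

    def test_monotone_length_seven_is_significant(self):
        """A strict trend over 7 timepoints reaches p < 0.005."""
        res = mann_kendall_tau_b([1, 2, 3, 4, 5, 6, 7])
        assert res.tau_b == 1.0 and res.p_value < 0.005

    def test_too_short(self):
        with pytest.raises(ValueError):
            mann_kendall_tau_b([1.0, 2.0])


class TestCohortTables:
    def test_no_change_cohort_all_p_one(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(10):
            v = rng.normal(10, 1)
            for t in (-1.0, 10.0):
                rows.append({"cell_id": f"c{i}", "timepoint_min": t, "volume": v})
        with pytest.warns(UserWarning):
            table = summarize_pairwise(pd.DataFrame(rows), -1.0, 10.0,
                                       features=["volume"])
        assert (table["mean_diff"] == 0).all()
        assert (table["p_value"] == 1.0).all()

    def test_sem_matches_direct_recomputation(self):
        coh = generate_cohort(n_cells=40, seed=8)
        table = summarize_pairwise(coh, -1.0, 10.0).set_index("parameter")
        ref = coh[coh.timepoint_min == -1.0].set_index("cell_id")["volume"]
        cmp_ = coh[coh.timepoint_min == 10.0].set_index("cell_id")["volume"]
        d = (cmp_ - ref).to_numpy()
        assert table.loc["volume", "sem"] == pytest.approx(d.std(ddof=1) / np.sqrt(len(d)))
        assert table.loc["volume", "mean_diff"] == pytest.approx(d.mean())

    def test_row_count_and_exclusion_accounting(self):
        coh = generate_cohort(n_cells=12, seed=2)
        dropped = coh[~((coh.cell_id == "cell0000") & (coh.timepoint_min == 10.0))]
        table = summarize_pairwise(dropped, -1.0, 10.0)
        assert len(table) == 16
        assert table.attrs["n_excluded"] == 1

    def test_too_few_pairs(self):
        coh = generate_cohort(n_cells=3, seed=1)
        only_one = coh[coh.cell_id == "cell0000"]
        with pytest.raises(ValueError):
            summarize_pairwise(only_one, -1.0, 10.0)

    def test_trend_composition(self):
        coh = generate_cohort(n_cells=30, seed=4)
        post = [10.0, 30.0, 50.0, 70.0, 90.0, 110.0, 120.0]
        res = trend_over_time(coh, "volume", timepoints=post)
        means = (coh[coh.timepoint_min.isin(post)]
                 .groupby("timepoint_min")["volume"].mean().sort_index().to_numpy())
        ref = mann_kendall_tau_b(means)
        assert res.tau_b == ref.tau_b and res.S_statistic == ref.S_statistic

    def test_control_cohort_trend_is_null(self):
        """Flat control cohorts rarely show a significant mean trend."""
        hits = 0
        for seed in range(20):
            coh = generate_cohort(n_cells=40, model=EffectModel.control(), seed=seed)
            res = trend_over_time(coh, "volume",
                                  timepoints=[10.0, 30.0, 50.0, 70.0, 90.0, 110.0, 120.0])
            if res.p_value > 0.05:
                hits += 1
        assert hits >= 18  # >= 90% of null replicates


class TestRayleighEnergy:
    def test_zero_radius(self):
        assert rayleigh_bubble_energy(0.0) == 0.0

    def test_cubic_scaling(self):
        assert rayleigh_bubble_energy(42.0) == pytest.approx(
            8.0 * rayleigh_bubble_energy(21.0), rel=1e-12)

    def test_closed_form(self):
        e = rayleigh_bubble_energy(CavitationParams(r_max_um=21.0, delta_p_pa=98986.0))
        expected = (4 / 3) * np.pi * (21e-6) ** 3 * 98986.0 * 1e9
        assert e == pytest.approx(expected, rel=1e-12)

    def test_invalid_pressure(self):
        with pytest.raises(ValueError):
            CavitationParams(r_max_um=21.0, delta_p_pa=0.0)
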