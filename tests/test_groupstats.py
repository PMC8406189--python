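"""Rank tests, KS, bootstrap SEs, log reduction, and the microcolony model."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from erovar.groupstats import (
    MicrocolonyOutcome,
    MicrocolonySurvivalModel,
    StabilityClassModel,
    bootstrap_se_fraction,
    kruskal_wallis_dunn,
    ks_two_sample,
    log_reduction,
    microcolony_survival_analysis,
)


class TestKruskalWallisDunn:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis_dunn({"a": [1, 1, 1], "b": [1, 1], "c": [1]})
        assert res.H == 0.0 and res.p == 1.0
        assert res.significant_pairs() == []

    def test_fewer_than_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn({"a": [1.0, 2.0]})

    def test_shifted_group_flagged(self):
        res = kruskal_wallis_dunn(
            {"a": [1, 2, 3, 4, 5], "b": [11, 12, 13, 14, 15]}
        )
        assert ("a", "b") in res.significant_pairs(alpha=0.05)

    def test_h_matches_scipy_and_bonferroni_exact(self):
        rng = np.random.default_rng(5)
        groups = {k: list(rng.normal(size=8)) for k in "abc"}
        res = kruskal_wallis_dunn(groups)
        H, p = stats.kruskal(*groups.values())
        assert res.H == pytest.approx(H)
        assert res.p == pytest.approx(p)
        for _, _, _, p_raw, p_adj, _ in res.pairwise:
            assert p_adj == pytest.approx(min(1.0, 3 * p_raw))
            assert p_adj >= p_raw

    def test_covers_all_pairs(self):
        res = kruskal_wallis_dunn({k: [float(i)] * 3 for i, k in enumerate("abcd")})
        assert len(res.pairwise) == 6

    def test_small_n_agrees_with_permutation_oracle(self):
        """Asymptotic KW p tracks the exact permutation distribution of H on
        tiny groups (Monte-Carlo oracle, label permutations)."""
        rng = np.random.default_rng(11)
        a, b = [0.1, 1.4, 2.2, 3.1], [2.9, 4.0, 5.5, 6.1]
        res = kruskal_wallis_dunn({"a": a, "b": b})
        pooled = np.array(a + b)
        h_obs = stats.kruskal(a, b).statistic
        count = 0
        trials = 2000
        for _ in range(trials):
            perm = rng.permutation(pooled)
            count += stats.kruskal(perm[:4], perm[4:]).statistic >= h_obs - 1e-12
        p_perm = count / trials
        assert abs(res.p - p_perm) < 0.1

    def test_holm_adjustment_available(self):
        rng = np.random.default_rng(6)
        groups = {k: list(rng.normal(size=6)) for k in "abc"}
        res = kruskal_wallis_dunn(groups, adjust="holm")
        assert all(pa >= pr for _, _, _, pr, pa, _ in res.pairwise)


class TestKs:
    def test_identical_samples(self):
        D, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert D == 0.0

    def test_disjoint_supports(self):
        D, _ = ks_two_sample([1.0, 2.0], [3.0, 4.0])
        assert D == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=40)
        b = rng.normal(0.5, 1.2, size=35)
        D1, _ = ks_two_sample(a, b)
        D2, _ = ks_two_sample(np.exp(a), np.exp(b))
        assert D1 == pytest.approx(D2)


class TestBootstrapSe:
    def test_all_success_zero(self):
        assert bootstrap_se_fraction([1] * 20, B=500, seed=1) == 0.0

    def test_matches_analytic_binomial_se(self):
        outcomes = [1] * 50 + [0] * 50
        se = bootstrap_se_fraction(outcomes, B=10_000, seed=42)
        assert abs(se - 0.05) / 0.05 < 0.05

    def test_converges_with_b(self):
        outcomes = [1] * 50 + [0] * 50
        se = bootstrap_se_fraction(outcomes, B=100_000, seed=7)
        assert abs(se - 0.05) / 0.05 < 0.02

    def test_seeded_determinism(self):
        outcomes = [1, 0, 1, 1, 0]
        a = bootstrap_se_fraction(outcomes, B=2000, seed=9)
        b = bootstrap_se_fraction(outcomes, B=2000, seed=9)
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_se_fraction([], B=10)


class TestLogReduction:
    @pytest.mark.parametrize(
        "n0,n,expected", [(1e8, 1e8, 0.0), (1e8, 1e5, 3.0), (2e6, 1e3, 3.301)]
    )
    def test_values(self, n0, n, expected):
        assert log_reduction(n0, n) == pytest.approx(expected, abs=5e-4)

    def test_zero_count_mentions_quantification_limit(self):
        with pytest.raises(ValueError, match="quantification"):
            log_reduction(1e8, 0)


def make_cells(frac_plus=1.0, frac_minus=1.0, lag_plus=2.0, lag_minus=2.0,
               n_colonies=4, cells_per_colony=4):
    cells = []
    for c in range(n_colonies):
        for i in range(cells_per_colony):
            pa = i == 0
            p = frac_plus if pa else frac_minus
            survived = (c * cells_per_colony + i) % 10 < p * 10
            cells.append(
                MicrocolonyOutcome(
                    colony_id=f"col{c}", cell_id=f"col{c}_{i}",
                    pa_status="PA_plus" if pa else "PA_minus", induced=True,
                    survived=survived,
                    resuscitation_time=(lag_plus if pa else lag_minus)
                    if survived else None,
                )
            )
    return cells


class TestMicrocolonyAnalysis:
    def test_all_survive_identical_lag(self):
        summary = microcolony_survival_analysis(make_cells(), B=500, seed=0)
        assert summary.survival_ratio == pytest.approx(1.0)
        for b in summary.bins.values():
            assert b.fraction == 1.0 and b.bootstrap_se == 0.0
        for _, _, D, _, _ in summary.ks_tests:
            assert D == 0.0

    def test_ratio_requires_nonzero_denominator(self):
        cells = make_cells(frac_minus=0.0)
        with pytest.raises(ValueError):
            microcolony_survival_analysis(cells, B=100, seed=0)

    def test_lag_cdfs_cover_survivors_only(self):
        cells = make_cells(frac_minus=0.5)
        summary = microcolony_survival_analysis(cells, B=200, seed=0)
        b = summary.bins["PA_minus_induced"]
        assert len(summary.lag_times["PA_minus_induced"]) == b.survivors < b.n

    def test_bonferroni_over_comparisons_made(self):
        cells = make_cells(lag_plus=1.0, lag_minus=5.0)
        cells += [
            MicrocolonyOutcome(
                colony_id=f"n{c}", cell_id=f"n{c}_{i}", pa_status="PA_minus",
                induced=False, survived=True, resuscitation_time=5.0 + i * 0.1,
            )
            for c in range(3) for i in range(4)
        ]
        summary = microcolony_survival_analysis(cells, B=200, seed=0)
        assert len(summary.ks_tests) == 3
        m = len(summary.ks_tests)
        for _, _, _, p_raw, p_adj in summary.ks_tests:
            assert p_adj == pytest.approx(min(1.0, m * p_raw))

    def test_cluster_bootstrap_runs_and_labels(self):
        cells = make_cells(frac_minus=0.5)
        summary = microcolony_survival_analysis(
            cells, B=300, seed=1, cluster_bootstrap=True
        )
        assert summary.se_method == "colony-clustered bootstrap"
        assert all(b.bootstrap_se >= 0 for b in summary.bins.values())


class TestModelObjects:
    def test_stability_model_summary(self):
        rng = np.random.default_rng(2)
        groups = {
            "heat_selected": list(rng.normal(5, 1, 8)),
            "accessible": list(rng.normal(1.5, 1, 60)),
            "natural": list(rng.normal(0.5, 1, 40)),
        }
        res = StabilityClassModel(groups).fit()
        text = res.summary()
        assert "Kruskal-Wallis" in text and "heat_selected" in text
        assert set(res.medians) == set(groups)

    def test_survival_model_from_dataframe_round_trip(self):
        import pandas as pd

        cells = make_cells(frac_minus=0.5, lag_plus=1.0, lag_minus=3.0)
        df = pd.DataFrame(
            {
                "colony_id": [c.colony_id for c in cells],
                "cell_id": [c.cell_id for c in cells],
                "induced": [c.induced for c in cells],
                "pa_status": [c.pa_status for c in cells],
                "survived": [c.survived for c in cells],
                "resuscitation_time_h": [
                    math.nan if c.resuscitation_time is None
                    else c.resuscitation_time for c in cells
                ],
            }
        )
        res = MicrocolonySurvivalModel.from_dataframe(df).fit(B=200, seed=0)
        direct = MicrocolonySurvivalModel(cells).fit(B=200, seed=0)
        assert res.to_dict() == direct.to_dict()
        assert "survival" in res.summary().lower()
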