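"""Exact rank tests and the zero-inflated Poisson mixed model."""

import numpy as np
import patsy
import pytest
from scipy import stats as sps

from usvkit import (
    CountTableSpec,
    fit_zi_poisson_mixed,
    mann_whitney_exact,
    synth_count_table,
    wilcoxon_signed_rank_exact,
)
from usvkit.stats import _marginal_loglik


class TestMannWhitneyExact:
    def test_complete_separation_n4(self):
        res = mann_whitney_exact([5, 6, 7, 8], [1, 2, 3, 4])
        assert res.statistic == 16
        assert res.p_two_sided == pytest.approx(2 / 70)
        assert res.method == "enumeration"

    def test_symmetry_under_sample_swap(self):
        x, y = [3.1, 4.5, 9.2, 1.0], [2.2, 8.8, 0.4]
        assert (
            mann_whitney_exact(x, y).p_two_sided
            == mann_whitney_exact(y, x).p_two_sided
        )

    def test_one_swap_from_separation_u44(self):
        x = [5, 7, 8, 9, 10, 11, 12, 13, 14]
        y = [1, 2, 3, 4, 6]
        res = mann_whitney_exact(x, y)
        assert res.statistic == 44
        assert round(res.p_two_sided, 3) == 0.002

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_exact([], [1, 2])

    def test_midranks_under_ties(self):
        # x = {1, 2, 2}, y = {2, 3}: U = #{x>y} + 0.5 * #ties = 0 + 0.5*2
        res = mann_whitney_exact([1, 2, 2], [2, 3])
        assert res.statistic == 1.0

    def test_matches_independent_exact_oracle(self):
        """Enumeration agrees with scipy's exact implementation on
        random tie-free datasets up to combined n = 12."""
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n1 = int(rng.integers(1, 9))
            n2 = int(rng.integers(1, min(12 - n1, 8) + 1))
            pooled = rng.permutation(rng.normal(size=n1 + n2))
            x, y = pooled[:n1], pooled[n1:]
            mine = mann_whitney_exact(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine.statistic == pytest.approx(ref.statistic)
            assert mine.p_two_sided == pytest.approx(ref.pvalue)

    def test_p_monotone_in_distance_from_mean_u(self):
        """Across all C(10,5) splits of 1..10, the exact two-sided p is
        non-increasing as U moves away from n1*n2/2."""
        from itertools import combinations

        pooled = list(range(1, 11))
        seen = {}
        for xs in combinations(pooled, 5):
            ys = [v for v in pooled if v not in xs]
            res = mann_whitney_exact(list(xs), ys)
            seen.setdefault(abs(res.statistic - 12.5), set()).add(
                round(res.p_two_sided, 12)
            )
        assert all(len(ps) == 1 for ps in seen.values())
        dists = sorted(seen)
        ps = [next(iter(seen[d])) for d in dists]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_large_samples_use_flagged_approximation(self):
        rng = np.random.default_rng(5)
        res = mann_whitney_exact(rng.normal(size=15), rng.normal(1.0, size=15))
        assert res.method == "approximation"
        ref = sps.mannwhitneyu(
            *(rng.normal(size=15), rng.normal(size=15)), method="asymptotic"
        )
        assert 0 < res.p_two_sided <= 1


class TestWilcoxonExact:
    def test_all_positive_n7_maximal_v(self):
        res = wilcoxon_signed_rank_exact([1, 2, 3, 4, 5, 6, 7])
        assert res.statistic == 28
        assert res.p_two_sided == pytest.approx(2 / 128)

    def test_single_positive_difference(self):
        res = wilcoxon_signed_rank_exact([2.5])
        assert res.statistic == 1
        assert res.p_two_sided == 1.0

    def test_three_mixed_differences(self):
        # V = 5; 2 of 8 sign patterns reach V >= 5, so p = 2 * 2/8
        res = wilcoxon_signed_rank_exact([3, -1, 2])
        assert res.statistic == 5
        assert res.p_two_sided == pytest.approx(0.5)

    def test_zero_differences_dropped_and_counted(self):
        res = wilcoxon_signed_rank_exact([0.0, 1.0, -2.0, 0.0, 3.0])
        assert res.n_zero_dropped == 2
        assert res.n1 == 3

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_exact([0.0, 0.0])

    def test_matches_independent_exact_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            n = int(rng.integers(3, 13))
            d = rng.normal(0.3, size=n)
            mine = wilcoxon_signed_rank_exact(d)
            ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
            # scipy reports min(V+, V-); tails are symmetric so p agrees
            assert mine.p_two_sided == pytest.approx(ref.pvalue)

    def test_large_n_uses_flagged_approximation(self):
        rng = np.random.default_rng(6)
        res = wilcoxon_signed_rank_exact(rng.normal(0.5, size=30))
        assert res.method == "approximation"


def _truth_on_design(spec: CountTableSpec, table) -> np.ndarray:
    """Project the generator's cell-mean log intensities onto the fitted
    design matrix to get the true coefficient vector."""
    cells = table[["group", "call_type"]].drop_duplicates().reset_index(drop=True)
    X = patsy.dmatrix("C(group) * C(call_type)", cells, return_type="dataframe")
    g_idx = (cells["group"] == spec.group_labels[1]).to_numpy().astype(float)
    t_idx = cells["call_type"].map(
        {t: i for i, t in enumerate(("NS", "NL", "JS", "JN", "JL", "JU", "MJ"))}
    ).to_numpy()
    eta = (
        spec.intercept
        + spec.group_effect * g_idx
        + np.asarray(spec.type_effects)[t_idx]
        + np.asarray(spec.interaction_effects)[t_idx] * g_idx
    )
    beta, *_ = np.linalg.lstsq(X.to_numpy(), eta, rcond=None)
    return beta


@pytest.fixture(scope="module")
def cohort():
    spec = CountTableSpec(n_animals_per_group=(20, 20), seed=101)
    return spec, synth_count_table(spec)


class TestZiPoissonMixed:
    def test_sigma_zero_matches_statsmodels_zip(self, cohort):
        from statsmodels.discrete.count_model import ZeroInflatedPoisson

        _, table = cohort
        mine = fit_zi_poisson_mixed(table, fix_sigma_b=0.0)
        X = patsy.dmatrix("C(group) * C(call_type)", table, return_type="dataframe")
        ref = ZeroInflatedPoisson(
            table["count"], X, exog_infl=np.ones((len(table), 1)), inflation="logit"
        ).fit(disp=0, method="bfgs", maxiter=500)
        assert abs(mine.loglik - ref.llf) < 1e-6

    def test_quadrature_converged_in_node_count(self, cohort):
        _, table = cohort
        fit = fit_zi_poisson_mixed(table, n_quad=20)
        X = patsy.dmatrix("C(group) * C(call_type)", table)
        y = table["count"].to_numpy(float)
        _, idx = np.unique(table["animal"], return_inverse=True)
        theta = np.concatenate(
            [fit.beta, [np.log(fit.pi / (1 - fit.pi))], [fit.sigma_b]]
        )
        ll20 = _marginal_loglik(theta, y, np.asarray(X), idx, fit.n_animals, 20, None)
        ll40 = _marginal_loglik(theta, y, np.asarray(X), idx, fit.n_animals, 40, None)
        assert abs(ll20 - ll40) < 1e-6

    def test_parameter_recovery_on_one_cohort(self, cohort):
        spec, table = cohort
        fit = fit_zi_poisson_mixed(table)
        assert fit.converged
        assert abs(fit.pi - spec.zero_inflation_prob) < 0.1
        assert abs(fit.sigma_b - spec.random_intercept_sd) < 0.2
        truth = _truth_on_design(spec, table)
        assert np.all(np.abs(fit.beta - truth) < 4 * fit.se_beta)

    def test_no_inflation_no_variance_consistency(self):
        spec = CountTableSpec(
            n_animals_per_group=(715, 715),
            zero_inflation_prob=0.0, random_intercept_sd=0.0, seed=55,
        )
        fit = fit_zi_poisson_mixed(synth_count_table(spec))
        assert fit.pi < 0.05
        assert fit.sigma_b < 0.1

    def test_all_zero_counts_flagged_as_boundary(self):
        spec = CountTableSpec(n_animals_per_group=(3, 3), seed=1)
        table = synth_count_table(spec)
        table["count"] = 0
        fit = fit_zi_poisson_mixed(table)
        assert fit.boundary

    def test_missing_column_rejected(self, cohort):
        _, table = cohort
        with pytest.raises(ValueError, match="column"):
            fit_zi_poisson_mixed(table.rename(columns={"count": "n"}))

    def test_non_integer_counts_rejected(self, cohort):
        _, table = cohort
        bad = table.copy()
        bad["count"] = bad["count"].astype(float)
        bad.loc[0, "count"] = 1.5
        with pytest.raises(ValueError, match="integer"):
            fit_zi_poisson_mixed(bad)
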