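"""Differential expression: size factors, trend fit, exact test, calling.

The exact test is checked against an independent enumeration oracle built
on log-gamma arithmetic (no shared code with the implementation) and
against the conditional-binomial closed form in the Poisson limit.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lightchrom as lc
from lightchrom.synth import CountModel
from conftest import make_const_var_fit


# ---------------------------------------------------------------------------
# Independent oracle: enumeration with log-gamma pmfs
# ---------------------------------------------------------------------------

def _log_nb_pmf(k, mu, var):
    if mu <= 0:
        return 0.0 if k == 0 else -math.inf
    if var <= mu * (1 + 1e-8):
        return k * math.log(mu) - mu - math.lgamma(k + 1)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return (
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log(1 - p)
    )


def enumeration_oracle(k_t, k_c, s_t, s_c, phi):
    """Brute-force two-sided conditional p by full enumeration."""
    total = k_t + k_c
    if total == 0:
        return 1.0
    mu0 = (k_t / s_t + k_c / s_c) / 2.0
    mu_t, mu_c = mu0 * s_t, mu0 * s_c
    var_t = mu_t + phi * mu_t**2
    var_c = mu_c + phi * mu_c**2
    f = [
        math.exp(_log_nb_pmf(a, mu_t, var_t) + _log_nb_pmf(total - a, mu_c, var_c))
        for a in range(total + 1)
    ]
    f_obs = f[k_t]
    return sum(x for x in f if x <= f_obs * (1 + 1e-12)) / sum(f)


class PhiFit:
    """Dispersion mapping with constant phi: sigma^2 = mu + phi mu^2."""

    def __init__(self, phi):
        self.phi = phi

    def __call__(self, mu):
        return mu + self.phi * np.asarray(mu, dtype=float) ** 2

    def dispersion(self, mu):
        return self.phi


# ---------------------------------------------------------------------------
# Size factors and filtering
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_samples_give_unity(self):
        t = pd.DataFrame({"a": [5, 9, 20], "b": [5, 9, 20]})
        np.testing.assert_allclose(lc.estimate_size_factors(t), [1.0, 1.0])

    def test_hand_computed_example(self):
        t = pd.DataFrame({"s1": [2, 8], "s2": [8, 32]})
        np.testing.assert_allclose(lc.estimate_size_factors(t), [0.5, 2.0])

    def test_scaling_one_sample_scales_its_relative_factor(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.integers(1, 200, size=(300, 4)), columns=list("abcd"))
        base = lc.estimate_size_factors(t)
        scaled = t.copy()
        scaled["b"] = scaled["b"] * 3
        after = lc.estimate_size_factors(scaled)
        np.testing.assert_allclose(
            (after["b"] / after["a"]) / (base["b"] / base["a"]), 3.0, rtol=1e-9
        )

    def test_no_all_positive_gene_is_error(self):
        t = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            lc.estimate_size_factors(t)


class TestFilterLowExpression:
    def test_ten_genes_eight_retained(self):
        t = pd.DataFrame(
            {"a": np.arange(1, 11) * 10, "b": np.arange(1, 11) * 10},
            index=[f"g{i}" for i in range(10)],
        )
        assert len(lc.filter_low_expression(t, 0.20)) == 8

    def test_quantile_zero_is_identity(self):
        t = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]})
        pd.testing.assert_frame_equal(lc.filter_low_expression(t, 0.0), t)

    def test_matches_sort_and_cut_oracle(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(
            rng.integers(1, 500, size=(200, 3)),
            columns=list("abc"),
            index=[f"g{i}" for i in range(200)],
        )
        sf = lc.estimate_size_factors(t)
        kept = set(lc.filter_low_expression(t, 0.20, sf).index)
        means = (t / sf).mean(axis=1)
        cutoff = np.quantile(means.to_numpy(), 0.20)
        oracle = set(means.index[means >= cutoff])
        assert kept == oracle


# ---------------------------------------------------------------------------
# Mean-variance fit
# ---------------------------------------------------------------------------

class TestMeanVarianceFit:
    def test_quadratic_dispersion_recovery(self):
        model = CountModel(frac_induced=0.0, phi0=0.1, phi1=0.0)
        genes = [f"g{i}" for i in range(10_000)]
        t, _ = lc.simulate_counts(model, genes, [f"wt_s{i}" for i in range(4)], seed=2)
        sf = lc.estimate_size_factors(t)
        fit = lc.fit_mean_variance(t, sf)
        lo, hi = np.percentile(fit.log_mu_grid, [10, 90])
        mus = np.exp(np.linspace(lo, hi, 40))
        ratio = fit(mus) / (mus + 0.1 * mus**2)
        assert ratio.min() >= 0.8 and ratio.max() <= 1.25

    def test_poisson_counts_floor_active(self):
        model = CountModel(frac_induced=0.0, phi0=0.0, phi1=0.0)
        genes = [f"g{i}" for i in range(10_000)]
        t, _ = lc.simulate_counts(model, genes, [f"wt_s{i}" for i in range(4)], seed=3)
        sf = lc.estimate_size_factors(t)
        fit = lc.fit_mean_variance(t, sf)
        mus = np.exp(np.linspace(fit.log_mu_grid[0], fit.log_mu_grid[-1], 40))
        assert np.all(fit(mus) <= 1.15 * mus)
        assert np.all(fit(mus) >= mus)

    def test_mapping_nondecreasing(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(
            rng.poisson(rng.lognormal(3, 1, size=(500, 1)), size=(500, 4)),
            columns=list("abcd"),
        )
        fit = lc.fit_mean_variance(t, lc.estimate_size_factors(t))
        mus = np.linspace(0.5, 200, 400)
        vals = fit(mus)
        assert np.all(np.diff(vals) >= -1e-9)

    def test_too_few_genes_is_error(self):
        t = pd.DataFrame({"a": np.arange(1, 31), "b": np.arange(1, 31)})
        with pytest.raises(ValueError, match="unstable"):
            lc.fit_mean_variance(t, lc.estimate_size_factors(t))


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_zero_counts_give_p_one(self, flat_fit):
        assert lc.exact_test(0, 0, 1.0, 1.0, flat_fit).p == 1.0

    def test_symmetric_observation_is_modal(self):
        r = lc.exact_test(10, 10, 1.0, 1.0, make_const_var_fit(20.0))
        assert r.p == pytest.approx(1.0)

    def test_known_case_matches_enumeration(self):
        r = lc.exact_test(18, 2, 1.0, 1.0, make_const_var_fit(15.0))
        phi = (15.0 - 10.0) / 100.0
        assert r.p == pytest.approx(enumeration_oracle(18, 2, 1.0, 1.0, phi), rel=1e-12)

    def test_random_grid_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            total = int(rng.integers(1, 300))
            k_t = int(rng.integers(0, total + 1))
            k_c = total - k_t
            s_t, s_c = rng.uniform(0.5, 2.0, size=2)
            phi = float(rng.uniform(0.0, 0.5))
            r = lc.exact_test(k_t, k_c, s_t, s_c, PhiFit(phi))
            assert r.p == pytest.approx(
                enumeration_oracle(k_t, k_c, s_t, s_c, phi), rel=1e-12
            ), (k_t, k_c, s_t, s_c, phi)

    def test_poisson_limit_equals_conditional_binomial(self, flat_fit):
        rng = np.random.default_rng(6)
        for _ in range(40):
            total = int(rng.integers(1, 200))
            k_t = int(rng.integers(0, total + 1))
            s_t, s_c = rng.uniform(0.5, 2.0, size=2)
            r = lc.exact_test(k_t, total - k_t, s_t, s_c, flat_fit)
            pr = s_t / (s_t + s_c)
            f = stats.binom.pmf(np.arange(total + 1), total, pr)
            p_bin = f[f <= f[k_t] * (1 + 1e-12)].sum()
            assert r.p == pytest.approx(p_bin, rel=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        k_t=st.integers(0, 80),
        k_c=st.integers(0, 80),
        s_t=st.floats(0.5, 2.0),
        s_c=st.floats(0.5, 2.0),
        phi=st.floats(0.0, 0.5),
    )
    def test_swap_symmetry(self, k_t, k_c, s_t, s_c, phi):
        fit = PhiFit(phi)
        a = lc.exact_test(k_t, k_c, s_t, s_c, fit)
        b = lc.exact_test(k_c, k_t, s_c, s_t, fit)
        assert a.p == pytest.approx(b.p, rel=1e-9)

    def test_monotone_in_deviation(self):
        fit = PhiFit(0.1)
        total = 40
        ps = [lc.exact_test(k, total - k, 1.0, 1.0, fit).p for k in range(20, 41)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_null_pvalues_conservative(self):
        """On null NB data the p distribution is stochastically >= uniform."""
        rng = np.random.default_rng(7)
        phi = 0.05
        mu = rng.lognormal(np.log(40), 0.7, 3000)
        r = 1 / phi
        k1 = rng.negative_binomial(r, r / (r + mu))
        k2 = rng.negative_binomial(r, r / (r + mu))
        fit = PhiFit(phi)
        ps = np.array([lc.exact_test(int(a), int(b), 1, 1, fit).p for a, b in zip(k1, k2)])
        for alpha in (0.01, 0.05):
            assert (ps <= alpha).mean() <= alpha + 0.01


# ---------------------------------------------------------------------------
# Calling and classification
# ---------------------------------------------------------------------------

def _results_frame(genes, p, fold):
    return pd.DataFrame(
        {"p": p, "fold": fold, "mean_treat": 0.0, "mean_control": 0.0},
        index=pd.Index(genes, name="gene_id"),
    )


class TestCallLightInduced:
    def test_threshold_semantics(self):
        genes = ["strong_but_small_fold", "induced"]
        res = {
            "30": _results_frame(genes, [1e-9, 1e-4], [1.9, 8.0]),
            "60": _results_frame(genes, [0.5, 0.01], [1.0, 4.0]),
            "120": _results_frame(genes, [0.5, 0.04], [1.0, 2.0]),
        }
        calls = lc.call_light_induced(res)
        assert not calls.table.at["strong_but_small_fold", "called"]
        assert calls.table.at["induced", "called"]
        assert calls.table.at["induced", "class"] == "immediate-early"

    def test_late_class_for_monotone_rise(self):
        res = {
            "30": _results_frame(["g"], [0.5], [1.2]),
            "60": _results_frame(["g"], [0.04], [3.0]),
            "120": _results_frame(["g"], [1e-4], [6.0]),
        }
        calls = lc.call_light_induced(res)
        assert calls.table.at["g", "class"] == "late"

    def test_missing_light_timepoints_error(self):
        with pytest.raises(ValueError):
            lc.call_light_induced({})

    def test_planted_recovery_and_classes(self):
        model = CountModel(frac_induced=0.10)
        genes = [f"g{i}" for i in range(2000)]
        samples = ["wt_DD", "wt_30", "wt_60", "wt_120"]
        table, truth = lc.simulate_counts(model, genes, samples, seed=8)
        calls, _, _ = lc.run_de(table)
        tab = calls.table
        early = truth.de_genes[truth.de_genes["class"] == "early"]["gene_id"]
        early = tab.index.intersection(early)
        assert tab.loc[early, "called"].mean() >= 0.85
        # planted early genes peak x8 at 30 min: immediate-early by definition
        assert (tab.loc[early][tab.loc[early, "called"]]["class"] == "immediate-early").mean() >= 0.9
        # classes partition the called set
        assert (tab.loc[tab["called"], "class"] != "").all()
        assert (tab.loc[~tab["called"], "class"] == "").all()


class TestCompareGenotypes:
    def test_identical_tables_flag_nothing(self):
        model = CountModel(frac_induced=0.0)
        genes = [f"g{i}" for i in range(500)]
        t, _ = lc.simulate_counts(model, genes, ["wt_DD", "wt_30", "wt_60", "wt_120"], seed=9)
        alt = t.rename(columns=lambda c: c.replace("wt_", "ko_"))
        flags = lc.compare_genotypes(t, alt, genes[:100], "lower")
        assert flags["flagged"].sum() == 0

    def test_planted_dependence_recovered(self):
        model = CountModel(
            mean_log_mu=float(np.log(20.0)), frac_induced=0.10, frac_dependent=1.0,
            early_profile={"30": 4.0, "60": 4.0, "120": 4.0},
            late_profile={"30": 4.0, "60": 4.0, "120": 4.0},
        )
        genes = [f"g{i}" for i in range(4000)]
        samples = [f"{g}_{t}" for g in ("wt", "ko") for t in ("DD", "30", "60", "120")]
        table, truth = lc.simulate_counts(model, genes, samples, seed=21)
        wt = table[[c for c in table.columns if c.startswith("wt_")]]
        ko = table[[c for c in table.columns if c.startswith("ko_")]]
        dep = truth.de_genes[truth.de_genes["dependent"]]["gene_id"].tolist()
        flags = lc.compare_genotypes(wt, ko, dep, "lower")
        assert flags["flagged"].mean() >= 0.8

    def test_absent_gene_is_error(self):
        model = CountModel(frac_induced=0.0)
        genes = [f"g{i}" for i in range(200)]
        t, _ = lc.simulate_counts(model, genes, ["wt_DD", "wt_30"], seed=10)
        alt = t.rename(columns=lambda c: c.replace("wt_", "ko_"))
        with pytest.raises(ValueError, match="absent"):
            lc.compare_genotypes(t, alt, ["not_a_gene"], "lower")
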