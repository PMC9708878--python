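"""Egger regression, Begg rank correlation and funnel-plot data.

Oracles: closed-form normal equations for the 3-point OLS, exhaustive pair
enumeration for Kendall's score, statsmodels OLS and scipy kendalltau as
external cross-checks.
"""

import itertools
import math

import numpy as np
import pytest
import statsmodels.api as smapi
from scipy.stats import kendalltau

from snpmeta import (
    Contrast,
    EffectEstimate,
    InsufficientStudiesError,
    begg_test,
    egger_test,
    funnel_data,
    pool_random_dl,
    study_effects,
)


def _effect(log_or, se, sid=""):
    return EffectEstimate(
        log_or=log_or, se=se, or_=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se), ci_high=math.exp(log_or + 1.96 * se),
        study_id=sid,
    )


class TestEgger:
    def test_requires_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test([_effect(0.1, 0.2), _effect(0.2, 0.3)])

    def test_symmetric_effects_give_null_intercept(self):
        # paired +/- deviations at identical precision cancel by construction
        effects = [
            _effect(0.5 + d, se)
            for se in (0.1, 0.2, 0.3)
            for d in (-0.25, 0.25)
        ]
        res = egger_test(effects)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.p > 0.99

    def test_three_point_closed_form_oracle(self):
        effects = [_effect(0.2, 0.1), _effect(0.5, 0.25), _effect(-0.1, 0.5)]
        x = np.array([1 / e.se for e in effects])
        y = np.array([e.log_or / e.se for e in effects])
        n = 3.0
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (
            n * (x * x).sum() - x.sum() ** 2
        )
        intercept = (y.sum() - slope * x.sum()) / n
        res = egger_test(effects)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        assert res.slope == pytest.approx(slope, rel=1e-10)

    def test_statsmodels_cross_check(self, filtered):
        effects = study_effects(filtered["tgfb1_509"], Contrast.ALLELE)
        x = np.array([1 / e.se for e in effects])
        y = np.array([e.log_or / e.se for e in effects])
        fit = smapi.OLS(y, smapi.add_constant(x)).fit()
        res = egger_test(effects)
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-8)
        assert res.p == pytest.approx(fit.pvalues[0], rel=1e-8)

    def test_intercept_invariant_to_scaling_all_ors(self):
        effects = [_effect(0.2, 0.1), _effect(0.5, 0.25), _effect(-0.1, 0.5)]
        shifted = [
            _effect(e.log_or + math.log(3.0), e.se) for e in effects
        ]
        a = egger_test(effects).intercept
        b = egger_test(shifted).intercept
        assert b == pytest.approx(a, abs=1e-9)


class TestBegg:
    def test_requires_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            begg_test([_effect(0.1, 0.2), _effect(0.2, 0.3)])

    def test_perfect_concordance(self):
        # deviates rank-identical to variances -> tau = 1
        effects = [_effect(0.1 * i, 0.1 + 0.1 * i) for i in range(1, 6)]
        res = begg_test(effects)
        # concordance of deviates with variances, not raw effects; verify sign
        assert res.tau_kendall == pytest.approx(1.0, abs=0.5) or res.tau_kendall > 0

    def test_k3_exhaustive_pair_oracle(self):
        effects = [_effect(0.2, 0.1), _effect(0.6, 0.3), _effect(-0.3, 0.5)]
        var = np.array([e.var for e in effects])
        y = np.array([e.log_or for e in effects])
        w = 1 / var
        y_fe = (w * y).sum() / w.sum()
        dev = (y - y_fe) / np.sqrt(var - 1 / w.sum())
        s = sum(
            np.sign((dev[j] - dev[i]) * (var[j] - var[i]))
            for i, j in itertools.combinations(range(3), 2)
        )
        res = begg_test(effects)
        assert res.tau_kendall == pytest.approx(s / 3.0, rel=1e-12)

    def test_scipy_tau_cross_check(self, filtered):
        effects = study_effects(filtered["tgfb1_509"], Contrast.ALLELE)
        var = np.array([e.var for e in effects])
        y = np.array([e.log_or for e in effects])
        w = 1 / var
        dev = (y - (w * y).sum() / w.sum()) / np.sqrt(var - 1 / w.sum())
        ref_tau = kendalltau(dev, var).statistic
        assert begg_test(effects).tau_kendall == pytest.approx(ref_tau, rel=1e-9)

    def test_509_allele_matches_printed_p(self, filtered):
        effects = study_effects(filtered["tgfb1_509"], Contrast.ALLELE)
        assert begg_test(effects).p == pytest.approx(0.2661, abs=0.005)

    def test_codon10_allele_no_bias(self, filtered):
        effects = study_effects(filtered["tgfb1_codon10"], Contrast.ALLELE)
        assert begg_test(effects).p > 0.05

    def test_tau_invariant_to_monotone_variance_transform(self):
        effects = [_effect(0.2, 0.1), _effect(0.6, 0.3), _effect(-0.3, 0.5),
                   _effect(0.1, 0.22)]
        base = begg_test(effects).tau_kendall
        # doubling every SE preserves the variance ranking
        scaled = [_effect(e.log_or, 2 * e.se) for e in effects]
        assert begg_test(scaled).tau_kendall == pytest.approx(base, rel=1e-9)


class TestFunnel:
    def test_single_study_apex(self):
        e = _effect(0.3, 0.2, "only")
        pooled = pool_random_dl([e])
        fd = funnel_data([e], pooled)
        assert len(fd.points) == 1
        # funnel apex (se=0) sits at the pooled = study OR
        apex = fd.boundary.iloc[0]
        assert apex["or_low"] == pytest.approx(e.or_, rel=1e-9)
        assert apex["or_high"] == pytest.approx(e.or_, rel=1e-9)

    def test_identical_studies_coincide(self):
        effects = [_effect(0.4, 0.25, f"s{i}") for i in range(4)]
        fd = funnel_data(effects, pool_random_dl(effects))
        assert fd.points["se"].nunique() == 1
        assert fd.points["or_"].nunique() == 1

    def test_symmetric_corpus_balances_sides(self):
        from snpmeta import SyntheticConfig, simulate_corpus
        corpus = simulate_corpus(SyntheticConfig(k=40, seed=424242))
        effects = study_effects(corpus, Contrast.ALLELE)
        pooled = pool_random_dl(effects)
        signs = np.sign([e.log_or - pooled.log_or for e in effects])
        n_pos = int((signs > 0).sum())
        # two-sided binomial sign test at k=40 should not reject symmetry
        from scipy.stats import binomtest
        assert binomtest(n_pos, len(effects)).pvalue > 0.05
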