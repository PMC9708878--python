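"""Fixed/random-effects pooling, heterogeneity and model selection.

Independent oracles: brute-force evaluation of the defining formulas on toy
inputs, and statsmodels' StratifiedTable as an external Mantel-Haenszel
cross-check (never the implementation).
"""

import math

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import StratifiedTable

from snpmeta import (
    Contrast,
    EffectEstimate,
    Heterogeneity,
    PoolingError,
    TwoByTwo,
    heterogeneity,
    meta_analyze,
    or_estimate,
    pool_fixed_iv,
    pool_fixed_mh,
    pool_random_dl,
    select_model,
    study_effects,
)

TOY_TABLES = [TwoByTwo(12, 30, 9, 41), TwoByTwo(25, 50, 20, 60), TwoByTwo(8, 19, 14, 17)]


def _effect(log_or, se, sid=""):
    return EffectEstimate(
        log_or=log_or, se=se, or_=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se), ci_high=math.exp(log_or + 1.96 * se),
        study_id=sid,
    )


def brute_force_dl(effects):
    """Direct evaluation of Q, tau2 and the DL pooled mean (oracle)."""
    w = [1 / e.se**2 for e in effects]
    ybar = sum(wi * e.log_or for wi, e in zip(w, effects)) / sum(w)
    q = sum(wi * (e.log_or - ybar) ** 2 for wi, e in zip(w, effects))
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (len(effects) - 1)) / c)
    ws = [1 / (e.se**2 + tau2) for e in effects]
    pooled = sum(wi * e.log_or for wi, e in zip(ws, effects)) / sum(ws)
    return q, tau2, pooled


class TestHeterogeneity:
    def test_identical_effects(self):
        h = heterogeneity([_effect(0.3, 0.1)] * 3)
        assert (h.q, h.i2, h.tau2) == (pytest.approx(0, abs=1e-20), 0.0, 0.0)

    def test_single_study_conventions(self):
        h = heterogeneity([_effect(0.5, 0.2)])
        assert (h.q, h.df, h.p_het, h.i2, h.tau2) == (0.0, 0, 1.0, 0.0, 0.0)

    def test_brute_force_oracle(self):
        effects = [or_estimate(t) for t in TOY_TABLES]
        q, tau2, _ = brute_force_dl(effects)
        h = heterogeneity(effects)
        assert h.q == pytest.approx(q, rel=1e-12)
        assert h.tau2 == pytest.approx(tau2, rel=1e-12)

    @pytest.mark.parametrize(
        "name,contrast,i2,p_het",
        [
            ("tgfb1_509", Contrast.ALLELE, 78, None),
            ("tgfb1_codon10", Contrast.ALLELE, 18, 0.27),
        ],
    )
    def test_published_i2(self, filtered, name, contrast, i2, p_het):
        h = heterogeneity(study_effects(filtered[name], contrast))
        assert round(h.i2) == i2
        if p_het is not None:
            assert h.p_het == pytest.approx(p_het, abs=0.01)


class TestMantelHaenszel:
    def test_single_study_equals_study_or(self):
        t = TwoByTwo(12, 30, 9, 41)
        pooled = pool_fixed_mh([t])
        assert pooled.or_ == pytest.approx(12 * 41 / (30 * 9), rel=1e-12)

    def test_brute_force_formula(self):
        r = sum(t.a * t.d / t.n for t in TOY_TABLES)
        s = sum(t.b * t.c / t.n for t in TOY_TABLES)
        assert pool_fixed_mh(TOY_TABLES).or_ == pytest.approx(r / s, rel=1e-12)

    def test_statsmodels_cross_check(self):
        tables = np.dstack(
            [[[t.a, t.b], [t.c, t.d]] for t in TOY_TABLES]
        )
        ref = StratifiedTable(tables.astype(float))
        pooled = pool_fixed_mh(TOY_TABLES)
        assert pooled.or_ == pytest.approx(ref.oddsratio_pooled, rel=1e-10)
        # statsmodels uses the exact 1.95996 quantile; we use the literature's 1.96
        lo, hi = ref.oddsratio_pooled_confint(alpha=0.05)
        assert pooled.ci_low == pytest.approx(lo, rel=1e-4)
        assert pooled.ci_high == pytest.approx(hi, rel=1e-4)

    def test_pooled_or_within_study_range(self):
        ors = [t.a * t.d / (t.b * t.c) for t in TOY_TABLES]
        assert min(ors) <= pool_fixed_mh(TOY_TABLES).or_ <= max(ors)

    def test_chb_codon10_homozygote_pair(self):
        pooled = pool_fixed_mh([TwoByTwo(5, 2, 13, 16), TwoByTwo(55, 23, 49, 46)])
        assert pooled.or_ == pytest.approx(2.33, abs=0.01)
        assert pooled.ci_low == pytest.approx(1.28, abs=0.01)
        assert pooled.ci_high == pytest.approx(4.22, abs=0.01)

    def test_aih_codon25_homozygote_pair(self):
        pooled = pool_fixed_mh([TwoByTwo(9, 154, 1, 156), TwoByTwo(10, 26, 2, 119)])
        assert pooled.or_ == pytest.approx(14.73, abs=0.01)

    def test_all_double_zero_raises(self):
        with pytest.raises(PoolingError):
            pool_fixed_mh([TwoByTwo(0, 5, 0, 7)])


class TestInverseVarianceAndDL:
    def test_identical_effects_pool_to_common_value(self):
        pooled = pool_fixed_iv([_effect(0.4, 0.1)] * 4)
        assert pooled.log_or == pytest.approx(0.4, rel=1e-12)

    def test_two_study_weighted_mean_oracle(self):
        e1, e2 = _effect(0.0, 0.1), _effect(1.0, 0.3)
        w1, w2 = 100.0, 1 / 0.09
        expected = (w1 * 0.0 + w2 * 1.0) / (w1 + w2)
        assert pool_fixed_iv([e1, e2]).log_or == pytest.approx(expected, rel=1e-12)

    def test_iv_close_to_mh_on_balanced_pair(self):
        tables = [TwoByTwo(5, 2, 13, 16), TwoByTwo(55, 23, 49, 46)]
        iv = pool_fixed_iv([or_estimate(t) for t in tables])
        mh = pool_fixed_mh(tables)
        assert iv.or_ == pytest.approx(mh.or_, abs=0.01)

    def test_dl_reduces_to_iv_when_homogeneous(self):
        effects = [_effect(0.3, 0.15)] * 3
        dl, iv = pool_random_dl(effects), pool_fixed_iv(effects)
        assert dl.log_or == pytest.approx(iv.log_or, rel=1e-12)
        assert dl.se == pytest.approx(iv.se, rel=1e-12)

    def test_dl_matches_brute_force(self):
        effects = [or_estimate(t) for t in TOY_TABLES]
        _, _, pooled = brute_force_dl(effects)
        assert pool_random_dl(effects).log_or == pytest.approx(pooled, rel=1e-12)

    def test_re_ci_at_least_as_wide_as_fe(self):
        effects = [_effect(0.0, 0.1), _effect(0.9, 0.1), _effect(-0.4, 0.2)]
        dl, iv = pool_random_dl(effects), pool_fixed_iv(effects)
        assert dl.se >= iv.se


class TestModelSelection:
    @pytest.mark.parametrize(
        "i2,p_het,expected",
        [
            (78.0, 1e-6, "RE"),
            (18.0, 0.27, "FE"),
            (50.0, 0.5, "RE"),   # I2 boundary goes random-effects
            (10.0, 0.1, "RE"),   # p_het boundary goes random-effects
            (49.9, 0.11, "FE"),
        ],
    )
    def test_rule(self, i2, p_het, expected):
        het = Heterogeneity(q=1.0, df=1, p_het=p_het, i2=i2, tau2=0.0)
        assert select_model(het) == expected


class TestMetaAnalyze:
    def test_509_allele_full_pipeline(self, corpora):
        pooled = meta_analyze(corpora["tgfb1_509"], Contrast.ALLELE)
        assert pooled.model == "RE-DL"
        assert pooled.k == 17
        assert pooled.or_ == pytest.approx(1.25, abs=0.02)
        assert (pooled.n_case, pooled.n_control) == (2611, 3387)

    def test_codon10_homozygote_fixed_effects(self, corpora):
        pooled = meta_analyze(corpora["tgfb1_codon10"], Contrast.HOMOZYGOTE)
        assert pooled.model == "FE-MH"
        assert pooled.k == 13
        assert pooled.or_ == pytest.approx(1.28, abs=0.02)
        assert pooled.ci_low == pytest.approx(1.06, abs=0.02)
        assert pooled.ci_high == pytest.approx(1.54, abs=0.02)

    def test_codon25_homozygote_drops_double_zero(self, corpora):
        pooled = meta_analyze(corpora["tgfb1_codon25"], Contrast.HOMOZYGOTE)
        assert pooled.k == 14
        reasons = dict(pooled.dropped)
        assert reasons["Falleti 2008 Cirrhosis"] == "double-zero 2x2"
        assert sum(v == "double-zero 2x2" for v in reasons.values()) == 5
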