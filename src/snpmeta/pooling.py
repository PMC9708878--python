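"""Fixed- and random-effects pooling of study odds ratios.

Fixed effects use the Mantel-Haenszel estimator on raw counts,
OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i), with the
Robins-Breslow-Greenland variance for its log.  Random effects use
DerSimonian-Laird: the moment estimator
tau^2 = max(0, (Q - df) / C), C = sum(w) - sum(w^2)/sum(w),
added to each study variance before inverse-variance weighting.  Q is
Cochran's statistic on the Woolf log odds ratios with fixed-effect
inverse-variance weights, I^2 = max(0, (Q - df)/Q) * 100.

Model choice follows the usual heterogeneity rule for this literature:
fixed effects when P_het > 0.1 and I^2 < 50%, random effects otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .corpus import StudyCorpus
from .errors import PipelineError, PoolingError
from .hwe import apply_hwe_filter
from .models import (
    Contrast,
    EffectEstimate,
    TwoByTwo,
    Z_95,
    build_contrast,
    or_estimate,
)


@dataclass(frozen=True)
class Heterogeneity:
    """Cochran Q, I^2 and the DerSimonian-Laird between-study variance."""

    q: float
    df: int
    p_het: float
    i2: float  # percent
    tau2: float

    @property
    def k(self) -> int:
        return self.df + 1


@dataclass(frozen=True)
class PooledResult:
    """Pooled odds ratio with significance test and heterogeneity context."""

    contrast: Contrast
    k: int
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    het: Heterogeneity
    model: str  # FE-MH, FE-IV or RE-DL
    n_case: int = 0
    n_control: int = 0
    log_or: float = 0.0
    se: float = 0.0
    dropped: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def single_study(self) -> bool:
        return self.k == 1

    @property
    def significant(self) -> bool:
        """CI excludes the null OR of 1."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def heterogeneity(effects: list[EffectEstimate]) -> Heterogeneity:
    """Cochran Q on fixed-effect inverse-variance weights, with I^2 and DL tau^2."""
    k = len(effects)
    if k == 0:
        raise PoolingError("heterogeneity undefined for an empty effect list")
    if k == 1:
        return Heterogeneity(q=0.0, df=0, p_het=1.0, i2=0.0, tau2=0.0)
    w = [1.0 / e.var for e in effects]
    sw = sum(w)
    y_bar = sum(wi * e.log_or for wi, e in zip(w, effects)) / sw
    q = sum(wi * (e.log_or - y_bar) ** 2 for wi, e in zip(w, effects))
    df = k - 1
    p_het = float(chi2_dist.sf(q, df))
    i2 = max(0.0, (q - df) / q * 100.0) if q > 0 else 0.0
    c = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return Heterogeneity(q=q, df=df, p_het=p_het, i2=i2, tau2=tau2)


def _wald(log_or: float, se: float) -> tuple[float, float, float, float]:
    z = log_or / se
    p = float(2.0 * norm.sf(abs(z)))
    return math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se), z, p


def pool_fixed_mh(
    tables: list[TwoByTwo],
    contrast: Contrast = Contrast.ALLELE,
    het: Heterogeneity | None = None,
    continuity: float = 0.5,
) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled OR.

    Studies containing a zero cell get the continuity constant added to all
    four of their cells (the convention of the standard meta-analysis
    software for this literature); other studies contribute raw counts.  The
    variance of the log pooled OR is Robins-Breslow-Greenland.  Heterogeneity
    is computed from the per-study Woolf effects unless supplied.
    """
    usable = [t for t in tables if not t.double_zero]
    if not usable:
        raise PoolingError("no usable 2x2 tables (all double-zero)")
    R = S = 0.0
    sum_pr = sum_ps_qr = sum_qs = 0.0
    for t in usable:
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
        if min(a, b, c, d) == 0:
            a, b, c, d = (x + continuity for x in (a, b, c, d))
        n = a + b + c + d
        r_i = a * d / n
        s_i = b * c / n
        p_i = (a + d) / n
        q_i = (b + c) / n
        R += r_i
        S += s_i
        sum_pr += p_i * r_i
        sum_ps_qr += p_i * s_i + q_i * r_i
        sum_qs += q_i * s_i
    if R == 0 or S == 0:
        raise PoolingError("Mantel-Haenszel estimate degenerate (R or S is zero)")
    log_or = math.log(R / S)
    var = sum_pr / (2 * R * R) + sum_ps_qr / (2 * R * S) + sum_qs / (2 * S * S)
    se = math.sqrt(var)
    ci_low, ci_high, z, p = _wald(log_or, se)
    if het is None:
        het = heterogeneity([or_estimate(t) for t in usable])
    return PooledResult(
        contrast=contrast, k=len(usable), or_=math.exp(log_or),
        ci_low=ci_low, ci_high=ci_high, z=z, p=p, het=het,
        model="FE-MH", log_or=log_or, se=se,
    )


def _pool_iv(
    effects: list[EffectEstimate], tau2: float, model: str, contrast: Contrast,
    het: Heterogeneity,
) -> PooledResult:
    w = [1.0 / (e.var + tau2) for e in effects]
    sw = sum(w)
    log_or = sum(wi * e.log_or for wi, e in zip(w, effects)) / sw
    se = math.sqrt(1.0 / sw)
    ci_low, ci_high, z, p = _wald(log_or, se)
    return PooledResult(
        contrast=contrast, k=len(effects), or_=math.exp(log_or),
        ci_low=ci_low, ci_high=ci_high, z=z, p=p, het=het,
        model=model, log_or=log_or, se=se,
    )


def pool_fixed_iv(
    effects: list[EffectEstimate], contrast: Contrast = Contrast.ALLELE
) -> PooledResult:
    """Inverse-variance fixed-effect pooling (cross-check estimator)."""
    if not effects:
        raise PoolingError("no effects to pool")
    return _pool_iv(effects, 0.0, "FE-IV", contrast, heterogeneity(effects))


def pool_random_dl(
    effects: list[EffectEstimate], contrast: Contrast = Contrast.ALLELE
) -> PooledResult:
    """DerSimonian-Laird random-effects pooling; reduces to FE-IV when tau^2=0."""
    if not effects:
        raise PoolingError("no effects to pool")
    het = heterogeneity(effects)
    return _pool_iv(effects, het.tau2, "RE-DL", contrast, het)


def select_model(het: Heterogeneity) -> str:
    """'FE' iff P_het > 0.1 and I^2 < 50%; 'RE' otherwise (boundaries go RE)."""
    return "FE" if (het.p_het > 0.1 and het.i2 < 50.0) else "RE"


def pool_auto(
    tables: list[TwoByTwo],
    contrast: Contrast = Contrast.ALLELE,
    model: str = "auto",
    continuity: float = 0.5,
) -> PooledResult:
    """Pool usable tables under the heterogeneity-driven model choice.

    ``model`` may force ``"fe"`` (Mantel-Haenszel) or ``"re"``
    (DerSimonian-Laird); ``"auto"`` applies the selection rule.
    """
    usable = [t for t in tables if not t.double_zero]
    dropped = tuple(
        (t.study_id, "double-zero") for t in tables if t.double_zero
    )
    if not usable:
        raise PoolingError("no usable 2x2 tables (all double-zero)")
    effects = [or_estimate(t, continuity) for t in usable]
    het = heterogeneity(effects)
    choice = model.lower()
    if choice == "auto":
        choice = select_model(het).lower()
    if choice == "fe":
        result = pool_fixed_mh(usable, contrast=contrast, het=het)
    elif choice == "re":
        result = pool_random_dl(effects, contrast=contrast)
    else:
        raise ValueError(f"model must be 'auto', 'fe' or 're', got {model!r}")
    if dropped:
        result = PooledResult(**{**result.__dict__, "dropped": dropped})
    return result


def meta_analyze(
    corpus: StudyCorpus,
    contrast: Contrast,
    alpha_hwe: float = 0.05,
    hwe_arm: str = "control",
    model: str = "auto",
    continuity: float = 0.5,
    apply_filter: bool = True,
) -> PooledResult:
    """Full pipeline for one contrast: HWE filter, 2x2s, model choice, pooling.

    Arm sizes (``n_case``/``n_control``) are summed over the studies that
    actually contribute to the pooled estimate; ``dropped`` records every
    exclusion with its reason.
    """
    contrast = Contrast(contrast)
    dropped: list[tuple[str, str]] = []
    if apply_filter:
        report = apply_hwe_filter(corpus, alpha=alpha_hwe, arm=hwe_arm)
        dropped += [
            (sid, f"HWE {arm} p={p:.4g} < {alpha_hwe}")
            for sid, arm, p in report.excluded
        ]
        corpus = report.retained
    if len(corpus) == 0:
        raise PipelineError("HWE filtering left no studies to pool")
    tables = [build_contrast(r, contrast) for r in corpus]
    usable_ids = {t.study_id for t in tables if not t.double_zero}
    dropped += [
        (t.study_id, "double-zero 2x2") for t in tables if t.double_zero
    ]
    if not usable_ids:
        raise PipelineError("double-zero exclusion left no studies to pool")
    result = pool_auto(tables, contrast=contrast, model=model, continuity=continuity)
    used = [r for r in corpus if r.study_id in usable_ids]
    return PooledResult(
        **{
            **result.__dict__,
            "n_case": sum(r.case.n for r in used),
            "n_control": sum(r.control.n for r in used),
            "dropped": tuple(dropped),
        }
    )


def study_effects(
    corpus: StudyCorpus,
    contrast: Contrast,
    continuity: float = 0.5,
) -> list[EffectEstimate]:
    """Per-study Woolf effects for a contrast, skipping double-zero studies."""
    out = []
    for r in corpus:
        t = build_contrast(r, Contrast(contrast))
        if not t.double_zero:
            out.append(or_estimate(t, continuity))
    return out
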