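"""Genetic-model contrasts and per-study odds ratios.

Each biallelic genotype table (aa / ab / bb per arm) collapses into a 2x2
exposure table under one of five standard contrasts:

==============  =======================================
allele          variant vs common allele (counts alleles, 2n per arm)
homozygote      bb vs aa (drops heterozygotes)
heterozygote    ab vs aa (drops variant homozygotes)
dominant        ab+bb vs aa
recessive       bb vs aa+ab
==============  =======================================

Per-study odds ratios use the Woolf log-normal method: OR = ad/bc,
SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d), 95% CI = exp(log OR +/- 1.96 SE).
A single zero cell triggers the conventional 0.5 continuity correction on
all four cells of that study; a table whose exposure class is empty in both
arms carries no information about the odds ratio and is signalled so pooling
can drop it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .corpus import StudyRecord
from .errors import EstimateUndefinedError

Z_95 = 1.96  # normal quantile used for all 95% intervals


class Contrast(str, enum.Enum):
    """The five genetic-model comparisons."""

    ALLELE = "allele"
    HOMOZYGOTE = "homozygote"
    HETEROZYGOTE = "heterozygote"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    def describe(self, common: str = "A", variant: str = "B") -> str:
        a, b = common, variant
        return {
            Contrast.ALLELE: f"{b} vs {a}",
            Contrast.HOMOZYGOTE: f"{b}{b} vs {a}{a}",
            Contrast.HETEROZYGOTE: f"{a}{b} vs {a}{a}",
            Contrast.DOMINANT: f"{a}{b}+{b}{b} vs {a}{a}",
            Contrast.RECESSIVE: f"{b}{b} vs {a}{a}+{a}{b}",
        }[self]


ALL_CONTRASTS = tuple(Contrast)


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 exposure table: a/b exposed/unexposed cases, c/d same for controls."""

    a: int
    b: int
    c: int
    d: int
    unit: str = "individuals"  # "alleles" for the allele contrast
    study_id: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def double_zero(self) -> bool:
        """True when an entire exposure column is empty in both arms."""
        return (self.a == 0 and self.c == 0) or (self.b == 0 and self.d == 0)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study Woolf log odds ratio with standard error and 95% CI."""

    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    corrected: bool = False
    study_id: str = ""

    @property
    def var(self) -> float:
        return self.se * self.se


def build_contrast(record: StudyRecord, contrast: Contrast) -> TwoByTwo:
    """Collapse a study's genotype counts into the 2x2 for one contrast."""
    contrast = Contrast(contrast)
    ca, co = record.case, record.control
    if contrast is Contrast.ALLELE:
        return TwoByTwo(
            a=ca.allele_variant, b=ca.allele_common,
            c=co.allele_variant, d=co.allele_common,
            unit="alleles", study_id=record.study_id,
        )
    if contrast is Contrast.HOMOZYGOTE:
        cells = (ca.n_bb, ca.n_aa, co.n_bb, co.n_aa)
    elif contrast is Contrast.HETEROZYGOTE:
        cells = (ca.n_ab, ca.n_aa, co.n_ab, co.n_aa)
    elif contrast is Contrast.DOMINANT:
        cells = (ca.n_ab + ca.n_bb, ca.n_aa, co.n_ab + co.n_bb, co.n_aa)
    else:  # recessive
        cells = (ca.n_bb, ca.n_aa + ca.n_ab, co.n_bb, co.n_aa + co.n_ab)
    return TwoByTwo(*cells, unit="individuals", study_id=record.study_id)


def or_estimate(t: TwoByTwo, continuity: float = 0.5) -> EffectEstimate:
    """Woolf odds-ratio estimate for one 2x2 table.

    Raises :class:`EstimateUndefinedError` for double-zero tables, which
    pooling should drop rather than correct.
    """
    if t.double_zero:
        raise EstimateUndefinedError(
            f"study {t.study_id or '<anon>'}: exposure class empty in both arms"
        )
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + continuity, b + continuity, c + continuity, d + continuity
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        corrected=corrected,
        study_id=t.study_id,
    )
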