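"""Etiology subgroup analysis and leave-one-out sensitivity analysis.

Subgroups are pooled independently: each partition gets its own
heterogeneity estimate, its own fixed/random model choice and its own
tau^2.  Single-study subgroups carry the study's Woolf estimate with the
k=1 heterogeneity conventions (Q=0, I^2=0, P_het=1).

The leave-one-out analysis re-pools the corpus k times, omitting one study
each time, under the random-effects model by default; the report flags
whether every omission keeps the pooled CI excluding 1 on the same side as
the full analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import StudyCorpus
from .errors import InsufficientStudiesError
from .hwe import apply_hwe_filter
from .models import Contrast
from .pooling import PooledResult, meta_analyze


@dataclass(frozen=True)
class SubgroupReport:
    """Per-etiology pooled results plus the overall analysis."""

    by: str
    contrast: Contrast
    groups: dict[str, PooledResult]
    overall: PooledResult


@dataclass(frozen=True)
class SensitivityReport:
    """Leave-one-out re-poolings and the stability flag."""

    contrast: Contrast
    model: str
    full: PooledResult
    omissions: tuple[tuple[str, PooledResult], ...]

    @property
    def all_significant(self) -> bool:
        """True iff every omission keeps the CI excluding 1 on the full
        analysis' side (False when the full CI already includes 1)."""
        if self.full.ci_low > 1.0:
            return all(r.ci_low > 1.0 for _, r in self.omissions)
        if self.full.ci_high < 1.0:
            return all(r.ci_high < 1.0 for _, r in self.omissions)
        return False


def subgroup_analysis(
    corpus: StudyCorpus,
    contrast: Contrast,
    by: str = "disease",
    alpha_hwe: float = 0.05,
    hwe_arm: str = "control",
    model: str = "auto",
    apply_filter: bool = True,
) -> SubgroupReport:
    """Pool each etiology partition independently, plus the overall corpus.

    Partitions appear in first-encounter (input) order.  Model selection runs
    per partition, so a heterogeneous overall analysis may still use fixed
    effects inside a homogeneous subgroup.
    """
    contrast = Contrast(contrast)
    if apply_filter:
        corpus = apply_hwe_filter(corpus, alpha=alpha_hwe, arm=hwe_arm).retained
    overall = meta_analyze(corpus, contrast, model=model, apply_filter=False)
    groups = {
        label: meta_analyze(part, contrast, model=model, apply_filter=False)
        for label, part in corpus.partition(by).items()
    }
    return SubgroupReport(by=by, contrast=contrast, groups=groups, overall=overall)


def leave_one_out(
    corpus: StudyCorpus,
    contrast: Contrast,
    model: str = "re",
    alpha_hwe: float = 0.05,
    hwe_arm: str = "control",
    apply_filter: bool = True,
) -> SensitivityReport:
    """Re-pool k times, omitting one study per pass (random effects by default)."""
    contrast = Contrast(contrast)
    if apply_filter:
        corpus = apply_hwe_filter(corpus, alpha=alpha_hwe, arm=hwe_arm).retained
    if len(corpus) < 2:
        raise InsufficientStudiesError(
            f"leave-one-out needs k >= 2 after filtering, got {len(corpus)}"
        )
    full = meta_analyze(corpus, contrast, model=model, apply_filter=False)
    omissions = tuple(
        (r.study_id,
         meta_analyze(corpus.without(r.study_id), contrast, model=model,
                      apply_filter=False))
        for r in corpus
    )
    return SensitivityReport(
        contrast=contrast, model=model, full=full, omissions=omissions
    )
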