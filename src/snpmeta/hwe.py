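"""Hardy-Weinberg equilibrium testing and study exclusion.

Genotype counts in a population sample are expected at proportions
p^2 : 2pq : q^2 under random mating.  Departure in the *control* arm of a
case-control study signals genotyping error or sampling bias, so studies
whose controls fail a Pearson chi-square goodness-of-fit test (1 df, no
continuity correction) at P < 0.05 are excluded before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as chi2_dist

from .corpus import GenotypeCounts, StudyCorpus, StudyRecord
from .errors import UndefinedInputError


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square HWE test outcome for one arm."""

    chi2: float
    df: int
    p: float
    maf: float
    monomorphic: bool = False


def hwe_test(g: GenotypeCounts) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions.

    Expected counts come from the observed allele frequencies:
    ``n*p^2, 2n*p*q, n*q^2``.  The statistic is referred to chi-square with
    1 df (3 genotype classes, 1 estimated allele frequency).  A monomorphic
    arm (one allele absent) has nothing to test and maps to the degenerate
    result chi2=0, p=1.
    """
    n = g.n
    if n == 0:
        raise UndefinedInputError("HWE test undefined for an empty arm (n=0)")
    p_hat = g.allele_common / (2 * n)
    q_hat = g.allele_variant / (2 * n)
    maf = min(p_hat, q_hat)
    if g.monomorphic:
        return HWEResult(chi2=0.0, df=1, p=1.0, maf=maf, monomorphic=True)
    expected = (n * p_hat * p_hat, 2 * n * p_hat * q_hat, n * q_hat * q_hat)
    observed = (g.n_aa, g.n_ab, g.n_bb)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HWEResult(chi2=chi2, df=1, p=float(chi2_dist.sf(chi2, 1)), maf=maf)


@dataclass(frozen=True)
class FilterReport:
    """Outcome of applying the HWE exclusion rule to a corpus."""

    retained: StudyCorpus
    excluded: tuple[tuple[str, str, float], ...]  # (study_id, arm, p)
    alpha: float

    @property
    def excluded_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _, _ in self.excluded)


def _arm_results(record: StudyRecord, arm: str) -> list[tuple[str, HWEResult]]:
    if arm == "control":
        return [("control", hwe_test(record.control))]
    if arm == "case":
        return [("case", hwe_test(record.case))]
    if arm == "both":
        return [("case", hwe_test(record.case)), ("control", hwe_test(record.control))]
    raise ValueError(f"arm must be 'control', 'case' or 'both', got {arm!r}")


def apply_hwe_filter(
    corpus: StudyCorpus, alpha: float = 0.05, arm: str = "control"
) -> FilterReport:
    """Partition a corpus into HWE-consistent and HWE-departing studies.

    A record is retained iff the designated arm(s) give p >= alpha.
    Monomorphic arms score p = 1 and are always retained.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for record in corpus:
        failing = [
            (which, res) for which, res in _arm_results(record, arm) if res.p < alpha
        ]
        if failing:
            which, res = failing[0]
            dropped.append((record.study_id, which, res.p))
        else:
            kept.append(record.study_id)
    return FilterReport(
        retained=corpus.subset(kept), excluded=tuple(dropped), alpha=alpha
    )
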