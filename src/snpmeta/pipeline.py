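"""End-to-end analysis pipeline and published-table reproduction report.

``run_pipeline`` executes the whole workflow for one study table: HWE
filtering, all five genetic-model contrasts, heterogeneity-driven model
choice, pooling, subgroup and leave-one-out analyses, publication-bias
tests and plot-ready forest/funnel tables, written deterministically under
an output directory.

``reproduce_reference`` recomputes every pooled row of the bundled
published-results table from the bundled genotype fixtures and reports
computed vs printed values side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .bias import begg_test, egger_test, funnel_data
from .corpus import StudyCorpus, load_fixture, read_study_table
from .errors import InsufficientStudiesError, SnpMetaError
from .hwe import apply_hwe_filter
from .models import ALL_CONTRASTS, Contrast
from .pooling import meta_analyze, study_effects
from .reporting import (
    effects_frame,
    forest_frame,
    to_serializable,
    write_results,
)
from .subgroup import leave_one_out, subgroup_analysis

log = logging.getLogger(__name__)

#: Absolute tolerance for OR/CI agreement with printed 2-decimal values; wide
#: intervals get a relative allowance on top (printed rounding plus software
#: variant ambiguity).
OR_ABS_TOL = 0.02
OR_REL_TOL = 0.01


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and switches; defaults reproduce the published pipeline."""

    hwe_alpha: float = 0.05
    hwe_arm: str = "control"
    contrasts: tuple[Contrast, ...] = ALL_CONTRASTS
    model: str = "auto"
    continuity: float = 0.5
    subgroup_key: str = "disease"
    loo_model: str = "re"
    output_dir: Path | None = None


def run_pipeline(
    table: str | Path | StudyCorpus, config: PipelineConfig = PipelineConfig()
) -> dict[str, dict]:
    """Run every analysis for a study table; optionally write a report bundle.

    Returns a mapping ``contrast value -> report dict`` with keys ``pooled``,
    ``subgroups``, ``leave_one_out``, ``egger``, ``begg`` (bias entries are
    None when fewer than three studies remain).
    """
    if isinstance(table, StudyCorpus):
        corpus = table
    else:
        corpus = read_study_table(table)
    filt = apply_hwe_filter(corpus, alpha=config.hwe_alpha, arm=config.hwe_arm)
    log.info(
        "read %d records; HWE filter retained %d, excluded %d",
        len(corpus), len(filt.retained), len(filt.excluded),
    )
    out: dict[str, dict] = {}
    for contrast in config.contrasts:
        pooled = meta_analyze(
            filt.retained, contrast, model=config.model,
            continuity=config.continuity, apply_filter=False,
        )
        log.info("contrast %s: model %s, k=%d", contrast.value, pooled.model, pooled.k)
        effects = study_effects(filt.retained, contrast, config.continuity)
        sub = subgroup_analysis(
            filt.retained, contrast, by=config.subgroup_key,
            model=config.model, apply_filter=False,
        )
        loo = (
            leave_one_out(
                filt.retained, contrast, model=config.loo_model, apply_filter=False
            )
            if len(effects) >= 2
            else None
        )
        try:
            egger = egger_test(effects)
            begg = begg_test(effects)
        except InsufficientStudiesError:
            egger = begg = None
        report = {
            "pooled": pooled,
            "effects": effects,
            "subgroups": sub,
            "leave_one_out": loo,
            "egger": egger,
            "begg": begg,
            "funnel": funnel_data(effects, pooled),
            "hwe_excluded": filt.excluded,
        }
        out[contrast.value] = report
        if config.output_dir is not None:
            _write_bundle(contrast, report, Path(config.output_dir))
    return out


def _write_bundle(contrast: Contrast, report: dict, outdir: Path) -> None:
    sub = outdir / contrast.value
    sub.mkdir(parents=True, exist_ok=True)
    write_results(report["pooled"], sub / "pooled.json", "json")
    write_results(effects_frame(report["effects"]), sub / "effects.tsv", "tsv")
    write_results(
        forest_frame(report["effects"], report["pooled"]), sub / "forest.tsv", "tsv"
    )
    write_results(report["subgroups"], sub / "subgroups.json", "json")
    if report["leave_one_out"] is not None:
        write_results(report["leave_one_out"], sub / "leave_one_out.json", "json")
    if report["egger"] is not None:
        write_results(
            {"egger": to_serializable(report["egger"]),
             "begg": to_serializable(report["begg"])},
            sub / "bias.json", "json",
        )
    write_results(report["funnel"].points, sub / "funnel_points.tsv", "tsv")
    write_results(report["funnel"].boundary, sub / "funnel_boundary.tsv", "tsv")
    excl = pd.DataFrame(
        report["hwe_excluded"], columns=["study_id", "arm", "p_hwe"]
    )
    write_results(excl, sub / "hwe_excluded.tsv", "tsv")


def load_reference_results() -> pd.DataFrame:
    """The bundled transcription of the published pooled-result tables."""
    ref = resources.files("snpmeta.data").joinpath("reference_results.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype={"i2": str, "p_het": str})


def _tolerance(value: float) -> float:
    return max(OR_ABS_TOL, OR_REL_TOL * abs(value))


def reproduce_reference(model: str = "auto") -> pd.DataFrame:
    """Recompute every published pooled row from the bundled fixtures.

    Returns one row per reference row with computed OR/CI/model alongside the
    printed values, absolute differences, and a ``pass`` flag at tolerance
    ``max(0.02, 1%)`` on OR and CI bounds plus exact k and model-label match
    (single-study rows print '-' and skip the label comparison).
    """
    reference = load_reference_results().rename(columns={"or": "or_"})
    corpora = {
        name: apply_hwe_filter(load_fixture(name)).retained
        for name in ("tgfb1_509", "tgfb1_codon10", "tgfb1_codon25")
    }
    rows = []
    for rec in reference.itertuples(index=False):
        corpus = corpora[rec.polymorphism]
        if rec.subgroup != "Overall":
            corpus = corpus.partition("disease").get(rec.subgroup)
            if corpus is None:
                raise SnpMetaError(
                    f"reference subgroup {rec.subgroup!r} absent from "
                    f"{rec.polymorphism} after HWE filtering"
                )
        pooled = meta_analyze(
            corpus, Contrast(rec.contrast), model=model, apply_filter=False
        )
        model_label = "-" if pooled.single_study else pooled.model[:2]
        ok = (
            pooled.k == rec.k
            and abs(pooled.or_ - rec.or_) <= _tolerance(rec.or_)
            and abs(pooled.ci_low - rec.ci_low) <= _tolerance(rec.ci_low)
            and abs(pooled.ci_high - rec.ci_high) <= _tolerance(rec.ci_high)
            and (rec.model == "-" or model_label == rec.model)
        )
        rows.append(
            {
                "table": rec.table,
                "polymorphism": rec.polymorphism,
                "contrast": rec.contrast,
                "subgroup": rec.subgroup,
                "k_printed": rec.k,
                "k": pooled.k,
                "or_printed": rec.or_,
                "or": round(pooled.or_, 4),
                "ci_low_printed": rec.ci_low,
                "ci_low": round(pooled.ci_low, 4),
                "ci_high_printed": rec.ci_high,
                "ci_high": round(pooled.ci_high, 4),
                "model_printed": rec.model,
                "model": model_label,
                "pass": ok,
            }
        )
    return pd.DataFrame(rows)
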