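"""Deterministic serialization and text rendering of analysis results.

Floats are rendered at 6 significant digits with fixed key/column order, so
two writes of the same object are byte-identical.  Text rendering mirrors
the conventions of the epidemiology literature: OR and CI at 2 decimals,
I^2 as an integer percent, p-values floored at "<0.00001", and "-" for
heterogeneity columns of single-study rows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd

from .bias import BiasResult
from .models import EffectEstimate
from .pooling import Heterogeneity, PooledResult
from .subgroup import SensitivityReport, SubgroupReport

SCHEMA_VERSION = "1"

P_FLOOR = 1e-5


def sig6(x: float) -> float:
    """Round to 6 significant digits (deterministic float rendering)."""
    return float(f"{x:.6g}")


def pooled_to_dict(r: PooledResult) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "contrast": r.contrast.value,
        "or": sig6(r.or_),
        "ci_low": sig6(r.ci_low),
        "ci_high": sig6(r.ci_high),
        "z": sig6(r.z),
        "p": sig6(r.p),
        "q": sig6(r.het.q),
        "p_het": sig6(r.het.p_het),
        "i2": sig6(r.het.i2),
        "tau2": sig6(r.het.tau2),
        "model": r.model,
        "k": r.k,
        "n_case": r.n_case,
        "n_control": r.n_control,
        "dropped": [list(d) for d in r.dropped],
    }


def bias_to_dict(r: BiasResult) -> dict[str, Any]:
    out: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "method": r.method,
        "statistic": sig6(r.statistic),
        "p": sig6(r.p),
        "k": r.k,
    }
    if r.method == "egger":
        out["intercept"] = sig6(r.intercept)
        out["intercept_se"] = sig6(r.intercept_se)
        out["slope"] = sig6(r.slope)
    else:
        out["tau_kendall"] = sig6(r.tau_kendall)
    return out


def to_serializable(obj: Any) -> Any:
    """Convert any snpmeta result object to plain JSON-ready structures."""
    if isinstance(obj, PooledResult):
        return pooled_to_dict(obj)
    if isinstance(obj, BiasResult):
        return bias_to_dict(obj)
    if isinstance(obj, SubgroupReport):
        return {
            "schema_version": SCHEMA_VERSION,
            "by": obj.by,
            "contrast": obj.contrast.value,
            "overall": pooled_to_dict(obj.overall),
            "groups": {label: pooled_to_dict(r) for label, r in obj.groups.items()},
        }
    if isinstance(obj, SensitivityReport):
        return {
            "schema_version": SCHEMA_VERSION,
            "contrast": obj.contrast.value,
            "model": obj.model,
            "all_significant": obj.all_significant,
            "full": pooled_to_dict(obj.full),
            "omissions": [
                {"omitted": sid, **pooled_to_dict(r)} for sid, r in obj.omissions
            ],
        }
    if isinstance(obj, Heterogeneity):
        return {
            "q": sig6(obj.q), "df": obj.df, "p_het": sig6(obj.p_het),
            "i2": sig6(obj.i2), "tau2": sig6(obj.tau2),
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: to_serializable(v)
            for k, v in dataclasses.asdict(obj).items()
        }
    if isinstance(obj, float):
        return sig6(obj)
    if isinstance(obj, (list, tuple)):
        return [to_serializable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: to_serializable(v) for k, v in obj.items()}
    return obj


def effects_frame(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Per-study effect table with fixed column order."""
    return pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "or": [sig6(e.or_) for e in effects],
            "ci_low": [sig6(e.ci_low) for e in effects],
            "ci_high": [sig6(e.ci_high) for e in effects],
            "log_or": [sig6(e.log_or) for e in effects],
            "se": [sig6(e.se) for e in effects],
            "corrected": [e.corrected for e in effects],
        }
    )


def forest_frame(effects: list[EffectEstimate], pooled: PooledResult) -> pd.DataFrame:
    """Forest-plot data: per-study OR/CI plus percent weight under the pooled model."""
    tau2 = pooled.het.tau2 if pooled.model == "RE-DL" else 0.0
    w = [1.0 / (e.var + tau2) for e in effects]
    sw = sum(w)
    return pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "or": [sig6(e.or_) for e in effects],
            "ci_low": [sig6(e.ci_low) for e in effects],
            "ci_high": [sig6(e.ci_high) for e in effects],
            "weight_pct": [sig6(100.0 * wi / sw) for wi in w],
        }
    )


def write_results(results: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a result object deterministically to JSON or TSV."""
    path = Path(path)
    if format == "json":
        payload = to_serializable(results)
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    elif format == "tsv":
        if isinstance(results, pd.DataFrame):
            frame = results
        else:
            payload = to_serializable(results)
            if isinstance(payload, dict):
                flat = {
                    k: v for k, v in payload.items()
                    if not isinstance(v, (dict, list))
                }
                frame = pd.DataFrame([flat])
            else:
                frame = pd.DataFrame(payload)
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    else:
        raise ValueError(f"format must be 'json' or 'tsv', got {format!r}")


# --- text rendering -------------------------------------------------------

def fmt_or_ci(r: PooledResult) -> str:
    return f"{r.or_:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})"


def fmt_p(p: float) -> str:
    if p < P_FLOOR:
        return "<0.00001"
    return f"{p:.5g}"


def fmt_het(r: PooledResult) -> tuple[str, str]:
    """(I^2 percent, P_het) strings; single-study rows print '-'."""
    if r.single_study:
        return "-", "-"
    return f"{round(r.het.i2):d}", fmt_p(r.het.p_het)


def render_pooled_line(label: str, r: PooledResult) -> str:
    i2, p_het = fmt_het(r)
    model = "-" if r.single_study else r.model
    return (
        f"{label}\tk={r.k}\t{fmt_or_ci(r)}\tP={fmt_p(r.p)}\t"
        f"I2={i2}\tP_het={p_het}\t{model}"
    )
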