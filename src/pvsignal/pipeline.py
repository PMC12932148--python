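"""End-to-end pipeline: ingest -> dedup/code -> describe -> detect -> onset.

One declarative :class:`RunConfig` drives the whole flow; every stage
failure is re-raised as :class:`PipelineError` naming the stage. The output
directory receives delimited text tables for each stage plus a
machine-readable run manifest (input hashes, echoed config, package
version) so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import List, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .contingency import build_tables
from .curation import (MeddraMap, build_corpus, code_events, load_toy_meddra,
                       primary_suspect_caseids, select_primary_suspect)
from .faers_io import read_quarters
from .onset import WeibullOnsetModel, collect_onsets
from .signals import DisproportionalityModel, SignalCriteria
from .summaries import characteristics_table, format_characteristics


class RunConfig(BaseModel):
    """Declarative configuration of one pipeline run."""

    quarters: List[str]
    target_patterns: List[str] = Field(default_factory=lambda: ["CHOLESTYRAMINE"])
    meddra_path: Optional[str] = None   # None -> packaged toy dictionary
    criteria: SignalCriteria = SignalCriteria()
    zero_policy: str = "shift_half_day"
    output_dir: str = "pvsignal_out"

    model_config = {"arbitrary_types_allowed": True}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full flow and return the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        bundle, parse_report = read_quarters(config.quarters)
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    try:
        corpus, curation_report = build_corpus(bundle)
        mmap = (MeddraMap.from_file(config.meddra_path)
                if config.meddra_path else load_toy_meddra())
        corpus, unmapped = code_events(corpus, mmap)
        target = primary_suspect_caseids(corpus, config.target_patterns)
        if not target:
            raise ValueError(
                f"no case matches target patterns {config.target_patterns}")
        filtered = select_primary_suspect(corpus, config.target_patterns)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("curate", exc) from exc

    try:
        tables = characteristics_table(filtered)
        (out / "characteristics.txt").write_text(
            format_characteristics(tables), encoding="utf-8")
    except Exception as exc:
        raise PipelineError("describe", exc) from exc

    detect_outputs = {}
    for level in ("PT", "SOC"):
        try:
            model = DisproportionalityModel(
                build_tables(corpus, target, level), criteria=config.criteria)
            res = model.fit()
            path = out / f"signals_{level.lower()}.txt"
            res.to_delimited(path)
            detect_outputs[level] = res
        except Exception as exc:
            raise PipelineError(f"detect-{level}", exc) from exc

    try:
        samples, excl = collect_onsets(filtered)
        onset_summary = None
        if len(samples) >= 10 and (samples["onset_days"] > 0).sum() >= 10:
            om = WeibullOnsetModel(samples, zero_policy=config.zero_policy)
            ores = om.fit()
            ores.bins().to_csv(out / "onset_bins.txt", sep="\t", index=False)
            ores.cumulative_incidence().to_csv(
                out / "onset_curve.txt", sep="\t", index=False)
            onset_summary = {
                "shape": ores.shape, "scale": ores.scale,
                "n_used": ores.n_used, "log_likelihood": ores.log_likelihood,
            }
    except Exception as exc:
        raise PipelineError("onset", exc) from exc

    manifest = {
        "pvsignal_version": __version__,
        "python": platform.python_version(),
        "pandas": pd.__version__,
        "config": json.loads(config.model_dump_json()),
        "inputs": {
            d: {f.name: _sha256(f) for f in sorted(Path(d).glob("*.txt"))}
            for d in config.quarters
        },
        "parse_report": {
            "line_counts": parse_report.line_counts,
            "orphans": parse_report.orphans,
            "warnings": parse_report.warnings,
        },
        "curation": {
            "n_input_versions": curation_report.n_input_versions,
            "n_cases": curation_report.n_cases,
            "n_deleted": curation_report.n_deleted,
            "unmapped_pts": unmapped,
        },
        "onset_exclusions": {
            "n_input": excl.n_input, "n_used": excl.n_used,
            "reasons": excl.reasons,
        },
        "onset_fit": onset_summary,
        "n_target_cases": len(target),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return out
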