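"""End-to-end orchestration: parse -> collapse -> NQT -> tests -> report.

The pipeline is a pure function of (input matrix, config): two runs with
identical inputs and seed produce byte-identical tables and identical
cluster orders.  Reporting failures never abort the statistics; they are
collected into the bundle and surfaced in the run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .detest import FeatureTestResult, run_de_analysis
from .errors import MirtempoError
from .matrix_io import (
    AnalysisConfig,
    CountMatrix,
    parse_count_matrix,
    write_heatmap_text,
    write_results_table,
)
from .normalization import NormalizedMatrix, nqt_transform
from .replicate_qc import CollapsedMatrix, collapse_replicates
from .reporting import (
    ReportBundle,
    render_heatmap,
    render_html,
    render_raw_vs_nqt,
)

logger = logging.getLogger(__name__)

OUTPUT_DIRNAME = "output_files"


@dataclass
class RunManifest:
    """Provenance record written to the output directory on every run."""

    input_path: str
    config: dict
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    feature_counts: dict[str, int] = field(default_factory=dict)
    exit_status: int = 0

    def write(self, path: Path) -> Path:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")
        return path


@dataclass
class PipelineResult:
    """Everything a run produced, for programmatic consumers."""

    count_matrix: CountMatrix
    collapsed: CollapsedMatrix
    normalized: NormalizedMatrix
    results: list[FeatureTestResult]
    bundle: ReportBundle
    manifest: RunManifest


def _qc_table(collapsed: CollapsedMatrix, path: Path) -> Path:
    lines = ["timepoint\treplicate\tretained\tr\treason"]
    for decisions in collapsed.replicate_report:
        for d in decisions:
            r_txt = "" if d.r is None else f"{d.r:.6f}"
            lines.append(
                f"{d.timepoint}\t{d.replicate}\t{d.retained}\t{r_txt}\t{d.reason}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def run_pipeline(
    source: str | Path | CountMatrix,
    config: AnalysisConfig,
    out_dir: str | Path = ".",
) -> PipelineResult:
    """Run the full analysis and write the report under ``out_dir/output_files``.

    *source* may be a path to a TSV count matrix or an in-memory
    :class:`CountMatrix`.
    """
    out_root = Path(out_dir) / OUTPUT_DIRNAME
    out_root.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out_root)
    manifest = RunManifest(
        input_path=str(source) if not isinstance(source, CountMatrix) else "<memory>",
        config={
            k: v for k, v in asdict(config).items()
        },
    )

    def timed(stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 4)
        return out

    try:
        if isinstance(source, CountMatrix):
            cm = source
        else:
            cm = timed("parse", parse_count_matrix, source, config)
        manifest.feature_counts["input"] = cm.n_features

        collapsed = timed("collapse", collapse_replicates, cm, config.corr_threshold)
        n_excluded = sum(
            1
            for decisions in collapsed.replicate_report
            for d in decisions
            if not d.retained
        )
        if n_excluded:
            manifest.warnings.append(f"{n_excluded} replicate column(s) excluded by QC")

        nm = timed("normalize", nqt_transform, collapsed, config)
        results = timed("detest", run_de_analysis, nm, config)
    except MirtempoError:
        manifest.exit_status = 1
        manifest.write(out_root / "run_manifest.json")
        raise

    linear_idx = [
        i for i, r in enumerate(results) if r.classification == "linear_significant"
    ]
    nonlinear_idx = [
        i for i, r in enumerate(results) if r.classification == "nonlinear_significant"
    ]
    manifest.feature_counts.update(
        {
            "linear_significant": len(linear_idx),
            "nonlinear_significant": len(nonlinear_idx),
            "not_significant": cm.n_features - len(linear_idx) - len(nonlinear_idx),
        }
    )

    # --- tables (part of the statistical contract, failures are fatal) ---
    sig = [r for r in results if r.classification != "not_significant"]
    results_path = out_root / "significant_mirnas.tsv"
    write_results_table(sig, results_path)
    all_path = out_root / "all_results.tsv"
    write_results_table(results, all_path)
    nqt_path = out_root / "nqt_matrix.tsv"
    write_heatmap_text(nm.feature_names, nm.nqt, nqt_path)
    qc_path = _qc_table(collapsed, out_root / "replicate_qc.tsv")
    bundle.tsvs += [results_path, all_path, nqt_path, qc_path]

    # --- figures (failures collected, never fatal) ---
    sections: dict[str, Path | None] = {}

    def safe_render(key: str, fn, *args, **kwargs):
        try:
            return timed(key, fn, *args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reporting must not abort stats
            msg = f"{key} rendering failed: {exc}"
            logger.error(msg)
            bundle.errors.append(msg)
            manifest.warnings.append(msg)
            return None

    out = safe_render(
        "raw_vs_nqt", render_raw_vs_nqt, collapsed, nm, out_root / "raw_vs_nqt.png"
    )
    sections["raw_vs_nqt"] = out
    if out is not None:
        bundle.pngs.append(out)

    for key, idx, title in (
        ("linear_heatmap", linear_idx, "Linearly DE miRNAs (clustered NQT)"),
        ("nonlinear_heatmap", nonlinear_idx, "Non-linearly DE miRNAs (clustered NQT)"),
    ):
        out = safe_render(
            key,
            render_heatmap,
            [nm.feature_names[i] for i in idx],
            nm.nqt[idx] if idx else np.empty((0, nm.n_timepoints)),
            title,
            out_root / f"{key}.png",
            config.linkage,
        )
        if out is not None:
            png, tsv, order = out
            sections[key] = png
            bundle.pngs.append(png)
            if tsv is not None:
                bundle.tsvs.append(tsv)
            bundle.cluster_orders[key] = order
        else:
            sections[key] = None

    config_echo = {
        "alpha": config.alpha,
        "correlation threshold": config.corr_threshold,
        "NQT mode": config.nqt_mode,
        "seed": config.seed,
        "time points": config.n_timepoints,
        "replicates": config.n_replicates,
        "linkage": config.linkage,
        "multiple testing": config.multiple_testing,
    }
    safe_render(
        "html", render_html, bundle, config_echo, sections, bundle.tsvs,
        manifest.warnings,
    )

    manifest.write(out_root / "run_manifest.json")
    return PipelineResult(cm, collapsed, nm, results, bundle, manifest)
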