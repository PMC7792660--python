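"""End-to-end cohort pipeline.

``simulate_inputs`` writes a complete synthetic study to disk: a cohort
covariate/metrics table, a handful of imaging subjects (T2w-like phantom +
ROI mask as NIfTI-1, with a JSON ground-truth sidecar) and per-eye retinal
rasters (PNG) with width tables (CSV). ``run_pipeline`` consumes such a
directory — or any directory laid out the same way from real data — and
writes per-subject PVS metrics, per-eye retinal metrics, the descriptives
table, the bootstrapped Spearman correlation matrix with FDR-adjusted
q values, and the covariate-adjusted model results, plus a deterministic
run log with per-subject QC status and the exclusion tally.

A failing subject never aborts the cohort run: its failure is logged, the
subject is excluded, and the exclusion tally is reported, mirroring how
observational imaging studies account for unprocessable scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .associations import RetinaPVSAssociation, describe_cohort
from .cohort import BRAIN_VARIABLES, RETINAL_VARIABLES, read_cohort_table
from .config import PipelineConfig
from .image import read_mask, read_volume
from .morphometry import subject_summary
from .retina import RetinalWidths, compute_retinal_metrics
from .segmentation import segment_subject
from .synthetic import (CohortSimParams, generate_cohort, generate_pvs_phantom,
                        generate_retinal_phantom, write_phantom)

__all__ = ["simulate_inputs", "run_pipeline", "PipelineResult"]

_CSV_FLOAT = "%.10g"


# ---------------------------------------------------------------------------
# synthetic study on disk
# ---------------------------------------------------------------------------

def _write_png(path, binary) -> None:
    from PIL import Image

    Image.fromarray((np.asarray(binary, dtype=np.uint8)) * 255).save(str(path))


def _read_png(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(str(path))) > 0


def simulate_inputs(outdir, n_subjects: int = 381, n_imaging: int = 4,
                    n_tubes_range=(15, 45), config: PipelineConfig | None = None,
                    seed: int = 0) -> Path:
    """Write a full synthetic study directory.

    The cohort table carries covariates and simulated brain/retinal
    metrics for every subject; the first ``n_imaging`` subjects also get
    raw imaging inputs (PVS phantom volumes and retinal rasters) whose
    pipeline-computed metrics overwrite their simulated columns during
    ``run_pipeline``.
    """
    outdir = Path(outdir)
    (outdir / "imaging").mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)

    cohort = generate_cohort(CohortSimParams(n_subjects=n_subjects, seed=seed))
    cohort.to_csv(outdir / "cohort.csv", index=False, float_format=_CSV_FLOAT)

    manifest_rows = []
    for i in range(n_imaging):
        sid = cohort["subject_id"].iloc[i]
        subj_dir = outdir / "imaging" / sid
        n_tubes = int(rng.integers(n_tubes_range[0], n_tubes_range[1] + 1))
        vol, roi, tubes = generate_pvs_phantom(n_tubes, seed=int(rng.integers(2 ** 31)))
        write_phantom(subj_dir, vol, roi, tubes)
        row = {"subject_id": sid,
               "t2w": str(subj_dir / "t2w.nii.gz"),
               "roi": str(subj_dir / "roi.nii.gz")}
        for eye in ("left", "right"):
            ph = generate_retinal_phantom(seed=int(rng.integers(2 ** 31)))
            _write_png(subj_dir / f"{eye}_arteries.png", ph.artery_map)
            _write_png(subj_dir / f"{eye}_veins.png", ph.vein_map)
            ph.widths.to_csv(subj_dir / f"{eye}_widths.csv", index=False,
                             float_format=_CSV_FLOAT)
            geo = {"od_center": list(ph.od_center), "od_diameter": ph.od_diameter}
            (subj_dir / f"{eye}_geometry.json").write_text(json.dumps(geo))
            row[f"{eye}_arteries"] = str(subj_dir / f"{eye}_arteries.png")
            row[f"{eye}_veins"] = str(subj_dir / f"{eye}_veins.png")
            row[f"{eye}_widths"] = str(subj_dir / f"{eye}_widths.csv")
            row[f"{eye}_geometry"] = str(subj_dir / f"{eye}_geometry.json")
        manifest_rows.append(row)
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    config.to_yaml(outdir / "config.yaml")
    return outdir


# ---------------------------------------------------------------------------
# the pipeline proper
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Paths and accounting for one pipeline run."""

    outdir: Path
    n_input: int
    n_included: int
    exclusions: dict = field(default_factory=dict)   # subject_id -> reason

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)


def _segment_stage(manifest: pd.DataFrame, config: PipelineConfig, log: list):
    rows = []
    qc_rows = []
    failures = {}
    for _, rec in manifest.iterrows():
        sid = rec["subject_id"]
        if not isinstance(rec.get("t2w"), str):
            continue
        try:
            vol = read_volume(rec["t2w"])
            roi = read_mask(rec["roi"])
            labelled, verdict, _mask = segment_subject(vol, roi, config)
            qc_rows.append({"subject_id": sid, "qc_accepted": int(verdict.accepted),
                            "qc_reasons": "; ".join(verdict.reasons),
                            "qc_warnings": "; ".join(verdict.warnings)})
            if not verdict.accepted:
                failures[sid] = f"QC rejected: {'; '.join(verdict.reasons)}"
                log.append(f"EXCLUDE {sid}: {failures[sid]}")
                continue
            comps = labelled.components(config.components.min_voxels,
                                        config.components.max_width_mm)
            metrics = subject_summary(comps)
            rows.append({"subject_id": sid, **metrics.to_row()})
            log.append(f"OK segment {sid}: {metrics.count} PVS")
        except Exception as exc:  # never abort the cohort for one subject
            failures[sid] = f"segmentation failed: {exc}"
            qc_rows.append({"subject_id": sid, "qc_accepted": 0,
                            "qc_reasons": str(exc), "qc_warnings": ""})
            log.append(f"EXCLUDE {sid}: {failures[sid]}")
    return pd.DataFrame(rows), pd.DataFrame(qc_rows), failures


def _retina_stage(manifest: pd.DataFrame, config: PipelineConfig, log: list):
    rows = []
    failures = {}
    for _, rec in manifest.iterrows():
        sid = rec["subject_id"]
        if not isinstance(rec.get("left_widths"), str):
            continue
        row = {"subject_id": sid}
        try:
            for eye in ("left", "right"):
                widths = pd.read_csv(rec[f"{eye}_widths"])
                rw = RetinalWidths(
                    eye,
                    widths.loc[widths["vessel_type"] == "artery", "width_px"].tolist(),
                    widths.loc[widths["vessel_type"] == "vein", "width_px"].tolist(),
                )
                artery = _read_png(rec[f"{eye}_arteries"]) if isinstance(rec.get(f"{eye}_arteries"), str) else None
                vein = _read_png(rec[f"{eye}_veins"]) if isinstance(rec.get(f"{eye}_veins"), str) else None
                m = compute_retinal_metrics(rw, artery, vein, config.retina)
                row.update(m.to_row())
            rows.append(row)
            log.append(f"OK retina {sid}")
        except Exception as exc:
            failures[sid] = f"retinal measurement failed: {exc}"
            log.append(f"EXCLUDE {sid}: {failures[sid]}")
    return pd.DataFrame(rows), failures


def run_pipeline(indir, outdir=None, config: PipelineConfig | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run segmentation, retinal morphometry and association analysis.

    ``indir`` must contain ``cohort.csv`` and optionally ``manifest.csv``
    (per-subject imaging file paths) and ``config.yaml``. Metrics computed
    from imaging replace the corresponding cohort-table columns for those
    subjects; QC-rejected or failed subjects lose their metrics and drop
    out of the analysis sample. Everything stochastic derives from the
    single seed (argument wins over config).
    """
    indir = Path(indir)
    outdir = Path(outdir) if outdir is not None else indir / "results"
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        cfg_path = indir / "config.yaml"
        config = PipelineConfig.from_yaml(cfg_path) if cfg_path.exists() else PipelineConfig()
    config.validate()
    seed = config.seed if seed is None else int(seed)

    log: list[str] = [f"config: {json.dumps(config.to_dict(), sort_keys=True)}",
                      f"seed: {seed}"]
    cohort = read_cohort_table(indir / "cohort.csv")
    n_input = len(cohort)
    manifest_path = indir / "manifest.csv"
    manifest = pd.read_csv(manifest_path) if manifest_path.exists() else pd.DataFrame(columns=["subject_id"])

    pvs_df, qc_df, seg_fail = _segment_stage(manifest, config, log)
    ret_df, ret_fail = _retina_stage(manifest, config, log)
    exclusions = {**seg_fail, **ret_fail}

    # imaging-derived metrics override tabulated values
    table = cohort.set_index("subject_id")
    for df in (pvs_df, ret_df):
        if len(df):
            df = df.set_index("subject_id")
            for col in df.columns:
                table.loc[df.index, col] = df[col]
    # excluded subjects lose their metrics entirely
    metric_cols = [c for c in BRAIN_VARIABLES + RETINAL_VARIABLES if c in table.columns]
    for sid in exclusions:
        if sid in table.index:
            table.loc[sid, metric_cols] = np.nan
    table = table.reset_index()
    table["included"] = (~table[metric_cols].isna().any(axis=1)).astype(int) \
        if metric_cols else 1

    analysis = table[table["included"] == 1]
    n_included = len(analysis)
    log.append(f"subjects: input={n_input} included={n_included} "
               f"excluded={n_input - n_included}")

    # outputs
    if len(pvs_df):
        pvs_df.to_csv(outdir / "pvs_metrics.csv", index=False, float_format=_CSV_FLOAT)
    if len(qc_df):
        qc_df.to_csv(outdir / "qc_log.csv", index=False)
    if len(ret_df):
        ret_df.to_csv(outdir / "retinal_metrics.csv", index=False, float_format=_CSV_FLOAT)
    table.to_csv(outdir / "analysis_table.csv", index=False, float_format=_CSV_FLOAT)

    if table["included"].nunique() > 1:
        desc = describe_cohort(table, continuous_vars=["age"] + metric_cols)
        desc.to_csv(outdir / "descriptives.csv", index=False, float_format=_CSV_FLOAT)
    else:
        log.append("descriptives: no excluded group, comparison table skipped")

    log.append(f"associate: {n_included} subjects")
    try:
        model = RetinaPVSAssociation(analysis, params=config.stats)
        results = model.fit(seed=seed, skip_failures=True)
        results.correlations_long().to_csv(outdir / "correlations.csv", index=False,
                                           float_format=_CSV_FLOAT)
        results.correlation_matrix().to_csv(outdir / "correlation_matrix.csv",
                                            float_format=_CSV_FLOAT)
        if results.models:
            results.models_table().to_csv(outdir / "glm_results.csv", index=False,
                                          float_format=_CSV_FLOAT)
        for outcome, predictor, why in results.failures:
            log.append(f"SKIP model {outcome} ~ {predictor}: {why}")
        (outdir / "summary.txt").write_text(results.summary() + "\n")
    except ValueError as exc:
        log.append(f"associate stage failed: {exc}")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return PipelineResult(outdir, n_input, n_included, exclusions)
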