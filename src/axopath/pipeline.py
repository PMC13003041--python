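"""Pipeline orchestration: synthetic fixtures through quantification to
staging and statistics, with a manifest of every stage."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adi as adi_mod
from . import stats as stats_mod
from . import swelling as swelling_mod
from .synthetic import (
    CohortSimConfig,
    ImageSimConfig,
    generate_cohort,
    generate_image_stack,
    read_stack,
    write_cohort,
    write_stack,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and per-stage settings for a full pipeline run."""

    stacks_dir: Path | None = None
    cohort_csv: Path | None = None
    out_dir: Path = Path("axopath_out")
    seed: int = 0
    swelling_params: swelling_mod.SwellingParams = field(
        default_factory=swelling_mod.SwellingParams
    )
    staging_rule: adi_mod.StagingRule = field(default_factory=adi_mod.StagingRule)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_demo_data(out_dir: str | Path, seed: int = 0, n_stacks: int = 4) -> dict:
    """Write the synthetic fixture set: image stacks, sidecars, cohort CSV.

    Stacks are rendered in brightfield orientation (dark signal on a bright
    field) to exercise the macro's contrast-inversion step.  Returns the
    file inventory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i in range(n_stacks):
        cfg = ImageSimConfig(seed=seed * 1000 + i, render="brightfield")
        stack, gt = generate_image_stack(cfg)
        p = write_stack(stack, gt, out / f"stack_{i:02d}.tif")
        files.extend([p, p.with_suffix(".json")])
    cohort = generate_cohort(CohortSimConfig(seed=seed))
    cpath = write_cohort(cohort, out / "cohort.csv")
    files.append(cpath)
    return {
        "seed": seed,
        "files": sorted(str(f.name) for f in files),
        "n_stacks": n_stacks,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis on a stacks directory plus cohort CSV.

    Stages: swelling quantification per stack, per-run summary, per-time-
    point z-scoring and staging, group summaries, and the sex comparison at
    every time point.  All intermediates are written as CSV; the manifest
    JSON lists every output with a content hash.  Deterministic for fixed
    inputs and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}, "warnings": []}

    def stage(name: str):
        t0 = time.perf_counter()
        manifest["stages"].append({"name": name, "start": t0})
        return t0

    def done(t0: float) -> None:
        manifest["stages"][-1]["seconds"] = round(time.perf_counter() - t0, 3)

    # 1. swelling quantification
    t0 = stage("swellings")
    rows = []
    if config.stacks_dir is not None:
        stacks_dir = Path(config.stacks_dir)
        if not stacks_dir.is_dir():
            raise FileNotFoundError(f"stacks directory not found: {stacks_dir}")
        for tif in sorted(stacks_dir.glob("*.tif")):
            stack, _ = read_stack(tif)
            res = swelling_mod.quantify_stack(
                stack, config.swelling_params, stack_id=tif.stem
            )
            rows.append(
                {
                    "stack_id": tif.stem,
                    "n_swellings": res.n_swellings,
                    "median_volume_um3": res.median_volume_um3,
                    "threshold": res.threshold,
                }
            )
    swell_df = pd.DataFrame(
        rows, columns=["stack_id", "n_swellings", "median_volume_um3", "threshold"]
    )
    swell_path = out / "swellings.csv"
    swell_df.to_csv(swell_path, index=False)
    done(t0)

    # 2. cohort load
    t0 = stage("cohort")
    if config.cohort_csv is None:
        raise FileNotFoundError("a cohort CSV is required")
    cohort_path = Path(config.cohort_csv)
    if not cohort_path.exists():
        raise FileNotFoundError(f"cohort CSV not found: {cohort_path}")
    cohort = pd.read_csv(cohort_path)
    done(t0)

    # 3. staging index
    t0 = stage("adi")
    records = adi_mod.compute_adi(cohort, config.staging_rule)
    adi_df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "sex": [r.sex for r in records],
            "timepoint_days": [r.timepoint for r in records],
            "th_z": [r.th_z for r in records],
            "swelling_z": [r.sw_z for r in records],
            "stage": [r.stage for r in records],
        }
    )
    adi_path = out / "adi.csv"
    adi_df.to_csv(adi_path, index=False)
    done(t0)

    # 4. group summaries
    t0 = stage("summaries")
    summaries = adi_mod.adi_summarise(records)
    summ_df = pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "n": [s.n for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
        }
    )
    summ_path = out / "adi_groups.csv"
    summ_df.to_csv(summ_path, index=False)
    done(t0)

    # 5. sex comparisons per time point
    t0 = stage("stats")
    tests = {}
    for tp in sorted(adi_df["timepoint_days"].unique()):
        sub = adi_df[adi_df["timepoint_days"] == tp]
        males = sub.loc[sub["sex"] == "male", "stage"].tolist()
        females = sub.loc[sub["sex"] == "female", "stage"].tolist()
        if males and females:
            res = stats_mod.mann_whitney(males, females)
            tests[f"day_{tp:g}"] = {
                "method": res.method,
                "U": res.statistic,
                "p": res.p_value,
                "notes": res.notes,
            }
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(tests, indent=1))
    done(t0)

    # 6. manifest
    t0 = stage("manifest")
    for p in (swell_path, adi_path, summ_path, stats_path):
        manifest["outputs"][p.name] = {
            "sha256": _sha256(p),
            "rows": sum(1 for _ in p.open()) - 1 if p.suffix == ".csv" else None,
        }
    done(t0)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
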