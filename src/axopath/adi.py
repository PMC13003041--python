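"""Axonal Degeneration Index: z-scored staging of axonal pathology.

Axonal swellings follow an inverted-U time course — scarce early, peaking
during active degeneration, vanishing again once fibres have fragmented —
so neither fibre optical density nor swelling count alone orders animals by
degeneration stage.  The index combines both: TH optical density and
swelling counts are z-scored within each time point (across transduced
animals only, since controls present no swellings), and each animal is
assigned a stage score:

* stage 1 (early): preserved TH (z > 0.3) with few swellings (z < -0.5);
* stage 2 (intermediate): moderate TH (-0.3 <= z <= 0.3), any swelling load;
* stage 3 (advanced): depleted TH (z < -0.3) with either abundant
  (z > 0.5, active degeneration) or scarce (z < -0.5, completed fibre
  loss) swellings.

Combinations not covered by the three rules fall back to the intermediate
score (configurable); the group-level index is the arithmetic mean of the
per-animal scores, and sexes are compared with the Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TestResult, mann_whitney

logger = logging.getLogger(__name__)


@dataclass
class StagingRule:
    """Z-score thresholds of the three-stage classification.

    The quoted inequalities are strict for stages 1 and 3; the stage-2 TH
    band is closed.  Boundary values that satisfy none of the three rules
    receive ``fallback_score``.
    """

    th_high: float = 0.3
    th_low: float = -0.3
    sw_low: float = -0.5
    sw_high: float = 0.5
    fallback_score: int = 2

    def __post_init__(self) -> None:
        if not self.th_low < self.th_high:
            raise ValueError("th_low must be below th_high")
        if not self.sw_low < self.sw_high:
            raise ValueError("sw_low must be below sw_high")
        if self.fallback_score not in (1, 2, 3):
            raise ValueError("fallback_score must be 1, 2 or 3")


@dataclass
class ADIRecord:
    animal_id: str
    sex: str
    timepoint: float
    th_z: float
    sw_z: float
    stage: int


@dataclass
class ADIGroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    scores: list[int] = field(default_factory=list, repr=False)


def zscore_by_timepoint(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = ("th_od", "swelling_count"),
    group_filter: str | None = "a53t",
) -> pd.DataFrame:
    """Z-score the given variables within each time point.

    By default only transduced (``a53t``) animals enter the normalisation —
    controls carry no swelling data by design.  Uses the sample SD (n-1);
    each within-time-point z-column then has mean 0 and SD 1.  Raises if a
    time point has fewer than two animals or zero variance in a variable.
    """
    df = cohort.copy()
    if group_filter is not None:
        df = df[df["group"] == group_filter].copy()
    for var in variables:
        zcol = f"{var}_z"
        df[zcol] = np.nan
        for tp, sub in df.groupby("timepoint_days"):
            if len(sub) < 2:
                raise ValueError(
                    f"time point {tp}: need >= 2 animals to z-score {var!r}"
                )
            x = sub[var].astype(float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(
                    f"zero within-time-point SD for {var!r} at time point {tp}"
                )
            df.loc[sub.index, zcol] = (x - x.mean()) / sd
    return df


def stage_classify(th_z: float, sw_z: float, rule: StagingRule | None = None) -> int:
    """Assign a degeneration stage from the two z-scores.

    Rules are evaluated in the order 1, 3, 2; any remaining combination
    (e.g. preserved TH with moderate swellings) maps to the fallback score.
    Total over all finite inputs.
    """
    rule = rule or StagingRule()
    if not (np.isfinite(th_z) and np.isfinite(sw_z)):
        raise ValueError("stage_classify requires finite z-scores")
    if th_z > rule.th_high and sw_z < rule.sw_low:
        return 1
    if th_z < rule.th_low and (sw_z > rule.sw_high or sw_z < rule.sw_low):
        return 3
    if rule.th_low <= th_z <= rule.th_high:
        return 2
    logger.debug(
        "staging fallback used for th_z=%.3f, sw_z=%.3f -> %d",
        th_z,
        sw_z,
        rule.fallback_score,
    )
    return rule.fallback_score


def compute_adi(
    cohort: pd.DataFrame, rule: StagingRule | None = None
) -> list[ADIRecord]:
    """Z-score a cohort per time point and stage every transduced animal."""
    rule = rule or StagingRule()
    scored = zscore_by_timepoint(cohort)
    records = []
    for _, row in scored.iterrows():
        records.append(
            ADIRecord(
                animal_id=row["animal_id"],
                sex=row["sex"],
                timepoint=row["timepoint_days"],
                th_z=row["th_od_z"],
                sw_z=row["swelling_count_z"],
                stage=stage_classify(row["th_od_z"], row["swelling_count_z"], rule),
            )
        )
    return records


def adi_summarise(records: list[ADIRecord]) -> list[ADIGroupSummary]:
    """Group mean and sample SD of stage scores per sex x time point."""
    if not records:
        raise ValueError("no records to summarise")
    out = []
    df = pd.DataFrame(
        {
            "sex": [r.sex for r in records],
            "timepoint": [r.timepoint for r in records],
            "stage": [r.stage for r in records],
        }
    )
    for (sex, tp), sub in df.groupby(["sex", "timepoint"], sort=True):
        scores = sub["stage"].tolist()
        sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
        out.append(
            ADIGroupSummary(
                group=f"{sex}_{tp:g}d",
                n=len(scores),
                mean=float(np.mean(scores)),
                sd=sd,
                scores=scores,
            )
        )
    return out


def adi_compare_sexes(
    scores_male: list[int], scores_female: list[int]
) -> TestResult:
    """Mann-Whitney U comparison of male vs female stage scores.

    Male sample first, so U = R_male - n_m(n_m + 1)/2 with midranks; the
    two-sided p-value uses the tie-corrected normal approximation with
    continuity correction.
    """
    return mann_whitney(scores_male, scores_female)
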