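"""Oral glucose tolerance test (OGTT) analysis helpers.

An OGTT challenges fasted animals with an oral glucose bolus and samples
blood glucose at fixed times (here 0, 1, 2, 3 h). The total glycemic
excursion is summarized by the area under the glucose-time curve (AUC,
mg·h/dL), estimated with the composite trapezoid rule. Group results are
reported as mean ± sample SD. Both total AUC and the incremental AUC
above the subject's own baseline are available; total is the default.

Welch's t-test and one-way ANOVA are provided as thin pass-throughs to
scipy for convenience; they are routine statistics, not part of the
modelling here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, InsufficientDataError

GROUPS = ("control", "sitagliptin", "dapagliflozin", "other")


@dataclass(frozen=True)
class OGTTRecord:
    """One subject's glucose time course (times in h, glucose in mg/dL)."""

    subject_id: str
    group: str
    times_h: tuple[float, ...]
    glucose_mgdl: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        t = np.asarray(self.times_h, float)
        g = np.asarray(self.glucose_mgdl, float)
        if t.size != g.size or t.size < 2:
            raise DataError("times and glucose must align with >= 2 points")
        if not np.all(np.diff(t) > 0):
            raise DataError("times must be strictly increasing")
        if np.any(g <= 0) or not np.all(np.isfinite(g)):
            raise DataError("glucose values must be positive and finite")

    @property
    def baseline_mgdl(self) -> float:
        return self.glucose_mgdl[0]


def auc_trapezoid(times_h: Sequence[float], glucose_mgdl: Sequence[float],
                  incremental: bool = False) -> float:
    """Composite-trapezoid AUC of a glucose time course, mg·h/dL.

    With ``incremental=True`` the subject's baseline (first sample) is
    subtracted first, giving the excursion above baseline (may be
    negative if glucose dips below baseline).
    """
    t = np.asarray(times_h, float)
    g = np.asarray(glucose_mgdl, float)
    if t.size != g.size or t.size < 2:
        raise DataError("need >= 2 aligned (time, glucose) points")
    if not np.all(np.diff(t) > 0):
        raise DataError("times must be strictly increasing")
    if incremental:
        g = g - g[0]
    return float(np.trapezoid(g, t))


def record_auc(record: OGTTRecord, incremental: bool = False) -> float:
    return auc_trapezoid(record.times_h, record.glucose_mgdl, incremental)


def group_summary(records: Iterable[OGTTRecord],
                  incremental: bool = False) -> pd.DataFrame:
    """Per-group mean ± sample SD (n−1) at each time point and of the AUC.

    Returns a tidy frame with columns (group, quantity, mean, sd, n);
    ``quantity`` is ``"glucose@<t>h"`` or ``"auc"``. Singleton groups get
    ``sd = NaN`` (SD undefined for n = 1).
    """
    recs = list(records)
    if not recs:
        raise InsufficientDataError("no records")
    times = recs[0].times_h
    for r in recs:
        if r.times_h != times:
            raise DataError("all records must share the same time grid")

    rows = []
    df = pd.DataFrame(
        {
            "group": [r.group for r in recs],
            "auc": [record_auc(r, incremental) for r in recs],
            **{
                f"glucose@{t:g}h": [r.glucose_mgdl[k] for r in recs]
                for k, t in enumerate(times)
            },
        }
    )
    for grp, sub in df.groupby("group", sort=True):
        for col in df.columns.drop("group"):
            vals = sub[col].to_numpy(float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
            rows.append(
                {"group": grp, "quantity": col, "mean": float(vals.mean()),
                 "sd": sd, "n": len(vals)}
            )
    return pd.DataFrame(rows)


def welch_ttest(a: Sequence[float], b: Sequence[float]):
    """Welch's two-sample t-test (unequal variances); scipy pass-through."""
    return stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=False)


def one_way_anova(*groups: Sequence[float]):
    """One-way ANOVA across groups; scipy pass-through."""
    return stats.f_oneway(*[np.asarray(g, float) for g in groups])


def read_ogtt_csv(path: str | Path) -> list[OGTTRecord]:
    """Read long-format OGTT data (subject_id, group, time_h, glucose_mgdl)."""
    df = pd.read_csv(path, comment="#")
    missing = {"subject_id", "group", "time_h", "glucose_mgdl"} - set(df.columns)
    if missing:
        raise DataError(f"OGTT file missing columns: {sorted(missing)}")
    records = []
    for (sid, grp), sub in df.groupby(["subject_id", "group"], sort=True):
        sub = sub.sort_values("time_h")
        records.append(
            OGTTRecord(
                subject_id=str(sid), group=str(grp),
                times_h=tuple(sub["time_h"].astype(float)),
                glucose_mgdl=tuple(sub["glucose_mgdl"].astype(float)),
            )
        )
    return records


def write_ogtt_csv(records: Iterable[OGTTRecord], path: str | Path) -> None:
    rows = [
        {"subject_id": r.subject_id, "group": r.group, "time_h": t,
         "glucose_mgdl": g}
        for r in records
        for t, g in zip(r.times_h, r.glucose_mgdl)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
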