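"""Primary outcome: mean heart rate per clock hour by LABA status.

Group means are patient-first: every person-time segment contributes one
hourly profile regardless of how many minutes it holds.  The overall
LABA-minus-non-LABA difference is the unweighted mean of the 24 hourly
differences.  Two uncertainty estimates accompany it:

* a pooled-minute normal (Welch) interval, which with millions of minutes
  collapses to a degenerate band around the pooled difference; and
* a patient-level nonparametric bootstrap of the patient-first estimate,
  the honest uncertainty statement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import HourlyPatientProfile, PersonTimeSegment

__all__ = [
    "AnalysisError",
    "GroupHourCurve",
    "GroupDifference",
    "hourly_group_curve",
    "overall_group_difference",
]

_Z95 = 1.959963984540054


class AnalysisError(RuntimeError):
    """An analysis cannot proceed (e.g. an empty comparison group)."""


@dataclass
class GroupHourCurve:
    """Per-hour group means and their difference (laba - non_laba)."""

    table: pd.DataFrame  # index hour 0..23; columns per group mean/n + difference

    @property
    def difference(self) -> pd.Series:
        return self.table["difference"]


def _group_profiles(
    profiles: list[HourlyPatientProfile],
) -> dict[bool, list[HourlyPatientProfile]]:
    groups: dict[bool, list[HourlyPatientProfile]] = {True: [], False: []}
    for p in profiles:
        if p.laba_status is not None:
            groups[bool(p.laba_status)].append(p)
    return groups


def hourly_group_curve(profiles: list[HourlyPatientProfile]) -> GroupHourCurve:
    """Patient-first group means per clock hour.

    Each segment profile is weighted equally; hours where a profile has no
    data simply do not contribute to that hour's group mean.
    """
    groups = _group_profiles(profiles)
    for flag, name in ((True, "laba"), (False, "non_laba")):
        if not groups[flag]:
            raise AnalysisError(f"no {name} person-time segments in cohort")

    table = pd.DataFrame(index=pd.RangeIndex(24, name="hour"))
    for flag, name in ((True, "laba"), (False, "non_laba")):
        means = np.vstack([p.means for p in groups[flag]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN hours
            table[f"{name}_mean"] = np.nanmean(means, axis=0)
        table[f"{name}_n"] = np.sum(~np.isnan(means), axis=0)
    table["difference"] = table["laba_mean"] - table["non_laba_mean"]
    return GroupHourCurve(table)


def _patient_first_difference(curve: GroupHourCurve) -> float:
    d = curve.difference.to_numpy()
    if np.isnan(d).all():
        raise AnalysisError("no hour is covered by both groups")
    return float(np.nanmean(d))


@dataclass
class GroupDifference:
    """Overall LABA-minus-non-LABA difference with both interval styles."""

    difference: float  # patient-first (mean of hourly differences), bpm
    pooled_difference: float  # difference of pooled-minute means, bpm
    pooled_ci: tuple[float, float]
    bootstrap_ci: tuple[float, float] | None
    n_segments: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "difference_bpm": self.difference,
            "pooled_difference_bpm": self.pooled_difference,
            "pooled_ci_bpm": list(self.pooled_ci),
            "bootstrap_ci_bpm": list(self.bootstrap_ci) if self.bootstrap_ci else None,
            "n_segments": self.n_segments,
        }


def overall_group_difference(
    profiles: list[HourlyPatientProfile],
    segments: list[PersonTimeSegment] | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> GroupDifference:
    """Overall group difference with pooled-minute and bootstrap 95% CIs.

    The headline estimate is the unweighted mean over the 24 hourly
    patient-first differences.  The pooled CI needs the raw minute data
    (``segments``); the bootstrap resamples segment profiles within group
    (skipped with a warning when a group has fewer than 2 segments).
    """
    curve = hourly_group_curve(profiles)
    diff = _patient_first_difference(curve)
    groups = _group_profiles(profiles)

    # pooled-minute normal CI
    if segments is not None:
        pools = {True: [], False: []}
        for seg in segments:
            if seg.laba_status is not None:
                pools[bool(seg.laba_status)].append(seg.hr.to_numpy(dtype=float))
        stats = {}
        for flag in (True, False):
            if not pools[flag]:
                raise AnalysisError("a group has no minutes for the pooled CI")
            x = np.concatenate(pools[flag])
            stats[flag] = (x.mean(), x.var(ddof=1) if len(x) > 1 else 0.0, len(x))
        pooled_diff = stats[True][0] - stats[False][0]
        se = float(np.sqrt(stats[True][1] / stats[True][2] + stats[False][1] / stats[False][2]))
        pooled_ci = (pooled_diff - _Z95 * se, pooled_diff + _Z95 * se)
    else:
        pooled_diff, pooled_ci = diff, (np.nan, np.nan)

    # patient-level bootstrap of the patient-first estimate
    bootstrap_ci: tuple[float, float] | None = None
    if min(len(groups[True]), len(groups[False])) < 2:
        warnings.warn(
            "fewer than 2 segments in a group: bootstrap CI skipped, "
            "pooled CI only",
            stacklevel=2,
        )
    else:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        laba, non = groups[True], groups[False]
        for b in range(n_boot):
            res = [laba[i] for i in rng.integers(0, len(laba), len(laba))] + [
                non[i] for i in rng.integers(0, len(non), len(non))
            ]
            reps[b] = _patient_first_difference(hourly_group_curve(res))
        bootstrap_ci = (
            float(np.percentile(reps, 2.5)),
            float(np.percentile(reps, 97.5)),
        )

    return GroupDifference(
        difference=diff,
        pooled_difference=float(pooled_diff),
        pooled_ci=(float(pooled_ci[0]), float(pooled_ci[1])),
        bootstrap_ci=bootstrap_ci,
        n_segments={"laba": len(groups[True]), "non_laba": len(groups[False])},
    )
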