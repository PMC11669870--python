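"""Independent brute-force oracle for the self-controlled event study.

Implements the whole analysis as naive per-timestamp nested loops over
dictionaries — no shared code or arrays with the production implementation —
so the two can be compared minute-for-minute on small cohorts.
"""

import statistics

import numpy as np
import pandas as pd


def oracle_event_study(
    bundle,
    pre=180,
    post=600,
    per_side=50,
    min_control_days=10,
    step_filter=True,
):
    grid = list(range(-pre, post + 1))
    ev_vals = {r: [] for r in grid}
    ctl_vals = {r: [] for r in grid}
    nctl = {r: 0 for r in grid}
    acct = {
        "total": 0,
        "included": 0,
        "excluded_by_steps": 0,
        "excluded_no_controls": 0,
        "excluded_no_wear": 0,
    }
    minute = pd.Timedelta(minutes=1)

    for patient in bundle:
        hr = dict(patient.hr.data.items())
        steps = dict(patient.steps.data.items())
        saba_ts = list(patient.events.of_type("SABA")["timestamp"])
        saba_dates = {ts.normalize() for ts in saba_ts}
        worn_dates = sorted({ts.normalize() for ts in patient.hr.data.index})

        def window_steps(base_ts):
            worn_any, total = False, 0.0
            for off in range(-60, 61):
                t = base_ts + off * minute
                if t in steps:
                    worn_any = True
                    total += steps[t]
            return worn_any, total

        for ts in saba_ts:
            acct["total"] += 1
            if not hr:
                acct["excluded_no_wear"] += 1
                continue
            d0 = ts.normalize()
            eligible = [d for d in worn_dates if d not in saba_dates and d != d0]
            prior = [d for d in eligible if d < d0][-per_side:]
            subseq = [d for d in eligible if d > d0][:per_side]
            ctl_dates = prior + subseq
            if not ctl_dates:
                acct["excluded_no_controls"] += 1
                continue
            if step_filter:
                worn_any, ev_total = window_steps(ts)
                if not worn_any:
                    acct["excluded_no_wear"] += 1
                    continue
                ctl_totals = []
                for d in ctl_dates:
                    w, tot = window_steps(d + (ts - d0))
                    if w:
                        ctl_totals.append(tot)
                if len(ctl_totals) < 2:
                    acct["excluded_no_wear"] += 1
                    continue
                bound = statistics.mean(ctl_totals) + 2 * statistics.stdev(ctl_totals)
                if ev_total > bound:
                    acct["excluded_by_steps"] += 1
                    continue
            acct["included"] += 1
            for r in grid:
                t = ts + r * minute
                ev = hr.get(t)
                cs = [hr[d + (t - d0)] for d in ctl_dates if d + (t - d0) in hr]
                if ev is not None and len(cs) >= min_control_days:
                    ev_vals[r].append(ev)
                    ctl_vals[r].append(statistics.fmean(cs))
                    nctl[r] += len(cs)

    rows = []
    for r in grid:
        n = len(ev_vals[r])
        rows.append(
            {
                "relative_minute": r,
                "event_mean": statistics.fmean(ev_vals[r]) if n else np.nan,
                "control_mean": statistics.fmean(ctl_vals[r]) if n else np.nan,
                "difference": (
                    statistics.fmean(ev_vals[r]) - statistics.fmean(ctl_vals[r])
                    if n
                    else np.nan
                ),
                "n_events": n,
                "n_control_days": nctl[r],
            }
        )
    return pd.DataFrame(rows), acct
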