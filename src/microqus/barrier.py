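"""Transepithelial-resistance (TER) barrier-function analysis.

TER converts a raw meter reading into an area-normalized barrier metric,
``TER = (Res - Res_control) * Area`` (ohm cm^2), where Res_control is the
resistance of a blank membrane insert. Monolayers with TER between 500 and
1000 ohm cm^2 are accepted as a small-intestine barrier model. The
insonation-response statistics are: percent drop from the pre-insonation
baseline to the post-baseline minimum, the time at which the series
re-attains baseline within a tolerance, and per-condition summaries across
wells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth.ter import CONDITIONS, TERTimeSeries

BARRIER_READY_RANGE = (500.0, 1000.0)  # ohm cm^2, inclusive


@dataclass(frozen=True)
class DropSummary:
    """Insonation response of one well (or a condition average)."""

    condition: str
    baseline_ter: float
    min_ter: float
    percent_drop: float
    recovery_time: float | None  # min from series start; None if never recovered
    n_wells: int = 1
    mean_percent_drop: float | None = None

    def __post_init__(self) -> None:
        if self.percent_drop < -1e-9:
            raise ValueError("percent_drop must be >= 0")
        if self.min_ter > self.baseline_ter + 1e-9:
            raise ValueError("min_ter cannot exceed baseline_ter")


def ter(res: float, res_control: float, area: float) -> float:
    """TER in ohm cm^2 from a meter reading and blank-insert control."""
    if area <= 0:
        raise ValueError("membrane area must be > 0")
    return (res - res_control) * area


def barrier_ready(ter_value: float) -> bool:
    """True when TER lies in the accepted 500-1000 ohm cm^2 window (inclusive)."""
    lo, hi = BARRIER_READY_RANGE
    return lo <= ter_value <= hi


def percent_drop(series: TERTimeSeries, baseline_window: float) -> DropSummary:
    """Percent TER drop from the pre-insonation baseline.

    Baseline is the mean TER over ``[0, baseline_window]`` minutes; the drop
    is from baseline to the minimum TER after the window.
    """
    t = series.time
    values = series.ter()
    if t.size < 2:
        raise ValueError("need at least two samples")
    in_window = t <= baseline_window
    if not in_window.any():
        raise ValueError("baseline window contains no samples")
    if in_window.all():
        raise ValueError("baseline window spans the whole series")
    baseline = float(values[in_window].mean())
    post = values[~in_window]
    min_ter = float(post.min())
    drop = 100.0 * max(baseline - min_ter, 0.0) / baseline
    rec = recovery_time(series, baseline)
    return DropSummary(
        condition=series.condition,
        baseline_ter=baseline,
        min_ter=min(min_ter, baseline),
        percent_drop=drop,
        recovery_time=rec,
    )


def recovery_time(
    series: TERTimeSeries,
    baseline: float,
    tolerance_fraction: float = 0.01,
) -> float | None:
    """First time after the post-baseline minimum at which TER re-attains
    ``baseline * (1 - tolerance_fraction)``; None if it never does."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    values = series.ter()
    i_min = int(np.argmin(values))
    after = values[i_min + 1 :]
    if after.size == 0:
        return None
    ok = after >= baseline * (1.0 - tolerance_fraction)
    if not ok.any():
        return None
    return float(series.time[i_min + 1 + int(np.argmax(ok))])


def summarize_conditions(
    all_series,
    baseline_window: float,
    tolerance_fraction: float = 0.01,
) -> list:
    """Per-condition mean drop and recovery across wells.

    Returns one DropSummary per condition present, in the fixed order
    MB_only, US_only, US_plus_MB; ``percent_drop`` and ``recovery_time``
    are means over wells, ``baseline_ter``/``min_ter`` likewise.
    """
    by_condition: dict = {}
    for s in all_series:
        if s.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {s.condition!r}")
        by_condition.setdefault(s.condition, []).append(s)

    out = []
    for cond in CONDITIONS:
        if cond not in by_condition:
            continue
        drops = [percent_drop(s, baseline_window) for s in by_condition[cond]]
        recs = [d.recovery_time for d in drops if d.recovery_time is not None]
        mean_drop = float(np.mean([d.percent_drop for d in drops]))
        out.append(
            DropSummary(
                condition=cond,
                baseline_ter=float(np.mean([d.baseline_ter for d in drops])),
                min_ter=float(np.mean([d.min_ter for d in drops])),
                percent_drop=mean_drop,
                recovery_time=float(np.mean(recs)) if recs else None,
                n_wells=len(drops),
                mean_percent_drop=mean_drop,
            )
        )
    return out


def plot_condition_drops(summaries, path) -> None:
    """Bar chart of mean percent TER drop per insonation condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    names = [s.condition for s in summaries]
    drops = [s.percent_drop for s in summaries]
    ax.bar(names, drops, color=["#999999", "#4477aa", "#cc6677"])
    ax.set_ylabel("mean TER drop (%)")
    ax.set_xlabel("condition")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tidy per-condition summary table."""
    return pd.DataFrame(
        [
            {
                "condition": s.condition,
                "n_wells": s.n_wells,
                "baseline_ter_ohm_cm2": s.baseline_ter,
                "min_ter_ohm_cm2": s.min_ter,
                "mean_percent_drop": s.percent_drop,
                "mean_recovery_time_min": s.recovery_time,
            }
            for s in summaries
        ]
    )
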