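"""Cohort-level temporal-ordering statistics.

These are the headline quantities of the single-axon cascade analysis:
signed per-axon time differences (dT = t_later - t_earlier, positive when
the claimed order holds) summarized as mean +- SEM; strict-before /
same-frame ordering fractions at the acquisition frame interval; and
ordinary-least-squares regressions with unadjusted R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .events import EventCalls


@dataclass(frozen=True)
class DeltaTSummary:
    event_pair: tuple[str, str]  # (earlier, later)
    delta_t: tuple[float, ...]  # per-axon, h
    mean: float
    sem: float
    n: int
    n_excluded: int = 0


@dataclass(frozen=True)
class OrderingFraction:
    n_strict_before: int
    n_same_frame: int
    n_after: int

    @property
    def n(self) -> int:
        return self.n_strict_before + self.n_same_frame + self.n_after

    @property
    def fraction_strict(self) -> float:
        return self.n_strict_before / self.n if self.n else float("nan")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    constant_y: bool = False


def delta_t(
    calls: Sequence[EventCalls], earlier: str, later: str
) -> DeltaTSummary:
    """Per-axon dT = t_later - t_earlier over axons with both events.

    Axons missing either event are excluded pairwise and counted in
    ``n_excluded``.  SEM is sample sd / sqrt(n) (0 for n = 1).
    """
    diffs = []
    excluded = 0
    for c in calls:
        te, tl = c.times.get(earlier), c.times.get(later)
        if te is None or tl is None:
            excluded += 1
        else:
            diffs.append(tl - te)
    if not diffs:
        raise ValueError(
            f"no axon has both events {earlier!r} and {later!r} called"
        )
    arr = np.asarray(diffs)
    n = len(arr)
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return DeltaTSummary(
        event_pair=(earlier, later),
        delta_t=tuple(float(d) for d in diffs),
        mean=float(arr.mean()),
        sem=sem,
        n=n,
        n_excluded=excluded,
    )


def _frame_index(t: float, frame_interval: float) -> int:
    # event times from the detectors lie on the acquisition grid; the
    # epsilon guards float fuzz at frame boundaries
    return int(math.floor(t / frame_interval + 1e-6))


def ordering_fraction(
    calls: Sequence[EventCalls], earlier: str, later: str, frame_interval: float
) -> OrderingFraction:
    """Bin both event times to acquisition frames and count axons where
    the earlier event's frame strictly precedes / equals / follows the
    later event's frame.  Axons missing either event are skipped."""
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    strict = same = after = 0
    for c in calls:
        te, tl = c.times.get(earlier), c.times.get(later)
        if te is None or tl is None:
            continue
        fe, fl = _frame_index(te, frame_interval), _frame_index(tl, frame_interval)
        if fe < fl:
            strict += 1
        elif fe == fl:
            same += 1
        else:
            after += 1
    return OrderingFraction(n_strict_before=strict, n_same_frame=same, n_after=after)


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; R^2 = 1 - SS_res / SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    if np.ptp(y) == 0:
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, n=len(x), constant_y=True
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(x),
    )


@dataclass
class AtpMotilityResult:
    """Per-axon paired table and the two group regressions."""

    table: list[dict]  # per axon: decline, stall_drop, time_to_arrest
    regression_stall: RegressionResult
    regression_time_to_arrest: RegressionResult
    n_violations: int  # axons where motility dropped more than the ATP sensor
    n_excluded: int


def atp_motility_analysis(
    axons: Sequence[dict], at_time: float = 3.5
) -> AtpMotilityResult:
    """Relate ATP-sensor decline to mitochondrial stalling.

    Each axon dict provides ``axon_id``, ``perceval_decline`` (% at
    ``at_time``), ``baseline_mobile_fraction``, ``mobile_fraction_at``
    (measured at ``at_time``) and ``arrest_time`` (h or None).  Regressions:
    decline vs percent drop in mobile fraction, and decline vs remaining
    time from ``at_time`` to arrest (minutes).  Axons without an arrest
    are excluded (flagged in ``n_excluded``).
    """
    table = []
    excluded = 0
    for a in axons:
        if a.get("arrest_time") is None:
            excluded += 1
            continue
        base = a["baseline_mobile_fraction"]
        if base <= 0:
            excluded += 1
            continue
        stall_drop = 100.0 * (1.0 - a["mobile_fraction_at"] / base)
        table.append(
            {
                "axon_id": a["axon_id"],
                "perceval_decline_pct": a["perceval_decline"],
                "motility_drop_pct": stall_drop,
                "time_to_arrest_min": 60.0 * (a["arrest_time"] - at_time),
            }
        )
    if len(table) < 3:
        raise ValueError("need at least 3 axons with arrest for the regressions")
    decline = [r["perceval_decline_pct"] for r in table]
    stall = [r["motility_drop_pct"] for r in table]
    tta = [r["time_to_arrest_min"] for r in table]
    violations = sum(s > d for d, s in zip(decline, stall))
    return AtpMotilityResult(
        table=table,
        regression_stall=linear_fit(decline, stall),
        regression_time_to_arrest=linear_fit(decline, tta),
        n_violations=violations,
        n_excluded=excluded,
    )


#: Event pairs of the cascade report: (earlier, later, label).
CASCADE_PAIRS = (
    ("mito_stop", "ca_onset", "mito_arrest_to_calcium"),
    ("tmrm_drop", "ca_onset", "tmrm_drop_to_calcium"),
    ("ca_onset", "ps_exposure", "calcium_to_ps_exposure"),
    ("ca_onset", "degeneration", "calcium_to_degeneration"),
)


def cohort_report(
    calls: Sequence[EventCalls],
    frame_interval: float = 10.0 / 60.0,
    second_peak: Optional[Sequence[dict]] = None,
) -> dict:
    """Assemble dT summaries, the TMRM-vs-calcium ordering fraction and
    (optionally) second-peak correlations into one JSON-serializable
    report.  Statistics whose events were never called are reported as
    not applicable rather than zero."""
    if not calls:
        raise ValueError("empty cohort")
    report: dict = {"n_axons": len(calls), "delta_t": {}, "ordering": {}}
    for earlier, later, name in CASCADE_PAIRS:
        try:
            s = delta_t(calls, earlier, later)
            report["delta_t"][name] = {
                "mean_h": s.mean,
                "sem_h": s.sem,
                "n": s.n,
                "n_excluded": s.n_excluded,
            }
        except ValueError:
            report["delta_t"][name] = {"status": "not_applicable"}
    frac = ordering_fraction(calls, "tmrm_drop", "ca_onset", frame_interval)
    if frac.n == 0:
        report["ordering"]["tmrm_before_calcium"] = {"status": "not_applicable"}
    else:
        report["ordering"]["tmrm_before_calcium"] = {
            "n_strict_before": frac.n_strict_before,
            "n_same_frame": frac.n_same_frame,
            "n_after": frac.n_after,
            "fraction_strict": frac.fraction_strict,
        }
    if second_peak:
        frag = [r["fragmentation_time"] for r in second_peak]
        report["second_peak"] = {}
        for key in ("initiation", "duration", "intensity"):
            vals = [r[key] for r in second_peak]
            if len(vals) >= 3 and np.ptp(vals) > 0 and np.ptp(frag) > 0:
                r, _ = stats.pearsonr(vals, frag)
                report["second_peak"][f"{key}_vs_fragmentation_r"] = float(r)
            else:
                report["second_peak"][f"{key}_vs_fragmentation_r"] = None
    return report
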