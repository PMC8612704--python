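"""Canonical single-axon acquisition designs, end to end.

Each function simulates a cohort under one of the imaging protocols used
for the cascade statistics, runs the full detection pipeline on the
simulated data, and returns the cohort-level statistic.  These are the
building blocks of the analysis drivers and of the reproduction script.

Protocols:

* arrest vs calcium — mitochondria are imaged in contiguous 300-s bouts
  (one bout per 5 min) from 3.5 h post-injury until movement has ceased,
  with calcium read out once per bout; arrest time comes from the
  kymograph classifier, calcium onset from the trace detector.
* two-channel 10-min imaging — TMRM+GCaMP6 (ordering fraction), GCaMP6+
  Annexin-V (calcium -> PS), GCaMP6+mRuby3 (calcium -> degeneration).
* ATP vs motility — PercevalHR every 5 min to 3.5 h, then motility bouts
  every 5 min until arrest; percent declines and regressions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import events, kymo, ordering
from .cascade import CascadeParams, sample_event_schedule
from .simulate import default_bout_times, simulate_kymograph_bouts, simulate_traces

BOUT_INTERVAL_H = 5.0 / 60.0


def _axon_rngs(n: int, rng: np.random.Generator):
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [np.random.default_rng(int(s)) for s in seeds]


def _arrest_from_bouts(bouts) -> Optional[float]:
    summaries = [kymo.summarize_bout(b) for b in bouts]
    return kymo.arrest_time(summaries)


def mito_arrest_vs_calcium(
    n_axons: int, params: CascadeParams, rng: np.random.Generator
) -> ordering.DeltaTSummary:
    """dT between kymograph-derived mitochondrial arrest and calcium onset."""
    params = params.with_cadence("GCaMP6", BOUT_INTERVAL_H)
    calls = []
    for i, arng in enumerate(_axon_rngs(n_axons, rng)):
        sched = sample_event_schedule(params, f"axon{i:03d}", arng)
        bouts = simulate_kymograph_bouts(
            sched, params, default_bout_times(sched, BOUT_INTERVAL_H), arng
        )
        traces = simulate_traces(sched, params, arng, channels=("GCaMP6",))
        t, v = traces.channels["GCaMP6"]
        base = events.compute_baseline(t, v, traces.baseline_window)
        ca_time, _ = events.detect_calcium_onset(t, v, base)
        c = events.EventCalls(axon_id=sched.axon_id)
        c.times["mito_stop"] = _arrest_from_bouts(bouts)
        c.times["ca_onset"] = ca_time
        calls.append(c)
    return ordering.delta_t(calls, "mito_stop", "ca_onset")


def _two_channel_delta_t(
    n_axons, params, rng, channels, earlier, later
) -> ordering.DeltaTSummary:
    calls = []
    for i, arng in enumerate(_axon_rngs(n_axons, rng)):
        sched = sample_event_schedule(params, f"axon{i:03d}", arng)
        traces = simulate_traces(sched, params, arng, channels=channels)
        calls.append(events.detect_all(traces))
    return ordering.delta_t(calls, earlier, later)


def calcium_vs_annexin(
    n_axons: int, params: CascadeParams, rng: np.random.Generator
) -> ordering.DeltaTSummary:
    """dT between calcium onset and phosphatidylserine exposure (h)."""
    return _two_channel_delta_t(
        n_axons, params, rng, ("GCaMP6", "AnnexinV"), "ca_onset", "ps_exposure"
    )


def calcium_vs_degeneration(
    n_axons: int, params: CascadeParams, rng: np.random.Generator
) -> ordering.DeltaTSummary:
    """dT between calcium onset and the beginning of degeneration (h)."""
    return _two_channel_delta_t(
        n_axons, params, rng, ("GCaMP6", "mRuby3"), "ca_onset", "degeneration"
    )


def tmrm_vs_calcium_ordering(
    n_axons: int, params: CascadeParams, rng: np.random.Generator
) -> ordering.OrderingFraction:
    """Frame ordering of the TMRM drastic drop vs calcium onset at the
    two-channel 10-min acquisition cadence."""
    frame = params.channel_cadences["GCaMP6"]
    calls = []
    for i, arng in enumerate(_axon_rngs(n_axons, rng)):
        sched = sample_event_schedule(params, f"axon{i:03d}", arng)
        traces = simulate_traces(sched, params, arng, channels=("GCaMP6", "TMRM"))
        calls.append(events.detect_all(traces))
    return ordering.ordering_fraction(calls, "tmrm_drop", "ca_onset", frame)


def atp_vs_motility(
    n_axons: int,
    params: CascadeParams,
    rng: np.random.Generator,
    at_time: float = 3.5,
    exact_fractions: bool = False,
) -> ordering.AtpMotilityResult:
    """ATP-sensor decline at 3.5 h vs mitochondrial stalling.

    ``exact_fractions`` replaces the per-bout binomial track sampling and
    the bout-grid arrest estimate with their noise-free expectations (the
    deterministic-coupling limit); the default runs the full kymograph
    pipeline.
    """
    from .cascade import mobile_fraction

    axons = []
    for i, arng in enumerate(_axon_rngs(n_axons, rng)):
        sched = sample_event_schedule(params, f"axon{i:03d}", arng)
        traces = simulate_traces(
            sched, params, arng, channels=("PercevalHR",), duration=at_time + 0.1
        )
        t, v = traces.channels["PercevalHR"]
        base = events.compute_baseline(t, v, traces.baseline_window)
        decline = events.perceval_decline(t, v, base, at_time=at_time)
        if exact_fractions:
            f0 = params.baseline_mobile_fraction
            f_at = float(mobile_fraction(at_time, sched, params))
            arrest = sched.t_mito_stop
        else:
            baseline_bout = simulate_kymograph_bouts(
                sched, params, [-params.baseline_duration / 2.0], arng
            )[0]
            bouts = simulate_kymograph_bouts(
                sched, params, default_bout_times(sched, BOUT_INTERVAL_H, start=at_time),
                arng,
            )
            s0 = kymo.summarize_bout(baseline_bout)
            s_at = kymo.summarize_bout(bouts[0])
            f0, f_at = s0.mobile_fraction, s_at.mobile_fraction
            arrest = kymo.arrest_time([kymo.summarize_bout(b) for b in bouts])
        axons.append(
            {
                "axon_id": sched.axon_id,
                "perceval_decline": decline,
                "baseline_mobile_fraction": f0,
                "mobile_fraction_at": f_at,
                "arrest_time": arrest,
            }
        )
    return ordering.atp_motility_analysis(axons, at_time=at_time)


def replicate_mean(values) -> float:
    return float(np.mean(np.asarray(values, dtype=float)))
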