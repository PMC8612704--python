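#!/usr/bin/env python
"""Cohort temporal-ordering statistics: the cascade sequence.

Reads the event calls from 02_detect_events.py, computes the dT summary
for each adjacent event pair, the strict-before/same-frame ordering of
the TMRM drop vs calcium onset at the 10-min acquisition cadence, and
the second-calcium-peak metrics vs fragmentation time, then writes the
cohort report.
"""

import json
from pathlib import Path

from axocascade import cohort_report, second_peak_metrics
from axocascade import io as axio
from axocascade.events import compute_baseline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    calls = axio.read_calls(ROOT / "calls.tsv")
    traces = {t.axon_id: t for t in axio.read_traces(ROOT / "cohort" / "traces.tsv")}
    schedules = {s.axon_id: s for s in axio.read_schedules(ROOT / "cohort" / "schedules.tsv")}

    second_peak = []
    for c in calls:
        onset = c.times.get("ca_onset")
        sched = schedules.get(c.axon_id)
        if onset is None or sched is None or sched.t_fragmentation is None:
            continue
        ts = traces[c.axon_id]
        t, v = ts.channels["GCaMP6"]
        base = compute_baseline(t, v, ts.baseline_window)
        m = second_peak_metrics(t, v, base, onset, sched.t_fragmentation)
        second_peak.append(
            {
                "initiation": m.initiation,
                "duration": m.duration,
                "intensity": m.intensity,
                "fragmentation_time": sched.t_fragmentation,
            }
        )

    report = cohort_report(calls, second_peak=second_peak)
    (ROOT / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    print(f"n = {report['n_axons']} axons")
    for name, row in report["delta_t"].items():
        if "mean_h" in row:
            print(f"  dT {name:28s} = {row['mean_h']:6.3f} +- {row['sem_h']:.3f} h "
                  f"(n = {row['n']})")
        else:
            print(f"  dT {name:28s} : {row['status']}")
    ordering = report["ordering"]["tmrm_before_calcium"]
    if "fraction_strict" in ordering:
        print(f"  TMRM drop strictly before calcium: "
              f"{ordering['n_strict_before']}/{ordering['n_strict_before'] + ordering['n_same_frame'] + ordering['n_after']} axons "
              f"({100 * ordering['fraction_strict']:.1f}%)")
    if "second_peak" in report:
        sp = report["second_peak"]
        print("  second-peak correlations with fragmentation time:")
        for key in ("initiation", "duration", "intensity"):
            r = sp[f"{key}_vs_fragmentation_r"]
            print(f"    {key:10s} r = {r:+.2f}" if r is not None else
                  f"    {key:10s} r = n/a")
    print(f"wrote {ROOT / 'report.json'}")


if __name__ == "__main__":
    main()
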