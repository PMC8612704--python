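#!/usr/bin/env python
"""Detect cascade events on the simulated cohort.

Reads the cohort written by 01_simulate_cohort.py, applies every trace
detector (calcium onset, TMRM drastic drop, continuity loss, Annexin-V
onset, ATP-sensor decline), derives each axon's mitochondrial arrest
time from the kymograph track tables, QCs baseline morphology images by
degeneration index, and writes the per-axon event calls.
"""

from pathlib import Path

from axocascade import detect_all, qc_baseline_axon, summarize_bout, arrest_time
from axocascade import io as axio

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    traces = axio.read_traces(ROOT / "cohort" / "traces.tsv")
    bouts = axio.read_tracks(ROOT / "cohort" / "tracks.tsv")

    calls = []
    for ts in traces:
        c = detect_all(ts)
        axon_bouts = [b for b in bouts.get(ts.axon_id, []) if b.bout_start >= 0]
        c.times["mito_stop"] = (
            arrest_time([summarize_bout(b) for b in axon_bouts])
            if axon_bouts
            else None
        )
        calls.append(c)
    axio.write_calls(calls, ROOT / "calls.tsv")

    image_dir = ROOT / "cohort" / "images"
    n_qc_pass = n_qc = 0
    if image_dir.exists():
        import imageio.v3 as iio

        for ts in traces:
            baseline_file = image_dir / axio.image_filename(ts.axon_id, 0.0)
            if not baseline_file.exists():
                continue
            n_qc += 1
            n_qc_pass += qc_baseline_axon(iio.imread(baseline_file))

    n_called = sum(c.times.get("ca_onset") is not None for c in calls)
    n_arrest = sum(c.times.get("mito_stop") is not None for c in calls)
    print(f"event calls for {len(calls)} axons -> {ROOT / 'calls.tsv'}")
    print(f"calcium onset called in {n_called}/{len(calls)} axons, "
          f"mitochondrial arrest in {n_arrest}/{len(calls)}")
    if n_qc:
        print(f"baseline morphology QC (DI < 0.2): {n_qc_pass}/{n_qc} axons pass")


if __name__ == "__main__":
    main()
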