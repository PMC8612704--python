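"""Operational event definitions on per-channel traces and images.

Each detector implements one published criterion: calcium influx is a
sustained >= 2-fold GCaMP6 rise over the pre-injury baseline; loss of
mitochondrial membrane potential is a > 30% frame-to-frame TMRM drop;
the beginning of degeneration is a sustained > 50% mRuby3 reduction;
phosphatidylserine exposure is a sustained >= 2-fold Annexin-V rise over
its background floor; and the degeneration index (DI) is the fraction of
binarized axonal area in fragment-like (high-circularity) particles,
with DI > 0.4 defining a degenerated axon and DI >= 0.2 at baseline
failing QC.

Boundary semantics follow the wording of the criteria: "two-fold or
greater" is >=, "more than 30% / 50%" is strictly >, "less than 0.2" is
strictly <.  Sustained rules (two consecutive frames by default) debounce
the documented ~10% frame-to-frame fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .simulate import AxonImage, AxonTraceSet

DI_DEGENERATED = 0.4  # DI strictly above this = degenerated axon
DI_BASELINE_QC = 0.2  # baseline DI must be strictly below this


@dataclass
class EventCalls:
    """Detected event times and magnitudes for one axon."""

    axon_id: str
    times: dict[str, Optional[float]] = field(default_factory=dict)
    magnitudes: dict[str, Optional[float]] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class SecondPeakMetrics:
    initiation: float  # h
    duration: float  # h
    intensity: float  # peak fold-change over baseline


@dataclass(frozen=True)
class DegenerationScore:
    time: Optional[float]
    di: float
    degenerated: bool


def _as_arrays(times, values):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, v


def compute_baseline(times, values, window) -> float:
    """Mean intensity over the pre-injury window [lo, hi).

    The upper bound is exclusive so that a window ending at t = 0 covers
    only frames strictly before the injury.
    """
    t, v = _as_arrays(times, values)
    lo, hi = window
    sel = (t >= lo) & (t < hi)
    if sel.sum() < 3:
        raise ValueError("baseline window must contain at least 3 frames")
    base = float(v[sel].mean())
    if base <= 0:
        raise ValueError("baseline must be strictly positive")
    return base


def _sustained_crossing(t, above, sustain):
    """Earliest index i with ``sustain`` consecutive True from i; None if none."""
    n = len(above)
    for i in range(n - sustain + 1):
        if all(above[i : i + sustain]):
            return i
    return None


def detect_calcium_onset(
    times,
    values,
    baseline: float,
    exclude_first_peak_window: float = 0.5,
    fold_threshold: float = 2.0,
    sustain: int = 2,
):
    """Sustained calcium influx: earliest frame at or after the injury
    transient exclusion window whose intensity is >= fold_threshold x
    baseline, confirmed over ``sustain`` consecutive frames.

    Returns (time, fold at the calling frame) or (None, None).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t, v = _as_arrays(times, values)
    sel = t >= exclude_first_peak_window
    if sel.sum() < sustain:
        return None, None
    ts, vs = t[sel], v[sel]
    above = vs >= fold_threshold * baseline
    i = _sustained_crossing(ts, above, sustain)
    if i is None:
        return None, None
    return float(ts[i]), float(vs[i] / baseline)


@dataclass(frozen=True)
class TmrmDropCall:
    time: Optional[float]  # earliest sustained >30% frame-to-frame reduction
    drop: Optional[float]  # fractional reduction at the calling frame
    largest_change_time: Optional[float]  # frame of largest |frame-to-frame| change


def detect_tmrm_drop(
    times,
    values,
    baseline: float,
    drop_threshold: float = 0.30,
    sustain: int = 2,
) -> TmrmDropCall:
    """Drastic loss of mitochondrial membrane potential.

    Computes the fractional change of each frame from the previous frame
    and calls the earliest frame whose reduction strictly exceeds
    ``drop_threshold``, confirmed by the signal staying below
    (1 - drop_threshold) of the pre-drop level for ``sustain`` frames in
    total.  Also locates the frame of largest frame-to-frame variation.
    """
    t, v = _as_arrays(times, values)
    if len(t) < 2:
        raise ValueError("need at least 2 frames")
    prev = v[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_change = np.where(prev > 0, (v[1:] - prev) / prev, 0.0)
    largest_i = int(np.argmax(np.abs(frac_change)))
    largest_time = float(t[largest_i + 1])
    call_time = call_drop = None
    for i in range(1, len(v)):
        if prev[i - 1] <= 0:
            continue
        drop = (v[i - 1] - v[i]) / v[i - 1]
        if drop > drop_threshold:
            level = (1.0 - drop_threshold) * v[i - 1]
            window = v[i : i + sustain]
            if len(window) >= 1 and np.all(window < level):
                call_time, call_drop = float(t[i]), float(drop)
                break
    return TmrmDropCall(time=call_time, drop=call_drop, largest_change_time=largest_time)


def perceval_decline(times, values, baseline: float, at_time: float = 3.5) -> float:
    """Percent decline of the ATP sensor from baseline at ``at_time``.

    Uses the frame at or latest before ``at_time``; the trace must span it.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t, v = _as_arrays(times, values)
    if t[-1] < at_time:
        raise ValueError(
            f"trace ends at {t[-1]:.3f} h, before the requested {at_time} h"
        )
    i = int(np.searchsorted(t, at_time, side="right")) - 1
    if i < 0:
        raise ValueError(f"trace begins after {at_time} h")
    return float(np.clip(100.0 * (1.0 - v[i] / baseline), 0.0, 100.0))


def detect_continuity_loss(
    times, values, baseline: float, reduction_threshold: float = 0.5, sustain: int = 2
) -> Optional[float]:
    """Beginning of degeneration: earliest sustained frame with the
    cytosolic reporter reduced by strictly more than ``reduction_threshold``
    of baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t, v = _as_arrays(times, values)
    below = v < (1.0 - reduction_threshold) * baseline
    i = _sustained_crossing(t, below, sustain)
    return None if i is None else float(t[i])


def detect_annexin_onset(
    times,
    values,
    baseline_floor: float,
    fold_threshold: float = 2.0,
    sustain: int = 2,
) -> Optional[float]:
    """Phosphatidylserine exposure: earliest sustained frame with
    F / F_base >= fold_threshold over the positive background floor."""
    if baseline_floor <= 0:
        raise ValueError("baseline floor must be positive")
    t, v = _as_arrays(times, values)
    above = v >= fold_threshold * baseline_floor
    i = _sustained_crossing(t, above, sustain)
    return None if i is None else float(t[i])


def degeneration_index(
    image,
    time: Optional[float] = None,
    binarize_threshold: Optional[float] = None,
    circularity_cutoff: float = 0.2,
    min_particle_px: int = 4,
) -> DegenerationScore:
    """Axon degeneration index: fragment-like area / total axonal area.

    The image is binarized (Otsu by default), connected components are
    extracted, and a component is fragment-like iff its circularity
    4*pi*area/perimeter^2 is >= ``circularity_cutoff``.  Components below
    ``min_particle_px`` pixels are ignored.  DI > 0.4 marks degeneration.
    """
    if isinstance(image, AxonImage):
        if time is None:
            time = image.time
        image = image.pixels
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        raise ValueError("image has no foreground (uniform intensity)")
    if binarize_threshold is None:
        binarize_threshold = float(threshold_otsu(img))
    mask = img > binarize_threshold
    if not mask.any():
        raise ValueError("image has no foreground after binarization")
    labels = cc_label(mask)
    total = 0.0
    fragment = 0.0
    for region in regionprops(labels):
        if region.area < min_particle_px:
            continue
        total += region.area
        perim = region.perimeter
        circularity = 1.0 if perim == 0 else 4.0 * np.pi * region.area / perim**2
        if circularity >= circularity_cutoff:
            fragment += region.area
    if total == 0:
        raise ValueError("image has no particles above the minimum size")
    di = float(np.clip(fragment / total, 0.0, 1.0))
    return DegenerationScore(time=time, di=di, degenerated=di > DI_DEGENERATED)


def qc_baseline_axon(image, **di_kwargs) -> bool:
    """Baseline morphology QC: pass iff DI is strictly below 0.2."""
    score = degeneration_index(image, **di_kwargs)
    return score.di < DI_BASELINE_QC


def second_peak_metrics(
    times, values, baseline: float, onset_time: Optional[float],
    fragmentation_time: float
) -> SecondPeakMetrics:
    """Initiation, duration and intensity of the sustained calcium peak.

    The peak persists until the axon fragments, so duration is the
    fragmentation time minus the initiation, and intensity is the
    maximum fold-change between them.
    """
    if onset_time is None:
        raise ValueError("calcium onset was not called for this axon")
    t, v = _as_arrays(times, values)
    sel = (t >= onset_time) & (t <= fragmentation_time)
    if not sel.any():
        raise ValueError("no frames between onset and fragmentation")
    intensity = float(v[sel].max() / baseline)
    return SecondPeakMetrics(
        initiation=float(onset_time),
        duration=float(fragmentation_time - onset_time),
        intensity=intensity,
    )


def detect_all(
    traces: AxonTraceSet,
    exclude_first_peak_window: float = 0.5,
    annexin_floor: Optional[float] = None,
) -> EventCalls:
    """Run every applicable detector on one axon's trace set."""
    calls = EventCalls(axon_id=traces.axon_id)
    window = traces.baseline_window
    ch = traces.channels
    if "GCaMP6" in ch:
        t, v = ch["GCaMP6"]
        base = compute_baseline(t, v, window)
        calls.baselines["GCaMP6"] = base
        time, fold = detect_calcium_onset(
            t, v, base, exclude_first_peak_window=exclude_first_peak_window
        )
        calls.times["ca_onset"] = time
        calls.magnitudes["ca_onset"] = fold
    if "TMRM" in ch:
        t, v = ch["TMRM"]
        base = compute_baseline(t, v, window)
        calls.baselines["TMRM"] = base
        drop = detect_tmrm_drop(t, v, base)
        calls.times["tmrm_drop"] = drop.time
        calls.magnitudes["tmrm_drop"] = drop.drop
    if "mRuby3" in ch:
        t, v = ch["mRuby3"]
        base = compute_baseline(t, v, window)
        calls.baselines["mRuby3"] = base
        calls.times["degeneration"] = detect_continuity_loss(t, v, base)
    if "AnnexinV" in ch:
        t, v = ch["AnnexinV"]
        floor = annexin_floor
        if floor is None:
            floor = max(compute_baseline(t, v, window), 1e-9)
        calls.baselines["AnnexinV"] = floor
        calls.times["ps_exposure"] = detect_annexin_onset(t, v, floor)
    if "PercevalHR" in ch:
        t, v = ch["PercevalHR"]
        base = compute_baseline(t, v, window)
        calls.baselines["PercevalHR"] = base
        if t[-1] >= 3.5:
            calls.magnitudes["perceval_decline_3p5h"] = perceval_decline(t, v, base)
        else:
            calls.qc_flags.add("perceval_trace_short")
    return calls
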