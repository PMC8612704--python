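"""Mitochondrial motility from kymograph bouts.

A mitochondrion is mobile if its net endpoint displacement within one
300-s bout exceeds 5 um, otherwise stationary.  Bout summaries give the
mobile fraction; the arrest time of an axon is the start of the first
bout with no mobile mitochondria that is followed only by bouts with no
mobile mitochondria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .simulate import KymographBout, MitoTrack

#: Net-displacement motility criterion, um (strictly greater than).
MOBILE_THRESHOLD_UM = 5.0


@dataclass(frozen=True)
class MotilityCall:
    track_id: int
    net_displacement: float  # um, >= 0
    label: str  # "mobile" | "stationary"


@dataclass(frozen=True)
class BoutSummary:
    bout_start: float  # h
    n_tracks: int
    n_mobile: int
    mobile_fraction: float
    degenerate: bool = False  # True when the bout had no tracks
    post_fragmentation: bool = False


def classify_motility(
    track: MitoTrack, threshold_um: float = MOBILE_THRESHOLD_UM
) -> MotilityCall:
    """Label a track mobile iff |last - first position| strictly exceeds
    the threshold.  Tracks entering/leaving the field are classified on
    their observed (finite) frames only."""
    pos = np.asarray(track.positions_um, dtype=float)
    pos = pos[np.isfinite(pos)]
    if pos.size < 2:
        raise ValueError(f"track {track.track_id}: need >= 2 observed positions")
    net = abs(float(pos[-1] - pos[0]))
    label = "mobile" if net > threshold_um else "stationary"
    return MotilityCall(track_id=track.track_id, net_displacement=net, label=label)


def summarize_bout(
    bout: KymographBout, threshold_um: float = MOBILE_THRESHOLD_UM
) -> BoutSummary:
    if not bout.tracks:
        return BoutSummary(
            bout_start=bout.bout_start,
            n_tracks=0,
            n_mobile=0,
            mobile_fraction=0.0,
            degenerate=True,
            post_fragmentation=bout.post_fragmentation,
        )
    calls = [classify_motility(t, threshold_um) for t in bout.tracks]
    n_mobile = sum(c.label == "mobile" for c in calls)
    return BoutSummary(
        bout_start=bout.bout_start,
        n_tracks=len(calls),
        n_mobile=n_mobile,
        mobile_fraction=n_mobile / len(calls),
        post_fragmentation=bout.post_fragmentation,
    )


def arrest_time(summaries: Sequence[BoutSummary]) -> Optional[float]:
    """Start time of the first bout with zero mobile mitochondria such
    that every later observed bout also has zero; None if never arrested."""
    if not summaries:
        raise ValueError("need at least one bout summary")
    starts = [s.bout_start for s in summaries]
    if starts != sorted(starts):
        raise ValueError("bout summaries must be sorted by bout_start")
    arrested_from = None
    for s in summaries:
        if s.n_mobile == 0:
            if arrested_from is None:
                arrested_from = s.bout_start
        else:
            arrested_from = None
    return arrested_from


def extract_tracks(
    kymograph_image: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    intensity_threshold: Optional[float] = None,
    max_step_um: float = 2.0,
    min_length: int = 10,
    min_separation_px: int = 3,
) -> list[MitoTrack]:
    """Recover tracks from a (frames x space) kymograph image.

    Per-frame local maxima above an intensity threshold (Otsu by default)
    are linked frame-to-frame by nearest neighbour under a maximum step
    constraint; tracks observed for fewer than ``min_length`` frames are
    discarded.  Unobserved frames of a surviving track are NaN.
    """
    img = np.asarray(kymograph_image, dtype=float)
    if img.size == 0 or img.max() == img.min():
        return []
    if intensity_threshold is None:
        intensity_threshold = float(threshold_otsu(img))
    n_frames = img.shape[0]
    max_step_px = max_step_um / pixel_size

    # active tracks: (positions list indexed by frame, last position, last frame)
    active: list[list] = []
    finished: list[list] = []
    for f in range(n_frames):
        peaks, _ = find_peaks(
            img[f], height=intensity_threshold, distance=min_separation_px
        )
        peaks = list(peaks.astype(float))
        claimed = [False] * len(peaks)
        still_active = []
        for positions, last_pos, last_frame in active:
            # greedy nearest unclaimed peak within the step constraint
            best, best_d = None, max_step_px
            for j, p in enumerate(peaks):
                if claimed[j]:
                    continue
                d = abs(p - last_pos)
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                claimed[best] = True
                positions[f] = peaks[best]
                still_active.append([positions, peaks[best], f])
            elif f - last_frame > 1:
                finished.append([positions, last_pos, last_frame])
            else:
                still_active.append([positions, last_pos, last_frame])
        for j, p in enumerate(peaks):
            if not claimed[j]:
                positions = {f: p}
                still_active.append([positions, p, f])
        active = still_active
    finished.extend(active)

    tracks = []
    tid = 0
    for positions, _, _ in finished:
        if len(positions) < min_length:
            continue
        full = np.full(n_frames, np.nan)
        for f, p in positions.items():
            full[f] = p * pixel_size
        tracks.append(MitoTrack(track_id=tid, positions_um=full))
        tid += 1
    return tracks
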