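"""Synthetic single-axon cohorts: traces, kymograph bouts and images.

Every generated object carries the statistical structure the downstream
analysis assumes: multi-channel fluorescence traces with the documented
~10% multiplicative frame noise, kymograph bouts whose mobile fraction is
coupled to the axon's ATP level, and morphology images whose degeneration
index crosses the 0.2/0.4 thresholds at the scheduled times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cascade import (
    CHANNELS,
    CascadeParams,
    EventSchedule,
    atp_level,
    event_free_schedule,
    mobile_fraction,
    perceval_response,
    sample_event_schedule,
)

# Amplitude of the injury-site calcium transient (fold over baseline) and
# its duration in frames.  The first peak is rapidly cleared.
FIRST_PEAK_FOLD = 3.0
FIRST_PEAK_FRAMES = 2

# Arbitrary-unit base intensity per channel; Annexin-V starts at a small
# background floor (its plateau is annexin_plateau_fold times this floor).
_BASE_INTENSITY = {
    "GCaMP6": 100.0,
    "TMRM": 100.0,
    "PercevalHR": 100.0,
    "mRuby3": 100.0,
    "AnnexinV": 10.0,
}


@dataclass
class AxonTraceSet:
    """Per-channel sampled intensity series for one axon."""

    axon_id: str
    channels: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (time_h, a.u.)
    baseline_window: tuple[float, float]

    def times(self, channel: str) -> np.ndarray:
        return self.channels[channel][0]

    def values(self, channel: str) -> np.ndarray:
        return self.channels[channel][1]


@dataclass
class MitoTrack:
    track_id: int
    positions_um: np.ndarray  # axial position per frame
    ground_truth_mobile: Optional[bool] = None


@dataclass
class KymographBout:
    bout_start: float  # h post-injury
    frame_interval: float  # s
    n_frames: int
    tracks: list[MitoTrack] = field(default_factory=list)
    post_fragmentation: bool = False

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class AxonImage:
    time: float  # h post-injury
    pixels: np.ndarray  # uint8 grayscale, rows x cols
    pixel_size: float  # um / px
    morphology_state: Optional[str] = None  # intact | swollen | fragmented


@dataclass
class Cohort:
    schedules: list[EventSchedule]
    traces: list[AxonTraceSet]
    bouts: list[list[KymographBout]]
    images: list[list[AxonImage]]
    params: CascadeParams
    seed: int


def _noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative log-normal frame noise with unit mean and cv ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, n)


def _channel_profile(channel, t, schedule, params, ca_fold):
    """Noise-free relative intensity of ``channel`` at times ``t``."""
    s = schedule
    v = np.ones_like(t)
    if channel == "GCaMP6":
        cad = params.channel_cadences["GCaMP6"]
        first = (t >= 0) & (t < FIRST_PEAK_FRAMES * cad)
        v[first] = FIRST_PEAK_FOLD
        if s.t_ca_onset is not None:
            v[t >= s.t_ca_onset] = ca_fold
    elif channel == "TMRM":
        if s.t_tmrm_drop is not None:
            after = t >= s.t_tmrm_drop
            v[after] = np.maximum(
                params.tmrm_drop_to
                - params.tmrm_decline_rate * (t[after] - s.t_tmrm_drop),
                0.05,
            )
    elif channel == "PercevalHR":
        v = perceval_response(atp_level(t, s))
    elif channel == "mRuby3":
        if s.t_degeneration is not None:
            t_frag = (
                s.t_fragmentation
                if s.t_fragmentation is not None
                else s.t_degeneration + 0.25
            )
            span = max(t_frag - s.t_degeneration, 1e-6)
            after = t >= s.t_degeneration
            v[after] = np.interp(
                t[after],
                [s.t_degeneration, t_frag],
                [params.mruby_drop_to, 0.1],
            )
            v[t >= t_frag] = 0.05
    elif channel == "AnnexinV":
        if s.t_ps_exposure is not None:
            # labeling jumps past the 2-fold readout immediately at
            # exposure, then saturates toward the plateau
            after = t >= s.t_ps_exposure
            rise = np.minimum((t[after] - s.t_ps_exposure) / params.annexin_rise_h, 1.0)
            initial = params.annexin_initial_fold
            v[after] = initial + (params.annexin_plateau_fold - initial) * rise
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return v


def simulate_traces(
    schedule: EventSchedule,
    params: CascadeParams,
    rng: np.random.Generator,
    channels: Sequence[str] = CHANNELS,
    duration: Optional[float] = None,
) -> AxonTraceSet:
    """Sample the per-channel intensity series of one axon.

    Each channel is sampled on its own cadence from ``-baseline_duration``
    to ``duration`` (default: one hour past fragmentation), and corrupted
    by multiplicative log-normal frame noise with cv ``frame_noise_cv``.
    """
    params.validate()
    if duration is None:
        duration = (
            schedule.t_fragmentation + 1.0
            if schedule.t_fragmentation is not None
            else 12.0
        )
    fold_mu, fold_sd, fold_min = params.ca_plateau_fold
    ca_fold = max(rng.normal(fold_mu, fold_sd) if fold_sd > 0 else fold_mu, fold_min)
    out = {}
    for channel in channels:
        cad = params.channel_cadences[channel]
        n_base = int(round(params.baseline_duration / cad))
        t = (np.arange(-n_base, int(np.floor(duration / cad)) + 1)) * cad
        v = _channel_profile(channel, t, schedule, params, ca_fold)
        v = _BASE_INTENSITY[channel] * v * _noise(rng, params.frame_noise_cv, len(t))
        out[channel] = (t, np.maximum(v, 0.0))
    return AxonTraceSet(
        axon_id=schedule.axon_id,
        channels=out,
        baseline_window=(-params.baseline_duration, 0.0),
    )


def cccp_perceval_trace(
    params: CascadeParams,
    rng: np.random.Generator,
    atp_drop: float = 0.6,
    duration: float = 2.0,
) -> AxonTraceSet:
    """PercevalHR trace under mitochondrial uncoupling (no axotomy).

    Relative ATP declines linearly from 1 to ``1 - atp_drop`` over
    ``duration`` hours; the sensor follows its calibrated response curve.
    """
    cad = params.channel_cadences["PercevalHR"]
    n_base = int(round(params.baseline_duration / cad))
    t = (np.arange(-n_base, int(np.floor(duration / cad)) + 1)) * cad
    atp = 1.0 - atp_drop * np.clip(t / duration, 0.0, 1.0)
    v = _BASE_INTENSITY["PercevalHR"] * perceval_response(atp)
    v = v * _noise(rng, params.frame_noise_cv, len(t))
    return AxonTraceSet(
        axon_id="cccp",
        channels={"PercevalHR": (t, np.maximum(v, 0.0))},
        baseline_window=(-params.baseline_duration, 0.0),
    )


def simulate_kymograph_bouts(
    schedule: EventSchedule,
    params: CascadeParams,
    bout_times: Sequence[float],
    rng: np.random.Generator,
    axon_length_um: float = 120.0,
) -> list[KymographBout]:
    """Simulate mitochondrial tracks for each requested imaging bout.

    Track count is constant across bouts.  Each track is mobile with the
    ATP-coupled probability at the bout start; mobile tracks drift with a
    net displacement drawn well above the 5 um criterion, stationary
    tracks jitter below it.  A bout at or after fragmentation is empty and
    flagged.
    """
    params.validate()
    if list(bout_times) != sorted(bout_times):
        raise ValueError("bout_times must be sorted")
    n = params.tracks_per_bout
    n_frames = params.bout_n_frames
    bouts = []
    for start in bout_times:
        if schedule.t_fragmentation is not None and start >= schedule.t_fragmentation:
            bouts.append(
                KymographBout(
                    bout_start=start,
                    frame_interval=params.bout_frame_interval_s,
                    n_frames=n_frames,
                    tracks=[],
                    post_fragmentation=True,
                )
            )
            continue
        frac = float(mobile_fraction(start, schedule, params))
        mobile = rng.random(n) < frac
        start_pos = rng.uniform(0.0, axon_length_um, n)
        # per-frame drift: net displacement 7-25 um over the bout for
        # mobile tracks, either direction; zero drift otherwise
        net = rng.uniform(7.0, 25.0, n) * rng.choice([-1.0, 1.0], n)
        drift = np.where(mobile, net / (n_frames - 1), 0.0)
        steps = drift[:, None] + rng.normal(0.0, 0.05, (n, n_frames - 1))
        pos = np.concatenate(
            [start_pos[:, None], start_pos[:, None] + np.cumsum(steps, axis=1)], axis=1
        )
        tracks = [
            MitoTrack(track_id=i, positions_um=pos[i], ground_truth_mobile=bool(mobile[i]))
            for i in range(n)
        ]
        bouts.append(
            KymographBout(
                bout_start=start,
                frame_interval=params.bout_frame_interval_s,
                n_frames=n_frames,
                tracks=tracks,
            )
        )
    return bouts


def render_kymograph(
    bout: KymographBout,
    pixel_size: float = 0.3,
    length_um: float = 160.0,
    spot_sigma_px: float = 1.5,
    amplitude: float = 200.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a bout as a (frames x space) grayscale kymograph image."""
    if rng is None:
        rng = np.random.default_rng(0)
    n_px = int(round(length_um / pixel_size))
    img = np.full((bout.n_frames, n_px), background, dtype=float)
    cols = np.arange(n_px)
    for track in bout.tracks:
        for f in range(bout.n_frames):
            x = track.positions_um[f] / pixel_size
            if -4 * spot_sigma_px < x < n_px + 4 * spot_sigma_px:
                img[f] += amplitude * np.exp(-0.5 * ((cols - x) / spot_sigma_px) ** 2)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Axon morphology images


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def simulate_axon_images(
    schedule: EventSchedule,
    params: CascadeParams,
    times: Sequence[float],
    rng: np.random.Generator,
    shape: tuple[int, int] = (64, 1024),
    pixel_size: float = 0.3,
) -> list[AxonImage]:
    """Render the axon's morphology at the requested times.

    Before calcium onset the axon is a thin continuous strip; between
    calcium onset and fragmentation swellings (local widenings) grow on
    the still-connected shaft; from fragmentation on, the foreground is a
    chain of disconnected near-circular fragments.
    """
    if list(times) != sorted(times):
        raise ValueError("times must be sorted")
    h, w = shape
    mid = h // 2
    images = []
    n_swell = rng.integers(6, 10)
    swell_x = rng.uniform(0.05 * w, 0.95 * w, n_swell)
    frag_x = np.sort(rng.uniform(0.03 * w, 0.97 * w, 28))
    frag_r = rng.uniform(3.0, 6.0, frag_x.size)
    for t in times:
        mask = np.zeros(shape, dtype=bool)
        t_ca = schedule.t_ca_onset
        t_frag = schedule.t_fragmentation
        if t_frag is not None and t >= t_frag:
            state = "fragmented"
            last = -1e9
            for x, r in zip(frag_x, frag_r):
                if x - last < 2.5 * max(frag_r):  # keep fragments disconnected
                    continue
                mask |= _disk_mask(shape, mid, x, r)
                last = x
        else:
            half = 4
            rows = np.abs(np.arange(h)[:, None] - mid)
            mask = rows <= half
            mask = np.broadcast_to(mask, shape).copy()
            state = "intact"
            if t_ca is not None and t >= t_ca:
                state = "swollen"
                grow = min((t - t_ca) / max((t_frag or t_ca + 2) - t_ca, 1e-6), 1.0)
                for x in swell_x:
                    mask |= _disk_mask(shape, mid, x, half + 2 + 6 * grow)
        px = np.where(mask, 180.0, 20.0)
        px += rng.normal(0.0, 4.0, shape)
        images.append(
            AxonImage(
                time=float(t),
                pixels=np.clip(px, 0, 255).astype(np.uint8),
                pixel_size=pixel_size,
                morphology_state=state,
            )
        )
    return images


# ---------------------------------------------------------------------------
# Cohorts


def default_bout_times(schedule: EventSchedule, interval_h: float = 5.0 / 60.0,
                       start: float = 3.5, trailing: int = 3) -> list[float]:
    """Bout schedule mimicking the acquisition protocol: image repeatedly
    from ``start`` hours post-injury until movement has ceased (a few
    bouts beyond the arrest), on a regular grid."""
    if schedule.t_mito_stop is None:
        return [start + i * interval_h for i in range(12)]
    stop = schedule.t_mito_stop + trailing * interval_h
    n = int(np.ceil((stop - start) / interval_h)) + 1
    return [start + i * interval_h for i in range(n)]


def generate_cohort(
    n: int,
    params: CascadeParams,
    seed: int,
    channels: Sequence[str] = CHANNELS,
    with_bouts: bool = True,
    with_images: bool = False,
    image_times: Optional[Sequence[float]] = None,
    event_free: bool = False,
) -> Cohort:
    """Generate a reproducible cohort of ``n`` simulated axons.

    Per-axon generators are spawned deterministically from ``seed`` so
    identical seeds give byte-identical cohorts.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    params.validate()
    ss = np.random.SeedSequence(seed)
    schedules, traces, bouts, images = [], [], [], []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        axon_id = f"axon{i:03d}"
        sched = (
            event_free_schedule(axon_id)
            if event_free
            else sample_event_schedule(params, axon_id, rng)
        )
        schedules.append(sched)
        traces.append(simulate_traces(sched, params, rng, channels=channels))
        if with_bouts:
            baseline_bouts = [-params.baseline_duration / 2.0]
            bouts.append(
                simulate_kymograph_bouts(
                    sched, params, baseline_bouts + default_bout_times(sched), rng
                )
            )
        else:
            bouts.append([])
        if with_images:
            if image_times is None:
                t_frag = sched.t_fragmentation or 8.0
                axon_times = [0.0, (sched.t_ca_onset or 4.0) + 0.5, t_frag + 0.5]
            else:
                axon_times = list(image_times)
            images.append(simulate_axon_images(sched, params, axon_times, rng))
        else:
            images.append([])
    return Cohort(
        schedules=schedules,
        traces=traces,
        bouts=bouts,
        images=images,
        params=params,
        seed=seed,
    )
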