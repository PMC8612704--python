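"""Generative model of the injury-induced axon degeneration cascade.

After axotomy, an injured axon passes through an ordered series of
physiological failures: ATP decline, arrest of mitochondrial transport,
loss of mitochondrial membrane potential, a sustained secondary calcium
influx, phosphatidylserine externalization, loss of membrane/cytosolic
integrity, and finally fragmentation.  This module samples per-axon event
schedules for that cascade.  A single latent "crisis" time — the moment
mitochondrial transport ceases — anchors each axon; every other event is
placed by a (mean, sd) offset relative to its upstream event, then clipped
so the cascade order is preserved by construction.

Times are in hours post-injury throughout; injury is t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

# Canonical channel names (keys of cadence maps and trace tables).
CHANNELS = ("GCaMP6", "TMRM", "PercevalHR", "mRuby3", "AnnexinV")

#: Cascade event names in causal order.
EVENT_ORDER = (
    "t_atp_onset",
    "t_mito_stop",
    "t_tmrm_drop",
    "t_ca_onset",
    "t_ps_exposure",
    "t_degeneration",
    "t_fragmentation",
)

# Relative ATP levels defining the logistic decline anchor points: the
# decline "onset" is the time ATP first falls below ATP_ONSET_LEVEL, and
# transport arrest occurs when ATP reaches ATP_ARREST_LEVEL.
ATP_ONSET_LEVEL = 0.95
ATP_ARREST_LEVEL = 0.2

# PercevalHR fluorescence response to relative ATP level: monotone
# piecewise-linear through (0, 0), (0.4, 0.3) and (1, 1).  The middle
# anchor encodes the CCCP calibration in which a 60% ATP drop produces a
# ~70% drop of the sensor signal.
_PERCEVAL_ATP = (0.0, 0.4, 1.0)
_PERCEVAL_SIGNAL = (0.0, 0.3, 1.0)


def perceval_response(atp_level):
    """Map relative ATP level (1 = baseline) to relative PercevalHR signal."""
    return np.interp(atp_level, _PERCEVAL_ATP, _PERCEVAL_SIGNAL)


class ParameterError(ValueError):
    """Raised when cascade parameters violate their invariants."""


@dataclass(frozen=True)
class CascadeParams:
    """Parameters of the cascade generator.

    All times are hours, all sds are standard deviations of per-axon
    normal draws.  Offset sds are chosen so that cohorts of the sizes
    used in the temporal-ordering analyses reproduce the reported
    cohort SEMs (sd = SEM * sqrt(n)).
    """

    #: (mean, sd, min, max) of the truncated-normal per-axon crisis time,
    #: i.e. the time mitochondrial transport arrests.
    crisis_time: tuple[float, float, float, float] = (5.5, 1.5, 3.5, 10.0)
    #: mito arrest -> calcium onset (mean, sd); 0.42 h with sd 0.02*sqrt(9).
    offset_mito_stop_to_ca: tuple[float, float] = (0.42, 0.06)
    #: TMRM drastic drop precedes calcium onset by this offset (mean, sd).
    #: Calibrated by Monte Carlo so that at 10-min frame binning ~5/7 of
    #: axons show the drop strictly one frame early and ~2/7 in the same
    #: frame.
    offset_tmrm_to_ca: tuple[float, float] = (7.85 / 60.0, 4.0 / 60.0)
    #: calcium onset -> phosphatidylserine exposure; 0.51 h, sd 0.04*sqrt(10).
    offset_ca_to_ps: tuple[float, float] = (0.51, 0.04 * math.sqrt(10.0))
    #: calcium onset -> degeneration (sustained >50% mRuby3 loss); 100 min.
    offset_ca_to_degeneration: tuple[float, float] = (100.0 / 60.0, 0.25)
    #: degeneration -> fragmentation.
    offset_degeneration_to_frag: tuple[float, float] = (0.25, 0.05)
    #: ATP logistic decline rate (1/h) and its per-axon sd.
    atp_decline_rate: tuple[float, float] = (1.2, 0.25)
    #: Motility-vs-ATP logistic coupling: (threshold, width) on relative ATP.
    atp_motility_coupling: tuple[float, float] = (0.5, 0.15)
    #: Fraction of mitochondria mobile in an uninjured axon.
    baseline_mobile_fraction: float = 0.3
    #: Mitochondria per kymograph bout (constant across bouts; injury does
    #: not change mitochondrial number).
    tracks_per_bout: int = 90
    #: Multiplicative per-frame intensity noise, coefficient of variation.
    frame_noise_cv: float = 0.10
    #: Frame interval per channel, hours.
    channel_cadences: dict[str, float] = field(
        default_factory=lambda: {
            "GCaMP6": 10.0 / 60.0,
            "TMRM": 10.0 / 60.0,
            "PercevalHR": 5.0 / 60.0,
            "mRuby3": 10.0 / 60.0,
            "AnnexinV": 10.0 / 60.0,
        }
    )
    #: Duration of the pre-injury baseline imaging window, hours.
    baseline_duration: float = 0.5
    #: Kymograph bout geometry: frame interval (s) and frames per bout.
    bout_frame_interval_s: float = 5.0
    bout_n_frames: int = 60
    #: Sustained calcium plateau fold-change over baseline (mean, sd, min).
    ca_plateau_fold: tuple[float, float, float] = (3.5, 0.5, 2.5)
    #: TMRM level immediately after the drastic drop (fraction of baseline)
    #: and subsequent steady decline rate (fraction of baseline per hour).
    tmrm_drop_to: float = 0.5
    tmrm_decline_rate: float = 0.15
    #: mRuby3 level right after continuity loss (fraction of baseline).
    mruby_drop_to: float = 0.40
    #: Annexin-V labeling over its background floor: fold reached
    #: immediately at exposure, saturating plateau fold, and rise time.
    annexin_initial_fold: float = 2.2
    annexin_plateau_fold: float = 4.0
    annexin_rise_h: float = 0.1

    def validate(self) -> None:
        mean, sd, lo, hi = self.crisis_time
        if not (lo < hi):
            raise ParameterError("crisis_time min must be < max")
        if sd < 0:
            raise ParameterError("crisis_time sd must be >= 0")
        for name in (
            "offset_mito_stop_to_ca",
            "offset_tmrm_to_ca",
            "offset_ca_to_ps",
            "offset_ca_to_degeneration",
            "offset_degeneration_to_frag",
            "atp_decline_rate",
        ):
            if getattr(self, name)[1] < 0:
                raise ParameterError(f"{name} sd must be >= 0")
        if self.frame_noise_cv < 0:
            raise ParameterError("frame_noise_cv must be >= 0")
        if not self.channel_cadences:
            raise ParameterError("channel_cadences must not be empty")
        for ch, cad in self.channel_cadences.items():
            if cad <= 0:
                raise ParameterError(f"cadence for {ch} must be positive")
        if not 0 <= self.baseline_mobile_fraction <= 1:
            raise ParameterError("baseline_mobile_fraction must be in [0, 1]")
        if self.tracks_per_bout < 0:
            raise ParameterError("tracks_per_bout must be >= 0")
        if self.atp_decline_rate[0] <= 0:
            raise ParameterError("ATP decline rate must be positive")

    def with_cadence(self, channel: str, hours: float) -> "CascadeParams":
        cad = dict(self.channel_cadences)
        cad[channel] = hours
        return replace(self, channel_cadences=cad)


@dataclass(frozen=True)
class EventSchedule:
    """Ground-truth event times (hours post-injury) for one axon.

    ``None`` marks an event that never occurs (uninjured / protected
    axons).  ``atp_rate`` is the per-axon ATP logistic decline rate; it is
    carried so that trace and kymograph simulation share one ATP curve.
    """

    axon_id: str
    t_injury: float = 0.0
    t_atp_onset: Optional[float] = None
    t_mito_stop: Optional[float] = None
    t_tmrm_drop: Optional[float] = None
    t_ca_onset: Optional[float] = None
    t_ps_exposure: Optional[float] = None
    t_degeneration: Optional[float] = None
    t_fragmentation: Optional[float] = None
    atp_rate: Optional[float] = None

    def __post_init__(self):
        times = [getattr(self, name) for name in EVENT_ORDER]
        present = [t for t in times if t is not None]
        if any(b < a - 1e-9 for a, b in zip(present, present[1:])):
            raise ValueError(
                f"event times of axon {self.axon_id} violate the cascade order"
            )

    @property
    def event_free(self) -> bool:
        return all(getattr(self, name) is None for name in EVENT_ORDER)

    def as_dict(self) -> dict[str, Optional[float]]:
        d = {"axon_id": self.axon_id, "t_injury": self.t_injury}
        for name in EVENT_ORDER:
            d[name] = getattr(self, name)
        return d


def atp_level(t, schedule: EventSchedule):
    """Relative ATP level of an axon at time(s) ``t`` (1 = baseline).

    The decline is logistic with the per-axon rate, anchored so that the
    level passes ATP_ONSET_LEVEL at ``t_atp_onset`` and ATP_ARREST_LEVEL at
    ``t_mito_stop``.  Event-free axons hold baseline forever.
    """
    t = np.asarray(t, dtype=float)
    if schedule.t_mito_stop is None or schedule.atp_rate is None:
        return np.ones_like(t)
    k = schedule.atp_rate
    midpoint = schedule.t_mito_stop - math.log(
        (1.0 - ATP_ARREST_LEVEL) / ATP_ARREST_LEVEL
    ) / k
    return 1.0 / (1.0 + np.exp(k * (t - midpoint)))


def mobile_fraction(t, schedule: EventSchedule, params: CascadeParams):
    """Expected fraction of mobile mitochondria at time(s) ``t``.

    Below the arrest time the fraction follows the baseline fraction
    scaled by a logistic function of the relative ATP level; transport
    ceases entirely (fraction 0) from ``t_mito_stop`` onward.
    """
    t = np.asarray(t, dtype=float)
    b = params.baseline_mobile_fraction
    if schedule.t_mito_stop is None:
        return np.full_like(t, b)
    theta, width = params.atp_motility_coupling

    def g(a):
        return 1.0 / (1.0 + np.exp(-(a - theta) / width))

    frac = b * g(atp_level(t, schedule)) / g(1.0)
    return np.where(t >= schedule.t_mito_stop, 0.0, frac)


def _truncnorm_rvs(mean, sd, lo, hi, rng):
    if sd == 0:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_event_schedule(
    params: CascadeParams, axon_id: str, rng: np.random.Generator
) -> EventSchedule:
    """Draw one axon's ground-truth cascade schedule.

    The crisis (mitochondrial arrest) time is truncated-normal; downstream
    events are placed by normal offsets and clipped to keep the cascade
    ordered.  With all sds zero the schedule is the deterministic cascade.
    """
    params.validate()
    mean, sd, lo, hi = params.crisis_time
    t_stop = _truncnorm_rvs(mean, sd, lo, hi, rng)

    def offset(pair):
        mu, s = pair
        return mu if s == 0 else rng.normal(mu, s)

    t_ca = t_stop + max(offset(params.offset_mito_stop_to_ca), 0.0)
    t_tmrm = min(max(t_ca - offset(params.offset_tmrm_to_ca), t_stop), t_ca)
    t_ps = t_ca + max(offset(params.offset_ca_to_ps), 0.0)
    t_deg = max(t_ca + offset(params.offset_ca_to_degeneration), t_ps)
    t_frag = t_deg + max(offset(params.offset_degeneration_to_frag), 0.0)

    k_mean, k_sd = params.atp_decline_rate
    k = max(rng.normal(k_mean, k_sd) if k_sd > 0 else k_mean, 0.3)
    # Time from ATP dropping below the onset level to reaching the arrest
    # level, for a logistic with rate k.
    onset_lag = (
        math.log(ATP_ONSET_LEVEL / (1.0 - ATP_ONSET_LEVEL))
        + math.log((1.0 - ATP_ARREST_LEVEL) / ATP_ARREST_LEVEL)
    ) / k
    t_atp = t_stop - onset_lag

    return EventSchedule(
        axon_id=axon_id,
        t_atp_onset=t_atp,
        t_mito_stop=t_stop,
        t_tmrm_drop=t_tmrm,
        t_ca_onset=t_ca,
        t_ps_exposure=t_ps,
        t_degeneration=t_deg,
        t_fragmentation=t_frag,
        atp_rate=k,
    )


def event_free_schedule(axon_id: str) -> EventSchedule:
    """Schedule of an axon in which the cascade never starts (control)."""
    return EventSchedule(axon_id=axon_id)
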