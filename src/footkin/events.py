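"""Stance detection, heel lift, stance sub-phases and dynamic variables.

Stance is bounded by vertical ground-reaction-force threshold crossings
(default 20 N with a 0.2 s debounce).  Heel lift is detected from the
rearfoot sagittal curve as the onset of sustained plantarflexion velocity in
late stance; when the criterion is never met a configured fixed percentage
of stance is used and a warning is logged.  Mid-stance runs from a foot-flat
proxy (default 15 % of stance) to heel lift, propulsion from heel lift to
toe off — the windows are conventions, configurable, not measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, NoStanceError
from .kinematics import InterSegmentAngleSeries

log = logging.getLogger(__name__)


@dataclass
class GaitEvents:
    """Stance bounds (s), heel lift, and stance sub-phase windows (% stance)."""

    heel_strike_s: float
    toe_off_s: float
    heel_lift_pct_stance: float
    midstance_start_pct: float = 15.0
    heel_lift_fallback_used: bool = False

    def __post_init__(self) -> None:
        if not self.heel_strike_s < self.toe_off_s:
            raise ContractError("heel strike must precede toe off")
        if not 0.0 < self.heel_lift_pct_stance < 100.0:
            raise ContractError("heel lift must fall strictly inside stance")
        if not self.midstance_start_pct < self.heel_lift_pct_stance:
            raise ContractError("mid-stance window start must precede heel lift")

    @property
    def stance_duration_s(self) -> float:
        return self.toe_off_s - self.heel_strike_s

    @property
    def heel_lift_s(self) -> float:
        return self.heel_strike_s + self.stance_duration_s * self.heel_lift_pct_stance / 100.0

    @property
    def midstance_window_pct(self) -> tuple[float, float]:
        return (self.midstance_start_pct, self.heel_lift_pct_stance)

    @property
    def propulsion_window_pct(self) -> tuple[float, float]:
        return (self.heel_lift_pct_stance, 100.0)


@dataclass
class GaitVariables:
    """The six scalar dynamic variables extracted per participant (degrees).

    Eversion peaks are signed minima of the frontal rearfoot curve (eversion
    is negative); dorsiflexion peaks are maxima of the sagittal curves.
    """

    peak_rearfoot_eversion_midstance: float
    peak_rearfoot_dorsiflexion_midstance: float
    rearfoot_sagittal_at_heel_lift: float
    rearfoot_sagittal_range_midstance: float
    peak_hallux_dorsiflexion_propulsion: float
    peak_rearfoot_eversion_propulsion: float

    FIELDS = (
        "peak_rearfoot_eversion_midstance",
        "peak_rearfoot_dorsiflexion_midstance",
        "rearfoot_sagittal_at_heel_lift",
        "rearfoot_sagittal_range_midstance",
        "peak_hallux_dorsiflexion_propulsion",
        "peak_rearfoot_eversion_propulsion",
    )

    def __post_init__(self) -> None:
        for name in self.FIELDS:
            if not np.isfinite(getattr(self, name)):
                raise ContractError(f"{name} is not finite")
        if self.rearfoot_sagittal_range_midstance < 0:
            raise ContractError("a range cannot be negative")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.FIELDS}


def detect_stance(force: np.ndarray, rate_hz: float = 1500.0,
                  threshold_n: float = 20.0,
                  min_duration_s: float = 0.2) -> tuple[float, float]:
    """First and last threshold crossing of the longest contact, in seconds.

    The longest contiguous supra-threshold run must last at least
    ``min_duration_s`` (debounce); otherwise :class:`NoStanceError`.
    """
    f = np.asarray(force, dtype=float)
    above = f >= threshold_n
    if not above.any():
        raise NoStanceError("force never exceeds the stance threshold")
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(f)]])
    lengths = ends - starts
    best = int(np.argmax(lengths))
    if lengths[best] < min_duration_s * rate_hz:
        raise NoStanceError(
            f"longest contact {lengths[best] / rate_hz:.3f} s shorter than "
            f"the {min_duration_s} s debounce")
    return starts[best] / rate_hz, ends[best] / rate_hz


def detect_heel_lift(rearfoot_sagittal_stance: np.ndarray,
                     search_start_pct: float = 40.0,
                     sustain_pct: float = 5.0,
                     fallback_pct: float = 60.0) -> tuple[float, bool]:
    """Heel lift as onset of sustained plantarflexion velocity in late stance.

    ``rearfoot_sagittal_stance`` is the 101-point stance-normalised sagittal
    rearfoot curve.  Returns (percent of stance, fallback_used).  The onset
    is the first sample at or after ``search_start_pct`` whose angular
    velocity is negative and stays negative for at least ``sustain_pct`` of
    stance; if none exists the configured ``fallback_pct`` is returned with
    a logged warning.
    """
    curve = np.asarray(rearfoot_sagittal_stance, dtype=float)
    if curve.ndim != 1 or curve.size != 101:
        raise ContractError("expected a 101-point stance-normalised curve")
    velocity = np.gradient(curve)
    step = 100.0 / (curve.size - 1)
    window = max(1, int(round(sustain_pct / step)))
    start = int(np.ceil(search_start_pct / step))
    for i in range(start, curve.size - window + 1):
        if np.all(velocity[i:i + window] < 0):
            return i * step, False
    log.warning("heel-lift velocity criterion never met; "
                "falling back to %.0f%% of stance", fallback_pct)
    return fallback_pct, True


def _window_slice(window_pct: tuple[float, float], n: int = 101) -> slice:
    lo, hi = window_pct
    i0 = int(np.floor(lo * (n - 1) / 100.0))
    i1 = int(np.ceil(hi * (n - 1) / 100.0))
    if i1 <= i0:
        raise ContractError(f"empty extraction window {window_pct}")
    return slice(i0, i1 + 1)


def extract_variables(series: InterSegmentAngleSeries,
                      events: GaitEvents) -> GaitVariables:
    """The six dynamic variables from a stance-normalised angle series.

    Peaks are signed extrema within the named stance sub-window; the range
    is max minus min within mid-stance; the heel-lift angle is the curve
    value at the heel-lift instant (nearest stance sample).
    """
    if series.basis != "stance":
        raise ContractError("extract_variables needs a stance-normalised series")
    sag = series.curve("rearfoot", "sagittal")
    frontal = series.curve("rearfoot", "frontal")
    hallux = series.curve("hallux_medial_forefoot", "sagittal")

    ms = _window_slice(events.midstance_window_pct, series.n_samples)
    prop = _window_slice(events.propulsion_window_pct, series.n_samples)
    hl_idx = int(round(events.heel_lift_pct_stance * (series.n_samples - 1) / 100.0))

    peak_ever_ms = float(np.min(frontal[ms]))
    # definition of a window minimum, asserted per run
    assert peak_ever_ms <= np.min(frontal[ms]) + 1e-12
    return GaitVariables(
        peak_rearfoot_eversion_midstance=peak_ever_ms,
        peak_rearfoot_dorsiflexion_midstance=float(np.max(sag[ms])),
        rearfoot_sagittal_at_heel_lift=float(sag[hl_idx]),
        rearfoot_sagittal_range_midstance=float(np.max(sag[ms]) - np.min(sag[ms])),
        peak_hallux_dorsiflexion_propulsion=float(np.max(hallux[prop])),
        peak_rearfoot_eversion_propulsion=float(np.min(frontal[prop])),
    )
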