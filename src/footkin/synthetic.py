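"""Synthetic gait cohorts with known ground truth.

No public deposit exists for multi-segment foot kinematics of this kind, so
every downstream stage is exercised on synthetic data whose truth is known
by construction:

* joint-angle waveforms are short harmonic series (<= 4 terms per channel),
  so peaks, ranges and crossing times are available analytically or by a
  dense scan of the closed-form curve;
* marker trajectories are produced by *inverting* the measurement chain —
  composing the per-joint Cardan x-y-z rotations down the segment chain
  leg -> calcaneus -> midfoot -> {medial forefoot -> hallux, lateral
  forefoot} about fixed joint centres, then adding isotropic Gaussian
  marker noise (default sd 0.5 mm, typical of optical capture);
* a smooth double-hump vertical force trace at 1500 Hz is non-zero exactly
  during stance;
* cohort statics and the dynamic waveform parameters are drawn so that each
  static measure and its hypothesised dynamic compensation have a
  configurable Pearson correlation rho, and deformity presence follows
  configurable prevalences.

Every random draw flows from a single integer seed; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sstats

from .errors import ConfigurationError, GeometryError
from .events import GaitVariables
from .io_formats import (ManifestEntry, MarkerTrialBundle, StaticAssessment,
                         write_cohort_manifest, write_marker_trial)
from .kinematics import compose_cardan
from .model import DEFAULT_MODEL, JOINT_NAMES, PLANES, SegmentModel

MAX_HARMONICS = 4

#: Deformity -> (dynamic target it shifts, flag attribute on the participant).
GROUP_EFFECT_TARGETS = {
    "ankle_equinus": "peak_rearfoot_dorsiflexion_midstance",
    "hallux_limited": "peak_hallux_dorsiflexion_propulsion",
    "first_ray_plantarflexed": "peak_rearfoot_eversion_midstance",
    "forefoot_varus": "peak_rearfoot_eversion_midstance",
}


# ---------------------------------------------------------------------------
# harmonic waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicCurve:
    """offset + sum_k amp_k * cos(2 pi k (phi - phase_k)) over cycle phase phi."""

    offset: float = 0.0
    harmonics: tuple[tuple[int, float, float], ...] = ()  # (k, amplitude, phase)

    def __post_init__(self) -> None:
        if len(self.harmonics) > MAX_HARMONICS:
            raise ConfigurationError(
                f"at most {MAX_HARMONICS} harmonics per channel")
        for k, amp, _ in self.harmonics:
            if k < 1 or not np.isfinite(amp):
                raise ConfigurationError("harmonic order must be >= 1, "
                                         "amplitude finite")

    def evaluate(self, phi: np.ndarray | float) -> np.ndarray | float:
        phi = np.asarray(phi, dtype=float)
        out = np.full(phi.shape, self.offset)
        for k, amp, phase in self.harmonics:
            out = out + amp * np.cos(2.0 * np.pi * k * (phi - phase))
        return out if out.shape else float(out)

    def derivative(self, phi: np.ndarray | float) -> np.ndarray | float:
        """d(angle)/d(phi) in degrees per cycle."""
        phi = np.asarray(phi, dtype=float)
        out = np.zeros(phi.shape)
        for k, amp, phase in self.harmonics:
            out = out - amp * 2.0 * np.pi * k * np.sin(2.0 * np.pi * k * (phi - phase))
        return out if out.shape else float(out)

    def extremum_in_window(self, lo: float, hi: float, kind: str = "max",
                           n_grid: int = 20001) -> tuple[float, float]:
        """(value, phi) of the window extremum by dense grid scan."""
        grid = np.linspace(lo, hi, n_grid)
        values = self.evaluate(grid)
        idx = int(np.argmax(values) if kind == "max" else np.argmin(values))
        return float(values[idx]), float(grid[idx])

    def jittered(self, delta_deg: float) -> "HarmonicCurve":
        """Shift the dominant harmonic's amplitude by ``delta_deg``."""
        if not self.harmonics:
            return self
        dominant = max(range(len(self.harmonics)),
                       key=lambda i: abs(self.harmonics[i][1]))
        harm = list(self.harmonics)
        k, amp, phase = harm[dominant]
        harm[dominant] = (k, amp + delta_deg, phase)
        return replace(self, harmonics=tuple(harm))


@dataclass(frozen=True)
class AngleWaveformSet:
    """Ground-truth angle curves (deg) per joint and plane over one cycle."""

    curves: dict[tuple[str, str], HarmonicCurve]
    stance_fraction: float = 0.62
    cycle_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0.4 < self.stance_fraction < 0.8:
            raise ConfigurationError(
                f"stance fraction {self.stance_fraction} outside (0.4, 0.8)")
        if self.cycle_duration_s <= 0:
            raise ConfigurationError("cycle duration must be positive")

    def curve(self, joint: str, plane: str) -> HarmonicCurve:
        return self.curves.get((joint, plane), HarmonicCurve())

    def sample(self, phi: np.ndarray) -> dict[str, np.ndarray]:
        """Joint -> (n, 3) array of angles at cycle phases ``phi``."""
        return {
            joint: np.column_stack([
                np.asarray(self.curve(joint, plane).evaluate(phi))
                for plane in PLANES])
            for joint in JOINT_NAMES
        }

    def sample_cycle(self, rate_hz: float = 100.0) -> dict[str, np.ndarray]:
        n = int(round(self.cycle_duration_s * rate_hz))
        return self.sample(np.arange(n) / n)

    def jittered(self, rng: np.random.Generator,
                 sd_deg: float = 0.5) -> "AngleWaveformSet":
        """Independent amplitude jitter (clipped to +/-1 deg) per channel."""
        deltas = np.clip(rng.normal(0.0, sd_deg, len(self.curves)), -1.0, 1.0)
        new = {key: curve.jittered(float(d))
               for (key, curve), d in zip(self.curves.items(), deltas)}
        return replace(self, curves=new)


def generate_angle_waveforms(
    joint_params: Mapping[tuple[str, str], Mapping],
    stance_fraction: float = 0.62,
    cycle_duration_s: float = 1.0,
) -> AngleWaveformSet:
    """Build a waveform set from explicit per-channel parameters.

    ``joint_params`` maps (joint, plane) to a mapping with keys ``offset``
    (deg) and ``harmonics`` (sequence of (order, amplitude_deg, phase)).
    Channels not mentioned are identically zero.
    """
    curves: dict[tuple[str, str], HarmonicCurve] = {}
    for key, spec in joint_params.items():
        joint, plane = key
        if joint not in JOINT_NAMES or plane not in PLANES:
            raise ConfigurationError(f"unknown channel {key}")
        curves[key] = HarmonicCurve(
            offset=float(spec.get("offset", 0.0)),
            harmonics=tuple((int(k), float(a), float(p))
                            for k, a, p in spec.get("harmonics", ())),
        )
    return AngleWaveformSet(curves=curves, stance_fraction=stance_fraction,
                            cycle_duration_s=cycle_duration_s)


# ---------------------------------------------------------------------------
# forward kinematics: waveforms -> markers (+ force)
# ---------------------------------------------------------------------------

def _joint_rotations(angles_deg: np.ndarray) -> np.ndarray:
    """(n, 3) Cardan angles -> (n, 3, 3) rotations, vectorised."""
    a, b, g = np.radians(angles_deg).T
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    r = np.empty((angles_deg.shape[0], 3, 3))
    # Rx(a) @ Ry(b) @ Rz(g)
    r[:, 0, 0] = cb * cg
    r[:, 0, 1] = -cb * sg
    r[:, 0, 2] = sb
    r[:, 1, 0] = ca * sg + sa * sb * cg
    r[:, 1, 1] = ca * cg - sa * sb * sg
    r[:, 1, 2] = -sa * cb
    r[:, 2, 0] = sa * sg - ca * sb * cg
    r[:, 2, 1] = sa * cg + ca * sb * sg
    r[:, 2, 2] = ca * cb
    return r


def synthetic_force_trace(n_samples: int, heel_strike_s: float,
                          stance_duration_s: float,
                          rate_hz: float = 1500.0,
                          peak_n: float = 800.0) -> np.ndarray:
    """Smooth double-hump vertical force, non-zero exactly during stance."""
    t = np.arange(n_samples) / rate_hz
    s = (t - heel_strike_s) / stance_duration_s
    inside = (s > 0.0) & (s < 1.0)
    force = np.zeros(n_samples)
    shape = np.sin(np.pi * s[inside]) + 0.25 * np.sin(3.0 * np.pi * s[inside])
    force[inside] = peak_n * np.clip(shape, 0.0, None) / 0.886  # unit peak
    return force


def markers_from_waveforms(
    waveforms: AngleWaveformSet,
    model: SegmentModel = DEFAULT_MODEL,
    noise_sd_mm: float = 0.5,
    seed: int | np.random.SeedSequence | None = 0,
    trial_id: str = "trial",
    kind: str = "walking",
    lead_s: float = 0.2,
    trail_s: float = 0.2,
) -> MarkerTrialBundle:
    """Generate one trial's marker (and force) data from angle waveforms.

    The trial spans ``lead_s`` + one gait cycle + ``trail_s``; heel strike is
    at ``lead_s``.  Waveforms are evaluated at the periodic cycle phase, so
    curves are smooth across the cycle boundary.  Standing-kind trials carry
    the anatomical calibration markers as well.
    """
    rng = np.random.default_rng(seed)
    for segment in model.segments:
        _, coords = model.cluster_array(segment)
        need = 4 if segment == "leg" else 3
        if coords.shape[0] < need:
            raise GeometryError(f"segment {segment!r} needs >= {need} markers")
        s = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise GeometryError(f"cluster of segment {segment!r} is collinear")

    duration_s = lead_s + waveforms.cycle_duration_s + trail_s
    n = int(round(duration_s * 100.0))
    t = np.arange(n) / 100.0
    phi = np.mod((t - lead_s) / waveforms.cycle_duration_s, 1.0)
    angles = waveforms.sample(phi)

    # propagate (R, t) transforms down the chain; leg fixed in the lab
    eye = np.broadcast_to(np.eye(3), (n, 3, 3))
    transforms: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "leg": (eye, np.zeros((n, 3)))
    }
    for joint, parent, child, centre in model.chain:
        r_j = _joint_rotations(angles[joint])
        r_p, t_p = transforms[parent]
        c = np.asarray(centre, dtype=float)
        r_c = np.einsum("nij,njk->nik", r_p, r_j)
        t_c = np.einsum("nij,nj->ni", r_p, c - np.einsum("nij,j->ni", r_j, c)) + t_p
        transforms[child] = (r_c, t_c)

    markers: dict[str, np.ndarray] = {}
    for segment in model.segments:
        r_s, t_s = transforms[segment]
        for label, pos in model.clusters[segment].items():
            p = np.asarray(pos, dtype=float)
            traj = np.einsum("nij,j->ni", r_s, p) + t_s
            markers[label] = traj
    anatomical_labels: tuple[str, ...] = ()
    if kind == "standing_reference":
        for label, pos in model.anatomical.items():
            markers[label] = np.broadcast_to(np.asarray(pos, dtype=float),
                                             (n, 3)).copy()
        anatomical_labels = tuple(model.anatomical)

    if noise_sd_mm > 0:
        for label in markers:
            markers[label] = markers[label] + rng.normal(
                0.0, noise_sd_mm, (n, 3))
    else:
        markers = {lab: arr.copy() for lab, arr in markers.items()}

    force = None
    if kind == "walking":
        n_force = int(round(duration_s * 1500.0))
        force = synthetic_force_trace(
            n_force, heel_strike_s=lead_s,
            stance_duration_s=waveforms.stance_fraction * waveforms.cycle_duration_s)

    return MarkerTrialBundle(
        trial_id=trial_id, kind=kind, markers=markers,
        registry=model.registry, force=force,
        anatomical_labels=anatomical_labels)


def static_trial_waveforms(stn_frontal_deg: float = 0.0,
                           cycle_duration_s: float = 1.0) -> AngleWaveformSet:
    """Constant-posture waveforms: all joints zero except an optional
    frontal rearfoot offset (the subtalar-neutral standing position)."""
    curves = {}
    if stn_frontal_deg != 0.0:
        curves[("rearfoot", "frontal")] = HarmonicCurve(offset=stn_frontal_deg)
    return AngleWaveformSet(curves=curves, cycle_duration_s=cycle_duration_s)


# ---------------------------------------------------------------------------
# ground-truth extraction from waveforms
# ---------------------------------------------------------------------------

def true_heel_lift_pct(waveforms: AngleWaveformSet,
                       search_start_pct: float = 40.0,
                       sustain_pct: float = 5.0,
                       fallback_pct: float = 60.0,
                       n_grid: int = 10001) -> float:
    """Heel lift (% stance) by dense scan of the true sagittal velocity."""
    fs = waveforms.stance_fraction
    curve = waveforms.curve("rearfoot", "sagittal")
    s = np.linspace(0.0, 1.0, n_grid)                 # stance-normalised
    vel = np.asarray(curve.derivative(s * fs))
    window = int(round(sustain_pct / 100.0 * (n_grid - 1)))
    start = int(np.ceil(search_start_pct / 100.0 * (n_grid - 1)))
    neg = vel < 0
    cs = np.concatenate([[0], np.cumsum(neg[start:].astype(np.int64))])
    run = cs[window:] - cs[:-window]          # sliding count of negatives
    hits = np.flatnonzero(run == window)
    if hits.size == 0:
        return fallback_pct
    return 100.0 * (start + hits[0]) / (n_grid - 1)


def true_gait_variables(waveforms: AngleWaveformSet,
                        midstance_start_pct: float = 15.0,
                        heel_lift_pct: float | None = None) -> GaitVariables:
    """The six dynamic variables by dense scans of the true curves."""
    fs = waveforms.stance_fraction
    hl = (true_heel_lift_pct(waveforms) if heel_lift_pct is None
          else heel_lift_pct)
    ms = (midstance_start_pct / 100.0 * fs, hl / 100.0 * fs)   # cycle phase
    prop = (hl / 100.0 * fs, fs)
    sag = waveforms.curve("rearfoot", "sagittal")
    frontal = waveforms.curve("rearfoot", "frontal")
    hallux = waveforms.curve("hallux_medial_forefoot", "sagittal")
    sag_max, _ = sag.extremum_in_window(*ms, kind="max")
    sag_min, _ = sag.extremum_in_window(*ms, kind="min")
    return GaitVariables(
        peak_rearfoot_eversion_midstance=frontal.extremum_in_window(
            *ms, kind="min")[0],
        peak_rearfoot_dorsiflexion_midstance=sag_max,
        rearfoot_sagittal_at_heel_lift=float(sag.evaluate(hl / 100.0 * fs)),
        rearfoot_sagittal_range_midstance=sag_max - sag_min,
        peak_hallux_dorsiflexion_propulsion=hallux.extremum_in_window(
            *prop, kind="max")[0],
        peak_rearfoot_eversion_propulsion=frontal.extremum_in_window(
            *prop, kind="min")[0],
    )


def true_stn_crossing(waveforms: AngleWaveformSet, neutral_deg: float,
                      window: str = "stance",
                      n_grid: int = 20001) -> tuple[bool, float]:
    """(passed, timing % cycle) by dense scan of the true frontal curve."""
    hi = waveforms.stance_fraction if window == "stance" else 1.0
    phi = np.linspace(0.0, hi, n_grid)
    diff = np.asarray(waveforms.curve("rearfoot", "frontal").evaluate(phi)) \
        - neutral_deg
    sign_change = np.flatnonzero(diff[:-1] * diff[1:] <= 0)
    if sign_change.size:
        i = sign_change[0]
        frac = diff[i] / (diff[i] - diff[i + 1]) if diff[i] != diff[i + 1] else 0.0
        return True, 100.0 * (phi[i] + frac * (phi[i + 1] - phi[i]))
    return False, 100.0 * phi[int(np.argmin(np.abs(diff)))]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the reference cohort: 100 feet, 8 walking trials each,
    0.5 mm marker noise, deformity prevalences of 97 % rearfoot varus, 87 %
    ankle equinus, 9 % limited hallux dorsiflexion, first ray 74/19/7 %
    plantarflexed/normal/dorsiflexed, forefoot 76/4/20 % varus/normal/valgus,
    and static-dynamic correlations of 0.43 (NCSP <-> mid-stance eversion),
    0.25 (ankle range <-> mid-stance dorsiflexion) and 0.38 (hallux range
    <-> propulsion dorsiflexion).  ``group_effects`` adds a fixed offset
    (deg) to the affected dynamic variable of feet carrying a deformity —
    zero by default, reflecting the observed absence of group differences.
    """

    n: int = 100
    trial_count: int = 8
    noise_sd_mm: float = 0.5
    seed: int = 0
    rho: Mapping[str, float] = field(default_factory=lambda: {
        "ncsp_eversion": 0.43,
        "ankle_dorsiflexion": 0.25,
        "hallux_dorsiflexion": 0.38,
    })
    prevalence: Mapping[str, float] = field(default_factory=lambda: {
        "rearfoot_varus": 0.97,
        "ankle_equinus": 0.87,
        "hallux_limited": 0.09,
        "first_ray_plantarflexed": 0.74,
        "first_ray_dorsiflexed": 0.07,
        "forefoot_varus": 0.76,
        "forefoot_valgus": 0.20,
    })
    group_effects: Mapping[str, float] = field(default_factory=dict)
    amplitude_jitter_deg: float = 0.5
    cycle_duration_s: float = 1.0
    stance_fraction: float = 0.62
    stn_offset_mean_deg: float = 3.0
    stn_offset_sd_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("cohort size must be >= 2")
        if self.noise_sd_mm < 0:
            raise ConfigurationError("marker noise sd must be >= 0")
        if self.trial_count < 1:
            raise ConfigurationError("trial count must be >= 1")
        for name, rho in self.rho.items():
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError(f"rho[{name!r}]={rho} outside [-1, 1]")
        for name, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"prevalence[{name!r}]={p} outside [0, 1]")
        for a, b in (("first_ray_plantarflexed", "first_ray_dorsiflexed"),
                     ("forefoot_varus", "forefoot_valgus")):
            if self.prevalence.get(a, 0) + self.prevalence.get(b, 0) > 1.0:
                raise ConfigurationError(
                    f"prevalences of {a} and {b} sum beyond 1")
        for name in self.group_effects:
            if name not in GROUP_EFFECT_TARGETS:
                raise ConfigurationError(f"unknown group effect {name!r}")


@dataclass
class SyntheticParticipant:
    participant_id: str
    static: StaticAssessment
    waveforms: AngleWaveformSet
    true_variables: GaitVariables
    stn_angle_deg: float
    true_stn_passed_stance: bool
    true_stn_timing_pct: float
    true_dynamics: dict[str, float]
    trials: list[MarkerTrialBundle] | None = None
    standing: MarkerTrialBundle | None = None
    stn_trial: MarkerTrialBundle | None = None


def _correlated(rng: np.random.Generator, z: np.ndarray, rho: float) -> np.ndarray:
    """Standard-normal draws with correlation ``rho`` to the latent ``z``."""
    return rho * z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.standard_normal(z.size)


def _truncnorm(rng: np.random.Generator, loc: float, scale: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return _sstats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                                 random_state=rng)


def _mixture_moments(w: float, params: Sequence[tuple[float, float, float, float]]
                     ) -> tuple[float, float]:
    """Mean and SD of a two-component truncated-normal mixture."""
    (l1, s1, lo1, hi1), (l2, s2, lo2, hi2) = params
    m1, v1 = _sstats.truncnorm.stats((lo1 - l1) / s1, (hi1 - l1) / s1,
                                     loc=l1, scale=s1, moments="mv")
    m2, v2 = _sstats.truncnorm.stats((lo2 - l2) / s2, (hi2 - l2) / s2,
                                     loc=l2, scale=s2, moments="mv")
    mean = w * m1 + (1 - w) * m2
    var = w * (v1 + m1 ** 2) + (1 - w) * (v2 + m2 ** 2) - mean ** 2
    return float(mean), float(np.sqrt(var))


# distribution constants for the study conditions (deg)
_NCSP_SD = 4.9
_ANKLE_EQUINUS = (4.8, 1.8, -3.0, 10.0)      # loc, scale, lo, hi
_ANKLE_NORMAL = (11.9, 1.5, 10.0, 20.0)
_HALLUX_LIMITED = (55.0, 6.0, 35.0, 65.0)
_HALLUX_NORMAL = (75.0, 6.0, 65.0, 95.0)
_EVERSION_MEAN, _EVERSION_SD = -3.9, 2.0     # peak mid-stance eversion
_DORSI_MEAN, _DORSI_SD = 5.6, 1.8            # peak mid-stance dorsiflexion
_HALLUX_DYN_MEAN, _HALLUX_DYN_SD = 44.0, 4.0  # peak propulsion dorsiflexion


def _participant_waveforms(rng: np.random.Generator, config: CohortConfig,
                           ever_target: float, dorsi_target: float,
                           hallux_target: float) -> AngleWaveformSet:
    """Waveforms whose window extrema hit the drawn dynamic targets."""
    sag_amp = 7.0 + rng.normal(0.0, 0.5)
    hallux_base = 5.0 + rng.normal(0.0, 1.0)
    # Rearfoot frontal plane: slight inversion at heel strike, eversion
    # trough at 28 % of the cycle, and a modest re-inversion by toe off,
    # solved as a two-harmonic curve through those three points.  The
    # trough is a stationary point by construction, but the curve's
    # symmetric side lobes can undershoot it slightly; the trough-point
    # constraint is therefore adjusted by fixed-point iteration until the
    # realised mid-stance minimum equals the drawn dynamic target, so the
    # configured static-dynamic correlations hold for the realised curves.
    heelstrike_inv = 0.5 + rng.normal(0.0, 0.5)
    toeoff_inv = 2.5 + rng.normal(0.0, 0.8)
    trough_phase = 0.28
    rows = []
    for phi in (0.0, trough_phase, config.stance_fraction):
        x = phi - trough_phase
        rows.append([1.0, np.cos(2 * np.pi * x), np.cos(4 * np.pi * x)])
    rows = np.array(rows)

    sagittal = HarmonicCurve(offset=dorsi_target - sag_amp,
                             harmonics=((1, sag_amp, 0.45),))
    # mid-stance window of the realised set (sagittal channel fixes heel lift)
    hl_pct = true_heel_lift_pct(AngleWaveformSet(
        curves={("rearfoot", "sagittal"): sagittal},
        stance_fraction=config.stance_fraction,
        cycle_duration_s=config.cycle_duration_s))
    window = (0.15 * config.stance_fraction,
              hl_pct / 100.0 * config.stance_fraction)
    def _solve(trough_value: float) -> tuple[HarmonicCurve, float]:
        c0, c1, c2 = np.linalg.solve(
            rows, [heelstrike_inv, trough_value, toeoff_inv])
        curve = HarmonicCurve(
            offset=float(c0),
            harmonics=((1, float(c1), trough_phase),
                       (2, float(c2), trough_phase)))
        return curve, curve.extremum_in_window(*window, kind="min",
                                               n_grid=4001)[0]

    # secant iteration on trough_value -> window minimum (the minimum can sit
    # on a side lobe, where the map's slope is well below one)
    tv_prev = ever_target
    frontal, measured = _solve(tv_prev)
    f_prev = measured - ever_target
    tv = tv_prev - f_prev
    for _ in range(20):
        frontal, measured = _solve(tv)
        f = measured - ever_target
        if abs(f) < 1e-7 or f == f_prev:
            break
        tv, tv_prev, f_prev = tv - f * (tv - tv_prev) / (f - f_prev), tv, f
    curves = {
        ("rearfoot", "sagittal"): sagittal,
        ("rearfoot", "frontal"): frontal,
        ("rearfoot", "transverse"): HarmonicCurve(
            harmonics=((1, 2.0 + rng.normal(0, 0.3), 0.30),)),
        ("hallux_medial_forefoot", "sagittal"): HarmonicCurve(
            offset=hallux_base,
            harmonics=((1, hallux_target - hallux_base, 0.58),)),
        ("hallux_medial_forefoot", "frontal"): HarmonicCurve(
            harmonics=((1, 1.5 + rng.normal(0, 0.2), 0.55),)),
        ("midfoot_calcaneus", "sagittal"): HarmonicCurve(
            harmonics=((1, 3.0 + rng.normal(0, 0.3), 0.40),)),
        ("midfoot_calcaneus", "frontal"): HarmonicCurve(
            harmonics=((1, 2.0 + rng.normal(0, 0.3), 0.35),)),
        ("medial_forefoot_midfoot", "sagittal"): HarmonicCurve(
            harmonics=((1, 3.0 + rng.normal(0, 0.3), 0.50),)),
        ("lateral_forefoot_midfoot", "sagittal"): HarmonicCurve(
            harmonics=((1, 2.5 + rng.normal(0, 0.3), 0.48),)),
    }
    return AngleWaveformSet(curves=curves,
                            stance_fraction=config.stance_fraction,
                            cycle_duration_s=config.cycle_duration_s)


def generate_cohort(config: CohortConfig,
                    include_markers: bool = True,
                    model: SegmentModel = DEFAULT_MODEL,
                    ) -> list[SyntheticParticipant]:
    """Draw a synthetic cohort under the configured study conditions.

    With ``include_markers=False`` only statics, waveforms and true dynamic
    variables are generated (fast path for statistical simulations); with
    markers, each participant gets ``trial_count`` walking trials that
    differ only by marker noise and small (< 1 deg) waveform amplitude
    jitter, plus a standing reference and a subtalar-neutral standing trial.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    prev = config.prevalence

    # --- statics ---------------------------------------------------------
    z_ncsp = rng.standard_normal(n)
    ncsp_mean = _NCSP_SD * _sstats.norm.ppf(prev.get("rearfoot_varus", 0.97))
    ncsp = ncsp_mean + _NCSP_SD * z_ncsp
    rcsp = ncsp - 8.5 + rng.normal(0.0, 2.0, n)

    equinus = rng.random(n) < prev.get("ankle_equinus", 0.87)
    ankle = np.where(
        equinus,
        _truncnorm(rng, *_ANKLE_EQUINUS, n),
        _truncnorm(rng, *_ANKLE_NORMAL, n))
    ankle_mean, ankle_sd = _mixture_moments(
        prev.get("ankle_equinus", 0.87), (_ANKLE_EQUINUS, _ANKLE_NORMAL))
    z_ankle = (ankle - ankle_mean) / ankle_sd

    limited = rng.random(n) < prev.get("hallux_limited", 0.09)
    hallux_static = np.where(
        limited,
        _truncnorm(rng, *_HALLUX_LIMITED, n),
        _truncnorm(rng, *_HALLUX_NORMAL, n))
    hallux_mean, hallux_sd = _mixture_moments(
        prev.get("hallux_limited", 0.09), (_HALLUX_LIMITED, _HALLUX_NORMAL))
    z_hallux = (hallux_static - hallux_mean) / hallux_sd

    u_ray = rng.random(n)
    p_pf = prev.get("first_ray_plantarflexed", 0.74)
    p_df = prev.get("first_ray_dorsiflexed", 0.07)
    first_ray = np.where(u_ray < p_pf, "plantarflexed",
                         np.where(u_ray < p_pf + p_df, "dorsiflexed", "normal"))
    u_ff = rng.random(n)
    p_var = prev.get("forefoot_varus", 0.76)
    p_val = prev.get("forefoot_valgus", 0.20)
    forefoot = np.where(u_ff < p_var, "varus",
                        np.where(u_ff < p_var + p_val, "valgus", "normal"))

    u_fpi = rng.random(n)
    fpi = np.where(u_fpi < 0.32, rng.normal(7.7, 1.5, n),
                   np.where(u_fpi < 0.88, rng.normal(2.6, 1.5, n),
                            rng.normal(-2.4, 1.5, n)))
    fpi = np.rint(fpi).astype(int)

    # --- dynamics, correlated with the statics ---------------------------
    rho = config.rho
    ever_target = _EVERSION_MEAN + _EVERSION_SD * _correlated(
        rng, z_ncsp, rho.get("ncsp_eversion", 0.0))
    dorsi_target = _DORSI_MEAN + _DORSI_SD * _correlated(
        rng, z_ankle, rho.get("ankle_dorsiflexion", 0.0))
    hallux_target = _HALLUX_DYN_MEAN + _HALLUX_DYN_SD * _correlated(
        rng, z_hallux, rho.get("hallux_dorsiflexion", 0.0))

    effects = config.group_effects
    if "ankle_equinus" in effects:
        dorsi_target = dorsi_target + effects["ankle_equinus"] * equinus
    if "hallux_limited" in effects:
        hallux_target = hallux_target + effects["hallux_limited"] * limited
    if "first_ray_plantarflexed" in effects:
        ever_target = ever_target + (effects["first_ray_plantarflexed"]
                                     * (first_ray == "plantarflexed"))
    if "forefoot_varus" in effects:
        ever_target = ever_target + (effects["forefoot_varus"]
                                     * (forefoot == "varus"))

    stn_offsets = rng.normal(config.stn_offset_mean_deg,
                             config.stn_offset_sd_deg, n)

    participants: list[SyntheticParticipant] = []
    seeds = np.random.SeedSequence(config.seed).spawn(n)
    for i in range(n):
        prng = np.random.default_rng(seeds[i])
        static = StaticAssessment(
            ncsp_deg=float(ncsp[i]), rcsp_deg=float(rcsp[i]),
            ankle_dorsiflexion_deg=float(ankle[i]),
            first_mpj_dorsiflexion_deg=float(hallux_static[i]),
            first_ray=str(first_ray[i]), forefoot=str(forefoot[i]),
            fpi=int(fpi[i]))
        waveforms = _participant_waveforms(
            prng, config, float(ever_target[i]), float(dorsi_target[i]),
            float(hallux_target[i]))
        truth = true_gait_variables(waveforms)
        passed, timing = true_stn_crossing(waveforms, float(stn_offsets[i]),
                                           window="stance")
        participant = SyntheticParticipant(
            participant_id=f"P{i + 1:03d}",
            static=static,
            waveforms=waveforms,
            true_variables=truth,
            stn_angle_deg=float(stn_offsets[i]),
            true_stn_passed_stance=passed,
            true_stn_timing_pct=timing,
            true_dynamics={
                "peak_rearfoot_eversion_midstance": float(ever_target[i]),
                "peak_rearfoot_dorsiflexion_midstance": float(dorsi_target[i]),
                "peak_hallux_dorsiflexion_propulsion": float(hallux_target[i]),
            },
        )
        if include_markers:
            participant.trials = [
                markers_from_waveforms(
                    waveforms.jittered(prng, config.amplitude_jitter_deg),
                    model=model, noise_sd_mm=config.noise_sd_mm,
                    seed=prng.integers(2 ** 31),
                    trial_id=f"{participant.participant_id}_walk{j + 1}",
                    kind="walking")
                for j in range(config.trial_count)
            ]
            participant.standing = markers_from_waveforms(
                static_trial_waveforms(0.0, config.cycle_duration_s),
                model=model, noise_sd_mm=config.noise_sd_mm,
                seed=prng.integers(2 ** 31),
                trial_id=f"{participant.participant_id}_standing",
                kind="standing_reference", lead_s=0.0, trail_s=0.0)
            participant.stn_trial = markers_from_waveforms(
                static_trial_waveforms(float(stn_offsets[i]),
                                       config.cycle_duration_s),
                model=model, noise_sd_mm=config.noise_sd_mm,
                seed=prng.integers(2 ** 31),
                trial_id=f"{participant.participant_id}_stn",
                kind="stn_standing", lead_s=0.0, trail_s=0.0)
        participants.append(participant)
    return participants


def write_cohort(participants: Sequence[SyntheticParticipant],
                 out_dir: str | Path) -> Path:
    """Write trials as TSV and a cohort manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in participants:
        if p.trials is None or p.standing is None or p.stn_trial is None:
            raise ConfigurationError(
                f"participant {p.participant_id} has no marker trials; "
                "generate the cohort with include_markers=True")
        pdir = out_dir / p.participant_id
        pdir.mkdir(exist_ok=True)
        standing_path = pdir / "standing.tsv"
        write_marker_trial(standing_path, p.standing)
        stn_path = pdir / "stn.tsv"
        write_marker_trial(stn_path, p.stn_trial)
        walk_paths = []
        for trial in p.trials:
            path = pdir / f"{trial.trial_id.split('_')[-1]}.tsv"
            write_marker_trial(path, trial)
            walk_paths.append(path)
        entries.append(ManifestEntry(
            participant_id=p.participant_id, static=p.static,
            standing_trial=standing_path, stn_trial=stn_path,
            walking_trials=walk_paths))
    manifest = out_dir / "manifest.csv"
    write_cohort_manifest(manifest, entries)
    return manifest
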