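"""Root-model static deformity classification and subtalar-neutral analysis.

The Root protocol defines five structural deformities from a static exam:

* rearfoot varus — calcaneus inverted (> 0 deg) in neutral calcaneal stance
  position (NCSP);
* ankle equinus — static ankle dorsiflexion range below 10 deg;
* limited hallux dorsiflexion — maximum 1st MPJ dorsiflexion below 65 deg;
* first-ray deviation — plantarflexed or dorsiflexed (clinician category);
* forefoot-to-rearfoot deviation — varus or valgus (clinician category).

Values exactly at a threshold classify as normal (strict inequalities);
thresholds are configurable.  The deformity count (0-5) gives the first-ray
and forefoot categories one slot each.

The subtalar-neutral (STN) analysis asks whether the frontal rearfoot curve
during gait ever coincides with the angle measured standing in subtalar
neutral: if it does, the first crossing time is reported (% gait cycle);
if not, the minimum difference and the time of closest approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .errors import ContractError
from .io_formats import StaticAssessment


@dataclass(frozen=True)
class ClassificationThresholds:
    """Deformity thresholds in degrees; strict inequalities throughout."""

    rearfoot_varus_deg: float = 0.0   # NCSP inversion beyond this -> varus
    ankle_equinus_deg: float = 10.0   # dorsiflexion range below this -> equinus
    hallux_limited_deg: float = 65.0  # 1st MPJ dorsiflexion below this -> limited


@dataclass
class DeformityProfile:
    """Per-foot classification with magnitudes for the five deformities."""

    rearfoot_varus: bool
    rearfoot_varus_deg: float
    ankle_equinus: bool
    ankle_dorsiflexion_deg: float
    hallux_limited: bool
    first_mpj_dorsiflexion_deg: float
    first_ray: str
    forefoot: str
    count: int = field(init=False)

    def __post_init__(self) -> None:
        indicators = (self.rearfoot_varus, self.ankle_equinus, self.hallux_limited,
                      self.first_ray != "normal", self.forefoot != "normal")
        self.count = int(sum(indicators))
        assert self.count == sum(int(i) for i in indicators)  # sum of indicators

    def as_dict(self) -> dict:
        return {
            "rearfoot_varus": self.rearfoot_varus,
            "rearfoot_varus_deg": self.rearfoot_varus_deg,
            "ankle_equinus": self.ankle_equinus,
            "ankle_dorsiflexion_deg": self.ankle_dorsiflexion_deg,
            "hallux_limited": self.hallux_limited,
            "first_mpj_dorsiflexion_deg": self.first_mpj_dorsiflexion_deg,
            "first_ray": self.first_ray,
            "forefoot": self.forefoot,
            "count": self.count,
        }


def classify_deformities(
    static: StaticAssessment,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> DeformityProfile:
    """Classify the five Root deformities from one static assessment.

    NCSP inversion is positive, so ``ncsp_deg > rearfoot_varus_deg`` (default
    0: a vertical calcaneus is not varus) flags rearfoot varus with the NCSP
    angle as its magnitude.  The first-ray and forefoot categories pass
    through from the clinician's judgement.
    """
    return DeformityProfile(
        rearfoot_varus=static.ncsp_deg > thresholds.rearfoot_varus_deg,
        rearfoot_varus_deg=static.ncsp_deg,
        ankle_equinus=static.ankle_dorsiflexion_deg < thresholds.ankle_equinus_deg,
        ankle_dorsiflexion_deg=static.ankle_dorsiflexion_deg,
        hallux_limited=(static.first_mpj_dorsiflexion_deg
                        < thresholds.hallux_limited_deg),
        first_mpj_dorsiflexion_deg=static.first_mpj_dorsiflexion_deg,
        first_ray=static.first_ray,
        forefoot=static.forefoot,
    )


@dataclass
class StnResult:
    """Did the rearfoot pass through subtalar neutral, and when?

    Exactly one of ``crossing_time_pct`` (passed) or ``min_difference_deg``
    (not passed) is populated.  Times are percent of the gait cycle.
    """

    passed: bool
    crossing_time_pct: float | None = None
    min_difference_deg: float | None = None
    closest_time_pct: float = 0.0
    all_crossings_pct: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.passed == (self.crossing_time_pct is None):
            raise ContractError("crossing time populated iff passed")
        if self.passed != (self.min_difference_deg is None):
            raise ContractError("min difference populated iff not passed")
        if not 0.0 <= self.closest_time_pct <= 100.0:
            raise ContractError("times must lie in [0, 100] % of the cycle")

    @property
    def timing_pct(self) -> float:
        """Crossing time when passed, else time of closest approach."""
        return self.crossing_time_pct if self.passed else self.closest_time_pct


def stn_passthrough(neutral_angle_deg: float,
                    frontal_rearfoot_cycle: np.ndarray,
                    window: str = "cycle",
                    stance_fraction: float = 0.62,
                    tolerance_deg: float = 1e-9) -> StnResult:
    """Compare the STN standing angle with the frontal rearfoot gait curve.

    ``frontal_rearfoot_cycle`` must be normalised to the full gait cycle
    (101 points, 0-100 %).  The foot "passed through" neutral when the
    difference curve changes sign or comes within ``tolerance_deg`` of zero.
    Crossing instants are located by linear interpolation between samples;
    with ``window="stance"`` only the stance portion (first
    ``stance_fraction`` of the cycle) is searched, but times remain percent
    of the full cycle.
    """
    curve = np.asarray(frontal_rearfoot_cycle, dtype=float)
    if curve.ndim != 1 or curve.size != 101:
        raise ContractError("expected a 101-point cycle-normalised curve")
    if window not in ("cycle", "stance"):
        raise ContractError(f"unknown STN window {window!r}")
    pct = np.linspace(0.0, 100.0, curve.size)
    if window == "stance":
        keep = pct <= 100.0 * stance_fraction + 1e-9
        pct, curve = pct[keep], curve[keep]
    diff = curve - neutral_angle_deg

    crossings: list[float] = []
    touching = np.abs(diff) <= tolerance_deg
    for i in np.flatnonzero(touching):
        crossings.append(pct[i])
    sign_change = np.flatnonzero((diff[:-1] * diff[1:] < 0)
                                 & ~touching[:-1] & ~touching[1:])
    for i in sign_change:
        frac = diff[i] / (diff[i] - diff[i + 1])
        crossings.append(pct[i] + frac * (pct[i + 1] - pct[i]))
    crossings.sort()

    closest = int(np.argmin(np.abs(diff)))
    if crossings:
        return StnResult(passed=True, crossing_time_pct=crossings[0],
                         closest_time_pct=crossings[0],
                         all_crossings_pct=tuple(crossings))
    return StnResult(passed=False,
                     min_difference_deg=float(np.abs(diff[closest])),
                     closest_time_pct=float(pct[closest]))


@dataclass
class StnSummary:
    percent_passing: float
    mean_timing_pct: float
    timing_ci95_pct: tuple[float, float]
    n: int


def cohort_stn_summary(results: list[StnResult]) -> StnSummary:
    """Cohort share passing through neutral, and pooled timing with 95% CI.

    The timing summary pools the crossing time of passers with the
    closest-approach time of non-passers, matching the single "passed
    through or was closest" statistic reported for this analysis.
    """
    if not results:
        raise ContractError("need at least one STN result")
    passed = [r for r in results if r.passed]
    timings = np.array([r.timing_pct for r in results])
    mean = float(np.mean(timings))
    if len(timings) > 1 and np.std(timings, ddof=1) > 0:
        half = float(_stats.t.ppf(0.975, len(timings) - 1)
                     * np.std(timings, ddof=1) / np.sqrt(len(timings)))
    else:
        half = 0.0
    return StnSummary(
        percent_passing=100.0 * len(passed) / len(results),
        mean_timing_pct=mean,
        timing_ci95_pct=(mean - half, mean + half),
        n=len(results),
    )


def deformity_count_histogram(profiles: list[DeformityProfile]) -> dict[int, int]:
    """Number of feet with 0..5 deformities."""
    hist = {k: 0 for k in range(6)}
    for p in profiles:
        hist[p.count] += 1
    return hist


def deformity_prevalence(profiles: list[DeformityProfile]) -> dict[str, float]:
    """Share of feet carrying each specific deformity type."""
    n = len(profiles)
    if n == 0:
        raise ContractError("need at least one profile")
    return {
        "rearfoot_varus": sum(p.rearfoot_varus for p in profiles) / n,
        "ankle_equinus": sum(p.ankle_equinus for p in profiles) / n,
        "hallux_limited": sum(p.hallux_limited for p in profiles) / n,
        "first_ray_plantarflexed": sum(p.first_ray == "plantarflexed"
                                       for p in profiles) / n,
        "first_ray_dorsiflexed": sum(p.first_ray == "dorsiflexed"
                                     for p in profiles) / n,
        "forefoot_varus": sum(p.forefoot == "varus" for p in profiles) / n,
        "forefoot_valgus": sum(p.forefoot == "valgus" for p in profiles) / n,
    }
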