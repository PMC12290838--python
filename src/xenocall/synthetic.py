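"""Seeded generators for every input table the pipeline consumes.

The generators emulate the study conditions of a cross-model PDX drug
trial so that every downstream classifier can be exercised against known
ground truth:

* mouse cohorts — exponential tumor growth with an additive log-kill
  rate during treatment (optional regrowth from a stated day) and
  multiplicative lognormal caliper noise; presets realize each of the
  five trajectory archetypes (MCR/CR/PR/SD/PD);
* larval zebrafish experiments — per-larva cell counts at 1 dpi and
  4 dpi from a negative-binomial (gamma-mixed Poisson) model with a
  mean/dispersion parameterization, injected cell numbers in the
  100-200 range and 12-20 larvae per group;
* patient lesion courses — sums of diameters derived exactly from
  stated percent changes versus baseline;
* HTS plates — duplicate viability wells on the 5-point, 10-fold
  ladder from a 4PL mean plus Gaussian replicate noise, with a
  simulated per-compound reference cohort.

Randomness contract: one root seed; each mouse/group/table draws from a
child stream derived from ``(seed, stable label hash, index)``, so
adding an arm never perturbs the draws of other arms.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .hts import DEFAULT_LADDER_NMOL, DoseResponsePlate, ReferenceCohort, four_pl
from .mouse import TumorVolumeSeries
from .patient import LesionCourse
from .zebrafish import LarvaGroup

MOUSE_ARCHETYPES = ("MCR", "CR", "PR", "SD", "PD")

_LN2_PER_WEEK = math.log(2) / 7.0  # tumor doubling once a week


def _child_rng(seed: int, label: str, index: int = 0) -> np.random.Generator:
    """Deterministic child stream for one labeled table/row."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(label.encode()), index])


# ---------------------------------------------------------------------------
# mouse cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MouseScenario:
    """Latent tumor-growth kinetics for one treatment arm.

    The noiseless log-volume is ``log V0 + g*t - k*min(t, t_kill_end)``
    with ``g = growth_rate_per_day``, ``k = kill_rate_per_day`` and
    ``t_kill_end = regrowth_day`` (defaulting to the end of treatment),
    i.e. the drug subtracts a constant log-kill rate until regrowth
    starts, after which net growth resumes.  Measurement noise is
    multiplicative lognormal with unit mean and coefficient of variation
    ``noise_cv``.
    """

    archetype: str
    n_mice: int = 6
    start_volume_mm3: float = 150.0
    growth_rate_per_day: float = _LN2_PER_WEEK
    kill_rate_per_day: float = 0.0
    regrowth_day: float | None = None
    noise_cv: float = 0.1
    schedule_days: tuple[float, ...] = tuple(np.arange(0.0, 42.1, 3.5))
    treatment_end_day: float = 28.0

    def __post_init__(self) -> None:
        if self.archetype not in MOUSE_ARCHETYPES:
            raise ValueError(f"archetype must be one of {MOUSE_ARCHETYPES}")
        if self.n_mice <= 0:
            raise ValueError("n_mice must be positive")
        if self.start_volume_mm3 <= 0:
            raise ValueError("start_volume_mm3 must be positive")
        if self.growth_rate_per_day <= 0:
            raise ValueError("growth_rate_per_day must be positive")
        if self.kill_rate_per_day < 0:
            raise ValueError("kill_rate_per_day must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        sched = tuple(float(d) for d in self.schedule_days)
        object.__setattr__(self, "schedule_days", sched)
        if not sched or sched[0] != 0:
            raise ValueError("schedule_days must start at 0")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule_days must be strictly ascending")
        if self.treatment_end_day < 0:
            raise ValueError("treatment_end_day must be non-negative")

    def latent_volume(self, day: float) -> float:
        """Noiseless trajectory volume at ``day`` (treatment starts at 0)."""
        kill_end = (
            self.regrowth_day if self.regrowth_day is not None else self.treatment_end_day
        )
        log_v = (
            math.log(self.start_volume_mm3)
            + self.growth_rate_per_day * day
            - self.kill_rate_per_day * min(day, kill_end)
        )
        return math.exp(log_v)


def mouse_archetype_scenario(archetype: str, **overrides) -> MouseScenario:
    """Preset scenario whose noiseless trajectory realizes ``archetype``.

    All presets double the tumor once a week off treatment and treat for
    28 days from day 0; the kill rate, start volume, schedule and
    regrowth day are tuned per archetype (e.g. PR starts at 300 mm^3 so
    a >=50 % regression stays above the 100 mm^3 measurable cutoff).
    """
    g = _LN2_PER_WEEK
    presets: dict[str, dict] = {
        # stays <100 mm^3 for the full 3-week post-treatment window
        "MCR": dict(
            start_volume_mm3=150.0,
            kill_rate_per_day=g - math.log(10.0 / 150.0) / 28.0,
            schedule_days=tuple(np.arange(0.0, 49.1, 3.5)),
        ),
        # drops below 100 mm^3 mid-treatment, regrows through the window
        "CR": dict(
            start_volume_mm3=150.0,
            kill_rate_per_day=g - math.log(20.0 / 150.0) / 21.0,
            regrowth_day=21.0,
        ),
        # nadir 120 mm^3 (60 % regression, still measurable)
        "PR": dict(
            start_volume_mm3=300.0,
            kill_rate_per_day=g - math.log(120.0 / 300.0) / 28.0,
        ),
        # mild net kill: 24 % regression, study ends at treatment end
        "SD": dict(
            start_volume_mm3=300.0,
            kill_rate_per_day=1.1 * g,
            schedule_days=tuple(np.arange(0.0, 28.1, 3.5)),
        ),
        # unchecked exponential growth
        "PD": dict(start_volume_mm3=150.0, kill_rate_per_day=0.0),
    }
    params = presets[archetype]
    params.update(overrides)
    return MouseScenario(archetype=archetype, **params)


def gen_mouse_cohort(
    scenario: MouseScenario, seed: int, model_id: str = "synthetic", arm: str | None = None
) -> list[TumorVolumeSeries]:
    """Simulate one treatment arm of tumor-volume series.

    Deterministic given ``(scenario, seed)``; volumes are strictly
    positive (lognormal noise on a positive latent trajectory).
    """
    arm = arm if arm is not None else scenario.archetype
    sigma = math.sqrt(math.log(1.0 + scenario.noise_cv**2))
    out = []
    for i in range(scenario.n_mice):
        rng = _child_rng(seed, f"mouse/{arm}", i)
        noise = (
            np.exp(sigma * rng.standard_normal(len(scenario.schedule_days)) - sigma**2 / 2)
            if sigma > 0
            else np.ones(len(scenario.schedule_days))
        )
        vols = [
            scenario.latent_volume(d) * float(z)
            for d, z in zip(scenario.schedule_days, noise)
        ]
        out.append(
            TumorVolumeSeries(
                mouse_id=f"{arm}-{i + 1}",
                model_id=model_id,
                arm=arm,
                measurements=tuple(zip(scenario.schedule_days, vols)),
                treatment_start_day=0.0,
                treatment_end_day=scenario.treatment_end_day,
                study_end_day=scenario.schedule_days[-1],
            )
        )
    return out


# ---------------------------------------------------------------------------
# zebrafish experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FishScenario:
    """Group structure and count model for one larval zebrafish experiment.

    Per-larva counts are negative binomial with the stated mean and
    ``dispersion`` equal to the NB size parameter (variance
    ``mu + mu^2/dispersion``): small values are strongly overdispersed,
    ``inf`` gives the Poisson limit, and 0 is a sentinel for noiseless
    deterministic counts (``round(mean)``).  The 1-dpi control mean is
    the mean injected cell number; the 4-dpi control mean multiplies it
    by ``control_growth_factor``; each arm's 4-dpi mean further
    multiplies by its ``treatment_effect`` (< 1 = kill).
    """

    n_injected_cells_low: int = 100
    n_injected_cells_high: int = 200
    control_growth_factor: float = 2.0
    treatment_effects: dict = field(default_factory=dict)  # arm -> multiplier
    dispersion: float = 8.0
    n_larvae_per_group: int = 16
    model_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 < self.n_injected_cells_low <= self.n_injected_cells_high:
            raise ValueError("injected cell range must be positive and ordered")
        if self.control_growth_factor <= 0:
            raise ValueError("control_growth_factor must be positive")
        if any(e <= 0 for e in self.treatment_effects.values()):
            raise ValueError("treatment effects must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 12 <= self.n_larvae_per_group <= 20:
            raise ValueError("n_larvae_per_group must be within [12, 20]")

    @property
    def injected_mean(self) -> float:
        return (self.n_injected_cells_low + self.n_injected_cells_high) / 2.0


def _draw_counts(
    mean: float, dispersion: float, n: int, rng: np.random.Generator
) -> tuple[int, ...]:
    if dispersion == 0:
        return (int(round(mean)),) * n
    if math.isinf(dispersion):
        return tuple(int(c) for c in rng.poisson(mean, n))
    p = dispersion / (dispersion + mean)
    return tuple(int(c) for c in rng.negative_binomial(dispersion, p, n))


def gen_fish_experiment(scenario: FishScenario, seed: int) -> list[LarvaGroup]:
    """Simulate 1-dpi control, 4-dpi control and per-arm 4-dpi groups."""
    mu0 = scenario.injected_mean
    groups = [
        LarvaGroup(
            scenario.model_id,
            "control",
            "1dpi",
            _draw_counts(
                mu0,
                scenario.dispersion,
                scenario.n_larvae_per_group,
                _child_rng(seed, "fish/control@1dpi"),
            ),
        ),
        LarvaGroup(
            scenario.model_id,
            "control",
            "4dpi",
            _draw_counts(
                mu0 * scenario.control_growth_factor,
                scenario.dispersion,
                scenario.n_larvae_per_group,
                _child_rng(seed, "fish/control@4dpi"),
            ),
        ),
    ]
    for arm, effect in scenario.treatment_effects.items():
        groups.append(
            LarvaGroup(
                scenario.model_id,
                arm,
                "4dpi",
                _draw_counts(
                    mu0 * scenario.control_growth_factor * effect,
                    scenario.dispersion,
                    scenario.n_larvae_per_group,
                    _child_rng(seed, f"fish/{arm}@4dpi"),
                ),
            )
        )
    return groups


# ---------------------------------------------------------------------------
# patient courses
# ---------------------------------------------------------------------------


def gen_patient_course(
    patient_id: str,
    treatment_id: str,
    baseline_sum_mm: float,
    percent_changes: Sequence[float],
    scan_weeks: Sequence[float],
    new_lesion_flags: Sequence[bool] | None = None,
) -> LesionCourse:
    """Lesion course with sums derived exactly from percent changes vs baseline."""
    if baseline_sum_mm <= 0:
        raise ValueError("baseline sum must be positive")
    if len(percent_changes) != len(scan_weeks):
        raise ValueError("one percent change per scan week required")
    flags = list(new_lesion_flags) if new_lesion_flags is not None else [False] * len(
        scan_weeks
    )
    scans = [(0.0, float(baseline_sum_mm), False)]
    for week, pct, flag in zip(scan_weeks, percent_changes, flags):
        total = baseline_sum_mm * (1.0 + pct / 100.0)
        if total < 0:
            raise ValueError(f"percent change {pct} yields a negative sum")
        scans.append((float(week), total, bool(flag)))
    return LesionCourse(patient_id, treatment_id, tuple(scans))


# ---------------------------------------------------------------------------
# HTS plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HtsScenario:
    """True 4PL curve, replicate noise and reference-cohort distribution."""

    top: float = 1.0
    bottom: float = 0.0
    hill: float = 1.0
    true_ic50_nmol: float = 50.0
    replicate_sd: float = 0.02
    ladder: tuple[float, ...] = DEFAULT_LADDER_NMOL
    cohort_n: int = 50
    cohort_auc_mean: float = 0.8
    cohort_auc_sd: float = 0.1
    cohort_logic50_mean: float = 2.5
    cohort_logic50_sd: float = 0.5
    compound: str = "drugA"
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.bottom <= self.top:
            raise ValueError("bottom must be <= top")
        if self.hill <= 0 or self.true_ic50_nmol <= 0:
            raise ValueError("hill and true_ic50_nmol must be positive")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")
        ladder = tuple(float(c) for c in self.ladder)
        object.__setattr__(self, "ladder", ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("ladder must be strictly ascending")
        if self.cohort_n < 2:
            raise ValueError("cohort_n must be >=2")


def gen_hts_plate(
    scenario: HtsScenario, seed: int, n_replicates: int = 2
) -> tuple[DoseResponsePlate, ReferenceCohort]:
    """Duplicate-well viability plate from the 4PL mean plus Gaussian noise,
    and an empirical reference cohort drawn from the stated distributions."""
    rng = _child_rng(seed, f"hts/{scenario.compound}")
    x = np.log10(np.asarray(scenario.ladder))
    mean = four_pl(
        x, scenario.top, scenario.bottom, scenario.hill, math.log10(scenario.true_ic50_nmol)
    )
    viability = tuple(
        tuple(
            float(max(0.0, m + scenario.replicate_sd * rng.standard_normal()))
            if scenario.replicate_sd > 0
            else float(m)
            for _ in range(n_replicates)
        )
        for m in mean
    )
    plate = DoseResponsePlate(
        scenario.sample_id, scenario.compound, scenario.ladder, viability
    )
    cohort_rng = _child_rng(seed, f"hts-cohort/{scenario.compound}")
    aucs = scenario.cohort_auc_mean + scenario.cohort_auc_sd * cohort_rng.standard_normal(
        scenario.cohort_n
    )
    logic50s = (
        scenario.cohort_logic50_mean
        + scenario.cohort_logic50_sd * cohort_rng.standard_normal(scenario.cohort_n)
    )
    ref = ReferenceCohort(
        compound=scenario.compound,
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)),
        logic50_mean=float(logic50s.mean()),
        logic50_sd=float(logic50s.std(ddof=1)),
        n=scenario.cohort_n,
    )
    return plate, ref
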