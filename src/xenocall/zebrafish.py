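"""Larval zebrafish PDX dosing, response classification and statistics.

Drug response in the larval zebrafish PDX is read from *ex vivo*
fluorescent tumor-cell counts per larva, quantified at 1 day
post-injection (dpi; baseline) and 4 dpi (endpoint).  The baseline
band is the mean +/- SEM of the 1-dpi control counts; a 4-dpi treatment
group whose mean falls below the band is a response (R), above it is
progressive disease (PD), and within it is stable disease (SD).

Dosing uses an immersion dose ladder: the maximum tolerated dose (MTD)
is the highest dose not causing general toxicity or death (with a
monotone-envelope reading of non-monotone toxicity ladders), and the
treating dose is 80 % of the MTD.

Group significance versus the 4-dpi control is assessed with a one-way
ANOVA layer: pooled-variance many-to-one t statistics with Dunnett
family-wise adjustment.  Adjusted p-values come from a seeded Monte
Carlo sample of the null distribution of the maximum absolute statistic
over the Dunnett multivariate-t correlation structure, which handles
unbalanced group sizes directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .calls import ResponseCall

TREATING_DOSE_FRACTION = 0.8  # treating dose = 80 % of the MTD
DUNNETT_MC_DRAWS = 100_000

_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class LarvaGroup:
    """Per-larva fluorescent cell counts for one experimental group."""

    model_id: str
    arm: str
    day: str  # "1dpi" or "4dpi"
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.day not in ("1dpi", "4dpi"):
            raise ValueError("day must be '1dpi' or '4dpi'")
        counts = tuple(int(c) for c in self.counts)
        if any(c != float(orig) for c, orig in zip(counts, self.counts)):
            raise ValueError("counts must be integers")
        object.__setattr__(self, "counts", counts)
        if not counts:
            raise ValueError("counts must be non-empty")
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sem(self) -> float:
        if len(self.counts) < 2:
            raise ValueError("SEM undefined for fewer than 2 larvae")
        return float(np.std(self.counts, ddof=1) / math.sqrt(len(self.counts)))


class BaselineBand(NamedTuple):
    """Mean +/- SEM band of the 1-dpi control counts."""

    mean: float
    sem: float
    low: float
    high: float


@dataclass(frozen=True)
class ToxicityTable:
    """Dose-ladder toxicity outcomes for one drug (n larvae per dose)."""

    drug: str
    doses: tuple[float, ...]
    n_tested: tuple[int, ...]
    n_toxic_or_dead: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.doses) == len(self.n_tested) == len(self.n_toxic_or_dead)):
            raise ValueError("doses and outcomes must have equal length")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly ascending")
        if any(t > n for t, n in zip(self.n_toxic_or_dead, self.n_tested)):
            raise ValueError("n_toxic_or_dead cannot exceed n_tested")


def mtd_and_treating_dose(
    tox: ToxicityTable, tox_threshold_fraction: float = 0.0
) -> tuple[float, float]:
    """Maximum tolerated dose and treating dose (80 % of MTD).

    The MTD is the highest dose whose toxicity fraction is within the
    threshold *and* below which every dose also passes (monotone
    envelope); a tolerated dose above an intolerable one triggers a
    warning and is ignored.
    """
    passes = [
        t / n <= tox_threshold_fraction
        for t, n in zip(tox.n_toxic_or_dead, tox.n_tested)
    ]
    if not passes[0]:
        raise ValueError("no MTD in tested range")
    mtd = tox.doses[0]
    for dose, ok in zip(tox.doses[1:], passes[1:]):
        if not ok:
            break
        mtd = dose
    envelope_len = passes.index(False) if False in passes else len(passes)
    if any(passes[envelope_len:]):
        warnings.warn(
            f"{tox.drug}: non-monotone toxicity ladder; envelope rule applied"
        )
    return mtd, TREATING_DOSE_FRACTION * mtd


def baseline_band(control_1dpi: LarvaGroup) -> BaselineBand:
    """The 1-dpi control mean +/- SEM band used as the response threshold."""
    if len(control_1dpi.counts) < 2:
        raise ValueError("SEM undefined for fewer than 2 larvae")
    mean, sem = control_1dpi.mean, control_1dpi.sem
    return BaselineBand(mean=mean, sem=sem, low=mean - sem, high=mean + sem)


def classify_fish_group(
    treatment_4dpi: LarvaGroup, band: BaselineBand, mode: str = "mean"
) -> ResponseCall:
    """Classify a 4-dpi treatment group against the baseline band.

    ``mode="mean"`` compares the group mean alone: below the band is R,
    above is PD, and band-boundary values classify (inclusively) as SD.
    ``mode="interval"`` compares the group's own mean +/- SEM interval:
    entirely below the band is R, entirely above is PD, overlap is SD.
    """
    if mode not in ("mean", "interval"):
        raise ValueError("mode must be 'mean' or 'interval'")
    mean = treatment_4dpi.mean
    if mode == "mean":
        lo = hi = mean
    else:
        sem = treatment_4dpi.sem if len(treatment_4dpi.counts) > 1 else 0.0
        lo, hi = mean - sem, mean + sem
    if hi < band.low:
        return ResponseCall("zebrafish", "R")
    if lo > band.high:
        return ResponseCall("zebrafish", "PD")
    return ResponseCall("zebrafish", "SD")


class DunnettResult(NamedTuple):
    arm: str
    t_statistic: float
    adjusted_p: float
    unadjusted_p: float
    stars: str


def _stars(p: float) -> str:
    for cutoff, mark in _STAR_LEVELS:
        if p < cutoff:
            return mark
    return "ns"


def dunnett_null_max_abs_t(
    group_sizes: Sequence[int],
    control_size: int,
    n_draws: int = DUNNETT_MC_DRAWS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte Carlo sample of max_i |T_i| under the Dunnett null.

    The many-to-one statistics share the control mean, giving the
    correlation lambda_i * lambda_j with lambda_i = sqrt(n_i/(n_i+n_0));
    each draw builds correlated normals on that structure, divides by a
    common pooled-variance chi factor and takes the max absolute value.
    """
    rng = rng if rng is not None else np.random.default_rng()
    sizes = np.asarray(group_sizes, dtype=float)
    n0 = float(control_size)
    df = n0 + sizes.sum() - (len(sizes) + 1)
    lam = np.sqrt(sizes / (sizes + n0))
    z0 = rng.standard_normal(n_draws)
    e = rng.standard_normal((n_draws, len(sizes)))
    z = lam * z0[:, None] + np.sqrt(1 - lam**2) * e
    chi = np.sqrt(rng.chisquare(df, n_draws) / df)
    return np.max(np.abs(z / chi[:, None]), axis=1)


def dunnett_anova(
    groups: Mapping[str, Sequence[float]],
    control_arm: str,
    alpha: float = 0.05,
    n_draws: int = DUNNETT_MC_DRAWS,
    seed: int = 0,
) -> dict[str, DunnettResult]:
    """One-way ANOVA layer: Dunnett many-to-one comparisons vs the control.

    Returns per-arm pooled-variance t statistics, family-wise adjusted
    p-values (Monte Carlo over the joint null of the maximum absolute
    statistic, seeded for reproducibility) and significance stars at the
    conventional 0.05/0.01/0.001/0.0001 levels.
    """
    if control_arm not in groups:
        raise ValueError(f"control arm {control_arm!r} missing")
    usable: dict[str, np.ndarray] = {}
    for arm, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            warnings.warn(f"arm {arm!r} has <2 observations; excluded")
            continue
        usable[arm] = arr
    if control_arm not in usable:
        raise ValueError("control arm has <2 observations")
    treatment_arms = [a for a in usable if a != control_arm]
    if not treatment_arms:
        raise ValueError("no treatment arm with >=2 observations")

    control = usable[control_arm]
    all_arms = [control_arm] + treatment_arms
    n_total = sum(usable[a].size for a in all_arms)
    df = n_total - len(all_arms)
    pooled_ss = sum(
        float(((usable[a] - usable[a].mean()) ** 2).sum()) for a in all_arms
    )
    s2 = pooled_ss / df
    if s2 == 0:
        # degenerate constant data: no evidence of any difference
        return {
            arm: DunnettResult(arm, 0.0, 1.0, 1.0, "ns") for arm in treatment_arms
        }

    sizes = [usable[a].size for a in treatment_arms]
    t_stats = {
        arm: float(
            (usable[arm].mean() - control.mean())
            / math.sqrt(s2 * (1 / usable[arm].size + 1 / control.size))
        )
        for arm in treatment_arms
    }
    null_max = dunnett_null_max_abs_t(
        sizes, control.size, n_draws=n_draws, rng=np.random.default_rng(seed)
    )
    out: dict[str, DunnettResult] = {}
    for arm in treatment_arms:
        t = t_stats[arm]
        p_adj = float(np.mean(null_max >= abs(t)))
        p_unadj = float(2 * stats.t.sf(abs(t), df))
        out[arm] = DunnettResult(arm, t, p_adj, p_unadj, _stars(p_adj))
    return out


def dunnett_critical_value(
    group_sizes: Sequence[int],
    control_size: int,
    alpha: float = 0.05,
    n_draws: int = DUNNETT_MC_DRAWS,
    seed: int = 0,
) -> float:
    """Two-sided Dunnett critical value for max_i |T_i| at level ``alpha``."""
    null_max = dunnett_null_max_abs_t(
        group_sizes, control_size, n_draws=n_draws, rng=np.random.default_rng(seed)
    )
    return float(np.quantile(null_max, 1 - alpha))
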