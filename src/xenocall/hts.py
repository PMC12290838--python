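"""High-throughput dose-response screening: 4PL fits, IC50, AUC, z-score hits.

Viability plates use a 5-point, 10-fold dilution ladder (0.5-5,000
nmol/L) in duplicate.  Mean viability versus log10 concentration is fit
with a four-parameter logistic (4PL)

    v(x) = bottom + (top - bottom) / (1 + 10^(hill * (x - log10 EC50)))

by bounded least squares with multi-start initialization over the EC50
decade grid.  The IC50 is the *absolute* concentration at 50 % survival
(solved from the fitted curve, censored at the ladder boundary when the
curve never crosses 0.5), not the relative EC50.  The AUC is the
trapezoidal area of viability over the log10 ladder span, normalized to
[0, 1] (1 = fully viable everywhere).

A compound is a sensitivity hit when both the AUC z-score and the log10
IC50 z-score against a per-compound reference cohort are <= -2
(inclusive); an "either" rule is available as configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

DEFAULT_LADDER_NMOL = (0.5, 5.0, 50.0, 500.0, 5000.0)
HIT_Z_CUTOFF = -2.0


@dataclass(frozen=True)
class DoseResponsePlate:
    """Replicate viability fractions at each ladder concentration."""

    sample_id: str
    compound: str
    concentrations_nmol: tuple[float, ...]
    viability: tuple[tuple[float, ...], ...]  # replicates per concentration

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations_nmol)
        via = tuple(tuple(float(v) for v in reps) for reps in self.viability)
        object.__setattr__(self, "concentrations_nmol", conc)
        object.__setattr__(self, "viability", via)
        if len(set(conc)) < 4:
            raise ValueError("need >=4 distinct concentrations")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly ascending")
        if any(c <= 0 for c in conc):
            raise ValueError("concentrations must be positive")
        if len(via) != len(conc):
            raise ValueError("one replicate tuple per concentration required")
        if any(not reps for reps in via):
            raise ValueError("each concentration needs >=1 replicate")
        flat = [v for reps in via for v in reps]
        if any(not math.isfinite(v) or v < 0 for v in flat):
            raise ValueError("viability values must be finite and >=0")

    @property
    def mean_viability(self) -> np.ndarray:
        return np.array([float(np.mean(reps)) for reps in self.viability])


class CurveFit(NamedTuple):
    top: float
    bottom: float
    hill: float
    ec50_nmol: float
    rss: float
    converged: bool


class ReferenceCohort(NamedTuple):
    """Per-compound cohort summary used for z-score hit calling."""

    compound: str
    auc_mean: float
    auc_sd: float
    logic50_mean: float
    logic50_sd: float
    n: int


def four_pl(x: np.ndarray, top: float, bottom: float, hill: float, log_ec50: float):
    """4PL viability at log10 concentration ``x`` (decreasing for hill > 0)."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log_ec50)))


def fit_dose_response(plate: DoseResponsePlate) -> CurveFit:
    """Least-squares 4PL fit of mean viability vs log10 concentration.

    EC50 is bounded to the ladder span +/- 2 decades; initialization is
    multi-start over a decade grid of EC50 guesses.  ``converged`` is
    false when the optimizer fails or when the 4PL does not improve
    meaningfully on a flat (constant) model.
    """
    x = np.log10(np.asarray(plate.concentrations_nmol))
    y = plate.mean_viability
    lo_ec, hi_ec = x.min() - 2.0, x.max() + 2.0
    y_lo, y_hi = float(y.min()), float(y.max())
    bounds = (
        [y_hi - 0.05, y_lo - 0.55, 0.05, lo_ec],
        [y_hi + 0.55, y_lo + 0.05, 5.0, hi_ec],
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return four_pl(x, *theta) - y

    best = None
    for guess_ec in np.arange(math.floor(lo_ec), math.ceil(hi_ec) + 1.0):
        theta0 = np.clip(
            [y_hi, y_lo, 1.0, guess_ec],
            bounds[0],
            bounds[1],
        )
        try:
            res = least_squares(residuals, theta0, bounds=bounds)
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return CurveFit(y_hi, y_lo, 1.0, 10 ** float(x.mean()), float("inf"), False)

    top, bottom, hill, log_ec50 = best.x
    rss = float(2 * best.cost)
    flat_rss = float(((y - y.mean()) ** 2).sum())
    # degenerate/flat data: the sigmoid adds nothing over a constant
    converged = flat_rss < 1e-12 * max(1.0, y.mean() ** 2) or rss < 0.999 * flat_rss
    if flat_rss < 1e-12 * max(1.0, y.mean() ** 2):
        # hill pinned: any slope fits constant data equally well
        hill = 1.0
        converged = False
    return CurveFit(
        float(top), float(bottom), float(hill), float(10**log_ec50), rss, converged
    )


def ic50_from_fit(
    fit: CurveFit, ladder: Sequence[float] = DEFAULT_LADDER_NMOL
) -> tuple[float | None, bool]:
    """Absolute IC50 (concentration at 50 % survival) from a 4PL fit.

    Returns ``(ic50_nmol, censored)``.  When the fitted curve never
    crosses 0.5 within [min ladder / 10, max ladder * 10] the IC50 is
    censored at the ladder maximum: ``(max ladder, True)``.
    """
    cmax = float(max(ladder))
    if not fit.converged:
        warnings.warn("IC50 from a non-converged fit; censoring at ladder max")
        return cmax, True
    top, bottom, hill = fit.top, fit.bottom, fit.hill
    # solve bottom + (top-bottom)/(1+10^(h*(x-x0))) = 0.5
    if not (bottom < 0.5 < top) or hill <= 0:
        return cmax, True
    ratio = (top - 0.5) / (0.5 - bottom)
    ic50 = fit.ec50_nmol * ratio ** (1.0 / hill)
    if not (min(ladder) / 10.0 <= ic50 <= cmax * 10.0):
        return cmax, True
    return float(ic50), False


def auc_dose_response(
    source: DoseResponsePlate | CurveFit,
    ladder: Sequence[float] = DEFAULT_LADDER_NMOL,
    n_grid: int = 101,
) -> float:
    """Normalized trapezoidal AUC of viability over the log10 ladder span.

    A plate integrates the observed mean viabilities at the ladder
    points; a fit integrates the fitted curve on a fine grid over the
    same span.  1 = fully viable everywhere, 0 = fully dead everywhere.
    """
    if isinstance(source, DoseResponsePlate):
        x = np.log10(np.asarray(source.concentrations_nmol))
        y = source.mean_viability
    else:
        x = np.linspace(math.log10(min(ladder)), math.log10(max(ladder)), n_grid)
        y = four_pl(
            x, source.top, source.bottom, source.hill, math.log10(source.ec50_nmol)
        )
    if len(x) < 2:
        raise ValueError("AUC needs >=2 concentrations")
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


class HitCall(NamedTuple):
    z_auc: float
    z_ic50: float
    hit: bool
    ic50_censored: bool


def zscore_hit(
    auc: float,
    ic50_nmol: float,
    ref: ReferenceCohort,
    rule: str = "both",
    ic50_censored: bool = False,
) -> HitCall:
    """Sensitivity hit call against a reference cohort.

    ``z_auc`` uses the raw AUC; ``z_ic50`` uses log10 IC50 (IC50s span
    decades).  A censored IC50 is scored at its censoring bound and the
    flag propagated.  The default rule requires *both* z-scores <= -2
    (inclusive); ``rule="either"`` accepts one.
    """
    if rule not in ("both", "either"):
        raise ValueError("rule must be 'both' or 'either'")
    if ref.auc_sd <= 0 or ref.logic50_sd <= 0:
        raise ValueError("reference cohort standard deviations must be positive")
    z_auc = (auc - ref.auc_mean) / ref.auc_sd
    z_ic50 = (math.log10(ic50_nmol) - ref.logic50_mean) / ref.logic50_sd
    flags = (z_auc <= HIT_Z_CUTOFF, z_ic50 <= HIT_Z_CUTOFF)
    hit = all(flags) if rule == "both" else any(flags)
    return HitCall(float(z_auc), float(z_ic50), bool(hit), ic50_censored)
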