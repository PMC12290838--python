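"""Patient objective-response classification (RECIST / PERCIST).

Clinical responses are read off serial imaging: RECIST works on the sum of
target-lesion diameters, PERCIST on a scalar standardized uptake value
(SUV).  Both use strict percent-change thresholds against an explicit
reference:

* RECIST — CR: disappearance of all lesions (sum 0); PR: decrease > 30 %
  versus the baseline sum; PD: increase > 20 % versus the smallest sum on
  study, or any new lesion; SD otherwise.  SD additionally requires a
  qualifying scan at least 6 weeks after treatment start, and CR/PR are
  confirmed on a follow-up scan.
* PERCIST — CR: uptake indistinguishable from background and below liver;
  PR: SUV decrease > 30 % versus baseline; PD: SUV increase > 30 % or a new
  lesion; SD otherwise.

The best overall response is the best category achieved before the first
progression.  All thresholds are strict inequalities: a change of exactly
30 % (or 20 %) never upgrades (or downgrades) a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .calls import PATIENT_ORDER, ResponseCall


class LesionScan(NamedTuple):
    week: float
    sum_diameters_mm: float
    new_lesion: bool = False


class SuvScan(NamedTuple):
    week: float
    suv: float
    indistinguishable_from_background: bool = False
    less_than_liver: bool = False
    new_lesion: bool = False


def _check_weeks(weeks: Sequence[float]) -> None:
    if not weeks or weeks[0] != 0:
        raise ValueError("first scan must be the baseline at week 0")
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError("scan weeks must be strictly ascending")


@dataclass(frozen=True)
class LesionCourse:
    """Serial sum-of-diameters measurements for one patient treatment."""

    patient_id: str
    treatment_id: str
    scans: tuple[LesionScan, ...]

    def __post_init__(self) -> None:
        scans = tuple(LesionScan(*s) for s in self.scans)
        object.__setattr__(self, "scans", scans)
        _check_weeks([s.week for s in scans])
        if any(s.sum_diameters_mm < 0 for s in scans):
            raise ValueError("sum of diameters must be non-negative")


@dataclass(frozen=True)
class SuvCourse:
    """Serial SUV measurements for one patient treatment."""

    patient_id: str
    treatment_id: str
    scans: tuple[SuvScan, ...]

    def __post_init__(self) -> None:
        scans = tuple(SuvScan(*s) for s in self.scans)
        object.__setattr__(self, "scans", scans)
        _check_weeks([s.week for s in scans])
        if any(s.suv < 0 for s in scans):
            raise ValueError("SUV must be non-negative")


def _best(categories: Sequence[str]) -> str:
    return max(categories, key=PATIENT_ORDER.index)


def classify_recist(
    course: LesionCourse,
    require_confirmation: bool = True,
    sd_min_weeks: float = 6.0,
) -> ResponseCall:
    """Best overall RECIST response for a lesion-diameter course.

    Parameters
    ----------
    course:
        Baseline scan (week 0) plus at least one follow-up.
    require_confirmation:
        When true, a CR or PR must recur on a subsequent scan; otherwise it
        is downgraded to the best confirmed category with qualifier
        ``"unconfirmed"``.
    sd_min_weeks:
        Minimum week of a qualifying non-PD scan for SD; a course whose
        only non-PD scans precede this interval is flagged
        ``"not evaluable"``.
    """
    scans = course.scans
    if len(scans) < 2:
        raise ValueError("no follow-up: RECIST needs baseline plus >=1 scan")
    baseline = scans[0].sum_diameters_mm
    if baseline <= 0:
        raise ValueError("baseline sum of diameters must be positive")

    # per-scan category, referencing baseline (PR) and the running smallest
    # sum on study including baseline (PD)
    per_scan: list[tuple[float, str]] = []  # (week, category) up to first PD
    nadir = baseline
    progressed = False
    for scan in scans[1:]:
        if scan.new_lesion:
            per_scan.append((scan.week, "PD"))
            progressed = True
            break
        if nadir > 0 and (scan.sum_diameters_mm - nadir) / nadir * 100 > 20:
            per_scan.append((scan.week, "PD"))
            progressed = True
            break
        if scan.sum_diameters_mm == 0:
            cat = "CR"
        elif (baseline - scan.sum_diameters_mm) / baseline * 100 > 30:
            cat = "PR"
        else:
            cat = "SD"
        per_scan.append((scan.week, cat))
        nadir = min(nadir, scan.sum_diameters_mm)

    pre_pd = [(w, c) for w, c in per_scan if c != "PD"]
    if not pre_pd:
        return ResponseCall("patient", "PD")

    best = _best([c for _, c in pre_pd])
    qualifier = None
    if best in ("CR", "PR") and require_confirmation:
        confirmed = _is_confirmed(pre_pd, best)
        if not confirmed:
            qualifier = "unconfirmed"
            # downgrade to the best confirmed category
            if best == "CR" and _is_confirmed(pre_pd, "PR"):
                best = "PR"
            else:
                best = "SD"

    if best == "SD":
        if any(w >= sd_min_weeks for w, c in pre_pd):
            return ResponseCall("patient", "SD", qualifier=qualifier)
        if progressed:
            return ResponseCall("patient", "PD", qualifier=qualifier)
        return ResponseCall("patient", "SD", qualifier="not evaluable")
    return ResponseCall("patient", best, qualifier=qualifier)


def _is_confirmed(pre_pd: Sequence[tuple[float, str]], category: str) -> bool:
    """True when ``category`` (or better) is met on two scans."""
    rank = PATIENT_ORDER.index
    hits = [i for i, (_, c) in enumerate(pre_pd) if rank(c) >= rank(category)]
    return len(hits) >= 2


def classify_percist(course: SuvCourse) -> ResponseCall:
    """Best overall PERCIST response for an SUV course."""
    scans = course.scans
    if len(scans) < 2:
        raise ValueError("no follow-up: PERCIST needs baseline plus >=1 scan")
    baseline = scans[0].suv
    if baseline == 0 and any(s.suv > 0 for s in scans[1:]):
        raise ValueError("zero baseline SUV with nonzero follow-up")

    per_scan: list[str] = []
    for scan in scans[1:]:
        if scan.new_lesion:
            per_scan.append("PD")
            break
        if scan.indistinguishable_from_background and scan.less_than_liver:
            per_scan.append("CR")
            continue
        change = 0.0 if baseline == 0 else (scan.suv - baseline) / baseline * 100
        if change > 30:
            per_scan.append("PD")
            break
        per_scan.append("PR" if change < -30 else "SD")

    pre_pd = [c for c in per_scan if c != "PD"]
    if not pre_pd:
        return ResponseCall("patient", "PD")
    return ResponseCall("patient", _best(pre_pd))
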