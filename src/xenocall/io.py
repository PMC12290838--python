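"""Table schemas, validated CSV IO, run configuration and the pipeline driver.

All inputs are plain CSV (comma-separated, UTF-8, header row required);
categories are uppercase tokens and days/weeks decimal numbers.  Readers
validate the header against the schema and collect row-level conversion
errors with their line numbers before failing, so a malformed table is
reported in one pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import concordance as conc
from . import hts as hts_mod
from . import mouse as mouse_mod
from . import patient as patient_mod
from . import zebrafish as fish_mod

log = logging.getLogger("xenocall")


class SchemaError(ValueError):
    """Header-level problem: missing column or unreadable file."""


class RowError(ValueError):
    """Row-level problems, each tagged with its 1-based CSV line number."""


def _bool(value) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no", "", "nan"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _nonneg(value) -> float:
    x = float(value)
    if x < 0:
        raise ValueError(f"negative value: {value!r}")
    return x


TABLE_SCHEMAS: dict[str, dict[str, Callable]] = {
    "patients.csv": {
        "patient_id": str,
        "treatment_id": str,
        "modality": str,
        "week": _nonneg,
        "value": _nonneg,
        "background_flag": _bool,
        "liver_flag": _bool,
        "new_lesion": _bool,
    },
    "mouse_volumes.csv": {
        "model_id": str,
        "arm": str,
        "mouse_id": str,
        "day": _nonneg,
        "volume_mm3": _nonneg,
    },
    "mouse_arms.csv": {
        "arm": str,
        "treatment_start_day": float,
        "treatment_end_day": float,
        "study_end_day": float,
    },
    "fish_counts.csv": {
        "model_id": str,
        "arm": str,
        "day": str,
        "larva_id": str,
        "cell_count": _nonneg,
    },
    "toxicity.csv": {
        "drug": str,
        "dose": float,
        "n_tested": int,
        "n_toxic": int,
    },
    "hts_plate.csv": {
        "sample_id": str,
        "compound": str,
        "concentration_nmol": float,
        "replicate": int,
        "viability": _nonneg,
    },
    "hts_reference.csv": {
        "compound": str,
        "auc_mean": float,
        "auc_sd": float,
        "logic50_mean": float,
        "logic50_sd": float,
        "n": int,
    },
    "calls.csv": {
        "sample_id": str,
        "treatment_id": str,
        "system": str,
        "category": str,
        "evaluable": _bool,
    },
}


def read_table(path: str | Path, schema: Mapping[str, Callable]) -> pd.DataFrame:
    """Read and validate one CSV against ``schema`` (column -> converter).

    Raises :class:`SchemaError` for missing columns and :class:`RowError`
    listing every failing cell with its line number.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise SchemaError(f"{path}: file not found") from None
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: unreadable ({exc})") from None
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")

    out: dict[str, list] = {c: [] for c in schema}
    errors: list[str] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # header is line 1
        for col in schema:
            value = getattr(row, col.replace(".", "_"), None)
            if value is None:
                value = raw.iloc[i][col]
            try:
                out[col].append(schema[col](value))
            except (TypeError, ValueError) as exc:
                errors.append(f"{path.name}:{line}: column {col}: {exc}")
                out[col].append(None)
    if errors:
        raise RowError("; ".join(errors))
    return pd.DataFrame(out)


def read_tables(
    directory: str | Path, names: Sequence[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Read every known (or requested) table present in ``directory``."""
    directory = Path(directory)
    names = list(names) if names is not None else list(TABLE_SCHEMAS)
    tables = {}
    for name in names:
        path = directory / name
        if path.exists():
            tables[name] = read_table(path, TABLE_SCHEMAS[name])
    return tables


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Pipeline configuration; every classifier constant is overridable."""

    seed: int = 0
    input_dir: str = "."
    output_dir: str = "out"
    # patient
    require_confirmation: bool = True
    sd_min_weeks: float = 6.0
    # mouse
    measurable_cutoff_mm3: float = mouse_mod.MEASURABLE_CUTOFF_MM3
    mcr_window_days: float = mouse_mod.MCR_WINDOW_DAYS
    # zebrafish
    fish_mode: str = "mean"
    tox_threshold_fraction: float = 0.0
    dunnett_draws: int = fish_mod.DUNNETT_MC_DRAWS
    # hts
    hts_hit_rule: str = "both"
    control_arm: str = "control"

    def __post_init__(self) -> None:
        if self.fish_mode not in ("mean", "interval"):
            raise ValueError("fish_mode must be 'mean' or 'interval'")
        if self.hts_hit_rule not in ("both", "either"):
            raise ValueError("hts_hit_rule must be 'both' or 'either'")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _classify_patients(df: pd.DataFrame, config: RunConfig) -> list[dict]:
    results = []
    for (pid, tid, modality), grp in df.groupby(
        ["patient_id", "treatment_id", "modality"], sort=True
    ):
        grp = grp.sort_values("week")
        if modality.upper() == "RECIST":
            course = patient_mod.LesionCourse(
                pid,
                tid,
                tuple(
                    (w, v, n)
                    for w, v, n in zip(grp["week"], grp["value"], grp["new_lesion"])
                ),
            )
            call = patient_mod.classify_recist(
                course, config.require_confirmation, config.sd_min_weeks
            )
        elif modality.upper() == "PERCIST":
            course = patient_mod.SuvCourse(
                pid,
                tid,
                tuple(
                    (w, v, b, l, n)
                    for w, v, b, l, n in zip(
                        grp["week"],
                        grp["value"],
                        grp["background_flag"],
                        grp["liver_flag"],
                        grp["new_lesion"],
                    )
                ),
            )
            call = patient_mod.classify_percist(course)
        else:
            raise ValueError(f"unknown modality {modality!r}")
        log.info("patient %s/%s: %s", pid, tid, call.category)
        results.append(
            {
                "sample_id": pid,
                "treatment_id": tid,
                "system": "patient",
                "category": call.category,
                "harmonized": call.harmonized,
                "qualifier": call.qualifier,
            }
        )
    return results


def _classify_mice(
    volumes: pd.DataFrame, arms: pd.DataFrame, config: RunConfig
) -> tuple[list[dict], dict]:
    windows = {
        r.arm: (r.treatment_start_day, r.treatment_end_day, r.study_end_day)
        for r in arms.itertuples()
    }
    calls_out, details = [], {}
    for (model, arm), grp in volumes.groupby(["model_id", "arm"], sort=True):
        if arm not in windows:
            raise ValueError(f"arm {arm!r} missing from mouse_arms.csv")
        t0, t1, t2 = windows[arm]
        mouse_calls, records = [], []
        for mouse_id, m in grp.groupby("mouse_id", sort=True):
            m = m.sort_values("day")
            series = mouse_mod.TumorVolumeSeries(
                mouse_id,
                model,
                arm,
                tuple(zip(m["day"], m["volume_mm3"])),
                treatment_start_day=t0,
                treatment_end_day=t1,
                study_end_day=t2,
            )
            mouse_calls.append(
                mouse_mod.classify_mouse_trajectory(
                    series, config.measurable_cutoff_mm3, config.mcr_window_days
                )
            )
            records.append(mouse_mod.event_time_quadrupling(series))
        group_call = mouse_mod.group_objective_response(mouse_calls)
        log.info("mouse %s/%s: %s", model, arm, group_call.category)
        calls_out.append(
            {
                "sample_id": model,
                "treatment_id": arm,
                "system": "mouse",
                "category": group_call.category,
                "harmonized": group_call.harmonized,
                "qualifier": None,
            }
        )
        details[f"{model}/{arm}"] = {
            "per_mouse": sorted(c.category for c in mouse_calls),
            "events": [
                {"mouse_id": r.mouse_id, "time_days": r.time_days, "event": r.event}
                for r in records
            ],
        }
    # log-rank of every arm against the control arm, per model
    for model, grp in volumes.groupby("model_id", sort=True):
        arms_here = sorted(grp["arm"].unique())
        if config.control_arm not in arms_here:
            continue
        recs = {
            key.split("/", 1)[1]: det["events"]
            for key, det in details.items()
            if key.startswith(f"{model}/")
        }
        ctrl = [
            mouse_mod.SurvivalRecord(e["mouse_id"], e["time_days"], e["event"])
            for e in recs[config.control_arm]
        ]
        for arm in arms_here:
            if arm == config.control_arm:
                continue
            trt = [
                mouse_mod.SurvivalRecord(e["mouse_id"], e["time_days"], e["event"])
                for e in recs[arm]
            ]
            stat, p = mouse_mod.logrank_test(trt, ctrl)
            details[f"{model}/{arm}"]["logrank_vs_control"] = {
                "statistic": stat,
                "p_value": p,
            }
    return calls_out, details


def _classify_fish(df: pd.DataFrame, config: RunConfig) -> tuple[list[dict], dict]:
    calls_out, details = [], {}
    for model, grp in df.groupby("model_id", sort=True):
        groups = {
            (arm, day): fish_mod.LarvaGroup(
                model, arm, day, tuple(int(c) for c in sub["cell_count"])
            )
            for (arm, day), sub in grp.groupby(["arm", "day"], sort=True)
        }
        key_1dpi = (config.control_arm, "1dpi")
        if key_1dpi not in groups:
            raise ValueError(f"model {model!r}: no {config.control_arm} 1dpi group")
        band = fish_mod.baseline_band(groups[key_1dpi])
        arm_counts = {
            arm: list(g.counts) for (arm, day), g in groups.items() if day == "4dpi"
        }
        stats = (
            fish_mod.dunnett_anova(
                arm_counts,
                config.control_arm,
                n_draws=config.dunnett_draws,
                seed=config.seed,
            )
            if config.control_arm in arm_counts and len(arm_counts) > 1
            else {}
        )
        for (arm, day), group in sorted(groups.items()):
            if day != "4dpi" or arm == config.control_arm:
                continue
            call = fish_mod.classify_fish_group(group, band, config.fish_mode)
            log.info("zebrafish %s/%s: %s", model, arm, call.category)
            calls_out.append(
                {
                    "sample_id": model,
                    "treatment_id": arm,
                    "system": "zebrafish",
                    "category": call.category,
                    "harmonized": call.harmonized,
                    "qualifier": None,
                }
            )
            entry = {
                "group_mean": group.mean,
                "group_sem": group.sem if len(group.counts) > 1 else 0.0,
                "band": list(band),
            }
            if arm in stats:
                entry["dunnett"] = {
                    "t": stats[arm].t_statistic,
                    "adjusted_p": stats[arm].adjusted_p,
                    "stars": stats[arm].stars,
                }
            details[f"{model}/{arm}"] = entry
    return calls_out, details


def _run_hts(plates: pd.DataFrame, reference: pd.DataFrame, config: RunConfig) -> dict:
    refs = {
        r.compound: hts_mod.ReferenceCohort(
            r.compound, r.auc_mean, r.auc_sd, r.logic50_mean, r.logic50_sd, r.n
        )
        for r in reference.itertuples()
    }
    out = {}
    for (sample, compound), grp in plates.groupby(["sample_id", "compound"], sort=True):
        conc_groups = sorted(grp["concentration_nmol"].unique())
        viability = tuple(
            tuple(grp.loc[grp["concentration_nmol"] == c, "viability"])
            for c in conc_groups
        )
        plate = hts_mod.DoseResponsePlate(sample, compound, tuple(conc_groups), viability)
        fit = hts_mod.fit_dose_response(plate)
        ic50, censored = hts_mod.ic50_from_fit(fit, plate.concentrations_nmol)
        auc = hts_mod.auc_dose_response(fit, plate.concentrations_nmol)
        entry = {
            "ec50_nmol": fit.ec50_nmol,
            "ic50_nmol": ic50,
            "ic50_censored": censored,
            "auc": auc,
            "converged": fit.converged,
        }
        if compound in refs:
            hit = hts_mod.zscore_hit(
                auc, ic50, refs[compound], config.hts_hit_rule, censored
            )
            entry.update(
                {"z_auc": hit.z_auc, "z_ic50": hit.z_ic50, "hit": hit.hit}
            )
        out[f"{sample}/{compound}"] = entry
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Classify every input table, harmonize, and compute concordance.

    Writes ``report.json``, ``calls.csv`` and ``concordance_matrix.csv``
    to ``config.output_dir`` and returns the report dict.  Identical
    config and inputs produce an identical report.
    """
    tables = read_tables(config.input_dir)
    if not tables:
        raise SchemaError(
            "empty input directory: expected at least one of "
            + ", ".join(TABLE_SCHEMAS)
        )
    report: dict = {"config": asdict(config)}
    calls: list[dict] = []

    if "patients.csv" in tables:
        calls.extend(_classify_patients(tables["patients.csv"], config))
    if "mouse_volumes.csv" in tables:
        if "mouse_arms.csv" not in tables:
            raise SchemaError("mouse_volumes.csv present but mouse_arms.csv missing")
        mouse_calls, mouse_details = _classify_mice(
            tables["mouse_volumes.csv"], tables["mouse_arms.csv"], config
        )
        calls.extend(mouse_calls)
        report["mouse"] = mouse_details
    if "fish_counts.csv" in tables:
        fish_calls, fish_details = _classify_fish(tables["fish_counts.csv"], config)
        calls.extend(fish_calls)
        report["zebrafish"] = fish_details
    if "toxicity.csv" in tables:
        tox_out = {}
        for drug, grp in tables["toxicity.csv"].groupby("drug", sort=True):
            grp = grp.sort_values("dose")
            tox = fish_mod.ToxicityTable(
                drug,
                tuple(grp["dose"]),
                tuple(grp["n_tested"]),
                tuple(grp["n_toxic"]),
            )
            mtd, dose = fish_mod.mtd_and_treating_dose(
                tox, config.tox_threshold_fraction
            )
            tox_out[drug] = {"mtd": mtd, "treating_dose": dose}
        report["toxicity"] = tox_out
    if "hts_plate.csv" in tables:
        ref = tables.get(
            "hts_reference.csv",
            pd.DataFrame(columns=list(TABLE_SCHEMAS["hts_reference.csv"])),
        )
        report["hts"] = _run_hts(tables["hts_plate.csv"], ref, config)
    if "calls.csv" in tables:
        for r in tables["calls.csv"].itertuples():
            calls.append(
                {
                    "sample_id": r.sample_id,
                    "treatment_id": r.treatment_id,
                    "system": r.system,
                    "category": r.category,
                    "harmonized": conc.harmonize_category(r.category)
                    if r.evaluable
                    else "NT",
                    "qualifier": None,
                    "evaluable": bool(r.evaluable),
                }
            )

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if calls:
        records = [
            (
                c["sample_id"],
                c["treatment_id"],
                c["system"],
                c["category"],
                c.get("evaluable", True),
            )
            for c in calls
        ]
        table = conc.ConcordanceTable.from_records(records)
        matrix, summary = conc.concordance_matrix(table)
        matrix.to_csv(out_dir / "concordance_matrix.csv")
        report["concordance"] = {
            pair: {
                "n_agree": s.n_agree,
                "n_total": s.n_total,
                "fraction": s.fraction,
            }
            for pair, s in summary.items()
        }
        write_table(
            pd.DataFrame(calls).sort_values(
                ["sample_id", "treatment_id", "system"]
            ),
            out_dir / "calls.csv",
        )
    report["calls"] = sorted(
        calls, key=lambda c: (c["sample_id"], c["treatment_id"], c["system"])
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
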