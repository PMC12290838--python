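"""Cross-model harmonization and agreement (concordance) analysis.

Patient, mouse-PDX and zebrafish-PDX calls for the same sample and
treatment are projected onto the common three-level scale {R, SD, PD}
(maintained CR, CR and PR all count as R) and compared cell by cell:
two systems agree on a (sample, treatment) pair when their harmonized
categories match exactly.  Cells marked NT (not treated/tested, i.e.
non-evaluable) are excluded from agreement denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .calls import SYSTEMS, ResponseCall, harmonize_category


def harmonize(call: ResponseCall) -> str:
    """Project a system-specific call onto {R, SD, PD}."""
    return harmonize_category(call.category)


class TableRow(NamedTuple):
    sample_id: str
    treatment_id: str
    system: str
    category: str
    harmonized: str
    evaluable: bool


@dataclass(frozen=True)
class ConcordanceTable:
    """The sample x treatment x system grid of harmonized calls."""

    rows: tuple[TableRow, ...]

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            if row.system not in SYSTEMS:
                raise ValueError(f"unknown system {row.system!r}")
            key = (row.sample_id, row.treatment_id, row.system)
            if key in seen:
                raise ValueError(f"duplicate row for {key}")
            seen.add(key)
            if row.evaluable and row.harmonized != harmonize_category(row.category):
                raise ValueError(
                    f"harmonized value inconsistent with category in {key}"
                )

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple],
    ) -> "ConcordanceTable":
        """Build from (sample_id, treatment_id, system, category, evaluable)
        tuples; the harmonized column is derived."""
        rows = []
        for sample_id, treatment_id, system, category, evaluable in records:
            harmonized = harmonize_category(category) if evaluable else "NT"
            rows.append(
                TableRow(
                    str(sample_id),
                    str(treatment_id),
                    str(system),
                    str(category),
                    harmonized,
                    bool(evaluable),
                )
            )
        return cls(tuple(rows))


class PairwiseConcordance(NamedTuple):
    n_agree: int
    n_total: int
    fraction: float | None  # None when no evaluable overlap


def pairwise_concordance(
    table: ConcordanceTable, system_a: str, system_b: str
) -> PairwiseConcordance:
    """Exact-match agreement between two systems over their shared
    evaluable (sample, treatment) pairs."""
    calls_a = {
        (r.sample_id, r.treatment_id): r.harmonized
        for r in table.rows
        if r.system == system_a and r.evaluable
    }
    calls_b = {
        (r.sample_id, r.treatment_id): r.harmonized
        for r in table.rows
        if r.system == system_b and r.evaluable
    }
    shared = sorted(set(calls_a) & set(calls_b))
    n_total = len(shared)
    n_agree = sum(calls_a[k] == calls_b[k] for k in shared)
    fraction = n_agree / n_total if n_total else None
    return PairwiseConcordance(n_agree, n_total, fraction)


def concordance_matrix(
    table: ConcordanceTable,
) -> tuple[pd.DataFrame, dict[str, PairwiseConcordance]]:
    """Harmonized-call matrix (rows: sample x treatment; columns: systems,
    NT rendered explicitly) plus the three pairwise agreement summaries."""
    keys = sorted({(r.sample_id, r.treatment_id) for r in table.rows})
    index = pd.MultiIndex.from_tuples(keys, names=["sample_id", "treatment_id"])
    matrix = pd.DataFrame("NT", index=index, columns=list(SYSTEMS))
    for r in table.rows:
        matrix.loc[(r.sample_id, r.treatment_id), r.system] = (
            r.harmonized if r.evaluable else "NT"
        )
    summary = {
        f"{a}_vs_{b}": pairwise_concordance(table, a, b)
        for a, b in (
            ("patient", "zebrafish"),
            ("patient", "mouse"),
            ("zebrafish", "mouse"),
        )
    }
    return matrix, summary
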