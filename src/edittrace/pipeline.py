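"""End-to-end convenience driver: simulated (or loaded) cohort -> summaries.

Thin orchestration over the module-level functions; exists so scripts and
closed-loop analyses run the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .edit_calling import AmpliconCaller, EditCallConfig, calls_table
from .inheritance import inheritance_table, match_generations, summarize
from .synthetic_data import SimulatedStudy


@dataclass
class CohortResult:
    calls: pd.DataFrame
    removed_switches: list  # (read_id, donor_locus, matched_locus)
    unassigned: list  # (read_id, reason)
    records: list
    summary: dict


def call_cohort(
    reads: pd.DataFrame,
    samples: pd.DataFrame,
    assays: list,
    config: EditCallConfig | None = None,
):
    """Assign, filter and call every plant's reads.

    -> (calls table, removed template-switch reads, unassigned reads).
    """
    caller = AmpliconCaller(assays, config)
    generation = dict(zip(samples["plant_id"], samples["generation"]))
    per_plant: dict[str, dict] = {}
    removed_all: list = []
    unassigned_all: list = []
    for plant_id, grp in reads.groupby("plant_id", sort=False):
        calls, removed, unassigned = caller.call_plant(
            list(zip(grp["read_id"], grp["sequence"])), generation[plant_id]
        )
        per_plant[plant_id] = calls
        removed_all += [(rid, donor, matched) for rid, _read, donor, matched in removed]
        unassigned_all += unassigned
    return calls_table(per_plant), removed_all, unassigned_all


def analyze_study(study: SimulatedStudy, config: EditCallConfig | None = None) -> CohortResult:
    """Run the full analysis on a simulated study and summarize it."""
    calls, removed, unassigned = call_cohort(
        study.reads, study.samples, study.assays, config
    )
    records = match_generations(calls, study.samples)
    summary = summarize(calls, study.samples, study.guide_loci, records)
    return CohortResult(calls, removed, unassigned, records, summary)


__all__ = ["CohortResult", "call_cohort", "analyze_study", "inheritance_table"]
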