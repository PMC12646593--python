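#!/usr/bin/env python
"""Run the staged triage over the synthetic nominee pool.

Applies the three selection stages with default thresholds (D_aw <= 1e-4,
log D_lip/w <= 4, purity >= 98%, cost <= 1,000 EUR, availability/safety
flags, per-group mechanism-diversity caps) and reports stage-wise attrition.
Writes results/triage_stage_counts.csv and the full audit report to
scratch/triage_audit.json.

The synthetic pool carries milder exclusion rates than a real nomination
campaign (its marginals are calibrated, not its pathologies), so stage-wise
attrition is reported as a qualitative readout, not matched to any
particular campaign.
"""

import warnings
from pathlib import Path

import pandas as pd

from toxtriage.errors import MissingInputError
from toxtriage.io import read_chemical_table, write_audit_report
from toxtriage.partitioning import PartitionConfig, partition_record
from toxtriage.triage import TriageConfig, run_triage

ROOT = Path(__file__).resolve().parents[1]


def main():
    records = read_chemical_table(ROOT / "scratch" / "pool.csv")
    pcfg = PartitionConfig()
    partitions = {}
    for rec in records:
        try:
            partitions[rec.identifier] = partition_record(
                rec.log_kow, rec.ionization, rec.log_kaw, config=pcfg
            )
        except MissingInputError:
            pass

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_triage(records, partitions, TriageConfig())

    rows = []
    for stage, c in result.stage_counts.items():
        excl = c["in"] - c["retained"]
        rows.append(
            {
                "stage": stage,
                "in": c["in"],
                "retained": c["retained"],
                "excluded": excl,
                "excluded_pct": 100.0 * excl / c["in"] if c["in"] else 0.0,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(ROOT / "results" / "triage_stage_counts.csv", index=False)
    write_audit_report(result, ROOT / "scratch" / "triage_audit.json")

    print(frame.to_string(index=False))
    print(
        f"overall: {len(records)} nominees -> {len(result.retained)} retained "
        f"({100 * len(result.retained) / len(records):.1f}%)"
    )
    reasons = {}
    for e in result.excluded:
        for r in e.reasons:
            reasons[r] = reasons.get(r, 0) + 1
    print("exclusion reasons:", dict(sorted(reasons.items(), key=lambda kv: -kv[1])))
    print("wrote results/triage_stage_counts.csv and scratch/triage_audit.json")


if __name__ == "__main__":
    main()
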