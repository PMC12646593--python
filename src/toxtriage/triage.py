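"""Three-stage chemical-panel triage with full exclusion bookkeeping.

Stage 1 (physicochemical applicability): drop volatile chemicals
(D_aw > 1e-4 at assay pH), overly hydrophobic chemicals
(log D_lip/w(pH 7.4) > 4) and chemicals unstable/insoluble in aqueous media
or DMSO. Nominees flagged ``moa_exception`` are retained despite a breach,
because a mechanism without in-domain representatives is worth the handling
burden; they stay flagged in the result.

Stage 2 (logistics): purity >= 98%, cost <= 1000 EUR, commercially
available, not a prohibited/controlled substance, not too hazardous for
routine laboratory handling. Every failed criterion is recorded, not just
the first.

Stage 3 (mechanism diversity): within each toxicity group, nominees are
ranked (exposome membership first, then reference compounds, then cheaper,
then identifier as a deterministic tie-break) and admitted greedily while no
mechanism tag exceeds its per-group cap (default 2) and the group stays at
or below its target maximum (default 30). A chemical qualifying for several
groups counts toward each group's size but appears once in the retained set
(deduplicated by identifier precedence). The greedy rule can be suboptimal
when records carry multiple mechanism tags; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import ValidationError
from .partitioning import PartitionSet
from .registry import ChemicalRecord

STAGE1 = "stage1_physchem"
STAGE2 = "stage2_logistics"
STAGE3 = "stage3_diversity"

R_MISSING = "missing_data"
R_VOLATILE = "volatile"
R_HYDROPHOBIC = "hydrophobic"
R_UNSTABLE = "unstable"
R_PURITY = "purity"
R_COST = "cost"
R_UNAVAILABLE = "unavailable"
R_RESTRICTED = "restricted"
R_HAZARD = "hazard_excluded"
R_MOA_REDUNDANT = "moa_redundant"
R_GROUP_FULL = "group_full"
R_DUPLICATE = "duplicate"

UNGROUPED = "(ungrouped)"


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the selection pipeline (package defaults as printed)."""

    daw_max: float = 1e-4
    log_dlipw_max: float = 4.0
    purity_min_pct: float = 98.0
    cost_max_eur: float = 1000.0
    group_target_min: int = 20
    group_target_max: int = 30
    moa_max_per_group: int = 2
    ph: float = 7.4

    def __post_init__(self):
        if self.daw_max <= 0 or self.purity_min_pct <= 0 or self.cost_max_eur <= 0:
            raise ValidationError("thresholds must be positive")
        if self.group_target_min > self.group_target_max:
            raise ValidationError("group_target_min > group_target_max")
        if self.moa_max_per_group < 1:
            raise ValidationError("moa_max_per_group must be >= 1")


@dataclass(frozen=True)
class Exclusion:
    """One excluded nominee: canonical stage plus every failed criterion."""

    record: ChemicalRecord
    stage: str
    reasons: tuple[str, ...]

    def __post_init__(self):
        if not self.reasons:
            raise ValidationError("an exclusion must carry >= 1 reason")


@dataclass
class StageOutcome:
    retained: list[ChemicalRecord]
    excluded: list[Exclusion]
    flagged: list[tuple[ChemicalRecord, tuple[str, ...]]] = field(default_factory=list)


@dataclass
class TriageResult:
    """Outcome of the full pipeline; retained + excluded == input."""

    retained: list[ChemicalRecord]
    excluded: list[Exclusion]
    stage_counts: dict[str, dict[str, int]]
    flagged_exceptions: list[tuple[ChemicalRecord, tuple[str, ...]]] = field(
        default_factory=list
    )


def stage1_physchem(
    records: list[ChemicalRecord],
    partitions: dict[str, PartitionSet],
    config: TriageConfig | None = None,
) -> StageOutcome:
    """Physicochemical applicability filter (volatility, hydrophobicity, stability)."""
    config = config or TriageConfig()
    out = StageOutcome(retained=[], excluded=[])
    for rec in records:
        pset = partitions.get(rec.identifier)
        if pset is None:
            out.excluded.append(Exclusion(rec, STAGE1, (R_MISSING,)))
            continue
        reasons = []
        if pset.daw > config.daw_max:
            reasons.append(R_VOLATILE)
        if pset.log_dlipw > config.log_dlipw_max:
            reasons.append(R_HYDROPHOBIC)
        if not rec.stability_ok:
            reasons.append(R_UNSTABLE)
        if reasons and rec.moa_exception:
            out.retained.append(rec)
            out.flagged.append((rec, tuple(reasons)))
        elif reasons:
            out.excluded.append(Exclusion(rec, STAGE1, tuple(reasons)))
        else:
            out.retained.append(rec)
    return out


def stage2_logistics(
    records: list[ChemicalRecord], config: TriageConfig | None = None
) -> StageOutcome:
    """Purity, cost, availability and safety filter; all failures recorded."""
    config = config or TriageConfig()
    out = StageOutcome(retained=[], excluded=[])
    for rec in records:
        if rec.purity_pct is None or rec.cost_eur is None or rec.available is None:
            out.excluded.append(Exclusion(rec, STAGE2, (R_MISSING,)))
            continue
        reasons = []
        if rec.purity_pct < config.purity_min_pct:
            reasons.append(R_PURITY)
        if rec.cost_eur > config.cost_max_eur:
            reasons.append(R_COST)
        if not rec.available:
            reasons.append(R_UNAVAILABLE)
        if rec.restricted:
            reasons.append(R_RESTRICTED)
        if rec.hazard_excluded:
            reasons.append(R_HAZARD)
        if reasons:
            out.excluded.append(Exclusion(rec, STAGE2, tuple(reasons)))
        else:
            out.retained.append(rec)
    return out


def _priority_key(rec: ChemicalRecord) -> tuple:
    cost = rec.cost_eur if rec.cost_eur is not None else float("inf")
    return (not rec.exposome, not rec.reference_compound, cost, rec.identifier)


def stage3_diversity(
    records: list[ChemicalRecord], config: TriageConfig | None = None
) -> StageOutcome:
    """Greedy mechanism-diversity capping within each toxicity group."""
    config = config or TriageConfig()
    groups: dict[str, list[ChemicalRecord]] = {}
    for rec in records:
        for g in sorted(rec.toxicity_groups) or [UNGROUPED]:
            groups.setdefault(g, []).append(rec)

    admitted_ids: set[str] = set()
    rejection_reasons: dict[str, set[str]] = {}
    for gname in sorted(groups):
        members = sorted(groups[gname], key=_priority_key)
        tag_counts: dict[str, int] = {}
        n_admitted = 0
        for rec in members:
            if n_admitted >= config.group_target_max:
                rejection_reasons.setdefault(rec.identifier, set()).add(R_GROUP_FULL)
                continue
            if any(
                tag_counts.get(t, 0) >= config.moa_max_per_group for t in rec.moa_tags
            ):
                rejection_reasons.setdefault(rec.identifier, set()).add(R_MOA_REDUNDANT)
                continue
            n_admitted += 1
            admitted_ids.add(rec.identifier)
            for t in rec.moa_tags:
                tag_counts[t] = tag_counts.get(t, 0) + 1
        if n_admitted < config.group_target_min:
            warnings.warn(
                f"toxicity group {gname!r} ends with {n_admitted} chemicals, "
                f"below the target minimum of {config.group_target_min}",
                stacklevel=2,
            )

    out = StageOutcome(retained=[], excluded=[])
    seen: set[str] = set()
    for rec in records:
        if rec.identifier in seen:
            # duplicate nominee: purchased once, surplus copies booked out
            out.excluded.append(Exclusion(rec, STAGE3, (R_DUPLICATE,)))
            continue
        seen.add(rec.identifier)
        if rec.identifier in admitted_ids:
            out.retained.append(rec)
        else:
            reasons = tuple(sorted(rejection_reasons.get(rec.identifier, {R_MOA_REDUNDANT})))
            out.excluded.append(Exclusion(rec, STAGE3, reasons))
    return out


def run_triage(
    records: list[ChemicalRecord],
    partitions: dict[str, PartitionSet],
    config: TriageConfig | None = None,
) -> TriageResult:
    """Apply stages 1 -> 2 -> 3 and collect audit statistics."""
    config = config or TriageConfig()
    s1 = stage1_physchem(records, partitions, config)
    s2 = stage2_logistics(s1.retained, config)
    s3 = stage3_diversity(s2.retained, config)
    excluded = s1.excluded + s2.excluded + s3.excluded
    counts = {
        STAGE1: {"in": len(records), "retained": len(s1.retained)},
        STAGE2: {"in": len(s1.retained), "retained": len(s2.retained)},
        STAGE3: {"in": len(s2.retained), "retained": len(s3.retained)},
    }
    return TriageResult(
        retained=s3.retained,
        excluded=excluded,
        stage_counts=counts,
        flagged_exceptions=s1.flagged,
    )
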