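"""Collection summaries and bipartite category-network export.

The category network mirrors how chemical panels are browsed: a bipartite
graph between category nodes (either use categories or toxicity groups) and
chemical nodes, where a chemical may attach to several categories. The graph
serializes to a small JSON schema (``nodes`` with id/kind/label, ``edges``
with source/target) that re-imports exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .partitioning import PartitionSet
from .registry import ChemicalRecord
from .speciation import species_fractions

CLASSIFICATIONS = ("use", "toxicity")

NEUTRAL_FRACTION_BINS = (0.0, 0.25, 0.50, 0.75, 1.0)


@dataclass(frozen=True)
class CategoryNetwork:
    """Bipartite category-chemical graph for one classification view."""

    classification: str
    nodes: tuple[tuple[str, str, str], ...]  # (id, kind, label)
    edges: tuple[tuple[str, str], ...]  # (category id, chemical id)

    def __post_init__(self):
        if self.classification not in CLASSIFICATIONS:
            raise ValidationError(
                f"classification must be one of {CLASSIFICATIONS}"
            )
        ids = {n[0] for n in self.nodes}
        for src, dst in self.edges:
            if src not in ids or dst not in ids:
                raise ValidationError(f"edge endpoint missing from nodes: {src}->{dst}")

    def degree(self, node_id: str) -> int:
        return sum(node_id in e for e in self.edges)

    def to_json(self) -> str:
        return json.dumps(
            {
                "classification": self.classification,
                "nodes": [
                    {"id": i, "kind": k, "label": l} for i, k, l in self.nodes
                ],
                "edges": [{"source": s, "target": t} for s, t in self.edges],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CategoryNetwork":
        raw = json.loads(text)
        return cls(
            classification=raw["classification"],
            nodes=tuple((n["id"], n["kind"], n["label"]) for n in raw["nodes"]),
            edges=tuple((e["source"], e["target"]) for e in raw["edges"]),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "CategoryNetwork":
        return cls.from_json(Path(path).read_text())


def build_category_network(
    records: list[ChemicalRecord], classification: str
) -> CategoryNetwork:
    """Bipartite graph between categories and chemicals (multi-membership)."""
    if classification not in CLASSIFICATIONS:
        raise ValidationError(f"classification must be one of {CLASSIFICATIONS}")
    getter = (
        (lambda r: r.use_categories)
        if classification == "use"
        else (lambda r: r.toxicity_groups)
    )
    nodes: dict[str, tuple[str, str, str]] = {}
    edges: list[tuple[str, str]] = []
    for rec in records:
        chem_id = f"chem:{rec.identifier}"
        nodes[chem_id] = (chem_id, "chemical", rec.name)
        for cat in sorted(getter(rec)):
            cat_id = f"cat:{cat}"
            nodes[cat_id] = (cat_id, "category", cat)
            edges.append((cat_id, chem_id))
    return CategoryNetwork(
        classification=classification,
        nodes=tuple(sorted(nodes.values())),
        edges=tuple(sorted(edges)),
    )


def summarize_collection(
    records: list[ChemicalRecord],
    partitions: dict[str, PartitionSet] | None = None,
    ph: float = 7.4,
) -> dict:
    """Headline property statistics of a chemical collection.

    Returns min/max/mean of log K_ow (and log D_lip/w when partitions are
    supplied), per-toxicity-group counts (a chemical counts in each of its
    groups) and a histogram of neutral-species fractions at ``ph``.
    """
    if not records:
        raise ValidationError("cannot summarize an empty collection")
    kows = np.array([r.log_kow for r in records if r.log_kow is not None], float)
    summary: dict = {
        "n": len(records),
        "log_kow": {
            "min": float(kows.min()),
            "max": float(kows.max()),
            "mean": float(kows.mean()),
        },
    }
    if partitions:
        dlip = np.array(
            [
                partitions[r.identifier].log_dlipw
                for r in records
                if r.identifier in partitions
            ]
        )
        summary["log_dlipw"] = {
            "min": float(dlip.min()),
            "max": float(dlip.max()),
            "mean": float(dlip.mean()),
        }
    group_counts: dict[str, int] = {}
    for rec in records:
        for g in rec.toxicity_groups:
            group_counts[g] = group_counts.get(g, 0) + 1
    summary["toxicity_group_counts"] = dict(sorted(group_counts.items()))

    f_neutral = [species_fractions(r.ionization, ph).f_neutral for r in records]
    hist, _ = np.histogram(f_neutral, bins=NEUTRAL_FRACTION_BINS)
    summary["f_neutral_histogram"] = {
        f"{lo:.2f}-{hi:.2f}": int(c)
        for lo, hi, c in zip(
            NEUTRAL_FRACTION_BINS[:-1], NEUTRAL_FRACTION_BINS[1:], hist
        )
    }
    return summary


def summary_frame(summary: dict) -> pd.DataFrame:
    """Flatten a summary dict into a tidy two-column table for CSV export."""
    rows = []

    def walk(prefix: str, obj):
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            rows.append({"statistic": prefix, "value": obj})

    walk("", summary)
    return pd.DataFrame(rows)
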