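"""Cross-study consolidation and validation of per-dataset association calls.

The rule system is deliberately plain set logic:

* a feature is *consolidated* in a direction when it is called in that
  direction in at least ``min_supporting_datasets`` studies and, when
  opposite-call exclusion is on, is never called in the opposite direction
  in any study;
* a consolidated feature *validates* when its differential is at least
  ``validation_min_abs_differential`` (and positive) in every validation
  dataset;
* denominator features for log-ratio assessment are those with a
  differential strictly below ``denominator_max_differential``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from metabiomark.ranking import AssociationCall, DifferentialResult

__all__ = [
    "BiomarkerLedger",
    "ConsistencyRules",
    "consolidate",
    "select_denominator",
    "validate",
    "write_ledger",
]

REMOVAL_REASONS = (
    "opposite_call",
    "insufficient_support",
    "contradiction_in_validation",
    "below_magnitude",
)


@dataclass(frozen=True)
class ConsistencyRules:
    """Thresholds of the consolidation/validation rule system."""

    min_supporting_datasets: int = 2
    exclusion_on_any_opposite: bool = True
    validation_min_abs_differential: float = 0.1
    denominator_max_differential: float = -0.5
    top_k_taxa: int = 20
    top_k_functions: int = 200

    def __post_init__(self) -> None:
        if self.min_supporting_datasets < 2:
            raise ValueError("min_supporting_datasets must be >= 2")
        for name in ("validation_min_abs_differential", "denominator_max_differential"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.top_k_taxa < 1 or self.top_k_functions < 1:
            raise ValueError("top-k values must be >= 1")


@dataclass
class BiomarkerLedger:
    """Per-feature association calls plus consolidated/validated sets.

    ``consolidated_rmi``/``consolidated_umi`` map feature ids to their
    supporting-study provenance; ``removed`` records why a candidate was
    dropped.  Consolidated and removed sets are disjoint per direction.
    """

    calls: list[AssociationCall] = field(default_factory=list)
    consolidated_rmi: dict[str, frozenset[str]] = field(default_factory=dict)
    consolidated_umi: dict[str, frozenset[str]] = field(default_factory=dict)
    validated_rmi: set[str] | None = None
    removed: dict[str, str] = field(default_factory=dict)

    def consolidated(self, direction: str) -> dict[str, frozenset[str]]:
        if direction == "RMI":
            return self.consolidated_rmi
        if direction == "UMI":
            return self.consolidated_umi
        raise ValueError(f"unknown direction {direction!r}")


def consolidate(
    calls: Iterable[AssociationCall],
    rules: ConsistencyRules | None = None,
    direction: str = "RMI",
) -> BiomarkerLedger:
    """Apply the cross-study inclusion/exclusion rules to association calls."""
    rules = rules or ConsistencyRules()
    if direction not in {"RMI", "UMI"}:
        raise ValueError(f"direction must be RMI or UMI, got {direction!r}")
    opposite = "UMI" if direction == "RMI" else "RMI"

    calls = sorted(set(calls), key=lambda c: (c.feature_id, c.study, c.call))
    studies = {c.study for c in calls}
    if len(studies) < 2:
        raise ValueError("consolidation requires calls from at least 2 studies")

    support: dict[str, set[str]] = {}
    against: dict[str, set[str]] = {}
    for c in calls:
        if c.call == direction:
            support.setdefault(c.feature_id, set()).add(c.study)
        elif c.call == opposite:
            against.setdefault(c.feature_id, set()).add(c.study)

    ledger = BiomarkerLedger(calls=calls)
    consolidated = ledger.consolidated(direction)
    for feature, studies_for in sorted(support.items()):
        has_opposite = rules.exclusion_on_any_opposite and feature in against
        if has_opposite:
            ledger.removed[feature] = "opposite_call"
        elif len(studies_for) < rules.min_supporting_datasets:
            ledger.removed[feature] = "insufficient_support"
        else:
            consolidated[feature] = frozenset(studies_for)
    return ledger


def validate(
    ledger: BiomarkerLedger,
    validation_results: Sequence[DifferentialResult],
    rules: ConsistencyRules | None = None,
) -> BiomarkerLedger:
    """Filter the consolidated RMI set against validation-dataset differentials.

    A candidate survives when its differential is at least
    ``validation_min_abs_differential`` in *every* validation dataset.  A
    missing feature (e.g. removed by a prevalence filter) is treated as a
    contradiction, with a warning.
    """
    rules = rules or ConsistencyRules()
    if not validation_results:
        raise ValueError("at least one validation result required")
    out = BiomarkerLedger(
        calls=list(ledger.calls),
        consolidated_rmi=dict(ledger.consolidated_rmi),
        consolidated_umi=dict(ledger.consolidated_umi),
        removed=dict(ledger.removed),
    )
    validated: set[str] = set()
    for feature in sorted(ledger.consolidated_rmi):
        reason = None
        for result in validation_results:
            diff = result.differentials.get(feature)
            if diff is None:
                warnings.warn(
                    f"{feature!r} absent from validation study {result.study!r}; "
                    "treated as a contradiction",
                    stacklevel=2,
                )
                reason = "contradiction_in_validation"
                break
            if diff <= 0:
                reason = "contradiction_in_validation"
                break
            if diff < rules.validation_min_abs_differential:
                reason = reason or "below_magnitude"
        if reason is None:
            validated.add(feature)
        else:
            out.removed[feature] = reason
    out.validated_rmi = validated
    return out


def select_denominator(
    result: DifferentialResult, rules: ConsistencyRules | None = None
) -> set[str]:
    """Features with a differential strictly below the denominator threshold."""
    rules = rules or ConsistencyRules()
    if not result.feature_ids:
        raise ValueError("empty differential result")
    selected = {
        f for f, d in result.differentials.items() if d < rules.denominator_max_differential
    }
    if not selected:
        raise ValueError(
            "no feature below the denominator threshold "
            f"{rules.denominator_max_differential}; fall back to the bottom-k UMI calls"
        )
    return selected


def write_ledger(
    ledger: BiomarkerLedger,
    path: str | Path,
    phylum: Mapping[str, str] | None = None,
) -> None:
    """Export the ledger as a TSV shaped like a published biomarker table."""
    phylum = phylum or {}
    rows = []
    for direction in ("RMI", "UMI"):
        for feature, studies in sorted(ledger.consolidated(direction).items()):
            status = "consolidated"
            if direction == "RMI" and ledger.validated_rmi is not None:
                status = "validated" if feature in ledger.validated_rmi else "consolidated"
                if feature in ledger.removed:
                    status = "removed_in_validation"
            rows.append(
                {
                    "feature_id": feature,
                    "phylum": phylum.get(feature, ""),
                    "direction": direction,
                    "supporting_studies": ";".join(sorted(studies)),
                    "status": status,
                    "removal_reason": ledger.removed.get(feature, ""),
                }
            )
    consolidated_any = set(ledger.consolidated_rmi) | set(ledger.consolidated_umi)
    for feature, reason in sorted(ledger.removed.items()):
        if feature in consolidated_any:
            continue
        rows.append(
            {
                "feature_id": feature,
                "phylum": phylum.get(feature, ""),
                "direction": "",
                "supporting_studies": "",
                "status": "removed",
                "removal_reason": reason,
            }
        )
    columns = ["feature_id", "phylum", "direction", "supporting_studies", "status", "removal_reason"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
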