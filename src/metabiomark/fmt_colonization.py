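"""Profile-level analysis of FMT cohorts: donor-derived species detection,
variance decomposition, and donor-derived feature tables.

Species origin is classified from abundance profiles of the donor baseline,
the recipient's pre-FMT baseline(s) and each post-FMT sample.  This is a
documented profile-level proxy for read-level origin attribution: species
present in both the donor and the recipient baseline are labelled "common"
and excluded from the donor-derived table by default, because their origin
is unresolvable from profiles alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from metabiomark.coda_stats import (
    PermanovaResult,
    aitchison_distance_matrix,
    benjamini_hochberg,
    bray_curtis_matrix,
    permanova,
)
from metabiomark.data_model import FeatureTable, SampleRecord

__all__ = [
    "EngraftmentProfile",
    "classify_species_origin",
    "donor_derived_table",
    "variance_decomposition",
    "write_engraftment_long",
]

CATEGORIES = ("donor_derived", "recipient_derived", "common", "new", "absent")


@dataclass
class EngraftmentProfile:
    """Origin classification of every species in one post-FMT sample."""

    recipient: str
    sample_id: str
    donor: str
    species_category: dict[str, str]
    donor_derived_abundance: dict[str, float] = field(default_factory=dict)
    timepoint_days: int | None = None


def classify_species_origin(
    feature_ids: Sequence[str],
    donor_baseline: np.ndarray,
    recipient_baseline: np.ndarray,
    post_sample: np.ndarray,
    presence_threshold: float = 0.0,
    recipient: str = "",
    sample_id: str = "",
    donor: str = "",
    timepoint_days: int | None = None,
) -> EngraftmentProfile:
    """Classify each species of a post-FMT sample by its likely origin.

    For species detected in the post sample (value > threshold):
    ``donor_derived`` if present in the donor but not the recipient baseline,
    ``recipient_derived`` if the reverse, ``common`` if present in both, and
    ``new`` if in neither.  Species not detected post-FMT are ``absent``.
    """
    donor_v = np.asarray(donor_baseline, dtype=float)
    recip_v = np.asarray(recipient_baseline, dtype=float)
    post_v = np.asarray(post_sample, dtype=float)
    if not (len(feature_ids) == donor_v.size == recip_v.size == post_v.size):
        raise ValueError("donor, recipient and post profiles must share a feature universe")
    if presence_threshold < 0:
        raise ValueError("presence threshold must be non-negative")

    theta = presence_threshold
    categories: dict[str, str] = {}
    dd_abundance: dict[str, float] = {}
    for i, f in enumerate(feature_ids):
        if post_v[i] <= theta:
            categories[f] = "absent"
            continue
        in_donor = donor_v[i] > theta
        in_recipient = recip_v[i] > theta
        if in_donor and not in_recipient:
            categories[f] = "donor_derived"
            dd_abundance[f] = float(post_v[i])
        elif in_recipient and not in_donor:
            categories[f] = "recipient_derived"
        elif in_donor and in_recipient:
            categories[f] = "common"
        else:
            categories[f] = "new"
    return EngraftmentProfile(
        recipient=recipient,
        sample_id=sample_id,
        donor=donor,
        species_category=categories,
        donor_derived_abundance=dd_abundance,
        timepoint_days=timepoint_days,
    )


def donor_derived_table(
    profiles: Sequence[EngraftmentProfile],
    feature_ids: Sequence[str] | None = None,
    include_common: bool = False,
    post_table: FeatureTable | None = None,
) -> FeatureTable:
    """Features x post-FMT-samples table of donor-derived abundances.

    By default only ``donor_derived`` species contribute; ``include_common``
    additionally attributes "common" species' post-FMT abundance to the
    donor (requires ``post_table`` to look the abundances up).
    """
    if not profiles:
        raise ValueError("at least one profile required")
    if feature_ids is None:
        universe: list[str] = []
        seen: set[str] = set()
        for p in profiles:
            for f in p.species_category:
                if f not in seen:
                    seen.add(f)
                    universe.append(f)
        feature_ids = universe
    index = {f: i for i, f in enumerate(feature_ids)}
    values = np.zeros((len(feature_ids), len(profiles)))
    for j, p in enumerate(profiles):
        for f, v in p.donor_derived_abundance.items():
            values[index[f], j] = v
        if include_common:
            if post_table is None:
                raise ValueError("include_common requires the post-FMT table")
            col = post_table.column(p.sample_id)
            for f, cat in p.species_category.items():
                if cat == "common":
                    values[index[f], j] = col[post_table.feature_index(f)]
    return FeatureTable(
        values,
        list(feature_ids),
        [p.sample_id for p in profiles],
        feature_kind="taxon",
    )


def variance_decomposition(
    table: FeatureTable,
    metadata: Sequence[SampleRecord],
    factors: Sequence[str] = ("donor", "response"),
    distance: str = "aitchison",
    n_permutations: int = 10_000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> dict[str, dict]:
    """Marginal PERMANOVA per factor on one shared distance matrix.

    Factors whose levels include a singleton (or that have fewer than two
    levels) are skipped with a warning; p-values are BH-adjusted across the
    factors actually tested.
    """
    by_sample = {r.sample_id: r for r in metadata}
    missing = [s for s in table.sample_ids if s not in by_sample]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    if distance == "aitchison":
        dist = aitchison_distance_matrix(table, pseudocount=pseudocount)
    elif distance == "bray_curtis":
        dist = bray_curtis_matrix(table)
    else:
        raise ValueError(f"unknown distance {distance!r}")

    results: dict[str, PermanovaResult] = {}
    for factor in factors:
        labels = [str(getattr(by_sample[s], factor)) for s in table.sample_ids]
        levels, counts = np.unique(labels, return_counts=True)
        if levels.size < 2 or np.any(counts < 2):
            warnings.warn(
                f"factor {factor!r} skipped: needs >=2 levels with >=2 samples each",
                stacklevel=2,
            )
            continue
        results[factor] = permanova(dist, labels, n_permutations=n_permutations, seed=seed)

    factors_tested = list(results)
    adjusted = benjamini_hochberg([results[f].p_value for f in factors_tested])
    return {
        f: {"permanova": results[f], "p_adjusted": float(q)}
        for f, q in zip(factors_tested, adjusted)
    }


def write_engraftment_long(
    profiles: Sequence[EngraftmentProfile], path: str | Path
) -> None:
    """Long-format engraftment export: one row per (sample, species).

    Note: species origin here is a profile-level proxy (presence/absence
    against donor and pre-FMT baselines), not read-level attribution.
    """
    rows = []
    for p in profiles:
        for f in sorted(p.species_category):
            cat = p.species_category[f]
            if cat == "absent":
                continue
            rows.append(
                {
                    "recipient": p.recipient,
                    "sample_id": p.sample_id,
                    "timepoint_days": "" if p.timepoint_days is None else p.timepoint_days,
                    "species": f,
                    "category": cat,
                    "abundance": p.donor_derived_abundance.get(f, ""),
                }
            )
    columns = ["recipient", "sample_id", "timepoint_days", "species", "category", "abundance"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
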