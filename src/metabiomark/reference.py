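"""Bundled reference tables from the published melanoma-immunotherapy cohorts.

Two small TSVs ship with the package:

* ``melanoma_cohorts.tsv`` — per-dataset characteristics of the seven public
  stool-metagenome cohorts (sample counts, responder/nonresponder split,
  analysis phase);
* ``rmi_species_support.tsv`` — the published consolidated response-associated
  species list with phylum annotations and, per species, the datasets that
  supported the call.

These are inputs for rule-system worked examples and arithmetic checks, not
outputs of this package.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from metabiomark.consistency import BiomarkerLedger, ConsistencyRules, consolidate
from metabiomark.ranking import AssociationCall

__all__ = [
    "consolidate_reference_support",
    "load_cohort_characteristics",
    "load_rmi_support_calls",
    "phase_sample_total",
    "phase_responder_total",
]


def _data_path(name: str):
    return files("metabiomark").joinpath("data", name)


def load_cohort_characteristics() -> pd.DataFrame:
    """Per-dataset characteristics of the seven published cohorts."""
    with _data_path("melanoma_cohorts.tsv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def phase_sample_total(phase: str | None = None) -> int:
    """Sum of metagenome sample counts, optionally restricted to one phase."""
    frame = load_cohort_characteristics()
    if phase is not None:
        frame = frame[frame["phase"] == phase]
        if frame.empty:
            raise ValueError(f"unknown phase {phase!r}")
    return int(frame["samples"].sum())


def phase_responder_total(phase: str) -> int:
    """Sum of responder counts across the datasets of one phase."""
    frame = load_cohort_characteristics()
    frame = frame[frame["phase"] == phase]
    if frame.empty:
        raise ValueError(f"unknown phase {phase!r}")
    return int(frame["responders"].sum())


def load_rmi_support_calls() -> tuple[list[AssociationCall], dict[str, str]]:
    """The published species-support table as per-dataset RMI calls.

    Returns the calls plus a species -> phylum mapping.
    """
    with _data_path("rmi_species_support.tsv").open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, sep="\t")
    calls: list[AssociationCall] = []
    phylum: dict[str, str] = {}
    for _, row in frame.iterrows():
        phylum[row["species"]] = row["phylum"]
        for study in str(row["supporting_datasets"]).split(";"):
            calls.append(AssociationCall(row["species"], study.strip(), "RMI"))
    return calls, phylum


def consolidate_reference_support(
    rules: ConsistencyRules | None = None,
) -> tuple[BiomarkerLedger, dict[str, str]]:
    """Run the consolidation rule system on the published support table."""
    calls, phylum = load_rmi_support_calls()
    ledger = consolidate(calls, rules or ConsistencyRules(), direction="RMI")
    return ledger, phylum
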