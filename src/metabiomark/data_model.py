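"""Core data structures and text IO for feature tables and sample metadata.

Feature tables are stored features-as-rows, samples-as-columns, mirroring
the merged-table convention of common taxonomic/functional profilers.  All
IO is UTF-8, tab-separated plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_RESPONSES = frozenset({"R", "NR", "NA"})
VALID_ROLES = frozenset({"patient", "donor", "recipient"})
VALID_FEATURE_KINDS = frozenset({"taxon", "gene_group"})

#: Columns of the sample-metadata TSV, in order.
METADATA_COLUMNS = (
    "sample_id",
    "study",
    "response",
    "subject_id",
    "role",
    "timepoint_days",
    "donor",
)


@dataclass
class FeatureTable:
    """A features x samples matrix of non-negative counts or abundances.

    Parameters
    ----------
    values
        Matrix of shape ``(n_features, n_samples)``; non-negative, finite.
    feature_ids, sample_ids
        Unique row / column identifiers.
    feature_kind
        Either ``"taxon"`` or ``"gene_group"``.
    feature_annotations
        Optional per-feature annotations, e.g. ``{"phylum": ..., "display_name": ...}``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    feature_kind: str = "taxon"
    feature_annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in feature table")
        if np.any(self.values < 0):
            raise ValueError("negative values in feature table")
        if self.feature_kind not in VALID_FEATURE_KINDS:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        return self._feature_index[feature_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def column(self, sample_id: str) -> np.ndarray:
        """Return one sample's vector (in feature order)."""
        return self.values[:, self._sample_index[sample_id]].copy()

    def phylum(self, feature_id: str) -> str:
        ann = self.feature_annotations.get(feature_id, {})
        if "phylum" not in ann:
            raise KeyError(f"feature {feature_id!r} has no phylum annotation")
        return ann["phylum"]

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        cols = [self._sample_index[s] for s in sample_ids]
        return FeatureTable(
            self.values[:, cols],
            list(self.feature_ids),
            [str(s) for s in sample_ids],
            self.feature_kind,
            dict(self.feature_annotations),
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        rows = [self._feature_index[f] for f in feature_ids]
        keep = set(feature_ids)
        return FeatureTable(
            self.values[rows, :],
            [str(f) for f in feature_ids],
            list(self.sample_ids),
            self.feature_kind,
            {f: a for f, a in self.feature_annotations.items() if f in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SampleRecord:
    """Per-sample metadata: study, response label and FMT structure."""

    sample_id: str
    study: str
    response: str = "NA"
    subject_id: str = ""
    role: str = "patient"
    timepoint_days: int | None = None
    donor: str | None = None

    def __post_init__(self) -> None:
        if self.response not in VALID_RESPONSES:
            raise ValueError(f"response must be one of {sorted(VALID_RESPONSES)}, got {self.response!r}")
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {sorted(VALID_ROLES)}, got {self.role!r}")
        if self.role == "donor" and self.response != "NA":
            raise ValueError(f"donor sample {self.sample_id!r} must have response=NA")

    @property
    def is_baseline(self) -> bool:
        """True for pre-FMT samples (timepoint at or before day 0)."""
        return self.timepoint_days is not None and self.timepoint_days <= 0


@dataclass
class Prevalence:
    """Fraction of samples in which a feature is detected (> 0)."""

    feature_id: str
    fraction_nonzero: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_nonzero <= 1.0:
            raise ValueError("fraction_nonzero must lie in [0, 1]")


# ---------------------------------------------------------------------------
# feature-table IO
# ---------------------------------------------------------------------------


def _parse_numeric_frame(frame: pd.DataFrame) -> pd.DataFrame:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {frame.index[i]!r}, sample {frame.columns[j]!r}: "
            f"{frame.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at feature {frame.index[i]!r}, sample {frame.columns[j]!r}")
    # re-parse with Python's correctly-rounded float() so write/read round-trips
    exact = np.array(
        [[float(x) for x in frame.iloc[i]] for i in range(len(frame))], dtype=float
    )
    return pd.DataFrame(exact, index=frame.index, columns=frame.columns)


def _split_metaphlan_lineage(lineage: str) -> tuple[str | None, str | None]:
    """Return (species, phylum) from a rank-prefixed lineage string.

    Only rows whose terminal rank is species (``s__``) yield a species name;
    genus-level and higher rows, and strain rows (``t__``), return None.
    """
    parts = lineage.split("|")
    if not parts or not parts[-1].startswith("s__"):
        return None, None
    species = parts[-1][3:]
    phylum = None
    for part in parts:
        if part.startswith("p__"):
            phylum = part[3:]
            break
    return species, phylum


def read_feature_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    feature_kind: str = "taxon",
    annotation_path: str | Path | None = None,
) -> FeatureTable:
    """Read a feature table from a TSV file.

    ``generic_tsv`` expects feature ids in the first column and sample ids in
    the header.  ``metaphlan_merged`` expects rank-prefixed lineage strings
    (``k__...|p__...|...|s__Species_name``) in the first column; only
    species-level rows are retained, the feature id becomes the ``s__`` name
    and the ``p__`` rank is recorded as the phylum annotation.
    """
    path = Path(path)
    if dialect not in {"generic_tsv", "metaphlan_merged"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if "NCBI_tax_id" in raw.columns:  # optional second column in merged profiles
        raw = raw.drop(columns=["NCBI_tax_id"])

    annotations: dict[str, dict[str, str]] = {}
    if dialect == "metaphlan_merged":
        keep_rows = []
        new_ids = []
        for lineage in raw.index:
            species, phylum = _split_metaphlan_lineage(str(lineage))
            if species is None:
                continue
            keep_rows.append(lineage)
            new_ids.append(species)
            ann: dict[str, str] = {"display_name": species.replace("_", " ")}
            if phylum is not None:
                ann["phylum"] = phylum
            annotations[species] = ann
        raw = raw.loc[keep_rows]
        raw.index = new_ids

    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValueError(f"duplicate feature ids: {dupes[:5]}")
    if pd.Index(raw.columns).duplicated().any():
        raise ValueError("duplicate sample ids in header")

    numeric = _parse_numeric_frame(raw)
    if (numeric.to_numpy() < 0).any():
        i, j = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ValueError(f"negative value at feature {numeric.index[i]!r}, sample {numeric.columns[j]!r}")

    if annotation_path is not None:
        ann_frame = pd.read_csv(annotation_path, sep="\t", dtype=str).fillna("")
        for _, row in ann_frame.iterrows():
            ann = {k: v for k, v in row.items() if k != "feature_id" and v != ""}
            annotations[row["feature_id"]] = ann

    return FeatureTable(
        numeric.to_numpy(dtype=float),
        [str(f) for f in numeric.index],
        [str(s) for s in numeric.columns],
        feature_kind=feature_kind,
        feature_annotations=annotations,
    )


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write a feature table (generic TSV dialect), optionally with annotations."""
    frame = table.to_frame()
    frame.index.name = "feature_id"
    # %.17g keeps float64 exact on the write -> read round trip
    frame.to_csv(path, sep="\t", float_format="%.17g")
    if annotation_path is not None:
        keys: list[str] = []
        for ann in table.feature_annotations.values():
            for k in ann:
                if k not in keys:
                    keys.append(k)
        rows = []
        for f in table.feature_ids:
            ann = table.feature_annotations.get(f, {})
            rows.append({"feature_id": f, **{k: ann.get(k, "") for k in keys}})
        pd.DataFrame(rows, columns=["feature_id", *keys]).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metadata IO
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[SampleRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "study", "response"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        tp = row.get("timepoint_days", "")
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                study=row["study"],
                response=row["response"] or "NA",
                subject_id=row.get("subject_id", ""),
                role=row.get("role", "") or "patient",
                timepoint_days=int(float(tp)) if tp != "" else None,
                donor=row.get("donor", "") or None,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in metadata")
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "study": r.study,
                "response": r.response,
                "subject_id": r.subject_id,
                "role": r.role,
                "timepoint_days": "" if r.timepoint_days is None else r.timepoint_days,
                "donor": r.donor or "",
            }
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def check_fmt_invariants(records: Sequence[SampleRecord]) -> None:
    """Raise if donors carry a response label or a recipient lacks a baseline."""
    by_subject: dict[str, list[SampleRecord]] = {}
    for r in records:
        if r.role == "donor" and r.response != "NA":
            raise ValueError(f"donor sample {r.sample_id!r} has response {r.response!r}")
        if r.role == "recipient":
            by_subject.setdefault(r.subject_id, []).append(r)
    for subject, recs in by_subject.items():
        if not any(r.is_baseline for r in recs):
            raise ValueError(f"recipient {subject!r} has no pre-FMT baseline sample")


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def compute_prevalence(table: FeatureTable) -> list[Prevalence]:
    """Fraction of samples with a nonzero value, per feature."""
    if table.n_samples == 0:
        raise ValueError("empty table")
    fractions = (table.values > 0).mean(axis=1)
    return [Prevalence(f, float(p)) for f, p in zip(table.feature_ids, fractions)]


def filter_by_prevalence(table: FeatureTable, min_fraction: float) -> FeatureTable:
    """Retain features detected in at least ``min_fraction`` of samples."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    fractions = (table.values > 0).mean(axis=1)
    keep = [f for f, p in zip(table.feature_ids, fractions) if p >= min_fraction]
    if not keep:
        raise ValueError(
            f"no features reach prevalence {min_fraction}; lower the threshold"
        )
    return table.subset_features(keep)


def as_model_counts(table: FeatureTable, pseudo_depth: float = 10_000.0) -> FeatureTable:
    """Return a table on count scale suitable for multinomial fitting.

    Tables whose columns all sum to 1 (within 1e-6) are treated as relative
    abundances and rescaled to ``pseudo_depth``; anything else is used as-is.
    """
    sums = table.values.sum(axis=0)
    if np.all(np.abs(sums - 1.0) <= 1e-6):
        return FeatureTable(
            table.values * pseudo_depth,
            list(table.feature_ids),
            list(table.sample_ids),
            table.feature_kind,
            dict(table.feature_annotations),
        )
    return table


def group_samples(
    records: Iterable[SampleRecord], **criteria: str | Mapping[str, str]
) -> list[SampleRecord]:
    """Select records whose attributes match all ``criteria`` exactly."""
    out = []
    for r in records:
        if all(getattr(r, key) == value for key, value in criteria.items()):
            out.append(r)
    return out
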