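"""Link functional biomarkers to taxa and rank species by biomarker content."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from metabiomark.coda_stats import benjamini_hochberg, wilcoxon_rank_sum

__all__ = [
    "LinkIncidence",
    "SpeciesRanking",
    "coverage_of_combination",
    "export_link_network",
    "phylum_contrast",
    "rank_species_by_biomarkers",
    "read_link_table",
    "write_link_table",
]


@dataclass
class LinkIncidence:
    """Bipartite taxon <-> gene-group incidence (unweighted presence pairs)."""

    pairs: frozenset[tuple[str, str]]
    taxon_phylum: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = frozenset((str(t), str(g)) for t, g in self.pairs)

    @property
    def taxa(self) -> set[str]:
        return {t for t, _ in self.pairs}

    def linked_gene_groups(self, taxon: str) -> set[str]:
        return {g for t, g in self.pairs if t == taxon}


@dataclass
class SpeciesRanking:
    """Per-taxon biomarker-link counts, a sorted order and coverage lookups."""

    counts: dict[str, int]
    order: list[str]
    coverage: dict[frozenset[str], float] = field(default_factory=dict)


def read_link_table(path: str | Path, phylum: dict[str, str] | None = None) -> LinkIncidence:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon_id", "gene_group_id"}
    if not required <= set(frame.columns):
        raise ValueError(f"link table must have columns {sorted(required)}")
    pairs = frozenset(zip(frame["taxon_id"], frame["gene_group_id"]))
    phyla = dict(phylum or {})
    if "phylum" in frame.columns:
        for _, row in frame.iterrows():
            if isinstance(row["phylum"], str) and row["phylum"]:
                phyla[row["taxon_id"]] = row["phylum"]
    return LinkIncidence(pairs, phyla)


def write_link_table(links: LinkIncidence, path: str | Path) -> None:
    rows = [
        {"taxon_id": t, "gene_group_id": g, "phylum": links.taxon_phylum.get(t, "")}
        for t, g in sorted(links.pairs)
    ]
    pd.DataFrame(rows, columns=["taxon_id", "gene_group_id", "phylum"]).to_csv(
        path, sep="\t", index=False
    )


def rank_species_by_biomarkers(
    links: LinkIncidence, biomarkers: Iterable[str]
) -> SpeciesRanking:
    """Count, per taxon, how many biomarker gene groups it is linked to."""
    biomarker_set = frozenset(biomarkers)
    if not biomarker_set:
        raise ValueError("biomarker set must be non-empty")
    counts = {
        taxon: len(links.linked_gene_groups(taxon) & biomarker_set)
        for taxon in links.taxa
    }
    order = sorted(counts, key=lambda t: (-counts[t], t))
    coverage = {
        frozenset({t}): counts[t] / len(biomarker_set) for t in counts
    }
    return SpeciesRanking(counts, order, coverage)


def coverage_of_combination(
    links: LinkIncidence, taxa: Iterable[str], biomarkers: Iterable[str]
) -> float:
    """Fraction of the biomarker set covered by the union of the taxa's links."""
    taxa = set(taxa)
    biomarker_set = set(biomarkers)
    if not taxa:
        raise ValueError("taxon set must be non-empty")
    if not biomarker_set:
        raise ValueError("biomarker set must be non-empty")
    covered: set[str] = set()
    for t in taxa:
        covered |= links.linked_gene_groups(t)
    return len(covered & biomarker_set) / len(biomarker_set)


def phylum_contrast(
    links: LinkIncidence, biomarkers: Iterable[str]
) -> tuple[dict[str, list[int]], pd.DataFrame]:
    """Per-phylum distributions of per-species biomarker counts, with pairwise
    Wilcoxon rank-sum tests BH-adjusted across phylum pairs.

    Phyla represented by fewer than two annotated taxa are excluded with a
    warning.
    """
    ranking = rank_species_by_biomarkers(links, biomarkers)
    by_phylum: dict[str, list[int]] = {}
    for taxon in sorted(links.taxa):
        phylum = links.taxon_phylum.get(taxon)
        if phylum is None:
            warnings.warn(f"taxon {taxon!r} has no phylum annotation; skipped", stacklevel=2)
            continue
        by_phylum.setdefault(phylum, []).append(ranking.counts[taxon])
    for phylum in [p for p, v in by_phylum.items() if len(v) < 2]:
        warnings.warn(f"phylum {phylum!r} has <2 taxa; excluded from contrasts", stacklevel=2)
        del by_phylum[phylum]
    if len(by_phylum) < 2:
        raise ValueError("need at least two phyla with >=2 taxa each")

    rows = []
    for a, b in combinations(sorted(by_phylum), 2):
        p = wilcoxon_rank_sum(by_phylum[a], by_phylum[b], mode="normal")
        rows.append({"phylum_a": a, "phylum_b": b, "n_a": len(by_phylum[a]), "n_b": len(by_phylum[b]), "p_value": p})
    frame = pd.DataFrame(rows, columns=["phylum_a", "phylum_b", "n_a", "n_b", "p_value"])
    frame["p_adjusted"] = benjamini_hochberg(frame["p_value"].to_numpy())
    return by_phylum, frame


def export_link_network(
    links: LinkIncidence, biomarkers: Iterable[str]
) -> pd.DataFrame:
    """Phylum-aggregated bipartite edge list restricted to biomarker gene groups.

    Each edge connects a phylum node to a gene-group node; the weight is the
    number of taxa of that phylum linked to the gene group.  The sum of the
    weights equals the total number of biomarker links.
    """
    biomarker_set = set(biomarkers)
    weights: dict[tuple[str, str], int] = {}
    for taxon, gene_group in sorted(links.pairs):
        if gene_group not in biomarker_set:
            continue
        phylum = links.taxon_phylum.get(taxon, "unknown")
        weights[(phylum, gene_group)] = weights.get((phylum, gene_group), 0) + 1
    rows = [
        {"phylum": p, "gene_group": g, "weight": w}
        for (p, g), w in sorted(weights.items())
    ]
    return pd.DataFrame(rows, columns=["phylum", "gene_group", "weight"])
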