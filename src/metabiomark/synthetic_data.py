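"""Synthetic multi-study compositional data with known planted truth.

Generates case-control count tables with planted log-fold effects and
study-specific bias, FMT cohorts with response-modulated engraftment, and
taxon-derived functional profiles.  Every generator is driven by a single
integer seed through the deterministic splitting scheme in
:mod:`metabiomark._rng`, so identical calls are bit-identical.

Generative model for case-control samples: per sample i in group g,

    composition_i = softmax(baseline + g * log_fold + study_bias + noise_i)

with counts drawn multinomially at a log-normal depth around ``depth_mean``
(CV 0.3).  Study bias is a per-study, per-feature Gaussian logit offset
(emulating extraction batch effects); sample noise is a per-sample Gaussian
logit jitter providing overdispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from metabiomark._rng import child_int_seed, child_rng
from metabiomark.data_model import FeatureTable, SampleRecord

__all__ = [
    "PlantedEffect",
    "StudyBundle",
    "StudySpec",
    "SyntheticTruth",
    "default_feature_ids",
    "derive_functional_profiles",
    "generate_case_control_study",
    "generate_fmt_cohort",
    "generate_link_table",
    "generate_multi_study",
]

PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria", "Verrucomicrobia")

DEPTH_CV = 0.3


@dataclass(frozen=True)
class PlantedEffect:
    """A log-scale shift of one feature's logit abundance in responders."""

    feature_id: str
    log_fold: float
    studies: frozenset[str]

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_fold):
            raise ValueError("log_fold must be finite")
        if not self.studies:
            raise ValueError("studies must be non-empty")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside generated data, for recovery tests."""

    effects: list[PlantedEffect] = field(default_factory=list)
    baseline_logits: dict[str, float] = field(default_factory=dict)
    study_bias: dict[tuple[str, str], float] = field(default_factory=dict)
    engraftment_truth: dict[tuple[str, str], str] = field(default_factory=dict)
    taxon_gene_links: set[tuple[str, str]] = field(default_factory=set)
    consistent_positive: set[str] = field(default_factory=set)
    inconsistent: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class StudySpec:
    """Per-study design parameters for the multi-study generator."""

    name: str
    n_r: int
    n_nr: int
    phase: str = "discovery"

    def __post_init__(self) -> None:
        if self.phase not in {"discovery", "validation", "fmt"}:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class StudyBundle:
    """One generated study: table, metadata and phase."""

    name: str
    table: FeatureTable
    records: list[SampleRecord]
    phase: str


def default_feature_ids(n_features: int, kind: str = "taxon") -> list[str]:
    prefix = "sp" if kind == "taxon" else "K"
    return [f"{prefix}{i:04d}" for i in range(1, n_features + 1)]


def _default_annotations(feature_ids: Sequence[str]) -> dict[str, dict[str, str]]:
    return {
        f: {"phylum": PHYLA[i % len(PHYLA)], "display_name": f}
        for i, f in enumerate(feature_ids)
    }


def _lognormal_depths(rng: np.random.Generator, n: int, depth_mean: float) -> np.ndarray:
    sigma2 = math.log(1.0 + DEPTH_CV**2)
    mu = math.log(depth_mean) - sigma2 / 2.0
    depths = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    return np.maximum(depths.round().astype(int), 1)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max()
    e = np.exp(shifted)
    return e / e.sum()


def generate_case_control_study(
    n_r: int,
    n_nr: int,
    n_features: int,
    effects: Sequence[PlantedEffect],
    depth_mean: float = 10_000.0,
    seed: int = 0,
    study: str = "study1",
    feature_ids: Sequence[str] | None = None,
    baseline_logits: Mapping[str, float] | None = None,
    study_bias_sigma: float = 0.5,
    sample_noise_sigma: float = 0.3,
) -> tuple[FeatureTable, list[SampleRecord], SyntheticTruth]:
    """Generate one case-control study with planted responder effects."""
    if n_r <= 0 or n_nr <= 0 or n_features <= 0:
        raise ValueError("counts must be positive")
    if len(effects) >= n_features:
        raise ValueError("need fewer effects than features")
    if feature_ids is None:
        feature_ids = default_feature_ids(n_features)
    if len(feature_ids) != n_features:
        raise ValueError("feature_ids length must equal n_features")
    index = {f: i for i, f in enumerate(feature_ids)}
    for e in effects:
        if e.feature_id not in index:
            raise ValueError(f"planted effect on unknown feature {e.feature_id!r}")

    if baseline_logits is None:
        base = child_rng(seed, "baseline").normal(0.0, 1.0, n_features)
    else:
        base = np.array([baseline_logits[f] for f in feature_ids])
    bias = child_rng(seed, "bias", study).normal(0.0, study_bias_sigma, n_features)

    log_fold = np.zeros(n_features)
    for e in effects:
        if study in e.studies:
            log_fold[index[e.feature_id]] += e.log_fold

    rng = child_rng(seed, "samples", study)
    n = n_r + n_nr
    groups = np.array([1.0] * n_r + [0.0] * n_nr)
    depths = _lognormal_depths(rng, n, depth_mean)
    values = np.zeros((n_features, n))
    for i in range(n):
        noise = rng.normal(0.0, sample_noise_sigma, n_features)
        p = _softmax(base + bias + groups[i] * log_fold + noise)
        values[:, i] = rng.multinomial(depths[i], p)

    sample_ids = [f"{study}_s{i:03d}" for i in range(1, n + 1)]
    records = [
        SampleRecord(
            sample_id=s,
            study=study,
            response="R" if groups[i] == 1.0 else "NR",
            subject_id=f"{study}_subj{i:03d}",
            role="patient",
        )
        for i, s in enumerate(sample_ids)
    ]
    table = FeatureTable(
        values, list(feature_ids), sample_ids, "taxon", _default_annotations(feature_ids)
    )
    truth = SyntheticTruth(
        effects=list(effects),
        baseline_logits={f: float(b) for f, b in zip(feature_ids, base)},
        study_bias={(study, f): float(b) for f, b in zip(feature_ids, bias)},
    )
    return table, records, truth


def generate_multi_study(
    study_specs: Sequence[StudySpec],
    consistent_positive: Iterable[str],
    inconsistent: Iterable[str],
    seed: int = 0,
    n_features: int = 200,
    effect_size: float = math.log(4.0),
    depth_mean: float = 10_000.0,
    study_bias_sigma: float = 0.5,
    sample_noise_sigma: float = 0.3,
) -> tuple[dict[str, StudyBundle], SyntheticTruth]:
    """Generate a multi-study layout with a shared baseline composition.

    ``consistent_positive`` features get a positive log-fold effect in every
    study (so they satisfy the consolidation rule by construction and
    persist into validation studies); ``inconsistent`` features get a
    positive effect in the first two studies and a negative one in the last,
    so the opposite-call exclusion removes them.
    """
    consistent_positive = set(consistent_positive)
    inconsistent = set(inconsistent)
    if consistent_positive & inconsistent:
        raise ValueError(
            f"overlapping consistent/inconsistent sets: {sorted(consistent_positive & inconsistent)}"
        )
    if len(study_specs) < 2:
        raise ValueError("at least two studies required")
    if inconsistent and len(study_specs) < 3:
        raise ValueError("inconsistent features require at least three studies")
    names = [s.name for s in study_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate study names")

    planted = sorted(consistent_positive | inconsistent)
    feature_ids = list(planted) + [
        f for f in default_feature_ids(n_features) if f not in set(planted)
    ]
    feature_ids = feature_ids[:n_features]
    missing = [f for f in planted if f not in set(feature_ids)]
    if missing:
        raise ValueError(f"planted features do not fit into {n_features} features")

    effects: list[PlantedEffect] = []
    for f in sorted(consistent_positive):
        effects.append(PlantedEffect(f, effect_size, frozenset(names)))
    for f in sorted(inconsistent):
        effects.append(PlantedEffect(f, effect_size, frozenset(names[:2])))
        effects.append(PlantedEffect(f, -effect_size, frozenset({names[-1]})))

    base_rng = child_rng(seed, "baseline")
    baseline = {f: float(v) for f, v in zip(feature_ids, base_rng.normal(0.0, 1.0, n_features))}

    bundles: dict[str, StudyBundle] = {}
    truth = SyntheticTruth(
        effects=effects,
        baseline_logits=baseline,
        consistent_positive=set(consistent_positive),
        inconsistent=set(inconsistent),
    )
    for spec in study_specs:
        table, records, study_truth = generate_case_control_study(
            spec.n_r,
            spec.n_nr,
            n_features,
            effects,
            depth_mean=depth_mean,
            seed=child_int_seed(seed, "study", spec.name),
            study=spec.name,
            feature_ids=feature_ids,
            baseline_logits=baseline,
            study_bias_sigma=study_bias_sigma,
            sample_noise_sigma=sample_noise_sigma,
        )
        truth.study_bias.update(study_truth.study_bias)
        bundles[spec.name] = StudyBundle(spec.name, table, records, spec.phase)
    return bundles, truth


def generate_fmt_cohort(
    n_donors: int,
    n_recipients: int,
    timepoints: Sequence[int],
    engraftment_prob_r: float,
    engraftment_prob_nr: float,
    seed: int = 0,
    study: str = "fmt1",
    n_features: int = 150,
    depth_mean: float = 10_000.0,
    responder_fraction: float = 0.5,
    response_linked: Iterable[str] | None = None,
    presence_prob: float = 0.45,
    new_species_prob: float = 0.02,
    sample_noise_sigma: float = 0.3,
) -> tuple[FeatureTable, list[SampleRecord], SyntheticTruth]:
    """Generate an FMT cohort: donors, recipient baselines and post-FMT series.

    Each recipient is assigned one donor.  Donor-specific species (present in
    the donor, absent from the recipient baseline) engraft with probability
    ``engraftment_prob_r`` or ``engraftment_prob_nr`` depending on the
    recipient's response; if ``response_linked`` is given, only those
    features are response-modulated and the rest engraft at the mean of the
    two probabilities.  Every species planted as present in a sample is
    guaranteed at least one count so presence matches the recorded truth.
    """
    if n_donors <= 0 or n_recipients <= 0:
        raise ValueError("counts must be positive")
    for p in (engraftment_prob_r, engraftment_prob_nr):
        if not 0.0 <= p <= 1.0:
            raise ValueError("engraftment probabilities must lie in [0, 1]")
    timepoints = [int(t) for t in timepoints]
    if not any(t <= 0 for t in timepoints):
        raise ValueError("timepoints must include a pre-FMT baseline (<= 0)")
    post_times = sorted(t for t in timepoints if t > 0)
    base_times = sorted(t for t in timepoints if t <= 0)

    feature_ids = default_feature_ids(n_features)
    annotations = _default_annotations(feature_ids)
    linked = set(response_linked) if response_linked is not None else None
    if linked is not None and not linked <= set(feature_ids):
        raise ValueError("response_linked features must exist in the feature set")

    donors = [f"donor{d:02d}" for d in range(1, n_donors + 1)]
    recipients = [f"rcpt{r:02d}" for r in range(1, n_recipients + 1)]
    n_resp = int(round(responder_fraction * n_recipients))
    responses = {r: ("R" if i < n_resp else "NR") for i, r in enumerate(recipients)}

    comm_rng = child_rng(seed, "communities")
    donor_present = {d: comm_rng.random(n_features) < presence_prob for d in donors}
    donor_logits = {d: comm_rng.normal(0.0, 1.0, n_features) for d in donors}
    recip_present = {r: comm_rng.random(n_features) < presence_prob for r in recipients}
    recip_logits = {r: comm_rng.normal(0.0, 1.0, n_features) for r in recipients}
    if linked:
        # planted response-linked engrafters are donor-specific by design:
        # present in every donor, absent from every recipient baseline
        linked_idx = [i for i, f in enumerate(feature_ids) if f in linked]
        for d in donors:
            donor_present[d][linked_idx] = True
        for r in recipients:
            recip_present[r][linked_idx] = False

    # balanced donor assignment (round-robin over a shuffled recipient order)
    assign_rng = child_rng(seed, "assignment")
    order = assign_rng.permutation(n_recipients)
    donor_of = {recipients[int(i)]: donors[k % n_donors] for k, i in enumerate(order)}

    eng_rng = child_rng(seed, "engraftment")
    truth = SyntheticTruth()
    engrafted: dict[str, np.ndarray] = {}
    new_species: dict[str, np.ndarray] = {}
    for r in recipients:
        d = donor_of[r]
        donor_specific = donor_present[d] & ~recip_present[r]
        p_resp = engraftment_prob_r if responses[r] == "R" else engraftment_prob_nr
        if linked is None:
            probs = np.full(n_features, p_resp)
        else:
            neutral = 0.5 * (engraftment_prob_r + engraftment_prob_nr)
            probs = np.array([p_resp if f in linked else neutral for f in feature_ids])
        engrafted[r] = donor_specific & (eng_rng.random(n_features) < probs)
        neither = ~donor_present[d] & ~recip_present[r]
        new_species[r] = neither & (eng_rng.random(n_features) < new_species_prob)
        for i, f in enumerate(feature_ids):
            if engrafted[r][i]:
                label = "donor_derived"
            elif recip_present[r][i] and donor_present[d][i]:
                label = "common"
            elif recip_present[r][i]:
                label = "recipient_derived"
            elif new_species[r][i]:
                label = "new"
            else:
                label = "absent"
            truth.engraftment_truth[(r, f)] = label

    count_rng = child_rng(seed, "counts")

    def draw_counts(present: np.ndarray, logits: np.ndarray, depth: int) -> np.ndarray:
        """Multinomial counts over the present species, each guaranteed >= 1."""
        counts = np.zeros(n_features)
        idx = np.flatnonzero(present)
        if idx.size == 0:
            return counts
        noisy = logits[idx] + count_rng.normal(0.0, sample_noise_sigma, idx.size)
        p = _softmax(noisy)
        spare = max(int(depth) - idx.size, 0)
        counts[idx] = 1 + count_rng.multinomial(spare, p)
        return counts

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    records: list[SampleRecord] = []
    depth_rng = child_rng(seed, "depths")

    for d in donors:
        depth = int(_lognormal_depths(depth_rng, 1, depth_mean)[0])
        columns.append(draw_counts(donor_present[d], donor_logits[d], depth))
        sample_ids.append(f"{study}_{d}_base")
        records.append(
            SampleRecord(
                sample_id=sample_ids[-1],
                study=study,
                response="NA",
                subject_id=d,
                role="donor",
                timepoint_days=0,
            )
        )

    for r in recipients:
        d = donor_of[r]
        post_present = recip_present[r] | engrafted[r] | new_species[r]
        post_logits = np.where(engrafted[r], donor_logits[d], recip_logits[r])
        post_logits = np.where(new_species[r], recip_logits[r] - 1.0, post_logits)
        for t in base_times:
            depth = int(_lognormal_depths(depth_rng, 1, depth_mean)[0])
            columns.append(draw_counts(recip_present[r], recip_logits[r], depth))
            sample_ids.append(f"{study}_{r}_t{t}")
            records.append(
                SampleRecord(
                    sample_id=sample_ids[-1],
                    study=study,
                    response=responses[r],
                    subject_id=r,
                    role="recipient",
                    timepoint_days=t,
                    donor=d,
                )
            )
        for t in post_times:
            depth = int(_lognormal_depths(depth_rng, 1, depth_mean)[0])
            columns.append(draw_counts(post_present, post_logits, depth))
            sample_ids.append(f"{study}_{r}_t{t}")
            records.append(
                SampleRecord(
                    sample_id=sample_ids[-1],
                    study=study,
                    response=responses[r],
                    subject_id=r,
                    role="recipient",
                    timepoint_days=t,
                    donor=d,
                )
            )

    table = FeatureTable(
        np.column_stack(columns), feature_ids, sample_ids, "taxon", annotations
    )
    return table, records, truth


def derive_functional_profiles(
    taxon_table: FeatureTable,
    links: Iterable[tuple[str, str]],
    copy_weights: Mapping[tuple[str, str], float] | None = None,
    gene_group_ids: Sequence[str] | None = None,
) -> FeatureTable:
    """Gene-group profiles as copy-weighted sums of linked taxon abundances."""
    links = sorted(set(links))
    copy_weights = dict(copy_weights or {})
    taxa = set(taxon_table.feature_ids)
    for t, g in links:
        if t not in taxa:
            raise ValueError(f"link references unknown taxon {t!r}")
    for pair, w in copy_weights.items():
        if w < 0:
            raise ValueError(f"negative copy weight for {pair}")

    if gene_group_ids is None:
        gene_group_ids = sorted({g for _, g in links})
    g_index = {g: i for i, g in enumerate(gene_group_ids)}
    values = np.zeros((len(gene_group_ids), taxon_table.n_samples))
    for t, g in links:
        if g not in g_index:
            continue
        w = copy_weights.get((t, g), 1.0)
        values[g_index[g], :] += w * taxon_table.values[taxon_table.feature_index(t), :]
    return FeatureTable(
        values,
        list(gene_group_ids),
        list(taxon_table.sample_ids),
        feature_kind="gene_group",
    )


def generate_link_table(
    taxon_ids: Sequence[str],
    n_gene_groups: int,
    seed: int = 0,
    min_links: int = 1,
    max_links: int = 3,
    phylum: Mapping[str, str] | None = None,
) -> set[tuple[str, str]]:
    """Random bipartite links: each gene group maps to 1..max_links taxa."""
    if n_gene_groups <= 0:
        raise ValueError("n_gene_groups must be positive")
    rng = child_rng(seed, "links")
    gene_groups = default_feature_ids(n_gene_groups, kind="gene_group")
    pairs: set[tuple[str, str]] = set()
    for g in gene_groups:
        k = int(rng.integers(min_links, max_links + 1))
        chosen = rng.choice(len(taxon_ids), size=min(k, len(taxon_ids)), replace=False)
        for c in chosen:
            pairs.add((taxon_ids[int(c)], g))
    return pairs
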