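"""End-to-end orchestration: discovery, FMT, validation, reporting.

Every stage reads and writes the plain-text TSV formats defined by the data
model, so stages can also be run independently from the CLI.  All
randomness is split deterministically from the single run seed per
(stage, dataset), and rerunning with the same config and seed produces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

import metabiomark
from metabiomark._rng import child_int_seed
from metabiomark.coda_stats import LogRatioResult, assess_log_ratio
from metabiomark.consistency import (
    BiomarkerLedger,
    ConsistencyRules,
    consolidate,
    select_denominator,
    validate,
    write_ledger,
)
from metabiomark.data_model import (
    FeatureTable,
    SampleRecord,
    check_fmt_invariants,
    filter_by_prevalence,
    group_samples,
    read_feature_table,
    read_metadata,
)
from metabiomark.fmt_colonization import (
    EngraftmentProfile,
    classify_species_origin,
    donor_derived_table,
    variance_decomposition,
    write_engraftment_long,
)
from metabiomark.ranking import AssociationCall, DifferentialResult, call_top_k, fit_differentials

__all__ = [
    "DatasetEntry",
    "PipelineConfig",
    "StatsConfig",
    "load_config",
    "run_all",
    "run_discovery",
    "run_fmt",
    "run_validation",
    "write_differentials",
    "read_differentials",
]

log = logging.getLogger("metabiomark")


@dataclass
class DatasetEntry:
    name: str
    table: str
    metadata: str
    phase: str
    dialect: str = "generic_tsv"
    feature_kind: str = "taxon"

    def __post_init__(self) -> None:
        if self.phase not in {"discovery", "fmt", "validation"}:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class StatsConfig:
    n_permutations: int = 10_000
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PipelineConfig:
    datasets: list[DatasetEntry]
    rules: ConsistencyRules = field(default_factory=ConsistencyRules)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    output_dir: str = "out"
    min_prevalence: float = 0.1
    regularization: float = 0.1
    presence_threshold: float = 0.0

    def __post_init__(self) -> None:
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dataset names")
        n_group_comparison = len(self.by_phase("discovery")) + len(self.by_phase("fmt"))
        if n_group_comparison < 2:
            raise ValueError("consolidation requires >=2 discovery/FMT datasets")

    def by_phase(self, phase: str) -> list[DatasetEntry]:
        return [d for d in self.datasets if d.phase == phase]

    def top_k(self, feature_kind: str) -> int:
        return self.rules.top_k_taxa if feature_kind == "taxon" else self.rules.top_k_functions

    def to_dict(self) -> dict:
        return {
            "datasets": [asdict(d) for d in self.datasets],
            "rules": asdict(self.rules),
            "stats": asdict(self.stats),
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "min_prevalence": self.min_prevalence,
            "regularization": self.regularization,
            "presence_threshold": self.presence_threshold,
        }


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent
    datasets = []
    for d in raw.get("datasets", []):
        d = dict(d)
        for key in ("table", "metadata"):
            p = Path(d[key])
            d[key] = str(p if p.is_absolute() else base / p)
        datasets.append(DatasetEntry(**d))
    return PipelineConfig(
        datasets=datasets,
        rules=ConsistencyRules(**raw.get("rules", {})),
        stats=StatsConfig(**raw.get("stats", {})),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "out")),
        min_prevalence=float(raw.get("min_prevalence", 0.1)),
        regularization=float(raw.get("regularization", 0.1)),
        presence_threshold=float(raw.get("presence_threshold", 0.0)),
    )


# ---------------------------------------------------------------------------
# small IO helpers for inter-stage artifacts
# ---------------------------------------------------------------------------


def write_differentials(result: DifferentialResult, path: str | Path) -> None:
    rows = [
        {"feature_id": f, "differential": result.differentials[f], "rank": i + 1}
        for i, f in enumerate(result.rank_order)
    ]
    pd.DataFrame(rows, columns=["feature_id", "differential", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def read_differentials(path: str | Path, study: str = "") -> DifferentialResult:
    frame = pd.read_csv(path, sep="\t")
    differentials = dict(zip(frame["feature_id"], frame["differential"].astype(float)))
    rank_order = sorted(differentials, key=lambda f: (-differentials[f], f))
    return DifferentialResult(
        study=study or Path(path).stem,
        feature_ids=list(frame["feature_id"]),
        differentials=differentials,
        rank_order=rank_order,
    )


def write_calls(calls: Sequence[AssociationCall], path: str | Path) -> None:
    rows = [
        {"feature_id": c.feature_id, "study": c.study, "call": c.call}
        for c in calls
        if c.call != "none"
    ]
    rows.sort(key=lambda r: (r["study"], r["feature_id"]))
    pd.DataFrame(rows, columns=["feature_id", "study", "call"]).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[AssociationCall]:
    frame = pd.read_csv(path, sep="\t")
    return [AssociationCall(r["feature_id"], r["study"], r["call"]) for _, r in frame.iterrows()]


def _write_logratio(result: LogRatioResult, study: str, path: Path) -> None:
    rows = [
        {"sample_id": s, "log_ratio": v}
        for s, v in sorted(result.per_sample_log_ratio.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "log_ratio"]).to_csv(path, sep="\t", index=False)


def _logratio_stats_row(result: LogRatioResult, study: str) -> dict:
    return {
        "study": study,
        "test": result.test or "",
        "n_samples": len(result.per_sample_log_ratio),
        "n_dropped": result.n_dropped,
        "p_value": "" if result.group_p_value is None else result.group_p_value,
    }


def _load_dataset(entry: DatasetEntry) -> tuple[FeatureTable, list[SampleRecord]]:
    table = read_feature_table(entry.table, dialect=entry.dialect, feature_kind=entry.feature_kind)
    records = read_metadata(entry.metadata)
    return table, records


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _analyze_group_comparison(
    entry: DatasetEntry,
    table: FeatureTable,
    records: Sequence[SampleRecord],
    config: PipelineConfig,
) -> tuple[DifferentialResult, list[AssociationCall], LogRatioResult | None]:
    filtered = filter_by_prevalence(table, config.min_prevalence)
    seed = child_int_seed(config.seed, "rank", entry.name)
    result = fit_differentials(
        filtered,
        records,
        regularization=config.regularization,
        seed=seed,
        study=entry.name,
    )
    calls = call_top_k(result, config.top_k(entry.feature_kind))
    rmi = {c.feature_id for c in calls if c.call == "RMI"}
    umi = {c.feature_id for c in calls if c.call == "UMI"}
    logratio = None
    if rmi and umi:
        logratio = assess_log_ratio(filtered, rmi, umi, records)
    log.info(
        "stage=rank dataset=%s n_features=%d n_samples=%d converged=%s",
        entry.name,
        filtered.n_features,
        result.fit_info.get("n_samples"),
        result.fit_info.get("converged"),
    )
    return result, calls, logratio


def run_discovery(
    config: PipelineConfig, write: bool = True
) -> tuple[BiomarkerLedger, dict[str, DifferentialResult], dict[str, LogRatioResult]]:
    """Per-dataset ranking, top-k calling and log-ratio assessment, then
    cross-dataset consolidation of the discovery-phase calls."""
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    results: dict[str, DifferentialResult] = {}
    logratios: dict[str, LogRatioResult] = {}
    all_calls: list[AssociationCall] = []
    for entry in config.by_phase("discovery"):
        table, records = _load_dataset(entry)
        result, calls, logratio = _analyze_group_comparison(entry, table, records, config)
        results[entry.name] = result
        all_calls.extend(calls)
        if logratio is not None:
            logratios[entry.name] = logratio
        if write:
            write_differentials(result, out / f"differentials_{entry.name}.tsv")
            write_calls(calls, out / f"calls_{entry.name}.tsv")
            if logratio is not None:
                _write_logratio(logratio, entry.name, out / f"logratio_{entry.name}.tsv")
    ledger = _consolidate_both(all_calls, config.rules)
    if write:
        write_ledger(ledger, out / "ledger_discovery.tsv")
        _write_summary(config, out, stage="discovery")
    return ledger, results, logratios


def _consolidate_both(calls: Sequence[AssociationCall], rules: ConsistencyRules) -> BiomarkerLedger:
    ledger = consolidate(calls, rules, direction="RMI")
    umi = consolidate(calls, rules, direction="UMI")
    ledger.consolidated_umi = umi.consolidated_umi
    for feature, reason in umi.removed.items():
        ledger.removed.setdefault(feature, reason)
    return ledger


def run_fmt(
    config: PipelineConfig, write: bool = True
) -> tuple[
    list[AssociationCall],
    dict[str, DifferentialResult],
    dict[str, dict],
    dict[str, list[EngraftmentProfile]],
]:
    """Donor-derived species analysis for the FMT-phase datasets.

    Per dataset: classify species origin per post-FMT sample, build the
    donor-derived table, decompose its variance by donor and response, rank
    donor-derived profiles against response and emit top-k calls.
    """
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    all_calls: list[AssociationCall] = []
    results: dict[str, DifferentialResult] = {}
    variance: dict[str, dict] = {}
    profiles_by_study: dict[str, list[EngraftmentProfile]] = {}
    for entry in config.by_phase("fmt"):
        table, records = _load_dataset(entry)
        check_fmt_invariants(records)
        profiles = _classify_cohort(table, records, config.presence_threshold)
        profiles_by_study[entry.name] = profiles
        if not profiles:
            log.warning("stage=fmt dataset=%s has no classifiable post-FMT samples", entry.name)
            continue
        dd_table = donor_derived_table(profiles, feature_ids=table.feature_ids)
        dd_table.feature_annotations = dict(table.feature_annotations)

        try:
            variance[entry.name] = variance_decomposition(
                dd_table,
                records,
                factors=("donor", "response"),
                distance="aitchison",
                n_permutations=config.stats.n_permutations,
                seed=child_int_seed(config.seed, "permanova", entry.name),
                pseudocount=config.stats.pseudocount,
            )
        except ValueError as err:
            log.warning("stage=fmt dataset=%s variance decomposition skipped: %s", entry.name, err)

        try:
            filtered = filter_by_prevalence(dd_table, config.min_prevalence)
            result = fit_differentials(
                filtered,
                records,
                regularization=config.regularization,
                seed=child_int_seed(config.seed, "rank", entry.name),
                study=entry.name,
            )
            calls = call_top_k(result, config.top_k(entry.feature_kind))
        except ValueError as err:
            log.warning("stage=fmt dataset=%s donor-derived ranking skipped: %s", entry.name, err)
            result, calls = None, []
        if result is not None:
            results[entry.name] = result
        all_calls.extend(calls)
        if write:
            write_engraftment_long(profiles, out / f"engraftment_{entry.name}.tsv")
            if result is not None:
                write_differentials(result, out / f"differentials_{entry.name}.tsv")
                write_calls(calls, out / f"calls_{entry.name}.tsv")
            if entry.name in variance:
                _write_variance(variance[entry.name], out / f"variance_{entry.name}.tsv")
    if write:
        _write_summary(config, out, stage="fmt")
    return all_calls, results, variance, profiles_by_study


def _classify_cohort(
    table: FeatureTable, records: Sequence[SampleRecord], threshold: float
) -> list[EngraftmentProfile]:
    donors = group_samples(records, role="donor")
    donor_columns: dict[str, np.ndarray] = {}
    for subject in sorted({r.subject_id for r in donors}):
        cols = [table.column(r.sample_id) for r in donors if r.subject_id == subject]
        donor_columns[subject] = np.mean(cols, axis=0)

    recipients = group_samples(records, role="recipient")
    by_subject: dict[str, list[SampleRecord]] = {}
    for r in recipients:
        by_subject.setdefault(r.subject_id, []).append(r)

    profiles: list[EngraftmentProfile] = []
    for subject in sorted(by_subject):
        recs = by_subject[subject]
        baselines = [r for r in recs if r.is_baseline]
        posts = [r for r in recs if r.timepoint_days is not None and r.timepoint_days > 0]
        if not baselines:
            log.warning("recipient %s has no baseline; excluded", subject)
            continue
        donor_id = next((r.donor for r in recs if r.donor), None)
        if donor_id is None or donor_id not in donor_columns:
            log.warning("recipient %s has no donor profile; excluded", subject)
            continue
        # multiple pre-FMT baselines: their element-wise max defines presence
        baseline_col = np.max([table.column(r.sample_id) for r in baselines], axis=0)
        for r in sorted(posts, key=lambda r: (r.timepoint_days, r.sample_id)):
            profiles.append(
                classify_species_origin(
                    table.feature_ids,
                    donor_columns[donor_id],
                    baseline_col,
                    table.column(r.sample_id),
                    presence_threshold=threshold,
                    recipient=subject,
                    sample_id=r.sample_id,
                    donor=donor_id,
                    timepoint_days=r.timepoint_days,
                )
            )
    return profiles


def _write_variance(variance: dict, path: Path) -> None:
    rows = []
    for factor, entry in sorted(variance.items()):
        res = entry["permanova"]
        rows.append(
            {
                "factor": factor,
                "r_squared": res.r_squared,
                "pseudo_f": res.pseudo_f,
                "p_value": res.p_value,
                "p_adjusted": entry["p_adjusted"],
                "n_permutations": res.n_permutations,
            }
        )
    columns = ["factor", "r_squared", "pseudo_f", "p_value", "p_adjusted", "n_permutations"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def run_validation(
    config: PipelineConfig, ledger: BiomarkerLedger, write: bool = True
) -> tuple[BiomarkerLedger, dict[str, DifferentialResult], dict[str, LogRatioResult]]:
    """Validate the consolidated RMI set on the validation-phase datasets."""
    entries = config.by_phase("validation")
    if not entries:
        raise ValueError("at least one validation dataset required")
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    results: dict[str, DifferentialResult] = {}
    tables: dict[str, tuple[FeatureTable, list[SampleRecord]]] = {}
    for entry in entries:
        table, records = _load_dataset(entry)
        filtered = filter_by_prevalence(table, config.min_prevalence)
        result = fit_differentials(
            filtered,
            records,
            regularization=config.regularization,
            seed=child_int_seed(config.seed, "rank", entry.name),
            study=entry.name,
        )
        results[entry.name] = result
        tables[entry.name] = (filtered, records)
        if write:
            write_differentials(result, out / f"differentials_{entry.name}.tsv")

    validated = validate(ledger, list(results.values()), config.rules)
    logratios: dict[str, LogRatioResult] = {}
    if validated.validated_rmi:
        for entry in entries:
            result = results[entry.name]
            try:
                denominator = select_denominator(result, config.rules)
            except ValueError as err:
                log.warning("dataset=%s: %s", entry.name, err)
                continue
            numerator = set(validated.validated_rmi) - denominator
            if not numerator:
                continue
            filtered, records = tables[entry.name]
            try:
                logratios[entry.name] = assess_log_ratio(filtered, numerator, denominator, records)
            except ValueError as err:
                log.warning("dataset=%s log-ratio skipped: %s", entry.name, err)
    else:
        log.info("validated set is empty (a legitimate outcome)")

    if write:
        write_ledger(validated, out / "ledger_final.tsv")
        stats_rows = [_logratio_stats_row(lr, s) for s, lr in sorted(logratios.items())]
        pd.DataFrame(
            stats_rows, columns=["study", "test", "n_samples", "n_dropped", "p_value"]
        ).to_csv(out / "logratio_validation_tests.tsv", sep="\t", index=False)
        for s, lr in logratios.items():
            _write_logratio(lr, s, out / f"logratio_{s}.tsv")
        _write_summary(config, out, stage="validation")
    return validated, results, logratios


def run_all(config: PipelineConfig, write: bool = True) -> dict:
    """Full pipeline: discovery + FMT calls, one consolidation, validation.

    Discovery and FMT evidence enter a single consolidation by default,
    mirroring a two-group discovery design.
    """
    discovery_ledger, discovery_results, logratios = run_discovery(config, write=write)
    fmt_calls: list[AssociationCall] = []
    fmt_results: dict[str, DifferentialResult] = {}
    variance: dict[str, dict] = {}
    if config.by_phase("fmt"):
        fmt_calls, fmt_results, variance, _ = run_fmt(config, write=write)
    all_calls = list(discovery_ledger.calls) + fmt_calls
    ledger = _consolidate_both(all_calls, config.rules)
    final = ledger
    validation_results: dict[str, DifferentialResult] = {}
    validation_logratios: dict[str, LogRatioResult] = {}
    if config.by_phase("validation"):
        final, validation_results, validation_logratios = run_validation(
            config, ledger, write=write
        )
    if write:
        out = Path(config.output_dir)
        write_ledger(final, out / "ledger_final.tsv")
        _write_summary(config, out, stage="all")
    return {
        "ledger": final,
        "discovery_results": discovery_results,
        "fmt_results": fmt_results,
        "validation_results": validation_results,
        "variance": variance,
        "logratios": {**logratios, **validation_logratios},
    }


def _write_summary(config: PipelineConfig, out: Path, stage: str) -> None:
    summary = {
        "tool": "metabiomark",
        "version": metabiomark.__version__,
        "stage": stage,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
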