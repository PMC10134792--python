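import math

import numpy as np
import pytest

from metabiomark.data_model import FeatureTable, SampleRecord
from metabiomark.synthetic_data import PlantedEffect, generate_case_control_study


@pytest.fixture
def toy_table() -> FeatureTable:
    """3 features x 2 samples with simple integer values."""
    return FeatureTable(
        np.array([[1.0, 2.0], [0.0, 5.0], [3.0, 3.0]]),
        ["fA", "fB", "fC"],
        ["s1", "s2"],
    )


@pytest.fixture
def generic_tsv(tmp_path):
    path = tmp_path / "table.tsv"
    path.write_text(
        "feature_id\ts1\ts2\n" "fA\t1\t2\n" "fB\t0\t5\n" "fC\t3\t3\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture
def metaphlan_tsv(tmp_path):
    path = tmp_path / "merged.tsv"
    lines = [
        "#mpa_v30 merged table",
        "clade_name\ts1\ts2",
        "k__Bacteria\t100\t100",
        "k__Bacteria|p__Firmicutes\t60\t70",
        "k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Ruminococcaceae|g__Faecalibacterium\t40\t50",
        "k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Ruminococcaceae|g__Faecalibacterium|s__Faecalibacterium_prausnitzii\t40\t50",
        "k__Bacteria|p__Bacteroidetes|c__Bacteroidia|o__Bacteroidales|f__Bacteroidaceae|g__Bacteroides|s__Bacteroides_ovatus\t20\t10",
        "k__Bacteria|p__Actinobacteria|c__Actinomycetia|o__Bifidobacteriales|f__Bifidobacteriaceae|g__Bifidobacterium|s__Bifidobacterium_longum\t0\t20",
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def planted_study():
    """Small case-control study with one strong planted effect."""
    effect = PlantedEffect("sp0001", math.log(4.0), frozenset({"study1"}))
    table, records, truth = generate_case_control_study(
        30, 30, 60, [effect], depth_mean=8000, seed=11
    )
    return table, records, truth


def make_records(sample_ids, responses, study="x") -> list[SampleRecord]:
    return [
        SampleRecord(sample_id=s, study=study, response=r)
        for s, r in zip(sample_ids, responses)
    ]
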