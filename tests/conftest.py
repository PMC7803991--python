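import numpy as np
import pandas as pd
import pytest

import gcnqsar as g

_ROW_DEFAULTS = dict(
    compound_id="CPD",
    smiles="CCO",
    standard_type="IC50",
    standard_value=100.0,
    standard_units="nM",
    standard_relation="=",
    assay_type="B",
    confidence_score=9,
    activity_comment="",
    potential_duplicates=0,
    data_validity_comment="",
    target_id="T1",
)


def make_row(**overrides) -> dict:
    row = dict(_ROW_DEFAULTS)
    row.update(overrides)
    return row


@pytest.fixture
def twelve_row_table() -> pd.DataFrame:
    """Hand-built raw table: 2 low-confidence, 1 wrong-units, 1 inconclusive,
    1 duplicate-flagged, and 7 clean rows (two of which share phenol/T1)."""
    rows = [
        make_row(compound_id="c1", smiles="CCO", standard_value=10.0),
        make_row(compound_id="c2", smiles="CCN", standard_value=50.0),
        make_row(compound_id="c3", smiles="c1ccccc1O", standard_value=20.0),
        make_row(compound_id="c4", smiles="c1ccccc1O", standard_value=5.0),
        make_row(compound_id="c5", smiles="CCCl", standard_value=300.0),
        make_row(compound_id="c6", smiles="CC(C)O", standard_value=1.0),
        make_row(compound_id="c7", smiles="CCC=O", standard_value=9000.0),
        make_row(compound_id="x1", smiles="CCBr", confidence_score=5),
        make_row(compound_id="x2", smiles="CCI", confidence_score=3),
        make_row(compound_id="x3", smiles="CCF", standard_units="ug.mL-1"),
        make_row(compound_id="x4", smiles="CCCC", activity_comment="Inconclusive"),
        make_row(compound_id="x5", smiles="CCCCC", potential_duplicates=1),
    ]
    return pd.DataFrame(rows)


def featurized(df):
    return (
        g.featurize_many(df["canonical_smiles"]),
        df["p_activity"].to_numpy(dtype=float),
    )


@pytest.fixture(scope="session")
def tiny_sets():
    """Small planted-SAR dataset, curated, split and featurized once."""
    spec = g.SARSpec(n=160, seed=7, noise_sd=0.2)
    curated, _ = g.build_dataset(g.generate_activity_table(spec))
    split = g.split_dataset(curated, seed=11)
    return {
        "train": featurized(split.train),
        "valid": featurized(split.valid),
        "test": featurized(split.test),
    }


@pytest.fixture(scope="session")
def tiny_models(tiny_sets):
    """Three small trained networks over the same data (ensemble material)."""
    models = []
    for seed, conv in ((0, 24), (1, 32), (2, 48)):
        cfg = g.GCNConfig(conv_size=conv, dense_size=conv, batch_size=40, seed=seed)
        model, _ = g.train_fixed_epochs(tiny_sets["train"], tiny_sets["valid"], cfg, 25)
        models.append(model)
    return models


@pytest.fixture(scope="session")
def skeleton_scheme():
    """15-bin desk-scale binning scheme over 150 enumerated carbon skeletons."""
    return g.build_binning(g.enumerate_carbon_skeletons(150), capacity=10)
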