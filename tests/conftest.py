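import numpy as np
import pandas as pd
import pytest

from stromascape import (
    ExpressionMatrix,
    SyntheticConfig,
    generate_compartment_dataset,
    normalize_by_housekeeping,
)
from stromascape.simulate import FactorSpec


def make_matrix(values: np.ndarray, probe_ids, sample_ids, compartments,
                reference=None, symbols=None) -> ExpressionMatrix:
    """Hand-build a small ExpressionMatrix for unit tests."""
    meta = pd.DataFrame(
        {
            "tumor_id": [s.split("_")[0] for s in sample_ids],
            "compartment": compartments,
            "is_reference": [s == reference for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    anno = None
    if symbols is not None:
        anno = pd.Series(symbols, index=probe_ids, name="symbol")
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        sample_meta=meta,
        probe_anno=anno,
    )


@pytest.fixture
def toy_paired():
    """Two tumors x two compartments, three probes plus housekeeping."""
    values = np.array(
        [
            [200.0, 400.0, 20.0, 40.0],   # stroma-specific gene
            [50.0, 100.0, 50.0, 100.0],   # balanced gene
            [10.0, 20.0, 100.0, 200.0],   # epithelium-specific gene
            [500.0, 1000.0, 500.0, 1000.0],  # housekeeping
        ]
    )
    return make_matrix(
        values,
        ["pS", "pB", "pE", "HK"],
        ["T01_str", "T02_str", "T01_epi", "T02_epi"],
        ["stroma", "stroma", "epithelium", "epithelium"],
        reference="T01_str",
        symbols=["GS", "GB", "GE", "GAPDH"],
    )


@pytest.fixture
def small_synthetic():
    """Seeded small-scale synthetic paired dataset with ground truth."""
    cfg = SyntheticConfig(
        n_probes=400,
        factors=[
            FactorSpec(name="CAFG", anchor_symbol="SPARC", n_member_probes=20,
                       planted_cse=12.0, anchor_cse=12.0, anchor_amount=300.0,
                       n_low_cse_decoys=4, n_low_amount_decoys=4,
                       member_symbols=("COL8A1", "COL5A2", "TAGLN", "PLAT")),
            FactorSpec(name="CTLG", anchor_symbol="CD8A", n_member_probes=10,
                       planted_cse=12.0, anchor_cse=4.7, anchor_amount=80.0),
        ],
        seed=11,
    )
    expr, truth = generate_compartment_dataset(cfg)
    return cfg, expr, truth


@pytest.fixture
def small_normalized(small_synthetic):
    cfg, expr, truth = small_synthetic
    return cfg, normalize_by_housekeeping(expr, cfg.housekeeping_probe), truth
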