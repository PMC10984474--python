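"""Probe-level expression tables and housekeeping normalization.

Expression values are raw microarray signal intensities laid out probes x
samples, with a sample-metadata table (tumor id, compartment, reference flag)
and an optional probe -> gene-symbol annotation.  Normalization follows the
single-housekeeping-probe convention: each sample's signals are expressed as
``100 * signal / housekeeping signal`` of the same sample, so the
housekeeping probe itself reads 100 everywhere and the unit is
"signal/GAPDH x 100".

Input dialect is plain TSV in the shape of a GEO series-matrix value block
(probe ids in column 1, sample ids in the header row); use standard GEO fetch
tools to produce it from SOFT/series-matrix files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

VALID_COMPARTMENTS = frozenset({"stroma", "epithelium", "bulk"})

META_COLUMNS = ("tumor_id", "compartment", "is_reference")


@dataclass
class ExpressionMatrix:
    """Probe x sample signal table with sample metadata and probe annotation.

    Parameters
    ----------
    values
        DataFrame of non-negative intensities, index = probe ids,
        columns = sample ids.
    sample_meta
        DataFrame indexed by sample id with columns ``tumor_id``,
        ``compartment`` (stroma / epithelium / bulk) and ``is_reference``.
    probe_anno
        Optional Series mapping probe id -> gene symbol (NaN allowed for
        unannotated probes).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    probe_anno: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if not v.index.is_unique:
            dup = v.index[v.index.duplicated()].tolist()
            raise FormatError(f"duplicate probe ids: {dup[:5]}")
        if not v.columns.is_unique:
            dup = v.columns[v.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValueError("missing values in the expression block are not allowed")
        if (arr < 0).any():
            raise ValueError("negative signal intensities are not allowed")

        meta = self.sample_meta
        missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise FormatError(f"sample metadata lacks columns: {missing_cols}")
        absent = [s for s in v.columns if s not in meta.index]
        if absent:
            raise FormatError(f"samples missing from metadata: {absent[:5]}")
        bad = set(meta["compartment"]) - VALID_COMPARTMENTS
        if bad:
            raise ValueError(f"unknown compartments: {sorted(bad)}")
        for comp, sub in meta.groupby("compartment"):
            if int(sub["is_reference"].sum()) > 1:
                raise FormatError(f"more than one reference sample in {comp}")
        if self.probe_anno is not None:
            # keep only probes present in the matrix, in matrix order
            self.probe_anno = self.probe_anno.reindex(v.index)

    # -- accessors -------------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, compartment: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.values.columns)]
        return list(meta.index[meta["compartment"] == compartment])

    def reference_sample(self, compartment: str = "stroma") -> str:
        meta = self.sample_meta.loc[list(self.values.columns)]
        mask = (meta["compartment"] == compartment) & meta["is_reference"].astype(bool)
        hits = list(meta.index[mask])
        if not hits:
            raise ConfigurationError(f"no reference sample flagged in {compartment}")
        return hits[0]

    def symbol_of(self, probe: str):
        if self.probe_anno is None:
            return None
        return self.probe_anno.get(probe)

    def probes_of(self, symbol: str) -> list[str]:
        if self.probe_anno is None:
            raise KeyError("no probe annotation attached")
        hits = self.probe_anno[self.probe_anno == symbol]
        if hits.empty:
            raise KeyError(f"unknown symbol: {symbol!r}")
        return sorted(hits.index)


@dataclass
class NormalizedMatrix(ExpressionMatrix):
    """Housekeeping-normalized matrix; unit is 100 x signal / housekeeping."""

    housekeeping_probe: str = field(default="")

    def validate(self) -> None:
        super().validate()
        if self.housekeeping_probe and self.housekeeping_probe not in self.values.index:
            raise KeyError(f"housekeeping probe {self.housekeeping_probe!r} not in matrix")


def normalize_by_housekeeping(
    m: ExpressionMatrix, hk_probe: str, log2_input: bool = False
) -> NormalizedMatrix:
    """Scale every sample so the housekeeping probe reads 100.

    value(p, s) = 100 * signal(p, s) / signal(hk_probe, s).

    ``log2_input=True`` exponentiates (base 2) before normalizing, for tables
    distributed on a log2 scale; default treats inputs as linear.
    """
    if hk_probe not in m.values.index:
        raise KeyError(f"housekeeping probe {hk_probe!r} not in matrix")
    values = m.values.astype(float)
    if log2_input:
        values = np.exp2(values)
    hk = values.loc[hk_probe]
    bad = list(hk.index[hk <= 0])
    if bad:
        raise DegenerateInputError(
            f"housekeeping signal non-positive in sample(s) {bad[:5]}"
        )
    norm = 100.0 * values.div(hk, axis=1)
    return NormalizedMatrix(
        values=norm,
        sample_meta=m.sample_meta.copy(),
        probe_anno=None if m.probe_anno is None else m.probe_anno.copy(),
        housekeeping_probe=hk_probe,
    )


# -- file I/O ------------------------------------------------------------


def load_expression_table(
    path, meta_path, anno_path=None
) -> ExpressionMatrix:
    """Read a probes-x-samples TSV plus a sample-metadata TSV (and optionally
    a probe annotation TSV with columns probe_id, symbol)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if not values.index.is_unique:
        raise FormatError("duplicate probe ids in expression table")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if "is_reference" in meta.columns:
        meta["is_reference"] = meta["is_reference"].astype(bool)
    anno = load_probe_annotation(anno_path) if anno_path is not None else None
    return ExpressionMatrix(values=values, sample_meta=meta, probe_anno=anno)


def load_probe_annotation(path) -> pd.Series:
    anno = pd.read_csv(path, sep="\t", index_col=0)
    anno.index = anno.index.astype(str)
    if "symbol" not in anno.columns:
        raise FormatError("annotation table needs a 'symbol' column")
    return anno["symbol"]


def write_expression_table(m: ExpressionMatrix, path, meta_path=None, anno_path=None) -> None:
    df = m.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")
    if meta_path is not None:
        meta = m.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")
    if anno_path is not None and m.probe_anno is not None:
        anno = m.probe_anno.rename("symbol").to_frame()
        anno.index.name = "probe_id"
        anno.to_csv(anno_path, sep="\t")


COHORT_CLINICAL_COLUMNS = ("time_months", "event", "age", "sex", "T_stage", "N_stage", "M_stage")


def load_survival_cohort(path) -> pd.DataFrame:
    """Read a cohort TSV: patient_id, time_months, event, clinical covariates,
    then one expression column per gene."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "time_months" not in df.columns or "event" not in df.columns:
        raise FormatError("cohort table needs time_months and event columns")
    if (df["time_months"] < 0).any():
        raise ValueError("negative follow-up times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return df


def write_survival_cohort(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t")


def cohort_gene_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in COHORT_CLINICAL_COLUMNS]
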