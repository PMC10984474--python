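"""Cancer-stroma / epithelium compartment specificity (cS/E) profiling.

For each probe of a housekeeping-normalized paired compartment dataset this
module computes the mean normalized expression in the stromal and epithelial
compartments, their ratio (the cS/E ratio), a three-level specificity class,
and the expression amount in the designated reference stromal sample (the
role the study cohort's reference case plays for abundance filtering).

Class boundaries are inclusive exactly as stated for the profiling rule:
High when cS/E >= 10, Middle when 5 <= cS/E < 10, Low when cS/E < 5.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import NormalizedMatrix

logger = logging.getLogger(__name__)

CSE_HIGH_MIN = 10.0
CSE_MIDDLE_MIN = 5.0

#: ordering used by monotonicity checks
CSE_CLASS_ORDER = {"Low": 0, "Middle": 1, "High": 2}


def classify_cse(r: float) -> str:
    """Map a cS/E ratio to High / Middle / Low (boundaries inclusive below)."""
    if not math.isfinite(r):
        raise ValueError(f"cS/E ratio must be finite, got {r}")
    if r < 0:
        raise ValueError(f"cS/E ratio must be >= 0, got {r}")
    if r >= CSE_HIGH_MIN:
        return "High"
    if r >= CSE_MIDDLE_MIN:
        return "Middle"
    return "Low"


def expression_amount(nm: NormalizedMatrix, probe: str) -> float:
    """Normalized expression of ``probe`` in the reference stromal sample."""
    ref = nm.reference_sample("stroma")  # ConfigurationError if none flagged
    return float(nm.values.at[probe, ref])


def compute_cse(nm: NormalizedMatrix, mode: str = "ratio-of-means") -> pd.DataFrame:
    """Per-probe compartment profile.

    Returns a DataFrame indexed by probe id with columns ``symbol``,
    ``mean_stroma``, ``mean_epi``, ``cse_ratio``, ``cse_class``,
    ``amount_ref`` and ``excluded``.

    mode
        ``ratio-of-means`` (default): cS/E = mean over stromal samples /
        mean over epithelial samples.  ``mean-of-ratios``: per-tumor ratio of
        compartment means, averaged across tumors.

    Probes with a zero epithelial mean get ``cse_ratio = +inf`` and
    ``excluded = True`` (they would trivially pass any specificity threshold);
    they are reported, logged, and skipped by signature filters.
    """
    stroma = nm.samples_in("stroma")
    epi = nm.samples_in("epithelium")
    if not epi:
        raise ConfigurationError("no epithelium samples in the dataset")
    if not stroma:
        raise ConfigurationError("no stroma samples in the dataset")
    ref = nm.reference_sample("stroma")

    mean_stroma = nm.values[stroma].mean(axis=1)
    mean_epi = nm.values[epi].mean(axis=1)

    if mode == "ratio-of-means":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mean_stroma.to_numpy() / mean_epi.to_numpy()
        ratio = np.where(mean_epi.to_numpy() == 0,
                         np.where(mean_stroma.to_numpy() == 0, np.nan, np.inf),
                         ratio)
    elif mode == "mean-of-ratios":
        meta = nm.sample_meta
        per_tumor = []
        tumors = sorted(set(meta.loc[stroma, "tumor_id"]) & set(meta.loc[epi, "tumor_id"]))
        if not tumors:
            raise ConfigurationError("no tumor has both compartments")
        for t in tumors:
            s_cols = [s for s in stroma if meta.at[s, "tumor_id"] == t]
            e_cols = [s for s in epi if meta.at[s, "tumor_id"] == t]
            ms = nm.values[s_cols].mean(axis=1).to_numpy()
            me = nm.values[e_cols].mean(axis=1).to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                rt = ms / me
            rt = np.where(me == 0, np.where(ms == 0, np.nan, np.inf), rt)
            per_tumor.append(rt)
        ratio = np.mean(np.stack(per_tumor, axis=0), axis=0)
    else:
        raise ConfigurationError(f"unknown cse mode: {mode!r}")

    excluded = ~np.isfinite(ratio)
    n_excl = int(excluded.sum())
    if n_excl:
        logger.warning("%d probe(s) with zero epithelial mean excluded from cS/E filters", n_excl)

    classes = np.select(
        [excluded, ratio >= CSE_HIGH_MIN, ratio >= CSE_MIDDLE_MIN],
        [None, "High", "Middle"],
        default="Low",
    )

    out = pd.DataFrame(
        {
            "symbol": nm.probe_anno.reindex(nm.values.index)
            if nm.probe_anno is not None
            else pd.Series(pd.NA, index=nm.values.index),
            "mean_stroma": mean_stroma,
            "mean_epi": mean_epi,
            "cse_ratio": ratio,
            "cse_class": classes,
            "amount_ref": nm.values[ref],
            "excluded": excluded,
        },
        index=nm.values.index,
    )
    out.index.name = "probe_id"
    return out


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t")
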