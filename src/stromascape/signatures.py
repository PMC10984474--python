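"""Anchor-marker co-expression signatures (the R-index rule).

A tumor-microenvironment signature is derived from one anchor marker gene
(e.g. SPARC for cancer-associated fibroblasts, PECAM1 for tumor-associated
endothelia): every probe whose normalized expression across the stromal
samples correlates with the anchor probe at R >= r_min, whose cS/E ratio is
>= cse_min, and whose expression amount in the reference stromal sample is
>= amount_min, is a member.  All three filters are inclusive.  Probe-level
members are collapsed to unique gene symbols ordered by abundance, from
which a top-n set can be taken for prognostic screening.

The "R index" is the Pearson correlation coefficient over stromal samples
of the normalized linear values; Spearman is offered as an alternative for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .compartments import classify_cse, expression_amount
from .errors import ConfigurationError, DegenerateInputError
from .io import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureThresholds:
    """Inclusive membership filters: R >= r_min, cS/E >= cse_min,
    reference-sample amount >= amount_min."""

    r_min: float = 0.9
    cse_min: float = 10.0
    amount_min: float = 40.0

    def __post_init__(self):
        if self.cse_min <= 0 or self.amount_min < 0:
            raise ConfigurationError("thresholds must be positive")


MEMBER_COLUMNS = ("symbol", "r_value", "cse_ratio", "amount_ref")


@dataclass
class SignatureDefinition:
    """One derived signature: anchor, thresholds, and the member table
    (indexed by probe id, sorted by reference amount descending)."""

    name: str
    anchor_symbol: str
    anchor_probe: str
    thresholds: SignatureThresholds
    members: pd.DataFrame
    n_correlated_probes: int = 0  # probes with R >= r_min regardless of cS/E or amount
    anchor_cse_ratio: float = float("nan")
    anchor_cse_class: str | None = None

    @property
    def member_probes(self) -> list[str]:
        return list(self.members.index)

    @property
    def member_symbols(self) -> list[str]:
        return collapse_to_symbols(self)

    def __len__(self) -> int:
        return len(self.members)


def compute_r_index(
    nm: NormalizedMatrix,
    anchor_probe: str,
    compartment: str = "stroma",
    method: str = "pearson",
) -> pd.Series:
    """Correlation of every probe against the anchor probe across the
    samples of one compartment.  Zero-variance probes get NaN (excluded
    from signatures); a zero-variance anchor is an error."""
    cols = nm.samples_in(compartment)
    if len(cols) < 3:
        raise DegenerateInputError(
            f"need >= 3 {compartment} samples for correlation, have {len(cols)}"
        )
    if anchor_probe not in nm.values.index:
        raise KeyError(f"anchor probe {anchor_probe!r} not in matrix")
    X = nm.values[cols].to_numpy(dtype=float)
    if method == "spearman":
        X = rankdata(X, axis=1)
    elif method != "pearson":
        raise ConfigurationError(f"unknown correlation method: {method!r}")
    a = X[nm.values.index.get_loc(anchor_probe)]
    a_c = a - a.mean()
    a_norm = np.sqrt((a_c**2).sum())
    # variance below ~1e-10 relative to the row scale is numerically constant
    if a_norm <= 1e-10 * max(np.abs(a).max(), 1e-300):
        raise DegenerateInputError(f"anchor probe {anchor_probe!r} has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    scale = np.maximum(np.abs(X).max(axis=1), 1e-300)
    zero_var = norms <= 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ a_c) / (norms * a_norm)
    r[zero_var] = np.nan
    return pd.Series(np.clip(r, -1.0, 1.0), index=nm.values.index, name="r_value")


def choose_anchor_probe(nm: NormalizedMatrix, symbol: str) -> str:
    """The probe of ``symbol`` with the largest reference-sample amount;
    ties broken by lexicographic probe id."""
    probes = nm.probes_of(symbol)  # KeyError on unknown symbol
    amounts = {p: expression_amount(nm, p) for p in probes}
    return min(probes, key=lambda p: (-amounts[p], p))


def derive_signature(
    nm: NormalizedMatrix,
    profiles: pd.DataFrame,
    anchor_symbol: str,
    thresholds: SignatureThresholds = SignatureThresholds(),
    name: str | None = None,
    method: str = "pearson",
) -> SignatureDefinition:
    """Apply the three inclusive filters against the chosen anchor probe.

    The anchor itself is a member only if it passes its own cS/E and amount
    filters; an anchor failing them (e.g. a low-specificity immune marker)
    is allowed with a warning, since the anchor merely defines the axis.
    """
    anchor_probe = choose_anchor_probe(nm, anchor_symbol)
    r = compute_r_index(nm, anchor_probe, method=method)
    prof = profiles.reindex(nm.values.index)

    anchor_cse = float(prof.at[anchor_probe, "cse_ratio"])
    if not (anchor_cse >= thresholds.cse_min):
        logger.warning(
            "anchor %s (%s) fails its own cS/E filter (%.3g < %g); it defines "
            "the axis but is not a member",
            anchor_symbol, anchor_probe, anchor_cse, thresholds.cse_min,
        )

    finite = np.isfinite(prof["cse_ratio"].to_numpy()) & ~prof["excluded"].to_numpy(dtype=bool)
    mask = (
        (r >= thresholds.r_min).to_numpy()
        & finite
        & (prof["cse_ratio"].to_numpy() >= thresholds.cse_min)
        & (prof["amount_ref"].to_numpy() >= thresholds.amount_min)
    )
    members = prof.loc[mask, ["symbol", "cse_ratio", "amount_ref"]].copy()
    members["r_value"] = r[mask]
    members = members[["symbol", "r_value", "cse_ratio", "amount_ref"]]
    # deterministic: amount desc, then probe id asc
    order = sorted(members.index, key=lambda p: (-members.at[p, "amount_ref"], p))
    members = members.loc[order]

    return SignatureDefinition(
        name=name or anchor_symbol,
        anchor_symbol=anchor_symbol,
        anchor_probe=anchor_probe,
        thresholds=thresholds,
        members=members,
        n_correlated_probes=int((r >= thresholds.r_min).sum()),
        anchor_cse_ratio=anchor_cse,
        anchor_cse_class=classify_cse(anchor_cse) if np.isfinite(anchor_cse) else None,
    )


def collapse_to_symbols(sig: SignatureDefinition) -> list[str]:
    """Unique member symbols ordered by each symbol's maximum probe amount,
    descending (ties by symbol).  Probes without a symbol are dropped."""
    members = sig.members
    has_symbol = members["symbol"].notna()
    n_dropped = int((~has_symbol).sum())
    if n_dropped:
        logger.info("collapse_to_symbols: dropped %d probe(s) without symbol", n_dropped)
    sub = members.loc[has_symbol]
    if sub.empty:
        return []
    best = sub.groupby("symbol")["amount_ref"].max()
    return sorted(best.index, key=lambda s: (-best[s], s))


def select_top_by_amount(symbols: list[str], n: int) -> list[str]:
    """First min(n, len) symbols of an abundance-ordered list."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return list(symbols[:n])


@dataclass
class OverlapTable:
    """Per-symbol membership flags across signatures, with a CAF-signature
    subclass: fibrosis (collagen-family & configured additions), non_fibrosis,
    or not_CAFG."""

    table: pd.DataFrame
    pairwise_counts: pd.DataFrame
    cafg_name: str | None = None


DEFAULT_FIBROSIS_EXTRA = frozenset({"SPARC", "TAGLN"})


def is_fibrosis_symbol(symbol: str, extra: frozenset = DEFAULT_FIBROSIS_EXTRA) -> bool:
    return str(symbol).startswith("COL") or symbol in extra


def intersect_signatures(
    sigs: list[SignatureDefinition],
    fibrosis_set: frozenset = DEFAULT_FIBROSIS_EXTRA,
    cafg_name: str | None = None,
) -> OverlapTable:
    """Membership flags of every symbol across >= 2 signatures, pairwise
    overlap counts, and (when a CAF signature is designated) the
    fibrosis / non-fibrosis subclassification of its members."""
    if len(sigs) < 2:
        raise ValueError("need at least two signatures to intersect")
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise ValueError("signature names must be unique")
    symbol_sets = {s.name: set(collapse_to_symbols(s)) for s in sigs}
    universe = sorted(set().union(*symbol_sets.values()))
    table = pd.DataFrame(
        {name: [sym in symbol_sets[name] for sym in universe] for name in names},
        index=pd.Index(universe, name="symbol"),
    )
    counts = pd.DataFrame(
        [[len(symbol_sets[a] & symbol_sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    if cafg_name is not None:
        if cafg_name not in names:
            raise ConfigurationError(f"no signature named {cafg_name!r} for subclassing")
        caf = symbol_sets[cafg_name]
        table["subclass"] = [
            ("fibrosis" if is_fibrosis_symbol(sym, fibrosis_set) else "non_fibrosis")
            if sym in caf
            else "not_CAFG"
            for sym in universe
        ]
    return OverlapTable(table=table, pairwise_counts=counts, cafg_name=cafg_name)
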