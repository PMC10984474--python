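"""Full-study orchestration: normalize -> cS/E -> signatures -> overlaps ->
prognosis -> report.

Signatures are derived on the paired compartment dataset; prognostic
evaluation runs on the bulk survival cohort; the two are bridged by gene
symbol (the only identity shared across array platforms).  The report
bundles, per signature: member counts at probe and symbol level, the count
of probes correlated with the anchor at R >= r_min regardless of the other
filters, the anchor's own cS/E class, the symbol-level overlap table with
fibrosis subclassing, per-gene prognostic results ranked by AUC, and any
configured two-gene combined stratifications, together with a manifest
(config, seed, package versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compartments import compute_cse
from .io import ExpressionMatrix, cohort_gene_columns, normalize_by_housekeeping
from .prognosis import (
    combined_stratification,
    evaluate_gene,
    rank_by_auc,
    results_table,
)
from .signatures import (
    DEFAULT_FIBROSIS_EXTRA,
    SignatureDefinition,
    SignatureThresholds,
    collapse_to_symbols,
    derive_signature,
    intersect_signatures,
    select_top_by_amount,
)

logger = logging.getLogger(__name__)

DEFAULT_MARKER_PANEL: tuple[tuple[str, str], ...] = (
    ("CAFG", "SPARC"),
    ("TAEG", "PECAM1"),
    ("CTLG", "CD8A"),
    ("TAMCG", "CD14"),
    ("CD3TILG", "CD3G"),
    ("fMDSCG", "ARG1"),
    ("iMDSCG", "CD33"),
    ("TregG", "FOXP3"),
    ("BTILG", "MS4A1"),
    ("TANG", "S100A9"),
)


@dataclass
class RunConfig:
    """Everything a full run needs besides the two datasets themselves."""

    marker_panel: tuple[tuple[str, str], ...] = DEFAULT_MARKER_PANEL
    thresholds: SignatureThresholds = field(default_factory=SignatureThresholds)
    top_n: int = 76
    alpha: float = 0.05
    hk_probe: str = "HK_GAPDH"
    cse_mode: str = "ratio-of-means"
    cutoff_mode: str = "youden"
    correlation_method: str = "pearson"
    cafg_name: str | None = "CAFG"
    fibrosis_extra: tuple[str, ...] = tuple(sorted(DEFAULT_FIBROSIS_EXTRA))
    combos: tuple[tuple[str, str], ...] = ()
    log2_input: bool = False
    seed: int | None = None

    def validate(self) -> None:
        anchors = [a for _, a in self.marker_panel]
        if len(set(anchors)) != len(anchors):
            raise ValueError("marker anchors must be unique")
        if self.top_n < 0:
            raise ValueError("top_n must be >= 0")


@dataclass
class PipelineReport:
    config: RunConfig
    profiles: pd.DataFrame
    signatures: dict[str, SignatureDefinition]
    skipped_markers: dict[str, str]
    top_symbols: dict[str, list[str]]
    overlap: "object | None"
    prognosis: pd.DataFrame | None
    combos: dict[str, dict]
    manifest: dict

    def summary(self) -> dict:
        """JSON-ready digest: counts, rankings, survival results."""
        sig_summ = {}
        for name, sig in self.signatures.items():
            sig_summ[name] = {
                "anchor_symbol": sig.anchor_symbol,
                "anchor_probe": sig.anchor_probe,
                "anchor_cse_ratio": round(float(sig.anchor_cse_ratio), 4),
                "anchor_cse_class": sig.anchor_cse_class,
                "n_member_probes": len(sig.members),
                "n_member_symbols": len(collapse_to_symbols(sig)),
                "n_correlated_probes": sig.n_correlated_probes,
                "n_top_selected": len(self.top_symbols.get(name, [])),
            }
        out = {
            "signatures": sig_summ,
            "skipped_markers": self.skipped_markers,
            "manifest": self.manifest,
        }
        if self.overlap is not None:
            out["overlap_pairwise_counts"] = self.overlap.pairwise_counts.to_dict()
            if "subclass" in self.overlap.table.columns:
                out["subclass_counts"] = (
                    self.overlap.table["subclass"].value_counts().to_dict()
                )
        if self.prognosis is not None:
            prog = self.prognosis
            out["prognosis"] = {
                "n_genes": int(len(prog)),
                "n_negative": int((prog["direction"] == "negative").sum()),
                "n_positive": int((prog["direction"] == "positive").sum()),
                "n_ns": int((prog["direction"] == "ns").sum()),
                "auc_ranking": list(prog.index),
            }
        if self.combos:
            out["combined_stratification"] = self.combos
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=1, default=str)
        self.profiles.to_csv(outdir / "compartment_profiles.tsv", sep="\t")
        for name, sig in self.signatures.items():
            sig.members.to_csv(outdir / f"signature_{name}.tsv", sep="\t")
        if self.overlap is not None:
            self.overlap.table.to_csv(outdir / "overlap.tsv", sep="\t")
        if self.prognosis is not None:
            self.prognosis.to_csv(outdir / "prognosis.tsv", sep="\t")


def run_full_pipeline(
    expr: ExpressionMatrix,
    cohort: pd.DataFrame | None,
    cfg: RunConfig = RunConfig(),
) -> PipelineReport:
    """Execute the whole workflow on in-memory inputs.

    ``cohort`` may be None to run the compartment-side derivation alone.
    Markers whose anchor symbol is absent from the compartment annotation
    are recorded as skipped rather than aborting the run.
    """
    cfg.validate()
    nm = normalize_by_housekeeping(expr, cfg.hk_probe, log2_input=cfg.log2_input)
    profiles = compute_cse(nm, mode=cfg.cse_mode)

    signatures: dict[str, SignatureDefinition] = {}
    skipped: dict[str, str] = {}
    top_symbols: dict[str, list[str]] = {}
    for name, anchor in cfg.marker_panel:
        try:
            sig = derive_signature(
                nm, profiles, anchor, cfg.thresholds, name=name,
                method=cfg.correlation_method,
            )
        except KeyError as err:
            logger.warning("marker %s skipped: %s", name, err)
            skipped[name] = str(err)
            continue
        signatures[name] = sig
        top_symbols[name] = select_top_by_amount(collapse_to_symbols(sig), cfg.top_n)

    overlap = None
    if len(signatures) >= 2:
        cafg = cfg.cafg_name if cfg.cafg_name in signatures else None
        overlap = intersect_signatures(
            list(signatures.values()),
            fibrosis_set=frozenset(cfg.fibrosis_extra),
            cafg_name=cafg,
        )

    prognosis_df = None
    combos: dict[str, dict] = {}
    if cohort is not None:
        genes = set()
        for syms in top_symbols.values():
            genes.update(syms)
        for sig in signatures.values():
            genes.add(sig.anchor_symbol)
        available = [g for g in sorted(genes) if g in cohort.columns]
        missing = sorted(genes - set(available))
        if missing:
            logger.info("%d signature symbols absent from the cohort", len(missing))
        t, e = cohort["time_months"], cohort["event"]
        results = [
            evaluate_gene(g, cohort[g], t, e, alpha=cfg.alpha,
                          cutoff_mode=cfg.cutoff_mode)
            for g in available
        ]
        if results:
            prognosis_df = results_table(rank_by_auc(results))
        for gene_a, gene_b in cfg.combos:
            if gene_a not in cohort.columns or gene_b not in cohort.columns:
                combos[f"{gene_a}|{gene_b}"] = {"evaluable": False,
                                                "reason": "gene absent from cohort"}
                continue
            combo = combined_stratification(
                cohort[gene_a], cohort[gene_b], t, e, gene_a=gene_a, gene_b=gene_b
            )
            combos[f"{gene_a}|{gene_b}"] = {
                "cutoff_a": combo.cutoff_a,
                "cutoff_b": combo.cutoff_b,
                "strata": {k: dataclasses.asdict(v) for k, v in combo.strata.items()},
            }

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "stromascape_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "n_probes": len(expr.probe_ids),
        "n_samples": len(expr.sample_ids),
        "n_patients": None if cohort is None else int(len(cohort)),
        "n_cohort_genes": None if cohort is None else len(cohort_gene_columns(cohort)),
    }
    return PipelineReport(
        config=cfg,
        profiles=profiles,
        signatures=signatures,
        skipped_markers=skipped,
        top_symbols=top_symbols,
        overlap=overlap,
        prognosis=prognosis_df,
        combos=combos,
        manifest=manifest,
    )
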