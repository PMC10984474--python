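"""Synthetic paired-compartment expression data and linked survival cohorts.

The generator emulates the two public datasets the analysis design targets:

* a paired micro-dissected dataset -- 13 tumors, each contributing one
  cancer-stroma and one epithelium sample, a few thousand probes with
  multiple probes per gene, a designated reference stromal sample, and
  latent co-expression factors anchored on tumor-microenvironment marker
  genes (SPARC, PECAM1, CD8A, CD14, ...) with designed stroma-specificity
  (cS/E) levels and reference-sample expression amounts; and

* a bulk-tumor survival cohort -- 232 patients whose hazard depends
  log-linearly on planted prognostic genes, with independent censoring and
  simple clinical covariates.

All randomness is multiplicative-lognormal so signals stay positive, as on
a microarray.  Planted quantities are exact by construction: each member
probe's value in the reference sample equals its planted amount, and each
probe's realized cS/E ratio equals its planted ratio (epithelial rows are
rescaled to hit the target mean), so ground truth is sharp even at non-zero
noise.  Same seed, same bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FactorSpec:
    """One latent co-expression factor anchored on a marker gene.

    ``n_member_probes`` member probes (grouped into genes by the global
    probes-per-gene distribution) share the factor's latent signal across
    stromal samples, scaled by ``loading`` and perturbed by lognormal noise.
    ``planted_cse`` / ``planted_amount_range`` set the members' designed
    stroma specificity and reference-sample abundance.  Decoy probes
    correlate with the latent but fail one filter, so recovery exercises the
    specificity and abundance criteria, not just correlation.  ``corr_with``
    makes this factor's latent correlate (log-scale coefficient ``corr``)
    with an earlier factor's, planting partial signature overlap.
    """

    name: str
    anchor_symbol: str
    n_member_probes: int = 20
    loading: float = 1.0
    planted_cse: float = 12.0
    anchor_cse: float | None = None
    anchor_amount: float = 100.0
    planted_amount_range: tuple[float, float] = (40.0, 300.0)
    n_low_cse_decoys: int = 0
    n_low_amount_decoys: int = 0
    decoy_cse: float = 4.0
    decoy_amount_range: tuple[float, float] = (5.0, 35.0)
    member_symbols: tuple[str, ...] = ()
    corr_with: str | None = None
    corr: float = 0.0


@dataclass
class InteractionSpec:
    """Gene B modifies the hazard only in the below-median stratum of gene
    A, log-linearly like every other planted effect: for patients with
    z_A < 0 the hazard is multiplied by ``hr_b_in_a_low ** z_B``, i.e.
    ``hr_b_in_a_low`` is B's per-SD hazard ratio inside the A-low half and
    B has no effect in the A-high half."""

    gene_a: str = "COL8A1"
    gene_b: str = "CD8A"
    hr_b_in_a_low: float = 0.4


def _default_betas() -> dict[str, float]:
    # per-SD log-hazard effects of the planted prognostic genes:
    # stromal/collagen genes harmful, CTL-axis genes protective
    return {
        "COL8A1": 0.7,
        "COL5A2": 0.6,
        "SPARC": 0.55,
        "PLAT": 0.5,
        "CD8A": -0.5,
        "IFNG": -0.45,
        "B2M": -0.4,
    }


@dataclass
class SurvivalSpec:
    """Bulk survival cohort at the study scale: 232 patients, exponential
    event times with hazard = baseline * exp(sum beta_g * z_g), independent
    uniform censoring calibrated to the target censored fraction."""

    n_patients: int = 232
    baseline_hazard: float = 0.01  # events per month; median survival ~69 months
    betas: dict[str, float] = field(default_factory=_default_betas)
    censor_rate: float = 0.6
    n_null_genes: int = 20
    expression_scale: float = 60.0  # median normalized expression of cohort genes
    expression_sigma: float = 0.5   # lognormal sigma linking z to expression
    interaction: InteractionSpec | None = None


def default_marker_factors() -> list[FactorSpec]:
    """The ten-marker panel at its designed study conditions.

    Anchor cS/E ratios follow the profiled marker values where the study
    design states them (PECAM1 15.2; CD8A and CD14 4.7; CD33 5.2; FOXP3
    1.9); SPARC is set High.  Member genes of the fibroblast factor carry
    collagen-family and canonical CAF symbols so abundance ranking, fibrosis
    subclassing and the cohort bridge are exercised with realistic names.
    """
    return [
        FactorSpec(
            name="CAFG", anchor_symbol="SPARC", n_member_probes=60,
            planted_cse=12.0, anchor_cse=12.0, anchor_amount=320.0,
            n_low_cse_decoys=5, n_low_amount_decoys=5,
            member_symbols=(
                "COL8A1", "COL5A2", "COL5A1", "COL12A1", "COL3A1", "COL1A1",
                "TAGLN", "PLAT", "ANXA1", "PTRF", "NNMT", "VIM", "ACTA2",
                "PDGFRB", "FAP", "LUM", "DCN", "IGFBP7",
            ),
        ),
        FactorSpec(
            name="TAEG", anchor_symbol="PECAM1", n_member_probes=24,
            planted_cse=12.0, anchor_cse=15.2, anchor_amount=60.0,
            n_low_cse_decoys=3, n_low_amount_decoys=3,
            member_symbols=("CAV1", "CDH5", "TIE1", "RGS5", "COL4A1", "COL4A2", "ETS1"),
        ),
        FactorSpec(
            name="CTLG", anchor_symbol="CD8A", n_member_probes=24,
            planted_cse=12.0, anchor_cse=4.7, anchor_amount=80.0,
            n_low_cse_decoys=3, n_low_amount_decoys=3,
            member_symbols=("IGFBP3", "C3", "FBN1", "CYBRD1", "IFNG", "B2M", "TLR4"),
        ),
        FactorSpec(
            name="TAMCG", anchor_symbol="CD14", n_member_probes=16,
            planted_cse=12.0, anchor_cse=4.7, anchor_amount=40.0,
            n_low_cse_decoys=2, n_low_amount_decoys=2,
            member_symbols=("CD163", "CXCR4", "DKK3"),
        ),
        FactorSpec(
            name="CD3TILG", anchor_symbol="CD3G", n_member_probes=12,
            planted_cse=12.0, anchor_cse=6.0, anchor_amount=45.0,
        ),
        FactorSpec(
            name="fMDSCG", anchor_symbol="ARG1", n_member_probes=6,
            planted_cse=3.0, anchor_cse=2.0, anchor_amount=2.0,
            planted_amount_range=(5.0, 30.0),
        ),
        FactorSpec(
            name="iMDSCG", anchor_symbol="CD33", n_member_probes=6,
            planted_cse=5.2, anchor_cse=5.2, anchor_amount=3.76,
            planted_amount_range=(5.0, 30.0),
        ),
        FactorSpec(
            name="TregG", anchor_symbol="FOXP3", n_member_probes=6,
            planted_cse=1.9, anchor_cse=1.9, anchor_amount=1.5,
            planted_amount_range=(2.0, 20.0),
        ),
        FactorSpec(
            name="BTILG", anchor_symbol="MS4A1", n_member_probes=6,
            planted_cse=3.0, anchor_cse=3.0, anchor_amount=20.0,
            planted_amount_range=(5.0, 35.0),
        ),
        FactorSpec(
            name="TANG", anchor_symbol="S100A9", n_member_probes=2,
            planted_cse=4.0, anchor_cse=4.0, anchor_amount=25.0,
            planted_amount_range=(5.0, 35.0),
        ),
    ]


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 13 paired tumors, 2000 probes, the ten-marker
    factor panel, multiple probes per gene, 5% relative noise, and a
    232-patient survival cohort."""

    n_tumors: int = 13
    n_probes: int = 2000
    factors: list[FactorSpec] = field(default_factory=default_marker_factors)
    probes_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15}
    )
    noise_sd: float = 0.05            # relative (lognormal sigma) probe-level noise
    gene_noise_sd: float | None = None  # gene-level noise shared by a gene's probes; defaults to noise_sd
    latent_sigma: float = 0.5     # log-sd of factor latents across tumors
    housekeeping_probe: str = "HK_GAPDH"
    reference_tumor: str = "T01"
    unannotated_frac: float = 0.05  # background probes without a gene symbol
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 1 or self.n_probes < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.noise_sd < 0 or (self.gene_noise_sd is not None and self.gene_noise_sd < 0):
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.survival.censor_rate <= 1:
            raise ConfigurationError("censor_rate must be in [0, 1]")
        if abs(sum(self.probes_per_gene.values()) - 1.0) > 1e-9:
            raise ConfigurationError("probes_per_gene probabilities must sum to 1")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ConfigurationError("factor names must be unique")
        anchors = [f.anchor_symbol for f in self.factors]
        if len(set(anchors)) != len(anchors):
            raise ConfigurationError("anchor symbols must be unique")
        seen: set[str] = set()
        for f in self.factors:
            if f.n_member_probes < 1:
                raise ConfigurationError(f"{f.name}: n_member_probes must be >= 1")
            if f.corr_with is not None and f.corr_with not in seen:
                raise ConfigurationError(
                    f"{f.name}: corr_with must name an earlier factor"
                )
            seen.add(f.name)
        budget = sum(
            f.n_member_probes + f.n_low_cse_decoys + f.n_low_amount_decoys + 3
            for f in self.factors
        )
        if budget + 1 > self.n_probes:
            raise ConfigurationError("n_probes too small for the configured factors")


# ---------------------------------------------------------------------------
# paired compartment dataset


def _draw_gene_sizes(rng, total_probes: int, dist: dict[int, float]) -> list[int]:
    sizes = sorted(dist)
    probs = np.array([dist[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    out: list[int] = []
    left = total_probes
    while left > 0:
        k = int(rng.choice(sizes, p=probs))
        k = min(k, left)
        out.append(k)
        left -= k
    return out


def generate_compartment_dataset(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, dict]:
    """Paired stroma/epithelium raw-signal matrix plus ground truth.

    Ground truth carries a per-probe table (factor, symbol, planted amount,
    planted cS/E, anchor/decoy flags) from which expected signature
    membership under any thresholds can be recomputed exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    n_t = cfg.n_tumors
    tumors = [f"T{i + 1:02d}" for i in range(n_t)]
    stroma_ids = [f"{t}_str" for t in tumors]
    epi_ids = [f"{t}_epi" for t in tumors]
    if cfg.reference_tumor not in tumors:
        raise ConfigurationError(f"reference tumor {cfg.reference_tumor!r} not generated")
    ref_idx = tumors.index(cfg.reference_tumor)

    # factor latents on log scale, optionally correlated with an earlier factor
    log_latents: dict[str, np.ndarray] = {}
    for f in cfg.factors:
        own = rng.normal(0.0, 1.0, n_t)
        if f.corr_with is not None:
            parent = log_latents[f.corr_with] / cfg.latent_sigma
            z = f.corr * parent + np.sqrt(max(0.0, 1 - f.corr**2)) * own
        else:
            z = own
        log_latents[f.name] = cfg.latent_sigma * z

    probe_rows: list[dict] = []  # planted per-probe metadata
    stroma_vals: list[np.ndarray] = []
    epi_vals: list[np.ndarray] = []
    probe_counter = 0
    gene_counter = 0

    def add_probe(symbol, factor, role, amount, cse, stroma_norm):
        nonlocal probe_counter
        pid = f"PRB{probe_counter:05d}"
        probe_counter += 1
        # pin the reference-sample value to the planted amount
        v = stroma_norm * (amount / stroma_norm[ref_idx])
        # epithelial row: same latent shape would leak correlation into the
        # epithelium; use flat noise around the target mean, then rescale so
        # the realized compartment-mean ratio equals the planted cS/E exactly
        e = np.exp(rng.normal(0.0, cfg.noise_sd, n_t)) if cfg.noise_sd > 0 else np.ones(n_t)
        target_mean = v.mean() / cse
        e = e * (target_mean / e.mean())
        probe_rows.append(
            {
                "probe_id": pid,
                "symbol": symbol,
                "factor": factor,
                "role": role,
                "planted_amount": amount,
                "planted_cse": cse,
            }
        )
        stroma_vals.append(v)
        epi_vals.append(e)
        return pid

    def probe_noise():
        if cfg.noise_sd == 0:
            return np.ones(n_t)
        return np.exp(rng.normal(0.0, cfg.noise_sd, n_t))

    truth_factors: dict[str, dict] = {}
    for f in cfg.factors:
        latent = np.exp(log_latents[f.name])
        anchor_cse = f.anchor_cse if f.anchor_cse is not None else f.planted_cse

        # anchor gene: its probes track the latent with *no* gene-level noise
        # (the anchor defines the factor axis); most-abundant probe first
        n_anchor_probes = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        anchor_probes = []
        for k in range(n_anchor_probes):
            amt = f.anchor_amount * (0.8**k)
            anchor_probes.append(
                add_probe(f.anchor_symbol, f.name, "anchor", amt, anchor_cse,
                          f.loading * latent * probe_noise())
            )

        def member_block(n_probes, role, amounts_lo, amounts_hi, cse, symbols):
            nonlocal gene_counter
            pids, syms = [], []
            gene_sizes = _draw_gene_sizes(rng, n_probes, cfg.probes_per_gene)
            sym_iter = iter(symbols)
            for size in gene_sizes:
                sym = next(sym_iter, None)
                if sym is None:
                    gene_counter += 1
                    sym = f"{f.name}{gene_counter:03d}"
                gsd = cfg.noise_sd if cfg.gene_noise_sd is None else cfg.gene_noise_sd
                gnoise = np.exp(rng.normal(0.0, gsd, n_t)) if gsd > 0 else np.ones(n_t)
                gene_latent = latent * gnoise
                for _ in range(size):
                    amt = float(rng.uniform(amounts_lo, amounts_hi))
                    pids.append(
                        add_probe(sym, f.name, role, amt, cse,
                                  f.loading * gene_latent * probe_noise())
                    )
                    syms.append(sym)
            return pids, syms

        member_probes, member_syms = member_block(
            f.n_member_probes, "member",
            f.planted_amount_range[0], f.planted_amount_range[1],
            f.planted_cse, f.member_symbols,
        )
        decoy_probes: list[str] = []
        if f.n_low_cse_decoys:
            p, _ = member_block(
                f.n_low_cse_decoys, "decoy_low_cse",
                f.planted_amount_range[0], f.planted_amount_range[1],
                f.decoy_cse, (),
            )
            decoy_probes += p
        if f.n_low_amount_decoys:
            p, _ = member_block(
                f.n_low_amount_decoys, "decoy_low_amount",
                f.decoy_amount_range[0], f.decoy_amount_range[1],
                f.planted_cse, (),
            )
            decoy_probes += p

        truth_factors[f.name] = {
            "anchor_symbol": f.anchor_symbol,
            "anchor_probes": anchor_probes,
            "anchor_cse": anchor_cse,
            "member_probes": member_probes,
            "member_symbols": sorted(set(member_syms)),
            "decoy_probes": decoy_probes,
            "planted_cse": f.planted_cse,
        }

    # background probes: independent gene latents, cS/E around 1
    n_background = cfg.n_probes - probe_counter - 1  # minus housekeeping
    bg_sizes = _draw_gene_sizes(rng, n_background, cfg.probes_per_gene)
    bg_gene = 0
    for size in bg_sizes:
        bg_gene += 1
        sym = None if rng.random() < cfg.unannotated_frac else f"BG{bg_gene:04d}"
        gene_latent = np.exp(rng.normal(0.0, cfg.latent_sigma, n_t))
        for _ in range(size):
            amt = float(np.exp(rng.normal(np.log(15.0), 1.0)))
            cse = float(np.exp(rng.normal(0.0, 0.3)))
            add_probe(sym, None, "background", amt, cse, gene_latent * probe_noise())

    # assemble normalized values, then un-normalize through a per-sample
    # housekeeping signal so the raw table exercises the normalizer
    norm_stroma = np.vstack(stroma_vals)
    norm_epi = np.vstack(epi_vals)
    norm = np.hstack([norm_stroma, norm_epi])
    hk_norm = np.full((1, 2 * n_t), 100.0)
    norm = np.vstack([norm, hk_norm])
    probe_ids = [r["probe_id"] for r in probe_rows] + [cfg.housekeeping_probe]
    sample_ids = stroma_ids + epi_ids
    hk_raw = np.exp(rng.normal(np.log(5000.0), 0.3, 2 * n_t))
    raw = norm * hk_raw[None, :] / 100.0

    values = pd.DataFrame(raw, index=probe_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "tumor_id": tumors + tumors,
            "compartment": ["stroma"] * n_t + ["epithelium"] * n_t,
            "is_reference": [t == cfg.reference_tumor for t in tumors] + [False] * n_t,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    symbols = {r["probe_id"]: r["symbol"] for r in probe_rows}
    symbols[cfg.housekeeping_probe] = "GAPDH"
    anno = pd.Series(symbols, name="symbol").reindex(probe_ids)

    truth = {
        "factors": truth_factors,
        "probe_table": pd.DataFrame(probe_rows).set_index("probe_id"),
        "housekeeping_probe": cfg.housekeeping_probe,
        "reference_sample": f"{cfg.reference_tumor}_str",
        "seed": cfg.seed,
    }
    return ExpressionMatrix(values=values, sample_meta=meta, probe_anno=anno), truth


def expected_members(truth: dict, factor: str, cse_min: float = 10.0,
                     amount_min: float = 40.0) -> list[str]:
    """Planted probes of one factor that pass the specificity and abundance
    filters (decoys drop out by construction); the recovery oracle."""
    tab = truth["probe_table"]
    sub = tab[(tab["factor"] == factor) & (tab["role"] != "anchor")]
    keep = (sub["planted_cse"] >= cse_min) & (sub["planted_amount"] >= amount_min)
    members = set(sub.index[keep])
    # anchor probes are members when they pass their own filters
    anc = tab[(tab["factor"] == factor) & (tab["role"] == "anchor")]
    keep_a = (anc["planted_cse"] >= cse_min) & (anc["planted_amount"] >= amount_min)
    members |= set(anc.index[keep_a])
    return sorted(members)


# ---------------------------------------------------------------------------
# survival cohort


def _calibrate_uniform_censoring(event_times: np.ndarray, u: np.ndarray,
                                 rate: float) -> float:
    """Scale T for censor times C = u * T so the censored fraction
    (C < event time) hits ``rate``; monotone in T, solved by bisection."""
    lo, hi = 1e-9, float(event_times.max()) / max(u.min(), 1e-12) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float((u * mid < event_times).mean())
        if frac > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival_cohort(
    cfg: SyntheticConfig, genes: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Cohort table (clinical columns + per-gene expression) plus ground
    truth (planted betas, latent z-scores, censoring calibration).

    Expression for gene g is ``scale * exp(sigma * z_g)`` with z ~ N(0,1)
    per patient; the hazard is ``baseline * exp(sum_g beta_g z_g)`` plus the
    optional A-low-only interaction term, so planted effects are per-SD
    log-hazard ratios.  Clinical covariates are drawn independently of the
    hazard (they are plumbing for multivariate fits, not planted signal).
    """
    cfg.validate()
    sv = cfg.survival
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = sv.n_patients

    planted = dict(sv.betas)
    gene_list = list(genes) if genes is not None else []
    for g in planted:
        if g not in gene_list:
            gene_list.append(g)
    if sv.interaction is not None:
        for g in (sv.interaction.gene_a, sv.interaction.gene_b):
            if g not in gene_list:
                gene_list.append(g)
    nulls = [f"NULL{i + 1:03d}" for i in range(sv.n_null_genes)]
    gene_list += [g for g in nulls if g not in gene_list]

    z = pd.DataFrame(
        rng.normal(0.0, 1.0, (n, len(gene_list))),
        index=[f"P{i + 1:04d}" for i in range(n)],
        columns=gene_list,
    )
    expr = sv.expression_scale * np.exp(sv.expression_sigma * z)

    linpred = np.zeros(n)
    for g, b in planted.items():
        linpred += b * z[g].to_numpy()
    if sv.interaction is not None:
        ia = sv.interaction
        a_low = z[ia.gene_a].to_numpy() < 0.0
        linpred += np.log(ia.hr_b_in_a_low) * z[ia.gene_b].to_numpy() * a_low

    hazard = sv.baseline_hazard * np.exp(linpred)
    event_times = rng.exponential(1.0 / hazard)

    if sv.censor_rate <= 0:
        time = event_times
        event = np.ones(n, dtype=int)
        censor_T = float("inf")
    elif sv.censor_rate >= 1:
        logger.warning("censor_rate = 1: no events will be observed")
        time = np.zeros(n)
        event = np.zeros(n, dtype=int)
        censor_T = 0.0
    else:
        u = rng.uniform(0.0, 1.0, n)
        censor_T = _calibrate_uniform_censoring(event_times, u, sv.censor_rate)
        censor_times = u * censor_T
        event = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)

    covars = pd.DataFrame(
        {
            "age": np.round(np.clip(rng.normal(67, 10, n), 30, 95)).astype(int),
            "sex": rng.choice(["M", "F"], n),
            "T_stage": rng.choice([1, 2, 3, 4], n, p=[0.1, 0.2, 0.5, 0.2]),
            "N_stage": rng.choice([0, 1, 2], n, p=[0.5, 0.3, 0.2]),
            "M_stage": rng.choice([0, 1], n, p=[0.85, 0.15]),
        },
        index=z.index,
    )
    cohort = pd.concat(
        [pd.DataFrame({"time_months": time, "event": event}, index=z.index), covars, expr],
        axis=1,
    )
    cohort.index.name = "patient_id"
    truth = {
        "betas": planted,
        "null_genes": nulls,
        "interaction": None if sv.interaction is None else asdict(sv.interaction),
        "z": z,
        "censor_T": censor_T,
        "realized_censor_rate": float(1 - event.mean()),
        "seed": cfg.seed,
    }
    return cohort, truth


def write_ground_truth(truth: dict, path) -> None:
    """JSON-serializable dump of a ground-truth dict (tables as records)."""
    def conv(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.reset_index().to_dict(orient="records")
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(conv(truth), fh, indent=1, default=str)
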