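"""Per-gene prognostic evaluation in a bulk-tumor survival cohort.

For each gene the pipeline (i) computes the ROC area under the curve for
prediction of death from the expression value, as the Mann-Whitney rank
statistic (ties counted 1/2); (ii) finds the best optimized cut-off -- the
threshold maximizing the Youden index over midpoints between consecutive
sorted unique values, direction-agnostically, with a minimum group-size
floor; (iii) dichotomizes the cohort at that cutoff and compares overall
survival of the two groups with Kaplan-Meier curves and the log-rank test;
(iv) estimates the high-vs-low hazard ratio from a univariate Cox model; and
(v) calls the prognostic direction: negative (high expression, worse
survival), positive, or ns at the chosen alpha.

Kaplan-Meier, log-rank and Cox proportional-hazards fits are delegated to
lifelines (Efron tie handling for Cox); the cutoff search, rank-statistic
AUC, direction logic and the two-gene combined stratification are
implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import rankdata

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


def _check_two_classes(events: np.ndarray) -> None:
    if events.sum() == 0 or events.sum() == len(events):
        raise DegenerateInputError("need at least one death and one survivor")


def roc_auc_death(values, events) -> float:
    """AUC for prediction of death: probability that a random death
    patient's value exceeds a random survivor's, ties counted 1/2."""
    v = np.asarray(values, dtype=float)
    e = np.asarray(events, dtype=int)
    if v.shape != e.shape:
        raise ValueError("values and events differ in length")
    _check_two_classes(e)
    ranks = rankdata(v)
    n1 = int(e.sum())
    n0 = len(e) - n1
    r1 = ranks[e == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float  # deaths above cutoff / deaths
    specificity: float  # survivors at/below cutoff / survivors
    j: float            # maximized |sensitivity + specificity - 1|
    n_high: int
    n_low: int


def best_cutoff(values, events, min_group_frac: float = 0.1) -> CutoffResult:
    """Threshold maximizing the Youden index J = |sens + spec - 1| over
    midpoints between consecutive sorted unique values.

    The absolute value makes the search direction-agnostic: for a protective
    gene the informative split has deaths *below* the cutoff, and the
    prognostic direction is decided afterwards from the survival comparison.
    Ties are broken toward more balanced group sizes, then the smaller
    cutoff.  Candidate cutoffs leaving fewer than ``min_group_frac`` of the
    cohort on either side are skipped (degenerate 1-vs-rest splits).
    """
    v = np.asarray(values, dtype=float)
    e = np.asarray(events, dtype=int)
    _check_two_classes(e)
    uniq = np.unique(v)
    if uniq.size < 2:
        raise DegenerateInputError("constant expression values admit no cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(v)
    floor = max(1, int(np.ceil(min_group_frac * n)))

    deaths = v[e == 1]
    survivors = v[e == 0]
    best = None
    best_key = None
    for c in mids:
        n_high = int((v > c).sum())
        n_low = n - n_high
        if n_high < floor or n_low < floor:
            continue
        sens = float((deaths > c).mean())
        spec = float((survivors <= c).mean())
        j = abs(sens + spec - 1.0)
        key = (j, -abs(n_high - n_low), -c)
        if best_key is None or key > best_key:
            best_key = key
            best = CutoffResult(float(c), sens, spec, j, n_high, n_low)
    if best is None:
        raise DegenerateInputError(
            "no cutoff satisfies the minimum group-size floor"
        )
    return best


def best_cutoff_logrank(values, times, events, min_group_frac: float = 0.1) -> CutoffResult:
    """Alternative cutoff mode: the threshold minimizing the two-group
    log-rank p over the same candidate set (same tie-breaks and floor)."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise DegenerateInputError("need at least one event")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise DegenerateInputError("constant expression values admit no cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(v)
    floor = max(1, int(np.ceil(min_group_frac * n)))
    deaths = v[e == 1]
    survivors = v[e == 0]
    best = None
    best_key = None
    for c in mids:
        high = v > c
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < floor or n_low < floor:
            continue
        res = _ll_logrank(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
        key = (-res.p_value, -abs(n_high - n_low), -c)
        if best_key is None or key > best_key:
            best_key = key
            sens = float((deaths > c).mean()) if deaths.size else float("nan")
            spec = float((survivors <= c).mean()) if survivors.size else float("nan")
            j = abs(sens + spec - 1.0) if deaths.size and survivors.size else float("nan")
            best = CutoffResult(float(c), sens, spec, j, n_high, n_low)
    if best is None:
        raise DegenerateInputError("no cutoff satisfies the minimum group-size floor")
    return best


def km_estimate(times, events, group_labels=None) -> dict[str, KaplanMeierFitter]:
    """Product-limit estimator, one fitted curve per group label
    (single group 'all' when labels are omitted)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("negative follow-up times")
    if group_labels is None:
        group_labels = np.array(["all"] * len(t))
    g = np.asarray(group_labels)
    out: dict[str, KaplanMeierFitter] = {}
    for label in pd.unique(g):
        mask = g == label
        if mask.sum() == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask], label=str(label))
        out[str(label)] = kmf
    if not out:
        raise ValueError("no groups supplied")
    return out


def km_coordinates(times, events, group_labels=None) -> pd.DataFrame:
    """Step-function coordinates (group, time, survival) for plotting/export."""
    curves = km_estimate(times, events, group_labels)
    frames = []
    for label, kmf in curves.items():
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"group": label, "time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float


def logrank_test(times, events, groups) -> LogrankResult:
    """Standard two-group log-rank statistic (chi-square, 1 df)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {len(labels)}")
    a = g == labels[0]
    if a.sum() == 0 or (~a).sum() == 0:
        raise ValueError("one group is empty")
    if e.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = _ll_logrank(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value))


def cox_fit(
    df: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    covariates: list[str] | None = None,
    penalizer: float = 0.0,
) -> pd.DataFrame:
    """Cox proportional-hazards partial-likelihood fit (Efron ties).

    Returns one row per fitted coefficient: beta, hr, ci_lower, ci_upper, p.
    Categorical covariates are expanded to treatment-coded dummies.  Fewer
    than 10 events triggers a warning; constant covariates are an error;
    non-convergence raises with the lifelines diagnostic attached.
    """
    if covariates is None:
        covariates = [c for c in df.columns if c not in (duration_col, event_col)]
    sub = df[[duration_col, event_col] + covariates].copy()
    n_events = int(sub[event_col].sum())
    if n_events < 10:
        logger.warning("Cox fit with only %d events; estimates may be unstable", n_events)
    cat_cols = [c for c in covariates if sub[c].dtype == object or str(sub[c].dtype) == "category"]
    if cat_cols:
        sub = pd.get_dummies(sub, columns=cat_cols, drop_first=True, dtype=float)
    fit_covs = [c for c in sub.columns if c not in (duration_col, event_col)]
    for c in fit_covs:
        if sub[c].nunique() <= 1:
            raise DegenerateInputError(f"constant covariate {c!r}")
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model did not converge: {err}") from err
    summ = cph.summary
    out = pd.DataFrame(
        {
            "beta": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    out.index.name = "variable"
    return out


def hazard_ratio_high_vs_low(times, events, high) -> float:
    """High-vs-low HR from a univariate Cox fit on the group indicator,
    falling back to the log-rank O-E estimate when the fit cannot converge
    (e.g. complete separation)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    h = np.asarray(high, dtype=float)
    df = pd.DataFrame({"time_months": t, "event": e, "high": h})
    try:
        res = cox_fit(df, covariates=["high"])
        return float(res.at["high", "hr"])
    except (RuntimeError, DegenerateInputError):
        o_minus_e, var = _logrank_o_minus_e(t, e, h.astype(bool))
        if var == 0:
            return float("nan")
        logger.info("Cox HR fell back to the log-rank O-E estimate")
        return float(np.exp(o_minus_e / var))


def _logrank_o_minus_e(t, e, group_a) -> tuple[float, float]:
    """Observed-minus-expected events in group A and its variance, summed
    over distinct event times (the log-rank tabulation)."""
    o_minus_e = 0.0
    var = 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        d = int(((t == tj) & (e == 1)).sum())
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        d_a = int(((t == tj) & (e == 1) & group_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e, var


DIRECTIONS = ("negative", "positive", "ns")


def classify_direction(logrank_p: float, hr_high_vs_low: float, alpha: float = 0.05) -> str:
    """negative: significant and high expression confers worse survival
    (HR > 1); positive: significant and HR < 1; otherwise ns."""
    if not np.isfinite(logrank_p):
        return "ns"
    if logrank_p < alpha and np.isfinite(hr_high_vs_low):
        if hr_high_vs_low > 1:
            return "negative"
        if hr_high_vs_low < 1:
            return "positive"
    return "ns"


@dataclass
class PrognosticResult:
    gene: str
    auc: float
    cutoff: float
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    hr_high_vs_low: float
    direction: str
    sensitivity: float = float("nan")
    specificity: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate_gene(
    gene: str,
    values,
    times,
    events,
    alpha: float = 0.05,
    cutoff_mode: str = "youden",
    min_group_frac: float = 0.1,
) -> PrognosticResult:
    """Full per-gene evaluation: AUC, best cutoff, log-rank on the
    dichotomized cohort, high-vs-low HR, and the direction call."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    auc = roc_auc_death(v, e)
    if cutoff_mode == "youden":
        cut = best_cutoff(v, e, min_group_frac=min_group_frac)
    elif cutoff_mode == "minp-logrank":
        cut = best_cutoff_logrank(v, t, e, min_group_frac=min_group_frac)
    else:
        raise ValueError(f"unknown cutoff mode: {cutoff_mode!r}")
    high = v > cut.cutoff
    lr = logrank_test(t, e, np.where(high, "high", "low"))
    hr = hazard_ratio_high_vs_low(t, e, high)
    return PrognosticResult(
        gene=gene,
        auc=auc,
        cutoff=cut.cutoff,
        n_high=cut.n_high,
        n_low=cut.n_low,
        logrank_chi2=lr.chi2,
        logrank_p=lr.p,
        hr_high_vs_low=hr,
        direction=classify_direction(lr.p, hr, alpha),
        sensitivity=cut.sensitivity,
        specificity=cut.specificity,
    )


def rank_by_auc(results: list[PrognosticResult]) -> list[PrognosticResult]:
    """Descending AUC, ties by gene id."""
    return sorted(results, key=lambda r: (-r.auc, r.gene))


@dataclass
class StratumResult:
    evaluable: bool
    n: int
    n_b_high: int = 0
    n_b_low: int = 0
    chi2: float = float("nan")
    p: float = float("nan")
    reason: str | None = None


@dataclass
class CombinedStratification:
    gene_a: str
    gene_b: str
    cutoff_a: float
    cutoff_b: float
    strata: dict[str, StratumResult] = field(default_factory=dict)


def combined_stratification(
    values_a,
    values_b,
    times,
    events,
    gene_a: str = "A",
    gene_b: str = "B",
    min_group_frac: float = 0.1,
) -> CombinedStratification:
    """Two-gene stratification: split the cohort at gene A's full-cohort
    cutoff, then within each A-stratum dichotomize by gene B's full-cohort
    cutoff and run the log-rank test.  A stratum where B yields a single
    group (or no events) is reported as not evaluable, not an error."""
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    cut_a = best_cutoff(va, e, min_group_frac=min_group_frac)
    cut_b = best_cutoff(vb, e, min_group_frac=min_group_frac)
    out = CombinedStratification(gene_a, gene_b, cut_a.cutoff, cut_b.cutoff)
    for label, mask in (("a_low", va <= cut_a.cutoff), ("a_high", va > cut_a.cutoff)):
        n = int(mask.sum())
        b_high = vb[mask] > cut_b.cutoff
        n_hi, n_lo = int(b_high.sum()), int((~b_high).sum())
        if n < 2 or n_hi == 0 or n_lo == 0:
            out.strata[label] = StratumResult(False, n, n_hi, n_lo, reason="single B group")
            continue
        if e[mask].sum() == 0:
            out.strata[label] = StratumResult(False, n, n_hi, n_lo, reason="no events")
            continue
        lr = logrank_test(t[mask], e[mask], np.where(b_high, "high", "low"))
        out.strata[label] = StratumResult(True, n, n_hi, n_lo, lr.chi2, lr.p)
    return out


def results_table(results: list[PrognosticResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_dict() for r in results]).set_index("gene")
    return df
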