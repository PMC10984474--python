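#!/usr/bin/env python
"""Per-gene prognostic screen of the survival cohort.

For every expression column of the cohort written by
01_simulate_study_data.py: death-prediction AUC, best optimized cutoff
(Youden), Kaplan-Meier split, log-rank p, high-vs-low hazard ratio and the
direction call; genes ranked by AUC.  Also measures the per-gene type-I
level of this cutoff-optimized screen on null genes across 100 seeded
cohorts -- the optimization inflates it well above the nominal 5%, which is
why the screen reports the measured level instead of assuming alpha.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "prognosis"

import json

from stromascape import evaluate_gene, load_survival_cohort, rank_by_auc
from stromascape.calibration import measure_direction_recovery
from stromascape.io import cohort_gene_columns
from stromascape.prognosis import results_table

SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = load_survival_cohort(DATA / "cohort.tsv")
    truth = json.loads((DATA / "ground_truth.json").read_text())
    betas = truth["survival"]["betas"]

    t, e = cohort["time_months"], cohort["event"]
    results = rank_by_auc(
        [evaluate_gene(g, cohort[g], t, e) for g in cohort_gene_columns(cohort)]
    )
    table = results_table(results)
    table.to_csv(OUT / "per_gene_results.tsv", sep="\t")

    print(f"{len(table)} genes screened "
          f"({int((table['direction'] == 'negative').sum())} negative, "
          f"{int((table['direction'] == 'positive').sum())} positive, "
          f"{int((table['direction'] == 'ns').sum())} ns)")
    print("top of the AUC ranking:")
    for g in table.index[:8]:
        planted = betas.get(g, 0.0)
        print(f"  {g:10s} AUC {table.at[g, 'auc']:.3f}  "
              f"p {table.at[g, 'logrank_p']:.2e}  HR {table.at[g, 'hr_high_vs_low']:6.2f}  "
              f"{table.at[g, 'direction']:8s}  planted beta {planted:+.2f}")

    study = measure_direction_recovery(n_seeds=100, seed=SEED, beta=0.7,
                                       n_patients=232, n_null_genes=3)
    calib = {
        "planted_beta_0p7_called_negative": study.n_negative_calls,
        "n_seeds": study.n_seeds,
        "null_gene_calls": study.null_calls,
        "measured_type1_error": study.type1_error,
    }
    (OUT / "screen_calibration.json").write_text(json.dumps(calib, indent=1))
    print(f"planted beta=+0.7 gene called negative in "
          f"{study.n_negative_calls}/{study.n_seeds} seeded cohorts")
    print(f"measured type-I level of the optimized-cutoff screen on null genes: "
          f"{study.type1_error:.3f} (nominal alpha 0.05; optimization inflates it)")
    print(f"tables written under {OUT}")


if __name__ == "__main__":
    main()
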