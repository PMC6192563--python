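#!/usr/bin/env python
"""Planted-signal association analysis with the weight-shuffling control.

Runs the full pipeline on the excitability cohort: per-subject c5T,
stimulation functional effects and graph statistics; synthetic response
times generated as a linear function of c5T plus noise; bootstrapped Pearson
correlations per (feature, task, condition) with BH-FDR across tasks. Then
repeats the analysis on weight-shuffled connectomes (same behavior table) —
the association must not survive, since shuffling preserves every subject's
weight distribution but destroys its organization.

Writes results/associations.tsv and results/associations_shuffled.tsv.
"""

import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import conndyn as cd
from conndyn import BehaviorSpec, default_grid

RESULTS = Path(__file__).resolve().parent.parent / "results"
GRID = default_grid(0.005)


def to_table(report):
    rows = [asdict(a) for a in report["associations"]]
    return pd.DataFrame(rows).drop(columns=[], errors="ignore")


def main():
    spec = cd.excitability_cohort_spec()
    cohort = cd.generate_cohort(spec)
    site = cd.default_stimulation_site(spec)
    bspec = BehaviorSpec(slope=80.0, noise_sd_ms=15.0, driving_feature="c5T", seed=5)
    report = cd.run_full_analysis(cohort, bspec, site, spec.circuit(), grid=GRID,
                                  sim_ms=500.0, n_boot=5000, seed=42)
    RESULTS.mkdir(exist_ok=True)
    report["features"].to_csv(RESULTS / "subject_features.tsv", sep="\t",
                              index=False, float_format="%.6g")
    table = to_table(report)
    table.to_csv(RESULTS / "associations.tsv", sep="\t", index=False,
                 float_format="%.4g")
    planted = table[table.feature == "c5T"]
    print("c5T vs response time (planted signal):")
    print(planted[["task", "condition", "r", "p", "ci_low", "ci_high",
                   "fdr_significant"]].to_string(index=False))

    behavior = cd.generate_behavior(report["features"]["c5T"].to_numpy(), bspec,
                                    subject_ids=list(report["features"]["subject_id"]))
    shuffled = cd.shuffled_cohort(cohort, seed=99)
    report_sh = cd.run_full_analysis(shuffled, behavior, site, spec.circuit(),
                                     grid=GRID, sim_ms=500.0, n_boot=5000, seed=43)
    table_sh = to_table(report_sh)
    table_sh.to_csv(RESULTS / "associations_shuffled.tsv", sep="\t", index=False,
                    float_format="%.4g")
    planted_sh = table_sh[table_sh.feature == "c5T"]
    print("\nsame behavior, weight-shuffled connectomes (control):")
    print(planted_sh[["task", "condition", "r", "p", "fdr_significant"]]
          .to_string(index=False))
    n_sig = planted.fdr_significant.sum()
    n_sig_sh = planted_sh.fdr_significant.sum()
    print(f"\nFDR-significant c5T associations: {n_sig}/6 original, "
          f"{n_sig_sh}/6 after shuffling — the association rests on network "
          "organization, not on the weight distribution")


if __name__ == "__main__":
    main()
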