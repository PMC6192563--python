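#!/usr/bin/env python
"""Structural graph statistics per subject of the excitability cohort.

Weighted degree, spectral radius (and its inverse, which bounds the coupling
at which network-wide synchronization can onset) and Laplacian
synchronizability. Writes results/network_stats.tsv.
"""

import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import conndyn as cd
from conndyn import network_features

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    spec = cd.excitability_cohort_spec()
    rows = [asdict(network_features(cd.generate_connectome(spec, s), f"sub-{s:02d}"))
            for s in range(spec.n_subjects)]
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "network_stats.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(table.to_string(index=False))
    print("\nmean degree is identical by construction; the spread in spectral "
          "radius reflects subject-specific hub concentration")


if __name__ == "__main__":
    main()
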