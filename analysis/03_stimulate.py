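#!/usr/bin/env python
"""In-silico stimulation of the 4-region site embedded in the task circuit.

For each subject of the circuit cohort: find c5T, hold the coupling one grid
step below it, stimulate the site with P = 1.15 for 1 s after a 1 s quiet
segment, and measure the change in max-lagged functional connectivity (dFC)
globally, within the planted task circuit, and outside it.

Writes per-subject dFC matrices (TSV) and results/functional_effects.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import conndyn as cd
from conndyn import WilsonCowanParams, default_grid, detect_transition, sweep_coupling
from conndyn.stimulation import stimulation_result

RESULTS = Path(__file__).resolve().parent.parent / "results"
GRID = default_grid(0.005)


def main():
    spec = cd.circuit_cohort_spec()
    params = WilsonCowanParams()
    site = cd.default_stimulation_site(spec)
    circuit = spec.circuit()
    out = RESULTS / "stimulation"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in range(spec.n_subjects):
        conn = cd.generate_connectome(spec, s)
        curve = sweep_coupling(conn, params, grid=GRID, sim_ms=500.0, seed=200 + s)
        c5T = detect_transition(curve)
        res = stimulation_result(conn, params, c5T, site, circuit, seed=300 + s,
                                 grid_step=0.005)
        pd.DataFrame(res.dfc, index=conn.labels, columns=conn.labels).to_csv(
            out / f"sub-{s:02d}_dfc.tsv", sep="\t", float_format="%.6g")
        rows.append({"subject_id": f"sub-{s:02d}", "c5T": c5T, "c5_used": res.c5,
                     "effect_global": res.effect_global,
                     "effect_circuit": res.effect_circuit,
                     "effect_outside": res.effect_outside})
        print(f"sub-{s:02d}: c5T={c5T:.3f}  effect global={res.effect_global:+.3f} "
              f"circuit={res.effect_circuit:+.3f} outside={res.effect_outside:+.3f}")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "functional_effects.tsv", sep="\t", index=False,
                 float_format="%.6g")
    n_win = (table.effect_circuit > table.effect_outside).sum()
    print(f"\nwithin-circuit effect exceeds outside-circuit in "
          f"{n_win}/{len(table)} subjects — stimulation spreads preferentially "
          "through the strongly coupled circuit")


if __name__ == "__main__":
    main()
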