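"""Global coupling sweep and detection of the excitability transition c5T.

As the global coupling c5 is increased with no external input, the network's
mean excitatory activity stays near the quiescent fixed point until, at a
subject-specific value c5T, it jumps abruptly to a high-amplitude oscillatory
("excited") state. c5T is a proxy for global excitability: brains with lower
c5T need less input to become active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import seedseq
from .connectome import StructuralConnectome
from .wilson_cowan import WilsonCowanParams, simulate

__all__ = ["SweepCurve", "default_grid", "sweep_coupling", "detect_transition",
           "NoTransitionError"]

#: canonical sweep range; the reference protocol uses step 0.001, desk-scale
#: runs coarsen the step (0.005) without changing the range
SWEEP_START, SWEEP_STOP, SWEEP_STEP = 0.05, 0.25, 0.001


def default_grid(step: float = SWEEP_STEP) -> np.ndarray:
    return np.round(np.arange(SWEEP_START, SWEEP_STOP + step / 2, step), 10)


class NoTransitionError(RuntimeError):
    """The sweep curve contains no jump large enough to call a transition."""


@dataclass
class SweepCurve:
    """Mean excitatory activity (time- and region-averaged, post-stabilization)
    per c5 grid value, plus the per-point noise seeds used."""

    c5_grid: np.ndarray
    mean_activity: np.ndarray
    seeds: list

    def __post_init__(self) -> None:
        self.c5_grid = np.asarray(self.c5_grid, dtype=float)
        self.mean_activity = np.asarray(self.mean_activity, dtype=float)
        if len(self.c5_grid) != len(self.mean_activity):
            raise ValueError("grid and activity lengths differ")
        if len(self.c5_grid) > 1 and not np.all(np.diff(self.c5_grid) > 0):
            raise ValueError("c5 grid must be strictly ascending")
        if not np.all(np.isfinite(self.mean_activity)):
            raise ValueError("activities must be finite")

    @property
    def grid_step(self) -> float:
        if len(self.c5_grid) < 2:
            raise ValueError("grid step undefined for a single-point curve")
        return float(np.diff(self.c5_grid).min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"c5": self.c5_grid, "mean_activity": self.mean_activity})


def sweep_coupling(conn: StructuralConnectome, params: WilsonCowanParams,
                   grid=None, sim_ms: float = 1000.0, seed=None,
                   stabilization_ms: float = 1000.0) -> SweepCurve:
    """Simulate ``sim_ms`` of unstimulated dynamics at each grid value.

    Each grid point runs an independent simulation (P = 0) from the standard
    initial condition; the recorded quantity is the mean of E over all
    regions and all retained samples. Seeds are derived per grid point from
    ``seed`` so the curve is reproducible as a whole.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("sweep grid must be nonempty")
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("sweep grid must be strictly ascending")
    point_seeds = seedseq(seed).spawn(len(grid))
    activity = np.empty(len(grid))
    for k, c5 in enumerate(grid):
        trace = simulate(conn, params, float(c5), schedule=None,
                         duration_ms=sim_ms, seed=point_seeds[k],
                         stabilization_ms=stabilization_ms)
        activity[k] = float(trace.E.mean())
    return SweepCurve(c5_grid=grid, mean_activity=activity, seeds=point_seeds)


def detect_transition(curve: SweepCurve, jump_factor: float = 5.0) -> float:
    """c5T: the grid value at the left edge of the curve's dominant jump.

    The dominant jump is the maximal forward difference of mean activity; it
    qualifies as a transition only if it exceeds ``jump_factor`` times the
    median absolute forward difference (a flat or smoothly rising curve has
    no transition). Ties break toward smaller c5. The left edge — the last
    grid value before the excited state — is returned, so "just below c5T"
    in the stimulation protocol is one grid step below the returned value.
    """
    if len(curve.c5_grid) < 3:
        raise ValueError("transition detection needs a curve of length >= 3")
    diffs = np.diff(curve.mean_activity)
    j = int(np.argmax(diffs))  # argmax takes the first maximum: smaller-c5 tie-break
    med = float(np.median(np.abs(diffs)))
    if not diffs[j] >= jump_factor * med or diffs[j] <= 0:
        raise NoTransitionError(
            f"largest activity increase {diffs[j]:.3g} is below "
            f"{jump_factor} x median |difference| ({med:.3g})"
        )
    return float(curve.c5_grid[j])
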