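"""In-silico stimulation, lagged functional connectivity, and functional effect.

Protocol: with global coupling held one sweep-grid step below the subject's
transition value c5T (the most perturbation-sensitive subthreshold state),
the network evolves unstimulated for 1 s and then receives a constant input
P = 1.15 to a small set of target regions for 1 s, pushing their dynamics
into a limit cycle. Functional connectivity (FC) — the maximum over lags
within +/-250 ms of the pairwise Pearson correlation of excitatory activity
in a 1 s window — is computed separately for the two segments; the
during-minus-before difference (dFC) quantifies the stimulation's spread,
summarized as its mean over all region pairs (global), pairs within a task
circuit, or pairs wholly outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import RegionSet, StructuralConnectome
from .wilson_cowan import (SimulationTrace, StimulusSchedule, WilsonCowanParams,
                           simulate)

__all__ = [
    "FunctionalConnectivityMatrix",
    "StimulationResult",
    "run_stimulation_experiment",
    "functional_connectivity",
    "delta_fc",
    "functional_effect",
    "stimulation_result",
    "fc_variability",
    "functional_variability",
]

STIM_AMPLITUDE = 1.15  # external input that drives a region into a limit cycle
DEFAULT_GRID_STEP = 0.001  # "just below c5T" = c5T minus one sweep-grid step


@dataclass
class FunctionalConnectivityMatrix:
    """Pairwise max-lagged correlation; NaN marks undefined (constant) pairs."""

    values: np.ndarray
    window_ms: float
    max_lag_ms: float
    condition: str  # "pre" | "during"
    stride_ms: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values[np.isfinite(self.values)]
        if v.size and (v.max() > 1 + 1e-9 or v.min() < -1 - 1e-9):
            raise ValueError("FC values outside [-1, 1]")


@dataclass
class StimulationResult:
    """dFC (during - pre) and its scalar summaries for one subject/run."""

    dfc: np.ndarray
    effect_global: float
    effect_circuit: float
    effect_outside: float
    c5: float
    seed: object = None


def run_stimulation_experiment(conn: StructuralConnectome, params: WilsonCowanParams,
                               c5T: float, targets: RegionSet, seed=None,
                               grid_step: float = DEFAULT_GRID_STEP,
                               amplitude: float = STIM_AMPLITUDE,
                               segment_ms: float = 1000.0,
                               stabilization_ms: float = 1000.0,
                               ) -> tuple[SimulationTrace, SimulationTrace]:
    """One continuous run at c5 = c5T - grid_step: a quiet segment, then a
    stimulated one. Returns the (pre, during) 1 s trace segments."""
    targets.validate_against(conn)
    c5 = max(c5T - grid_step, 0.0)
    schedule = StimulusSchedule.single_pulse(targets, amplitude,
                                             onset_ms=segment_ms,
                                             offset_ms=2 * segment_ms)
    trace = simulate(conn, params, c5, schedule=schedule,
                     duration_ms=2 * segment_ms, seed=seed,
                     stabilization_ms=stabilization_ms)
    return trace.segment(0.0, segment_ms), trace.segment(segment_ms, 2 * segment_ms)


def _standardized(X: np.ndarray):
    mean = X.mean(axis=1, keepdims=True)
    Z = X - mean
    sd = np.sqrt((Z**2).mean(axis=1, keepdims=True))
    defined = (X.max(axis=1) > X.min(axis=1))
    sd[~defined] = 1.0
    return Z / sd, defined


def functional_connectivity(segment: SimulationTrace, window_ms: float = 1000.0,
                            max_lag_ms: float = 250.0, stride_ms: float = 1.0,
                            condition: str = "pre") -> FunctionalConnectivityMatrix:
    """FC_ij = max over lags l in [-max_lag, +max_lag] of corr(E_i(t), E_j(t+l)).

    The correlation at each lag is the Pearson correlation over the
    overlapping samples only (no padding); the maximum is signed. Signals are
    sampled at ``stride_ms`` (a multiple of the integration step); a pair is
    undefined (NaN) if either signal is constant at every lag window.
    """
    h = segment.step_h
    stride = max(int(round(stride_ms / h)), 1)
    X = segment.E[:, ::stride]
    W = int(round(window_ms / (h * stride)))
    if X.shape[1] < W:
        raise ValueError(
            f"segment has {X.shape[1]} samples at stride {stride_ms} ms; window needs {W}"
        )
    X = X[:, :W]
    max_lag = int(round(max_lag_ms / (h * stride)))
    n = X.shape[0]
    best = np.full((n, n), -np.inf)
    any_defined = np.zeros((n, n), dtype=bool)
    for lag in range(max_lag + 1):
        X1 = X[:, : W - lag] if lag else X
        X2 = X[:, lag:]
        Z1, d1 = _standardized(X1)
        Z2, d2 = _standardized(X2)
        C = Z1 @ Z2.T / (W - lag)  # C[i, j] = corr(E_i(t), E_j(t+lag))
        ok = np.outer(d1, d2)
        C = np.where(ok, np.clip(C, -1.0, 1.0), -np.inf)
        # lag >= 0 covers negative lags of the transposed pair
        best = np.maximum(best, np.maximum(C, C.T))
        any_defined |= ok | ok.T
    values = np.where(any_defined, best, np.nan)
    return FunctionalConnectivityMatrix(values=values, window_ms=window_ms,
                                        max_lag_ms=max_lag_ms,
                                        condition=condition, stride_ms=stride_ms)


def delta_fc(pre: FunctionalConnectivityMatrix,
             during: FunctionalConnectivityMatrix) -> np.ndarray:
    """Pairwise FC change (during - pre); NaN where either side is undefined."""
    return during.values - pre.values


def functional_effect(dfc: np.ndarray, labels: list[str],
                      scope: RegionSet | None = None,
                      complement: bool = False) -> float:
    """Mean dFC over unordered off-diagonal pairs in scope.

    ``scope=None`` averages all pairs; a RegionSet restricts to pairs with
    both endpoints in the set, or — with ``complement`` — both outside it.
    Cross pairs (one endpoint in, one out) belong to neither restricted
    scope. Undefined (NaN) pairs are excluded from the average.
    """
    dfc = np.asarray(dfc, dtype=float)
    n = dfc.shape[0]
    if scope is None:
        idx = np.arange(n)
    else:
        member = np.isin(labels, scope.labels)
        if not member.sum() == len(scope.labels):
            missing = set(scope.labels) - set(labels)
            raise ValueError(f"scope labels not in connectome: {sorted(missing)}")
        idx = np.flatnonzero(~member if complement else member)
    if len(idx) < 2:
        raise ValueError("functional-effect scope needs at least 2 regions")
    sub = dfc[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def stimulation_result(conn: StructuralConnectome, params: WilsonCowanParams,
                       c5T: float, targets: RegionSet, circuit: RegionSet,
                       seed=None, grid_step: float = DEFAULT_GRID_STEP,
                       amplitude: float = STIM_AMPLITUDE,
                       stride_ms: float = 1.0) -> StimulationResult:
    """Full single-subject stimulation readout: dFC and its three summaries."""
    pre, during = run_stimulation_experiment(conn, params, c5T, targets, seed=seed,
                                             grid_step=grid_step, amplitude=amplitude)
    fc_pre = functional_connectivity(pre, stride_ms=stride_ms, condition="pre")
    fc_during = functional_connectivity(during, stride_ms=stride_ms, condition="during")
    dfc = delta_fc(fc_pre, fc_during)
    return StimulationResult(
        dfc=dfc,
        effect_global=functional_effect(dfc, conn.labels, None),
        effect_circuit=functional_effect(dfc, conn.labels, circuit),
        effect_outside=functional_effect(dfc, conn.labels, circuit, complement=True),
        c5=max(c5T - grid_step, 0.0),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cross-subject variability maps

def _cv_map(per_subject: np.ndarray) -> np.ndarray:
    """std/mean across subjects (axis 0), NaN where the mean is zero."""
    if per_subject.shape[0] < 2:
        raise ValueError("variability maps need at least 2 subjects")
    mean = per_subject.mean(axis=0)
    sd = per_subject.std(axis=0, ddof=1)
    out = np.full(mean.shape, np.nan)
    nz = mean != 0
    out[nz] = sd[nz] / mean[nz]
    return out


def fc_variability(fc_list: list[FunctionalConnectivityMatrix]) -> np.ndarray:
    """Per-region coefficient of variation of mean FC to all other regions."""
    rows = []
    for fc in fc_list:
        v = fc.values.copy()
        np.fill_diagonal(v, np.nan)
        rows.append(np.nanmean(v, axis=1))
    return _cv_map(np.stack(rows))


def functional_variability(traces: list[SimulationTrace]) -> np.ndarray:
    """Per-region coefficient of variation of time-averaged excitatory activity."""
    rows = [tr.E.mean(axis=1) for tr in traces]
    return _cv_map(np.stack(rows))
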