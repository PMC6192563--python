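"""Delay-coupled Wilson-Cowan network dynamics on a structural connectome.

Each brain region i carries a Wilson-Cowan oscillator: the fractions of
active excitatory and inhibitory neurons, E_i(t) and I_i(t), obey

    tau dE_i/dt = -E_i + (S_E^max - E_i) * S_E(c1 E_i - c2 I_i
                    + c5 sum_j A_ij E_j(t - d_ij/t_d) + P_i(t)) + sigma w_i(t)
    tau dI_i/dt = -I_i + (S_I^max - I_i) * S_I(c3 E_i - c4 I_i
                    + c6 sum_j A_ij I_j(t - d_ij/t_d))            + sigma v_i(t)

with the shifted logistic S(x) = 1/(1+exp(-a(x-theta))) - 1/(1+exp(a*theta)),
so S(0) = 0 and the origin is a fixed point. A is the subject's structural
connectivity matrix; c5 scales excitatory inter-regional coupling and
c6 = c5/4 the inhibitory one; d_ij/t_d is the axonal conduction delay between
region centroids at transmission velocity t_d = 10 mm/ms. P_i(t) is an
external (stimulation) input to the excitatory population. Integration is a
stochastic midpoint Runge-Kutta at a fixed 0.1 ms step with small additive
Gaussian noise on both state variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import seedseq
from .connectome import RegionSet, StructuralConnectome

__all__ = [
    "WilsonCowanParams",
    "Pulse",
    "StimulusSchedule",
    "SimulationTrace",
    "sigmoid",
    "sigmoid_max",
    "derivatives",
    "simulate",
    "region_noise_streams",
    "IntegrationError",
]

try:  # numba gives a ~50x faster inner loop; the numpy path is equivalent
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: states beyond this magnitude abort the run (the model's states are
#: population fractions, bounded well below 1 in any sane regime)
BLOWUP_LIMIT = 10.0


@dataclass(frozen=True)
class WilsonCowanParams:
    """Model constants. Defaults are the standard biologically derived set.

    Units: time in ms, distances in mm, velocity t_d in mm/ms (= m/s).
    ``c6_ratio`` fixes the inhibitory inter-regional coupling at
    c6 = c6_ratio * c5 (the approximate inhibitory/excitatory coupling ratio).
    """

    c1: float = 16.0
    c2: float = 12.0
    c3: float = 15.0
    c4: float = 3.0
    a_E: float = 1.3
    a_I: float = 2.0
    theta_E: float = 4.0
    theta_I: float = 3.7
    tau: float = 8.0
    sigma: float = 1e-5
    t_d: float = 10.0
    step_h: float = 0.1
    c6_ratio: float = 0.25

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4", "a_E", "a_I", "tau", "step_h", "t_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def S_E_max(self) -> float:
        """Asymptotic maximum of the excitatory sigmoid."""
        return sigmoid_max(self.a_E, self.theta_E)

    @property
    def S_I_max(self) -> float:
        return sigmoid_max(self.a_I, self.theta_I)


def sigmoid(x, a: float, theta: float):
    """Shifted logistic S(x) = 1/(1+e^{-a(x-theta)}) - 1/(1+e^{a theta}).

    The subtracted constant pins S(0) = 0, making the origin an equilibrium
    of the unforced model. Strictly increasing; sup S = sigmoid_max(a, theta).
    """
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-a * (x - theta))) - 1.0 / (1.0 + np.exp(a * theta))


def sigmoid_max(a: float, theta: float) -> float:
    return 1.0 - 1.0 / (1.0 + np.exp(a * theta))


# ---------------------------------------------------------------------------
# stimulation schedules

@dataclass(frozen=True)
class Pulse:
    """Constant external input to a set of regions over [onset_ms, offset_ms)."""

    regions: tuple[str, ...]
    amplitude: float
    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("pulse onset must precede offset")
        if not np.isfinite(self.amplitude):
            raise ValueError("pulse amplitude must be finite")


@dataclass(frozen=True)
class StimulusSchedule:
    """Piecewise-constant external input P_i(t); times relative to trace start."""

    pulses: tuple[Pulse, ...] = ()

    @classmethod
    def single_pulse(cls, targets: RegionSet, amplitude: float,
                     onset_ms: float, offset_ms: float) -> "StimulusSchedule":
        return cls((Pulse(tuple(targets.labels), amplitude, onset_ms, offset_ms),))

    def render(self, conn: StructuralConnectome, n_steps: int, step_h: float,
               offset_steps: int = 0) -> np.ndarray:
        """P as an (n_regions, n_steps) array on the integration grid.

        ``offset_steps`` shifts the schedule right (used to place the trace
        origin after the stabilization window).
        """
        P = np.zeros((conn.n_regions, n_steps))
        for pulse in self.pulses:
            idx = conn.index_of(pulse.regions)
            a = max(int(round(pulse.onset_ms / step_h)) + offset_steps, 0)
            b = min(int(round(pulse.offset_ms / step_h)) + offset_steps, n_steps)
            if a < b:
                P[idx, a:b] += pulse.amplitude
        return P


@dataclass
class SimulationTrace:
    """E/I time series on a uniform grid, plus run metadata."""

    time_ms: np.ndarray
    E: np.ndarray
    I: np.ndarray
    labels: list[str]
    c5: float
    seed: object = None
    schedule: StimulusSchedule | None = None

    @property
    def step_h(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def segment(self, t0_ms: float, t1_ms: float) -> "SimulationTrace":
        """Sub-trace on [t0_ms, t1_ms) of the trace's own time axis."""
        m = (self.time_ms >= t0_ms - 1e-9) & (self.time_ms < t1_ms - 1e-9)
        return replace(self, time_ms=self.time_ms[m], E=self.E[:, m], I=self.I[:, m])

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.E.T, columns=self.labels)
        df.insert(0, "time_ms", self.time_ms)
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset("E", data=self.E)
            f.create_dataset("I", data=self.I)
            f.create_dataset("labels", data=np.array(self.labels, dtype="S"))
            f.attrs["c5"] = self.c5


class IntegrationError(RuntimeError):
    """Raised when the state leaves the physically meaningful range."""


# ---------------------------------------------------------------------------
# right-hand side (reference implementation; the integrator core re-derives
# the same expressions in compiled form)

def derivatives(E, I, history_E, history_I, conn: StructuralConnectome,
                c5: float, params: WilsonCowanParams, P=None):
    """Deterministic drift (dE/dt, dI/dt) at the current time.

    ``history_E``/``history_I`` are (n, H) arrays of past samples on the
    integration grid whose last column is the current time; they must cover
    the maximum conduction delay of the connectome.
    """
    E = np.asarray(E, float)
    I = np.asarray(I, float)
    n = conn.n_regions
    dsteps = delay_steps(conn, params)
    H = np.asarray(history_E).shape[1]
    if dsteps.max() >= H:
        raise ValueError(
            f"history of {H} samples shorter than max delay of {int(dsteps.max())} steps"
        )
    cols = H - 1 - dsteps  # (n, n): sample index of E_j(t - tau_dij)
    Ed = np.take_along_axis(np.asarray(history_E, float), cols.T, axis=1)  # Ed[j,i]
    Id = np.take_along_axis(np.asarray(history_I, float), cols.T, axis=1)
    coup_E = c5 * np.einsum("ij,ji->i", conn.A, Ed)
    coup_I = params.c6_ratio * c5 * np.einsum("ij,ji->i", conn.A, Id)
    if P is None:
        P = np.zeros(n)
    xE = params.c1 * E - params.c2 * I + coup_E + np.asarray(P, float)
    xI = params.c3 * E - params.c4 * I + coup_I
    dE = (-E + (params.S_E_max - E) * sigmoid(xE, params.a_E, params.theta_E)) / params.tau
    dI = (-I + (params.S_I_max - I) * sigmoid(xI, params.a_I, params.theta_I)) / params.tau
    return dE, dI


def delay_steps(conn: StructuralConnectome, params: WilsonCowanParams) -> np.ndarray:
    """Conduction delays d_ij / t_d rounded to integer integration steps."""
    return np.rint(conn.distances / params.t_d / params.step_h).astype(np.int64)


def region_noise_streams(seed, n_regions: int, n_steps: int):
    """Independent per-region Gaussian noise streams (wE, wI), each (n, T).

    Region i's stream depends only on (seed, i) — not on how many regions are
    simulated — so a subnetwork simulated alone sees the same noise it would
    see inside the full network.
    """
    children = seedseq(seed).spawn(n_regions)
    wE = np.empty((n_regions, n_steps))
    wI = np.empty((n_regions, n_steps))
    for i, child in enumerate(children):
        arr = np.random.default_rng(child).standard_normal((2, n_steps))
        wE[i] = arr[0]
        wI[i] = arr[1]
    return wE, wI


# ---------------------------------------------------------------------------
# integrator cores

def _core_numpy(E, I, wE, wI, P, A_idx_i, A_idx_j, A_w, A_d, c5, c6,
                c1, c2, c3, c4, aE, aI, thE, thI, SEm, SIm, tau, sigma, h, E0, I0):
    n, T1 = E.shape
    n_steps = T1 - 1
    sE_off = 1.0 / (1.0 + np.exp(aE * thE))
    sI_off = 1.0 / (1.0 + np.exp(aI * thI))
    for t in range(n_steps):
        tcols = t - A_d
        past = tcols >= 0
        Ed = np.where(past, E[A_idx_j, np.maximum(tcols, 0)], E0)
        Id = np.where(past, I[A_idx_j, np.maximum(tcols, 0)], I0)
        coup_E = c5 * np.bincount(A_idx_i, weights=A_w * Ed, minlength=n)
        coup_I = c6 * np.bincount(A_idx_i, weights=A_w * Id, minlength=n)
        Et, It, Pt = E[:, t], I[:, t], P[:, t]
        xE = c1 * Et - c2 * It + coup_E + Pt
        xI = c3 * Et - c4 * It + coup_I
        k1E = (-Et + (SEm - Et) * (1.0 / (1.0 + np.exp(-aE * (xE - thE))) - sE_off)) / tau
        k1I = (-It + (SIm - It) * (1.0 / (1.0 + np.exp(-aI * (xI - thI))) - sI_off)) / tau
        Em = Et + 0.5 * h * k1E
        Im = It + 0.5 * h * k1I
        xE = c1 * Em - c2 * Im + coup_E + Pt
        xI = c3 * Em - c4 * Im + coup_I
        k2E = (-Em + (SEm - Em) * (1.0 / (1.0 + np.exp(-aE * (xE - thE))) - sE_off)) / tau
        k2I = (-Im + (SIm - Im) * (1.0 / (1.0 + np.exp(-aI * (xI - thI))) - sI_off)) / tau
        E[:, t + 1] = Et + h * k2E + sigma * wE[:, t]
        I[:, t + 1] = It + h * k2I + sigma * wI[:, t]
        if np.max(np.abs(E[:, t + 1])) > BLOWUP_LIMIT or np.max(np.abs(I[:, t + 1])) > BLOWUP_LIMIT:
            return t + 1
    return -1


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _core_numba(E, I, wE, wI, P, indptr, indices, weights, dsteps, c5, c6,
                    c1, c2, c3, c4, aE, aI, thE, thI, SEm, SIm, tau, sigma, h,
                    E0, I0):  # pragma: no cover - exercised via simulate()
        n, T1 = E.shape
        n_steps = T1 - 1
        sE_off = 1.0 / (1.0 + np.exp(aE * thE))
        sI_off = 1.0 / (1.0 + np.exp(aI * thI))
        coup_E = np.empty(n)
        coup_I = np.empty(n)
        for t in range(n_steps):
            for i in range(n):
                accE = 0.0
                accI = 0.0
                for k in range(indptr[i], indptr[i + 1]):
                    j = indices[k]
                    tt = t - dsteps[k]
                    if tt >= 0:
                        accE += weights[k] * E[j, tt]
                        accI += weights[k] * I[j, tt]
                    else:
                        accE += weights[k] * E0
                        accI += weights[k] * I0
                coup_E[i] = c5 * accE
                coup_I[i] = c6 * accI
            bad = False
            for i in range(n):
                Et = E[i, t]
                It = I[i, t]
                xE = c1 * Et - c2 * It + coup_E[i] + P[i, t]
                xI = c3 * Et - c4 * It + coup_I[i]
                k1E = (-Et + (SEm - Et) * (1.0 / (1.0 + np.exp(-aE * (xE - thE))) - sE_off)) / tau
                k1I = (-It + (SIm - It) * (1.0 / (1.0 + np.exp(-aI * (xI - thI))) - sI_off)) / tau
                Em = Et + 0.5 * h * k1E
                Im = It + 0.5 * h * k1I
                xE = c1 * Em - c2 * Im + coup_E[i] + P[i, t]
                xI = c3 * Em - c4 * Im + coup_I[i]
                k2E = (-Em + (SEm - Em) * (1.0 / (1.0 + np.exp(-aE * (xE - thE))) - sE_off)) / tau
                k2I = (-Im + (SIm - Im) * (1.0 / (1.0 + np.exp(-aI * (xI - thI))) - sI_off)) / tau
                E[i, t + 1] = Et + h * k2E + sigma * wE[i, t]
                I[i, t + 1] = It + h * k2I + sigma * wI[i, t]
                if abs(E[i, t + 1]) > BLOWUP_LIMIT or abs(I[i, t + 1]) > BLOWUP_LIMIT:
                    bad = True
            if bad:
                return t + 1
        return -1


def simulate(conn: StructuralConnectome, params: WilsonCowanParams, c5: float,
             schedule: StimulusSchedule | None = None, duration_ms: float = 1000.0,
             seed=None, stabilization_ms: float = 1000.0,
             keep_stabilization: bool = False, initial_value: float = 0.1,
             noise: tuple[np.ndarray, np.ndarray] | None = None) -> SimulationTrace:
    """Integrate the network for ``stabilization_ms + duration_ms``.

    The system starts from E_i(0) = I_i(0) = 0.1 (pre-history is held at the
    initial condition for the delayed coupling terms), runs unstimulated for
    ``stabilization_ms``, then for ``duration_ms`` with the schedule applied
    (schedule times are relative to the end of stabilization). The returned
    trace drops the stabilization window unless ``keep_stabilization``.

    Midpoint RK2 at step ``params.step_h`` with additive per-step noise
    sigma*N(0,1) on each state variable; delayed coupling is evaluated from
    the integration-grid history, delays rounded to the nearest step. A
    custom ``noise`` pair (wE, wI) of shape (n, total_steps) overrides the
    seeded per-region streams.
    """
    if c5 < 0:
        raise ValueError("c5 must be >= 0")
    if duration_ms <= 0:
        raise ValueError("duration_ms must be > 0")
    h = params.step_h
    n = conn.n_regions
    stab_steps = int(round(stabilization_ms / h))
    n_steps = stab_steps + int(round(duration_ms / h))

    schedule = schedule or StimulusSchedule()
    P = schedule.render(conn, n_steps + 1, h, offset_steps=stab_steps)

    if noise is not None:
        wE, wI = noise
        if wE.shape[1] < n_steps or wI.shape[1] < n_steps:
            raise ValueError("noise arrays shorter than the simulation")
    elif params.sigma > 0:
        wE, wI = region_noise_streams(seed, n, n_steps)
    else:
        wE = wI = np.zeros((n, n_steps))

    E = np.empty((n, n_steps + 1))
    I = np.empty((n, n_steps + 1))
    E[:, 0] = initial_value
    I[:, 0] = initial_value

    dmat = delay_steps(conn, params)
    args = (c5, params.c6_ratio * c5, params.c1, params.c2, params.c3, params.c4,
            params.a_E, params.a_I, params.theta_E, params.theta_I,
            params.S_E_max, params.S_I_max, params.tau, params.sigma, h,
            initial_value, initial_value)
    if _HAVE_NUMBA:
        import scipy.sparse

        csr = scipy.sparse.csr_matrix(conn.A)
        dvals = dmat[csr.nonzero()] if csr.nnz else np.zeros(0, dtype=np.int64)
        bad = _core_numba(E, I, wE, wI, P,
                          csr.indptr.astype(np.int64), csr.indices.astype(np.int64),
                          csr.data.astype(np.float64), dvals.astype(np.int64), *args)
    else:  # pragma: no cover
        ii, jj = np.nonzero(conn.A)
        bad = _core_numpy(E, I, wE, wI, P, ii, jj, conn.A[ii, jj], dmat[ii, jj], *args)
    if bad >= 0:
        raise IntegrationError(
            f"state exceeded |{BLOWUP_LIMIT}| at step {bad} (t = {bad * h:.1f} ms, c5 = {c5})"
        )

    time_ms = np.arange(n_steps + 1) * h - stab_steps * h
    trace = SimulationTrace(time_ms=time_ms, E=E, I=I, labels=list(conn.labels),
                            c5=c5, seed=seed, schedule=schedule)
    if not keep_stabilization:
        keep = time_ms >= -1e-9
        trace = replace(trace, time_ms=time_ms[keep], E=E[:, keep], I=I[:, keep])
    return trace
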