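"""Synthetic cohort generator: connectomes, region geometry, circuits, behavior.

The generator emulates the statistical structure a cohort of subject-specific
DSI connectomes presents to the downstream analysis:

* sparse, nonnegative, symmetric weight matrices with heavy-tailed
  (log-normal) weights and a hemisphere-like two-block structure;
* region centroids forming two spatially separated clusters, so that
  inter-regional conduction delays are heterogeneous;
* a planted, densely connected task-circuit subnetwork;
* per-subject, per-task, per-condition median response times generated as a
  linear function of a chosen model feature plus Gaussian noise.

Subjects share the region atlas (labels, centroids, volumes) *and* the edge
weight multiset: a single sorted weight list is drawn per cohort and, for
each subject, assigned to region pairs by the rank of a noisy hub-affinity
score with subject-specific strength. Individual differences therefore live
entirely in weight *placement* (how strongly large weights concentrate on a
subject's hub regions), not in the weight distribution itself. This is what
makes the weight-shuffling null a true control: shuffling preserves each
subject's multiset exactly, so any across-subject feature ordering that
survives shuffling could not have come from network organization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import RegionSet, StructuralConnectome, write_connectome, write_region_set

__all__ = [
    "CohortSpec",
    "BehaviorSpec",
    "generate_connectome",
    "generate_cohort",
    "generate_behavior",
    "default_stimulation_site",
    "weakly_connected_site",
    "excitability_cohort_spec",
    "circuit_cohort_spec",
    "DEFAULT_CIRCUIT",
    "write_cohort",
]

TASKS = ("VG", "SC", "NR")  # verb generation, sentence completion, number reading
CONDITIONS = ("before", "after")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``weight_sigma`` is the log-normal shape parameter of the edge-weight
    distribution and ``mean_degree`` its scale, expressed as the cohort's
    mean weighted node degree (each subject is normalized to it exactly, so
    subjects differ in structure, never in total connection weight).
    ``hub_heterogeneity`` is the (low, high) range of the per-subject
    hub-affinity strength; subject s receives the s-th value of an even grid
    over the range, giving the cohort a reproducible spread of network
    concentration and hence of dynamical excitability.
    """

    n_subjects: int = 10
    n_regions: int = 50
    density: float = 0.15
    weight_sigma: float = 1.0
    mean_degree: float = 70.0
    hemisphere_block_bonus: float = 1.2
    circuit_labels: tuple[str, ...] = ()
    circuit_bonus: float = 1.0
    hub_heterogeneity: tuple[float, float] = (0.0, 1.2)
    coordinate_extent: float = 140.0
    volume_range: tuple[float, float] = (1500.0, 8000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 8:
            raise ValueError("n_regions must be >= 8")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.hemisphere_block_bonus < 1 or self.circuit_bonus < 1:
            raise ValueError("bonuses must be >= 1")
        if not (0 < self.volume_range[0] < self.volume_range[1]):
            raise ValueError("volume_range must be strictly positive and increasing")
        if self.weight_sigma <= 0 or self.mean_degree <= 0:
            raise ValueError("weight_sigma and mean_degree must be > 0")
        if self.coordinate_extent <= 0:
            raise ValueError("coordinate_extent must be > 0")
        object.__setattr__(self, "circuit_labels", tuple(self.circuit_labels))

    @property
    def labels(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_regions)]

    def circuit(self, name: str = "task_circuit") -> RegionSet:
        if not self.circuit_labels:
            raise ValueError("spec has no circuit_labels")
        return RegionSet(name=name, labels=self.circuit_labels)


def _atlas(spec: CohortSpec):
    """Shared region geometry: two hemisphere-like centroid clouds + volumes."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA71A5]))
    n = spec.n_regions
    half = n // 2
    hemi = np.zeros(n, dtype=int)
    hemi[half:] = 1
    centroids = rng.normal(scale=spec.coordinate_extent / 6, size=(n, 3))
    # separate hemispheres along x by half the coordinate extent
    centroids[:, 0] += (hemi - 0.5) * spec.coordinate_extent / 2
    volumes = rng.uniform(*spec.volume_range, size=n)
    return centroids, volumes, hemi


def _shared_weights(spec: CohortSpec) -> np.ndarray:
    """One descending weight list per cohort (zeros pad below the density cut)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xED6E5]))
    m = spec.n_regions * (spec.n_regions - 1) // 2
    nnz = max(int(round(spec.density * m)), 1)
    w = np.zeros(m)
    w[:nnz] = np.sort(rng.lognormal(0.0, spec.weight_sigma, size=nnz))[::-1]
    return w


def _hub_strength(spec: CohortSpec, subject_index: int) -> float:
    lo, hi = spec.hub_heterogeneity
    if spec.n_subjects == 1:
        return 0.5 * (lo + hi)
    return float(np.linspace(lo, hi, spec.n_subjects)[subject_index])


def generate_connectome(spec: CohortSpec, subject_index: int) -> StructuralConnectome:
    """One subject's structural connectome; bit-identical per (spec, index).

    The cohort's shared weight list is assigned to region pairs in rank order
    of ``gamma_s * (hub_i + hub_j)/sqrt(2) + noise``, where the hub scores and
    the noise are subject-specific and gamma_s is the subject's hub-affinity
    strength. Hemisphere and circuit bonuses multiply the assigned weights,
    and the matrix is rescaled so every subject has exactly the spec's mean
    weighted degree.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    centroids, volumes, hemi = _atlas(spec)
    labels = spec.labels
    n = spec.n_regions
    iu = np.triu_indices(n, k=1)
    m = len(iu[0])
    weights = _shared_weights(spec)
    nnz = int((weights > 0).sum())

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1 + subject_index]))
    gamma = _hub_strength(spec, subject_index)
    hub = rng.standard_normal(n)
    score = gamma * (hub[iu[0]] + hub[iu[1]]) / np.sqrt(2) + rng.standard_normal(m)

    # topology: every within-circuit pair carries an edge (the planted circuit
    # is densely connected); the remaining edges go to the highest-scoring
    # region pairs up to the spec's density. Circuit pairs receive a fixed
    # mid-band of the shared weight list (the contiguous run whose mean is
    # closest to the overall nonzero mean), so the circuit's internal coupling
    # is set by circuit_bonus alone, not by accidental hub alignment.
    if spec.circuit_labels:
        in_circ = np.isin(labels, spec.circuit_labels)
        circuit_pair = in_circ[iu[0]] & in_circ[iu[1]]
    else:
        circuit_pair = np.zeros(m, dtype=bool)
    w = np.zeros(m)
    k = min(int(circuit_pair.sum()), nnz)
    if k:
        nz = weights[:nnz]
        window_means = np.convolve(nz, np.ones(k) / k, mode="valid")
        start = int(np.argmin(np.abs(window_means - nz.mean())))
        circuit_vals = nz[start:start + k]
        free_vals = np.concatenate([nz[:start], nz[start + k:]])
        w[np.flatnonzero(circuit_pair)[:k]] = rng.permutation(circuit_vals)
    else:
        free_vals = weights[:nnz]
    # largest remaining weights onto the highest-scoring non-circuit pairs
    free_order = np.argsort(-np.where(circuit_pair, -np.inf, score))[: len(free_vals)]
    w[free_order] = np.sort(free_vals)[::-1]

    same_hemi = hemi[iu[0]] == hemi[iu[1]]
    w[same_hemi] *= spec.hemisphere_block_bonus
    w[circuit_pair] *= spec.circuit_bonus

    A = np.zeros((n, n))
    A[iu] = w
    A = A + A.T
    mean_deg = A.sum(axis=1).mean()
    if mean_deg > 0:
        A *= spec.mean_degree / mean_deg
    return StructuralConnectome(labels=labels, A=A, centroids=centroids, volumes=volumes)


def generate_cohort(spec: CohortSpec) -> list[StructuralConnectome]:
    """All subjects' connectomes; atlas shared, weights subject-specific."""
    return [generate_connectome(spec, s) for s in range(spec.n_subjects)]


def weakly_connected_site(conn: StructuralConnectome, circuit: RegionSet,
                          size: int = 4, name: str = "weak_site") -> RegionSet:
    """A stimulation site outside the planted pathway: the ``size`` non-circuit
    regions with the lowest weighted degree (weakest structural routes into
    the rest of the network, hence into the circuit)."""
    deg = conn.A.sum(axis=1)
    order = np.argsort(deg, kind="stable")
    labels = [conn.labels[i] for i in order if conn.labels[i] not in circuit.labels]
    if len(labels) < size:
        raise ValueError("not enough non-circuit regions")
    return RegionSet(name=name, labels=tuple(labels[:size]))


def default_stimulation_site(spec: CohortSpec, size: int = 4,
                             name: str = "stim_site") -> RegionSet:
    """The synthetic analogue of the 4-region stimulation seed: the first
    ``size`` circuit regions (the planted circuit contains its own site,
    mirroring a stimulation target embedded in its task circuit)."""
    if len(spec.circuit_labels) < size:
        raise ValueError("circuit smaller than the requested site")
    return RegionSet(name=name, labels=spec.circuit_labels[:size])


# ---------------------------------------------------------------------------
# canonical study conditions
#
# Two fixed synthetic-cohort conditions cover the analyses: a heterogeneous
# cohort for excitability mapping and behavior association (hub-affinity
# spread drives individual differences in c5T; the planted circuit carries no
# weight bonus so it does not pin the transition), and a homogeneous cohort
# with a strongly coupled circuit for stimulation-specificity experiments
# (fixed mid-range hub affinity; bonus 2.5 makes the circuit the preferred
# propagation pathway without saturating its members).

DEFAULT_CIRCUIT = tuple(f"R{i:03d}" for i in range(8, 20))


def excitability_cohort_spec(n_subjects: int = 12, seed: int = 7) -> CohortSpec:
    """Cohort for c5T mapping and behavior association (planted-signal runs)."""
    return CohortSpec(n_subjects=n_subjects, circuit_labels=DEFAULT_CIRCUIT,
                      circuit_bonus=1.0, seed=seed)


def circuit_cohort_spec(n_subjects: int = 5, seed: int = 21) -> CohortSpec:
    """Cohort for stimulation experiments with a strongly coupled task circuit."""
    return CohortSpec(n_subjects=n_subjects, circuit_labels=DEFAULT_CIRCUIT,
                      circuit_bonus=2.5, hub_heterogeneity=(0.5, 0.5), seed=seed)


# ---------------------------------------------------------------------------
# behavior

@dataclass(frozen=True)
class BehaviorSpec:
    """Linear response-time model: RT = intercept + slope * z(feature) + noise.

    ``driving_feature`` names which model feature generates the planted
    signal ("c5T", "circuit_functional_effect", or "independent" for a pure
    null in which response times ignore the features entirely). Features are
    z-scored before entering, so ``slope`` is ms per standard deviation of
    the driving feature regardless of its units.
    """

    intercept_ms: float = 900.0
    slope: float = 80.0
    noise_sd_ms: float = 20.0
    driving_feature: str = "c5T"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be >= 0")
        if self.driving_feature not in ("c5T", "circuit_functional_effect", "independent"):
            raise ValueError(f"unknown driving_feature {self.driving_feature!r}")


def generate_behavior(features, spec: BehaviorSpec,
                      tasks=TASKS, conditions=CONDITIONS,
                      subject_ids=None) -> pd.DataFrame:
    """Behavior table (subject_id, task, condition, median_rt_ms).

    With a driving feature, every (task, condition) cell gets its own noise
    draw around the same linear trend; with ``independent`` the response
    times are feature-free Gaussian draws around the intercept.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 1 or len(features) < 3:
        raise ValueError("need feature values for at least 3 subjects")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    n = len(features)
    if subject_ids is None:
        subject_ids = [f"sub-{i:02d}" for i in range(n)]
    rng = np.random.default_rng(spec.seed)
    if spec.driving_feature == "independent":
        trend = np.zeros(n)
    else:
        sd = features.std(ddof=0)
        if sd == 0:
            raise ValueError("driving feature has zero variance across subjects")
        trend = spec.slope * (features - features.mean()) / sd
    rows = []
    for task in tasks:
        for cond in conditions:
            rt = spec.intercept_ms + trend + rng.normal(0.0, spec.noise_sd_ms, size=n)
            rows.append(pd.DataFrame({
                "subject_id": subject_ids, "task": task,
                "condition": cond, "median_rt_ms": rt,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# on-disk cohort

def write_cohort(spec: CohortSpec, out_dir, behavior: pd.DataFrame | None = None) -> None:
    """Write the cohort in the pipeline's exchange formats (all TSV/text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in range(spec.n_subjects):
        conn = generate_connectome(spec, s)
        write_connectome(conn, out / f"sub-{s:02d}_connectome.tsv",
                         out / "regions.tsv" if s == 0 else out / "regions.tsv")
    if spec.circuit_labels:
        write_region_set(spec.circuit(), out / "task_circuit.txt")
    if behavior is not None:
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
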