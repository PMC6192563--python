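"""Structural connectome data model, I/O, nulls and variability maps.

A structural connectome is a weighted, undirected, zero-diagonal graph whose
nodes are parcellated brain regions. Edge weights are streamline densities
(streamline counts normalized by the summed volume of the two endpoint
regions); region centroids (mm) provide the Euclidean distances that set
inter-regional conduction delays in the dynamical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StructuralConnectome",
    "RegionSet",
    "read_connectome",
    "write_connectome",
    "read_region_set",
    "write_region_set",
    "build_from_streamlines",
    "shuffle_edge_weights",
    "structural_variability",
]

#: relative asymmetry above this is treated as data corruption, not round-off
ASYMMETRY_RTOL = 1e-9


@dataclass
class StructuralConnectome:
    """Weighted symmetric adjacency plus region metadata.

    Attributes
    ----------
    labels : list of str
        Ordered region identifiers; defines the row/column order of ``A``.
    A : (n, n) ndarray
        Nonnegative symmetric weights with zero diagonal (streamline density).
    centroids : (n, 3) ndarray
        Region centroid coordinates in mm.
    volumes : (n,) ndarray
        Region volumes in mm^3, strictly positive.
    """

    labels: list[str]
    A: np.ndarray
    centroids: np.ndarray
    volumes: np.ndarray
    _distances: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("region labels must be unique")
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}, got {self.A.shape}")
        if self.centroids.shape != (n, 3):
            raise ValueError(f"centroids must be {n}x3, got {self.centroids.shape}")
        if self.volumes.shape != (n,):
            raise ValueError("volumes must be length n")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be strictly positive")
        if np.any(self.A < 0):
            raise ValueError("negative weights are not allowed")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("diagonal of A must be zero")
        scale = np.abs(self.A).max() or 1.0
        asym = np.abs(self.A - self.A.T).max()
        if asym > ASYMMETRY_RTOL * scale:
            raise ValueError(
                f"A is asymmetric beyond tolerance (max |A-A'| = {asym:g})"
            )
        if asym > 0:  # symmetrize round-off level asymmetry
            self.A = 0.5 * (self.A + self.A.T)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def distances(self) -> np.ndarray:
        """Euclidean inter-centroid distances d_ij in mm (symmetric, zero diag)."""
        if self._distances is None:
            diff = self.centroids[:, None, :] - self.centroids[None, :, :]
            self._distances = np.sqrt((diff**2).sum(axis=2))
        return self._distances

    def index_of(self, labels) -> np.ndarray:
        """Integer indices of the given labels, in order; unknown label -> KeyError."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([pos[lab] for lab in labels], dtype=int)
        except KeyError as e:
            raise KeyError(f"label {e.args[0]!r} not in connectome") from None


@dataclass(frozen=True)
class RegionSet:
    """A named subset of connectome regions (a stimulation site or task circuit)."""

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("region set must be nonempty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region set labels must be unique")
        object.__setattr__(self, "labels", tuple(self.labels))

    def validate_against(self, conn: StructuralConnectome) -> None:
        missing = [lab for lab in self.labels if lab not in conn.labels]
        if missing:
            raise ValueError(f"region set {self.name!r}: labels not in connectome: {missing}")


# ---------------------------------------------------------------------------
# file I/O (tab-separated text; see docs/methods.md for the layout)

def write_connectome(conn: StructuralConnectome, matrix_path, metadata_path) -> None:
    mat = pd.DataFrame(conn.A, index=conn.labels, columns=conn.labels)
    mat.to_csv(matrix_path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "label": conn.labels,
            "x_mm": conn.centroids[:, 0],
            "y_mm": conn.centroids[:, 1],
            "z_mm": conn.centroids[:, 2],
            "volume_mm3": conn.volumes,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.17g")


def read_connectome(matrix_path, metadata_path) -> StructuralConnectome:
    """Read a connectome from matrix + metadata TSV files.

    The matrix file is a labelled square table; the metadata file has columns
    label, x_mm, y_mm, z_mm, volume_mm3. Label sets must agree; the metadata
    is reordered to the matrix's label order.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"matrix is not square: {mat.shape}")
    labels = [str(x) for x in mat.index]
    if [str(c) for c in mat.columns] != labels:
        raise ValueError("matrix row and column labels disagree")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"label": str})
    meta = meta.set_index("label")
    missing = [lab for lab in labels if lab not in meta.index]
    if missing:
        raise ValueError(f"metadata missing labels: {missing}")
    meta = meta.loc[labels]
    return StructuralConnectome(
        labels=labels,
        A=mat.to_numpy(dtype=float),
        centroids=meta[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        volumes=meta["volume_mm3"].to_numpy(dtype=float),
    )


def write_region_set(rs: RegionSet, path) -> None:
    Path(path).write_text("\n".join(rs.labels) + "\n")


def read_region_set(path, name: str | None = None) -> RegionSet:
    labels = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return RegionSet(name=name or Path(path).stem, labels=tuple(labels))


# ---------------------------------------------------------------------------
# construction and nulls

def build_from_streamlines(counts, volumes, labels=None, centroids=None) -> StructuralConnectome:
    """Connection weights from streamline counts: A_ij = counts_ij / (vol_i + vol_j).

    Normalizing a pairwise streamline count by the summed volume of its two
    endpoint regions converts counts into a volume-corrected streamline
    density, so large parcels do not dominate purely by size.
    """
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    n = counts.shape[0]
    if counts.shape != (n, n):
        raise ValueError("counts must be square")
    if np.any(counts != counts.T):
        raise ValueError("streamline counts must be symmetric")
    if np.any(np.diag(counts) != 0):
        raise ValueError("streamline counts must have zero diagonal")
    if np.any(counts < 0):
        raise ValueError("streamline counts must be nonnegative")
    if np.any(volumes <= 0):
        raise ValueError("volumes must be strictly positive")
    A = counts / (volumes[:, None] + volumes[None, :])
    np.fill_diagonal(A, 0.0)
    if labels is None:
        labels = [f"R{i:03d}" for i in range(n)]
    if centroids is None:
        centroids = np.zeros((n, 3))
    return StructuralConnectome(labels=list(labels), A=A, centroids=centroids, volumes=volumes)


def shuffle_edge_weights(conn: StructuralConnectome, seed) -> StructuralConnectome:
    """Null model: randomly reassign connection strengths to region pairs.

    The full upper-triangle multiset of weights (zeros included) is permuted
    uniformly at random and mirrored, so the overall weight distribution —
    and hence the total weight and average degree — is preserved exactly
    while the network organization is destroyed.
    """
    n = conn.n_regions
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    vals = conn.A[iu].copy()
    rng.shuffle(vals)
    A = np.zeros_like(conn.A)
    A[iu] = vals
    A = A + A.T
    return StructuralConnectome(
        labels=list(conn.labels), A=A, centroids=conn.centroids.copy(),
        volumes=conn.volumes.copy(),
    )


def structural_variability(cohort: list[StructuralConnectome]):
    """Cross-subject edge-weight variability (coefficient of variation).

    Returns ``(edge_map, regional_map)``: the edge map is the sample standard
    deviation of each edge weight across subjects divided by its mean across
    subjects (NaN where the mean is zero, i.e. the edge is absent in every
    subject); the regional map averages each region's defined incident edges.
    """
    if len(cohort) < 2:
        raise ValueError("structural variability needs at least 2 subjects")
    labels = cohort[0].labels
    for c in cohort[1:]:
        if c.labels != labels:
            raise ValueError("cohort subjects must share region labels")
    stack = np.stack([c.A for c in cohort])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        edge_map = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    np.fill_diagonal(edge_map, np.nan)
    with np.errstate(invalid="ignore"):
        regional_map = np.nanmean(edge_map, axis=1)
    return edge_map, regional_map
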