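"""Graph statistics of the structural matrix.

Weighted degree, spectral radius of the adjacency (whose inverse bounds the
coupling at which network-wide synchronization can onset), and Laplacian
synchronizability lambda2(L)/lambda_max(L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .connectome import StructuralConnectome

__all__ = [
    "NetworkFeatureRecord",
    "weighted_degree",
    "spectral_radius",
    "synchronizability",
    "network_features",
]


@dataclass(frozen=True)
class NetworkFeatureRecord:
    subject_id: str
    average_degree: float
    spectral_radius: float
    inverse_spectral_radius: float
    synchronizability: float


def weighted_degree(conn: StructuralConnectome):
    """Per-region weighted degree k_i = sum_j A_ij and its mean over regions."""
    k = conn.A.sum(axis=1)
    return k, float(k.mean())


def spectral_radius(conn: StructuralConnectome) -> float:
    """Largest eigenvalue of the (symmetric) adjacency matrix."""
    return float(scipy.linalg.eigvalsh(conn.A)[-1])


def inverse_spectral_radius(conn: StructuralConnectome) -> float:
    sr = spectral_radius(conn)
    if sr <= 0:
        raise ValueError("inverse spectral radius undefined for a zero matrix")
    return 1.0 / sr


def synchronizability(conn: StructuralConnectome) -> float:
    """lambda2(L) / lambda_max(L) with L = D - A; 0 for disconnected graphs."""
    if conn.n_regions < 2:
        raise ValueError("synchronizability needs at least 2 regions")
    L = np.diag(conn.A.sum(axis=1)) - conn.A
    ev = scipy.linalg.eigvalsh(L)
    lam_max = ev[-1]
    if lam_max <= 0:
        return 0.0
    lam2 = max(ev[1], 0.0)  # clip tiny negative round-off; disconnected -> 0
    return float(lam2 / lam_max)


def network_features(conn: StructuralConnectome, subject_id: str = "") -> NetworkFeatureRecord:
    _, avg_k = weighted_degree(conn)
    sr = spectral_radius(conn)
    return NetworkFeatureRecord(
        subject_id=subject_id,
        average_degree=avg_k,
        spectral_radius=sr,
        inverse_spectral_radius=(1.0 / sr if sr > 0 else float("nan")),
        synchronizability=synchronizability(conn),
    )
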