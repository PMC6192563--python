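"""Statistical layer: bootstrapped Pearson correlations between model features
and behavior, FDR control across tasks, and the randomization controls
(random subnetworks, alternate stimulation sites, weight-shuffled cohorts).

The inference is small-n by design (a cohort of ~10 subjects):
Pearson r with the standard t reference distribution, a 90% CI from 5,000
pair-resampling bootstrap replicates (0.05/0.95 quantiles), and
Benjamini-Hochberg FDR across the task family within each feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from ._rng import seedseq
from .connectome import RegionSet, StructuralConnectome, shuffle_edge_weights
from .excitability import default_grid, detect_transition, sweep_coupling
from .netstats import network_features
from .stimulation import functional_effect, stimulation_result
from .wilson_cowan import WilsonCowanParams

__all__ = [
    "AssociationResult",
    "NullSummary",
    "pearson_bootstrap",
    "fdr_across_tasks",
    "random_subnetwork_null",
    "knn_adjacency",
    "enumerate_connected_sites",
    "alternate_site_control",
    "run_full_analysis",
]


@dataclass
class AssociationResult:
    feature: str
    task: str
    condition: str
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    p_fdr: float = float("nan")
    fdr_significant: bool = False


@dataclass
class NullSummary:
    """Outcome of a subnetwork permutation null."""

    n_draws: int
    fraction_significant: float
    r_values: np.ndarray
    p_values: np.ndarray
    overlap_fraction: np.ndarray  # per-draw overlap with the true circuit
    rule: str = "r>0.5 and p<0.05"


def pearson_bootstrap(x, y, n_boot: int = 5000, quantiles=(0.05, 0.95),
                      seed=None, feature: str = "", task: str = "",
                      condition: str = "") -> AssociationResult:
    """Pearson r, two-sided t-test p, and a bootstrap quantile CI.

    The CI resamples (x, y) pairs with replacement ``n_boot`` times;
    degenerate resamples (zero variance in either variable) are redrawn so
    every replicate yields a defined correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-d samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = scipy.stats.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    todo = np.arange(n_boot)
    for _ in range(1000):  # redraw degenerate resamples
        idx = rng.integers(0, n, size=(len(todo), n))
        xs, ys = x[idx], y[idx]
        sx = xs.std(axis=1)
        sy = ys.std(axis=1)
        ok = (sx > 0) & (sy > 0)
        xs_c = xs - xs.mean(axis=1, keepdims=True)
        ys_c = ys - ys.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rb = (xs_c * ys_c).mean(axis=1) / (sx * sy)
        boots[todo[ok]] = np.clip(rb[ok], -1.0, 1.0)
        todo = todo[~ok]
        if len(todo) == 0:
            break
    else:  # pragma: no cover - would need pathological inputs
        raise RuntimeError("could not draw non-degenerate bootstrap resamples")
    ci_low, ci_high = np.quantile(boots, quantiles)
    return AssociationResult(feature=feature, task=task, condition=condition,
                             r=float(r), p=float(p), ci_low=float(ci_low),
                             ci_high=float(ci_high), n=n)


def fdr_across_tasks(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up over the task family.

    Returns ``(significant_flags, adjusted_p)`` in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    flags, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return flags, p_adj


def annotate_fdr(results: list[AssociationResult], alpha: float = 0.05) -> None:
    """FDR-correct p-values across tasks, separately per (feature, condition)."""
    keyed: dict[tuple, list[AssociationResult]] = {}
    for res in results:
        keyed.setdefault((res.feature, res.condition), []).append(res)
    for group in keyed.values():
        flags, p_adj = fdr_across_tasks([g.p for g in group])
        for g, f, pa in zip(group, flags, p_adj):
            g.fdr_significant = bool(f)
            g.p_fdr = float(pa)


# ---------------------------------------------------------------------------
# randomization controls

def random_subnetwork_null(dfc_per_subject: list[np.ndarray], behavior,
                           labels: list[str], circuit: RegionSet,
                           circuit_size: int | None = None, n_draws: int = 10000,
                           r_threshold: float = 0.5, p_threshold: float = 0.05,
                           seed=None) -> NullSummary:
    """Circuit-specificity null: random region subsets of the circuit's size.

    Each draw picks ``circuit_size`` regions uniformly at random, computes
    every subject's within-subset functional effect from the already-computed
    dFC matrices (no re-simulation), and correlates it with behavior. The
    summary records the fraction of draws reaching r > 0.5 and p < 0.05, and
    each draw's overlap with the true circuit.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    circuit_size = len(circuit.labels) if circuit_size is None else circuit_size
    n = len(labels)
    if circuit_size < 2:
        raise ValueError("circuit_size must be >= 2")
    if circuit_size > n:
        raise ValueError("circuit_size exceeds the number of regions")
    behavior = np.asarray(behavior, dtype=float)
    rng = np.random.default_rng(seed)
    circ_mask = np.isin(labels, circuit.labels)
    rs = np.empty(n_draws)
    ps = np.empty(n_draws)
    overlap = np.empty(n_draws)
    label_arr = np.asarray(labels)
    for d in range(n_draws):
        idx = rng.choice(n, size=circuit_size, replace=False)
        subset = RegionSet(name=f"draw{d}", labels=tuple(label_arr[idx]))
        effects = np.array([functional_effect(dfc, labels, subset)
                            for dfc in dfc_per_subject])
        overlap[d] = circ_mask[idx].mean()
        if effects.std() == 0 or behavior.std() == 0:
            rs[d], ps[d] = 0.0, 1.0
        else:
            rs[d], ps[d] = scipy.stats.pearsonr(effects, behavior)
    hits = (rs > r_threshold) & (ps < p_threshold)
    return NullSummary(n_draws=n_draws, fraction_significant=float(hits.mean()),
                       r_values=rs, p_values=ps, overlap_fraction=overlap)


def knn_adjacency(conn: StructuralConnectome, k: int = 3) -> np.ndarray:
    """Symmetric k-nearest-neighbor spatial adjacency on region centroids."""
    d = conn.distances.copy()
    np.fill_diagonal(d, np.inf)
    n = conn.n_regions
    adj = np.zeros((n, n), dtype=bool)
    nn = np.argsort(d, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    adj[rows, nn.ravel()] = True
    return adj | adj.T


def enumerate_connected_sites(adjacency: np.ndarray, candidates: list[int],
                              site_size: int, max_sites: int | None = None,
                              seed=None) -> list[tuple[int, ...]]:
    """All connected ``site_size``-subsets of ``candidates`` under the adjacency.

    Standard connected-subgraph enumeration restricted to the candidate set;
    with ``max_sites`` the full enumeration is subsampled reproducibly.
    """
    if site_size < 1:
        raise ValueError("site_size must be >= 1")
    cand = sorted(candidates)
    if site_size > len(cand):
        raise ValueError("site_size exceeds the candidate set")
    cset = set(cand)
    found: set[tuple[int, ...]] = set()

    def grow(subset: set[int], frontier: set[int]) -> None:
        if len(subset) == site_size:
            found.add(tuple(sorted(subset)))
            return
        for v in sorted(frontier):
            # only extend with vertices larger than the seed to avoid duplicates
            new_frontier = {u for u in np.flatnonzero(adjacency[v])
                            if u in cset and u not in subset and u > min(subset)}
            grow(subset | {v}, (frontier | new_frontier) - {v} - subset)

    for v in cand:
        nbrs = {u for u in np.flatnonzero(adjacency[v]) if u in cset and u > v}
        grow({v}, nbrs)
    sites = sorted(found)
    if not sites:
        raise ValueError(f"no connected group of size {site_size} in the candidate set")
    if max_sites is not None and len(sites) > max_sites:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(sites), size=max_sites, replace=False)
        sites = [sites[i] for i in sorted(pick)]
    return sites


def alternate_site_control(cohort: list[StructuralConnectome], c5T_values,
                           circuit: RegionSet, behavior, params: WilsonCowanParams,
                           site_size: int = 4, k_neighbors: int = 3,
                           max_sites: int | None = 7, seed=None,
                           grid_step: float = 0.001, task: str = "",
                           condition: str = "before", n_boot: int = 1000,
                           ) -> list[tuple[RegionSet, AssociationResult]]:
    """Stimulation-site specificity control.

    Enumerates spatially contiguous ``site_size``-region groups inside the
    task circuit (symmetric kNN adjacency on centroids), re-runs the full
    stimulation readout with each group as the stimulation target, and
    correlates the within-circuit functional effect with behavior.
    """
    if len(circuit.labels) <= site_size:
        raise ValueError("circuit must be larger than the site")
    conn0 = cohort[0]
    adjacency = knn_adjacency(conn0, k=k_neighbors)
    cand = list(conn0.index_of(circuit.labels))
    ss = seedseq(seed)
    site_seed, *subj_seeds = ss.spawn(1 + len(cohort))
    sites = enumerate_connected_sites(adjacency, cand, site_size,
                                      max_sites=max_sites, seed=site_seed)
    out = []
    for s_idx, site in enumerate(sites):
        site_set = RegionSet(name=f"alt_site_{s_idx}",
                             labels=tuple(conn0.labels[i] for i in site))
        effects = []
        for conn, c5T, sseed in zip(cohort, c5T_values, subj_seeds):
            res = stimulation_result(conn, params, c5T, site_set, circuit,
                                     seed=sseed.spawn(1)[0], grid_step=grid_step)
            effects.append(res.effect_circuit)
        assoc = pearson_bootstrap(effects, behavior, n_boot=n_boot, seed=site_seed,
                                  feature=f"circuit_effect[{site_set.name}]",
                                  task=task, condition=condition)
        out.append((site_set, assoc))
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class SubjectFeatures:
    subject_id: str
    c5T: float
    effect_global: float
    effect_circuit: float
    effect_outside: float
    average_degree: float
    spectral_radius: float
    inverse_spectral_radius: float
    synchronizability: float
    dfc: np.ndarray = field(repr=False, default=None)


def compute_subject_features(conn: StructuralConnectome, params: WilsonCowanParams,
                             site: RegionSet, circuit: RegionSet, seed=None,
                             grid=None, sim_ms: float = 1000.0,
                             subject_id: str = "") -> SubjectFeatures:
    """One subject's full feature set: c5T, stimulation dFC summaries, and
    structural network statistics."""
    grid = default_grid() if grid is None else np.asarray(grid, float)
    sweep_seed, stim_seed = seedseq(seed).spawn(2)
    curve = sweep_coupling(conn, params, grid=grid, sim_ms=sim_ms, seed=sweep_seed)
    c5T = detect_transition(curve)
    grid_step = float(np.diff(grid).min()) if len(grid) > 1 else 0.001
    stim = stimulation_result(conn, params, c5T, site, circuit, seed=stim_seed,
                              grid_step=grid_step)
    net = network_features(conn, subject_id)
    return SubjectFeatures(
        subject_id=subject_id, c5T=c5T,
        effect_global=stim.effect_global, effect_circuit=stim.effect_circuit,
        effect_outside=stim.effect_outside,
        average_degree=net.average_degree, spectral_radius=net.spectral_radius,
        inverse_spectral_radius=net.inverse_spectral_radius,
        synchronizability=net.synchronizability, dfc=stim.dfc,
    )

FEATURE_COLUMNS = ("c5T", "effect_global", "effect_circuit", "effect_outside",
                   "average_degree", "spectral_radius", "inverse_spectral_radius",
                   "synchronizability")


def run_full_analysis(cohort: list[StructuralConnectome], behavior,
                      site: RegionSet, circuit: RegionSet,
                      params: WilsonCowanParams | None = None, grid=None,
                      sim_ms: float = 1000.0, n_boot: int = 5000, seed=None,
                      features=FEATURE_COLUMNS, alpha: float = 0.05) -> dict:
    """The full per-subject feature extraction + association report.

    ``behavior`` is either the long-format table (subject_id, task,
    condition, median_rt_ms), subjects in cohort order, or a
    :class:`~conndyn.synth.BehaviorSpec`, in which case response times are
    generated from the computed driving feature. Returns a report dict with
    the per-subject feature table, AssociationResults per (feature, task,
    condition) — FDR-corrected across tasks within each (feature, condition)
    family — and a manifest of any per-subject failures (those subjects are
    dropped from the associations).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    params = params or WilsonCowanParams()
    subj_seeds = seedseq(seed).spawn(len(cohort) + 1)
    feats: list[SubjectFeatures] = []
    failures: dict[str, str] = {}
    for s, conn in enumerate(cohort):
        sid = f"sub-{s:02d}"
        try:
            feats.append(compute_subject_features(
                conn, params, site, circuit, seed=subj_seeds[s], grid=grid,
                sim_ms=sim_ms, subject_id=sid))
        except Exception as e:  # persist partial results with a manifest
            failures[sid] = f"{type(e).__name__}: {e}"
    if len(feats) < 3:
        raise RuntimeError(f"fewer than 3 subjects succeeded; failures: {failures}")
    table = pd.DataFrame([{c: getattr(f, c) for c in ("subject_id",) + tuple(features)}
                          for f in feats])
    if not isinstance(behavior, pd.DataFrame):  # a BehaviorSpec
        from .synth import generate_behavior

        col = {"c5T": "c5T", "circuit_functional_effect": "effect_circuit",
               "independent": "c5T"}[behavior.driving_feature]
        behavior = generate_behavior(table[col].to_numpy(dtype=float), behavior,
                                     subject_ids=list(table["subject_id"]))
    results: list[AssociationResult] = []
    boot_seed = subj_seeds[-1]
    kept = set(table["subject_id"])
    beh = behavior[behavior["subject_id"].isin(kept)]
    for feature in features:
        x = table[feature].to_numpy(dtype=float)
        if np.std(x) <= 1e-9 * max(np.abs(x).max(), 1e-300):  # constant feature
            continue
        for (task, cond), grp in beh.groupby(["task", "condition"], sort=True):
            grp = grp.set_index("subject_id").loc[table["subject_id"]]
            y = grp["median_rt_ms"].to_numpy(dtype=float)
            results.append(pearson_bootstrap(
                x, y, n_boot=n_boot, seed=boot_seed.spawn(1)[0],
                feature=feature, task=task, condition=cond))
    annotate_fdr(results, alpha=alpha)
    return {"features": table, "associations": results, "failures": failures,
            "subject_features": feats}


def shuffled_cohort(cohort: list[StructuralConnectome], seed=None):
    """Weight-shuffled copy of every subject (the network-randomization control)."""
    seeds = seedseq(seed).spawn(len(cohort))
    return [shuffle_edge_weights(c, s) for c, s in zip(cohort, seeds)]
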