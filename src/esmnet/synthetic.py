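"""Synthetic connectomes, cohorts and voxel tables for end-to-end testing.

Generators emulate the statistical structure of the real inputs — a
symmetric anatomical-connection-probability matrix with unit
self-connections and millimetre fiber lengths, per-subject deposition
patterns snapshotted from lifetime ESM trajectories, and PET-like voxel
signal tables with a non-binding reference region — without requiring any
imaging data.  Every generator is deterministic given its ``rng_seed``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .connectome import Connectome
from .model import ESMParams, simulate

__all__ = ["SyntheticSpec", "make_connectome", "make_cohort", "make_voxel_table"]

GEOMETRIES = ("chain", "ring", "hub_spoke", "geometric-random")
REFERENCE_LABEL = "cerebellum"


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Cohort priors default to the parameter-recovery regime used throughout:
    beta0 ~ U(0.3, 0.9), delta0 ~ U(0.1, 0.5), PET-snapshot day
    ~ U(2000, 12000) within a 50-year horizon, noiseless patterns.  The
    model template starts the outbreak region heavily infested
    (p_seed_init = 0.9, above the production sigmoid's knee, so the cascade
    ignites) and uses a slow effective propagation velocity
    (V_MP = 0.004 mm/day) so transmission delays stretch the cascade across
    the 50-year horizon and mid-life snapshots are informative.
    """

    n_regions: int = 10
    rng_seed: int = 0
    geometry: str = "geometric-random"
    edge_density: float = 0.5
    acp_range: tuple[float, float] = (0.5, 0.9)
    length_scale_mm: float = 10.0
    cohort_size: int = 20
    beta0_range: tuple[float, float] = (0.3, 0.9)
    delta0_range: tuple[float, float] = (0.1, 0.5)
    snapshot_range: tuple[float, float] = (2000, 12000)
    sigma: float = 0.0
    seeds: frozenset = dataclasses.field(default_factory=lambda: frozenset({0}))
    voxels_per_region: int = 500
    reference_noise_sd: float = 1.0
    horizon_days: int = 18250
    params: ESMParams = dataclasses.field(
        default_factory=lambda: ESMParams(p_seed_init=0.9, velocity=0.004)
    )

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.cohort_size < 1 or self.voxels_per_region < 1:
            raise ValueError("sizes must be >= 1 (and n_regions >= 2)")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        lo, hi = self.acp_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("acp_range must satisfy 0 < lo <= hi <= 1")


def _geometric_edges(spec: SyntheticSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random geometric graph: connect pairs closer than a density quantile."""
    import networkx as nx

    for _ in range(50):
        coords = rng.uniform(0.0, 100.0, size=(spec.n_regions, 3))
        d = squareform(pdist(coords))
        radius = np.quantile(d[np.triu_indices_from(d, k=1)], spec.edge_density)
        adj = (d <= radius) & ~np.eye(spec.n_regions, dtype=bool)
        if nx.is_connected(nx.from_numpy_array(adj)):
            return adj, coords
    raise ValueError("edge_density too low to obtain a connected geometric graph")


def make_connectome(spec: SyntheticSpec) -> Connectome:
    """Generate a connected connectome of the requested geometry.

    ACP weights are drawn uniformly from ``acp_range``; fiber lengths are
    Euclidean inter-centroid distances for the geometric-random geometry and
    index distance x ``length_scale_mm`` otherwise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_regions
    coords = None
    adj = np.zeros((n, n), dtype=bool)
    if spec.geometry == "chain":
        idx = np.arange(n - 1)
        adj[idx, idx + 1] = adj[idx + 1, idx] = True
    elif spec.geometry == "ring":
        idx = np.arange(n)
        adj[idx, (idx + 1) % n] = adj[(idx + 1) % n, idx] = True
    elif spec.geometry == "hub_spoke":
        adj[0, 1:] = adj[1:, 0] = True
    else:
        adj, coords = _geometric_edges(spec, rng)

    w = rng.uniform(*spec.acp_range, size=(n, n))
    w = (w + w.T) / 2.0
    acp = np.where(adj, w, 0.0)
    np.fill_diagonal(acp, 1.0)
    if coords is not None:
        fl = squareform(pdist(coords))
    else:
        ii = np.arange(n)
        fl = np.abs(ii[:, None] - ii[None, :]) * spec.length_scale_mm
    fl = np.where(adj, fl, 0.0)
    labels = [f"R{i:03d}" for i in range(n)]
    return Connectome(acp=acp, fiber_length=fl, labels=labels, coords=coords)


def make_cohort(
    conn: Connectome, spec: SyntheticSpec
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Simulate a cohort of deposition patterns with known ground truth.

    Per subject, (beta0, delta0) and a snapshot day are drawn from the spec's
    priors; the ESM is run from the spec's seed set and the pattern is the
    deposition vector at the snapshot day.  Returns the patterns and a truth
    table (subject, beta0, delta0, t_days, sigma, rng_seed) for recovery
    scoring.
    """
    rng = np.random.default_rng(spec.rng_seed)
    patterns, rows = [], []
    seeds = sorted(spec.seeds)
    for s in range(spec.cohort_size):
        b = rng.uniform(*spec.beta0_range)
        d = rng.uniform(*spec.delta0_range)
        day = int(rng.integers(int(spec.snapshot_range[0]), int(spec.snapshot_range[1]) + 1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = spec.params.replace(
            beta0=float(b), delta0=float(d), noise_sd=spec.sigma,
            horizon_days=max(day, 1),
        )
        traj = simulate(conn, params, seeds, rng_seed=sub_seed if spec.sigma > 0 else None)
        step = int(round(day / params.dt))
        patterns.append(traj.p[step].copy())
        rows.append({
            "subject": s, "beta0": b, "delta0": d, "t_days": day,
            "sigma": spec.sigma, "rng_seed": sub_seed,
        })
    return patterns, pd.DataFrame(rows)


def make_voxel_table(pattern, spec: SyntheticSpec) -> pd.DataFrame:
    """Emulate a regional PET voxel table for one deposition pattern.

    Reference-region voxels are Normal(0, sd); region i's voxels are
    Normal(3 * sd * P_i, sd), a linear shift so regional separability scales
    with deposition.  The reference region is labelled ``cerebellum``.
    """
    pattern = np.asarray(pattern, dtype=float)
    rng = np.random.default_rng(spec.rng_seed)
    sd = spec.reference_noise_sd
    m = spec.voxels_per_region
    frames = [pd.DataFrame({
        "region_id": REFERENCE_LABEL,
        "value": rng.normal(0.0, sd, size=m),
    })]
    for i, p in enumerate(pattern):
        frames.append(pd.DataFrame({
            "region_id": f"R{i:03d}",
            "value": rng.normal(3.0 * sd * p, sd, size=m),
        }))
    return pd.concat(frames, ignore_index=True)
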