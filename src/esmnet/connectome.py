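"""Structural connectome container, I/O, graph distances and null models.

The connectome is a symmetric matrix of anatomical connection probabilities
(ACP) between gray-matter regions, with self-connections fixed at 1, plus a
matrix of inter-region fiber path lengths in millimetres.  Effective
anatomical distance re-expresses connection probability as a path length so
that weakly supported connections are "far": an edge with probability p has
length 1 - ln(p), and the distance of a region to an outbreak set is the
shortest-path length to its nearest member.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "read_connectome",
    "write_connectome",
    "effective_distance",
    "weighted_degree",
    "randomize_connectome",
]

_SYM_TOL = 1e-9


@dataclasses.dataclass
class Connectome:
    """Anatomical connection probabilities and fiber lengths for N regions.

    Attributes
    ----------
    acp : (N, N) ndarray
        Symmetric anatomical connection probabilities in [0, 1], diagonal 1.
    fiber_length : (N, N) ndarray
        Symmetric non-negative connection path lengths, mm; 0 on the diagonal
        and wherever there is no connection.
    labels : list of str
        Unique region names, length N.
    coords : (N, 3) ndarray, optional
        Region centroid coordinates, mm.
    """

    acp: np.ndarray
    fiber_length: np.ndarray
    labels: list[str]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.acp = np.asarray(self.acp, dtype=float)
        self.fiber_length = np.asarray(self.fiber_length, dtype=float)
        self.labels = list(self.labels)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    @property
    def n_regions(self) -> int:
        return self.acp.shape[0]

    def validate(self) -> None:
        a, fl = self.acp, self.fiber_length
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("acp must be a square matrix")
        n = a.shape[0]
        if fl.shape != (n, n):
            raise ValueError("fiber_length shape does not match acp")
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(fl)):
            raise ValueError("non-finite values in connectome matrices")
        if a.min() < 0 or a.max() > 1:
            raise ValueError("acp value out of range [0, 1]")
        if not np.allclose(a, a.T, atol=_SYM_TOL):
            raise ValueError("acp must be symmetric")
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("acp diagonal (self-connections) must be 1")
        if fl.min() < 0:
            raise ValueError("fiber_length must be non-negative")
        if not np.allclose(fl, fl.T, atol=_SYM_TOL):
            raise ValueError("fiber_length must be symmetric")
        if not np.allclose(np.diag(fl), 0.0):
            raise ValueError("fiber_length diagonal must be 0")
        if len(self.labels) != n:
            raise ValueError("labels length does not match matrix size")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if self.coords is not None and self.coords.shape != (n, 3):
            raise ValueError("coords must be N x 3")

    def _check_indices(self, idx) -> list[int]:
        out = sorted(int(i) for i in idx)
        if not out:
            raise ValueError("region index set is empty")
        if out[0] < 0 or out[-1] >= self.n_regions:
            raise ValueError("region index out of range")
        return out


def _read_matrix(path) -> np.ndarray:
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in matrix file {path}: {exc}") from exc


def read_connectome(path, lengths_path, labels_path=None) -> Connectome:
    """Read ACP and fiber-length matrices from delimited text files.

    Matrices may be comma-, tab- or whitespace-delimited, without headers.
    Near-symmetric matrices (max asymmetry <= 1e-9) are symmetrized by
    averaging; anything worse is an error.  ``labels_path`` holds one region
    name per line; omitted labels default to R000, R001, ...
    """
    acp = _read_matrix(path)
    fl = _read_matrix(lengths_path)
    if acp.shape != fl.shape:
        raise ValueError(
            f"dimension mismatch: acp {acp.shape} vs fiber_length {fl.shape}"
        )
    for name, m in (("acp", acp), ("fiber_length", fl)):
        if np.abs(m - m.T).max() > _SYM_TOL:
            raise ValueError(f"{name} matrix is not symmetric")
    acp = (acp + acp.T) / 2.0
    fl = (fl + fl.T) / 2.0
    n = acp.shape[0]
    if labels_path is not None:
        labels = [
            ln.strip() for ln in Path(labels_path).read_text().splitlines() if ln.strip()
        ]
    else:
        labels = [f"R{i:03d}" for i in range(n)]
    return Connectome(acp=acp, fiber_length=fl, labels=labels)


def write_connectome(conn: Connectome, path, lengths_path, labels_path=None) -> None:
    """Write a connectome as tab-delimited matrices plus a label list."""
    np.savetxt(path, conn.acp, delimiter="\t", fmt="%.17g")
    np.savetxt(lengths_path, conn.fiber_length, delimiter="\t", fmt="%.17g")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(conn.labels) + "\n")


def acp_to_length(p, transform: str = "effective"):
    """Map a connection probability to a path length.

    ``effective`` is 1 - ln(p) (the effective-distance convention: p = 1 gives
    length 1, rare links are long); ``neglog`` is -ln(p); ``inverse`` is 1/p.
    """
    p = np.asarray(p, dtype=float)
    if transform == "effective":
        return 1.0 - np.log(p)
    if transform == "neglog":
        return -np.log(p)
    if transform == "inverse":
        return 1.0 / p
    raise ValueError(f"unknown ACP->length transform {transform!r}")


def _length_graph(conn: Connectome, transform: str) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(conn.n_regions))
    ii, jj = np.nonzero(np.triu(conn.acp, k=1))
    lengths = acp_to_length(conn.acp[ii, jj], transform)
    g.add_weighted_edges_from(zip(ii.tolist(), jj.tolist(), lengths.tolist()))
    return g


def effective_distance(
    conn: Connectome, sources, transform: str = "effective"
) -> np.ndarray:
    """Effective anatomical distance from every region to an outbreak set.

    The distance of region i is the minimum over sources of the shortest-path
    length using edge lengths from :func:`acp_to_length`; self-loops are
    excluded; sources are at distance 0; unreachable regions get +inf.
    """
    src = conn._check_indices(sources)
    g = _length_graph(conn, transform)
    dist = nx.multi_source_dijkstra_path_length(g, set(src))
    out = np.full(conn.n_regions, np.inf)
    for node, d in dist.items():
        out[node] = d
    out[src] = 0.0
    return out


def weighted_degree(conn: Connectome) -> np.ndarray:
    """Weighted connectivity degree: sum of off-diagonal ACP per region."""
    return conn.acp.sum(axis=1) - np.diag(conn.acp)


def randomize_connectome(
    conn: Connectome, rng_seed: int, n_swaps: int | None = None
) -> Connectome:
    """Degree-, weight- and (approximately) strength-preserving rewiring.

    Maslov-Sneppen double-edge swaps on the binarized off-diagonal topology
    preserve the binary degree sequence exactly; the original multiset of
    (ACP weight, fiber length) edge pairs is then reassigned to the rewired
    edges by rank-matching edge weight against the sum of the endpoints'
    original strengths, so node strengths are approximately preserved.
    """
    n = conn.n_regions
    ii, jj = np.nonzero(np.triu(conn.acp, k=1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    if n_swaps is None:
        n_swaps = max(1, 10 * len(edges))
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=200 * n_swaps, seed=int(rng_seed))
    except nx.NetworkXError as exc:
        raise ValueError(f"graph cannot be rewired: {exc}") from exc

    strength = weighted_degree(conn)
    # (weight, length) pairs travel together so fiber_length stays consistent.
    pairs = sorted(
        ((conn.acp[i, j], conn.fiber_length[i, j]) for i, j in edges), reverse=True
    )
    new_edges = sorted(g.edges(), key=lambda e: -(strength[e[0]] + strength[e[1]]))
    acp = np.eye(n)
    fl = np.zeros((n, n))
    for (u, v), (w, ln) in zip(new_edges, pairs):
        acp[u, v] = acp[v, u] = w
        fl[u, v] = fl[v, u] = ln
    return Connectome(acp=acp, fiber_length=fl, labels=list(conn.labels), coords=None)
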