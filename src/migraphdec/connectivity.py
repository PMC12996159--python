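"""Phase-locking-value connectivity graphs and eigenvector centrality.

Each trial's broadband signal defines a functional-connectivity graph over
the electrodes: the phase locking value (PLV)

    PLV_ij = | (1/T) * sum_t exp(i (phi_i[t] - phi_j[t])) |

with phi the instantaneous phase of the analytic (Hilbert) signal, measures
phase synchrony between channels i and j.  The graph keeps only the k
strongest undirected edges (default k = 100), discarding weak links that are
treated as spurious.  Eigenvector centrality of the resulting adjacency
ranks electrode importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

DEFAULT_EDGE_BUDGET = 100


@dataclass
class PLVMatrix:
    """Symmetric C x C matrix of pairwise phase locking values in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("PLV matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLV entries must lie in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class Adjacency:
    """Binary undirected adjacency (zero diagonal) with a fixed edge budget."""

    matrix: np.ndarray
    edge_budget: int

    def __post_init__(self):
        a = np.asarray(self.matrix)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.matrix = a.astype(np.float64)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.matrix, 1).sum())


@dataclass
class CentralityVector:
    """Unit-norm leading eigenvector of an adjacency, one score per channel."""

    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=np.float64)
        if s.ndim != 1:
            raise ValueError("centrality scores must be a vector")
        self.scores = s


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Per-channel instantaneous phase (radians in (-pi, pi]) via Hilbert.

    Zero-variance channels carry no phase information; they are reported as
    phase 0 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] < 8:
        raise ValueError("need at least 8 samples for a meaningful phase")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")

    flat = np.ptp(x, axis=-1) == 0
    if np.any(flat):
        warnings.warn(
            "constant channel(s) have degenerate phase, set to 0", stacklevel=2
        )
    phase = np.angle(hilbert(x, axis=-1))
    phase[flat] = 0.0
    return phase


def plv_matrix(phase: np.ndarray) -> PLVMatrix:
    """Pairwise PLV from a (C, T) phase matrix."""
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim != 2:
        raise ValueError("phase must be (C, T)")
    C, T = phase.shape
    if C < 2:
        raise ValueError("need at least 2 channels")
    if T == 0:
        raise ValueError("empty phase input")
    # |mean_t exp(i phi_c)| for all pairs at once via the phasor Gram matrix
    phasor = np.exp(1j * phase)
    plv = np.abs(phasor @ phasor.conj().T) / T
    plv = np.clip((plv + plv.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(plv, 1.0)
    return PLVMatrix(values=plv)


def threshold_adjacency(plv: PLVMatrix, k: int = DEFAULT_EDGE_BUDGET) -> Adjacency:
    """Keep the k largest strict-upper-triangle PLV entries as edges.

    The k-th value itself is retained.  Ties at the cutoff are broken by
    (PLV descending, then (i, j) lexicographic) so the result is
    deterministic across platforms.
    """
    C = plv.n_channels
    max_k = C * (C - 1) // 2
    if not 1 <= k <= max_k:
        raise ValueError(f"edge budget k={k} outside [1, {max_k}]")
    iu, ju = np.triu_indices(C, 1)
    vals = plv.values[iu, ju]
    # lexsort: primary -vals, then i, then j (last key is primary)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    adj = np.zeros((C, C))
    adj[iu[keep], ju[keep]] = 1.0
    adj += adj.T
    return Adjacency(matrix=adj, edge_budget=k)


def build_graph(
    trial: np.ndarray, k: int = DEFAULT_EDGE_BUDGET
) -> Adjacency:
    """Per-trial graph: broadband signal -> phase -> PLV -> top-k adjacency."""
    return threshold_adjacency(plv_matrix(instantaneous_phase(trial)), k)


def average_plv(trials: np.ndarray) -> PLVMatrix:
    """Mean PLV across (n, C, T) trials, for a per-subject static graph."""
    trials = np.asarray(trials)
    acc = np.zeros((trials.shape[1], trials.shape[1]))
    for trial in trials:
        acc += plv_matrix(instantaneous_phase(trial)).values
    return PLVMatrix(values=acc / trials.shape[0])


def eigenvector_centrality(adj: Adjacency | np.ndarray) -> CentralityVector:
    """Leading eigenvector of the adjacency, unit norm, dominant entry >= 0.

    For a disconnected graph the eigenvector localises on the dominant
    component; the computation proceeds on the full matrix with a warning.
    """
    a = adj.matrix if isinstance(adj, Adjacency) else np.asarray(adj, dtype=np.float64)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0:
        raise ValueError("adjacency must be non-negative")

    n_comp = _n_components(a)
    if n_comp > 1:
        warnings.warn(
            f"graph has {n_comp} components; centrality localises on the "
            "dominant one",
            stacklevel=2,
        )
    evals, evecs = np.linalg.eigh(a)
    # largest-magnitude eigenvalue; on a bipartite tie (|l_min| = l_max)
    # take the positive one, whose eigenvector is the non-negative
    # Perron-Frobenius vector
    idx = len(evals) - 1 if evals[-1] >= -evals[0] else 0
    lead = evecs[:, idx]
    lead = lead / np.linalg.norm(lead)
    if lead[np.argmax(np.abs(lead))] < 0:
        lead = -lead
    # numerical dust from eigh may leave tiny negatives on a PF eigenvector
    lead[np.abs(lead) < 1e-12] = 0.0
    return CentralityVector(scores=lead)


def _n_components(a: np.ndarray) -> int:
    n = a.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = 0
    for start in range(n):
        if seen[start]:
            continue
        comps += 1
        stack = [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            for v in np.nonzero(a[u] > 0)[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
    return comps


# ---------------------------------------------------------------------------
# import/export helpers

def adjacency_to_edgelist(adj: Adjacency) -> str:
    """One '<i> <j>' line per undirected edge, 0-based, i < j."""
    iu, ju = np.nonzero(np.triu(adj.matrix, 1))
    return "\n".join(f"{i} {j}" for i, j in zip(iu, ju)) + "\n"


def adjacency_from_edgelist(text: str, n_channels: int) -> Adjacency:
    adj = np.zeros((n_channels, n_channels))
    edges = 0
    for line in text.strip().splitlines():
        i, j = (int(tok) for tok in line.split())
        adj[i, j] = adj[j, i] = 1.0
        edges += 1
    return Adjacency(matrix=adj, edge_budget=edges)


def centrality_to_tsv(cent: CentralityVector, channel_names: list[str]) -> str:
    lines = ["channel\tscore"]
    lines += [
        f"{name}\t{score:.10f}"
        for name, score in zip(channel_names, cent.scores)
    ]
    return "\n".join(lines) + "\n"
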