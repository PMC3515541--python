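"""Connectivity-matrix construction and sparsity thresholding.

Two network families share one edge definition (Pearson correlation) but
differ in what the correlation is taken over:

* functional: region x region correlation of band-passed, nuisance-regressed
  ROI time series -> one matrix per subject;
* structural (covariance) network: region x region correlation of mean gray
  matter volumes ACROSS subjects -> one matrix per group.

Matrices are binarized at a fixed sparsity S (fraction of the N(N-1)/2
possible edges retained), which equalizes wiring cost across subjects and
groups: every network keeps exactly K = round(S * N(N-1)/2) edges, the K
strongest under the configured edge ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from scipy import signal
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

EdgeRanking = Literal["absolute", "positive"]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric region x region Pearson correlation matrix.

    ``kind`` records whether edges are across-time (functional, one per
    subject) or across-subjects (structural, one per group); ``provenance``
    is the subject or group id.
    """

    values: np.ndarray
    kind: Literal["structural", "functional"]
    provenance: str = ""
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (np.nanmax(np.abs(off)) > 1 + 1e-10):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        if self.labels is not None and len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted graph at a fixed sparsity.

    ``adjacency`` is boolean, symmetric, with a zero diagonal; ``edge_count``
    equals round(S * N(N-1)/2) exactly by construction.
    """

    adjacency: np.ndarray
    sparsity: float
    labels: tuple[str, ...] | None = None
    provenance: str = ""

    def __post_init__(self):
        a = self.adjacency
        if a.dtype != bool:
            raise ValueError("adjacency must be boolean")
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(a)):
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return n_comp == 1

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency.astype(np.int8))
        if self.labels is not None:
            nx.set_node_attributes(g, dict(enumerate(self.labels)), "abbrev")
        return g


# ---------------------------------------------------------------------------
# time-series cleaning


def bandpass_filter(
    series: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    tr_seconds: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    ``series`` is regions x timepoints sampled every ``tr_seconds``. The
    filter is applied forward and backward (``sosfiltfilt``), so the passband
    is traversed twice (no phase shift, squared magnitude response).
    Retains fluctuations in [low_hz, high_hz]; removes slow drift below and
    high-frequency noise above the band.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[None, :]
    fs = 1.0 / tr_seconds
    nyquist = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz at TR={tr_seconds}s"
        )
    n_t = series.shape[-1]
    if n_t < 4 * order:
        raise ValueError(f"need at least {4 * order} timepoints, got {n_t}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, series, axis=-1)


def regress_nuisance(series: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Project nuisance time courses (plus an intercept) out of each ROI series.

    ``nuisance`` is k x timepoints (e.g. white-matter mean, CSF mean and six
    rigid-body motion parameters). Residuals are exactly orthogonal to every
    nuisance row and mean-free. Rank-deficient nuisance sets are rejected,
    naming the first redundant row.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[1] != series.shape[1]:
        raise ValueError("series and nuisance must share the time axis length")
    k, n_t = nuisance.shape
    demeaned = nuisance - nuisance.mean(axis=1, keepdims=True)
    # incremental rank check names the first row dependent on its predecessors
    for i in range(1, k + 1):
        if np.linalg.matrix_rank(demeaned[:i]) < i:
            raise ValueError(
                f"nuisance row {i - 1} is linearly dependent on earlier rows "
                "after de-meaning"
            )
    design = np.column_stack([np.ones(n_t), demeaned.T])  # T x (k+1)
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    return series - (design @ beta).T


# ---------------------------------------------------------------------------
# correlation matrices


def functional_matrix(
    series: np.ndarray, provenance: str = "", labels: Sequence[str] | None = None
) -> ConnectivityMatrix:
    """Region x region Pearson correlation of ROI time series (one subject).

    The correlation coefficient itself is kept as the functional connective
    intensity; no r-to-z transform at this stage.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be regions x timepoints")
    if series.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sd = series.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    r = np.corrcoef(series)
    np.fill_diagonal(r, 0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(
        values=r, kind="functional", provenance=provenance,
        labels=tuple(labels) if labels is not None else None,
    )


def structural_matrix(
    gm: np.ndarray,
    subject_subset: Sequence[int] | None = None,
    provenance: str = "",
    labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Region x region correlation of gray-matter volumes ACROSS subjects.

    ``gm`` is subjects x regions. Unlike the functional case the sampling
    unit is the subject, so one matrix describes a whole group; group
    comparisons therefore require rebuilding the matrix under permuted
    group labels (see :mod:`cortexnets.inference`).
    """
    gm = np.asarray(gm, dtype=float)
    if gm.ndim != 2:
        raise ValueError("gm must be subjects x regions")
    if subject_subset is not None:
        gm = gm[np.asarray(subject_subset)]
    if gm.shape[0] < 3:
        raise ValueError(f"need at least 3 subjects, got {gm.shape[0]}")
    sd = gm.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s) across subjects: {dead.tolist()}")
    r = np.corrcoef(gm.T)
    np.fill_diagonal(r, 0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(
        values=r, kind="structural", provenance=provenance,
        labels=tuple(labels) if labels is not None else None,
    )


# ---------------------------------------------------------------------------
# thresholding


def edge_count_at_sparsity(n_nodes: int, sparsity: float) -> int:
    """K = round(S * N(N-1)/2), rounding half away from zero."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    x = sparsity * max_edges
    return int(np.floor(x + 0.5))


def _ranked_edges(values: np.ndarray, ranking: EdgeRanking) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges ordered by descending strength, ties by (i, j)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    strength = values[iu, ju]
    if ranking == "absolute":
        strength = np.abs(strength)
    elif ranking != "positive":
        raise ValueError(f"unknown edge ranking {ranking!r}")
    order = np.lexsort((ju, iu, -strength))
    return iu[order], ju[order]


def threshold_at_sparsity(
    matrix: ConnectivityMatrix, sparsity: float, ranking: EdgeRanking = "absolute"
) -> BinaryNetwork:
    """Binarize a correlation matrix keeping exactly the top-K edges.

    K = round(S * N(N-1)/2); edges ranked by |r| (default) or signed r,
    ties broken by lexicographic (i, j) so edge sets are nested across S
    and bit-identical across runs.
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = matrix.n_regions
    k = edge_count_at_sparsity(n, sparsity)
    if k < 1:
        raise ValueError(f"sparsity {sparsity} yields no edges for {n} nodes")
    iu, ju = _ranked_edges(matrix.values, ranking)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[:k], ju[:k]] = True
    adj |= adj.T
    return BinaryNetwork(
        adjacency=adj, sparsity=float(sparsity),
        labels=matrix.labels, provenance=matrix.provenance,
    )


def largest_component_curve(
    matrix: ConnectivityMatrix,
    sparsity_grid: Sequence[float],
    ranking: EdgeRanking = "absolute",
) -> dict:
    """Largest-connected-component size as a function of sparsity.

    Returns the per-S node counts plus the minimal S on the grid at which
    the network is fully connected (None if never). Because edge sets are
    nested in S, the curve is non-decreasing.
    """
    grid = sorted(float(s) for s in sparsity_grid)
    n = matrix.n_regions
    curve = []
    min_connected = None
    for s in grid:
        net = threshold_at_sparsity(matrix, s, ranking=ranking)
        n_comp, comp = connected_components(csr_matrix(net.adjacency), directed=False)
        size = int(np.bincount(comp).max())
        curve.append((s, size))
        if size == n and min_connected is None:
            min_connected = s
    return {"curve": curve, "min_connected_sparsity": min_connected}
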