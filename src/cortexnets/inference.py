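"""Nonparametric group inference: permutation tests, NBS, FDR, partial correlation.

All group comparisons are permutation-based: the null distribution of a
statistic is built by relabeling subjects, and the two-sided p-value is the
plus-one-corrected tail proportion

    p = (#{|null| >= |observed|} + 1) / (n_perm + 1),

which can never be exactly zero. Functional metrics are per-subject, so a
permutation just relabels values; structural (covariance) networks exist
only at the group level, so every permutation REBUILDS both group
correlation matrices, re-thresholds at the same sparsity, and recomputes
the metric.

Edge-level inference uses the network-based statistic (NBS): edge-wise
two-sample t on Fisher-z correlations, a primary threshold, and a
family-wise-corrected p-value for each connected component of
suprathreshold edges against the permutation null of the maximal
component size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from ._rng import rng_from
from .networks import structural_matrix, threshold_at_sparsity

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PermutationResult:
    metric: str
    observed_difference: float
    p_value: float
    n_perm: int
    null_distribution: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    seed: int | None = None


@dataclass(frozen=True)
class NBSComponent:
    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    p_value: float

    @property
    def size(self) -> int:
        """Component size = number of suprathreshold edges."""
        return len(self.edges)


@dataclass(frozen=True)
class NBSResult:
    primary_threshold: float
    components: tuple[NBSComponent, ...]
    suprathreshold_edges: tuple[tuple[int, int], ...]
    edge_t: np.ndarray = field(repr=False)
    max_null_sizes: np.ndarray = field(repr=False)
    n_perm: int = 0
    seed: int | None = None

    @property
    def significant(self) -> tuple[NBSComponent, ...]:
        return tuple(c for c in self.components if c.p_value < 0.05)


@dataclass(frozen=True)
class ClinicalAssociation:
    metric: str
    covariate: str
    r_partial: float
    p_value: float
    n: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# group handling


def _two_groups(groups) -> tuple[np.ndarray, np.ndarray, str, str]:
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels.tolist()}")
    g1 = np.flatnonzero(groups == labels[0])
    g2 = np.flatnonzero(groups == labels[1])
    return g1, g2, str(labels[0]), str(labels[1])


# ---------------------------------------------------------------------------
# global-metric permutation tests


def permute_functional_metric(
    values, groups, n_perm: int = 5000, seed=None, metric: str = "metric"
) -> PermutationResult:
    """Permutation test on a per-subject metric (e.g. each subject's C).

    Observed statistic: mean(group1) - mean(group2), groups in sorted label
    order. The null relabels subjects and recomputes the mean difference.
    """
    values = np.asarray(values, dtype=float)
    g1, g2, *_ = _two_groups(groups)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if values.shape[0] != len(g1) + len(g2):
        raise ValueError("one value per subject required")
    rng = rng_from(seed)
    n1, n = len(g1), len(values)
    observed = values[g1].mean() - values[g2].mean()
    total = values.sum()
    # vectorized relabeling: each row of perms is a shuffled subject order
    perms = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    sums_g1 = values[perms].sum(axis=1)
    null = sums_g1 / n1 - (total - sums_g1) / (n - n1)
    p = (np.count_nonzero(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1)
    return PermutationResult(metric=metric, observed_difference=float(observed),
                             p_value=float(p), n_perm=n_perm,
                             null_distribution=null, seed=_seed_int(seed))


def permute_structural_metric(
    gm, groups, sparsity: float, metric_fn, n_perm: int = 1000, seed=None,
    metric: str = "metric", ranking: str = "absolute",
) -> PermutationResult:
    """Permutation test on a structural-network metric.

    The statistic exists only per group: each permutation relabels
    subjects, rebuilds BOTH group covariance matrices from gray-matter
    volumes, re-thresholds at the same sparsity, and recomputes
    metric_fn(group1 network) - metric_fn(group2 network).
    """
    gm = np.asarray(gm, dtype=float)
    g1, g2, *_ = _two_groups(groups)
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each group needs at least 3 subjects for a covariance network")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng_from(seed)

    def stat(idx1: np.ndarray, idx2: np.ndarray) -> float:
        nets = []
        for idx in (idx1, idx2):
            mat = structural_matrix(gm, subject_subset=idx)
            nets.append(threshold_at_sparsity(mat, sparsity, ranking=ranking))
        return metric_fn(nets[0]) - metric_fn(nets[1])

    observed = stat(g1, g2)
    n1 = len(g1)
    all_idx = np.concatenate([g1, g2])
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(all_idx)
        null[b] = stat(perm[:n1], perm[n1:])
    p = (np.count_nonzero(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1)
    return PermutationResult(metric=metric, observed_difference=float(observed),
                             p_value=float(p), n_perm=n_perm,
                             null_distribution=null, seed=_seed_int(seed))


def _seed_int(seed) -> int | None:
    return int(seed) if isinstance(seed, (int, np.integer)) else None


# ---------------------------------------------------------------------------
# network-based statistic


def _edge_tstats(z: np.ndarray, g1_mask: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t per edge; rows of z are subjects.

    ``g1_mask`` may be 1-D (one labeling) or 2-D (n_perm labelings);
    returns matching shape. Degenerate edges (zero pooled variance) get
    t = 0 when the means agree, +/-inf otherwise.
    """
    single = g1_mask.ndim == 1
    masks = np.atleast_2d(g1_mask).astype(np.float64)
    n1 = masks[0].sum()
    n2 = masks.shape[1] - n1
    z2 = z * z
    s1 = masks @ z
    s2 = z.sum(axis=0) - s1
    ss1 = masks @ z2
    ss2 = z2.sum(axis=0) - ss1
    m1, m2 = s1 / n1, s2 / n2
    var1 = (ss1 - n1 * m1**2) / (n1 - 1)
    var2 = (ss2 - n2 * m2**2) / (n2 - 1)
    sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    np.clip(sp2, 0.0, None, out=sp2)  # guard tiny negative round-off
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    degenerate = denom == 0
    if degenerate.any():
        t[degenerate] = np.where(diff[degenerate] == 0, 0.0,
                                 np.sign(diff[degenerate]) * np.inf)
        if single:
            logger.warning("degenerate variance on %d edge(s); guarded t applied",
                           int(degenerate.sum()))
    return t[0] if single else t


def _max_component_size(edge_mask: np.ndarray, iu, ju, n_nodes: int) -> int:
    """Largest connected component of the suprathreshold graph, in EDGES."""
    ei, ej = iu[edge_mask], ju[edge_mask]
    if ei.size == 0:
        return 0
    adj = csr_matrix((np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes))
    _, comp = connected_components(adj + adj.T, directed=False)
    return int(np.bincount(comp[ei]).max()) if ei.size else 0


def nbs(
    matrices, groups, primary_threshold: float | None = None,
    primary_p: float | None = 0.005, n_perm: int = 1000, seed=None,
    perm_block: int = 250,
) -> NBSResult:
    """Network-based statistic on per-subject connectivity matrices.

    ``matrices``: n_subjects x N x N correlation matrices. Edge-wise
    two-sample t-statistics are computed on Fisher-z transformed
    correlations; edges with |t| above the primary threshold (given
    directly or as the two-sided p-value ``primary_p``) form the
    suprathreshold graph. Each connected component is assigned a
    family-wise-corrected p-value: the proportion of permutations whose
    MAXIMAL component size reaches the component's size.
    """
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("matrices must be n_subjects x N x N")
    g1, g2, *_ = _two_groups(groups)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_subj, n_nodes = mats.shape[0], mats.shape[1]
    if n_subj != len(g1) + len(g2):
        raise ValueError("group labels must cover every matrix")
    df = n_subj - 2
    if primary_threshold is None:
        if primary_p is None:
            raise ValueError("give primary_threshold (t) or primary_p")
        primary_threshold = float(stats.t.ppf(1 - primary_p / 2, df))

    iu, ju = np.triu_indices(n_nodes, k=1)
    z = np.arctanh(np.clip(mats[:, iu, ju], -1 + 1e-12, 1 - 1e-12))

    g1_mask = np.zeros(n_subj, dtype=bool)
    g1_mask[g1] = True
    t_obs = _edge_tstats(z, g1_mask)

    supra = np.abs(t_obs) >= primary_threshold
    # observed components
    components: list[tuple[tuple[int, ...], tuple[tuple[int, int], ...]]] = []
    if supra.any():
        ei, ej = iu[supra], ju[supra]
        adj = csr_matrix((np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes))
        _, comp = connected_components(adj + adj.T, directed=False)
        for cid in np.unique(comp[ei]):
            in_comp = comp[ei] == cid
            edges = tuple(zip(ei[in_comp].tolist(), ej[in_comp].tolist()))
            nodes = tuple(sorted({n for e in edges for n in e}))
            components.append((nodes, edges))

    # permutation null of the max component size
    rng = rng_from(seed)
    max_sizes = np.empty(n_perm, dtype=np.int64)
    n1 = len(g1)
    done = 0
    while done < n_perm:
        block = min(perm_block, n_perm - done)
        masks = np.zeros((block, n_subj), dtype=bool)
        for b in range(block):
            masks[b, rng.permutation(n_subj)[:n1]] = True
        t_null = _edge_tstats(z, masks)
        supra_null = np.abs(t_null) >= primary_threshold
        for b in range(block):
            max_sizes[done + b] = _max_component_size(supra_null[b], iu, ju, n_nodes)
        done += block

    out = []
    for nodes, edges in sorted(components, key=lambda c: -len(c[1])):
        p = (np.count_nonzero(max_sizes >= len(edges)) + 1) / (n_perm + 1)
        out.append(NBSComponent(nodes=nodes, edges=edges, p_value=float(p)))
    return NBSResult(
        primary_threshold=float(primary_threshold),
        components=tuple(out),
        suprathreshold_edges=tuple(zip(iu[supra].tolist(), ju[supra].tolist())),
        edge_t=t_obs,
        max_null_sizes=max_sizes,
        n_perm=n_perm,
        seed=_seed_int(seed),
    )


# ---------------------------------------------------------------------------
# FDR and clinical correlations


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up; returns (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def partial_correlation(x, y, control, metric: str = "", covariate: str = "") -> ClinicalAssociation:
    """Pearson correlation of x and y after removing a control variable.

    Both x and y are residualized on (intercept, control); the correlation
    of the residuals is tested with t on n - 3 degrees of freedom. A
    residual with (near-)zero variance — e.g. y identical to the control —
    yields a degenerate result flagged rather than a spurious number.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    control = np.asarray(control, dtype=float)
    n = len(x)
    if not (len(y) == len(control) == n):
        raise ValueError("x, y, control must have equal length")
    if n < 4:
        raise ValueError("need n >= 4 for a partial correlation")
    if np.ptp(control) == 0:
        raise ValueError("control variable is constant")
    design = np.column_stack([np.ones(n), control])
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    res = np.column_stack([x, y]) - design @ coef
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if res[:, 0].std() < 1e-12 * scale or res[:, 1].std() < 1e-12 * scale:
        return ClinicalAssociation(metric=metric, covariate=covariate,
                                   r_partial=np.nan, p_value=np.nan, n=n,
                                   degenerate=True)
    r = float(np.corrcoef(res[:, 0], res[:, 1])[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return ClinicalAssociation(metric=metric, covariate=covariate,
                               r_partial=r, p_value=p, n=n)
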