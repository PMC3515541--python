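"""Synthetic two-group ROI-level cohorts with known, injectable group effects.

The generator emulates the statistical structure the downstream analysis
assumes, at the study's scale: two groups of 43 subjects, 90 regions, 200
usable timepoints at TR = 2 s. Region time series are stationary
multivariate Gaussian draws whose population correlation matrix has a
modular block structure (``within_module_corr`` inside ground-truth
modules, ``between_module_corr`` elsewhere); gray-matter volumes share the
same cross-region correlation structure across subjects, so the structural
covariance network is modular too. Nuisance series (white-matter mean, CSF
mean, six motion parameters) are smooth Gaussian processes partially mixed
into the ROI series so that nuisance regression has something real to
remove.

Group effects are injected into the patient population and recorded in a
``truth`` ledger: correlation increments on chosen edge sets, region-wise
volume shifts, and extra triangle wiring that raises clustering. A
duration covariate can scale each patient's effect magnitude so
metric–duration correlations are recoverable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .atlas import load_atlas

logger = logging.getLogger(__name__)

# Cohort-level demographic targets (mean, sd) on which clinical covariates
# are drawn; truncation keeps values physically sensible.
AGE_CONTROL = (33.4, 10.2)
AGE_PATIENT = (32.6, 11.1)
DURATION_YEARS = (14.5, 6.8)
FREQUENCY_PER_MONTH = (4.3, 2.1)
INTENSITY_0_10 = (5.5, 1.6)


# ---------------------------------------------------------------------------
# effect specifications


@dataclass(frozen=True)
class EdgeEffect:
    """Add ``delta_r`` to the population correlation of each listed edge."""

    edges: tuple[tuple[int, int], ...]
    delta_r: float
    target: str = "functional"  # functional | structural | both


@dataclass(frozen=True)
class VolumeShift:
    """Shift patient-group mean gray-matter volume in the listed regions."""

    regions: tuple[int, ...]
    delta: float  # volume units


@dataclass(frozen=True)
class TriangleEffect:
    """Wire extra triangles: set the 3 pairwise correlations of each triple.

    Placing strong triangles across module boundaries raises the thresholded
    network's clustering coefficient in the patient group.
    """

    triples: tuple[tuple[int, int, int], ...]
    corr: float
    target: str = "functional"


@dataclass(frozen=True)
class CliqueEffect:
    """Couple the listed regions through a shared latent factor.

    Each clique region gains a loading ``g`` on one common Gaussian factor:
    the correlation of two clique regions becomes (r + g^2) / (1 + g^2) and
    correlations to outside regions shrink by 1 / sqrt(1 + g^2). The update
    is a rank-1 covariance addition, so positive semi-definiteness is
    preserved by construction. Spreading the clique across modules wires
    many extra triangles and is the generator's mechanism for raising mean
    clustering in the patient group (isolated triangles barely move C
    because they also inflate node degrees).
    """

    nodes: tuple[int, ...]
    loading: float
    target: str = "functional"


@dataclass(frozen=True)
class CovariateLink:
    """Scale patient i's injected effects by (1 + slope * z(duration_i))."""

    slope: float = 0.5


Effect = EdgeEffect | VolumeShift | TriangleEffect | CliqueEffect


# ---------------------------------------------------------------------------
# cohort spec


def default_module_assignment(n_regions: int = 90, n_modules: int = 8) -> np.ndarray:
    """Contiguous equal-size ground-truth modules (region -> module id)."""
    return (np.arange(n_regions) * n_modules // n_regions).astype(np.int64)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort; identical seeds give identical data."""

    n_per_group: int = 43
    n_regions: int = 90
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    module_assignment: np.ndarray | None = None
    within_module_corr: float = 0.5
    between_module_corr: float = 0.1
    gm_mean_per_region: float | np.ndarray = 6.0
    gm_noise_sd: float = 0.6
    nuisance_mixing: float = 0.2
    effect_spec: tuple[Effect, ...] = ()
    covariate_model: CovariateLink | None = None
    seed: int = 0

    def modules(self) -> np.ndarray:
        if self.module_assignment is None:
            return default_module_assignment(self.n_regions)
        m = np.asarray(self.module_assignment, dtype=np.int64)
        if m.shape != (self.n_regions,):
            raise ValueError("module_assignment must have one entry per region")
        return m

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1 (empty cohort)")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if not (0 <= self.between_module_corr < self.within_module_corr < 1):
            raise ValueError(
                "require within_module_corr > between_module_corr >= 0, both < 1; "
                f"got within={self.within_module_corr}, between={self.between_module_corr}"
            )
        self.modules()


@dataclass
class SyntheticCohort:
    """One realized cohort: data tables plus the ground-truth effect ledger."""

    gm_volumes: pd.DataFrame  # subjects x regions
    timeseries: np.ndarray  # n_subjects x regions x timepoints
    nuisance: np.ndarray  # n_subjects x 8 x timepoints
    groups: pd.Series  # subject id -> {control, patient}
    clinical: pd.DataFrame  # age, duration, frequency, intensity
    truth: dict
    spec: CohortSpec

    @property
    def subject_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_labels(self) -> np.ndarray:
        return self.groups.to_numpy()

    def group_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.group_labels == label)


# ---------------------------------------------------------------------------
# population correlation matrices


def block_correlation(spec: CohortSpec) -> np.ndarray:
    """Population correlation matrix implied by the module structure."""
    m = spec.modules()
    same = m[:, None] == m[None, :]
    r = np.where(same, spec.within_module_corr, spec.between_module_corr)
    np.fill_diagonal(r, 1.0)
    return r


def _apply_effects(r: np.ndarray, effects, scale: float, target: str) -> np.ndarray:
    out = r.copy()
    for eff in effects:
        if isinstance(eff, EdgeEffect) and eff.target in (target, "both"):
            for i, j in eff.edges:
                out[i, j] = out[j, i] = out[i, j] + scale * eff.delta_r
        elif isinstance(eff, TriangleEffect) and eff.target in (target, "both"):
            for a, b, c in eff.triples:
                for i, j in ((a, b), (a, c), (b, c)):
                    base = r[i, j]
                    out[i, j] = out[j, i] = base + scale * (eff.corr - base)
        elif isinstance(eff, CliqueEffect) and eff.target in (target, "both"):
            u = np.zeros(len(out))
            u[list(eff.nodes)] = eff.loading * scale
            np.fill_diagonal(out, 1.0)
            cov = out + np.outer(u, u)
            d = np.sqrt(np.diag(cov))
            out = cov / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -0.99, 0.99) * (1 - np.eye(len(out))) + np.eye(len(out))


def ensure_psd(r: np.ndarray, floor: float = 1e-6, reject_below: float = -0.1) -> np.ndarray:
    """Validate/repair a correlation matrix.

    Gross indefiniteness (an eigenvalue below ``reject_below``) means the
    requested effects are mutually incompatible and is rejected with the
    offending eigenvalue. Mild violations are repaired by clipping
    eigenvalues at ``floor`` and re-normalizing to unit diagonal (standard
    nearest-correlation fallback), logged when triggered.
    """
    w = np.linalg.eigvalsh(r)
    if w[0] < reject_below:
        raise ValueError(
            f"implied correlation matrix is not PSD after effect injection "
            f"(minimum eigenvalue {w[0]:.4f}); effects are incompatible"
        )
    if w[0] >= floor:
        return r
    logger.warning("PSD repair triggered (min eigenvalue %.2e); clipping at %.0e",
                   w[0], floor)
    w_full, v = np.linalg.eigh(r)
    fixed = (v * np.clip(w_full, floor, None)) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


# ---------------------------------------------------------------------------
# nuisance processes


def _smooth_noise(rng: np.random.Generator, n_rows: int, n_t: int,
                  sigma_samples: float) -> np.ndarray:
    """Unit-variance rows of Gaussian-kernel-smoothed white noise."""
    pad = int(4 * sigma_samples)
    x = rng.standard_normal((n_rows, n_t + 2 * pad))
    t = np.arange(-pad, pad + 1)
    kernel = np.exp(-0.5 * (t / sigma_samples) ** 2)
    kernel /= kernel.sum()
    sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, x)
    sm = sm[:, pad:pad + n_t]
    sd = sm.std(axis=1, keepdims=True)
    return sm / np.where(sd == 0, 1.0, sd)


def _make_nuisance(rng: np.random.Generator, n_t: int) -> np.ndarray:
    """8 x T nuisance block: WM mean, CSF mean (slow), 6 motion (slower)."""
    tissue = _smooth_noise(rng, 2, n_t, sigma_samples=5.0)
    motion = _smooth_noise(rng, 6, n_t, sigma_samples=10.0)
    return np.vstack([tissue, motion])


# ---------------------------------------------------------------------------
# clinical covariates


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _draw_clinical(rng: np.random.Generator, n: int, group: str) -> pd.DataFrame:
    if group == "control":
        age = _truncnorm(rng, *AGE_CONTROL, 18, 70, n)
        na = np.full(n, np.nan)
        return pd.DataFrame({"age": age, "duration": na, "frequency": na,
                             "intensity": na})
    age = _truncnorm(rng, *AGE_PATIENT, 18, 70, n)
    duration = _truncnorm(rng, *DURATION_YEARS, 0.5, 40, n)
    frequency = _truncnorm(rng, *FREQUENCY_PER_MONTH, 0.5, 15, n)
    intensity = _truncnorm(rng, *INTENSITY_0_10, 0, 10, n)
    return pd.DataFrame({"age": age, "duration": duration,
                         "frequency": frequency, "intensity": intensity})


# ---------------------------------------------------------------------------
# generation


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort according to ``spec``.

    Controls come first in subject order (HC01..), then patients (PM01..).
    Patient time series use the effect-modified population correlation
    matrix; when a :class:`CovariateLink` is present, each patient's effect
    magnitude is scaled by their standardized migraine duration. The
    ``truth`` dict records every injected effect.
    """
    spec.validate()
    n, n_reg, n_t = spec.n_per_group, spec.n_regions, spec.n_timepoints
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    r_null = ensure_psd(block_correlation(spec))
    r_patient_fun = ensure_psd(_apply_effects(r_null, spec.effect_spec, 1.0, "functional"))
    r_struct_hc = r_null
    r_struct_pm = ensure_psd(_apply_effects(r_null, spec.effect_spec, 1.0, "structural"))

    ids = [f"HC{i + 1:02d}" for i in range(n)] + [f"PM{i + 1:02d}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["patient"] * n, index=ids, name="group")

    clinical = pd.concat(
        [_draw_clinical(rng, n, "control"), _draw_clinical(rng, n, "patient")],
        ignore_index=True,
    )
    clinical.index = pd.Index(ids, name="subject")

    # per-patient effect scale from the duration covariate
    scales = np.ones(n)
    if spec.covariate_model is not None and spec.effect_spec:
        dur = clinical.loc[[f"PM{i + 1:02d}" for i in range(n)], "duration"].to_numpy()
        z = (dur - dur.mean()) / dur.std() if n > 1 else np.zeros(n)
        # clip keeps scaled effects inside the PSD-feasible range
        scales = np.clip(1.0 + spec.covariate_model.slope * z, 0.0, 2.0)

    # --- functional time series
    chol_hc = np.linalg.cholesky(r_null)
    timeseries = np.empty((2 * n, n_reg, n_t))
    nuisance = np.empty((2 * n, 8, n_t))
    need_per_patient = spec.covariate_model is not None and spec.effect_spec
    chol_pm = None if need_per_patient else np.linalg.cholesky(r_patient_fun)
    for s in range(2 * n):
        if s < n:
            chol = chol_hc
        elif need_per_patient:
            r_s = ensure_psd(_apply_effects(r_null, spec.effect_spec,
                                            scales[s - n], "functional"))
            chol = np.linalg.cholesky(r_s)
        else:
            chol = chol_pm
        signal = chol @ rng.standard_normal((n_reg, n_t))
        nuis = _make_nuisance(rng, n_t)
        weights = rng.standard_normal((n_reg, 8)) / np.sqrt(8)
        timeseries[s] = signal + spec.nuisance_mixing * (weights @ nuis)
        nuisance[s] = nuis

    # --- gray-matter volumes (correlated across regions, per subject draw)
    means_hc = np.broadcast_to(np.asarray(spec.gm_mean_per_region, dtype=float),
                               (n_reg,)).copy()
    means_pm = means_hc.copy()
    shifted_regions: list[int] = []
    for eff in spec.effect_spec:
        if isinstance(eff, VolumeShift):
            means_pm[list(eff.regions)] += eff.delta
            shifted_regions.extend(eff.regions)
    gm = np.empty((2 * n, n_reg))
    gm[:n] = means_hc + spec.gm_noise_sd * (
        np.linalg.cholesky(r_struct_hc) @ rng.standard_normal((n_reg, n))).T
    gm[n:] = means_pm + spec.gm_noise_sd * (
        np.linalg.cholesky(r_struct_pm) @ rng.standard_normal((n_reg, n))).T
    labels = (load_atlas().abbrevs if n_reg == 90
              else [f"R{i + 1:02d}" for i in range(n_reg)])
    gm_volumes = pd.DataFrame(gm, index=pd.Index(ids, name="subject"),
                              columns=labels)

    truth = {
        "effects": [dataclasses.asdict(e) for e in spec.effect_spec],
        "modified_edges": sorted({
            tuple(sorted(e)) for eff in spec.effect_spec
            if isinstance(eff, EdgeEffect) for e in eff.edges
        } | {
            tuple(sorted(p)) for eff in spec.effect_spec
            if isinstance(eff, TriangleEffect) for t in eff.triples
            for p in ((t[0], t[1]), (t[0], t[2]), (t[1], t[2]))
        } | {
            (a, b) for eff in spec.effect_spec
            if isinstance(eff, CliqueEffect)
            for a in eff.nodes for b in eff.nodes if a < b
        }),
        "shifted_regions": sorted(set(shifted_regions)),
        "covariate_link": (dataclasses.asdict(spec.covariate_model)
                           if spec.covariate_model else None),
        "effect_scales": scales.tolist() if spec.effect_spec else [],
        "module_assignment": spec.modules().tolist(),
    }
    return SyntheticCohort(gm_volumes=gm_volumes, timeseries=timeseries,
                           nuisance=nuisance, groups=groups, clinical=clinical,
                           truth=truth, spec=spec)


def null_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Cohort with both groups drawn from the identical population.

    Effects and covariate links are stripped; used to calibrate the type-I
    error of every downstream test.
    """
    return generate_cohort(replace(spec, effect_spec=(), covariate_model=None))


# ---------------------------------------------------------------------------
# planted-effect helpers


def planted_component_edges(
    spec: CohortSpec, n_edges: int = 10, seed: int = 0
) -> tuple[tuple[int, int], ...]:
    """A connected ``n_edges``-edge path spanning regions of distinct modules.

    Consecutive path nodes sit in different ground-truth modules, so the
    planted component's edges lie on weak between-module background
    correlation and a positive increment is unambiguous.
    """
    m = spec.modules()
    rng = np.random.default_rng(seed)
    n_nodes = n_edges + 1
    nodes: list[int] = []
    candidates = rng.permutation(spec.n_regions)
    for c in candidates:
        if not nodes or m[c] != m[nodes[-1]]:
            nodes.append(int(c))
        if len(nodes) == n_nodes:
            break
    if len(nodes) < n_nodes:
        raise ValueError("not enough regions across modules for the component")
    return tuple((min(a, b), max(a, b)) for a, b in zip(nodes, nodes[1:]))


def between_module_triples(spec: CohortSpec, n_triples: int, seed: int = 0,
                           exclude: set[int] | None = None) -> tuple[tuple[int, int, int], ...]:
    """Disjoint region triples spanning three distinct modules."""
    m = spec.modules()
    rng = np.random.default_rng(seed)
    used = set(exclude or ())
    triples: list[tuple[int, int, int]] = []
    order = rng.permutation(spec.n_regions)
    pool = [int(i) for i in order if i not in used]
    while len(triples) < n_triples:
        trip: list[int] = []
        for c in pool:
            if c in used:
                continue
            if all(m[c] != m[t] for t in trip):
                trip.append(c)
            if len(trip) == 3:
                break
        if len(trip) < 3:
            raise ValueError(f"ran out of regions after {len(triples)} triples")
        triples.append(tuple(trip))
        used.update(trip)
    return tuple(triples)


def spread_clique_nodes(spec: CohortSpec, size: int, seed: int = 0,
                        exclude: set[int] | None = None) -> tuple[int, ...]:
    """``size`` regions taken round-robin across ground-truth modules."""
    m = spec.modules()
    rng = np.random.default_rng(seed)
    used = set(exclude or ())
    per_module = {k: [int(i) for i in rng.permutation(np.flatnonzero(m == k))
                      if i not in used]
                  for k in np.unique(m)}
    nodes: list[int] = []
    while len(nodes) < size:
        progressed = False
        for k in sorted(per_module):
            if per_module[k] and len(nodes) < size:
                nodes.append(per_module[k].pop())
                progressed = True
        if not progressed:
            raise ValueError(f"not enough regions for a clique of {size}")
    return tuple(sorted(nodes))


def calibrate_clustering_effect(
    spec: CohortSpec,
    target_sd: float = 1.0,
    sparsity: float = 0.17,
    loading: float = 0.7,
    pilot_per_group: int = 20,
    min_size: int = 8,
    max_size: int = 30,
    seed: int = 0,
    exclude: set[int] | None = None,
) -> CliqueEffect:
    """Latent-clique wiring sized to shift mean clustering by ``target_sd`` SDs.

    The clustering effect is specified on the metric scale (units of the
    pooled per-subject SD of the mean clustering coefficient C) but
    injected on the data scale (a cross-module latent clique). This helper
    closes the gap empirically: pilot cohorts, run through the same
    cleaning -> correlation -> threshold -> clustering path as the
    analysis, measure the standardized C shift of candidate clique sizes,
    and the size whose realized shift is closest to the target is
    returned. Pilot cohorts share a seed across candidates (common random
    numbers), so the size -> shift curve is stable and monotone.
    """
    from .metrics import mean_clustering
    from .networks import (bandpass_filter, functional_matrix, regress_nuisance,
                           threshold_at_sparsity)

    def subject_c(series: np.ndarray, nuis: np.ndarray) -> float:
        filt = bandpass_filter(series, tr_seconds=spec.tr_seconds)
        clean = regress_nuisance(filt, bandpass_filter(nuis, tr_seconds=spec.tr_seconds))
        net = threshold_at_sparsity(functional_matrix(clean), sparsity)
        return mean_clustering(net)

    def standardized_shift(effect: CliqueEffect | None) -> float:
        eff_spec = () if effect is None else (effect,)
        pilot = generate_cohort(replace(spec, n_per_group=pilot_per_group,
                                        effect_spec=eff_spec,
                                        covariate_model=None,
                                        seed=spec.seed + 7919))
        c = np.array([subject_c(pilot.timeseries[s], pilot.nuisance[s])
                      for s in range(2 * pilot_per_group)])
        pm = pilot.group_labels == "patient"
        pooled = np.sqrt((c[pm].var(ddof=1) + c[~pm].var(ddof=1)) / 2)
        return float((c[pm].mean() - c[~pm].mean()) / pooled)

    best: tuple[float, CliqueEffect] | None = None
    for size in range(min_size, max_size + 1):
        eff = CliqueEffect(nodes=spread_clique_nodes(spec, size, seed, exclude),
                           loading=loading)
        shift = standardized_shift(eff)
        logger.info("clustering calibration: clique size %d -> %+.2f SD",
                    size, shift)
        if best is None or abs(shift - target_sd) < abs(best[0] - target_sd):
            best = (shift, eff)
        if shift >= target_sd:
            break
    if best is None or best[0] < 0.5 * target_sd:
        raise ValueError(
            f"clique sizes up to {max_size} shift C by at most "
            f"{0.0 if best is None else best[0]:.2f} SD; raise loading or max_size"
        )
    return best[1]


def functional_matrix_from_population(r: np.ndarray):
    """Wrap a population correlation matrix as a ConnectivityMatrix."""
    from .networks import ConnectivityMatrix

    vals = r.copy()
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(values=vals, kind="functional",
                              provenance="population")


def simulate_partial_correlation_triplet(
    n: int, r_partial: float, seed=None,
    age_mean: float = AGE_PATIENT[0], age_sd: float = AGE_PATIENT[1],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(metric x, duration y, age control) with exact population partial corr.

    Both x and y load on age; their age-independent residuals are bivariate
    normal with correlation ``r_partial``, so the population partial
    correlation of x and y given age equals ``r_partial`` by construction.
    """
    rng = np.random.default_rng(seed)
    age = rng.normal(age_mean, age_sd, n)
    cov = np.array([[1.0, r_partial], [r_partial, 1.0]])
    resid = rng.multivariate_normal([0, 0], cov, size=n)
    z_age = (age - age_mean) / age_sd
    x = 0.5 * z_age + resid[:, 0]  # metric-like
    y = 0.8 * z_age + resid[:, 1]  # duration-like
    return x, y, age


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(cohort: SyntheticCohort, path: str | Path) -> Path:
    """Write a cohort as plain TSV matrices plus a YAML manifest."""
    path = Path(path)
    (path / "timeseries").mkdir(parents=True, exist_ok=True)
    (path / "nuisance").mkdir(exist_ok=True)
    cohort.gm_volumes.to_csv(path / "gm_volumes.tsv", sep="\t")
    cohort.groups.to_frame().to_csv(path / "groups.tsv", sep="\t")
    cohort.clinical.to_csv(path / "clinical.tsv", sep="\t")
    for s, sid in enumerate(cohort.subject_ids):
        np.savetxt(path / "timeseries" / f"{sid}.tsv", cohort.timeseries[s],
                   delimiter="\t")
        np.savetxt(path / "nuisance" / f"{sid}.tsv", cohort.nuisance[s],
                   delimiter="\t")
    spec_dict = dataclasses.asdict(cohort.spec)
    spec_dict["module_assignment"] = cohort.spec.modules().tolist()
    if isinstance(spec_dict["gm_mean_per_region"], np.ndarray):
        spec_dict["gm_mean_per_region"] = spec_dict["gm_mean_per_region"].tolist()
    manifest = {"spec": spec_dict, "truth": cohort.truth,
                "n_subjects": len(cohort.subject_ids)}
    with open(path / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=True)
    return path


def read_cohort(path: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort` (or the same layout)."""
    path = Path(path)
    gm = pd.read_csv(path / "gm_volumes.tsv", sep="\t", index_col=0)
    groups = pd.read_csv(path / "groups.tsv", sep="\t", index_col=0)["group"]
    clinical = pd.read_csv(path / "clinical.tsv", sep="\t", index_col=0)
    with open(path / "manifest.yaml") as f:
        manifest = yaml.safe_load(f)
    sd = dict(manifest["spec"])
    sd["module_assignment"] = np.asarray(sd["module_assignment"])
    sd["effect_spec"] = ()  # effects live in truth; spec carries parameters
    sd["covariate_model"] = None
    spec = CohortSpec(**sd)
    ids = list(groups.index)
    ts = np.stack([np.loadtxt(path / "timeseries" / f"{sid}.tsv", delimiter="\t")
                   for sid in ids])
    nuis = np.stack([np.loadtxt(path / "nuisance" / f"{sid}.tsv", delimiter="\t")
                     for sid in ids])
    return SyntheticCohort(gm_volumes=gm, timeseries=ts, nuisance=nuis,
                           groups=groups, clinical=clinical,
                           truth=manifest.get("truth", {}), spec=spec)
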