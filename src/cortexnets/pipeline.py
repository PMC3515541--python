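"""End-to-end orchestration: cohort -> matrices -> networks -> metrics -> inference.

The pipeline reproduces the analysis workflow shape: clean each subject's
ROI time series (band-pass, nuisance regression), build per-subject
functional and per-group structural correlation matrices, verify full
connectedness at the analysis sparsity, sweep global metrics over the
sparsity grid, run permutation tests (functional: subject-level metrics;
structural: matrix-rebuild scheme), test nodal betweenness with FDR
correction, run the network-based statistic on functional matrices,
decompose the significant NBS component into modules, and correlate
patient metrics with migraine duration controlling for age.

Every stage draws its randomness from a child seed of ``master_seed``
(fixed spawn keys), so two runs with the same configuration produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, metrics, modularity, networks, synthetic
from ._rng import stage_seed

logger = logging.getLogger(__name__)


def default_sparsity_grid() -> tuple[float, ...]:
    """0.15 to 0.30 in 0.01 increments."""
    return tuple(round(0.15 + 0.01 * i, 2) for i in range(16))


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a full run needs; see field names for the knobs."""

    cohort_spec: synthetic.CohortSpec | None = None
    input_dir: str | None = None
    sparsity_grid: tuple[float, ...] = field(default_factory=default_sparsity_grid)
    analysis_sparsity: float = 0.17
    edge_ranking: str = "absolute"
    n_null_graphs: int = 100  # group-level random-graph nulls
    n_null_subject: int = 20  # per-subject gamma/lambda nulls
    n_perm_global: int = 5000
    n_perm_structural: int = 1000
    n_perm_nbs: int = 1000
    nbs_primary_p: float = 0.005
    fdr_q_global: float = 0.01
    fdr_q_nodal: float = 0.01
    modularity_restarts: int = 1000
    master_seed: int = 0
    cohort_seed_from_master: bool = True

    def validate(self) -> None:
        grid = self.sparsity_grid
        if not grid or any(not 0 < s < 1 for s in grid):
            raise ValueError("sparsity grid values must lie in (0, 1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("sparsity grid must be strictly increasing")
        if not any(np.isclose(self.analysis_sparsity, s) for s in grid):
            raise ValueError(
                f"analysis sparsity {self.analysis_sparsity} must be on the grid")
        if self.cohort_spec is None and self.input_dir is None:
            raise ValueError("provide a cohort_spec or an input_dir")


def _stage_rng_int(master_seed: int, stage: str) -> int:
    return int(stage_seed(master_seed, stage).generate_state(1)[0] % (2**31 - 1))


def clean_functional(cohort: synthetic.SyntheticCohort) -> np.ndarray:
    """Band-pass then nuisance-regress every subject's ROI time series."""
    tr = cohort.spec.tr_seconds
    out = np.empty_like(cohort.timeseries)
    for s in range(cohort.timeseries.shape[0]):
        filt = networks.bandpass_filter(cohort.timeseries[s], tr_seconds=tr)
        nuis = networks.bandpass_filter(cohort.nuisance[s], tr_seconds=tr)
        out[s] = networks.regress_nuisance(filt, nuis)
    return out


def functional_matrices(cohort: synthetic.SyntheticCohort,
                        cleaned: np.ndarray | None = None) -> np.ndarray:
    """n_subjects x N x N functional correlation matrices."""
    if cleaned is None:
        cleaned = clean_functional(cohort)
    mats = np.empty((cleaned.shape[0], cleaned.shape[1], cleaned.shape[1]))
    for s in range(cleaned.shape[0]):
        mats[s] = networks.functional_matrix(
            cleaned[s], provenance=cohort.subject_ids[s]).values
    return mats


@dataclass
class AnalysisReport:
    config: dict
    cohort_truth: dict
    connectivity_check: dict
    largest_component: dict
    global_metrics: pd.DataFrame  # tidy: network, group/subject, S, metric, value
    global_tests: pd.DataFrame
    nodal_table: pd.DataFrame
    nbs_summary: dict
    modularity_summary: dict
    clinical: pd.DataFrame

    def to_json_dict(self) -> dict:
        return _jsonify({
            "config": self.config,
            "cohort_truth": self.cohort_truth,
            "connectivity_check": self.connectivity_check,
            "largest_component": self.largest_component,
            "global_tests": self.global_tests.to_dict(orient="records"),
            "nodal_significant": self.nodal_table[
                self.nodal_table.get("reject_fdr", pd.Series(dtype=bool)) == True  # noqa: E712
            ].to_dict(orient="records") if len(self.nodal_table) else [],
            "nbs": self.nbs_summary,
            "modularity": self.modularity_summary,
            "clinical": self.clinical.to_dict(orient="records"),
        })

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as f:
            json.dump(self.to_json_dict(), f, indent=2, sort_keys=True)
            f.write("\n")
        self.global_metrics.to_csv(out / "global_metrics.tsv", sep="\t", index=False)
        self.global_tests.to_csv(out / "global_tests.tsv", sep="\t", index=False)
        self.nodal_table.to_csv(out / "nodal_betweenness.tsv", sep="\t", index=False)
        self.clinical.to_csv(out / "clinical_associations.tsv", sep="\t", index=False)
        return out


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _log_stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %6.1f s", name, t1 - t0)
    return t1


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full analysis; deterministic under ``master_seed``."""
    config.validate()
    t0 = time.perf_counter()
    s_analysis = config.analysis_sparsity
    ranking = config.edge_ranking

    # --- cohort
    if config.input_dir is not None:
        cohort = synthetic.read_cohort(config.input_dir)
    else:
        spec = config.cohort_spec
        if config.cohort_seed_from_master:
            spec = replace(spec, seed=_stage_rng_int(config.master_seed, "cohort"))
        cohort = synthetic.generate_cohort(spec)
    labels = list(cohort.gm_volumes.columns)
    groups = cohort.group_labels
    is_patient = groups == "patient"
    t0 = _log_stage("cohort", t0)

    # --- functional cleaning and matrices
    cleaned = clean_functional(cohort)
    fmats = functional_matrices(cohort, cleaned)
    t0 = _log_stage("functional matrices", t0)

    # --- structural matrices (one per group)
    gm = cohort.gm_volumes.to_numpy()
    smats = {
        g: networks.structural_matrix(gm, np.flatnonzero(groups == g),
                                      provenance=g, labels=labels)
        for g in ("control", "patient")
    }

    # --- connectivity check at the analysis sparsity
    def connected(mat_values) -> bool:
        cm = networks.ConnectivityMatrix(values=mat_values, kind="functional")
        return networks.threshold_at_sparsity(cm, s_analysis, ranking).is_connected()

    disconnected_subjects = [cohort.subject_ids[s] for s in range(len(fmats))
                             if not connected(fmats[s])]
    disconnected_groups = [g for g, m in smats.items()
                           if not networks.threshold_at_sparsity(
                               m, s_analysis, ranking).is_connected()]
    if disconnected_subjects or disconnected_groups:
        raise RuntimeError(
            "network(s) disconnected at the analysis sparsity "
            f"S={s_analysis} (subjects: {disconnected_subjects}, "
            f"structural groups: {disconnected_groups}); the analysis "
            "sparsity must be the lowest S at which every network is fully "
            "connected — raise it or inspect the largest-component curve"
        )
    connectivity_check = {"sparsity": s_analysis, "all_connected": True}

    # --- largest-component curves (structural, per group)
    largest_component = {
        g: networks.largest_component_curve(m, config.sparsity_grid, ranking)
        for g, m in smats.items()
    }
    t0 = _log_stage("structural + connectivity", t0)

    # --- metric sweep over the grid
    rows = []
    func_c = {}  # (S) -> per-subject array
    func_l = {}
    for s in config.sparsity_grid:
        cs = np.empty(len(fmats))
        ls = np.empty(len(fmats))
        for i in range(len(fmats)):
            cm = networks.ConnectivityMatrix(values=fmats[i], kind="functional",
                                             provenance=cohort.subject_ids[i])
            net = networks.threshold_at_sparsity(cm, s, ranking)
            cs[i] = metrics.mean_clustering(net)
            ls[i], _ = metrics.characteristic_path_length(net)
        func_c[s], func_l[s] = cs, ls
        for g in ("control", "patient"):
            sel = groups == g
            rows.append(("functional", g, s, "C", float(cs[sel].mean())))
            rows.append(("functional", g, s, "L", float(ls[sel].mean())))
        for g, m in smats.items():
            net = networks.threshold_at_sparsity(m, s, ranking)
            rows.append(("structural", g, s, "C", metrics.mean_clustering(net)))
            rows.append(("structural", g, s, "L",
                         metrics.characteristic_path_length(net)[0]))
    t0 = _log_stage("metric sweep", t0)

    # --- small-world ratios at the analysis sparsity
    null_seed = stage_seed(config.master_seed, "null_graphs")
    sub_seeds = null_seed.spawn(len(fmats) + 2)
    func_gamma = np.empty(len(fmats))
    func_lambda = np.empty(len(fmats))
    for i in range(len(fmats)):
        cm = networks.ConnectivityMatrix(values=fmats[i], kind="functional")
        net = networks.threshold_at_sparsity(cm, s_analysis, ranking)
        gm_i = metrics.small_world_metrics(net, n_null=config.n_null_subject,
                                           seed=np.random.default_rng(sub_seeds[i]))
        func_gamma[i], func_lambda[i] = gm_i.gamma, gm_i.lam
    for k, (g, m) in enumerate(smats.items()):
        net = networks.threshold_at_sparsity(m, s_analysis, ranking)
        sw = metrics.small_world_metrics(net, n_null=config.n_null_graphs,
                                         seed=np.random.default_rng(sub_seeds[len(fmats) + k]))
        for name, val in (("gamma", sw.gamma), ("lambda", sw.lam),
                          ("C_rand", sw.clustering_random),
                          ("L_rand", sw.path_length_random)):
            rows.append(("structural", g, s_analysis, name, float(val)))
    for g in ("control", "patient"):
        sel = groups == g
        rows.append(("functional", g, s_analysis, "gamma", float(func_gamma[sel].mean())))
        rows.append(("functional", g, s_analysis, "lambda", float(func_lambda[sel].mean())))
    global_metrics = pd.DataFrame(
        rows, columns=["network", "group", "sparsity", "metric", "value"])
    t0 = _log_stage("small-world ratios", t0)

    # --- global-metric permutation tests
    perm_seed = stage_seed(config.master_seed, "perm_global")
    perm_children = perm_seed.spawn(4 * len(config.sparsity_grid) + 4)
    test_rows = []
    ci = 0
    for s in config.sparsity_grid:
        for name, vals in (("C", func_c[s]), ("L", func_l[s])):
            res = inference.permute_functional_metric(
                vals, groups, n_perm=config.n_perm_global,
                seed=np.random.default_rng(perm_children[ci]), metric=name)
            ci += 1
            test_rows.append(("functional", s, name, res.observed_difference,
                              res.p_value, res.n_perm))
        for name, fn in (("C", metrics.mean_clustering),
                         ("L", lambda n: metrics.characteristic_path_length(n)[0])):
            res = inference.permute_structural_metric(
                gm, groups, s, fn, n_perm=config.n_perm_structural,
                seed=np.random.default_rng(perm_children[ci]), metric=name,
                ranking=ranking)
            ci += 1
            test_rows.append(("structural", s, name, res.observed_difference,
                              res.p_value, res.n_perm))
    for name, vals in (("gamma", func_gamma), ("lambda", func_lambda)):
        res = inference.permute_functional_metric(
            vals, groups, n_perm=config.n_perm_global,
            seed=np.random.default_rng(perm_children[ci]), metric=name)
        ci += 1
        test_rows.append(("functional", s_analysis, name,
                          res.observed_difference, res.p_value, res.n_perm))
    global_tests = pd.DataFrame(
        test_rows,
        columns=["network", "sparsity", "metric", "observed_difference",
                 "p_value", "n_perm"])
    # FDR within each (network, metric) family across the sparsity grid
    global_tests["reject_fdr"] = False
    for (net_kind, met), idx in global_tests.groupby(["network", "metric"]).groups.items():
        rej, _ = inference.fdr_correct(global_tests.loc[idx, "p_value"],
                                       q=config.fdr_q_global)
        global_tests.loc[idx, "reject_fdr"] = rej
    t0 = _log_stage("global permutation tests", t0)

    # --- nodal betweenness at the analysis sparsity
    nodal_seed = stage_seed(config.master_seed, "perm_nodal")
    nodal_children = nodal_seed.spawn(2)
    n_reg = fmats.shape[1]
    bc = np.empty((len(fmats), n_reg))
    for i in range(len(fmats)):
        cm = networks.ConnectivityMatrix(values=fmats[i], kind="functional")
        net = networks.threshold_at_sparsity(cm, s_analysis, ranking)
        bc[i] = metrics.betweenness_all(net).betweenness
    nodal_rows = []
    rng_nodal = np.random.default_rng(nodal_children[0])
    for r in range(n_reg):
        res = inference.permute_functional_metric(
            bc[:, r], groups, n_perm=config.n_perm_global, seed=rng_nodal,
            metric=f"betweenness[{labels[r]}]")
        nodal_rows.append(("functional", labels[r],
                           float(bc[~is_patient, r].mean()),
                           float(bc[is_patient, r].mean()),
                           res.observed_difference, res.p_value))
    snull = _permute_structural_nodal(
        gm, groups, s_analysis, n_perm=config.n_perm_structural,
        seed=np.random.default_rng(nodal_children[1]), ranking=ranking)
    for r in range(n_reg):
        nodal_rows.append(("structural", labels[r], snull["observed_hc"][r],
                           snull["observed_pm"][r], snull["observed_diff"][r],
                           snull["p_values"][r]))
    nodal_table = pd.DataFrame(
        nodal_rows, columns=["network", "region", "mean_control",
                             "mean_patient", "observed_difference", "p_value"])
    nodal_table["reject_fdr"] = False
    for net_kind, idx in nodal_table.groupby("network").groups.items():
        rej, _ = inference.fdr_correct(nodal_table.loc[idx, "p_value"],
                                       q=config.fdr_q_nodal)
        nodal_table.loc[idx, "reject_fdr"] = rej
    t0 = _log_stage("nodal betweenness", t0)

    # --- NBS on functional matrices
    nbs_res = inference.nbs(
        fmats, groups, primary_p=config.nbs_primary_p,
        n_perm=config.n_perm_nbs,
        seed=np.random.default_rng(stage_seed(config.master_seed, "nbs")))
    nbs_summary = {
        "primary_threshold_t": nbs_res.primary_threshold,
        "n_suprathreshold_edges": len(nbs_res.suprathreshold_edges),
        "components": [
            {"n_edges": c.size, "n_nodes": len(c.nodes), "p_value": c.p_value,
             "regions": [labels[i] for i in c.nodes],
             "edges": [[labels[i], labels[j]] for i, j in c.edges]}
            for c in nbs_res.components
        ],
        "n_perm": nbs_res.n_perm,
    }
    t0 = _log_stage("NBS", t0)

    # --- modularity of the significant NBS component
    modularity_summary: dict = {"computed": False}
    significant = [c for c in nbs_res.components if c.p_value < 0.05]
    if significant:
        comp = max(significant, key=lambda c: c.size)
        sub_adj = np.zeros((len(comp.nodes), len(comp.nodes)), dtype=bool)
        node_pos = {n: i for i, n in enumerate(comp.nodes)}
        for i, j in comp.edges:
            sub_adj[node_pos[i], node_pos[j]] = True
        sub_adj |= sub_adj.T
        sub_net = networks.BinaryNetwork(
            adjacency=sub_adj, sparsity=s_analysis,
            labels=tuple(labels[n] for n in comp.nodes))
        part = modularity.optimal_partition(
            sub_net, n_restarts=config.modularity_restarts,
            seed=np.random.default_rng(stage_seed(config.master_seed, "modularity")))
        modularity_summary = {
            "computed": True,
            "component_p": comp.p_value,
            "Q": part.q,
            "n_modules": part.n_modules,
            "n_restarts": part.n_solutions_evaluated,
            "ranked_q_quantiles": {
                q: float(np.quantile(part.ranked_q, float(q)))
                for q in ("0.0", "0.5", "0.9", "1.0")},
            "modules": {
                str(mid): [sub_net.labels[i] for i in part.members(mid)]
                for mid in range(part.n_modules)},
        }
    t0 = _log_stage("modularity", t0)

    # --- clinical partial correlations (patients; duration controlling age)
    clin_rows = []
    pat = cohort.clinical.loc[is_patient]
    if pat["duration"].notna().all():
        for name, vals in (("C", func_c[s_analysis]), ("L", func_l[s_analysis])):
            assoc = inference.partial_correlation(
                vals[is_patient], pat["duration"].to_numpy(),
                pat["age"].to_numpy(), metric=name, covariate="duration")
            clin_rows.append((name, "duration", assoc.r_partial, assoc.p_value,
                              assoc.n, assoc.degenerate))
    else:
        logger.warning("clinical covariates missing; clinical stage skipped")
    clinical = pd.DataFrame(
        clin_rows, columns=["metric", "covariate", "r_partial", "p_value",
                            "n", "degenerate"])
    _log_stage("clinical", t0)

    config_dict = dataclasses.asdict(config)
    if config_dict.get("cohort_spec") is not None:
        cs = config_dict["cohort_spec"]
        if isinstance(cs.get("module_assignment"), np.ndarray):
            cs["module_assignment"] = cs["module_assignment"].tolist()
        cs["effect_spec"] = [dataclasses.asdict(e) if dataclasses.is_dataclass(e) else e
                             for e in cs.get("effect_spec", ())]
    return AnalysisReport(
        config=_jsonify(config_dict),
        cohort_truth=_jsonify(cohort.truth),
        connectivity_check=connectivity_check,
        largest_component=_jsonify(largest_component),
        global_metrics=global_metrics,
        global_tests=global_tests,
        nodal_table=nodal_table,
        nbs_summary=_jsonify(nbs_summary),
        modularity_summary=_jsonify(modularity_summary),
        clinical=clinical,
    )


def _permute_structural_nodal(gm, groups, sparsity, n_perm, seed, ranking):
    """Permutation test of per-region betweenness on structural networks.

    One matrix-rebuild per permutation serves all regions at once: each
    relabeling rebuilds both group covariance networks and records the full
    90-vector of betweenness differences.
    """
    groups = np.asarray(groups)
    g1 = np.flatnonzero(groups == "control")
    g2 = np.flatnonzero(groups == "patient")
    n1 = len(g1)
    all_idx = np.concatenate([g1, g2])

    def bc_diff(idx1, idx2):
        out = []
        for idx in (idx1, idx2):
            mat = networks.structural_matrix(gm, subject_subset=idx)
            net = networks.threshold_at_sparsity(mat, sparsity, ranking)
            out.append(metrics.betweenness_all(net).betweenness)
        return out[0], out[1]

    obs_hc, obs_pm = bc_diff(g1, g2)
    observed = obs_hc - obs_pm
    null = np.empty((n_perm, len(observed)))
    for b in range(n_perm):
        perm = seed.permutation(all_idx)
        h, p = bc_diff(perm[:n1], perm[n1:])
        null[b] = h - p
    p_vals = (np.count_nonzero(
        np.abs(null) >= np.abs(observed)[None, :], axis=0) + 1) / (n_perm + 1)
    return {"observed_hc": obs_hc, "observed_pm": obs_pm,
            "observed_diff": observed, "p_values": p_vals}
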