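"""Synthetic-cohort generator: determinism, block structure, effect fidelity."""

import dataclasses
import hashlib

import numpy as np
import pytest
from scipy import stats

from cortexnets.synthetic import (
    CliqueEffect,
    CohortSpec,
    CovariateLink,
    EdgeEffect,
    TriangleEffect,
    VolumeShift,
    block_correlation,
    default_module_assignment,
    ensure_psd,
    generate_cohort,
    null_cohort,
    planted_component_edges,
    read_cohort,
    simulate_partial_correlation_triplet,
    spread_clique_nodes,
    write_cohort,
)


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


class TestSpecValidation:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_cohort(CohortSpec(n_per_group=0))

    def test_correlation_ordering_enforced(self):
        with pytest.raises(ValueError, match="within_module_corr"):
            CohortSpec(within_module_corr=0.1, between_module_corr=0.5).validate()

    def test_module_assignment_length_checked(self):
        spec = CohortSpec(n_regions=10,
                          module_assignment=np.zeros(7, dtype=int))
        with pytest.raises(ValueError, match="one entry per region"):
            spec.validate()


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, tiny_cohort_spec):
        a = generate_cohort(tiny_cohort_spec)
        b = generate_cohort(tiny_cohort_spec)
        assert _hash(a.gm_volumes.to_numpy()) == _hash(b.gm_volumes.to_numpy())
        assert _hash(a.timeseries) == _hash(b.timeseries)
        assert _hash(a.nuisance) == _hash(b.nuisance)
        assert a.clinical.equals(b.clinical)

    def test_different_seed_differs(self, tiny_cohort_spec):
        a = generate_cohort(tiny_cohort_spec)
        b = generate_cohort(dataclasses.replace(tiny_cohort_spec, seed=8))
        assert _hash(a.timeseries) != _hash(b.timeseries)


class TestBlockStructure:
    def test_within_exceeds_between_at_study_scale(self):
        spec = CohortSpec(n_per_group=43, seed=1)
        co = null_cohort(spec)
        m = spec.modules()
        same = m[:, None] == m[None, :]
        iu = np.triu_indices(spec.n_regions, k=1)
        within_mask = same[iu]
        r = np.corrcoef(co.timeseries[0])[iu]
        assert r[within_mask].mean() > r[~within_mask].mean() + 0.2

    def test_block_gap_converges_with_long_series(self):
        spec = CohortSpec(n_per_group=1, n_timepoints=2000, seed=2,
                          nuisance_mixing=0.0)
        co = null_cohort(spec)
        m = spec.modules()
        iu = np.triu_indices(spec.n_regions, k=1)
        within_mask = (m[:, None] == m[None, :])[iu]
        r = np.corrcoef(co.timeseries[0])[iu]
        gap = r[within_mask].mean() - r[~within_mask].mean()
        assert gap == pytest.approx(
            spec.within_module_corr - spec.between_module_corr, abs=0.05)

    def test_structural_volumes_share_block_structure(self):
        spec = CohortSpec(n_per_group=200, n_regions=30, n_timepoints=3, seed=3)
        co = null_cohort(spec)
        gm = co.gm_volumes.to_numpy()
        r = np.corrcoef(gm.T)
        m = spec.modules()
        iu = np.triu_indices(30, k=1)
        within_mask = (m[:, None] == m[None, :])[iu]
        assert r[iu][within_mask].mean() > r[iu][~within_mask].mean() + 0.2


class TestEffects:
    def test_edge_increment_recovered(self):
        spec0 = CohortSpec(seed=0)
        edges = planted_component_edges(spec0, 6, seed=4)
        delta = 0.2
        spec = CohortSpec(seed=5, effect_spec=(EdgeEffect(edges, delta),))
        co = generate_cohort(spec)
        ei = [e[0] for e in edges]
        ej = [e[1] for e in edges]
        r_by_subject = np.array([np.corrcoef(ts)[ei, ej] for ts in co.timeseries])
        pm = co.group_labels == "patient"
        recovered = r_by_subject[pm].mean() - r_by_subject[~pm].mean()
        assert recovered == pytest.approx(delta, abs=0.1)

    def test_volume_shift_applied_to_patients_only(self):
        regions = (0, 3, 5)
        spec = CohortSpec(n_per_group=200, n_regions=20, n_timepoints=3,
                          seed=6, effect_spec=(VolumeShift(regions, 1.0),))
        co = generate_cohort(spec)
        gm = co.gm_volumes.to_numpy()
        pm = co.group_labels == "patient"
        diff = gm[pm].mean(axis=0) - gm[~pm].mean(axis=0)
        assert np.all(diff[list(regions)] > 0.5)
        others = [i for i in range(20) if i not in regions]
        assert np.abs(diff[others]).max() < 0.5

    def test_clique_effect_is_psd_and_recorded(self):
        spec0 = CohortSpec(seed=0)
        nodes = spread_clique_nodes(spec0, 12, seed=7)
        spec = CohortSpec(seed=8, effect_spec=(CliqueEffect(nodes, 0.7),))
        co = generate_cohort(spec)  # would raise if implied matrix non-PSD
        pairs = {(a, b) for a in nodes for b in nodes if a < b}
        assert pairs <= {tuple(e) for e in co.truth["modified_edges"]}

    def test_gross_psd_violation_rejected_with_eigenvalue(self):
        # mutually contradictory strong triangles sharing nodes
        triples = ((0, 1, 2), (0, 1, 3))
        eff = (TriangleEffect(triples, corr=0.95),
               EdgeEffect(((2, 3),), delta_r=-1.0))
        spec = CohortSpec(n_regions=10, seed=9, effect_spec=eff,
                          module_assignment=np.zeros(10, dtype=int),
                          within_module_corr=0.2, between_module_corr=0.0)
        with pytest.raises(ValueError, match="eigenvalue"):
            generate_cohort(spec)

    def test_mild_violation_repaired(self, caplog):
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.99
        r[0, 2] = r[2, 0] = 0.99
        r[1, 2] = r[2, 1] = 0.9595  # slightly below the consistency bound
        with caplog.at_level("WARNING"):
            fixed = ensure_psd(r)
        assert np.linalg.eigvalsh(fixed)[0] >= 0
        assert np.allclose(np.diag(fixed), 1.0)
        assert "PSD repair" in caplog.text

    def test_covariate_link_scales_with_duration(self):
        spec0 = CohortSpec(seed=0)
        edges = planted_component_edges(spec0, 6, seed=10)
        spec = CohortSpec(seed=11, effect_spec=(EdgeEffect(edges, 0.15),),
                          covariate_model=CovariateLink(slope=0.6))
        co = generate_cohort(spec)
        scales = np.array(co.truth["effect_scales"])
        pm_ids = [s for s in co.subject_ids if s.startswith("PM")]
        dur = co.clinical.loc[pm_ids, "duration"].to_numpy()
        assert np.corrcoef(scales, dur)[0, 1] > 0.95


class TestNullCohort:
    def test_truth_records_no_effects(self, tiny_cohort_spec):
        spec = dataclasses.replace(
            tiny_cohort_spec,
            effect_spec=(VolumeShift((0,), 5.0),))
        co = null_cohort(spec)
        assert co.truth["effects"] == []
        assert co.truth["modified_edges"] == []
        assert co.truth["shifted_regions"] == []

    def test_gm_group_difference_pvalues_uniform(self):
        spec = CohortSpec(n_per_group=43, seed=12)
        co = null_cohort(spec)
        gm = co.gm_volumes.to_numpy()
        pm = co.group_labels == "patient"
        p = np.array([stats.ttest_ind(gm[pm, r], gm[~pm, r]).pvalue
                      for r in range(gm.shape[1])])
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_controls_have_na_disease_fields(self, tiny_cohort_spec):
        co = null_cohort(tiny_cohort_spec)
        hc = co.clinical.loc[co.group_labels == "control"]
        pm = co.clinical.loc[co.group_labels == "patient"]
        assert hc[["duration", "frequency", "intensity"]].isna().all().all()
        assert pm[["duration", "frequency", "intensity"]].notna().all().all()
        assert hc["age"].notna().all()

    def test_group_sizes_match_spec(self, tiny_cohort_spec):
        co = null_cohort(tiny_cohort_spec)
        assert (co.group_labels == "control").sum() == tiny_cohort_spec.n_per_group
        assert (co.group_labels == "patient").sum() == tiny_cohort_spec.n_per_group


class TestHelpers:
    def test_default_modules_partition_all_regions(self):
        m = default_module_assignment(90)
        assert len(m) == 90
        assert set(np.diff(np.flatnonzero(np.diff(m)))).issubset({11, 12})

    def test_planted_edges_form_connected_path_across_modules(self):
        spec = CohortSpec(seed=0)
        edges = planted_component_edges(spec, 10, seed=0)
        assert len(edges) == 10
        m = spec.modules()
        for i, j in edges:
            assert m[i] != m[j]
        nodes = {n for e in edges for n in e}
        assert len(nodes) == 11  # a path: edges+1 nodes, connected

    def test_block_correlation_matrix_psd(self):
        r = block_correlation(CohortSpec(seed=0))
        assert np.linalg.eigvalsh(r)[0] > 0

    def test_partial_correlation_triplet_population_value(self):
        xs = []
        for rep in range(200):
            x, y, age = simulate_partial_correlation_triplet(400, 0.5, seed=rep)
            from cortexnets.inference import partial_correlation

            xs.append(partial_correlation(x, y, age).r_partial)
        assert np.mean(xs) == pytest.approx(0.5, abs=0.02)


class TestIO:
    def test_roundtrip(self, tiny_cohort_spec, tmp_path):
        co = generate_cohort(tiny_cohort_spec)
        write_cohort(co, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        np.testing.assert_allclose(back.timeseries, co.timeseries, rtol=0, atol=0)
        np.testing.assert_allclose(back.nuisance, co.nuisance, rtol=0, atol=0)
        assert back.gm_volumes.columns.tolist() == co.gm_volumes.columns.tolist()
        np.testing.assert_allclose(back.gm_volumes.to_numpy(),
                                   co.gm_volumes.to_numpy(), atol=1e-12)
        assert back.groups.tolist() == co.groups.tolist()
        assert back.spec.n_per_group == tiny_cohort_spec.n_per_group
        assert back.truth["effects"] == []
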