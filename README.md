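# cortexnets

Graph-theoretic group comparison of brain correlation networks.

`cortexnets` implements the complete analysis chain used in connectome
studies that contrast a patient cohort with matched controls on ROI-level
MRI derivatives — no raw images involved. It is aimed at methodologists
and neuroimaging analysts who need a tested, reproducible implementation
of:

* **structural covariance networks** — region × region Pearson correlation
  of mean gray-matter volumes computed *across subjects*, one 90 × 90
  matrix per group;
* **functional networks** — region × region correlation of band-passed
  (0.01–0.1 Hz), nuisance-regressed resting-state ROI time series, one
  matrix per subject;
* **sparsity thresholding** — binarization keeping exactly
  K = round(S · N(N−1)/2) strongest edges, so every network has the same
  wiring cost; the analysis sparsity (default S = 0.17, K = 681 for
  N = 90) is validated as the lowest S at which all networks are fully
  connected;
* **small-world metrics** — mean clustering coefficient C, characteristic
  path length L, and their normalizations γ = C/C_rand, λ = L/L_rand
  against degree-preserving rewired nulls (small-world regime: γ ≫ 1,
  λ ≈ 1);
* **nodal betweenness centrality** — B_i = Σ_{j≠k≠i} σ_jk(i)/σ_jk
  (unnormalized shortest-path counts);
* **Newman modularity** — Q = (1/2m) Σ_ij (A_ij − k_i k_j/2m) δ(c_i,c_j),
  maximized over 1000 ranked restart solutions;
* **permutation inference** — subject-relabeling nulls for global and
  nodal metrics (structural networks are rebuilt per permutation, since
  they exist only at the group level), Benjamini–Hochberg FDR, the
  network-based statistic (NBS) for edge-level effects with
  component-size family-wise control, and partial correlations of metrics
  with clinical covariates controlling for age.

Because cohort MRI data of this kind are private, the package ships a
first-class synthetic-cohort generator (`cortexnets.synthetic`) that
emulates the study design — 43 subjects per group, 90 regions (packaged
AAL label table), 200 timepoints at TR = 2 s — with modular covariance
structure, nuisance processes, clinical covariates, and *injectable,
ground-truth-recorded* group effects. Every stage of the pipeline is
validated against this generator: type-I calibration on null cohorts and
planted-effect recovery.

## Worked example

```python
import numpy as np
import cortexnets as cn
from cortexnets import pipeline

spec = cn.CohortSpec(seed=7)              # 43+43 subjects, 90 regions
cohort = cn.generate_cohort(spec)
fmats = pipeline.functional_matrices(cohort)   # band-pass -> regress -> r

m = cn.ConnectivityMatrix(values=fmats[0], kind="functional")
net = cn.threshold_at_sparsity(m, 0.17)
print(net.edge_count, net.is_connected())
# 681 True

sw = cn.small_world_metrics(net, n_null=100, seed=1)
print(f"C={sw.clustering_mean:.3f} L={sw.path_length:.3f} "
      f"gamma={sw.gamma:.2f} lambda={sw.lam:.2f}")
# C=0.614 L=2.151 gamma=3.57 lambda=1.14

c_vals = np.array([
    cn.mean_clustering(cn.threshold_at_sparsity(
        cn.ConnectivityMatrix(values=f, kind="functional"), 0.17))
    for f in fmats])
res = cn.permute_functional_metric(c_vals, cohort.group_labels,
                                   n_perm=5000, seed=2, metric="C")
print(f"C diff {res.observed_difference:+.4f}  p={res.p_value:.3f}")
# C diff -0.0078  p=0.218
```

The first subject's network keeps exactly 681 of 4005 possible edges and
is fully connected at S = 0.17. γ = 3.57 with λ = 1.14 places it firmly in
the small-world regime. This cohort carries no injected effects, so the
clustering difference between groups is noise (p = 0.218); rerun with an
`effect_spec` (e.g. `cn.EdgeEffect`, `cn.CliqueEffect`) to plant
detectable group differences.

The same workflow is available from the shell:

```bash
cortexnets simulate --seed 7 --out cohort/
cortexnets build-networks --cohort cohort/ --sparsity 0.17 --out nets/
cortexnets run-all --seed 7 --out report/
```

`run-all` executes the full analysis (metric sweep over S = 0.15–0.30,
permutation tests, nodal FDR, NBS, modularity of the significant
component, clinical partial correlations) and writes `report.json` plus
tidy TSV tables. Runs are byte-identical under a fixed master seed.

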