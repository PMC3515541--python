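# Methods

This note documents the models, defaults and numerical choices behind
`cortexnets`, and what the synthetic validation does and does not show
about real data.

## Networks

**Nodes.** The 90 cortical/subcortical regions of the AAL parcellation,
shipped as a TSV resource (45 base regions × two hemispheres, suffixed
`_l`/`_r`). The insula is abbreviated `INS` (its standard AAL
abbreviation) so that all 90 abbreviations are unique.

**Edges.** Pearson correlation in both network families, but over
different sampling units:

* functional: correlation over *time* between two regions' cleaned ROI
  series → one matrix per subject;
* structural covariance: correlation over *subjects* between two regions'
  mean gray-matter volumes → one matrix per group. This asymmetry drives
  the inference design below.

**Functional cleaning.** Band-pass 0.01–0.1 Hz (4th-order Butterworth,
zero-phase forward–backward, i.e. an 8th-order magnitude response),
followed by regression of eight nuisance series (white-matter mean, CSF
mean, six motion parameters, band-passed the same way) plus an intercept.
Residuals are exactly orthogonal to the regressors. The first-volume
discard is the data provider's responsibility; the pipeline takes the
timepoint count from the cohort manifest.

**Thresholding.** At sparsity S, exactly K = round(S · N(N−1)/2) edges
are kept (round-half-away-from-zero, so K is bit-exact across platforms).
Edges are ranked by |r| by default; ranking by signed r is available
(`edge_ranking`) because the literature is split on the treatment of
negative correlations, and the two modes can give different networks.
Ties break lexicographically by (i, j), which makes edge sets nested
across S and runs reproducible. The analysis sparsity (default 0.17) must
lie on the sweep grid (default 0.15–0.30 step 0.01), and the pipeline
refuses to proceed if any network is disconnected there — the analysis
sparsity is meant to be the lowest S at which every network is fully
connected, and the largest-component-vs-S curve is reported for checking
that.

## Graph metrics

Mean clustering C averages the per-node ratio of realized to possible
neighbor–neighbor edges over **all** nodes; nodes of degree < 2, where the
ratio is undefined, contribute 0 (the dominant convention; keeps
C ∈ [0, 1]). Path length L is the mean shortest-path hop count over node
pairs; for disconnected graphs the mean is over connected pairs only and
a flag is set — infinities are never silently averaged.

γ = C/C_rand and λ = L/L_rand use degree-preserving (Maslov–Sneppen)
rewired nulls: 10·K double-edge swaps, resampled (up to 10 times) if the
null is disconnected; graphs admitting no swap (e.g. complete graphs) are
their own null, making γ = 1 exact there. An Erdős–Rényi G(N, K) null is
available as an option, but degree-preserving rewiring is the default
because C and L are strongly degree-sequence-dependent. Default
n_null = 100 at the group level; the per-subject sweep uses 20 (the
per-subject γ/λ enter a subject-level permutation test, where null noise
averages out across 86 subjects).

γ/λ are computed at the analysis sparsity only by default: rewiring every
subject × grid-point × null would add ~10⁵ rewired graphs per run without
changing any downstream inference, which uses per-subject values at the
analysis sparsity.

Betweenness is reported unnormalized (raw shortest-path counts, the scale
on which nodal group differences in the tens–hundreds are interpretable);
normalization by (N−1)(N−2)/2 is a flag.

## Modularity

Q is maximized by 1000 independently seeded restarts, each a Louvain run
followed by refinement to a fixed point of single-node best moves
(including moves into a fresh singleton module) and pairwise module
merges. All restart scores are kept ("ranked solutions"); ties at the
maximum break toward fewer modules, then the lexicographically smallest
canonical assignment, so the result is a deterministic function of the
seed. On every random graph with ≤ 8 nodes tested, this reaches the
exhaustive-enumeration optimum (Bell-number loop, shipped as a test
oracle); planted three-block 90-node networks are recovered with adjusted
Rand ≥ 0.9. In the pipeline, modularity is applied to the significant NBS
component's subgraph — the dysregulated subnetwork — not to the full
network.

## Inference

All group tests are subject-relabeling permutation tests with the
plus-one-corrected two-sided p = (#{|null| ≥ |obs|} + 1)/(n_perm + 1),
which is never exactly 0. Functional metrics are per-subject values, so
permutation is cheap (default 5000 permutations). Structural metrics
exist only per group, so each permutation **rebuilds** both group
covariance matrices, re-thresholds at the same sparsity, and recomputes
the metric (default 1000 permutations); the nodal variant records the
whole 90-region betweenness difference vector per rebuild, so one rebuild
serves all regions.

NBS: edge-wise two-sample pooled-variance t on Fisher-z-transformed
correlations (variance stabilization), a primary threshold (default
edge-level p < 0.005, configurable), connected components of the
suprathreshold graph sized by **edge count**, and component p-values
against the permutation null of the *maximal* component size — family-wise
control at the component level. Degenerate zero-variance edges get a
guarded t (0 for zero mean difference, ±∞ otherwise) and are logged.

Two properties of NBS discovered in validation and worth knowing:

* with 86 subjects, an edge threshold of p = 0.005 admits ~20 null edges
  into the suprathreshold graph; these attach to any true component, so
  *edge-exact* recovery of a planted component requires a stricter
  primary threshold. Recovery analyses here use p = 10⁻³, at which a
  planted 10-edge component (Δr = 0.2) is recovered with Jaccard
  0.91–1.0 and component p ≈ 0.002–0.017;
* per-subject correlation matrices have globally dependent edges (finite
  effective df after band-passing), so permutation nulls contain
  occasional large components. The test remains exactly valid under the
  null (exchangeability), as the calibration runs confirm, but component
  sizes should not be over-interpreted at lenient thresholds.

FDR is Benjamini–Hochberg (via statsmodels), applied across the 90
regions for nodal tests (q = 0.01) and across the sparsity grid per
metric family for global tests. Partial correlation residualizes both
variables on (intercept, control) and tests r with t on n − 3 df;
degenerate residuals (e.g. the metric *is* the control) are flagged, not
reported as numbers.

## Synthetic cohorts

The generator draws region time series from a stationary multivariate
Gaussian whose correlation matrix is block-structured: 0.5 within and 0.1
between eight ground-truth modules by default. A hemodynamic model is
deliberately absent — the analysis consumes only Pearson correlations, so
second-order structure suffices. Gray-matter volumes are drawn per
subject from the same cross-region correlation structure (mean 6.0,
SD 0.6 volume units), which gives the structural covariance networks
modular topology. Nuisance series are smoothed Gaussian processes
(tissue: σ = 10 s; motion: σ = 20 s) mixed into the ROI series at weight
0.2, so nuisance regression removes something real. Clinical covariates
are truncated normals at the cohort scale (patients: age 32.6 ± 11.1 y,
duration 14.5 ± 6.8 y, frequency 4.3 ± 2.1 /month, intensity 5.5 ± 1.6;
controls: age 33.4 ± 10.2 y with the disease fields not applicable).

The module count (8) was chosen so that, at the default within/between
correlations, every subject's functional network is fully connected at
S = 0.17 (0 disconnected of 344 simulated subjects) — mirroring the
criterion by which the analysis sparsity is chosen — while retaining
strong modular clustering. With 6 modules, ~2% of subject networks
disconnect at that sparsity.

**Injectable effects**, applied to the patient population matrix and
recorded in a `truth` ledger:

* `EdgeEffect` — add Δr to chosen edges (the planted NBS component is a
  10-edge path whose consecutive nodes lie in different modules);
* `VolumeShift` — shift patient mean volumes in chosen regions;
* `TriangleEffect` — set the three correlations of chosen triples;
* `CliqueEffect` — couple chosen regions through one latent factor
  (rank-1 covariance update, hence PSD by construction).

The clustering increment uses `CliqueEffect`, not isolated triangles, for
two geometric reasons found during design: dense cross-module correlation
bundles violate positive semi-definiteness outright (peers of bundled
nodes cannot stay at background correlation), and isolated wired
triangles *lower* mean clustering at fixed K — each one adds two
between-module edges per node, and the degree inflation outweighs the
single closed triangle. A latent clique spread across modules wires many
mutually closing triangles at once; empirically small cliques still lower
C and large ones raise it, so the effect size is calibrated, not assumed:
`calibrate_clustering_effect` scans clique sizes through the same
cleaning → correlation → threshold → clustering path as the analysis
(common random numbers across candidates) and returns the size whose
realized shift is closest to the requested multiple of the pooled
per-subject SD.

A `CovariateLink` scales each patient's effect magnitude by
1 + slope · z(duration) (clipped to [0, 2] to stay PSD-feasible), which
makes metric–duration partial correlations recoverable. Implied
correlation matrices are checked before sampling: eigenvalues below −0.1
mean the requested effects are geometrically incompatible and are
rejected with the offending eigenvalue; mild violations are repaired by
eigenvalue clipping at 10⁻⁶ with re-normalization to unit diagonal,
logged whenever triggered.

**What passing tests show — and don't.** Calibration and power results
certify the *inference machinery* under the generator's assumptions:
stationary Gaussianity, exchangeable subjects, linear nuisance
contamination, homogeneous within-group populations. Real resting-state
data violate several of these (hemodynamic autocorrelation, motion
artifacts surviving regression, site and vigilance effects, non-Gaussian
tails), so passing here does not certify performance on real cohorts —
it certifies that the statistics do what they claim when their
assumptions hold, and that planted signal of the stated size is
recovered.

## Determinism and problem sizes

Every stochastic stage draws from a child of the master seed via
`numpy.random.SeedSequence` with fixed spawn keys, so stages are
independently reproducible and full runs are byte-identical (the
determinism test compares report files byte for byte).

Validation problem sizes, chosen to bound each check's Monte-Carlo error
while keeping the suite runnable on one CPU: graph-metric oracles on the
full connected-graph atlas to N = 6; modularity oracle on 30 random
graphs to N = 8 with 1000 restarts; type-I calibration on 200 replicate
null cohorts at full study scale (43/43 × 90 × 200) with 500-permutation
tests, acceptance via the exact central 95% binomial region around
α = 0.05; clustering power over 200 replicates; NBS recovery over 5
replicates; partial-correlation recovery over 500 replicates.

## Known limitations

* Binary networks only; no weighted metric variants.
* No voxel-level processing: inputs are ROI tables by design.
* The structural permutation rebuild scheme is the only coherent option
  for group-level covariance networks, but other labs sometimes test
  covariate-adjusted volumes (age, total GM); no adjustment is applied by
  default.
* "1000 ranked solutions" for modularity is realized as 1000 optimizer
  restarts; a simulated-annealing schedule with 1000 accepted solutions
  would be an alternative reading.
* The NBS primary threshold is a genuine analysis knob: conclusions at
  p = 0.005 versus 10⁻³ can differ, as quantified above.
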