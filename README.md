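# scnkit

Lifespan mouse-brain volumetrics, Y-maze working memory, and structural
covariance network (SCN) analysis.

`scnkit` is for neuroimaging groups running cross-sectional lifespan (or
treatment) studies in rodents whose endpoint is a table of MRI-derived
regional brain volumes plus simple behavioural readouts.  Starting from
per-animal volume tables (280 fine regions with hemisphere tags, or the
reduced 32-ROI representation) and per-animal Y-maze choice sequences, it
covers:

- **Volumetrics** — hemisphere averaging, hierarchical reduction to 32 ROIs,
  and pairwise age-group contrasts from the linear model
  `V_region ~ β₀ + β₁·group + β₂·TBV`, reporting the group-indicator *t*
  (negative = the older group is smaller) with Bonferroni–Holm correction
  over the declared family.
- **Working memory** — spontaneous alternation scoring (percent of
  adjacent-trial arm switches; chance = 50%), one-way ANOVA and a joint
  Wald χ² from a binomial logistic regression of alternation counts on
  group; sample-wide brain–behaviour association via
  `logit P(alternate) = α + β·resid(V | TBV)` with the signed Wald *z* per
  region.
- **Structural covariance networks** — per group, Pearson correlations of
  TBV-residualized volumes with negative edges removed, thresholded to the
  top *d* fraction of connections for *d* = 0.05…0.40 (step 0.01); degree,
  transitivity, mean shortest-path distance, Newman–Girvan modularity *Q*,
  Walktrap communities, and Guimerà–Amaral hub cartography
  (within-community degree z-score *z_i*, participation coefficient
  `P_i = 1 − Σ_c (κ_ic/k_i)²`, provincial/connector hub labels).
- **Permutation inference** — group-label permutations of animals drive
  empirical two-tailed p-values per density (add-one rule), with a finding
  declared significant only at *p* < 0.05 for ≥ 5 consecutive densities.
- **Synthetic cohorts** — a generator with planted ground truth (group
  volume shifts, block covariance communities, trial-level behaviour
  coupling, per-group connectivity attenuation) so every stage is testable
  without raw imaging data.

## Worked example

```python
from scnkit import (CohortConfig, generate_cohort, glm_group_contrast,
                    build_covariance, threshold_at_density,
                    walktrap_communities, compare_metric)

cohort = generate_cohort(CohortConfig(seed=1))   # 10/10/9 animals, 32 ROIs

res = glm_group_contrast(cohort.volumes, "anterior cingulate area",
                         ("young", "middle"))
print(f"t = {res.t:.3f}, p = {res.p_raw:.4f}")

cov = build_covariance(cohort.volumes, "young")
net = threshold_at_density(cov, 0.20)
comm = walktrap_communities(net)
print(f"Q = {comm.modularity:.3f}, {len(set(comm.membership))} communities")

prof = compare_metric(cohort.volumes, ("young", "middle"), "modularity",
                      n_perm=500, seed=2)
print(f"significant: {prof.significant}, runs: {prof.runs}")
```

prints

```
t = -7.219, p = 0.0000
Q = 0.240, 5 communities
significant: False, runs: []
```

The anterior cingulate contrast recovers the planted maturational volume
loss (the default cohort plants a −2.19 noise-SD shift there, so a strongly
negative *t* is expected); the young network partitions into a handful of
communities at density 0.20 with modest modularity; and the maturational
modularity comparison is not flagged, since the default cohort plants no
group difference in covariance structure.

The same pipeline runs from the shell:

```bash
scnkit simulate --seed 1 --out data/
scnkit run-all --seed 1 --out results/ --n-perm 500
```

`run-all` writes contrast and association tables, per-group covariance
matrices and hub cartography, long-format density profiles with permutation
p-values, a JSON summary of significant findings (each naming its density
interval), and a manifest (config hash, seed, input hashes) that suffices to
reproduce the run bit-exactly.

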