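# Methods

This note documents the statistical models behind `scnkit`, the defaults it
ships, the design decisions taken where the protocol leaves room, and what
the synthetic-cohort tests do and do not establish about real data.

## Study design assumed

A cross-sectional lifespan design: three age groups (young, middle-aged,
old) with ~10 animals each (the default cohort uses 10/10/9, reflecting a
typical single-animal exclusion), 32 regions of interest (ROIs) obtained by
hemisphere-averaging and hierarchically reducing a 280-region
deformation-based-morphometry parcellation, and a 7-trial two-goal-arm
Y-maze session per animal.  `scnkit` starts from the volume table; image
processing is upstream.

## Volumetric contrasts

For each region and each ordered group pair (young vs middle, middle vs
old), an ordinary linear model

    V = b0 + b1 * older + b2 * TBV + e

is fit on the two groups' animals only, where `older` indicates the second
group and TBV is total brain volume in mm³.  The reported statistic is
t = b1/SE(b1) on n−3 df, two-tailed; negative t means a period-specific
decrease.  Fitting each pair separately (rather than one three-group model)
keeps each contrast's error variance local to the animals it compares.  The
implementation is the closed-form multi-response OLS; it is verified against
statsmodels OLS to 1e-8 in the tests.  Exact fits (zero residual variance)
report t = 0 when the group coefficient also vanishes rather than
propagating 0/0.

Family-wise error is controlled by the Bonferroni–Holm step-down, applied to
the declared family: the focused (a-priori) family is 6 tests (3
age-sensitive ROIs — anterior cingulate area, hippocampal formation, orbital
area — × 2 comparisons), and the brain-wide family is 32 tests per
comparison.  Holm is implemented directly (sort, multiply by m−rank, running
maximum, cap at 1) and checked against an independent brute-force version on
10,000 random vectors.

## Working memory

An alternation is a trial whose goal-arm choice differs from the previous
trial's.  The percent-alternation index divides the alternation count by the
number of scorable adjacent pairs, i.e. trials − 1 (default).  The
alternative divisor `trials` is available (`denominator_rule="trials"`), but
trials − 1 is the default because only it puts random responding at exactly
the 50% chance level for a binary sequence — the two conventions disagree
and the package resolves the conflict in favour of internal consistency
with the chance-level interpretation.  Alternation is defined against the
immediately preceding trial only (discrete-trial forced-start protocol),
not the 3-arm sliding window used in continuous Y-maze variants.

Group differences are tested twice: a one-way ANOVA on the percent scores,
and — because 7-trial proportions are discrete and non-normal — a joint
Wald χ² (df = groups − 1) for the group factor in a binomial GLM of
(alternations, misses) on group dummies.  Degenerate designs (zero
within-group variance; separation) are flagged rather than reported as
numbers.

Brain–behaviour association pools all animals: for each region, a binomial
GLM of per-animal alternation counts on the region's TBV-residualized
volume; the reported statistic is the signed Wald z for the slope (the sign
convention matches the slope).  A χ²₁ would be z²; the signed z is exposed
because the direction of the association is scientifically meaningful.  The
binomial likelihood is the default; a quasi-binomial variant (Pearson-X²
scale) is available via `dispersion=True` since trial-level dependence could
overdisperse the counts.  All-zero or all-perfect outcomes and non-converged
fits are flagged `converged=False` with NaN p and are excluded from the Holm
family.

## Structural covariance networks

Within each group, regional volumes are residualized on TBV and Pearson
correlations are computed across animals; negative correlations are set to
zero (unsigned networks), the diagonal is cleared.  Networks are built at
densities d = 0.05 … 0.40 in steps of 0.01 by keeping the k = round(d·496)
strongest positive correlations as unweighted edges (n = 32 → 496 possible
pairs; half-up rounding — the rounding rule is stated because no convention
is universal, and it makes edge counts bit-reproducible).  Ties at the
threshold are broken by the lexicographic order of the sorted region-name
pair: ties have measure zero for continuous data but arise in tests, and a
deterministic order keeps results platform-independent.  The ranked edge
list is shared across the sweep, so the edge set at density d is nested in
the edge set at any d′ > d.  If fewer positive correlations exist than
requested, the network is built from all of them and the shortfall is
logged.

Graph measures (via python-igraph, each verified against brute-force
references on random graphs — exact for integers, 1e-12 for reals):

- degree: per-node edge count;
- transitivity: 3·triangles / connected triples (0 when no triples);
- mean distance: average shortest-path length over reachable pairs;
  unreachable pairs are excluded rather than infinite, keeping the
  statistic finite on sparse networks (the behaviour of the common graph
  libraries' default); a network with no edges reports a missing value;
- modularity: Newman–Girvan Q;
- communities: Walktrap (random-walk agglomeration, walk length 4 — the
  algorithm's common default, exposed as `steps`), cut at maximum
  modularity; isolated nodes are singleton communities; an edgeless network
  yields all singletons with Q = 0 by convention.

Hub cartography follows the within-community degree z-score / participation
coefficient scheme: z_i standardizes a node's within-community degree over
its community (population SD; z = 0 for degenerate communities), and
P_i = 1 − Σ_c (κ_ic/k_i)².  Since only qualitative "high/low" guidance
exists for hub thresholds, the defaults z ≥ 1.0 and P ≥ 0.30 are named,
config-exposed constants reported in the output; the "most prominent"
provincial (highest z) and connector (highest P) hub per community are also
reported, so both fixed-threshold and top-ranking readings are available.

## Permutation inference

The exchangeable unit under "no group difference" is the animal: each of
n_perm draws shuffles group labels within the pooled two-group sample,
preserving group sizes, and the entire pipeline (correlate → remove
negatives → threshold → measure) is recomputed.  TBV residualization is fit
once on the pooled sample and reused across relabelings — the adjustment is
label-free, so refitting per draw would only add noise.  One relabeling
drives the full density sweep, preserving the cross-density dependence of
the profiles.  For modularity the relabeled network is re-partitioned by
Walktrap on every draw: the statistic is "maximum-modularity Q of the
network", partition included.

Per density, the empirical two-tailed p is the add-one rule on absolute
differences, p = (1 + #{|null| ≥ |obs|}) / (1 + N); it can never be 0, and
two-tailedness via |diff| (rather than doubling a tail) is well defined for
discrete nulls.  Densities where a metric is undefined (e.g. edgeless
networks) are dropped from the null with the denominator reduced; an
undefined observed value is non-significant at that density.  A difference
is declared significant when p < α (0.05) at ≥ 5 consecutive densities;
reported findings carry their density interval.

Default permutation tiers follow the protocol: 5,000 draws for the focused
degree analyses and the global measures, 1,000 for the brain-wide degree
sweep.  Tests and the bundled demo (`scripts/acceptance.py`) run 100–500
draws — the package's chosen demo problem size; every inferential default
remains available through the config.

### Calibration facts (computed by the test suite)

On null cohorts (n = 10/group, no planted structure, 500 replicates,
n_perm = 200):

- The per-density permutation test is valid but conservative for degree:
  rejection ≈ 0.031 at α = 0.05.  Two mechanisms: the add-one rule caps the
  attainable rate at floor(α(N+1))/(N+1) ≈ 0.0497, and the integer
  degree-difference statistic is heavily tied at this sample size.  With a
  continuous statistic (transitivity) the measured rate is 0.050.
- The consecutive-threshold rule does **not** control the per-profile
  family-wise error at α: measured ≈ 0.064–0.070 for degree profiles (and
  ≈ 0.10 for transitivity in a smaller pilot), versus ≈ 0.21 for flagging
  any single density.  The 36 density thresholds are strongly but not
  perfectly dependent, so a null profile gets several semi-independent
  chances at a 5-run.  The rule is therefore a substantial — but not
  α-level — familywise tightening, and findings that barely clear it
  warrant caution.  This is a property of the significance convention
  itself, not of this implementation.

## Synthetic cohorts

The generator draws, per animal: TBV ~ N(450, 15²) mm³ (C57BL/6-scale);
region volumes V_j = f_j·TBV + (δ_gj + ε_j)·σ, with fixed fractions f_j
spanning 0.010–0.046 (so regions range ~4.5–21 mm³ and TBV is a genuine
confounder that the covariate adjustment must remove), planted standardized
group shifts δ_gj accumulated along the group order, noise SD σ = 0.5 mm³,
and ε correlated by a block-constant matrix (within-community r = 0.5,
between = 0.15 by default, over four anatomically coherent communities:
isocortex, subcortical grey, brainstem+cerebellum, white matter).  A
per-group, per-region attenuation factor can scale a region's correlations
to plant connectivity differences.  Behaviour is simulated trial by trial:
the first arm choice is random; each later trial alternates with
probability logistic(Σ_j β_j·z_j) where z_j is the standardized
TBV-residual of region j — the zero intercept makes an uncoupled cohort
alternate at exactly chance.

Default planted effects emulate the characteristic lifespan pattern this
pipeline targets: maturational isocortical volume loss with brainstem,
cerebellar-nuclei and white-matter gain (18 regions, |δ| 1.2–3.1), a
sparser aging pattern (6 regions), and a weak behaviour coupling through
the anterior cingulate area (+0.35) and hippocampal formation (−0.33).
Shift magnitudes were chosen so that the expected group-contrast t at
n = 10/group (t ≈ δ·√(n/2)) lies in the 2.6–6.8 range typical of reported
rodent lifespan effects; variance components are otherwise free parameters,
not calibrated to any dataset.

What passing the synthetic tests shows: the estimators recover exactly the
structure the generator plants, at the planted scale, with calibrated
type-I error under Gaussian block-correlated noise.  What it does not show:
robustness to non-Gaussian volume distributions, segmentation error,
spatially heterogeneous variance, litter/batch structure, or behaviour
dynamics beyond a first-order alternation process.

## Numerical and degenerate-input conventions

- CSV round-trips use `float_precision="round_trip"` so written cohorts
  re-read bit-exactly.
- Exact-fit contrasts report t = 0 (coefficient also ~0) instead of 0/0.
- Zero-variance regions inside a group abort covariance construction with
  the region named.
- Pooled samples of fewer than 8 animals are rejected for permutation
  comparisons (correlations too unstable).
- All randomness flows from named substreams of a single seed
  (`SeedSequence([seed, crc32(tag)])`), making every pipeline output —
  including permutation p-values — byte-identical across reruns.

## Known limitations

- The run rule's familywise error exceeds α under the null (see
  calibration facts above).
- Pooled-sample TBV residualization injects a small amount of
  slope-estimation noise that is independent across groups; at realistic
  correlation levels this is negligible, but with near-deterministic
  planted blocks it measurably lowers the attenuated node's intact-group
  correlations (visible only in extreme synthetic settings).
- Weighted or signed network variants, small-world/rich-club statistics,
  and longitudinal models are out of scope.
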