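# Methods

## Overview

`ageflow` treats the gene regulatory network (GRN) as a closed linear
system and age-associated DNA-methylation changes as its external inputs.
The pipeline has six stages: marker calling, DMP–TF linking, subnetwork
reconstruction, signal flow analysis, reverse-target ranking, and a
perturbagen screen. This note records the model, the parameters that
matter, the synthetic-data generator, and the design choices made where
the design was genuinely open.

## Signal flow model

Node activities satisfy `x = αWx + (1−α)b` with
`W[i,j] = s(j→i)/d_in(i)`, `s ∈ {−1,+1}` the edge mode of action, and
`α ∈ [0,1)` the damping that balances upstream flow against basal
activity (default 0.5). Choices worth stating:

- **Weight normalization.** Dividing each incoming edge by the target's
  in-degree shares influence equally among regulators and guarantees
  `‖αW‖∞ ≤ α < 1`, hence a unique fixed point for every α < 1 and every
  network, with no per-network tuning. Other normalizations (e.g. column
  or spectral) would also converge but change relative edge influence;
  in-degree sharing is the simplest choice consistent with treating all
  regulators of a gene symmetrically.
- **Solving.** The direct solve `x = (1−α)(I−αW)⁻¹b` is exact; Jacobi
  iteration from `x₀ = b` is kept as an independent oracle. The
  contraction bound gives geometric error decay at rate α, so both agree
  to solver precision (tested to 1e-8 over 1,000 random networks).
- **Inputs enter through `b`**, not as clamped states, matching the
  fixed-point form in which α balances upstream flow and basal activity.
- **Input construction.** Per sample and per representative DMP:
  `z = (β − mean)/sd` across the cohort, `v = z / max_samples|z|`
  (max-abs scaling, a monotone odd map attaining the stated [−1,1]
  range; `tanh(z/2)` would also qualify but compresses extremes), and
  `b_TF = v · sign(r_link)`. If two representative links ever target the
  same TF, their values are averaged.
- **Contributions.** Linearity makes the per-input decomposition exact:
  solving with `b` masked to one input at a time yields columns that sum
  to the full solution (checked to 1e-10).

## Marker statistics

- **DMPs**: Pearson correlation of beta with age, two-sided P from the
  exact t transform, raw P < 0.05, *no* multiple-testing correction —
  the position count dwarfs the cohort size and the calls feed a
  downstream network filter rather than standing alone. Zero-variance
  positions are excluded as untestable rather than assigned P = 1
  (a correlation there is undefined, not null).
- **Sex adjustment**: per position, each sex group's mean is shifted to
  the pooled mean, then clipped to [0,1]. This is a deliberate,
  dependency-free location-only two-level batch adjustment: with sex as
  the only batch variable, matching group means is the first-order
  correction; group variances are left untouched.
- **DEGs**: per-gene negative-binomial GLM (log link), design
  `intercept + age + sex`, offset = log median-of-ratios size factor,
  method-of-moments NB dispersion floored at 1e-8, Wald test on the age
  coefficient, BH adjustment. The per-year coefficient is reported in
  log2 units. This intentionally reproduces the *design* of a DESeq2-style
  analysis (age continuous, sex covariate, BH) without shrinkage
  estimators; a gene whose NB fit fails falls back to a Gaussian fit on
  log2(normalized+1) with a logged flag.
- **DMP–TF links**: candidate pairs where the CpG is within 5,000 bp
  (inclusive) of the TF's TSS or gene body; distance to the half-open
  body interval is measured to the nearest contained base. Correlation
  uses log2 size-factor-normalized expression (the natural scale for a
  count covariate against a bounded beta value). Per TF, the
  smallest-p link is the representative; p ties break by larger |r|,
  then lexicographic DMP id, so representative selection is total and
  deterministic.
- **Overlap enrichment**: upper-tail hypergeometric P computed in log
  space (`hypergeom.logsf`), robust far below double underflow.

## Network reconstruction

Kept nodes are the DMP-linked input TFs, the output DEGs, and every node
both reachable from an input and co-reachable to an output; kept edges
must connect a reachable source to a co-reachable target; self-loops are
removed (the weight normalization assumes no self-regulation). Network
outputs are *non-TF* DEGs: a TF that is itself differentially expressed
participates as a regulator inside the network rather than as a terminal
endpoint, which keeps it eligible for the intermediate-node perturbation
scan. The lower-5% expression-variance tail (quantile over the candidate
node set, strict inequality so an all-tied set loses nothing) is removed
before edge testing.

Each surviving edge TF→g is tested twice: plain Pearson and partial
correlation controlling for g's other retained regulators (the computable
reading of "exclude expression changes regulated by other TFs"). Both
must have P < 0.05; the sign is that of the partial correlation. When the
control count approaches the sample count, the n−5 controls with largest
marginal |r| to the target are kept (df stays positive); collinear
controls are pruned by pivoted-QR rank detection. Filter order — variance
filter, then edge significance, then path re-enforcement — is iterated to
a fixed point; the order itself was an open choice and is exposed by
the module boundaries.

## Target ranking and screen

Per sample, DMP inputs are propagated and each output DEG's activity is
correlated with age; outputs are classed consistent / inconsistent /
nonsignificant at P < 0.05 against the sign of their measured per-year
trend. Only consistent ("validated") DEGs are scored. The ±1 scan
solves one system per intermediate node and sign (antisymmetry makes the
−1 solve the negation of the +1 solve); a DEG counts as reversed when its
activity opposes its aging direction with |x| > ε = 1e-9 (floating-point
hygiene — reversal should not hinge on numerically-zero activity).
"Top 5%" is 5% of intermediate *nodes* (best sign per node),
floored with a minimum of one candidate: with 167 intermediates this
yields exactly 8 candidates. Ties break by total reversed activity mass,
then node id.

The drug screen percentile-transforms each condition's modZ vector
within the condition (average ranks for ties, `100·(rank−0.5)/G`), calls
genes up/down at the inclusive tertile boundaries, counts signature DEGs
called opposite to their aging direction, keeps each drug's best
dose/time condition (ties by summed distance of reversed genes from the
50th percentile, then label), and flags drugs reversing strictly more
than half of the screenable DEGs. Percentiles are computed per condition
rather than per gene across conditions: the transform is applied to
profile vectors, and per-condition ranking keeps conditions with
different dynamic ranges comparable.

## Synthetic data generator

The generator emulates a blood aging cohort: ages uniform on 20–74 years,
sexes Bernoulli(1/2), smokers only among males (about a third of them,
mirroring a small male-only smoker subgroup; smoking is simulated but not
adjusted for, with a toggle).

- **Methylation**: `β = invlogit(intercept + slope·(age−47) + sex_offset
  + N(0, 0.3))` on the logit scale, which keeps β in (0,1) without a
  two-parameter beta regression. The configured DMP slope is in
  beta-units/year (default 0.004) and maps to the logit scale by the
  canonical factor 4 (the inverse-logit derivative at ½). Planted DMPs
  sit within 5 kb of their input TF; null CpGs are intergenic, >5 kb from
  every gene.
- **Network**: only TFs have out-edges. Input TFs feed a chain of on-path
  intermediate TFs (preferential attachment in scale-free mode) which
  feed the output DEGs; the other half of the intermediates are off-path
  regulators driving the background genes, so background expression
  carries no aging signal and the genome-wide DEG rate stays realistic.
  Edge signs are −1 with probability `frac_negative_edges` (0.3). One
  on-path intermediate is planted as a **reverser**: fed directly by an
  input TF (so no scanned node sits upstream of it) with direct edges
  into ~80% of outputs whose signs are set against the propagated aging
  direction, iterated to a fixed point because flipping them feeds back
  into that direction, and verified by the solver (+1 at the reverser
  must reverse ≥60% of planted DEGs; otherwise the topology is
  regenerated). Outputs whose parent trends cancel exactly have one
  parent edge dropped so every planted DEG has a definite direction.
- **Expression**: generated through the *same* damped linear rule the
  inference assumes, which makes parameter recovery a well-posed test of
  the pipeline rather than of model mismatch (`model_mismatch_sd` adds
  log-scale noise breaking the rule for robustness checks). Every TF node
  receives independent basal-activity noise (sd 1.0) in `b`; without it,
  all propagated signal would live in the low-dimensional input subspace
  and edge modes of action would not be identifiable from partial
  correlations. Input TFs add `2 · c · z` of their driving DMP (coupling
  sign `c` random; the ×2 gain against unit basal noise puts the realized
  methylation–expression correlation near the 0.8 target). Counts are
  negative-binomial (dispersion 0.05) around
  `2^(baseline + 2·x + lfc·(age−47) + sex_offset)` times a lognormal
  library factor; planted DEGs get lfc = 0.02 log2/year signed by their
  propagated aging direction, so DAC consistency is attainable by
  construction.
- **Perturbation profiles**: 20 drugs × 2–4 dose/time conditions of
  N(0,1) modZ noise over all genes; each planted reverser drug (default
  one) has exactly one condition in which every planted DEG's modZ
  opposes its aging direction with |modZ| in 3–6.

What the generator does **not** emulate: linkage among neighboring CpGs,
batch effects beyond sex, cell-type composition, read-level noise, and
drug effects on non-signature genes. Passing recovery tests therefore
demonstrates that the pipeline inverts its own generative assumptions at
realistic noise levels — not that it is robust to the full texture of
real blood data.

## Reference problem sizes

Reference conditions: 100 samples, 1,500 CpGs (10% planted DMPs), 300
genes (40 TFs, 10 DMP-coupled inputs, 45 planted DEGs), α = 0.5.
Recovery and calibration summaries use 20 replicate studies at these
conditions; null calibrations use ≥1,000 features; solver sweeps use
1,000 random networks of up to 100 nodes. The full test suite runs in
about a minute on one CPU; `scripts/acceptance.py` likewise.

## Numerical notes and limitations

- Pearson P values come from the exact t transform; |r| = 1 maps to P = 0.
- The linear solve is dense (`numpy.linalg.solve`); networks of a few
  thousand nodes remain trivial, but very large canonical GRNs should be
  subnetwork-extracted first (the pipeline always does).
- Duplicate parallel edges in canonical GRNs keep the first occurrence,
  logged — silent collapse would hide data issues.
- The DAC classification depends only on signs, not magnitudes, so it is
  invariant to uniform rescaling of inputs; conversely it cannot
  distinguish strong from marginal regulation.
- With small gene panels, median-of-ratios size factors absorb shared
  signal; the normalization assumes most genes are not age-responsive,
  as in genome-scale data.
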