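# Methods

## Dominant-marker model

A dominant marker (ISSR band) is scored per individual as presence (1)
or absence (0). Under a biallelic locus with Hardy–Weinberg equilibrium,
absence is the recessive null homozygote, so the null-allele frequency is
estimated from the band phenotype frequency B as q = √(1 − B) and the
band-presence allele as p = 1 − q (the POPGENE dominant-data default).
The Lynch–Milligan estimator, q = √x / (1 − Var(x)/(8x²)) with x = 1 − B
and Var(x) = x(1 − x)/N, is available behind `method="lynch_milligan"`;
the square-root form is the default because it is what the classical
software applies and the two differ only at small sample sizes. Estimates
are clamped to [0, 1]; missing calls are not supported — any non-{0,1}
cell is a hard error.

### Index suite

Per locus: Na = 2 if the locus is polymorphic in the unit, else 1;
Ne = 1/(p² + q²); h = 1 − p² − q²; I = −p ln p − q ln q (natural log,
0 ln 0 := 0). A locus is polymorphic under the default `"any"` criterion
when both phenotypes occur in the unit (0 < B < 1); the `"freq95"`
criterion instead requires minor-allele frequency > 5%. The default is
`"any"` because it makes Na = 1 + P/100 an exact identity, which the
published per-population table satisfies row by row (a 95% criterion
would break it). Unit summaries average over **all** loci, monomorphic
included, and report the across-locus sample SD (denominator L − 1);
both conventions are required to reproduce published magnitudes.
P = 100·n/L where L is the total locus count.

### Differentiation and gene flow

Per locus, Ht = 1 − p̄² − q̄² with p̄ the **unweighted** mean of unit
allele frequencies, and Hs the unweighted mean of unit gene diversities.
Ht and Hs are averaged over loci first, then Gst = (H̄t − H̄s)/H̄t — the
locus-mean convention avoids 0/0 at loci monomorphic everywhere and
matches the classical implementation. Gene flow uses the island-model
equilibrium Nm = (1 − Gst)/(2 Gst); the inverse Gst = 1/(2 Nm + 1) is
exposed for round-trip checks. Gst is clamped at 0 from below (float
noise when units coincide), in which case the pooled summary reports
Nm = ∞; `gene_flow` itself rejects Gst ≤ 0. Species-level summaries pool
all individuals, ignoring population labels.

## AMOVA

The distance between two 0/1 profiles is the squared Euclidean distance,
i.e. the count of differing loci. Sums of squares per stratum follow the
classical decomposition (sum of pairwise squared distances within a
stratum divided by stratum size); variance components equate mean
squares to expectations with the standard unequal-sample-size
coefficients (n₀ for one level; n, n′, n″ for two levels), and
Φ-statistics are the usual component ratios. Degrees of freedom are
individual-based (total = N − 1). Negative components are truncated to
zero for the percentage column but kept signed in `raw_components`.
Permutation schemes: individuals among populations (Φ_ST), whole
populations among groups (Φ_CT), individuals among populations within
their group (Φ_SC); p = (1 + #{perm ≥ obs})/(B + 1) with B = 999 by
default, so the smallest attainable p is 1/(B + 1).

Threshold classification assigns a population whose value falls exactly
on a break to the **lower** class; tertile classification splits by rank
into sizes as equal as possible (20 → 7/7/6) with ties broken by input
order.

## Climate indices

From 12 monthly mean temperatures tᵢ (°C) and rainfalls rᵢ (mm):
AMT = mean(t); ART = max(t) − min(t) of the monthly means (not absolute
extremes); WI = Σ(tᵢ − 5) over months with tᵢ > 5; CI = Σ(5 − tᵢ) over
months with tᵢ < 5 (a month at exactly 5 °C contributes to neither);
AP = Σr; S = Σ 0.18 rₜ/1.045^Tₜ over all 12 months. The 1.045 term is
exponentiation in the monthly mean temperature — the standard
hydrothermal/aridity form, under which S falls as a rainy month warms; a
product reading would do the opposite. Sub-zero months simply contribute
factors 1.045^T > 1. Rainfall is taken in mm, consistent with AP.

## Redundancy analysis

Responses (default: the five indices P, Na, Ne, h, I; the polymorphic
count n is excluded as a rescaled duplicate of P) and explanatory
variables are log(x+1)-transformed, centred, and by default standardized
(sample SD, ddof = 1) — the indices and environment variables live on
very different scales. Both standardization switches are exposed.

The fit regresses each centred response column on the explanatory column
space via an orthonormal basis (SVD); the constrained eigenvalues are
the squared singular values of the fitted matrix over (n − 1), and the
explained fraction tr(Ŷ′Ŷ)/tr(Y′Y) is the multivariate redundancy
statistic. Collinear explanatory columns are reduced to a maximal
independent subset (greedy, in column order) with a logged warning.
The fit requires n > rank(X); with n − 1 independent constraints the
explained fraction is exactly 1. Tests verify the fit against the
explicit projection oracle H = X(X′X)⁻¹X′.

Permutation tests use pseudo-F = (SS_fit/m)/(SS_res/(n − 1 − m)). The
whole-model test permutes response rows freely; a single-term test
conditions on the remaining variables by permuting reduced-model
residuals. Forward selection adds, at each step, the candidate with the
largest additional explained variance (ties broken by column order, so
one of two duplicated columns is ever selected), tests the addition by
reduced-model permutation, and stops when the best candidate's p exceeds
α = 0.05. Marginal contributions are single-variable RDA fractions.
The detrended-correspondence screen used historically to choose between
linear and unimodal ordination is noted in the run log but not
implemented; the response here is five smooth indices over 20 sites,
squarely in the linear regime.

### The published variance decompositions

The packaged climate table is **region-level**: five distinct rows
inherited by the 20 populations. Any explanatory matrix built from it is
constant within regions, so its explainable variance is capped by the
between-region share of the response variance — about 44% of the
standardized index variance (≈51% unstandardized), with at most four
independent climate columns (the package logs the two collinear drops).
The soil table is population-level and caps near 62–72% depending on
standardization. The published decompositions (78.4% climate, 88.6%
soil, and the corresponding axis-1 and single-variable figures) exceed
these ceilings under every documented preprocessing combination, which
indicates they were computed from per-population environmental data that
the printed tables do not carry. The package therefore reports the
honest recomputed values from the printed tables; the qualitative
published findings — WI carries the largest climate contribution and is
the only climate variable to pass forward selection, SOP likewise for
soil — are reproduced exactly.

## Synthetic generators

`simulate_dominant_markers` draws, per locus, an ancestral band-allele
frequency p₀ ~ U(0.1, 0.9) (bounds configurable; the interior default
avoids quasi-monomorphic loci dominating summaries), then population
frequencies from the Balding–Nichols beta with parameters
p₀(1 − F)/F and (1 − p₀)(1 − F)/F — a single interpretable F_ST dial;
F = 0 short-circuits to pₖ = p₀ exactly. Diploid genotypes follow
Hardy–Weinberg and collapse to band presence with probability
1 − (1 − p)², assuming complete dominance; an optional per-cell flip
error (default 0) stress-tests scoring robustness. Defaults mirror the
study design: 20 populations × 13 individuals, 288 loci, F = 0.11 (the
scale of the study's overall Φ_ST). What the generator does **not**
emulate: linkage, isolation-by-distance/spatial structure, selection,
primer-specific band-size collision, or missing calls — so passing
recovery tests demonstrate estimator correctness under the island model,
not robustness to those features of real ISSR data.

`simulate_env_linked_diversity` draws iid standard-normal environment
and sets each response column to x·b + e with coefficient norm √R² and
noise SD √(1 − R²), so the population redundancy equals the configured
R² exactly; finite-n fits overfit by roughly rank(X)/(n − 1) under the
null, which the calibration tests check. `simulate_monthly_climate`
builds a July-peaked sinusoid for temperature (site mean in the
temperate 3–7 °C band by default, amplitude ~15–19 °C matching
continental annual ranges of ~35 °C) and splits an annual rainfall total
(350–500 mm default) over months with summer-heavy exponential weights.
All generators are deterministic given their seed.

## Problem sizes in the test suite

The suite favours many small instances: oracle checks run at n ≤ 20
individuals or sites; null calibrations use 40–200 replicates with 99
permutations; monotone-recovery simulations use 8 populations × 10
individuals × 150 loci over 20 replicate pairs. These sizes give stable
pass/fail behaviour at fixed seeds while keeping the full suite in the
seconds range. The analysis scripts run the study-scale design
(260 × 288) with 999 permutations throughout.

## Known limitations

- Missing marker calls are rejected rather than imputed.
- No codominant estimators, bootstrap CIs, pairwise-population Φ_ST
  matrix, three-plus-level AMOVA, partial RDA, or CCA.
- The AMOVA permutation engine recomputes stratum sums per permutation
  on the full distance matrix; fine at study scale, unoptimized beyond
  a few thousand individuals.
- Species-level pooled Na printed in the source table (1.9931) is not an
  output of any convention implemented here (pooled "any" polymorphism
  gives 1 + P/100 = 1.9340 on the printed species P); the convention
  behind the printed value is unknown and it is not used as a check.
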