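# Methods

## The hemizygous burden model

In a monosomy-X (45,X) sample every X-chromosome locus is single-copy,
so carrier status for a variant is a Bernoulli event with probability
equal to the population allele frequency — there are no heterozygous or
homozygous states to model. For a clinical condition the analysis set
splits into n₁ with-condition and n₂ without-condition samples (samples
with unknown status are excluded, never imputed), and each unit — a gene
(any qualifying variant, unique individuals) or a single variant —
yields the 2×2 table (a, n₁−a; c, n₂−c).

Inference is exact and conditional on both margins:

- **Fisher two-sided p** uses the point-probability rule: the sum of
  hypergeometric point probabilities not exceeding the observed one,
  with relative tolerance 1 + 10⁻⁷ on the comparison. This is the
  convention of the mainstream statistical environments; mid-p or
  tail-doubling conventions give different numbers, which matters when
  comparing to published values. A zero row or column margin makes the
  distribution degenerate and returns p = 1.
- **Odds ratio** is the conditional MLE: the root ψ̂ of E_ψ[A] = a under
  Fisher's noncentral hypergeometric likelihood, solved by bracketed
  root-finding on log ψ (log-space weights for numerical stability;
  xtol 10⁻¹²). Support-boundary counts give 0 or +∞. The 95% CI inverts
  one-sided exact tests at 2.5% per side; one-sided intervals at
  boundaries. Degenerate margins: undefined (NaN).
- **Orientation.** The OR is always oriented carriers-with vs
  carriers-without, so sign(Δ) and sign(log OR) agree. Published
  per-gene tables occasionally print the reciprocal orientation for
  protective-direction genes; the orientation here is deliberately
  uniform.
- **Multiplicity**: Bonferroni with m = number of units having at least
  one qualifying carrier across both groups for that condition. m is
  computed from the data per condition rather than fixed, since the
  exact historical m is not recoverable; adjusted p-values therefore
  depend mildly on the generated or supplied cohort.
- **Effect threshold**: |Δ| must strictly exceed 0.35 to be flagged.

The common-variant window [0.1, 0.9] on population AF is inclusive at
both ends (configurable); records with no population AF cannot satisfy
the criterion and are dropped with a logged count.

The pseudoautosomal extension uses the same operations with GRCh38 PAR
coordinates (PAR1 X:10,001–2,781,479; PAR2 X:155,701,383–156,030,895,
shipped as editable constants) and a multi-karyotype analysis set in
which any alt call marks a carrier.

## Filtering

The somatic-mosaic window — depth ≥ 40×, VAF ∈ [0.05, 0.25], both VAF
bounds inclusive and the depth bound an "at least" — balances
sensitivity for genuine low-fraction changes against noise below and
heterozygous germline calls above. The standard pipeline's criteria are
exposed entirely as configuration (quality ≥ 20, depth ≥ 10,
VAF ≥ 0.25 as conservative defaults; an optional somatic quality floor
is off by default). Both filters are pure row predicates: idempotent,
order-preserving, and monotone in every threshold.

## Group comparisons

Variant-count comparisons across karyotype groups use Kruskal–Wallis
with midrank tie correction (p from χ² with k−1 df); all-identical
inputs return the degenerate p = 1. Pairwise follow-ups are Dunn-style
rank contrasts with Bonferroni adjustment — a deliberate choice where
the published analysis does not specify its post-hoc method. The paired
comparison of historical karyotype-derived versus array-derived
mosaicism percentages is the two-sided Wilcoxon signed-rank test, zeros
dropped, exact null distribution for ≤ 25 untied pairs and the
tie-corrected normal approximation above.

## Mosaic-fraction estimation

The two-cell-line model gives BAF = ((1−f)a₁ + f·a₂)/((1−f)c₁ + f·c₂)
and LRR = log₂(((1−f)c₁ + f·c₂)/2). The BAF estimator excludes
homozygous markers (BAF < 0.05 or > 0.95, configurable), takes the
median of each residual band side of 0.5, uses the median distance b of
the band centers from the nearer extreme, and inverts the informative
branch (a₁=0, a₂=1): f = b·c₁/(1 − b(c₂−c₁)) — b/(1−b) for the ring
preset (copy 1 vs 2), b/(1−2b) for isochromosome Xq (1 vs 3). Exact
band clustering of the original cytogenetic pipeline is not published,
so this detection rule is this package's own and is validated by
forward simulation: with 500 markers and BAF noise sd 0.03 the
estimator recovers f ∈ {0.1,…,0.9} within ±0.02 (tolerance ±0.03 in
the tests); the LRR route with noise sd 0.15 recovers within ±0.05.
Fewer than 10 markers in the heterozygous window is reported as "no
band" (f̂ = 0), and the combined method then falls back to LRR. Median
statistics make both routes robust to the few homozygous markers whose
noise leaks past the exclusion threshold.

## Power

The screen's design point is a carrier-proportion difference of 0.35.
Power uses the pooled-variance normal approximation
Φ((|Δ|−z·se₀)/se₁) + Φ((−|Δ|−z·se₀)/se₁); at Δ=0 this equals α
exactly. The approximation sits within 0.015 of a 50,000-replicate
Fisher-exact Monte-Carlo at the diabetes group sizes (25/24,
baseline 0.3, α=0.05: power ≈ 0.70); the analytic route is used for
speed and cross-checked against both the Monte-Carlo and an independent
library implementation in the tests. The exact test's discreteness
makes true power slightly lower than the approximation — acceptable for
a design-stage screen.

## The synthetic cohort

The generator reproduces the study structure exactly where it is known:
seven karyotype groups of sizes 75/20/5/34/23/101/11; within the
monosomy group, fixed with/without counts per condition (diabetes 25/24,
obesity 19/53, autoimmunity 24/28, hypothyroidism 32/43, hypertension
16/36, CCA 17/35, hearing loss 14/33 — remainder unknown), assigned by
seeded permutation so the analysis subgroup sizes are exact; other
groups draw status at the matching prevalence and known-fraction. 650 X
genes (24 of them pseudoautosomal) carry common variants with AF
uniform on (0.05, 0.95) so the 0.1–0.9 window is exercised on both
sides; per-sample X carrier probability is 1−(1−AF)^κ with κ the
X-dosage multiplier (1 for 45,X and 46,XY; 1.2 ring; 1.4 complex;
1.7 isochromosome; 2 for 46,XX and POI), so X variant counts scale with
X material. Autosomal genes use diploid Hardy–Weinberg genotypes.
Germline hemizygous VAF sits near 1 (het ≈ 0.5, hom-alt ≈ 1 for
diploid); somatic mosaic calls are generated as *separate* records at
offset positions with VAF in (0.02, 0.3) and no population AF — they
are new mutations, not degraded germline calls, so they feed the
somatic pipeline without thinning germline carriers. Depth is negative
binomial (mean 60, dispersion 6), putting mass on both sides of the 40×
somatic floor. All randomness derives from one seed via fixed
SeedSequence spawns; identical configs produce byte-identical outputs.

**Planted signals as positive controls.** A planted (gene, condition,
Δ) assigns the gene a single common variant and gene-level carrier
probability `baseline` (default 0.5) in unaffected samples and
`baseline+Δ` in affected ones. Two defaults are deliberate calibration
choices: the 0.5 baseline is the minimum-variance feasible operating
point for a +0.45 shift, and the per-gene density of 5 common variants
concentrates null gene-level carrier rates near saturation, bounding
the null spread of gene-level effect sizes (max |Δ| ≈ 0.33 over 649
genes at the hypertension group sizes). Under these conditions a
planted Δ = 0.45 is recovered as the top-|Δ| hit in ≈ 82–84% of
simulated screens, so recovery failures indicate implementation defects
rather than simulation noise; with a sparser variant panel the null
background alone reaches |Δ| ≈ 0.45 and the positive control becomes
uninformative. The recovery margin over the 80% validation bar is
intentionally thin — the planted effect's own sampling noise
(sd ≈ 0.11 at n=16/36) is irreducible at the study's group sizes.

**What the generator does not model:** linkage disequilibrium, a
realistic site-frequency spectrum, sequence context, batch effects,
relatedness, or phenotype misclassification. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability
of planted structure, not performance on real exomes, where LD between
common X variants would correlate gene-level tests and inflate the
effective null spread.

## Problem sizes and numerical choices

Simulation studies use the monosomy-only reduced configuration (75
samples, 650 X genes, no autosomal background) for the burden sweeps —
the screen never reads the other groups — with 200 replicates for
recovery/FWER rates and 1000 for the rank-test size; exact-test oracle
equivalence is enumerated over every 2×2 table with all margins ≤ 30
(integer-exact reference arithmetic, agreement to 10⁻¹²; CMLE vs direct
likelihood maximization to 10⁻⁶ relative). Conditional-MLE computation
can be skipped (`compute_or=False`) in large sweeps where only effect
sizes and p-values are consumed. Dedup on merge keeps the
higher-quality record, first-in-order on exact ties (logged). Floats in
exports are written at 6 significant digits; round-trips are exact at
that precision.

## Known limitations

- The standard pipeline's historical thresholds are not recoverable;
  results depend on the configured values.
- Adjusted p-values use the data-derived m, not the study's exact m.
- The BAF estimator assumes at most two mirror-image heterozygous
  bands; exotic multi-line mosaics (three cell populations) are out of
  scope, as is genome-wide CNV segmentation.
- Candidate-gene genotypes are inferred from VAF (hom-alt at
  VAF ≥ 0.8) when no explicit genotype is supplied.
- Absolute variant totals of any real cohort are not reproducible from
  synthetic data and are not modeled.
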