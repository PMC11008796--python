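# Methods

## Model

Phenotypes are additive over biallelic loci:

    Y = Y* + Σ_l g_l α_l^d + Σ_l (g_l^m + g_l^f) α_l^i + ε,   ε ~ N(0, V_E),

with g_l ∈ {0,1,2} the count of the focal allele (by convention the allele
whose direct effect α^d is non-negative), α^i an equal maternal/paternal
indirect ("nurture") effect, and no G×E or G×G interactions. Populations are
strictly monogamous with discrete generations: every individual mates exactly
once, every pair leaves exactly two offspring (full siblings), and brood sex
composition is fixed (¼ of pairs two daughters, ¼ two sons, ½ one of each,
assigned after a random permutation of pairs), so the population size and the
1:1 sex ratio are exact invariants. Population sizes must be divisible by 4.

Meiosis is interference-free: per chromosome the transmitted haplotype starts
from a fair coin and switches between the parent's haplotypes after each
interval with probability equal to the interval's sex-specific recombination
fraction. Two map conventions are supported: a single-chromosome "toy" map
on which the adjacent-locus spacing in Morgans is read directly as the
adjacent recombination fraction and non-adjacent fractions follow from
independent per-interval crossovers, c(l₁,l₂) = ½(1 − Π(1 − 2cᵢ)) — exactly
the simulator's own transmission model — and an empirical-map convention on
which pairwise fractions are Kosambi's map function c(d) = ½·tanh(2d) applied
to the female and male distances separately and averaged. Cross-chromosome
pairs always have c = ½. The small inconsistency between interference-free
transmission and the Kosambi pairwise fractions (Kosambi implies
interference) is inherited from standard practice; it is negligible at the
distances that matter here, where the harmonic-mean recombination fraction is
dominated by cross-chromosome pairs.

## Assortative mating

Mate assignment with a target score correlation ρ uses perturbed rank
matching: rank females on one score and males on another and accept the
ranking outright if its correlation is already below ρ + ε (default
ε = ρ/100); otherwise perturb all scores with i.i.d. Gaussian noise of scale
ξ before ranking, trying each ξ five times and keeping the realisation whose
true-score correlation is closest to ρ, then doubling, halving or averaging
ξ according to whether the last two achieved correlations sit above, below
or astride the target, starting from ξ₀ = 4·(range of pooled scores) and
ξ₁ = 2ξ₀. The noise is redrawn within an iteration while ξ stays fixed. At
2,000 mate pairs the realisation-to-realisation spread of the achieved
correlation is ≈ 0.03, so reaching |ρ_k − ρ| < ρ/100 is a stochastic search;
the iteration cap is therefore 500 (an error is raised beyond it). Much
smaller caps suffice at larger population sizes.

## LD bookkeeping

Cis-LD D is the covariance, across individuals, between allele indicators at
two loci on the haploid genome inherited from the same parent (averaged over
the two origins); trans-LD D̃ is the same across origins (symmetrised over
the two orderings). Both are population covariances (divisor n) taken about
the *pooled* allele frequency of the locus, not per-origin means: with this
centering the identity D − D̃ = (H_coup − H_rep)/2 — the excess of coupling
over repulsion double heterozygotes — holds exactly on any finite phased
sample, and the diagonal of D is exactly p(1−p). LD entries involving
monomorphic loci are reported as 0 with a mask flag so matrix shapes are
stable. Per-locus inbreeding coefficients use F = 1 − H_obs/(2p(1−p)).

## Estimators

All three designs are marginal per-locus regressions with no covariates,
isolating confounding from correction machinery: trait on genotype
(population), sibling trait difference on sibling genotype difference
(sibling), and trait jointly on transmitted and untransmitted genotypes
(parent–offspring), the direct-effect estimate being α̂(T) − α̂(U).
Transmitted/untransmitted genotypes are resolved exactly from phase and
pedigree (g_U = g_m + g_f − g). Where sibships exist, population-design
samples take one sibling per family at random to avoid family clustering.
Zero-variance and collinear loci are masked, never zero-filled. The summary
metrics are the mean bias E[α̂ − α], the heterozygosity-weighted mean square
E[2p̂(1−p̂) α̂²] (proportional to the association χ²), and the cross-trait
product E[2p̂(1−p̂) α̂β̂]; the weight uses sample frequencies 2p̂(1−p̂)
rather than the genotypic variance with F, matching how the metric is
normally quoted, even though the per-locus estimator denominators do carry
the (1+F) factor.

## Expectation formulas and their domain

`theory.expected_population_estimate`, `expected_family_estimate` and
`expected_untransmitted_estimate` evaluate the closed-form expectations of
the three designs from LD matrices, effects, recombination fractions, H and
F. The "local" causal set is the locus itself (simulations genotype causal
loci directly); a tagging window is not needed for any experiment here. The
untransmitted-allele formula's F couples the offspring inbreeding coefficient
to the parents' same-locus trans-LD, which presumes a mating structure that
is stationary across the two generations; it is accurate under ongoing
assortative mating or stable stratification, but not across one-off
transitions (e.g. the first random-mating generation after a merge), where
no single F describes both generations. The test suite checks plug-in
consistency (measured LD in, replicate-mean estimates out, within 3 Monte
Carlo SE) in the two stationary regimes.

## Stabilizing selection (Bulmer equilibrium)

Gaussian viability selection of width V_S about an optimum shrinks the
additive variance within a generation by δ = −V_A²/(V_S + V_P), entirely as
disequilibrium, split evenly between cis and trans pairs. Per locus pair,
transmission keeps (1 − c) of cis-LD and converts trans with probability c,
and random(-ish) pairing resets trans-LD, so at equilibrium the
pre-selection pairwise cis-LD is (pair share of δ/2)/c; aggregating over
pairs with equal effects gives d* = δ/(2c̄_h) with c̄_h the harmonic-mean
recombination fraction — this is why the harmonic (not arithmetic) mean
governs the aggregate. Anchored on observed (pre-selection, equilibrium)
h² and V_P the solution is closed-form (`solve_bulmer_observed`); anchored
on genic parameters (V_g, V_E) it is found by damped fixed-point iteration
from d = 0 with relative tolerance 1e-10 (`solve_bulmer`). The proportionate
attenuations are −d*/V_g (population design, pre-selection sample),
−d*(1 + 2c̄_h)/V_g (post-selection; selection within the sampled generation
adds δ = 2c̄_h·d*), and −d*(1 − 2c̄_h)/V_g (within-family, either timing).

Stabilizing selection also *masks* assortative mating: the negative
unlinked-pair LD it maintains cancels part of the positive LD that mating
correlations create, so AM-strength estimates built from cross-chromosome
PGS correlations are biased downward. The implemented closed form is

    ρ̂ = ρ − T · k / h⁴,   k = V_P/(V_P + V_S),

with T = 1 for a sample measured before selection acts in its generation and
T = 2 after (within-generation selection doubles the unlinked-pair
disequilibrium, so the post-selection masking is exactly twice the
pre-selection masking); k is the within-generation proportional variance
reduction and h⁴ converts between the phenotypic mate-correlation scale and
the PGS-covariance scale. The factor-of-two structure and the limiting
behaviour (no masking without selection; masked *fraction* growing as ρ
falls or selection strengthens) are exact properties of the equilibrium LD
accounting; the h⁻⁴ scale calibration of the estimator inversion is adopted
as the package's closed form and validated against the equilibrium
attenuation machinery above. The harmonic-mean recombination fraction for a
human-like genome is computed by apportioning loci to 22 autosomes by
physical length (largest-remainder rounding, ties to the lower chromosome
index) and spreading each chromosome's allotment evenly over its
sex-averaged genetic length; the bundled autosome table is a synthetic
linear approximation to pedigree maps (female ≈ 1.50 cM/Mb + 37 cM, male ≈
0.88 cM/Mb + 15 cM) that yields c̄_h ≈ 0.47 at 1,000 loci — adequate for
simulation, but analyses quoting the height numbers use the published
c̄_h = 0.464 as a parameter, since the exact value requires a measured map.

Viability selection in the simulator draws survivors per sex without
replacement with Gumbel-top-k weights proportional to
exp(−(Y − θ)²/(2V_S)); survivors then enter the monogamous scheme. This is
one of several equivalent ways to realise Gaussian viability selection and
is used only for qualitative cross-checks of the analytic results (variance
reduction, sign of the induced LD), which are analytic everywhere else.

## Sibling indirect effects

With mutual sibling feedback Y_i = Y* + αg_i + βY_j + ε_i the solved system
gives Y_i = (B_i + βB_j)/(1 − β²) for bases B = Y* + αg + ε, requiring
|β| < 1; the sibling design estimates α/(1+β) (defined for β > −1 via the
difference equation) and the population design (one sibling per family)
estimates (α + αβ·r_sib)/(1 − β²) with sibling genotype correlation
r_sib = ½ at a Hardy–Weinberg locus. At β = 1 individual phenotypes are
undefined and the experiment driver simulates sibling differences directly,
reporting only the sibling design there.

## Synthetic-data generator: what it does and does not emulate

The simulator generates exactly the study conditions analysed: Bernoulli
founders at Hardy–Weinberg and linkage equilibrium, drift-like two-population
divergence (Gaussian frequency perturbations of variance 2p(1−p)F_ST,
clamped to [0,1]), heritability-1 phenotypes in the mating-scenario
experiments, and the monogamous two-offspring demography above. It does not
model mutation, overlapping generations, non-monogamy, unequal broods,
crossover interference, sex chromosomes, G×E/G×G, ascertainment, or real
minor-allele-frequency and effect-size spectra. Passing tests therefore
demonstrate the *logic* of confounding — which design absorbs which LD, at
which rate it decays — under the idealised demography, not the magnitude of
any bias in real cohorts.

## Scales, seeds and numerics

Experiments run at desk scale by default: N = 4,000 individuals, ~200 causal
loci, 100–300 replicates, 30-generation burn-in where drift equilibrium is
needed (the burn-in plateau is checked against the post-run plateau in the
same-trait AM experiment). These are the package's study conditions; the
published-scale N = 40,000 / 1,000 loci / 10,000 replicates can be requested
through the config dataclasses but is not exercised by the tests. Replicate
r of an experiment with seed s uses `SeedSequence([s, r])`, so every table
is bit-reproducible from (config, seed) and replicates are independent.
Genotypes are stored as (n, 2, loci) uint8 phased arrays; meiosis draws
float32 uniforms; estimator algebra is float64. Monte Carlo assertions in
the tests use 3 standard errors of the replicate mean unless a wider band is
stated inline.

## Known limitations

* The untransmitted-allele expectation needs a stationary mating structure
  (see above); its F ≠ 0 path follows the general formula but has only been
  validated against simulation in the stationary regimes.
* The masked-mate-correlation formula's h⁻⁴ calibration is the package's own
  reconstruction of the estimator inversion; alternative first-principles
  accountings of the estimator differ by O(ρh²) factors.
* Equal-effect loci are assumed throughout the Bulmer machinery; unequal
  effects would weight the harmonic mean by effect sizes.
* At desk scale the assortative-mating search is noisy near its tolerance;
  the achieved mate correlation is within ρ/100 of target but individual
  generations may need tens of search iterations.
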