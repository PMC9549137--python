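# Methods

This note records the statistical models implemented in `microkin`, the
defaults and why they were chosen, what the simulation engine does and does
not emulate, and the numerical and design decisions a maintainer would want
to know. Notation: alleles at a locus have population frequencies `p_i`;
unordered genotypes use Hardy–Weinberg probabilities `p_i²` and `2·p_i·p_j`.

## Panel model and candidate screening

A microhaplotype locus is defined by ≥ 2 SNPs on one chromosome; its extent
is the inclusive base-pair span from first to last SNP
(`last − first + 1`), the convention validated against all 36 extents of
the packaged panel definition. Locus names follow the community
nomenclature `mh<chromosome two digits><lab code><serial>` with an optional
single lower-case suffix marking a variant SNP combination of a previously
published locus; the suffix is stored but not interpreted.

Candidate screening applies four numeric criteria as **strict**
inequalities, mirroring their verbal form ("smaller than 100 bp", "larger
than 3.00", "greater than 0.65", "larger than 5 Mb"): extent < 100 bp,
Ae > 3.00, heterozygosity > 0.65, and same-chromosome spacing > 5 Mb
measured between locus start coordinates. Spacing conflicts are resolved
greedily in genomic order, keeping the higher-Ae locus of a conflicting
pair and re-checking the survivor against its new predecessor; this is
deterministic and favours panel power where the sources are silent on
tie-breaking. A further optional predicate — per-SNP minor-allele
frequencies pairwise differing by more than a tolerance (default 0.01) —
is exposed for screening pipelines; no tolerance is standard, so it is a
parameter.

VCF extraction concatenates the allele characters of each phased haplotype
column across the locus's SNP positions, in genomic order, and returns the
lexicographically ordered pair. Unphased heterozygotes, missing positions
and non-SNP alleles are hard errors: imputing phase or sites would
fabricate alleles.

## Forensic parameters

* `Ae = 1/Σp_i²` — effective number of alleles; `1 ≤ Ae ≤ n_alleles`, with
  equality on the right iff frequencies are uniform.
* `Ho` — fraction of typed individuals with two different alleles.
* `PD = 1 − Σg_j²` over genotype frequencies, in two modes: `observed`
  (tally genotypes from typed data — the convention of Powerstats-class
  tools) and `hwe_expected` (derive genotype frequencies from allele
  frequencies; the only option when genotypes are unavailable, e.g. in
  simulation studies or per-population comparisons). The mode is always
  explicit in reports because the two can differ in the second decimal on
  real data.
* `PE = h²(1 − 2hH²)`, `h = Ho`, `H = 1 − h` — the trio exclusion-power
  convention. This formula was fixed only after verifying it reproduces
  every published per-locus PE of the reference panel from the published
  Ho within ±0.01 (two-decimal rounding), including the range endpoints
  0.79 → 0.58 and 0.58 → 0.27.
* Combined powers `1 − Π(1 − v_i)` accumulate the complement as
  `Σ log(1 − v_i)`; the complement is a first-class output because values
  like `1 − 2.96e-26` are indistinguishable from 1.0 in double precision.

Published frequency tables rounded to two decimals do not always sum to 1
(column sums 0.99–1.03 in the packaged table); the loader renormalises by
the column sum, logs the adjustment, and pushes the residual
floating-point error onto the largest allele so sums are exactly 1. The
renormalised object is shared between the simulator and the LR evaluator —
one frequency source, no silent mismatch.

## Hardy–Weinberg exact test (MCMC)

Conditional on allele counts, genotype tables follow Levene's law
`P(table) ∝ n!·2^h / Π n_ij!` (`h` heterozygote count). The p-value is the
total probability of tables no more probable than the observed one. Full
enumeration is infeasible for the allele counts microhaplotypes reach, so
the p-value is estimated by MCMC: the chain state is an explicit pairing of
the `2n` alleles into `n` individuals, and a step picks two individuals and
one allele of each, then swaps them. The proposal is symmetric and every
move is accepted; the walk is uniform over allele pairings, and the number
of pairings realising a table is proportional to Levene's law, so the
induced chain on tables has exactly the right stationary distribution.
This is equivalent in law to the classical switch-proposal chain for this
problem but needs no Metropolis ratio. The log-probability is updated
incrementally per swap (four cell updates), and allele counts are conserved
by construction.

Defaults are 1,000,000 steps after 100,000 burn-in, mirroring the defaults
of the population-genetics packages practitioners use for this test; tests
run far shorter chains against a full-enumeration oracle (≤ 6 alleles,
n ≤ 10). Ties between table probabilities are counted as "≤ observed" with
a 1e-9 absolute log tolerance. Monomorphic loci return p = 1 with a warning
(no alternative table exists). Because a single chain's hit indicator is
autocorrelated, calibration tests compare the *mean over independent
chains* with the exact value within three standard errors of that mean.

## Linkage-disequilibrium test (EM + permutation)

With gametic phase unknown, two-locus haplotype frequencies are fitted by
EM: initialisation is uniform over all haplotypes compatible with the
observed genotypes (deterministic), the E-step distributes each
double-heterozygote's mass over its two phasings, and iteration stops when
the log-likelihood gain drops below 1e-8 (default) or at 1000 iterations.
The log-likelihood is asserted non-decreasing every iteration. Datasets
containing double heterozygotes are flagged `phase_ambiguous`: symmetric
likelihood ties exist in degenerate cases and the returned optimum is the
one reached from the uniform start.

The test statistic is `2(logL_EM − logL_LE)` where the linkage-equilibrium
model sets haplotype frequencies to products of single-locus allele
frequencies. The null is built by permuting one locus's genotype column
across samples — both single-locus genotype distributions are preserved
exactly while any gametic association is destroyed — and re-running EM on
each permuted dataset. P-values use the add-one estimator
`(1 + #{perm ≥ obs}) / (1 + B)`, standard for Monte-Carlo tests (never
exactly zero); B defaults to 10,000 (the reference tool's setting is
unpublished). Type-I error is verified ≈ α on data simulated under both
nulls.

The default pipeline order follows the two-stage workflow of a panel
study: HWE on all loci with threshold `α/n_loci`, then pairwise LD on the
HWE-passing loci with threshold `α/C(k,2)`.

## Pair simulation

Founders are drawn under Hardy–Weinberg proportions from the supplied
frequencies. Related pairs are built structurally, not by perturbing
genotypes: parent-child = founder parent, one transmitted allele plus one
population allele; full siblings = two shared founder parents; half
siblings = one shared parent and two independent mates; first cousins =
children of two full siblings married to founders; unrelated = independent
founders. Mutation acts independently on every transmission edge (1 meiosis
separates a parent-child pair, 2 per shared parent for siblings, 4 for
first cousins), which is how pedigree-based kinship simulators operate.

Mutation models:

* **equal_probability** (microhaplotypes, default rate 10⁻⁸ per meiosis per
  locus): a mutating allele becomes any *other* allele of the locus's
  observed allele set with equal probability `μ/(A−1)`.
* **extended_stepwise** (STRs, default rate 10⁻³): repeat number moves ±s
  steps along the ladder of observed repeat alleles, s geometric with
  parameter `step_geometric_p` (default 0.9, mostly single-step), direction
  uniform, reflected off the ladder ends. The exact multi-step law of the
  reference simulator is unpublished; this geometric parameterisation is
  the package's documented choice, and at μ = 10⁻³ and 100,000 pairs the
  single-step/multi-step distinction is numerically invisible, so
  `step_geometric_p = 1.0` is used in the packaged STR example path.
* First-cousin studies default to μ = 0, the simplification used for
  third-degree analyses.

Loci are simulated independently (linkage equilibrium assumed — the panel
was screened for it). Two equivalent engines exist: a scalar per-pair
generator (streaming, used for pair files and small studies) and a
vectorised per-locus engine encoding unordered genotypes as integers
`j(j+1)/2 + i`, used by the 100,000-pair power studies (seconds per study).
Both implement the same pedigree and mutation semantics; all randomness
comes from numpy Generators, with cohort streams spawned from one
SeedSequence so every study is reproducible from one seed.

## Likelihood-ratio indices

For IBD coefficients `k = (k0, k1, k2)`,
`P(g₂ | g₁, k) = k0·P(g₂) + k1·P₁(g₂|g₁) + k2·[g₂ = g₁]`, where `P₁` shares
one uniformly chosen allele of `g₁` and draws the other from the
population. The indices are PI (parent-child vs unrelated), FSI
(full-sibling vs unrelated), HSI (half-sibling vs unrelated) and FHSI
(full- vs half-sibling); in log₁₀, `FHSI = FSI − HSI` identically, which is
asserted. Panel values are per-locus sums.

The PI numerator uses mutation-adjusted transmission
`T(a→b) = 1−μ` if `b = a`, else `μ·m(a,b)` with `m` the mutation model's
target law, so Mendelian inconsistencies yield large negative finite log
LRs whenever μ > 0. Mutation is *not* inserted into the sibling-class
indices: at microhaplotype rates the effect is below floating-point
visibility there, and pairwise k-coefficient likelihoods have no
single-meiosis factorisation to attach it to; this interpretation is
recorded here because reference tools do not document their choice.
With μ = 0 a true exclusion gives −∞, which is retained (never clamped)
and counts as supporting the alternative at any threshold.

Alleles present in a pair but absent from the frequency table raise an
error by default; an optional minimum-frequency floor (5/(2·96) when
enabled) exists for casework-style robustness, but the default simulation
path never needs it because simulator and evaluator share one frequency
object. Exact identities verified by enumeration: `Σ P(pair|Hd)·LR = 1`
(to 1e-9) and both hypothesis distributions sum to 1.

For the vectorised studies, each locus's log₁₀ LR is precomputed as a
genotype-index lookup matrix (≤ 91×91 at 13 alleles); the matrix is tested
entry-wise against the scalar implementation.

## System power

For threshold pair `t1 ≥ t2`: log₁₀ LR **strictly** above `t1` supports the
claimed relationship, strictly below `t2` the alternative, and boundary
values fall in the uncertain zone — following the strict "larger
than"/"smaller than"/"between" wording of the decision rule. The six
metrics follow their defining count ratios; PPV/NPV with empty denominators
are reported as missing (`None`) rather than 0 or 1, which would fabricate
certainty. `effectiveness + error_rate + uncertain_fraction = 1` holds
exactly by construction. UCR uses strict inequalities against the opposing
cohort's extremum; −∞ values participate normally. Human-readable output
rounds percentages to two decimals; machine output keeps full precision
plus the underlying tallies.

UCR depends on sample extrema and is reproducible only in order of
magnitude across seeds even at 100,000 pairs; it is reported as an output
but not used as a correctness check.

## Problem sizes and what the tests show

The packaged acceptance runs use the study's own conditions: 100,000 pairs
per cohort per comparison, μ = 10⁻⁸ equal-probability, thresholds 4/−4
(parent-child), 2/−2 (full sibling), 1/−1 (half sibling and full vs half
sibling). These complete in seconds via the vectorised engine. Calibration
tests run reduced-scale: MCMC chains of 3×10⁴ steps against enumeration,
200 null replicates with 99 permutations for LD type-I error, 2×10⁵
Monte-Carlo pairs against exact outcome enumeration on 1–2-locus toy
panels.

Reproduction accuracy is limited by the input resolution, not the model:
the packaged frequencies are printed to two decimals, while the original
study simulated from unrounded 96-sample frequencies. Empirically this
moves effectiveness values by up to ~0.5 percentage points (largest for
the half-sibling comparison, whose LR distribution is steepest near t=1);
resampling frequencies at the study's own counting resolution (192
gametes) reproduces exactly this spread. Agreement within half a
percentage point on all four comparisons is therefore the strongest claim
the printed inputs support.

What the simulation does **not** emulate: genotyping error, allele
dropout/degradation (the wet-lab arm of a panel study), linked loci,
population substructure or θ-correction, and mutation-rate variation
between loci. Passing tests show the *evaluation machinery* is correct
under the stated population model; they do not validate a panel against
laboratory artefacts.

## Known limitations

* The HWE chain is pure Python (≈ 3–5 s per million steps); adequate for a
  36-locus scan, not for genome-wide screening.
* The LD permutation test re-fits EM per permutation; 10,000 permutations
  × 406 pairs at n = 96 is an overnight run, matching the reference tool's
  scale rather than improving on it.
* Sibling-class LRs ignore mutation (see above) — at STR mutation rates
  (10⁻³) this choice becomes visible and should be revisited before using
  FSI/HSI on STR panels in casework.
* `population_ae_matrix` derives PE from *expected* heterozygosity when
  only frequencies are available; per-population CPE values are therefore
  model-based, not observed.
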