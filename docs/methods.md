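# Methods

This note documents the statistical model, the simulation machinery, the
numerical choices, and what the synthetic data do and do not establish.

## The ICS statistic

For two diploid individuals genotyped at the same ordered panel of
biallelic autosomal SNPs, the IBS state at a locus is the size of the
maximum matching between the two unordered allele pairs (for dosages g ∈
{0, 1, 2} this is `2 − |g₁ − g₂|`). Loci uncalled in either individual are
deleted before any further step, so a shared segment may bridge a missing
locus but always begins and ends at called loci. A **shared segment** is a
maximal run of ≥ 2 consecutive retained loci with IBS ≥ 1 within one
chromosome; its length is the cM difference between its first and last
SNP. Single-locus runs are "isolated sharing" and are never segments (they
also have zero cM length). Chromosome boundaries always break runs;
zero-length multi-SNP segments (coincident cM positions) are kept but
contribute nothing.

`ics(Th)` sums the lengths **strictly greater** than Th. `ics` is
non-increasing in Th, bounded by the total map length, and attains that
bound for an error-free self-comparison or parent–child pair at any Th
below the shortest chromosome.

## Threshold calibration

Th is chosen per relationship group by sweeping an integer cM grid from 0
to the shortest chromosome length (63 cM) and computing, at each Th, the
Mann–Whitney AUC (midrank ties) of each adjacent comparison:

- collateral chain: C-1 vs C-2, C-2 vs C-3, C-3 vs C-4, C-4 vs C-5,
  C-5 vs UN;
- lineal chain: L-1 vs L-2, L-2 vs L-3, L-3 vs UN.

The Th maximising the chain's mean AUC is adopted (C-Th / L-Th), ties to
the smallest Th. Segments are detected once per pair and re-thresholded
across the grid via a sorted suffix sum. A 1 cM grid step is used: the
sweep endpoints are integers and a finer step does not change the selected
threshold materially on these data.

On the default synthetic panel the selected thresholds land around 9–11 cM
for C and vary more for L (the lineal chain's first comparison is already
perfectly separated at every Th, leaving fewer informative components) —
larger than thresholds calibrated on a real ~174k-SNP array, because at
one quarter of that SNP density the chance segments of unrelated pairs are
correspondingly longer.

## Distribution fitting and model selection

Per relationship, the simulated ICS sample is fitted by maximum likelihood
under three two-parameter families:

- **normal** (closed form: sample mean, ML variance);
- **truncated normal** on [0, total map length], maximised numerically over
  (μ, log σ) by L-BFGS-B with the analytic gradient of the truncated
  log-likelihood, initialised at the untruncated MLE, gradient tolerance
  1e-8;
- **log-normal** (normal MLE of log values; μ, σ live on the log scale).

Families are compared per group by the **sum of per-relationship AICs**
(each relationship keeps its own μ, σ; k = 2 per fit). The collateral group
comprises C-1…C-5 + UN; the lineal group L-2, L-3 + UN. L-1 is excluded:
with error-free genotypes its ICS is a point mass at the map total, which
no density represents; classification handles it with a deterministic
pre-check (fraction of loci with IBS ≥ 1 above 1 − 1e-3, the tolerance
absorbing realistic typing-error rates).

Numerical details:

- exact zeros are inadmissible under the log-normal; up to 5% of a class is
  dropped with a logged count, more is a fitting error. Inside the group
  AIC comparison a family that cannot be fitted for this reason has
  maximum likelihood zero and is assigned AIC = +∞ (disqualified) rather
  than aborting the selection — on the sparse synthetic map unrelated
  pairs can have ICS exactly 0 at the selected L-Th, which is exactly this
  case;
- normal and truncated-normal AICs tie to numerical precision whenever the
  data sit far from the bounds; |ΔAIC| < 1e-6 resolves deterministically in
  the order log-normal, truncated-normal, normal;
- which family wins is a property of the data. On the default synthetic
  cohort the truncated normal typically wins; on draws that are actually
  log-normal the AIC recovers the log-normal in ≥ 95% of replicates (tested).

A two-sided z test compares held-out ICS observations against a fitted
distribution on its natural scale (log scale for the log-normal):
z = (x̄ − μ)/(σ/√n), treating the fitted distribution as the null. Under
the null its p-values are uniform (tested by KS over seeded replicates).

## Inference

All density arithmetic is in log space (LRs reach hundreds of orders of
magnitude). The likelihood ratio between two hypotheses is the density
ratio at the observed ICS, reported as log10 alongside the linear value,
with an explicit infinity flag when the denominator underflows. Posteriors
over a hypothesis set use flat priors by default (arbitrary priors
accepted) and normalise via log-sum-exp. An observed ICS of exactly 0
under an all-log-normal hypothesis set is evaluated in the limit from
above, which assigns the pair to the heaviest-lower-tail hypothesis (UN in
practice). Verdicts follow Hummel's predicate bands on the best
hypothesis's posterior: ≥ 0.998 practically proven, [0.99, 0.998) highly
likely, [0.95, 0.99) very likely, [0.90, 0.95) likely, < 0.90
undetermined.

Two distribution-level summaries support reporting:

- **predicate ranges**: the ICS axis is scanned (default 0.1 cM step) and
  consecutive points in the same predicate band for a target relationship
  are merged into intervals;
- **predicate mass**: the probability, under a target's own fitted
  distribution, of obtaining an ICS whose posterior for that target clears
  a threshold. The qualifying region's boundaries are refined by Brent
  root-finding on the posterior-minus-threshold function between grid
  points, and the mass is computed as exact CDF differences of the fitted
  family over the refined intervals — more accurate than generic
  quadrature, since all three families have closed-form CDFs. The scan
  domain extends past the nominal ICS maximum when a fitted (unbounded)
  density carries mass there. Agreement with Monte-Carlo estimates from
  10⁶ draws is within 5 × 10⁻³ (tested).

## Simulation machinery

**Map.** The synthetic genetic map has 22 autosomes with fixed lengths
totalling exactly 3662.5 cM, the conventional autosomal total also used as
the maximum ICS; chromosome 21 is the shortest at 63.0 cM. Locus positions
are sorted uniform draws with the chromosome ends pinned, so the total is
exact by construction. Default density is 2000 SNPs per chromosome
(44,000 genome-wide, ~12 per cM) — a deliberate scale-down from a ~174k
array that keeps runtimes in seconds while preserving the qualitative
regime (unrelated pairs' chance segments stay short relative to IBD
segments). Physical bp positions are synthesised for file export only; no
computation uses them.

**Founder panel.** A Li–Stephens-style copying mosaic: per chromosome,
K = 50 ancestral haplotypes carry i.i.d. Bernoulli alleles with
frequencies drawn uniformly from the configured MAF range (default
0.01–0.5, folded to either allele); each panel haplotype copies from one
ancestor at a time, switching ancestors between adjacent loci with
probability 1 − exp(−d/ld_scale). The default ld_scale of 0.1 cM matches
the ~50–100 kb scale over which human r² decays; r² in the panel decays
monotonically with cM distance (tested). A MAF floor equal to the range's
lower bound is enforced by resampling offending loci's ancestral alleles
(bounded retries). Hardy-Weinberg or call-rate QC filters are pointless
for synthetic data and are not emulated; only the MAF floor is.

**Pedigree and gene drop.** The fixed 12-member pedigree couples six
founders (A, B, C, F, G, J) such that one family realisation yields one
pair per target relationship: A×B → D, E; C×D → H; E×F → I; G×H → K;
I×J → L. Meiosis is interference-free: per adjacent-locus interval the
crossover probability is cM/100 capped at 0.5, the starting parental
haplotype per chromosome is uniform, chromosomes are independent. Founder
sextets are assigned to families without replacement after a seeded
permutation (1494 donors → at most 249 families), and each family runs on
its own substream spawned from the master seed, so cohorts are reproducible
family-by-family. Unrelated pairs are founders of different families —
panel members, not extra simulated individuals. An optional error model
(uniform miscall + missingness) is off by default: calibration simulations
are error-free, and the model exists to study how typing errors depress
parent–child ICS below the map total.

With origins tracking enabled, every descendant allele records the founder
haplotype it descends from, giving the tests direct access to true IBD
(e.g. sibling IBD ≥ 1 fraction ≈ 3/4).

## What the synthetic data do and do not show

The generator reproduces the *structure* of the real calibration inputs —
distance-decaying LD, realistic MAF spectrum, recombination-driven IBD —
but at reduced SNP density and without array-specific artefacts (typing
error, missingness, ascertainment of array SNPs, population-specific LD
patterns). Consequently thresholds, fitted parameters, AIC winners, LR
magnitudes and predicate-mass percentages computed here characterise the
*method* under controlled conditions; they are not estimates of the values
a specific real array and cohort would give. Passing tests establish
correctness of the machinery and the qualitative behaviour (ICS ordering by
kinship degree, separability of unrelated pairs, C-4 being the hardest
collateral relationship), not numeric transferability to a particular
population.

## Problem sizes used by the test suite and acceptance script

Calibration uses 200 simulated families with 50 held-out families (the
donor pool scales accordingly: 1500 donors), the default 44,000-SNP map,
10⁴ meioses for the crossover-count check, 10⁴ draws for parameter
recovery, 50 replicates for AIC self-consistency, 500 replicates for z-test
calibration, and 10⁶ draws for Monte-Carlo validation of predicate masses.
These sizes were chosen so the full pipeline completes in minutes on one
CPU while leaving Monte-Carlo error well below the asserted tolerances.
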