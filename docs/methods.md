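# Methods

This note documents the models, parameter choices and numerical decisions
behind `crosskin`, and what the synthetic-data tests do and do not
establish about real herds.

## Simulation model (`crosskin.synth`)

**Population design.**  Two divergent founder breeds: `n_sires` sires and
`n_dams` dams.  F1 offspring draw one parent from each breed; backcross F2
draw an F1 dam and a founder sire (mirroring the use of purebred semen on
F1 cows); intercross F2 draw two distinct F1 parents.  Defaults mirror the
modelled herd: 24 sires, 28 dams, 923 offspring split ≈ 615 F1 / 246
backcross / 62 intercross F2.  The F1/F2 split is approximate by
necessity — it is taken from classified counts rather than recorded herd
proportions, which are not available — and the backcross:intercross split
within F2 (≈ 4:1) reflects the observation that intercross offspring are a
minority.  Desk-scale configurations used in tests keep the founder
structure and shrink offspring and locus counts.

**Genetics.**  Loci are autosomal, biallelic and unlinked; genotypes are
dosages of the alternate allele (0/1/2).  A fraction `frac_fixed_divergent`
(default 0.3) of loci is fixed for alternative alleles between the breeds,
with per-locus orientation drawn at random and recorded as construction
truth; remaining loci draw breed-specific allele frequencies from
configurable distributions (default Uniform(0.05, 0.95) per breed) and
founder genotypes binomially.  Offspring receive one allele drawn uniformly
from each parent's two, independently per locus (gene dropping).  Ignoring
linkage keeps all Mendelian expectations exact, at the cost of not
reproducing the correlated transmission real chromosomes show; linked loci
would widen the spread of per-animal ratios without moving their means.

**Observation model.**  Per call: read depth ~ Poisson(`mean_depth`,
default 12 reads); each read reports the wrong allele with probability
`genotype_error_rate` (default 0.002); calls drop out with
`missing_rate` (default 0.05) on top of zero-depth dropout, and dropouts
have their depths zeroed, so a call is missing iff it has no reads.  The
caller is deliberately naive: reads of both alleles ⇒ heterozygote,
otherwise the homozygote of the observed allele.  This is the simplest
model that reproduces the two RAD-seq failure modes that matter
downstream: heterozygote under-calling at low depth (P(het call | het) =
1 − 2^(1−d) at depth d with no read errors) and spurious heterozygotes
from read errors at high depth.  It does not model allele-specific bias,
restriction-site dropout (null alleles), index hopping or contamination;
parentage accuracies on synthetic data are therefore upper bounds for
herds where null alleles are common.

**I/O.**  Genotypes round-trip through a minimal VCF v4.2 writer (one
record per locus on a synthetic contig, FORMAT `GT:AD:DP`, `./.` for
missing) and a `cyvcf2`-based reader; identical seeds produce
byte-identical VCFs.

## Panel selection (`crosskin.variants`)

**Hard filter.**  GATK-style site thresholds with strict inequality
semantics exactly as printed in their conventional presentation: a site is
removed when QUAL < 250, DP < 1500, DP > 6000, (MQ < 50 ∥ QD < 4 ∥
FS > 15 ∥ BaseQRankSum < −4 ∥ ReadPosRankSum < −3.5 ∥ MQRankSum < −10),
SOR > 4, AN < n_samples, or MQ0 ≥ 30.  Boundary values therefore pass
(QUAL = 250.0 is retained).  A site lacking an annotation is never removed
by that annotation's rule (the GATK convention for rank sums, which exist
only for heterozygous sites).  The AN bound is expressed relative to the
sample count — requiring at least half of all calls present — rather than
hard-coding any particular cohort size.  These thresholds target a real
variant-calling cohort; the simulated VCFs carry only AN/DP, so pipeline
runs on synthetic data leave the hard filter off by default.

**Generation panel.**  A locus is diagnostic when the sires are (nearly)
fixed for one allele and the dams for the other.  With counts: the modal
allele among sires must account for `2·n_sires − slack … 2·n_sires`
allele copies (default slack 5; with 24 sires and 28 dams this produces
the windows [43, 48] and [51, 56]), same for dams, and the two modal
alleles must differ.  Ties for the modal allele disqualify a locus
(ambiguous orientation is not diagnostic).  Calls with total allele depth
below 6 are treated as missing first.  Whether a locus with a missing
founder call should be dropped outright or absorbed by the window slack is
genuinely open; the function defaults to dropping (conservative) and
exposes `require_complete_founders=False`, which the analysis drivers use
at 12× depth, where requiring 52 complete founder calls would discard
nearly everything the slack was designed to keep.

**Parentage panel.**  Multiallelic loci are excluded first; then, computed
on the paternal samples: minor allele frequency > 0.25, *observed*
heterozygosity (het fraction among called sires) > 0.2, missingness
< 0.7, and a two-sided exact Hardy–Weinberg test p > 0.01.  A final
screen drops loci with per-call depth < 6 (as missing) and missingness
> 0.8 across all samples.  Observed rather than expected heterozygosity
is the simpler reading of a bare "heterozygosity" threshold; with the MAF
bound already at 0.25 the two differ little.  The HWE test conditions on
the observed allele counts and sums the probabilities of all heterozygote
counts no more probable than the observed one, computed by a two-sided
recurrence (validated in the tests against full enumeration).  Reference
allele frequencies recorded in the panel come from the called sire
genotypes.

## Generation classification (`crosskin.generations`)

Per offspring, over non-missing generation-panel calls: heterozygous
ratio *h*, paternal ratio *p* (homozygous for the sire-diagnostic
allele), maternal ratio *m*.  For a biallelic panel these partition the
called loci.  Labels: *h* > 0.5 ⇒ F1; else *p* > 0.5 ⇒ MSF2; else
*m* > 0.5 ⇒ MDF2; else LSF2 when *p* ≥ *m*, LDF2 otherwise.  Ties
(*h* = 0.5 ⇒ F2; *p* = *m* ⇒ LSF2) follow the strict reading of the
thresholds.  An offspring with zero called panel loci is reported
`unclassified` rather than forced into a class.

An intrinsic limit worth stating plainly: a backcross F2's *h* is a
Binomial(L, ½)/L draw, so its distribution straddles 0.5 at any panel
size and roughly half of backcross F2 land in the F1 class *even with
perfect genotypes*.  Classification accuracy against truth is therefore
reported at both the F1-vs-F2 and five-way granularity, and perfect
accuracy is expected only for F1 cohorts (where *h* = 1 exactly under
zero error).

## Relatedness (`crosskin.relatedness`)

**Method-of-moments IBD.**  Per pair, observed IBS0/IBS1/IBS2 counts over
co-called informative loci are equated to their expectations given the
per-locus allele frequencies (e.g. E[IBS0 | IBD=0] = 2p²q²,
E[IBS1 | IBD=1] = 2pq), solved sequentially for P(IBD=0,1,2), clamped to
non-negative and renormalised to the simplex; π̂ = P2 + P1/2.
Frequencies come from an explicit array, a parentage panel, or estimation
from all samples — founder-derived frequencies are preferred, since
offspring inflate apparent sharing.  Monomorphic loci are skipped; pairs
with under 50 informative co-called loci trigger a warning.  In
structured data (two breeds, shared founders) π̂ for nominal "unrelated"
or half-sib pairs is biased upward relative to the textbook 0 / 0.25 —
the tests verify the clean bands only on panmictic synthetic data, which
is the regime where the estimator's guarantees hold.

**Kinship.**  Centered-IBS: dosages mean-centered per locus (missing
mean-imputed), cross-product normalised by 2·Σ 2p̂q̂, landing on the
coancestry scale (self 0.5, parent–offspring 0.25 for non-inbred
samples); the `times_two` option rescales to expected-covariance /
numerator-relationship units (self 1, parent–offspring 0.5), the scale
used when comparing against pedigree expectations.  The matrix is
symmetric and positive semi-definite by construction.

**Distances and trees.**  p-distance is the mean per-locus allele-sharing
distance |g₁ − g₂|/2 ∈ {0, ½, 1} over pairwise-complete loci.
Neighbor-joining follows Saitou–Nei with two pinned-down details: Q-matrix
ties break toward the lowest pair index in the current node ordering
(making results order-reproducible), and negative branch lengths are
clamped to zero with the deficit transferred to the sister branch so the
joined pair's distance is preserved.  NJ is exact on additive metrics,
which the tests exploit (random additive trees, path-length oracle,
cross-check against scikit-bio's implementation).

## Parentage (`crosskin.parentage`)

**Likelihood engine.**  Per locus, the ratio of P(offspring genotype |
candidate is the sire) to P(offspring genotype | candidate unrelated),
with the unknown dam's allele drawn from the population at the panel
frequency.  Genotyping error mixes the Mendelian transmission probability
with the Hardy–Weinberg genotype probability at rate *e*, so an
incompatible transmission has small but non-zero likelihood whenever
*e* > 0; at *e* = 0 the per-locus log-ratio is floored at −30 to avoid
−∞ while still dominating any realistic sum.  Missing calls contribute a
neutral ratio of 1.  LOD is the natural-log sum over co-typed panel loci;
Delta is the gap between the best and second-best surviving candidate
(the LOD itself when only one candidate survives the `min_typed_loci`
screen).

**Delta critical values.**  Simulated under the documented conditions
(defaults: 30% of loci typed, 0.01% genotyping error, 10,000 simulated
offspring, 50 candidate fathers, 90% of true fathers among the
candidates, minimum 10 typed loci): each simulated offspring is assigned
to its best candidate, and the critical Delta for a confidence level
(strict 95%, relaxed 80%) is the smallest value such that the proportion
of correct assignments at or above it reaches the level — 0 when the
whole simulated set already qualifies, ∞ when no threshold does.  The
simulation is chunked and fully vectorised; analysis drivers use 2,000
simulated offspring, which stabilises the thresholds at desk panel sizes.

**Transmission engine.**  Every sire × dam pair is scored by the mean
per-locus Mendelian transmission probability P(g_off | g_sire, g_dam)
(pure pair transmission, no population allele), skipping loci missing in
offspring or either parent.  Pairs are ranked; mendel1 ≥ mendel2 ≥
mendel3 and delta1/delta2 are reported.  Acceptance keeps the top
1 − α of the empirical delta1 distribution (α default 0.05).  This
quantile rule is an approximation to the original error-rate calibration,
which the source tooling does not specify precisely; it has the right
monotone behaviour (harder assignments rejected first) and the exact
asymptotic acceptance rate.

**Exclusion engine.**  Counts loci where the offspring genotype has zero
probability under pair transmission (or, in single-candidate mode, where
offspring and candidate are opposing homozygotes); candidates are ranked
by ascending mismatch count with input order breaking ties.  Exclusion is
exact on error-free data and brittle under error — exactly why the
consensus step exists.

**Consensus.**  The intersection of the likelihood and transmission
engines' (offspring, sire) calls, with agreement/disagreement counts and
three-way Venn-style overlaps.  Dams are treated as known herd records
when scoring sire-only assignment; pair mode is available in the
transmission and exclusion engines.

## Pipeline and reproducibility

`run_pipeline` executes simulate → read → (optional hard filter) →
panels → classify → relate → assign from one config with one global seed,
records every stage's parameters and the SHA-256 of every output in
`manifest.json`, and halts with a stage-tagged error on failure.  Reruns
with the same config are byte-identical.  All randomness flows through
`numpy.random.Generator` seeded from the config; no global state.

## Problem sizes used in verification

The verification script and acceptance-style tests run at the design's
desk scale: 24 × 28 founders with 1,000 fixed-divergent loci and
100–200 offspring per cross type for the Mendelian checks; 10,000
single-locus intercross genotypes for the 3:1 phenotype ratio; 5,000
loci with frequencies ~ Uniform(0.1, 0.9) and 20–50 pairs per
relationship class for the π̂ bands; 500-locus panels, 25 candidate
sires and 100 offspring for the engine-recovery checks.  Tolerances for
stochastic quantities are 4 binomial standard deviations at the simulated
size (pooled fractions) or the fixed bands ±0.02/±0.03 (π̂ means).

## Known limitations

- Linkage, null alleles and family-correlated missingness are not
  simulated; real RAD data will degrade parentage accuracy below the
  synthetic figures.
- The backcross/intercross mix of the default configuration is an
  educated reconstruction, not a recorded herd parameter.
- The APIS-style acceptance threshold is a quantile approximation (see
  above).
- Hard-filter thresholds are meaningful only for VCFs carrying the GATK
  site annotations; synthetic VCFs exercise the boundary semantics in
  tests rather than in pipeline runs.
- X-chromosome and mitochondrial inheritance are out of scope; all loci
  are treated as autosomal.
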