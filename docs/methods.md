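# Methods

This note documents the models, parameter choices and numerical decisions
behind `evotraj`, in the order the pipeline runs.

## Serial-transfer simulator (`simdata`)

**Model.** One population is a set of genotypes on a tree rooted at the
ancestor. Each transfer day:

1. *Growth* — genotype *i* grows deterministically by `(1+s_i)^g` relative
   to the population, where `g = log2(dilution_factor)` doublings/day
   (6.64 at 1:100), and the census is renormalized to
   `n_bottleneck × dilution_factor` cells. Selection therefore acts as
   expected relative growth; all stochasticity lives in the steps below.
2. *Mutation supply* — each genotype receives `Poisson(μ_i × cells_i)` new
   mutations, taking one terminal division per end-of-day cell as the
   number of rate-relevant divisions. `μ_i = mu × mutator_multiplier` on
   mutator clades, `mu` otherwise. Every mutation founds a new single-cell
   child genotype (infinite sites), so mutation frequency ≡ inclusive
   clade frequency of the genotype it founded, and child ≤ parent holds
   in truth by construction.
3. *Bottleneck* — biofilm mode first draws a binomial bead propagule
   (`bead_fraction` of the census); then a multinomial sample of
   `n_bottleneck` founders seeds the next day. Drift therefore acts once
   per day at scale `n_bottleneck`: neutral absorption happens on the
   order of 2×`n_bottleneck` transfers, not generations — relevant when
   choosing sizes for drift tests.

**DFE.** A fraction `frac_beneficial` of mutations draws
s ~ Exponential(`dfe_mean_s`); the rest (including mutator alleles, which
arise at `mutator_target` per division and are heritable) are strictly
neutral. The deleterious class is omitted: it is irrelevant to the
recovery tests this generator serves and the simplest DFE already produces
clonal interference.

**Defaults and what they emulate.** `n_bottleneck = 1e5` (census 1e7),
`mu = 1e-3` per genome per division (a typical bacterial genome-wide
rate), `frac_beneficial = 0.05`, `dfe_mean_s = 0.08`,
`mutator_target = 3e-7` (≈ mu × a ~2-kb mismatch-repair target / genome),
`mutator_multiplier = 116`, `bead_fraction = 0.1`, depth 617.1 ± 142.3,
`detection_floor = 0.05`. Real experiments of this design run at censuses
well above 1e8; the bottleneck here is a desk-scale placeholder, and the
DFE was calibrated once so that a 90-day run yields tens of lineages
reaching ≥ 1% — the regime of interest, with ~30–50 contending genotypes —
rather than a mutation-starved one. Sampled days default to the biofilm
schedule {17, 25, 44, 66, 75, 90}; planktonic runs use {17, 44, 66, 90}.

**Sequencing noise.** Depth ~ round(Normal(617.1, 142.3)) truncated at 1;
alt reads ~ Binomial(D, f) split Binomial(alt, ½) between strands;
reported frequency alt/D; below `detection_floor` a call is dropped, as a
polymorphism caller would drop it. Sequencing *error* (non-sampling noise)
is out of scope, as are spatial biofilm structure and recombination.

**What passing recovery tests do not show.** The generator has no shared
breakpoints between cohorts beyond true genealogy, no depth-correlated
artifacts, no repeat-region misalignment; real data violates all three,
which is precisely why the filter stage exists. Recovery results bound
algorithmic, not data, error.

**Planted fixture.** `planted_genotype_table` bypasses the dynamics and
emits five fixed cohort trajectories (two roots, a nested chain and a
sibling) with ≥ 0.145 pairwise mean-|Δf| separation, each with 3–4 member
mutations jittered by Gaussian noise (default SD 0.02 ≈ binomial SE at
~600× depth). It gives deterministic, interpretable targets for
clustering/genealogy tests, where the full simulator's truth is itself
stochastic.

## Variant filtering (`variants`)

Coordinates are 1-based inclusive; mutation identity is (position, ref,
alt), so two alts at one site are distinct mutations and the same mutation
in two populations counts as independent cases downstream.

* *Ancestral subtraction* drops (position, alt) pairs present in the
  ancestor-vs-reference set before anything else.
* *Strand support* requires ≥ `min_per_strand` (default 3) reads on each
  strand. For trajectory building the rule is applied per mutation at
  ≥ 1 timepoint (`strand_qualified_keys`): once a mutation qualifies
  anywhere, its weaker calls at other days are kept, which avoids zeroing
  real trajectories at low-frequency days.
* *Dense windows*: a call is dropped when more than `max_neighbors`
  (default 2) other same-population-and-day calls lie within ±15 bp. This
  is a deterministic surrogate for manual alignment inspection around
  variant-dense windows; the window and count are configurable because
  the right strictness is data-dependent.
* *Repeat mask*: inclusive-end intervals; BED input is converted from
  0-based half-open.
* Ancestor/strand/mask filters commute (each is a row predicate);
  dense-window filtering depends on the surviving call set and is applied
  last in the pipeline.

Undetected cells in a `TrajectoryTable` are 0 with a parallel boolean
`detected` mask, so "sampled but below detection" stays distinguishable
from "day not sequenced".

## Genotype and genealogy inference (`genotypes`)

Distance between two mutations is the mean |Δ frequency| over days where
at least one of the pair exceeds `detection_floor`; never-co-detected
pairs are maximally distant. Single-linkage agglomeration joins everything
at distance ≤ `cutoff`. The cutoff is interpreted on this mean-absolute
scale so the conventional settings 0.1–0.2 remain meaningful knobs: a
larger cutoff groups more mutations per genotype. Cohort trajectories are
unweighted member means (depths are near-uniform, so inverse-variance
weighting would change little). Determinism: rows are canonicalized by
mutation key before clustering, making the result invariant to input
order; cohort labels follow first-detection day, then peak frequency.

Genealogy: cohorts are placed in order of first detection then descending
peak; each attaches to the already-placed cohort that (a) dominates it
within `nest_tolerance` on every day, (b) keeps the children-sum
constraint, and (c) minimizes the enclosed area Σ_t (parent − child) —
the "tightest valid background". `nest_tolerance = 0.05` absorbs sampling
noise at ~600× depth (binomial SE ≤ 0.02, with headroom). A cohort with no
valid parent roots, unless roots would exceed total frequency 1 + tol, in
which case no consistent genealogy exists and the error is surfaced rather
than silently repaired — on noisy data this typically means the cutoff
merged incompatible trajectories.

Fixation: a cohort fixes at the first sampled day its trajectory reaches
`fixed_threshold` (default 0.97, since sampled frequencies rarely hit 1.0
at finite depth) and stays above `fixed_threshold − nest_tolerance`
afterwards. Only the first crossing counts: reach-collapse-recover is not
a fixation. Each event sweeps the cohort's own mutations plus those of
ancestors not counted by an earlier event, so nested sweeps partition
mutation counts.

Muller tables report exclusive frequencies (own minus direct children,
clamped at 0) plus a synthetic background row; per-day totals are
renormalized to exactly 1, but if clamping has to discard more than
`nest_tolerance` of mass the forest is reported inconsistent instead.

## Parallelism statistics (`parallelism`)

The multiplicity screen keeps loci with ≥ 2 independent cases; summaries
report the ≥ 3-case subset. The Fisher table orientation — bases
mutated/unmutated × inside/outside locus — makes the one-sided "greater"
test exactly the hypergeometric upper tail P(X ≥ k | G, M, L), which is
also how it is validated (brute-force tail summation). BH is the standard
step-up with m = number of loci actually tested; ties at the cut p-value
share significance, and the implementation is cross-checked against
statsmodels.

Normalized dN/dS divides the observed NS/S count ratio by a neutral
expectation (default 2.96 for the PA14 genome); zero synonymous counts
yield NaN, not infinity. `neutral_dnds_from_codon_usage` recomputes such
an expectation from a codon-usage table by enumerating all 9 single-base
changes per codon under the standard genetic code, weighting by usage;
stop gains/losses count as nonsynonymous, matching the convention of
pooling nonsense with NS. Whether a published neutral ratio derives from
uniform or spectrum-weighted enumeration is often unstated, so this
function is a tool for recomputation, not a claim to reproduce any
particular printed constant.

**Bundled reference tables** (`refdata`): a 40-locus parallelism summary
and treatment-level mutation totals from a published 90-day PA14
biofilm/planktonic experiment serve as end-to-end accounting anchors. The
locus table is locus-level; `expand_cases` unrolls it one row per case,
assigning populations round-robin within each treatment (the replicate
split is not part of the summary — faithful at treatment level, synthetic
at replicate level; locus lengths are likewise a 1000-bp placeholder not
consumed by the accounting paths). One locus (pitA) prints treatment
counts summing to 5 against a case total of 4; the case total is treated
as authoritative.

## Diversity and enrichment (`popstats`)

Diversity treats a day's detected mutation frequencies as community
abundances normalized to proportions — the only self-consistent reading
when feeding allele frequencies to community-ecology indices. All three
modes (Shannon in nats, Simpson, inverse Simpson) are emitted since
analyses differ in which they quote. The two-sample t-test defaults to
pooled-variance Student's (df = n₁+n₂−2), the variant consistent with
df = 4 at n = 3 + 3.

Enrichment regresses biofilm frequency (y) on planktonic frequency (x) —
the orientation is a package choice, flagged in output, and flippable —
and computes Cook's distance D_i = (e_i²/(2s²))·(h_ii/(1−h_ii)²).
A mutation is enriched when D_i ≥ 4 × mean(D); direction follows the
residual sign. Only mutations detected in both conditions should enter
the fit. An exact fit (all residuals ~ 0 at machine precision) returns
all-zero distances rather than 0/0 noise.

## Rate estimators (`rates`)

The selective rate constant divides the log-ratio difference by 2 by
default, preserving the printed form of the statistic it reproduces for
comparability (the competition spans one day, so a per-day rate would
divide by 1; the divisor is a parameter). Zero counts mark a replicate
invalid — undetectable competitors make the estimate unreliable and such
replicates are conventionally omitted, not zero-filled.

Vmax is the maximum least-squares slope of ln(OD) over a sliding window,
default 4 readings (~30 min at 10-minute sampling — short enough to catch
the exponential phase, long enough to smooth plate-reader noise); windows
containing OD ≤ 0 are skipped.

Fluctuation analysis implements the MSS recursion exactly and maximizes
the log-likelihood over ln m with bounded scalar optimization (tolerance
1e-6), bracketed by the p₀ estimate and the count mean. Cultures with
≥ `censor_at` (512) colonies enter as right-censored via the upper tail,
keeping the O(r²) recursion tractable while retaining jackpot information;
plating efficiency and post-plating growth corrections are not modelled.
The companion simulator draws Poisson(m) mutation events per culture with
clone sizes from the classic P(size ≥ k) = 1/k tail by inversion
(floor(1/U), capped at 1e7) — adequate as a distributional oracle for the
pmf it must match, without explicit growth timing. Note the harmonic tail:
partial pmf sums approach 1 only as ~m/r_max.

## Pipeline and CLI

`run_pipeline` executes filters → trajectories → genotypes → statistics
per population, writes every table in plain TSV/CSV, and records config,
version and input checksums in a JSON manifest; reruns are byte-identical.
The CLI is a thin click layer over the same functions; YAML config keys
mirror `PipelineConfig` and flags override them.

## Known limitations

* The genealogy inference is greedy and deterministic, not probabilistic:
  it will not resolve ambiguous nestings a Bayesian method might, and on
  over-merged clusters it reports inconsistency rather than repairing it.
* The simulator's deterministic-growth assumption suppresses within-day
  drift; with very small bottlenecks the effective drift rate is set by
  the transfer, not by generations.
* Treatment-level reference data cannot validate per-replicate claims
  (see `refdata` above).
* Trajectory distances ignore measurement-error heteroscedasticity;
  at extreme frequencies (f near 0 or 1) binomial noise is smaller than
  the constant tolerance assumes.
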