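# Methods

## The model

The simulator reproduces the structure of a serial-transfer yeast evolution
experiment with an intracellular killer virus. Time is measured in host
generations. Each day a culture is diluted 1:2^g (g = 10 by default, i.e.
dilution factor 1024) into fresh medium and regrows to saturation, so each
transfer comprises exactly g doublings at an effective bottleneck size
N_b ≈ 10^5 cells. A host cell carries a pool of N_v ≈ 100 viral copies.

Three selective forces act simultaneously:

1. **Host-level selection.** A genotype with Malthusian coefficient s grows
   by a factor 2·e^s per generation. Fitness is defined, as in competition
   assays, as the slope of ln(count ratio) against generation, which makes
   e^s (not 1+s) the faithful growth model: a fitness difference of 0.05
   then yields a log-ratio gain of exactly 0.5 per 10-generation transfer.
2. **Toxin-mediated interference.** Killing is well-mixed and memoryless: a
   non-immune cell dies in a generation with probability κ·f_killer, where
   f_killer is the current frequency of toxin-producing cells and κ (the
   kill coefficient, default 0.2, dimensionless per generation per unit
   killer frequency) is a free parameter — no dose–response kinetics are
   published, so the simplest model producing positive frequency dependence
   is used, with optional saturation at probability 1. With a killer at
   frequency f competing against a susceptible clone with nuclear advantage
   s, the susceptible clone's per-generation log-ratio change is
   s + ln(1 − κf): the sign flips at f = (1 − e^{−s})/κ, which produces the
   bistable threshold analytically (≈ 0.76 for s = 0.05, κ = 0.2, in Late-
   clone frequency units) and is recovered empirically by the
   frequency-dependence regression (f* ≈ 0.76–0.77).
3. **Within-cell viral selection.** At each cell division the viral pool is
   resampled: N_v copies drawn with weights proportional to
   count × (1 + within-cell advantage). A cell produces toxin iff the
   fraction of toxin-functional copies is ≥ θ_K (default 0.5) and is immune
   iff the immunity-functional fraction is ≥ θ_I (default 0.05) — immunity
   derives from the unprocessed preprotoxin, so sparse functional copies
   suffice, which is why killing is always lost before immunity.

## Population-scale simulation

Population runs are cohort-based: the state is a table of cell counts per
(nuclear genotype, viral-pool composition), so runtime scales with the
number of distinct cohorts rather than with N_b. Growth and toxin death are
applied as expectations; stochasticity enters through (a) the daily
dilution, a multinomial draw of N_b cells over cohorts, (b) one multinomial
resampling of each heteroplasmic cohort's composition per generation (all
cells of a cohort share one realisation — an approximation that preserves
within-cell selection and drift at cohort resolution), and (c) Poisson
mutation events. Mutation supply is evaluated at the effective
(bottleneck) size rather than the transient census: lineages arising in the
excess above N_b are almost surely removed at the next dilution.

De novo viral variants draw their phenotype from a configurable effect
table (default: 60 % toxin-null/immune, 20 % null for both, 20 % silent;
within-cell advantages uniform on [0.02, 0.15]) and their nucleotide change
with transitions weighted 6.4 : 1 per transversion class. Nuclear
beneficial mutations arise at 4×10⁻⁷ per cell per generation with
exponentially distributed effects (mean 0.04), chosen to give a few
selective sweeps per 1000 generations as observed in such experiments.
Viral variants spread mainly by hitchhiking: a sweep founded in a cell
whose pool a toxin-null variant has taken over fixes that pool
population-wide.

Population phenotype grades map the fraction of toxin-producing (immune)
cells onto the halo-assay scale: full ≥ 0.75, weak ≥ 0.25, none below.
Under heavy clonal interference an interrupted sweep can make the
population-level killing grade dip to *weak* and later return to *full*;
the transition audit therefore distinguishes the strict ordering constraint
(immunity is never lost while killing is full — this holds in all
simulations) from grade increases, which occur only as interference noise
and are absent at default mutation supply. The wet-lab analogue is scoring
noise in population-level halo assays.

## Heteroplasmic lines

Single-cell-bottleneck propagation is simulated exactly as a random
root-to-leaf path: an unstructured colony after g doublings is a full
binary tree, so a uniformly sampled cell is reached by following one
daughter at random per division. Each division doubles the pool (2N_v
weighted draws with replacement, with per-copy mutation) and passes N_v
copies to the followed daughter by multivariate hypergeometric sampling.
The neutral limit is a martingale, so the fixation probability equals the
initial frequency; the neutral drift check uses N_v = 20 and 10 bottlenecks
of 20 generations so that nearly all lines reach absorption within the run.
Bottleneck spacing defaults to 20 generations (a 48-hour colony); the
true value is not published.

## Analysis conventions

- **Fitness.** OLS slope of ln(count_a/count_b) on generation; standard
  error from the regression (absent with two timepoints). Zero-count
  timepoints terminate the usable window and are reported as boundary
  outcomes rather than pseudocounted. Per-interval estimates treat each
  consecutive timepoint pair independently; frequency dependence is an OLS
  of interval fitness on interval starting frequency with a two-sided
  t-test at α = 0.01, and the equilibrium f* = −intercept/slope is reported
  only for a significantly positive slope with the crossing inside (0, 1).
- **Transitivity.** An observed long-range fitness is called negative when
  the estimate is below zero by more than twice its standard error (ties
  are conservatively transitive); the verdict is frequency-dependent
  nontransitive when significantly negative and positive outcomes coexist
  across tested starting frequencies. Deviations are reported against the
  sum-mode additive expectation.
- **Association.** Pearson χ² on the 2×2 table, uncorrected by default
  (the reconstructed mutation/killing-loss table [[57,0],[1,9]] gives 59.3
  uncorrected, matching the reported statistic); Yates correction is a
  flag.
- **Read counting.** Exact substring matching of the 11-nt flanked-allele
  probes (and their reverse complements); reads with errors inside the
  window fall into *unmatched* and are reported, not guessed. Wilson score
  intervals at 95 %. Coordinates are 0-based internally; 1-based at the CLI.
- **Spectrum.** Transitions are A↔G and C↔T; the χ² null is ts:tv = 1:2.
  The headline ratio R counts distinct substitutions (32:5 = 6.4);
  per-occurrence weighting (recurrent fixations counted each time) is
  available via the `weights` argument but gives a different ratio by
  construction. dN/dS is Nei–Gojobori (1986) proportions without
  multiple-hit correction — appropriate for these small counts — with
  stop-gains counted as nonsynonymous and the terminal stop codon included
  in site counts.
- **Trajectory classification.** *Transient* (rose near fixation, then fell
  to near loss) takes precedence over *lost* when both apply, since the
  displacement of one variant by a later competitor is the biologically
  distinct outcome being flagged. Thresholds (0.95/0.05, relaxation 0.25)
  are conventions exposed as arguments.

## Synthetic stand-ins and what tests do not show

The K1 ORF reference used in read-counting and effect-classification
fixtures is a synthetic 316-codon sequence (random sense codons,
constrained so the recurrent amino-acid changes P47S, D106G, G131D, D253N,
I292M are consistent), and the bundled substitution spectrum is a synthetic
reconstruction matching the published marginals (37 distinct substitutions,
32 transitions, recurrence counts 13/14/15). Effect labels and dN/dS values
computed **on these stand-ins** exercise the machinery but carry no
information about the real K1 sequence; only the marginal statistics
(recurrence sum 42, R = 6.4) are anchored to reported values. The
generator emulates demographic structure (dilution bottlenecks, within-cell
pools, toxin killing) but not real flow-cytometry gating artefacts, halo
scoring subjectivity, sequencing library biases, or the unknown
distribution of viral fitness effects, so passing tests validate the
estimators and the mechanism, not wet-lab measurement error models.

## Problem sizes and reproducibility

Default analysis runs use 40 populations × 1000 generations at
N_b = 10⁵ (cohort-based, ~1 s per population), 100 simulated competitions
for estimator recovery, 300 for the frequency-dependence null, and 500
heteroplasmic lines for the drift check. All randomness flows from a single
root seed through per-population/per-line `SeedSequence(seed, spawn_key)`
streams, so identical configurations give bit-identical outputs.

## Known limitations

- Toxin kinetics are memoryless with a single free parameter κ; no toxin
  accumulation, spatial structure, or dose–response saturation below the
  probability-1 clamp.
- The cohort approximation resamples each cohort's viral pool once per
  generation collectively; within-cohort cell-to-cell heterogeneity is not
  represented at population scale (the line simulator is fully per-cell).
- The within-cell advantage, κ, founding heteroplasmy fractions and the
  de novo effect table are placeholders constrained only qualitatively by
  the published observations; the population-level killing-loss fraction
  at generation 1000 (~0.3 under the default founding heteroplasmy) scales
  with these choices.
- No mating/recombination beyond the heteroplasmic-diploid setup, no
  sequence-level simulation of the full viral genome, and no
  phylogenetic-model dN/dS.
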