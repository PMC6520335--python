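# Methods

`scallop_popgen` reimplements, as one tested toolkit, the population-genomic
analysis of the European scallops *Pecten maximus* (an Atlantic and a
Norwegian group) and *P. jacobeus* (Mediterranean): SNP quality control,
population structure, genetic diversity, coalescent demographic inference
from the folded joint site-frequency spectrum (SFS), genotype–environment
association (GEA) scans with a two-method consensus, and neutral-versus-
candidate phylogenies. A synthetic-data generator emulates the study design
(14 populations along a European latitudinal cline, three lineages) so
every stage can be exercised and calibrated against known ground truth.

## Coalescent engine

The engine simulates one genealogy per SNP in a multi-deme coalescent
without migration. Time is measured in generations before present; sizes
are diploid effective sizes; a deme holding *k* lineages of size *N*
coalesces at rate *k(k−1)/2 · 1/(2N)* per generation, simulated in
continuous time with a next-reaction scheme (each deme carries an absolute
candidate event time, redrawn only when its lineage count changes or an
epoch boundary is crossed). Demography is described by demes (contemporary
size, historical size, growth onset) and events (`merge_demes`,
`set_size`, `start_growth`); growth between historical and contemporary
size is exponential by default, with an instantaneous mode per deme.

Mutations are placed with probability proportional to branch length,
conditioning every SNP on polymorphism; no mutation rate enters. Because a
SNP occurs on a genealogy with probability proportional to its *total*
length, sampling uses two passes: the first records genealogy lengths, a
length-weighted multinomial allocates the SNPs, and the second pass
replays the same genealogies (identical RNG consumption; mutation uniforms
come from a separate stream) and places the mutations. The finite batch
normalization leaves a relative bias of order 1/batch (batches are at
least 256 genealogies). The expected folded SFS is estimated by
accumulating every branch's absolute length into its folded frequency
class — the length-weighted (Rao-Blackwellized) estimator, with far lower
variance than one placement per genealogy — and normalizing.

Two consequences of conditioning on polymorphism matter downstream.
First, the expected SFS is *exactly* invariant to a joint rescaling of all
sizes and times (same-seed simulations are bitwise identical under
rescaling). Second, even with one size fixed, the likelihood surface
carries a broad plateau trading divergence time against refugial size
(a split *t* generations ago from refugium *N_h* is nearly
indistinguishable from a more recent split from a smaller, faster-growing
refugium). Both shape the inference protocol below.

## Demographic models

Three topologies over the demes ATL, NOR (the two *P. maximus* groups) and
JAC (*P. jacobeus*), all assuming post-glacial expansion (contemporary >
historical size per deme — enforced as a model constraint):

* **M1 (two refugia, 9 parameters)** — ATL and NOR split from the
  ancestral *P. maximus* lineage `t_div` generations ago, each expanding
  from its own refugial size; JAC split `t_dmj` ago. The ancestral
  *P. maximus* size is `Ne_hist_MAX`; above `t_dmj` the ancestor has
  JAC's historical size.
* **M2 (single refugium, 10 parameters)** — the *P. maximus* lineage
  begins expanding from its refugial size at `t_exp`; NOR is founded at
  `t_div` by a founder event (`t_div < t_exp < t_dmj`).
* **M3 (single refugium without growth before the split, 10
  parameters)** — as M2 but the lineage size plateaus between `t_exp`
  and `t_div`; group growth starts only at `t_div`, which is expected to
  be more recent (its default prior upper bound is halved).

M1 is the `t_exp → t_div` boundary of M2 and M3, which matters for model
selection (below).

Default parameter point (generator truth and documented defaults):
`t_dmj` = 95,000 and `t_div` = 3,700 generations — the study system's
point estimates — with sizes calibrated once against the simulator so
that realized between-lineage Weir–Cockerham FST falls in the empirically
observed ranges (0.03–0.09 between species, 0.02–0.05 within
*P. maximus*): `Ne_hist_JAC` = 800k, `Ne_cur_JAC` = 900k,
`Ne_hist_MAX` = 750k, `Ne_hist_ATL` = 20k, `Ne_cur_ATL` = 200k,
`Ne_hist_NOR` = 60k, `Ne_cur_NOR` = 120k diploids. These preserve the
qualitative claims (all lineages expanded; the *P. jacobeus* expansion
modest; the Norwegian refugium larger than the Atlantic one) but not
every printed ordering of contemporary sizes, which cannot be reconciled
with the FST ranges at the printed split times under a
polymorphism-conditioned SFS. Prior bounds are log-uniform: times
100–500,000 generations, sizes 100–1,000,000 diploids.

## Composite-likelihood fitting

The observed folded joint SFS is multinomial over polymorphic folded
entries; `lnCL = Σ m_e ln p̂_e` with Monte-Carlo entry probabilities.
Numerical choices:

* **Entry pooling** (`pool_min`, default 5): entries observed fewer than
  5 times are aggregated before the likelihood, as SFS likelihood
  implementations pool rare entries; this cuts the Monte-Carlo noise of a
  20,000-simulation evaluation from a standard deviation of ~100 to ~10
  log-likelihood units on a 20,000-SNP spectrum.
* **Zero floor** `p_min = 1e-8` for observed entries with estimated zero
  probability (floored entries are counted and reported).
* **Optimizer**: per independent run, a continuous adaptive Nelder–Mead
  search in log10-parameter space whose simulation seed is refreshed every
  `evals_per_cycle` evaluations (common random numbers within a cycle);
  starts are the best of a pool of log-uniform prior draws, optionally
  augmented with warm starts (`extra_starts`) from rival nested models.
  Invalid topologies incur smooth penalties rather than failures.
* **Polish and final comparison**: the winning run is refined with an
  objective that *averages probabilities across seeds before the log*.
  Averaging after the log leaves the Jensen bias of `E[ln p̂]`, which
  penalizes parameter regions with higher Monte-Carlo variance and biased
  divergence times downward by ~5% at 20,000 simulations (worse at fewer);
  probability averaging removes most of it. Runs and models are compared
  on a common probability-averaged evaluation.
* **AIC** is the plain composite-likelihood `2k − 2 lnCL` (natural log).
  The effective-parameter (sandwich) correction for composite likelihoods
  is not estimated; this is a documented divergence, and model ranking
  should be read accordingly.
* **Parametric bootstrap**: simulate-and-refit percentile CIs by default;
  a bias-corrected "basic" (reflected) interval is available and is the
  appropriate choice at heavily reduced fit settings, where the maximizer
  of the noisy likelihood is visibly biased and replicates inherit the
  bias.

**Identifiability and anchoring.** Absolute times are undefined without an
anchor (exact scale invariance), and remain practically unidentifiable on
a 20,000-SNP spectrum whenever the historical sizes float (the
divergence-time/refugial-size plateau: configurations with a several-fold
more recent `t_div` and correspondingly smaller, faster-growing refugia
fit as well as the truth). Analyses that report times in generations
therefore fix the effective sizes at their documented defaults (via
`ModelSpec.fixed`) and estimate the event times — mirroring how empirical
SFS studies anchor the absolute scale through external information (a
mutation rate, monomorphic-site counts, or independent size estimates).
With sizes anchored, profile analysis shows ±25% displacements of `t_div`
cost tens of log-likelihood units against a polish noise of ~3, and
recovery experiments at full protocol scale (40/40/20 haploid samples,
20,000 SNPs, 20,000 simulations per evaluation) recover both divergence
times within ~7%.

Model selection compares the three topologies with each candidate's sizes
fixed at its own documented defaults and its event times free. In their
size-free form the topologies are nested and selection is dominated by the
richer models chasing noise; with sizes specified, the generating model
wins the AIC ranking in ≥80% of replicate datasets at reduced settings.

## Synthetic data generator

One deme per population; populations within a lineage merge shallowly
(Atlantic 300, Norwegian 50, Mediterranean 500 generations ago) into a
carrier deme that follows the two-refugia history above. An optional
recent bottleneck reproduces a Mulroy-Bay-like outlier population.
Defaults: 14 populations with the study's post-QC sample sizes (219
individuals), 10,000 SNPs, 150 environmentally associated loci.

The environment table has 15 statistics (min/max/mean annual chlorophyll,
dissolved oxygen, salinity, sea-bottom and sea-surface temperature) plus
latitude and longitude. Mean SST decreases strictly with latitude before
noise; mean DOC increases with it (cold water holds more oxygen), so the
two drivers are strongly anticorrelated, as in the real system.

Environmentally associated loci are spiked by post-hoc per-population
frequency shifts of `adaptive_effect` (default 0.15) per standard
deviation of the driving variable (alternating mean SST / mean DOC),
followed by Hardy–Weinberg resampling within populations; shifts outside
[0, 1] are clamped with a warning. Only loci with intermediate pooled
frequency (0.10–0.90) are eligible — rare-variant shifts would clamp away
and real detectable clines sit at common variants. Ground truth (locus
ids and drivers) is returned. Per-call depth is negative-binomial (mean
16, matching the study's coverage), genotype quality a noisy monotone map
of depth, missingness and genotype errors are applied last.

What the generator does **not** emulate: linkage between SNPs within RAD
tags (every locus is an independent genealogy; the LD-pruning step is
exercised only by chance correlations), selection dynamics (spikes are
post-hoc), sequencing batch effects, and within-population kin structure.
Passing calibration tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to every real-data
artifact.

## Quality control

The chain follows the study's stated order and strictness: biallelic SNPs
only; calls with GQ ≤ 5 or DP ≤ 5 masked; site call rate ≥ 80%; loci with
mean depth > 2× the raw-dataset mean removed; individuals with > 20%
missingness removed; MAF > 0.01; Hardy–Weinberg exact test (standard,
non-mid-p cumulative test; pooled sample by default, population-stratified
mode available — pooled testing on structured data removes strongly
clinal loci via the Wahlund effect, which is why GEA calibration
experiments run on unfiltered generator output) at α = 0.05; greedy
windowed LD pruning at r² > 0.5 (window 50, step 5, lower call rate
removed, at most one SNP per RAD tag, passes iterated to a fixpoint so the
operation is idempotent). r² is computed on mean-imputed dosages.

## Structure and diversity

Pairwise FST is the Weir–Cockerham (1984) two-population θ combined as a
ratio of summed variance components; significance by permutation of
individuals (add-one convention by default), with table-wide Bonferroni
correction over the pairs actually tested. Note that sample-based θ runs
a few percent *below* the drift expectation 1 − exp(−t/2N); the engine
agrees with an independent simulator (msprime) to within Monte-Carlo
error. PCA mean-imputes missing dosages, centers columns, and fixes each
component's sign by its largest-magnitude loading. The coancestry matrix
is mean allele sharing per pair over co-typed loci — a transparent
surrogate for haplotype-painting coancestry, labelled as such — clustered
by UPGMA.

Rarefied NPL draws five individuals with replacement 1,000 times per
population (the smallest population has exactly five members, so
without-replacement draws would be constant; a without-replacement mode
exists and reproduces the observed polymorphic count at full sample
size). MLH is the raw proportion of typed loci heterozygous (sMLH
available). Group comparisons use one-way ANOVA; latitude relationships
use OLS r².

## Environment association

The **latent-factor scan** regresses each locus dosage on the
standardized variable plus K latent factors (default K = 3, one per major
lineage boundary). Factors are leading left singular vectors of the
dosage matrix after *partial* (0.5) residualization on the variable — the
ridge-penalty analogue of joint latent-factor solvers. The shrinkage was
calibrated on synthetic truth: full residualization leaves the large
environment-collinear drift axes in every locus's slope (genomic
inflation λ ≈ 3.6, power 0.49), none lets the factors swallow the signal
axis (power 0.01), and 0.5 absorbs the dominant lineage axes while mostly
sparing the weaker adaptive cline. Z scores from five runs (randomized
imputation of missing calls) are combined by the median; λ =
median(z²)/0.455 recalibrates (floored at 1 — deflation is noise);
p-values use the exact t reference; Benjamini–Hochberg at α = 0.01.
At the frozen default effect size the scan's spiked-locus power is ~0.80
with neutral false flags ≤ 0.1%; most misses are loci whose realized
frequency/environment correlation is genuinely weak after binomial
resampling.

The **covariance scan** standardizes population frequencies per locus and
models them as multivariate normal with covariance Ω (across-locus
covariance of standardized frequencies, eigenvalue-floored). The Bayes
factor integrates a N(0,1) slope prior on a dense grid and is reported in
deciban; the decision threshold is 10 dB ("strong evidence"; the raw-BF
reading of the threshold is available). Ω should be re-estimated on a
control set (`control_set_omega`: one trimming round dropping loci with
first-pass BF > 5 dB); estimating Ω over all loci absorbs real signal
into the covariance and costs ~15 points of power. Under the null ≤5% of
loci exceed 10 dB; spiked-locus power is ~0.9.

Candidates are the **intersection** of the two methods' union-over-
variables sets. Variable importance is ranked by mean locus-frequency r²
against each variable, z-standardized against a population-permutation
null — a transparent stand-in for tree-ensemble importance, labelled as
such in outputs.

## Trees

Allele-sharing distance (1 − mean proportion of shared alleles per
co-typed locus) feeds a Saitou–Nei neighbor-joining implementation
(negative branch lengths clamped to zero, Q-ties joined at the lowest
index pair), exact on additive matrices. Locus bootstrap support is the
percentage of replicate trees containing each internal bipartition of the
full-data tree. Neutral and candidate-locus trees are compared by
unweighted Robinson–Foulds distance (dendropy's bipartition machinery).

## Reproducibility and problem sizes

Every stochastic operation takes one integer seed; the pipeline expands a
global seed into independent per-stage streams, so changing one stage's
settings does not perturb another's draws. The test suite runs reduced
problem sizes chosen for a desk-scale run (e.g., recovery at 24/24/12
haploids and 8,000 SNPs; model selection at 16/16/8 and 5,000 SNPs with 5
seeds per generating model; bootstrap coverage with 5 truths × 16
replicates; GEA power over 10 generator seeds at 4,000 SNPs), while the
acceptance script uses the full documented protocol (40/40/20 haploids,
20,000 SNPs, 10 runs × 20 cycles × 20,000 simulations per evaluation).

## Known limitations

* The coalescent engine supports no migration or admixture (the three
  study models contain none) and no within-locus recombination.
* Composite-likelihood AIC without the sandwich correction overstates
  support differences when SNPs are not independent.
* The simplified coancestry, variable-importance and latent-factor
  components are deliberate transparent surrogates for fineRADstructure,
  gradientForest and the Gibbs-sampler LFMM respectively; they reproduce
  the analysis roles, not the algorithms.
* Absolute demographic times are meaningful only relative to the anchored
  sizes; with a different anchor the times rescale proportionally.
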