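# Methods

This note documents the models, conventions and design choices behind
`mitopop`, in the order the analysis chain runs.

## Sequence handling

Alignments are rectangular matrices over `{A, C, G, T, -, N}` with one
record per specimen and a sampling-site label.  Missing data follow
*pairwise deletion* by default (`ignore_missing_sites`): a site missing in
either member of a pair is skipped for that pair; `strict_identity` treats
`-`/`N` as ordinary states.  Haplotype collapsing under the missing-tolerant
rule assigns each sequence to the first existing haplotype it is compatible
with (agreement at all jointly called sites).  Compatibility is not
transitive, so the assignment depends on record order; it is deterministic
for a given input, and the strict rule is available when exact identity is
wanted.  Block excision (e.g. removing a tandem duplication present in a
few records) is an explicit user-invoked operation with 1-based inclusive
coordinates, never automatic outlier detection.

## Diversity and neutrality

* `h` uses Nei's small-sample correction `n(1 − Σp_i²)/(n − 1)`; with all
  haplotypes unique it equals exactly 1.
* `θ̂_π` is the mean pairwise difference count per locus over specimen
  pairs; `π = θ̂_π/L` with `L` the alignment length.
* Tajima's `D` uses the standard a₁…e₂ constants; it is undefined (NaN
  sentinel, never numeric 0) when `S = 0`.
* Fu's `F_S` evaluates the Ewens sampling distribution
  `P(K = j) = |s(n, j)| θ^j / θ^{(n)}` with unsigned Stirling numbers of the
  first kind computed by a log-space recurrence (stable to n = 300, far
  beyond the study's largest sample of 52).  The θ plugged in is `θ̂_π` per
  locus, the convention of the statistic's definition; `F_S` is undefined at
  `k = 1`.
* P-values are lower-tail (negative, expansion-like values are "small") and
  come from neutral constant-size coalescent replicates at `θ = θ̂_π`.
  Conditioning on the observed `S` instead (placing exactly S mutations per
  genealogy, multinomially by branch length) is available; the default is
  θ-conditioning.  Replicates use the exchangeable coalescent with
  infinite-sites mutations tracked on branches, so S, θ̂_π and the haplotype
  count are exact functions of the genealogy plus mutation placement.

Verification: the Ewens machinery is tested against an exact-rational
(integer Stirling + `fractions.Fraction`) enumeration for n ≤ 10, and the
printed survey values cross-check well — e.g. the Cabo Verde sample
(n = 52, k = 21, θ̂_π = 0.0049·637) gives F_S = −10.62 against the printed
−10.695, the gap attributable to π being printed at two significant
figures.

## Mismatch distributions and expansion models

The expected distribution of pairwise differences is derived from the pair
coalescent in mutational time (x = 2ut):

* **Sudden expansion** `(τ, θ₀, θ₁)` — coalescence hazard `1/θ₁` until
  `x = τ`; survivors fall into the ancestral equilibrium, a geometric law
  with mean `θ₀`, carrying Poisson(τ) additional mutations.  The
  within-epoch piece integrates to an incomplete-gamma closed form; the
  survivor piece is a Poisson⊗geometric convolution.  At `τ = 0` (or
  `θ₀ = θ₁`, `τ` arbitrary) the law reduces exactly to the equilibrium
  geometric `θ^i/(1+θ)^{i+1}`.
* **Spatial expansion** `(τ, θ, M)` — at `τ` a single deme seeds an
  infinite island array of demes of size θ exchanging migrants at scaled
  rate `M = 2Nm`.  A co-deme pair coalesces (hazard `1/θ`) or separates
  forever within the epoch (hazard `2M/θ`); separated and surviving pairs
  join the ancestral equilibrium at `τ`.  `M = 0` reduces exactly to the
  sudden model with `θ₀ = θ₁ = θ`; `M → ∞` approaches a pure
  Poisson(τ)⊗geometric law.

Both laws were validated against Monte-Carlo simulation of the generating
process (max absolute class deviation at MC-error level) and sum to 1 over
the full support.

**Fitting** minimises `SSD = Σ_i (obs_i − exp_i)²` over the observed
support (trailing empty classes trimmed; expected tail mass beyond the
support is simply absent, making SSD invariant to padding).  The SSD
surface is multimodal, so a coarse grid (τ linear, θ and M logarithmic)
seeds Nelder–Mead refinement with τ clipped at 0 and the positive
parameters in log space.  Sudden-model θ₁ estimates beyond 99 999 are
reported as the conventional "effectively infinite" cap.  A single-class
distribution degenerates to τ = 0 with a warning.

**Goodness of fit** is a parametric bootstrap that simulates full
*coalescent samples* of the same size under the fitted model — a bespoke
structured pair-coalescent builds the n-sample genealogy (within-deme
coalescence, emigration to a migrant pool, epoch collapse at τ) and lays
Poisson mutations on branches — then refits and compares SSD and
Harpending's raggedness `r = Σ(x_{i+1} − x_i)²` (with a closing step to 0).
Resampling pairs independently would ignore the genealogical correlation
between pairs and make the observed SSD look spuriously extreme; the
coalescent bootstrap is calibrated (P approximately uniform on model-true
data, verified by KS test in the suite).

**τ recovery** is tested on multinomial resamples from the model law
itself (identifiability of the fitter), achieving ~12%/6%/3% median
relative error at τ = 1/5/25 with 50-sequence pair counts.  On fully
coalescent data the genealogical variance of the mismatch is much larger —
a whole-sample history is a single draw — so per-dataset τ̂ scatter is
wide; this is a property of the estimator, not the optimizer.

## Differentiation, IBD, Mantel

Pairwise F_ST is the two-population AMOVA variance ratio computed from a
specimen-level distance matrix: haplotype identity (conventional F_ST,
default, as frequency-based surveys report) or pairwise difference counts
(Φ_ST).  Significance permutes specimens between the two sites
(default 10 100 permutations, the survey's setting), counting the observed
configuration once and ties at the observed value as extreme; on small
discrete samples the identity flavor therefore ties heavily and its P is
valid but conservative, while the difference-weighted statistic is
effectively continuous and calibrates uniformly.  Negative estimates are
retained everywhere — clamping would bias the significant-pair mean and
the regression inputs.

Isolation by distance regresses `F/(1 − F)` on `ln(km)` over all site
pairs (OLS), with great-circle (haversine, R = 6371 km) distances; a
Mantel test (joint row/column permutation, one-sided for positive
association) runs on the same matrices.  Zero-distance pairs are dropped
with a warning.

**Known deviation.**  On the published F_ST matrix and site coordinates
this method gives R² = 0.651 (Mantel r = 0.807), against the printed
R² = 0.5482 (r = 0.7627).  The survey does not state its distance metric;
no plain variant (raw vs linearized F_ST, log vs linear distance, either
reading of the degree/minute coordinate typography) reproduces 0.5482, so
the published distances were presumably sea-route or otherwise adjusted.
The package reports what the stated method yields; the acceptance suite
keeps the comparison against 0.5482 as an explicit failing check rather
than silently widening the tolerance.  Coordinate note: one printed
latitude ("32°63'") cannot be degrees+minutes and is read as 32.63°; the
competing parses change R² by < 0.003.

## Median-joining networks

The minimum spanning network is built by levelwise Kruskal with lagged
union: at each weight level every edge joining components *as they stood ε
levels earlier* is admitted, so tied (and with ε > 0 near-tied)
alternative connections are retained.  Median joining then repeatedly
proposes the per-site majority consensus of each connected triplet (ties
at a site resolve to the hub node's state), inserts the candidate whose
inclusion most shortens the network (ties broken lexicographically), and
stops when no insertion strictly shortens it — total length is a
decreasing integer, so termination is guaranteed.  Obsolete medians
(degree ≤ 2, removal not lengthening) are pruned.  Defaults ε = 0 and
uniform site weights.

Haplogroups: remove the heaviest bridge edge (or all bridges above a
mutation threshold); specimens inherit their haplotype's component, and
the larger component is labelled α by convention.  A network whose every
edge lies on a cycle has no bridge and raises an explicit
ambiguous-partition error instead of guessing.

## Dating

Rates are carried per site per year internally.  The chain:
`μ_cal = d_net/(2T)` from a geminate (trans-isthmian) clade pair or a
model-based clock value; `μ_target = μ_cal · θ_target/θ_cal` (effective
size cancels for loci sequenced in the same specimens);
`t_years = τ/(2 μ L)` with `t_generations = t_years/g` — the generation
time g affects only the generation count, asserted explicitly in the
suite.  L defaults to the 637-site control-region alignment.  The
printed-inputs chain rounds the transferred rate to its three printed
significant figures (5.44×10⁻⁸) before dating, matching the precision at
which the published arithmetic was carried; full precision would shift the
oldest date by 0.1 Kya.

## Synthetic data generator

`simulate_dataset` emulates the survey's structure: six sites at the
survey coordinates with n = 44–52 (296 total), L = 637, AT fraction
0.8235, two haplogroup founders exactly 25 mutations apart, haplogroup-α
site frequencies following an opposing cline (0 at the northernmost site
to 1 at the southernmost, ≈50/50 globally), and per-haplogroup sudden
expansions with τ_α = 4.1, τ_β = 1.2 and present-day θ_α = 3.7, θ_β = 1.0
(θ matched to the printed per-haplogroup π·L; expansion ratio 10³).
Genealogies come from msprime (haploid, single locus) with population size
θ/2 so one branch-time unit is one mutational-time unit; mutations are
dropped by the package's own finite-sites equal-input model (rate i→j ∝
stationary frequency of j, AT-biased stationary), which keeps tip
composition at the target — the founder is drawn with exactly the target
base counts so composition is a pinned design property, not a per-dataset
random variable.  Clinal structure is imposed by binomial founder mixing
per site rather than an explicit migration matrix: truth bookkeeping stays
exact, at the price of no within-haplogroup geographic signal (see
limitations).

What passing tests on these data do show: correct statistic arithmetic,
calibrated permutation/bootstrap P-values, recoverable haplogroup
structure, and monotone F_ST/IBD responses to configured divergence.  What
they do not show: robustness to alignment error, indels and sequencing
artefacts; recombination (absent in mtDNA by assumption); selection;
within-haplogroup isolation by distance (the generator is panmictic within
haplogroups, so simulated IBD reflects the cline only).

## Numerical conventions

Probabilities from permutations and bootstraps include the observed
configuration (`p ≥ 1/n_perm`); undefined statistics propagate as NaN
sentinels; every stochastic entry point takes a seed and the pipeline
derives per-stage seeds from the config; report files embed a config hash
so reruns are byte-identical.  Expected-mismatch evaluation guards
θ → 0 with an ε floor of 10⁻⁹; the fitter caps exponentials at 10×99 999
to avoid overflow.  Test problem sizes (e.g. 2000 neutral replicates for
the D calibration, 30 fits per τ for recovery, 10 datasets for assignment
accuracy) were chosen to put Monte-Carlo error well inside the asserted
bands at interactive runtimes.

## Known limitations

* Identity-F_ST permutation P is conservative on very small, low-diversity
  samples (tie mass at the observed statistic); use Φ_ST when calibrated
  tail behaviour matters.
* The spatial-model M estimate is weakly identified when the observed
  distribution is compatible with θ₁ → ∞ sudden expansion (the two limits
  coincide); τ remains well determined.
* Median-joining inserts one median per round (globally best); on heavily
  reticulate data this is slower than batch insertion but deterministic.
* Geographic distances are great-circle; least-cost sea routes are not
  implemented, which is the leading explanation for the IBD R² deviation
  documented above.
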