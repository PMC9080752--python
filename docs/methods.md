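# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
package's numerical choices and known limitations.

## Sequence handling and site numbering

Opsin residues are named in bovine rhodopsin coordinates: the shipped
348-residue bovine reference (checked internally for the K296 retinal
attachment site, the E113 counterion and the C110/C187 disulfide pair) is
globally aligned to each query and every bovine residue column carries its
1-based position. Alignment is Needleman–Wunsch with BLOSUM62, affine gaps
(open 10, extend 1), implemented with Biopython's `PairwiseAligner`; ties are
broken by taking the first optimal alignment in the aligner's deterministic
ordering. Pairwise alignment stands in for a multiple alignment on the
grounds that opsins within a class are ≥85% identical, where pairwise and
multiple alignments assign identical site homology; this is an assumption,
not a theorem, and breaks down for divergent or partial sequences (those are
flagged when fewer than half the bovine sites are covered).

Translation uses the standard genetic code; a trailing stop codon is trimmed,
an internal stop is a hard error naming the codon, and codons containing N
translate to X unless every resolution agrees. X never matches anything:
identity fractions exclude X columns from numerator and denominator.

Transmembrane helix ranges (seven intervals in bovine numbering, shipped as
editable YAML) gate the polarity-candidate flagging. They come from the
bovine rhodopsin crystal structure; users with a different helix definition
can substitute their own.

## λmax prediction

Predictions are strictly additive: reference λmax plus the sum of per-site
shifts. Two rules assign shifts. *Documented*: the exact (site, from, to)
exchange is in the tuning table. *Polarity-matched*: the exchange is not in
the table but changes side-chain polarity in the same direction as a
documented exchange at the same site, whose shift is borrowed. Exchanges at
known sites with no polarity change get nothing. When several polarity-matched
rows disagree on the shift, nothing is applied and the substitution is
reported as ambiguous — auditable predictions were preferred over averaging.

The polarity scheme is a two-class table (polar: S T C Y N Q D E K R H W;
nonpolar: A V L I P F M G). C and W are borderline in the literature; both
are classed polar here, C because its thiol hydrogen-bonds in the retinal
pocket. The table is an argument everywhere it is used.

Candidate flagging returns polarity-changing substitutions inside
transmembrane helices at or within `proximity` residues of a known tuning
site of the class (default 2 — "close to" a site is not a sharp notion, and
two residues is under one helix turn).

The shipped tuning table contains only effects with in-vitro support quoted
for these opsin classes (RH1 299 S→A −2; SWS2 265 W→T −29, 46 F→V +8; RH2
88 M→C +3, 88 C→A −3, 112 I→V +1, 266 T→V −2, 185 T→C −4, 97 T→A −8,
151 N→S +4). It is deliberately not exhaustive: predictions for pigments
whose tuning depends on effects outside this table (notably SWS2B and the
absolute RH2C values) will differ from fuller tables, and users should extend
the TSV for their system.

Reference pigments must be supplied with their λmax (502/425/472/528/560 nm
are the conventional percomorph reference values for RH1/SWS2B/RH2B/
RH2A/LWS). Because real reference coding sequences cannot be bundled, the
test-suite and acceptance inputs build *synthetic* reference opsins: the
bovine scaffold with the relevant tuning-site residues planted. Only
substitution bookkeeping and shift arithmetic are exercised by these; they
are not biological sequences.

## Expression quantification

R/L length normalisation, rod share of the total, and within-class fractions
are exact arithmetic; all proportions are scale-invariant in total read
depth. Genes with zero counts stay in profiles with proportion 0 — trace
opsins must not vanish. Group summaries report mean ± s.e.m. (sd/√n, n−1
denominator) as percentages; a group of one is reported with s.e.m. 0 and an
explicit `sem_undefined` flag. T_opsin includes all supplied opsin genes,
including zero-count ones (they contribute 0).

## Photoreceptor templates and quantum catch

Sensitivities use the standard A1 visual-pigment absorbance template — an
alpha band that is a sum of exponentials in x = λmax/λ with a λmax-dependent
long-wave limb, plus a Gaussian beta band whose position and width scale with
λmax — peak-normalised on a 300–750 nm, 1 nm grid. For λmax below ~390 nm the
beta band skews the discrete summit one grid point short of λmax (≤0.14% in
value); the curve is kept faithful rather than renormalised, and the peak
check allows that single-step skew. Measured sensitivities can be supplied as
CSV spectra instead.

Quantum catches integrate reflectance × illuminant × sensitivity by the
trapezoidal rule on the intersection of the spectra's supports, resampled
linearly at the finest step present. Normalisation is to an ideal 100%
reflector under the same illuminant, so illuminant scaling cancels; no von
Kries receptor adaptation is applied. The double-cone luminance signal is the
arithmetic mean of the two members' normalised catches, and the isoluminance
gap is |Qa − Qb| / mean(Qa, Qb). Published catch values for printed stimuli
are usable directly as inputs to the gap via `relative_gap`; reproducing them
from first principles would require the original measured spectra.

## Stereology and topography

The whole-mount optical fractionator reduces to Σ counts × (grid² / frame
area): section and height sampling fractions are 1 for 2-D counting.
Frame/grid defaults in the synthetic generator are a 50 × 50 µm frame and a
0.65 mm grid, tuned so a ~5 × 4 mm retina yields on the order of 150–200
sites, the conventional design that keeps the Scheaffer CE below 0.1. The
Scheaffer CE is the systematic-sampling ratio-estimator form, algebraically
sem/mean of the per-site counts.

Density maps are Nadaraya–Watson Gaussian-kernel smoothers of per-site
densities (bandwidth σ defaulting to the sampling grid step, raster at half
the grid step), masked to the retina outline. This weighted-average form
reproduces flat fields exactly and behaves like reflective edge handling
inside the mask; it is not spatstat's edge-corrected kernel density, and
integral mass agreement with the fractionator is approximate (tested to 5%).
Peak density follows the sub-sampling protocol: the provisional peak on the
coarse grid is refined by taking the maximum site density within 1.5 grid
steps, including half-step subsample sites. Note the maximum of ~10–20 noisy
Poisson site densities is biased slightly upward; with ~100 cells per frame
at the peak this bias is a few per cent.

SRP uses a = arctan(1/f) degrees per mm of retina, f = 2.55 r (Matthiessen's
ratio), linear density √D, two cells per cycle: SRP = (√D/a)/2. No amacrine
correction is applied by default; `density_correction=0.76` reproduces the
convention of discounting displaced amacrine cells. `lens_radius_for_srp`
inverts the formula exactly, used for round-trip consistency checks when lens
radii are not recorded. The regular cone mosaic (one single cone per unit
cell, four double cones shared pairwise between cells) is constructed as a
periodic lattice; counting unique positions gives the 2:1 double:single
ratio.

Coordinates are millimetres with the origin at the retina centroid and
temporal direction +x.

## Psychophysics

The psychometric model is logistic between a fixed guess rate γ = 0.5
(two-passage forced choice) and 1, with lapse rate 0 and performance
*decreasing* in spatial frequency: ψ(x) = γ + (1−γ)·expit(−β(x−α)). Fitting
is Bernoulli maximum likelihood on aggregated per-level counts (L-BFGS-B with
analytic gradients, nine spread starting points, slope bounded at |β| ≤ 50).
A likelihood maximum on the parameter boundary marks separated or degenerate
data (`separation` flag); a best-fitting non-positive slope marks
monotone-wrong data (`non_monotone` flag). The fit runs on linear spatial
frequency by default; `log_frequency=True` fits on ln(x) and reports
thresholds back in cpd.

The threshold criterion is recomputed, not assumed: the smallest k/n whose
exact one-tailed binomial tail at chance falls below α (62% for n = 110,
α = 0.01). Threshold inversion is closed-form,
t = α + ln((1−c)/(c−γ))/β. Confidence intervals are percentile parametric
bootstraps (binomial redraws at each level from the fitted ψ, refit warm-
started at the parent estimates); runs failing to refit or fitting
monotone-wrong count as failures, and more than 10% failures aborts. A single
integer seed drives each bootstrap.

Treatment comparison uses permutation tests on mean threshold differences:
sign-flips of within-fish differences when the design is fully paired,
treatment-label permutation across fish otherwise, with exact enumeration
whenever the permutation space fits the requested count. A mixed model was
deliberately not used: with 4–5 fish per treatment, exact permutation is the
more defensible inference at this scale.

## Synthetic generators

Noise models are the minimal consistent choices: multinomial reads (per-gene
probability ∝ proportion × CDS length, so length normalisation recovers the
proportion), Poisson frame counts (small integers per frame), Bernoulli
choices, deterministic sequence mutation. Named scenarios fix the study
conditions: expression scenarios plant a 68.9% rod share and the
aquarium/field double-cone splits (60.30/27.38/12.14/0.18% and
35.04/45.89/17.34/1.70%), with single cones taking one third of the cone
share in line with the 2:1 double:single mosaic — the molecular single:double
expression split is otherwise unconstrained, and only within-class fractions
and the rod share are treated as estimable. Acuity scenarios plant 3.94 cpd
(gratings 0.5–5 cpd, slope 1.2 cpd⁻¹) and 1.71 / 1.89 cpd (0.5–3 cpd, slope
2.0 cpd⁻¹) with 110 trials per grating; slopes were chosen so the planted
observers produce CI widths comparable to the behavioural study's (~±13%).
The retina scenario plants a 38,643 cells mm⁻² temporal peak over an 8,000
background with 3× horizontal elongation.

The generators emulate sampling noise, not biology: no individual variation,
no session or side-bias structure in trials, no retinal shrinkage or
histology artefacts, no sequencing error or mapping ambiguity in reads.
Passing recovery tests therefore shows the estimators are correct and
well-calibrated under their assumed noise models — not that those models
exhaust real data.

Determinism contract: identical (scenario, seed) produce byte-identical
outputs; every generator returns a ledger of planted truths, and recovery
tests read truths only from ledgers.

## Problem sizes

Recovery and calibration tests use 100 psychometric replicates with 200
bootstrap resamples each, 200 synthetic retinas for fractionator
unbiasedness, ~150–200 counting sites per retina, 10⁶ reads for expression
recovery, and 25–60 replicate draws where an empirical standard error is
needed. These sizes give stable pass/fail behaviour for the properties
tested while keeping the default suite fast.

## Known limitations

- Additive tuning ignores documented synergistic site interactions; pigments
  tuned by effects missing from the shipped table will be mispredicted by
  the size of the missing effects.
- The polarity-match rule transfers a shift measured for one exchange to a
  chemically different exchange; it is a screening heuristic, not a
  quantitative model.
- The A1 template approximates measured sensitivities; ocular media and
  corneal filtering are not modelled.
- The Nadaraya–Watson map is a smoother, not a density estimator with exact
  edge correction; iso-density contours near the retinal margin are
  approximate.
- SRP is an upper bound: it assumes every counted cell contributes to acuity
  and exact Matthiessen optics.
- Bootstrap CIs are percentile intervals; no bias correction is applied.
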