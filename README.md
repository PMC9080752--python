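# ovk — opsin and vision toolkit

`ovk` is a Python package for characterising the visual system of a teleost
fish from molecular, anatomical and behavioural data. It was built around the
kind of integrative study done on reef fishes such as the Picasso triggerfish
(*Rhinecanthus aculeatus*), where the same animal is described by its opsin
repertoire, opsin expression, photoreceptor spectral sensitivities, retinal
cell topography and behavioural acuity. It is aimed at visual ecologists and
sensory biologists who want each of those stages as a testable, scriptable
unit.

## What it computes

**Spectral tuning (`ovk.spectral_tuning`).** A visual pigment's peak
absorbance λmax is predicted from a reference pigment with a known λmax by
adding documented tuning-site shifts:

    λmax(query) = λmax(reference) + Σᵢ Δλᵢ

where each Δλᵢ is the shift of a substitution the query carries at a known
tuning site, in bovine-rhodopsin residue numbering (e.g. S299A → −2 nm).
Undocumented exchanges at known sites are assigned the documented shift when
they reproduce its side-chain polarity transition; polarity-changing
transmembrane substitutions near tuning sites that receive no shift are
flagged as candidates. Sequence handling (translation, Needleman–Wunsch
global alignment with BLOSUM62, bovine site numbering) lives in
`ovk.opsin_sequences`.

**Opsin expression (`ovk.expression`).** Read counts are normalised to
coding-sequence length, Rᵢ,norm = Rᵢ/Lᵢ; the rod proportion is
Rrod,norm / Σ Rᵢ,norm, and per-gene proportions within single- and
double-cone classes are fractions of the class total.

**Quantum catch (`ovk.visual_models`).** Receptor sensitivities come from the
standard A1 pigment template at a given λmax; the quantum catch of a surface
is ∫ R(λ) I(λ) S(λ) dλ, reported as a percentage of an ideal white reflector.
The mean of the two double-cone members models the luminance channel used to
check stimulus isoluminance.

**Retinal topography and anatomical acuity (`ovk.retinal_topography`).**
Optical-fractionator population estimates, Scheaffer coefficients of error,
Gaussian-smoothed density maps, and the spatial resolving power

    SRP = (√D / a) / 2,   a = arctan(1 / f) in degrees,   f = 2.55 r

with D the peak ganglion-cell density (cells mm⁻²), r the lens radius in mm
and 2.55 Matthiessen's ratio.

**Behavioural acuity (`ovk.psychophysics`).** Two-alternative grating choices
are fitted with a logistic psychometric function ψ(x) = γ + (1−γ)/(1+e^{β(x−α)})
(guess rate γ = 0.5) by maximum likelihood; the acuity threshold inverts ψ at
the smallest proportion significantly above chance under an exact one-tailed
binomial test (62% at n = 110 trials per grating, p < 0.01), with parametric
bootstrap CIs and permutation tests between treatments.

**Synthetic data (`ovk.synthetic`).** Every stage has a generator that plants
known truths (substitutions, proportions, density surfaces, observer
thresholds) and records them in a ledger for recovery testing.

## Worked example

Simulate a behavioural experiment at the study's achromatic conditions
(gratings 0.5–5 cpd, ~110 trials per grating, planted threshold 3.94 cpd) and
estimate the fish's acuity:

```sh
$ ovk simulate achromatic_acuity --seed 3 -o sim
$ ovk acuity --trials sim/trials.csv --boot 150 --seed 2
achromatic/pooled: 4.01 cpd (95% CI 3.67-4.31) at criterion 0.618
```

The criterion 0.618 is recomputed from the pooled per-grating trial count
(68/110 successes is the smallest significantly non-random proportion), and
the recovered threshold 4.01 cpd sits inside the bootstrap CI around the
planted 3.94 cpd.

The anatomical counterpart, from a simulated ganglion-cell whole-mount with a
horizontal streak and temporal peak:

```sh
$ ovk simulate ganglion_streak --seed 4 -o ret
$ ovk topography --sites ret/sites.csv --lens-radius 1.55
sites: 148 (+9 subsample)
total population: 1,111,851
Scheaffer CE: 0.0433
peak density: 46,000 cells/mm^2
SRP: 7.55 cpd (f = 3.95 mm)
```

A CE below 0.1 marks adequate systematic sampling; the SRP is the anatomical
upper bound on acuity implied by the peak density and a 1.55 mm lens.

λmax prediction from sequences:

```sh
$ ovk align --query q.fa --reference ref.fa -o aln.fasta
S299A
identity: 0.997
$ ovk predict-lmax --query q.fa --reference-set refs.fa
rh1_q: 500 nm
```

A rod opsin differing from a 502 nm reference pigment only by S299A is
predicted at 500 nm (documented −2 nm shift).

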