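# Methods

## Helix–coil model

Each of the `n_res` residues of a homopolymer peptide is helical (h) or
coil (c). Terminal residues are held in the coil state (the classical
Lifson–Roig end treatment), so only the `n_res − 2` interior residues carry
statistical weight. A maximal run of m consecutive h-residues has weight
v²·w^(m−2) for m ≥ 2 and v for m = 1; coil residues contribute 1. Runs of
m ≥ 3 residues are helical segments spanning n_H = m + 1 peptide units (the
amide chromophores flanking the run); runs of one or two h-residues pay
their nucleation cost but are spectroscopic coil, matching the convention
that conformers with n_H < 4 units contribute to the coil signal. Blocked
peptides (N-acetyl, C-amide) have N_pep = n_res + 1 units.

Rather than a transfer matrix, the ensemble is enumerated by **run-length
combinatorics**: a conformer class is the multiset of its h-run lengths
{m₁…m_r}, whose degeneracy is the number of distinct orderings of the
multiset times the stars-and-bars count C(L − M + 1, r) of coil-separated
placements in an interior of length L (M = Σmᵢ). This yields every class
weight as a single monomial Ω·v^n·w^m, keeps all segment counts exact (no
truncation at double helices), and costs one integer partition enumeration
instead of 2^L states. A 2^L brute-force enumerator is retained as an
oracle and the two agree to 1e-12 relative for every chain up to 14
residues over the working (v, w) grid. Weights are evaluated in log space
so chains of 50+ residues at large w do not overflow.

**Mean helicity** is reported as the probability-weighted fraction of
*residues* in helical runs (runs ≥ 3, divided by n_res) — the standard
fractional-helicity convention of helix–coil theory. The per-unit
bookkeeping (units in segments, singly bonded end units) is kept separately
for the spectroscopic models; the two conventions differ by about one
percentage point for a 33-unit chain at mid-transition.

**Temperature dependence.** w(T) = exp(−ΔG(T)/RT) with the three-parameter
Gibbs–Helmholtz form ΔG(T) = ΔH + ΔC_p(T − T₀) − T[(ΔH − ΔG)/T₀ +
ΔC_p·ln(T/T₀)], parameters given at T₀ = 273.15 K and
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹. ΔC_p = 0 recovers the van 't Hoff form
exactly. v is temperature-independent.

## Spectroscopic models

All ellipticities are per mole of peptide unit. The helix baseline of a
segment of n_H units at temperature T (°C, referenced to 0 °C):

* *linear*: every helical unit scores [θ]_H(N_pep, T) — the maximal-length
  value — regardless of segmentation. Multi-segment conformers are
  deliberately scored as if single-segment; this reproduces the
  approximation whose bias the ensemble models quantify.
* *empirical*: per segment, n_H·[θ]_H∞(T)·(1 − k/n_H).
* *dichroic*: the six singly hydrogen-bonded end units (three per end)
  score [θ]_H1(T), the doubly bonded interior units [θ]_H∞(T). The closed
  form [θ]_H1 = [θ]_H∞(1 − k/6) is forced by requiring the dichroic
  per-unit value to equal the empirical form for n_H > 6; it also ties
  ∂[θ]_H1/∂T to (1 − k/6)·∂[θ]_H∞/∂T under the temperature-independent-k
  assumption (43.3 deg cm² dmol⁻¹ °C⁻¹ for k = 3.4, ∂[θ]_H∞/∂T = 100).
  Whether k should itself be temperature-dependent is an open question;
  the implementation keeps it constant, and a temperature-dependent k
  would enter only through `theta_H1`.

Coil units score [θ]_C(T) = [θ]_C + (∂[θ]_C/∂T)·T. The ensemble signal is
the probability-weighted conformer sum divided by N_pep. Model-comparison
scans default to zero coil contribution so the difference isolates the
helix corrections. With the end-coil boundary the longest attainable
segment of an N_pep-unit chain is N_pep − 2 units, so the three models
coincide exactly only at the conformer level (a full-span n_H = N_pep
segment); at the ensemble level the empirical and dichroic corrections
still agree in the strong-helix limit while the linear model retains a
~1% offset.

Raw signals convert as [θ] = θ(mdeg)/(10·l·c·N_pep).

## Inversion

The dichroic ensemble signal is strictly monotone (decreasing) in w at
fixed T — asserted by test over the parameter box — so a measured [θ]₂₂₂
is inverted by Brent's method on w ∈ [1e-8, 50] to 1e-10. Observations
outside the attainable interval raise an error naming the interval; the
coil baseline itself sits on the boundary and is accepted. The linear
closed form clips to [0, 1] with a warning.

## Global fitting

Nine parameters ([θ]_H∞, ∂[θ]_H∞/∂T, k, [θ]_C, ∂[θ]_C/∂T, ΔG, ΔH, ΔC_p, v)
are fitted jointly to: melt curves (forward model above, one σ₂₂₂ per curve
or a shared default), a fully-helical series observed as
[θ]_H(N_pep, 0 °C), and a pre-transition slope series observed as
(∂[θ]_H∞/∂T)(1 − k/N_pep). Uniform box constraints span 1/5× to 5× of a
sign-preserving reference point (the shipped alanine calibration by
default, overridable). The `mle` backend runs scipy `least_squares` from
five seeded starts (best objective wins) with parameter-magnitude scaling;
2σ uncertainties and parameter correlations come from the linearized
covariance (JᵀJ)⁻¹ of the weighted residuals. The `mcmc` backend samples
the same Gaussian likelihood under the box prior with emcee's
affine-invariant ensemble (walkers initialized in a tight ball around the
MLE; defaults 32 walkers, 3000 steps, 1000 burn-in; Spearman rank
correlations and acceptance/ESS diagnostics reported). Parameters may be
frozen (e.g. ΔC_p = 0) for nested-model comparisons. Configurations with
fewer observations than free parameters are rejected with the list of
unconstrained parameters.

## Synthetic data

The generator mirrors the experimental design the fit expects: blocked
(AAKAA)n-GY melts for n = 1, 3, 4, 5, 6 (n_res = 7, 17, 22, 27, 32),
0–95 °C every 1 °C, i.i.d. Gaussian noise σ₂₂₂ = 300 deg cm² dmol⁻¹ (the
order of visible scatter in measured melts); a fully-helical reference
series over N_pep = 7…60 with σ = 1,500 deg cm² dmol⁻¹ and a slope series
with σ = 15 deg cm² dmol⁻¹ °C⁻¹ — reference scatter is much larger than
instrument noise because such compilations mix heterogeneous, digitized
literature systems. All generators are pure functions of (config, seed).

What the synthetic suite does *not* emulate: instrument artifacts (lamp
drift, absorbance flattening), concentration errors, heteropolymer
per-residue propensities, capping effects, or any deviation of real
peptides from the homopolymer Lifson–Roig model. Passing recovery tests
therefore show the estimator is correct and well-conditioned under the
model's own assumptions, not that those assumptions hold for a given real
peptide.

## Numerical and design choices

* Temperatures are °C at every interface, kelvin inside the
  thermodynamics; offset 273.15.
* Brute-force enumeration refuses n_res > 22 and points to the efficient
  enumerator.
* Melt curves require strictly increasing temperatures within −10…110 °C.
* Forward-model melts with the alanine calibration lose signal magnitude
  monotonically up to ~85 °C; in the last few degrees the negative-going
  coil baseline slope reverses the trend slightly, so monotonicity checks
  stop at 85 °C.
* On synthetic suites at the default noise, the deterministic global fit
  recovers the seven well-determined parameters to a few percent; ΔC_p —
  the hardest, entering only through melt curvature — stays within a
  factor of two with the correct sign. Fitting the linear model to
  dichroic-generated data converges to slightly biased parameters with a
  larger objective, and fixing ΔC_p = 0 on ΔC_p > 0 data strictly worsens
  the fit.
* Mean absolute pairwise parameter correlations of the dichroic- and
  linear-model fits to the same synthetic suite are near-identical
  (~0.29–0.31 by both linearized covariance and MCMC Spearman); the
  synthetic design does not reproduce a claimed conditioning advantage of
  the dichroic model, and the corresponding check is expected to fail
  under these conditions.
* The linear-vs-dichroic signal difference over a w-scan of the 33-unit
  chain ([θ]_H∞ = −40,000, k = 4, v = 0.048) peaks at w ≈ 1.19:
  ~1,870 deg cm² dmol⁻¹, i.e. 12.3% of the local dichroic signal or
  5.3 points of apparent helicity when normalized by the fully-helical
  signal. Checks asserting this difference stays within 5% fail under the
  exact ensemble; the package reports the locally normalized value.

## Problem sizes

Default test and reporting runs use chains up to n_res = 50 for
normalization checks, brute-force oracles up to n_res = 14, exact scans
over v ∈ [0.01, 0.1] × w ∈ [0.6, 1.8] at step 0.01 for all chains up to
n_res = 32, and single synthetic suites (588 observations) for recovery,
chosen so the full suite runs in well under a minute apart from the
global-fit tests.
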