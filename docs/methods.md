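# Methods

## The error model

Dynamical (multiple elastic) electron scattering transfers intensity
from strong Bragg reflections into weak ones. `edcorr` models the effect
statistically: each observed structure factor is the kinematical one
plus a complex-valued dynamical component that is uncorrelated with it
and has expected power ε(d)², generally dependent on resolution d. Two
exact consequences drive everything else:

* **Second-moment hyperbola.** E|F_obs|² = |F_kin|² + ε², so a plot of
  observed against calculated amplitudes bends away from the diagonal
  at the weak end and intercepts the y axis at ε.
* **Intensity inflation.** The expected observed intensity exceeds the
  kinematic one by the factor k_dyn = (I_kin + ε(d)²)/I_kin, the
  reciprocal of a generalized Wiener filter. Its inverse is the
  correction weight.

No assumption is made about crystal thickness, shape or orientation;
the price is that ε(d) must be determined empirically from the data
against a reasonably accurate model.

## Fitting ε

`fit_epsilon` fits the hyperbola by least squares *in the squared
ordinate*: it minimizes Σ(|F_obs|² − |F_calc|² − ε²)², whose minimizer
is the closed-form moment estimate ε̂² = mean(|F_obs|² − |F_calc|²),
clamped at zero. The squared domain matters. The relation between the
*mean observed amplitude* and the quadrature sum (|F|²+ε²)^½ is not
exact: expanding |F + δ| for a complex perturbation δ with E|δ|² = ε²
gives E|F_obs| = F + ε²/4F for strong reflections — only half the
quadrature excess ε²/2F — so least squares on amplitude residuals
converges to ≈ ε/√2 no matter how much data is used. The squared-domain
fit is a consistent estimator of the generative dynamical power under
the model's own assumptions, and it is what the recovery tests verify.

A variance-weighted (IRLS) variant was considered and rejected: the
optimal weights 1/(2F²ε²+ε⁴) concentrate on weak reflections, where the
correction necessarily leaves a residual excess (see below), making the
estimator's post-correction value less comparable with the
pre-correction one. The unweighted fit measures the overall excess
power, which is the quantity the correction acts on.

When observed and calculated amplitudes are on different scales,
`fit_scale_and_epsilon` alternates the two closed-form steps on squared
amplitudes — scale k² by regression of I_obs on (F_calc² + ε²) through
the origin, then ε on the rescaled data — to relative tolerance 1e-8
(at most 50 rounds; both moment conditions hold exactly at the true
parameters, so the fixed point is consistent).

Resolution dependence uses ten equal-count resolution bins by default
(sizes differing by at most one reflection, d descending, stable ties).
A bin's representative resolution is the arithmetic mean of its member
d values. Per-bin ε fits feed one of three continuous forms:

* `linear`: ε(d) = a·d + b (ordinary least squares);
* `exp2`: ε(d) = a·exp(b·d) + c·exp(e·d) (multi-start nonlinear least
  squares, seeded; falls back to `discrete` with a warning if no start
  converges);
* `discrete`: the per-bin step function itself — preferable when ε(d)
  is not smooth, as for protein data with solvent contributions.

Evaluation clamps d to the fitted bin range (the exponential and linear
forms misbehave outside it) and clamps negative ε to zero. Bins with
fewer than 5 reflections fall back to the global fit with a warning.

## The correction

k_dyn requires the unknown kinematic intensity. Because
E[I_obs] = I_kin + ε², the module uses the plug-in estimate
Ĩ = max(I_obs − ε(d)², σ): the subtraction is the moment estimate of
I_kin, and the σ floor keeps the factor positive and meaningful for
observations that are weak, zero or negative — these are retained, never
deleted, and receive the strongest down-weighting. Intensity and sigma
are multiplied by the same factor Ĩ/(Ĩ+ε²) ∈ (0, 1], so I/σ is exactly
preserved and intensity ordering is maintained. Amplitude data use the
square root of the same factor with the bin's ε
(Ĩ = max(F² − ε_b², σ_F²)), so correcting amplitudes and correcting the
corresponding intensities agree.

The correction is deliberately *not* idempotent and not a full
deconvolution: for a truly weak reflection (F_kin ≈ 0) the corrected
intensity retains an expected excess of e⁻¹·ε² ≈ 0.37 ε² — a
multiplicative, order-preserving weight cannot remove the excess from
single noisy observations without zeroing them. Strong and moderate
reflections lose their excess essentially completely. Refitting ε after
one correction pass therefore contracts it by a factor that reflects the
weak-reflection fraction of the data (≥ 2.4 under the default synthetic
conditions below); a second pass changes ε by less than the first.
Fixed-model R1 is reported before and after but is not expected to drop
on synthetic data: the correction trades the bias of weak amplitudes for
variance, and R1 improvements materialize when the model is re-refined
against the corrected data, which is outside this package's scope.

## Kinematic structure factors

F(h) = Σ_sym Σ_atoms occ·f(s)·T_adp·exp(2πi·h·(Rx+t)) with electron
form factors evaluated at s = sinθ/λ = 1/(2d) — this s convention is
used everywhere in the package. Symmetry is applied in reciprocal space
(phase and displacement factor evaluated at h′ = h·R), which is
algebraically identical to expanding atoms with rotated ADP tensors.
Isotropic ADPs use T = exp(−8π²U s²); anisotropic ones the CIF
convention T = exp(−2π² Σ U_ij h_i h_j a*_i a*_j). Hydrogens without an
ADP ride at 1.2× the equivalent isotropic U of the nearest heavy atom.
Dispersion and absorption are ignored, appropriate for the kinematic
electron case. The engine is verified against an independently coded
direct-space summation (atoms pre-expanded, plain loops, transformed
tensors) to 1e-10 relative on random models.

Form factors come from the standard 5-Gaussian electron
parameterization (any element; tables embedded in gemmi), refit on
demand to the 9-coefficient Cromer–Mann form (4 Gaussians + constant)
by unweighted least squares on an s grid of 0–2 Å⁻¹, step 0.01 —
initialization keeps the four largest source Gaussians and seeds the
constant with the fifth amplitude, widths bounded at zero, making the
fit deterministic. Typical max residuals: ≤ 4e-3 across H/C/N/O/S, with
f(0) preserved to well under 0.5%.

## Merging statistics

Observations are grouped by a canonical representative under the Laue
group (lexicographically largest index over all point-group rotations
and Friedel mates — cross-checked against gemmi's reciprocal-ASU
mapping in the tests). R_merge = ΣΣ|I−⟨I⟩|/ΣΣI and R_meas (with the
√(n/(n−1)) multiplicity factor) run over reflections measured at least
twice; with none, they are reported as absent, not zero. CC1/2 is the
Pearson correlation of mean intensities over a random, seeded
half-dataset split. Completeness compares unique observed reflections
against direct enumeration of the theoretically measurable set
(systematic absences excluded). The conventional truncation checks —
I/σ > 1.0 and CC1/2 > 50% — are reported as the first failing bin in
each criterion, but never auto-applied, since the exact bin-walk rule is
a matter of taste.

## Unit-cell refinement against restraints

In electron diffraction the cell dimensions and effective detector
distance are too correlated to refine together from geometry alone, so
the lattice is refined against idealized model geometry instead:
holding fractional coordinates fixed, Σ((d_model − target)/σ)² is
minimized over the unmasked cell parameters (default: a, b, c free,
angles fixed — the orthorhombic case; a single-parameter cubic mask and
arbitrary parameter subsets are supported). Distances are taken to the
nearest symmetry/lattice image, recomputed inside the objective so
bonded pairs may straddle cell boundaries. The optimizer is Nelder–Mead
simplex with restarts (3 free parameters at most; robustness over
speed), and the reported cell never has a worse residual than the
start. DANG is treated as a 1–3 distance restraint, per its SHELX
meaning; sigma defaults are 0.02 Å (DFIX) and 0.04 Å (DANG) when
omitted. Alternating cell refinement with coordinate re-refinement is
an iteration the caller can drive; a single fixed-coordinate cell
refinement is the primitive provided.

As a small related utility, `solvent_cube_side(ΔV, Z)` converts a
per-cell volume change into the side (ΔV/Z)^⅓ of the equivalent cube
per formula unit — e.g. interpreting a ~90 Å³ cell shrinkage in a Z=4
crystal as one lost water molecule per asymmetric unit (≈2.82–2.83 Å
cube, close to the ~3 Å cube of a water molecule in the liquid).

## The simulator and what it shows

`simulate_observed` draws, for every unique reflection to d_min
(Laue-reduced, absences excluded), F_dyn with independent Gaussian
real/imaginary parts of standard deviation ε(d)/√2 — so E|F_dyn|² =
ε(d)² — and records I_obs = |F_kin + F_dyn|², optionally with Gaussian
or scaled-Poisson counting noise and multi-crystal wedges with
log-normal(0, 0.1) scales for exercising the merging statistics. The
default study condition is a 24-atom organic-mix (C₃NO₂S) toy structure
in an 11×12×13 Å P1 cell, U_iso ∈ [0.01, 0.05] Å², d_min 0.8 Å
(> 5000 unique reflections), constant ε* = 2.0 in amplitude units —
placing strong reflections well above the error term and the weakest
shell comparable to it, the regime of sub-ångström organic ED data.

The perturbation is drawn independently per reflection — the minimal
model consistent with the uncorrelatedness assumption the correction
itself relies on. Real dynamical diffraction couples reflections
excited simultaneously, depends on thickness and orientation, and can
vary along a rotation series; none of that is emulated. Passing
recovery and contraction tests therefore validate the estimator and the
correction algebra under the model's own assumptions, not the physics
of any particular crystal. ε as a function of rotation-angle groups can
be explored by fitting subsets, but no angular model is built in.

## Numerical choices and degenerate inputs

* ε fits clamp at zero rather than reporting negative power; an empty
  input is an error.
* Correction factors are floored at Ĩ ≥ 1e-30 so they stay in (0, 1]
  even for all-nonpositive observations with zero sigma.
* HKLF4 I/O is strict fixed-width (3I4, 2F8.2), accepts terminator- and
  EOF-ended files, ignores batch columns, and refuses values that
  overflow the format (rescale first). Writers are deterministic
  byte-for-byte.
* Equal-count binning resolves d ties by input order (stable sort);
  with n not divisible by n_bins the low-resolution bins take the extra
  reflection.
* Cell parameters are validated (positive lengths, angles in (0°,180°),
  positive volume by the triclinic closed form).
* The CC1/2 half-dataset split is seeded and reproducible; with fewer
  than two multiply-observed uniques it is reported as absent.

## Known limitations

* The correction needs |F_calc| from an initial model; fitting ε
  without a model (e.g. from Wilson statistics) is not implemented.
* Atoms-only F_calc: no bulk-solvent model, so for protein data the
  low-resolution bins absorb solvent signal into ε(d) — one reason the
  discrete per-bin form is the default recommendation there.
* Completeness enumeration is practical for small-molecule cells; for
  large protein cells it is slow and can be disabled.
* Coordinate/ADP refinement, phasing, and R_complete cross-validation
  belong to the surrounding programs (SHELXL etc.), not this package.
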