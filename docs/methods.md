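# Methods

This note documents the models behind the three analysis pipelines, the
synthetic-data generator they are validated against, and the numerical and
design choices that were genuinely open.

## Partition coefficients by derivative spectrophotometry

### Model

A drug at fixed concentration distributes between water and lipid vesicles.
With total lipid concentration [L] (M) and partition coefficient K_p
(M⁻¹), the membrane-bound fraction is

    f_bound = K_p[L] / (1 + K_p[L]).

Binding shifts and reshapes the drug's UV absorbance band, but vesicle
suspensions add a large, smooth light-scattering background that grows with
[L]. Differentiating the spectrum three times with respect to wavelength
suppresses any slowly varying background (locally ≈ cubic contributions
vanish) while amplifying the sharp band shift, so the third-derivative
value D_T at a fixed analytical wavelength is an affine function of
f_bound:

    D_T([L]) = D_W + b·f_bound([L])

with D_W the derivative value of the fully aqueous drug and b the
bound-minus-free amplitude. D_T(0) = D_W exactly, D_T is monotone in [L]
with the sign of b, and D_T(∞) → D_W + b. Fitting this isotherm by
nonlinear least squares yields K_p; the dimensionless distribution
coefficient is log D = log₁₀(K_p/V_φ), where V_φ (L/mol) is the molar
volume of the lipid system, so the K_p/V_φ ratio compares moles of drug per
litre of lipid versus per litre of water.

### Parameters and defaults

- Analytical wavelengths: 213 nm (naproxen), 321 nm (diclofenac);
  overridable, and `scan_wavelengths` reports the |b| landscape as a
  convenience for unfamiliar drugs. Readout uses the nearest grid point (no
  interpolation) — spectra are dense (1 nm).
- Smoothing: Savitzky–Golay filter, window 9 points, polynomial order 5,
  on a 1-nm grid. Order 5 rather than 4 is deliberate: for odd derivatives
  the coefficient sets pair across parity (order 4 reproduces order 3), and
  the order-5 filter reduces the pointwise error against the analytic third
  derivative of a Gaussian band from ~3% to ~0.03% at window = band
  width/3, at modest extra noise gain. Edge points (half a window at each
  end) come from one-sided fits and are flagged unusable.
- Fit: unweighted least squares on the isotherm with D_W, b, K_p free;
  initialisation D_W ← D_T(0), b ← D_T(L_max) − D_W, K_p ← 1/median
  positive [L]. K_p is bounded to [10⁻², 10⁸] M⁻¹; a fit pinned at a bound
  or a flat (unidentifiable) series reports `converged=False` rather than
  raising. Standard errors come from the covariance of the converged fit.
- Replicates are fitted independently; reports aggregate mean ± sd over
  converged fits (≥3 replicates recommended).

### Lipid-system registry

POPC 0.756, POPC:CHOL (80:20) 0.681, POPC:TMCL (85:15) 0.987, POPC:PI
(85:15) 0.687 L/mol. These system values are used verbatim; the component
molar volumes shipped alongside (CHOL 0.381, TMCL 2.296, PI 0.296 L/mol)
are the values consistent with mole-fraction weighting against POPC, and
`mixture_molar_volume` supports custom compositions.

## Dye-leakage analysis

Leakage % = (I₀ − I_t)/(I₀ − I_tot) × 100 is affine-invariant in the
intensity scale, 0 when I_t = I₀, 100 at full lysis, and undefined when
I₀ = I_tot (rejected). Intensities are first corrected by subtracting the
drug-only blank (replicate mean per concentration) from treated and lysed
wells; I₀ is a zero-drug reading and is left untouched. I_tot is modelled
per drug concentration, matching plates where the detergent set spans the
same dose series; a single-value fallback broadcasts. Values pushed
slightly outside [0, 100] by noise are preserved raw and clipped to
[−5, 105] only for reporting. Dilution by the ~15 µL detergent aliquot
(≲5% in a standard well) is neglected by default.

The dose axis is the drug:lipid molar ratio, using the phosphate-assay
lipid concentration of the vesicle stock: an OLS calibration line of
A₇₉₇ vs phosphate standards (0–100 nmol), inverted per sample, with a
configurable phosphate:lipid stoichiometry (1 for glycerophospholipids,
2 for cardiolipins).

## SAXS lamellar analysis

Bragg peaks are modelled as height-parameterised Lorentzians
A·γ²/((q−q₀)² + γ²), fwhm = 2γ. Initial guesses come from local maxima of
the median-filtered profile (prominence ≥ 5% of the intensity span by
default). Each guess gets a fitting window of ±3 fwhm; overlapping windows
are merged and their peaks fitted jointly (this is what resolves split
first-order peaks), each window group with its own constant baseline. With
the diffuse background model enabled, the whole profile is fitted jointly
with one constant plus one broad Lorentzian (center bounded to 0.5–2 nm⁻¹),
and the sample is flagged as vesicle-dominated when the diffuse amplitude
exceeds 20% of the tallest Bragg amplitude.

Derived quantities: repeat distance d = 2π/q₀ and correlation length
ξ = 4π²/fwhm, both computed at construction so the identities hold to
machine precision for every emitted peak. The 4π²/fwhm convention yields
values a factor 2π larger than the more common 2π/fwhm; both are exposed
(`xi` / `xi_2pi`, and a summary switch) with 4π² as the default here.

Order indexing takes q₁ from the most intense peak in the low-q candidate
set (peaks within the order-1 tolerance band of the lowest-q peak) and
assigns order n when |q₀ − n·q₁| ≤ tol·q₁ (default tol = 5% of q₁; split
first-order peaks may need ~10%). Assignment is idempotent and independent
of peak ordering. Per-sample summaries report d and ξ of the most intense
order-1 peak; samples with no indexed first order get missing values and a
flag. q is canonically nm⁻¹; Å⁻¹ input is converted (×10) on ingest only.

## Synthetic-data generator

The generator emulates what each pipeline assumes, not the instruments:

- **Titrations**: Gaussian aqueous and bound bands mixed by the isotherm,
  plus a λ⁻⁴ scattering background scaled per molar lipid (chosen because
  derivative spectrophotometry is predicated on suppressing smooth
  scattering; at the defaults its third derivative at the analytical
  wavelength is <0.1% of |b|), plus additive white absorbance noise. Band
  parameters per drug place the analytical wavelength on the derivative
  shoulder; 12 lipid concentrations over 0–2 mM; drug concentrations 5 µM
  (NAP) and 40 µM (DIC). Reference conditions set the true K_p from the
  registered log D of each drug/system pair via K_p = V_φ·10^logD.
  "2% derivative noise" is implemented by dividing the target derivative
  noise (2% of |b|) by the filter's white-noise gain (the ℓ₂ norm of the
  Savitzky–Golay coefficient vector) to obtain the absorbance noise sd.
- **Plates**: true released fraction follows a Hill curve (defaults:
  plateau 0.05–0.20 matching the observed 5–20% release range, EC₅₀
  ~150 µM within the 0–400 µM dose span, coefficient 1.5); wells add a
  linear drug-autofluorescence term (the simplest model a blank-subtraction
  correction can remove exactly) and Gaussian noise; 3 replicates by
  default. Measured noise levels and replicate counts per well are not
  documented for this assay class, so the defaults are conventions (noise
  ~1% of the I₀ − I_tot dynamic range).
- **SAXS**: baseline + optional broad diffuse Lorentzian + Bragg
  Lorentzians, with counting-like noise (sd ∝ √intensity). With noise off,
  all three simulators emit the analytic model exactly, and identical
  seed + config gives identical arrays (explicit per-config seeds, no
  global state).

What the generator does **not** emulate: real band shapes and solvent
shifts, Mie scattering, instrument response and detector geometry, leakage
kinetics, quenching mechanisms (Stern–Volmer), multilamellar form factors.
Passing round-trip tests therefore demonstrates correctness of the
estimators under their own model assumptions, not robustness to every
real-data artefact.

## Problem sizes

The recovery studies use 200 seeded titrations per drug/system pair
(12 lipid concentrations, 201-point spectra each) and 100 seeded SAXS
refits at 1% noise — sizes at which the Monte-Carlo error on the mean
recovered log D (~0.005) is far below the ±0.1 comparison scale, while a
full run stays in the tens of seconds on one CPU.

## Known limitations

- Only the printed isotherm is fitted; no background subtraction or other
  pre-treatments some derivative-spectrophotometry tools apply.
- No multi-wavelength simultaneous fitting, and drug ionisation equilibria
  (pKa) are out of scope.
- The leakage dilution correction is optional and off by default.
- SAXS analysis starts from 1-D averaged profiles; azimuthal integration,
  calibration and electron-density reconstruction are out of scope.
- For strongly overlapping split peaks the joint Lorentzian fit is
  well-conditioned only when detection separates the maxima; a single broad
  asymmetric peak will be fitted as one Lorentzian.
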