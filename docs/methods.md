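# Methods

## The problem

The UV sensitivity of a bird's eye is set jointly by which sws1 cone opsin
it expresses — ultraviolet-sensitive (UVS, λ_max ≈ 360–373 nm) or
violet-sensitive (VS, λ_max ≈ 402–426 nm) — and by how much UV light the
ocular media (cornea, aqueous humour, lens, vitreous humour) transmit to the
retina. This package implements the quantitative machinery for both sides:
descriptive metrics of ocular media transmittance (OMT) curves, a
receptor-noise-limited (RNL) model of UV colour discrimination, and the
comparative statistics that relate transmittance, pigment class and eye
size across species.

## OMT processing and metrics

Raw transmittance measurements are resampled by linear interpolation to the
common grid (300–700 nm, 1 nm; extrapolation is refused), smoothed by an
11-point centered running average, and normalized to the maximum value
within 300–700 nm. Edge handling of the running average uses a
symmetrically shrinking window (half-width `min(5, distance to edge)`),
which preserves length and endpoint values; with 401-point spectra and the
cut-off far from either edge the choice is inconsequential.

λ_T0.5 — the wavelength at which half of the incident light reaches the
retina — is found by scanning from the in-range maximum toward shorter
wavelengths and linearly interpolating the first downward crossing of 0.5.
Scanning downward from the maximum (rather than upward from 300 nm) makes
the statistic robust to noise wiggles on the near-zero short-wavelength
tail. Crossing levels are interpolated rather than snapped to the nearest
1 nm sample; the two conventions differ by under 0.5 nm, below the 1 nm
reporting precision of the field.

Cut-off slopes divide the normalized transmittance range into twenty 5%
bands and report, for each band, 0.05 divided by the wavelength width of the
band (fraction per nm). Bands whose bounding level is never attained (e.g.
the 0–5% band of a curve that never reaches zero) are NaN. The 100% level is
the wavelength of the in-range maximum.

The retinal UV fraction is the trapezoid-rule ratio
∫₃₀₀⁴⁰⁰ I(λ)T(λ)dλ / ∫₃₀₀⁴⁰⁰ I(λ)dλ with I in photon units. All
integrations in the package use the trapezoid rule on the 1 nm grid.
Transmittance is held as a fraction in [0, 1]; percent-scaled input files
are divided by 100 on read (`percent=True`).

## Receptor sensitivities and visual systems

Cone spectral sensitivities are built from the Govardovskii et al. (2000)
A1 pigment template (α- plus β-band; valid λ_max 330–600 nm), normalized to
peak 1, then multiplied pointwise by an OMT curve. The product is *not*
renormalized: ocular screening reduces absolute sensitivity and shifts the
effective peak to longer wavelengths, and both effects are part of the
model. Template constants live in one configuration block
(`visual_system.A1_TEMPLATE`) so an alternative nomogram can be swapped in.

The two standard tetrachromatic parameter sets are surrogates for the model
species commonly used in avian colour-vision work: a budgerigar-like UVS
set (single-cone λ_max 371, 440, 499, 566 nm) and a chicken-like VS set
(418, 455, 508, 571 nm), both with relative cone abundances 1 : 2 : 2 : 4
(sws1 : sws2 : mws : lws) and Weber fraction ν = 0.1 assigned to the most
abundant (lws) channel, giving channel noise e_i = ν·√(η_max/η_i)
= {0.2, 0.141, 0.141, 0.1}. All four parameters are overridable per channel
in `build_visual_system`. An optional per-channel oil-droplet long-pass
filter (logistic cut-on) is available but disabled in the standard builds;
for the UV discrimination task it changes the computed limits by ≤ 1 nm
because the screened sws1 flank, not the droplet-filtered longer-wave
channels, carries the signal.

The noise model is the bright-light (Weber) regime: channel noise is
independent of intensity. No photon-shot-noise extension is provided.

## Stimuli and the threshold experiment

Stimuli are double-Gaussian reflectance spectra
R(λ) = baseline + A_uv·g(λ; λ_uv, FWHM_uv) + A_long·g(λ; λ_uv+200, FWHM_long)
with unit-height Gaussians parameterized by FWHM. Defaults: baseline 0.05,
A_uv = A_long = 0.5, FWHM_uv 36 nm (narrow) or 96 nm (broad), long peak
FWHM 96 nm, long peak 200 nm above the UV peak (anchored by the canonical
320/520 nm pair; because log contrasts cancel common scale factors under
Weber noise, only the relative amplitudes matter). Illumination is CIE D65
converted to photon units (energy × λ) and normalized to unit integral.

The discrimination threshold at a UV peak position is the smallest k ∈
{1, …, 100} for which reducing the UV amplitude by k% produces ΔS > 1 JND
against the original (strict inequality). A threshold of 100% — removing
the peak entirely — marks the limit of no discrimination, so stored
thresholds span 1–99% and the "discrimination limit" of a sweep is the
shortest UV-peak wavelength with a finite threshold.

The general-n RNL distance is implemented directly from the
elementary-product formula (see README); the test suite verifies it to
1e-9 against an independent characterization — the noise-weighted distance
of the contrast vector from the achromatic direction, computed by 1-D
numeric minimization — on a thousand random 2–4 channel systems, and
against the dichromat closed form |Δf₁−Δf₂|/√(e₁²+e₂²).

## Comparative statistics

Two-group comparisons apply a Shapiro–Wilk gate at α = 0.05 to each group;
if both pass (and n ≥ 3 in each), an unpaired two-tailed t-test is used,
otherwise a two-tailed Wilcoxon rank-sum (Mann–Whitney) test — exact
enumeration for tie-free samples with both n < 8, tie-corrected normal
approximation otherwise. Families of tests (the twenty slope bands) use the
Dunn–Šidák corrected level α' = 1 − (1 − α)^(1/m). Spearman correlations
are tie-corrected and drop incomplete pairs, reporting the n actually used.

The two-term exponential a·e^{bx} + c·e^{dx} is fitted by
Levenberg–Marquardt least squares over a deterministic multi-start grid:
candidate rates from a log-linear seed and span-scaled defaults, crossed
with both sign patterns, with amplitudes seeded by a linear solve at fixed
rates. The best converged fit by residual sum of squares is returned, so
fits are reproducible without any random state. The species with
unexpectedly low UV transparency for their eye size (the four diurnal
raptors, the common swift and the great crested grebe, which likely carry
UV-blocking lens pigments) are listed in
`species.LOW_UV_TRANSMITTANCE_OUTLIERS` for exclusion before exponential
fits of the eye-size relation; the list is an explicit, overridable input.

## Synthetic data

Real OMT curves are smooth long-pass functions; the generator emulates them
as logistics T(λ) = plateau/(1 + exp(−(λ − λ₅₀)/s)) plus optional Gaussian
noise, clipped at zero. For plateau 1 the logistic's λ_T0.5 equals λ₅₀
exactly, which anchors the recovery tests. Class surrogates use λ₅₀ = 323 nm
(UV-transparent class), 358 nm (medium class) and 379 nm (raptor class) —
the class means of the reference table — with steepness s = 6 nm for the
UV class and 8–10 nm for the others, reflecting the steeper cut-off of
UV-transparent media (10–90% width ≈ 4.4·s, i.e. ≈ 26 nm vs ≈ 44 nm).

Synthetic species tables draw pigment λ_max uniformly within the published
class ranges (UVS 359–373 nm, VS 404–421 nm) and generate λ_T0.5 from a
linear eye-size relation λ_T0.5 = 300 + 2.5·(axial length, mm) + ε,
ε ~ N(0, 6 nm), with axial lengths uniform in 6–12 mm for UVS groups
(parrots and UVS-passerines are small-bodied) and 8–30 mm for VS groups.
The class contrast in λ_T0.5 therefore emerges through eye size, mirroring
the hypothesized mechanism rather than being painted on directly. Default
group sizes mirror the reference table (38 species). Every generator takes
one explicit seed; there is no global random state.

What the generator does **not** emulate: non-logistic curve shapes (e.g.
lens-pigment absorption notches), wavelength-correlated measurement error,
phylogenetic correlation between species, and the raptor/swift departure
from the eye-size trend. Tests passing on synthetic data therefore
demonstrate correct recovery of the stated generative structure, not
robustness to those real-data features.

## Problem sizes and numerical choices

The model sweeps evaluate 101 UV-peak positions × up to 100 amplitude steps
× 4 channels on the 401-point grid per system; a four-system narrow-band
sweep completes in a few seconds. The pipeline's summary JSON rounds floats
to 6 decimals and sorts keys so identical configuration + seed give
byte-identical output. Ties in the parabolic peak refinement fall back to
the grid argmax; degenerate inputs (all-zero spectra, constant correlation
inputs, unattained crossing levels, non-positive quantum catches) raise
errors rather than returning silent NaNs.

## Known limitations

- The receptor parameter sets (λ_max, abundances, Weber fraction) are
  surrogate defaults for the two standard model species, not measured
  per-species values; the discrimination-limit landmarks shift by several
  nm under plausible alternatives (e.g. ν = 0.15–0.2 raises the VS/medium
  limit by 6–11 nm; removing the pigment β-band raises it by ~2 nm). The
  qualitative ordering of the four systems is stable across all of these.
- Average-OMT surrogates are single logistics; averages of real curve
  families have heavier short-wavelength feet.
- No phylogenetic correction is applied in the comparative statistics.
- The eye-size relation treats axial length as error-free.
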