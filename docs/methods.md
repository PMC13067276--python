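# Methods

## The generative model

A sample is described by a `SampleModel`: molar fractions of lignin units
over {G, S, H, FA, pCA} (summing to 1), a labeling fraction `p` (the
probability that a *labelable* lignin carbon carries ¹³C from the fed
precursor), the natural ¹³C abundance `a` (default 0.011), and a
lignin-to-carbohydrate carbon ratio.

The central statistical assumptions, stated explicitly:

* **Uniform labeling.** The fed precursors are uniformly ring-labeled, so a
  single `p` applies to every labelable carbon of every lignin unit. No
  site-specific labeling patterns are modeled.
* **Independence of sites.** Whether two carbons of the same unit are ¹³C
  is treated as independent. A labelable carbon is ¹³C with probability
  `q = p + (1−p)a`; a pair of labelable carbons is doubly ¹³C with
  probability `q² = p² + 2p(1−p)a + (1−p)²a²`. With `p ≫ a` the `p²` term
  dominates, which is what makes 2D cross-peaks lignin-specific.
* **Methoxy carbons are never precursor-labeled.** They arrive through
  SAM-dependent O-methylation from the general one-carbon pool, so they sit
  at `a` regardless of `p`. Their cross-peaks to ring carbons are generated
  only at the mixed-isotopomer level `a·q`, further damped by a factor 0.2
  for the dipolar transfer across the two-bond O-bridge (C–O–CH₃ distance
  ≈ 2.4 Å vs ≈ 1.4 Å for bonded ring carbons; couplings scale as r⁻³).
  This keeps methoxy-aromatic cross-peaks below 2% of the strongest
  aromatic cross-peak at realistic labeling levels — effectively absent,
  as observed in such spectra.
* **Unlabeled background.** Carbohydrates (and, implicitly, protein/lipid)
  contribute only natural-abundance signal: a dominant 1D envelope with its
  maximum at 73 ppm, and diagonal-only 2D intensity.

1D peak areas are `composition × n_carbons × q` for labelable sites and
`… × a` for unlabeled ones; carbohydrate carbon amounts follow from the
lignin-to-carbohydrate ratio. 2D cross-peak volumes are
`composition × n_a × n_b × (pair probability)`, placed symmetrically about
the diagonal; diagonal volumes use the single-carbon probability. Noise is
additive i.i.d. Gaussian, specified as a fraction of the tallest noise-free
peak, with one recorded seed per spectrum.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| natural abundance `a` | 0.011 | standard ¹³C isotopic abundance |
| lignin/carbohydrate carbon ratio | 0.05 | young hydrated plantlet tissue: aromatic signal weak next to polysaccharides, 73-ppm peak remains the global maximum even at p ≈ 0.3 |
| 1D lineshape | Gaussian, FWHM 2.0 ppm (lignin), 2.5 ppm (carbohydrate) | conventional CP-MAS at moderate field with Gaussian apodization gives near-Gaussian 1–3 ppm lines; see "Numerical choices" |
| 2D lineshape | Gaussian, FWHM 2.5 ppm | resolves the 4-ppm-spaced peaks of the G f2 = 135 ppm column at the 1.5-ppm box half-width |
| 1D axis | 0–200 ppm, 0.05 ppm step | ≥ 40 points per FWHM |
| 2D axis | 90–180 ppm, 0.25 ppm step | aromatic window, ≥ 10 points per FWHM |
| integration box half-width | 1.5 ppm | comparable to the 2D linewidth |
| deconvolution bounds | centers ±2 ppm around 147/153, FWHM 1–8 ppm, η ∈ [0,1] | keeps the two-component fit identified despite heavy overlap |

All are config-exposed; true linewidths and sideband intensities of real
spectra vary with field, temperature and processing, so none of these
defaults should be read as instrument claims.

## The quantification chain

**Normalization** divides by the *height* (not area) of the tallest peak in
the 70–75 ppm window — the carbohydrate C2/C3/C5 envelope, which is not
precursor-enriched and therefore calibrates overall spectral intensity
across samples of different mass and contact time.

**Incorporation index.** `I = (A_lab/N_lab)/(A_unl/N_unl)` with `A` the
trapezoidal 108–165 ppm integral (boundary-interpolated; no baseline by
default since synthetic spectra are baseline-free — a linear endpoint
baseline is available for real data). Because every labelable lignin
carbon scales by the same factor `q/a` between labeled sample and control,
lignin signal leaking *out* of the window cancels exactly; the index obeys
`I = 1 + p(1−a)/a` up to contamination of the window by unlabeled signal
(see below). The conversion `p(%) = 100·a·(I−1)/(1−a)` is the exact inverse
of that closed form; it is the package's accounting for natural-abundance
¹³C and residual unlabeled lignin. Indices below 1 clamp to 0% with a
warning. Note the carbonyl carbons of FA/pCA (≈168 ppm) fall outside the
108–165 ppm window by construction.

**G/S deconvolution** fits two pseudo-Voigt components (bounded nonlinear
least squares via lmfit, deterministic for identical inputs) in the
140–158 ppm window. Both components represent two carbons per unit (G C3+C4
plus the coincident FA C3/C4, vs S C3+C5), so area percentages are molar
percentages directly. Non-convergence is reported as a flag, never
silently.

**2D composition** integrates rectangular boxes (± half-width in both
dimensions, symmetric twins averaged) around one curated probe cross-peak
per unit: G C2–C1 (111, 135), S C2/6–C3/5 (104, 153), H C3/5–C4 (116, 160),
FA C2–C9 (111, 168). Raw volumes are divided by the pair multiplicity
(n_a·n_b: 1, 4, 2, 1 respectively) before forming
`X(%) = I_X/I_total × 100`. The probes were chosen for ≥ 5 ppm clearance
from every other unit's peaks in at least one dimension; notably the
full diagnostic catalogue retains peaks such as G2/5–3/4 (111, 147) that
are *not* used for quantification because they coincide with FA C2–C3/4
(111, 148–149). The estimates are semiquantitative and describe the
¹³C-labeled lignin fraction, not absolute lignin content.

**Fold changes** default to equal-total normalization (each sample's
`I_total`), in which case `r_X` reduces to the ratio of molar percentages;
a user-supplied reference volume per sample is the alternative. Zero
wild-type volumes yield flagged infinities rather than silent drops.

**DNP** uses peak height in a chosen probe region (default: the 70–75 ppm
reference window) for `ε = on/off`, and reports the `ε²` time saving that
follows from sensitivity–time scaling.

## Numerical choices

* **Lineshapes.** The defaults are Gaussian rather than pseudo-Voigt, and
  the carbohydrate FWHM is 2.5 ppm. This is deliberate: the carbohydrate C1
  line sits at 105 ppm, 3 ppm below the aromatic window edge, and a broad
  or Lorentzian-tailed C1 line bleeds enough unlabeled intensity into
  108–165 ppm to bias the incorporation index low by several percent (the
  contamination adds equally to both spectra of a pair and therefore does
  not cancel in the ratio). With Gaussian 2.5-ppm lines the leakage is
  < 1% of the control's aromatic lignin signal and the closed-form index is
  reproduced to better than 1%. Pseudo-Voigt and Lorentzian shapes remain
  available per call.
* **Box bleed in 2D.** At the 2.5-ppm default linewidth, the largest
  inter-peak contamination of a probe box is ~1% relative (the G C5–C1
  tail into the C2–C1 box), bounding composition errors at ≈ 0.4
  percentage points; this is why the single C2–C1 probe is preferred over
  averaging the G column.
* **Integration.** 1D region integrals interpolate the boundary ordinates
  so results are insensitive to grid registration; 2D volumes are plain
  box sums times pixel area. Off-diagonal boxes that would overlap the
  diagonal band (|f1−f2| < 2 × half-width) are rejected.
* **Determinism.** Every stochastic element takes an explicit seed; the
  pipeline derives per-sample seeds from the study seed, records them in
  metadata, and produces byte-identical reports for identical configs.
* **Degenerate inputs.** Non-positive reference peaks, empty windows,
  all-zero cross-peak totals, and sub-unity enhancement factors raise
  informative errors; sub-unity indices clamp with a warning.

## Problem sizes

The default grids (4001-point 1D spectra, 361×361 2D planes) resolve all
default linewidths with ≥ 10 points per FWHM while keeping a full synthetic
study — four conditions, 1D and 2D, plus recovery scans over labeling
fractions and 20 random compositions — in the tens of seconds on one core.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the analyses assume:
isotopomer probabilities, natural-abundance background, additive noise.
It does not model CP/DARR transfer dynamics, relaxation, DNP polarization
physics, spinning sidebands (available as optional fixed-amplitude
satellites, off by default), baseline roll, or protein/lipid spectral
detail. Recovery of ground-truth parameters on synthetic data therefore
validates the estimators' correctness and calibration under the stated
model, not their robustness to every artifact of real spectra — in
particular, real-data use should consider baseline handling and the
sideband content of the 108–165 ppm window.

## Known limitations

* Shift defaults not anchored in well-established assignments may differ
  by 1–3 ppm from any particular instrument's table; they are
  CSV-overridable for that reason.
* Composition is only as good as the probe isolation; heavily modified
  lignins with shifted resonances need a re-curated probe set.
* The equal-total fold-change normalization cannot detect a uniform change
  in total lignin signal between genotypes; an external reference volume
  is required for that.
* `p(%)` estimates assume the control and labeled sample share the same
  background composition; strong matrix differences violate the
  cancellation that makes the index scale-free.
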