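# Methods

This note documents the models implemented in `mrsiquant`, the defaults
and why they were chosen, what the digital phantom does and does not
emulate, and the numerical conventions.

## Signal model and quantification

A metabolite amplitude `SM(v)` in an MRSI voxel is proportional to the
moles of metabolite it contains, which for a molal concentration `c`
(mmol per kg of non-CSF tissue water) is `c · ρw · (H2O − fCSF·dCSF) · V`
attenuated by the metabolite relaxation factor
`RM = e^{−TE/T2M}(1 − e^{−TR/T1M})`. The unsuppressed water amplitude is
proportional to the voxel's water content attenuated by the water factor
`A_w = e^{−TE/T2}(1 − e^{−TR/T1})`. All scanner gains cancel in the
ratio `SM/SW`, which all three methods scale by the molality of water and
correct for `RM` and CSF partial volume:

* **ref** (literature scaling): the per-compartment water densities
  `α_c` (GM/WM/CSF) and literature `T1_c, T2_c` build molal water
  fractions `f_c^{H2O} = f_c α_c / Σ_j f_j α_j` and an effective
  attenuation `Σ_c f_c^{H2O} A_c`; the water content entering the molar
  conversion is the segmentation estimate `Σ_j f_j α_j`. The exact
  published form of this comparator is not reproduced in the main text we
  implement from; the formulation here is the standard compartment
  water-scaling reconstruction and is flagged as such.
* **ref_qmri** (measured-map scaling): `A_w` is evaluated per
  high-resolution voxel from measured T1/T2 maps and PSF-averaged
  weighted by water content, `Ā = ⟨H2O·A_w⟩/⟨H2O⟩` — signal formation
  is linear in attenuation, so averaging attenuations (not relaxation
  times) is the consistent order of operations. Evaluating `A_w` at
  resliced T1/T2 instead is available (`attenuation_mode="mrsi"`).
* **proposed** (synthetic reference): no acquired water grid. The STEAM
  water amplitude is corrected for the stimulated-echo half signal
  (factor 2, toggleable), T1 (including the mixing time TM), T2, B1⁺ and
  voxel volume, then scaled by the PSF-resliced water-content map
  normalized to the STEAM-box mean water content. The reference is
  thereby already relaxation-corrected and no water term appears in the
  concentration formula.

### Correction-factor conventions

All STEAM correction factors are **reciprocals of attenuations**
(multiplying the measured amplitude undoes the loss). The printed form
of the longitudinal steady-state term is itself an attenuation (< 1);
multiplying it in directly would attenuate twice, so the reciprocal is
applied. A strict `t1_mode="as_printed"` exists for comparison; at
TR = 10 s the two differ by ≲ 2%. Similarly the flip-angle term is
implemented as printed, `sin α / sin³(B1⁺α)`, with a
`b1_mode="cubed_numerator"` switch for the fully cubed form — at the
nominal α = 90° the two are identical. The water-reference normalization
uses the *mean* water content over the STEAM box rather than a raw sum,
which would scale with voxel count and break units.

The voxel-volume factor uses the MRSI geometry's reconstructed
("interpolated") voxel volume when a reconstruction matrix is set
(e.g. 7.5×7.5×12 mm³ for a 20×20 acquisition reconstructed to 32×32 over
a 240 mm FOV, giving 675/1000 = 0.675 against a 10³ mm³ STEAM box), else
the nominal acquired volume (fov/matrix).

### Constants

* `T2 = T2* · 59/47` (factor 1.255): constant white-matter calibration
  from T2* to T2, using the literature WM pair T2 = 59 ms, T2* = 47 ms.
  Both constants live in the user-editable `RelaxationTable`.
* Molality of water: stored as 55 100 mmol/kg (55.1 mol/kg), the
  convention that puts outputs on the familiar mmol scale; the physical
  value 55 510 mmol/kg is available as
  `RelaxationTable.physical_water_preset()`.
* `dCSF = 1`, `ρw = 1 kg/L`.
* Literature water compartment defaults (GM/WM/CSF T1 = 1300/830/4300 ms,
  T2 = 110/80/500 ms, densities 0.78/0.65/0.97) and tissue-averaged
  metabolite T1M/T2M defaults are editable assumptions meant to be
  replaced by the user's preferred literature source; they are serialized
  with every result.

## PSF reslicing

Phase-encoded MRSI measures the low spatial frequencies of the object:
the default reslicing operator truncates the k-space of the
slab-averaged high-resolution field to the central MRSI matrix (top-hat
window) and evaluates the inverse DFT on the coarse grid. A
Hamming-weighted window mimics weighted phase-encode averaging. The
operator is linear, keeps constant fields constant, and its kernel
integrates to one. The window shape and the order of operations are not
uniquely determined by common vendor practice; both window choices are
configurable, and the same operator is used on the forward (phantom) and
inverse (quantification) paths.

Tissue fractions default to box averaging over the nominal voxel —
common practice for partial-volume correction — with PSF-weighted
fractions behind a flag (`use_psf=True`). PSF-weighted fractions are the
consistent choice against PSF-formed signals and are therefore used in
the recovery and agreement studies; they may slightly over/undershoot
[0, 1] near sharp boundaries (Gibbs ringing) and are deliberately not
clipped so that linearity is exact.

### Numerical conventions

Voxel-center, 0-based indices; world coordinates in mm via affines;
only axis-aligned (diagonal) affines are supported, since inputs are
assumed co-registered. NaN marks invalid voxels and propagates: an MRSI
voxel whose nominal box contains any invalid high-resolution voxel is
NaN. Even matrix sizes retain the asymmetric frequency set
[−M/2, M/2), so a pure Nyquist pattern loses half its amplitude. The T2
fit is log-linear weighted least squares (weights S², the small-noise
maximum-likelihood weighting) with an optional nonlinear refinement; a
two-parameter model `S0·e^{−TE/T2}` is fitted because measured signals
are not normalized. Degenerate voxels (non-positive or non-decaying
signal, < 2 valid echoes) yield NaN. Voxels with `fCSF ≥ 0.95`,
non-positive water reference, or `H2O − fCSF·dCSF ≤ 0` are masked
invalid, never silently zeroed.

## The phantom

`mrsiquant.phantom` builds a 96×96×24 grid at 2.5 mm (240 mm FOV, 60 mm
slab) with a WM core (|x|,|y| < 60 mm), GM rim, two 24 mm CSF pockets on
the anterior/posterior midline, an optional lesion box with T1/T2/T2*
elevated ×1.5 and water content ×1.4 (capped at 1) that the segmentation
deliberately mislabels as its host tissue, and a smooth radial B1⁺ field
(1.10 at isocenter falling to 0.85 at the FOV corner). Tissue values
default to physiological 3 T numbers; WM satisfies the constant
calibration `T2 = 1.255·T2*` exactly when `calibrated_wm=True` (default),
which is the proposed method's operating assumption. CSF water content
is 1.0, matching the convention of water-content mapping pipelines that
normalize CSF to unity. The MRSI grid is 20×20 over 240 mm with a 12 mm
slice; the STEAM box (10³ mm³) sits fully inside the WM core.

Signals follow the forward model in the module docstring — the same
reslicing operator, attenuation formulas and constants as the inverse
path, which is what makes exact noise-free recovery a meaningful test of
the algebra rather than of floating-point luck. Noise is multiplicative
Gaussian on measured amplitudes only (metabolite grid, water grid, STEAM
scalar), seeded, with a fixed draw order; map noise can be added
separately. Simulated amplitudes that ring non-positive inside CSF
pockets are emitted as NaN (a spectral fitter would reject such voxels).

What the phantom does **not** emulate: spectral fitting itself
(lineshapes, baselines, fit correlations — amplitudes are generated
directly), receive-field inhomogeneity, eddy currents, motion,
registration error between maps, through-slice tissue variation, and the
T2 prolongation of adiabatic refocusing (a known ~5–10% STEAM-vs-sLASER
water discrepancy in vivo that is observed, not corrected, by all of
these methods). Passing recovery tests therefore demonstrates the
correctness of the correction algebra and its implementation, not
robustness to those real-world effects.

Five-subject cohorts (`cohort_configs`) jitter tissue T1/T2*/H2O by ±5%
per subject (keyed, seeded RNG), keep WM calibrated, share true
concentrations (tNAA 13.0, tCr 9.3, tCho 2.6 mmol/kg — healthy-brain
scale values), and apply 1% amplitude noise: a desk-scale stand-in for
inter-subject variability. Because the proposed method hinges on a
single STEAM amplitude per subject, its 1% noise draw acts as a global
concentration scale per subject; with five subjects the cohort
Bland–Altman bias then carries a sampling SD of ≈ 1%/√5 ≈ 0.45% of the
mean, so the bias estimate at this cohort size is noise-limited, not
method-limited (the noise-free bias between the proposed and
measured-map methods is < 0.01%).

## Agreement statistics

ROI statistics are NaN-aware means with sample (n−1) SDs over four
disjoint anterior/posterior/left/right blocks placed inside the VOI
(two-voxel border margin). Bland–Altman differences are taken
method-a − method-b with the order logged; percent forms are normalized
by the grand mean of pair means. ROI-level pairs are the default
(voxel-level pairs are available through the library). The Friedman and
post-hoc tests are delegated to scipy, not re-implemented.

## Design choices that were genuinely open

* Whether the printed longitudinal STEAM term is an attenuation or its
  reciprocal (reciprocal implemented; see above).
* Flip-angle term exponent placement (as printed; switch provided).
* PSF window shape and its placement before/after downsampling (top-hat
  Fourier truncation at the acquisition matrix; Hamming option).
* Whether the acquired-water comparators' CSF fraction uses PSF or box
  averaging (configurable; PSF used where consistency with the forward
  model matters).
* The K receive-field factor divides the relaxation-corrected water
  signal of the purest-WM voxel (f_WM > 0.98) by the fully corrected
  STEAM amplitude; it is applied only on request, since it is needed only
  when the STEAM voxel lies outside the MRSI slice.

## Problem sizes used in the shipped studies

The recovery sweep runs 100 seeded noise-free phantoms (full default
geometry) and asserts worst-case molal recovery error < 0.1% per method
under each method's assumptions; the agreement study uses 5 subjects ×
4 ROIs × 3 metabolites = 60 ROI-mean pairs with 1% amplitude noise.
Both complete in seconds on one CPU.
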