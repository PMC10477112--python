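# Methods

## The measurement model

A proximity ligation assay renders each protein–protein colocalization event
as a bright, diffraction-limited dot. The quantification problem is therefore
segmentation plus normalization: how much dot area does an image contain, and
per how many cells (macro 1: DAPI nuclear area as the cell-number proxy) or
inside which compartment (macro 2: GFP-organelle area as the denominator).

Both macros share the same structure — every channel is processed
independently, an automatic threshold is computed once per channel on the
best-focus plane, and that single band is applied to the whole 3D stack.
"Area" of a 3D stack is the total foreground voxel count summed over z; the
units cancel in every reported ratio or percentage, so neither the xy pixel
size nor the 0.5 µm z-spacing enters any result (both are carried as
metadata only).

### Pipeline steps and defaults

| step | choice | default | rationale |
|---|---|---|---|
| pre-blur | isotropic 3D Gaussian, reflective borders | σ = 3 (nucleus), σ = 1 (PLA, organelle) | noise suppression scaled to object size; blurred data kept real-valued so thresholds see sub-integer structure |
| best focus | argmax over z of plane mean intensity | ties → smallest z | in-focus planes carry the most fluorescence |
| nucleus threshold | Li minimum cross-entropy, exhaustive scan | lower cut; upper = top of range | histogram-shape method suited to a large, bright object |
| dot/organelle threshold | Triangle, 256 bins over observed range | lower cut; upper = top of range | standard choice for sparse faint puncta: cuts just above the background mode |
| band application | `lower ≤ v ≤ upper`, inclusive | whole stack, one band per channel | bright-on-dark signal makes the upper bound non-binding |
| size filter (macro 1 only) | 3D connected components, 26-connectivity | min 4 voxels (PLA), 500 (nucleus) | rejects hot pixels and debris; config-exposed, recorded per image |

Li's threshold is found by exhaustively scanning every distinct intensity cut
and minimizing `−(S_b·log μ_b + S_f·log μ_f)` (class intensity sums and
means), which is the global optimum of the cross-entropy objective rather
than the usual fixed-point iteration. The objective is evaluated on **raw**
intensities: minimum cross-entropy is scale- but not shift-invariant, and the
histogram-based reference implementations operate on raw gray levels.
Consequence (documented, deliberate): the Li cut depends on the intensity
origin, so adding a constant offset to a nucleus channel moves its
segmented area, while the Triangle cut is exactly shift-covariant. Shifting
the image minimum to zero before the scan would make Li shift-invariant but
places the cut far too low on dark-background nuclear images, roughly
doubling the segmented nuclear area.

The Triangle cut maximizes the perpendicular distance between the
peak-normalized histogram and the chord joining the peak to the farthest
non-empty bin on the longer-tail side; mirrored images yield mirrored cuts
by construction (the histogram is flipped, solved, and mapped back).

Degenerate inputs are errors, not silent defaults: a constant best-focus
plane (no threshold exists) raises and the image is excluded with a logged
reason, as does an image whose nucleus or organelle foreground is empty
after filtering.

## Statistics

The image is the statistical unit for PLA and occupancy comparisons.
Outliers are removed per group before testing with a ROUT-style procedure
specialized to a location-only model: an iteratively reweighted fit with
Lorentzian weights `1/(1+(r/s)²)` estimates the robust center; the robust
residual scale is `RSDR = P68.27(|r|)·n/(n−1)`; each point receives a
two-tailed tail probability from `t = |r|/RSDR` on n−1 degrees of freedom;
and the most extreme residuals pass through a Benjamini–Hochberg gate at
level Q (equivalently, the i-th ranked residual is tested against
`α_i = Q(n−i+1)/n`). At most ⌊n/2⌋ points can be removed. At the default
Q = 0.1 % this flags any point in ≈0.2 % of clean normal samples (n = 50)
while catching a 10σ contaminant essentially always — "definite outliers
only". Whether ROUT runs per group (default) or on pooled fold changes is a
flag.

Group means are compared with the pooled-variance two-tailed Student's *t*
(Welch behind a flag), significance at p < 0.05, no correction across
panels. Zero-pooled-variance cases use the conventions t = 0, p = 1 for
equal means and p = 0 with a degenerate flag otherwise. Fold changes divide
every value by the calibrator-group mean. qPCR relative quantities follow
the ΔΔCT rule with technical duplicates averaged first and the mean of the
reference genes (e.g. RPL27 and HPRT1) as endogenous control; concentrations
below an assay's detection limit are replaced by half that limit (strictly-
below rule, censored count reported).

## CTF signal decomposition

With a C-terminal antibody the PLA total is `T = F + C` (flAPP and CTF
contributions), assuming equal per-event detection efficiency for the two
species — the model's central assumption. Measured fold changes
`F_neu = r_F·F_npc` and `T_neu = r_T·T_npc`, with `C ≥ 0` in both cell
types, constrain the unobserved split. Over all feasible splits:

* `min C_npc/C_neu = 1/r_T` (attained as `F_npc → 0`);
* `C_neu ≥ 0` forces `C_npc/F_npc ≥ (r_F − r_T)/r_T`.

Defaults `r_F = 1.63`, `r_T = 0.21` give bounds 4.76 and 6.76. `r_T` is
exposed as a parameter and a sensitivity table scans it (both bounds are
strictly decreasing in `r_T`); when `r_F < r_T` the whole C-terminal signal
could be flAPP, both infima collapse to 0 and the result is flagged
infeasible rather than silently adjusted. Only fold changes enter, so the
bounds are invariant to rescaling all absolute signals, and
`bound₁·r_T = 1` exactly in the feasible regime. A grid minimizer over the
split fraction (`brute_force_bounds`) is included so the closed forms can be
checked numerically on any inputs.

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the acquisition regime the pipelines were designed
for — 21-plane z-stacks at 0.5 µm spacing holding large DAPI-like nuclei,
sparse truncated-Gaussian PLA dots (σ = 1.5 voxels, cut at 3σ), and
vesicular organelle fields — with unit-gain Poisson noise plus Gaussian read
noise (σ = 3) applied after compositing, then quantization and clipping to
the bit depth. One seeded generator per scene consumes draws in a fixed
order (nuclei, organelles, in-organelle dots, outside dots, primary-channel
noise, PLA-channel noise), so scenes are bit-reproducible. Nuclei are
non-overlapping ellipsoids that may be clipped by the stack in z (a 10 µm
nucleus spans the whole acquisition); dots may overlap anything, stay 3σ
clear of the stack border, and outside-organelle dots stay 3σ clear of
organelles so the in/out split is exact.

Intensity defaults (8-bit scale: background 20, nucleus/organelle 160, dot
peak 235, in-plane nucleus radius ≈ 0.18 of the frame, 150 dots and 40
radius-6 vesicles per 160-px field) were fixed by a one-time calibration of
the thresholding regime: the Triangle cut must sit just above the background
mode and the Li cut on the nuclear edge, which is the regime the real
bright-dot/dark-background images occupy. They are config-exposed but the
defaults define the package's standard test conditions.

Dot ground truth is the **painted support** of the noise-free spot — every
voxel receiving at least 0.5 intensity units, i.e. what quantization makes
visible; for σ = 1.5 dots this is the full truncated ball. A half-peak
(FWHM) alternative is available (`dot_truth="fwhm"`), but it does not
correspond to anything a low Triangle cut recovers: the method deliberately
segments the whole visible dot, not its core.

What the generator does **not** model: optical PSF physics (no
Gibson–Lanni), z-anisotropic blur, spectral bleed-through, photobleaching,
autofluorescence structure, camera gain calibration, or per-cell biological
variability. Passing recovery tests therefore show that the pipeline
measures what was painted under realistic noise — not that it is unbiased
on real microscopes.

## Validation conditions and problem sizes

The standard validation experiments (`plaquant.validation`, run by both the
test suite and `scripts/acceptance.py`) use reduced, documented scales
chosen as the package's demo size: 160-px frames for ground-truth recovery
(20 seeds, noise-free and default-noise), 96-px frames for the power sweep
(50 repetitions of 15 images/group with a 4× dot-density difference,
full pipeline + ROUT + t test), and 10,000 / 5,000 datasets for the ROUT
null and contaminant calibrations. Typical results: ratio recovery within
~5 % noise-free and ~13 % under default noise (the noise raises the
Triangle cut and trims the dot halo); occupancy within ~8–10 percentage
points; power 100 %; ROUT null false-flag rate ~0.2 %.

## Known limitations

* **Empty PLA fields.** An image with no true dots has a constant noise-free
  PLA channel (threshold undefined → image excluded with a logged reason);
  with noise, any automatic threshold segments the noise tail and reports a
  spurious nonzero area. Fields expected to be empty need a control, not an
  auto-threshold.
* **Systematic halo bias.** Thresholded dot area includes the blur halo, so
  absolute areas are method-defined quantities; they are comparable across
  groups processed identically, which is how they are used.
* **Li origin-dependence.** See above; nucleus areas are comparable only
  across images with similar background offsets.
* **ROUT specialization.** The published procedure is for regression; the
  location-only adaptation here fixes the 68.27 percentile, n/(n−1)
  correction and the largest-first FDR gate, and is calibrated only for the
  univariate use made of it.
* **No per-dot statistics.** The pipelines measure areas, not dot counts or
  localization; object-level colocalization coefficients (Manders, Pearson)
  are out of scope.
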