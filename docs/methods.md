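# Methods

`cstetquant` converts voxel intensities of bright-field (BF) cryo-STEM
tomograms into absolute densities of mitochondrial calcium-phosphate
granules, using internal standards of known composition, and validates the
whole chain on synthetic phantoms. This note records the model, the
parameter choices, and their limits.

## Physical model

In the thin-sample, single-scattering regime the BF detector loses exactly
the electrons scattered beyond its outer acceptance semi-angle. The expected
signal lost per nm of path through a material is

    S = Σ_e  n_e σ_e      [nm⁻¹]

with `n_e` the number density of element *e* (atoms/nm³) and `σ_e` its
partial elastic cross-section for scattering beyond the cutoff (nm²). A
reconstructed BF voxel value is modelled as

    I = x − g · S

with one additive background `x` from unscattered illumination and one
global contrast gain `g`. Both are unknown per tomogram; the predicted
*ratios* of `(x − I)` between materials of known composition eliminate `g`,
and imposing one such ratio on two measured levels solves for `x` exactly:

    (I_ref − x)/(I_water − x) = S_ref/S_water   ⇒
    x = (ratio · I_water − I_ref)/(ratio − 1).

Given `x`, the intensity of a hypothetical solid block of crystalline
tricalcium phosphate (TCP, Ca₃(PO₄)₂ at 3.14 g/cm³) is extrapolated with
the predicted TCP/water ratio, fixing a linear scale on which any intensity
reads directly as a fraction of crystalline-TCP density, hence as a mass
density (× 3.14 g/cm³) and a molar density of formula units (÷ 310.17 g/mol,
computed from the packaged atomic weights).

Assumptions worth keeping in mind: linearity of intensity in local signal
(no exponential attenuation, no multiple scattering), a single additive
background (no per-voxel thickness or illumination correction), and
reconstruction fidelity sufficient that interior voxel values of objects a
few PSF widths across are quantitative.

## Reference compositions

Number-density profiles for the internal standards come from a packaged
table and can be recomputed from first principles:

* **Ribosome** — atom counts of the full particle spread over a 7000 nm³
  envelope, with the 42% solvent volume inside the envelope counted as bulk
  vitreous ice (the H and O rows therefore include solvent atoms).
* **Ribosomal RNA** — atom counts over the volume implied by a partial
  specific volume of 0.569 cm³/g. The RNA is the densest ribosomal
  component, so its ratio is paired with *peak* ribosome intensities while
  the whole-particle ratio pairs with *inclusive* levels.
* **TCP** — formula stoichiometry at 3.14 g/cm³.
* **Vitreous water** — H₂O at 0.93 g/cm³ (low-density amorphous ice);
  configurable.

The packaged table quotes densities at the precision of the published
reference values; recomputation reproduces every entry within 1% except the
RNA magnesium density, whose quoted 0.24 atoms/nm³ is inconsistent with its
own atom count (239 atoms over ≈2202 nm³ gives 0.109). The quoted value is
retained in the table; either choice moves the RNA signal by <0.5%, far
inside the calibration's other uncertainties.

Cross-sections ship as a per-element table for 200 keV and a 5 mrad BF
cutoff, with hydrogen set to zero (it does not scatter beyond the cutoff).
A screened-Rutherford (Lenz) model — Wentzel potential with screening
radius a₀Z^(−1/3), small-angle momentum transfer, relativistic wavelength —
is provided for sensitivity analysis. Its closed-form partial integral is
verified against quadrature, but its absolute values are roughly two orders
of magnitude below the packaged table, whose underlying convention is not
identified; the packaged table is authoritative for all calibration math,
and the model is never used there.

## Rounding and report conventions

All operations keep full precision internally. Reports quote signals to
three decimals and ratios to two, and — deliberately — compute ratios
*between the quoted signals* (e.g. 0.963/0.159 = 6.06, where the unrounded
quotient is 6.075): the reference evaluation chains its arithmetic through
table-precision intermediates, and the report layer reproduces that chain
so its cells can be compared digit-for-digit. Likewise the reported TCP
intensity row chains from the three-significant-figure background (30.9 →
−59.4, where the unrounded background 30.912 would give −59.5). The
op-level API (`estimate_background`, `extrapolate_tcp_intensity`,
`density_fraction`) never rounds. The ~0.3% gap between quoted-ratio and
unrounded-ratio chains is far below the method's real uncertainties
(threshold placement, composition assumptions).

Intensities above the calibrated background imply negative densities and
raise an error rather than clipping: they signal a calibration or
measurement problem the caller must see.

## Segmentation and morphometry

Granules are segmented by plain intensity thresholding (BF polarity:
foreground = voxels at or below the level) followed by connected-component
labelling, 26-connectivity by default (granules are compact blobs; 6 and 18
available). Per-component statistics report voxel count, volume, equivalent
spherical diameter d = (6V/π)^(1/3) and centroid; components below 10 nm
equivalent diameter are counted separately as noise specks (granules of
interest start around 20 nm). Volume fraction within an axis-aligned box
ROI (half-open voxel bounds) is foreground voxels over total voxels — the
estimator behind "granules occupy ~20% of the mitochondrial volume".

The Fourier band-pass used to remove reconstruction shading keeps spatial
wavelengths between the two cutoffs (in pixels), removing the DC component
whenever the upper cutoff is finite; it runs per (y, x) slice by default
(shading is a per-slice artifact) with a 3D radial option.

## Synthetic phantoms and what they test

A phantom is an ellipsoidal mitochondrion in cytosol, non-overlapping
spherical granules placed by rejection sampling with lognormal diameters
truncated to [20, 100] nm (median 50 nm, σ = 0.35), and 25 nm ribosome
spheres in the cytosol. Defaults encode the study conditions: a 256³ grid
at 2 nm voxels, granule fill 0.20 of the ellipsoid, granule density 0.40 of
TCP, background 24.3 with the gain set so pure water reads 16 — the same
scale as the reference evaluation. Each region takes the scattering signal
of its material (granules: fraction × TCP signal), intensities follow the
linear model above, then a Gaussian PSF (σ = 2 nm) and additive Gaussian
noise (σ = 1 intensity unit, ≈12% of the water-to-background contrast) are
applied. No noise magnitude or PSF width is published for real data; these
defaults were chosen once as a moderate-noise regime and are not tuned.
All randomness derives from the single spec seed.

Parameter recovery mimics the real workflow with ground-truth masks in
place of manual level picking: interior means of eroded masks give peak
levels (only granules ≥ 40 nm contribute, since smaller ones never reach
their plateau under the PSF); inclusive levels are half-contrast levels,
which cross the true boundary under a symmetric PSF; the background is
solved from the ribosome interior level with the *whole-ribosome* ratio
(phantom ribosomes are homogeneous, unlike real ones where RNA concentrates
the density). Recovered granule density and fill land within ±0.05 and
±0.02 of truth at the default conditions.

What passing these tests does **not** show about real data: the phantom
shares the analysis' own linearity assumption, so it cannot detect
nonlinear thickness effects; it has no reconstruction artifacts in the
calibration path (volumes are generated directly), no membranes or cristae,
no intensity gradients, and idealized uniform-density spheres for both
granules and ribosomes.

## Toy tomography path

A separate module projects volumes into single-axis parallel-beam tilt
series (±60° in 2° steps by default) and reconstructs by ramp-filtered back
projection or SIRT (additive correction from back-projected reprojection
residuals, Cimmino-style row/column normalization; the per-slice residual
norm is non-increasing). It exists to demonstrate missing-wedge behavior —
a ±60° series elongates a disk by ~1.2–1.3× along the beam axis — and is
deliberately kept out of the calibration tests so their correctness is not
hostage to reconstruction artifacts. Projection requires a square (z, x)
cross-section with content inside the inscribed circle.

## Numerical and I/O choices

* Lengths in nm, number densities atoms/nm³, mass densities g/cm³,
  cross-sections nm²; every cm³↔nm³ conversion goes through one helper.
* Atomic weights: IUPAC 2021 conventional values as a static table.
* Volumes read/written as MRC mode 2 (float32) via gemmi, voxel size from
  the header cell (override flag for absent headers). Label volumes are
  also written as float maps and cast back to integers on read — component
  counts can exceed the small-integer MRC modes.
* Problem sizes in the test suite: 128³–160³ phantoms at 4 nm voxels for
  routine checks and one 256³ phantom at 2 nm for the full-scale recovery;
  reconstruction demos run on 48–64 px slices. These sizes already put all
  estimators well inside their asymptotic regime (ROIs of 10⁶–10⁷ voxels).

## Known limitations

* The linear intensity model ignores exponential attenuation; thick or very
  dense specimens violate it.
* One additive background per tomogram; real reconstructions can carry
  residual shading beyond what the band-pass removes.
* The Lenz cross-section module is a relative/sensitivity tool only.
* Threshold "peak"/"inclusive" semantics follow the manual practice of
  adjusting a level until the objects of interest are selected; the package
  does not automate that judgement on real data.
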