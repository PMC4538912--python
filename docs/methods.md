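# Methods

## Physical model

⁹⁰Y is a pure β⁻ emitter (endpoint 2.28 MeV, mean energy per disintegration
E_avg = 0.937 MeV, physical half-life 64.1 h).  Microspheres are permanent
implants, so the cumulated disintegrations per voxel are
`N = A · T½ / ln 2` with no biological clearance term.  The maximum β range
is 11 mm in reference soft tissue (1.04 g/cc) and scales inversely with
density — 44 mm in 0.26 g/cc lung — which is the physics that drives every
difference between the dose engines at the liver–lung interface.

All volumes live on one isotropic grid (default 4.8 mm, a typical
reconstructed SPECT voxel).  Units are fixed throughout: Bq, g/cc, Gy, MeV,
with the single conversion constant 1.602176e-10 Gy per (MeV/g).

## The bundled dose-point kernel

The radial dose-point kernel Φ(r) (MeV/g per decay around a point source in
an infinite reference-tissue medium) is shipped as a plain-text table,
`data/y90_dpk_soft_tissue_synthetic.tsv`, generated by
`scripts/generate_dpk_table.py`.  It is a synthetic stand-in for a Monte
Carlo kernel tabulation: the classical Loevinger analytic β point-kernel
shape (c = 1 for endpoint energies above 1.5 MeV) with the apparent
absorption coefficient ν calibrated once so that X90 — the radius containing
90 % of the emitted energy — equals the widely published 5.3 mm for ⁹⁰Y in
unit-density water (giving ν = 7.105 cm²/g).  The kernel is expressed at
1.04 g/cc, truncated at the 11 mm maximum range (0.24 % of the energy), and
renormalized so its total energy is exactly E_avg.  Compared with Monte
Carlo kernels the Loevinger shape has a somewhat fatter exponential tail
near the range end; the X90 anchor keeps the energetically dominant region
realistic.  `load_dpk` accepts any user-supplied two-column table with the
same conventions.

## Voxel kernel (SK/SKD)

`build_voxel_kernel` voxelizes Φ into K: the mean dose to a target voxel
from a uniformly distributed source in the center voxel, by deterministic
8³ × 8³ sub-voxel quadrature per voxel pair.  Two numerical points:

* the **self-voxel integral is singular** (Φ ~ r⁻²); point quadrature
  converges as slowly as O(1/n), so the self value is computed by an exact
  radial reduction instead: the pair integral equals
  (1/V) ∫ Φ(|u|) T(u) du with the separable tent T (the cube
  autocorrelation), which in spherical coordinates becomes a 1D integral
  against the spherically averaged tent W(t).  A 3·10⁷-pair Monte Carlo
  oracle in the test suite confirms the value to well under 1 %;
* only one sorted octant of offsets is computed and the kernel is filled by
  symmetry, so K is exactly invariant under sign flips and axis
  permutations; after construction K is rescaled so its total energy is
  exactly E_avg (conservation is then exact for fully contained sources).

The default grid is 7×7×7 at 4.8 mm, the smallest odd grid containing the
11 mm support.  Convolution (`dose_sk`) is a zero-padded FFT convolution —
no wrap-around — with sub-1e-6 negative residues clamped to zero.

## Reference transport engine

`dose_rt` is the package's deterministic reference ("truth") engine.  For
each target voxel t it sums over source voxels s

    D(t) = Σ_s N_s · Φ_pair(ℓ_eff) · (ℓ_eff / ℓ_geo)³ · (ρ_ref / ρ_t) · c

where ℓ_geo is the center-to-center distance, ℓ_eff the radiological path
length (line integral of ρ/ρ_ref along the segment, traced with the
standard Amanatides–Woo/Siddon voxel traversal), and pairs beyond the
kernel support contribute nothing.  The construction makes three deliberate
numerical choices:

* **Pair-averaged profile.**  Φ_pair(r) is the orientation-averaged
  voxel-to-voxel dose for two voxel-sized cubes at center distance r, not a
  point evaluation of Φ: with 4.8 mm voxels and an 11 mm-range kernel,
  point sampling at lattice distances cannot conserve energy.  Φ_pair is
  computed by the same exact radial reduction as the self value (for two
  independent isotropic directions the relative-vector magnitude has the
  classical t/(2sr) density, collapsing the 6D pair integral to 1D
  integrals against t·W(t)).  The profile is truncated at the radius
  containing 99.8 % of its energy and normalized so its continuum lattice
  limit conserves E_avg.
* **Equilibrium-exact self term.**  The self-voxel contribution is
  tabulated as the remainder that makes the uniform-medium lattice sum
  reproduce the local-deposition dose exactly at every density scale
  s = ρ/ρ_ref (s ∈ [0.1, 3.2]).  At s = 1 it equals the physical self dose
  (the voxel kernel's center value); at other densities it additionally
  absorbs the small residual anisotropy of the isotropized pair profile
  (|correction| < 1 % of the equilibrium bracket, occasionally slightly
  negative; any resulting negative voxel dose is clamped like a convolution
  residue).  Uniform-medium equilibrium at 1.04 and 0.26 g/cc is exact to
  < 0.1 % — the property the interface comparison rests on.
* **Exact uniformity shortcuts.**  A per-pair lower bound from the minimum
  density over the spanned z-slab range rejects out-of-range pairs without
  tracing, and when the density is constant over that range (uniform
  compartments) ℓ_eff = ℓ_geo · ρ/ρ_ref is used directly.  Both shortcuts
  are exact; they make slab and phantom studies tractable on one CPU.  The
  expensive engine accepts a target mask and is evaluated only on analyzed
  voxels (profile columns, VOI voxels).

Compared with a condensed-history Monte Carlo, this engine has no lateral
scatter redistribution or backscatter at interfaces; it shares the Monte
Carlo's equilibrium limits and range stretching, which are the effects the
interface analysis measures.

## Slab interface study

`run_interface_study` builds a two-compartment slab (liver z ≤ 0 at
1.04 g/cc, lung z > 0 at 0.26 g/cc) on a 61³ core at 4.8 mm, extended by a
10-voxel (48 mm ≥ lung-range) margin on every face with the same pattern so
the profile region is at equilibrium — the desk-scale equivalent of padding
the phantom to quasi-infinite dimensions.  Uniform activity is placed in
one compartment at a time; limited resolution is emulated by isotropic
Gaussian blur (σ = FWHM/2.3548, reflective boundaries, which continue the
mirror-symmetric slab pattern exactly); lung shunt fractions are realized
by superposing the per-unit-activity compartment doses with weights
(1−LS, LS) — superposition is exact because all engines are linear in N.
Each compartment's dose is normalized per unit total compartment activity,
so the LS weights act as activity fractions.

Profiles average the central 7×7 voxels per x-y plane; percent differences
are taken against the truth, defined as the reference transport engine
applied to the unblurred activity at the same LS.  Agreement intervals
(|Δ| ≤ 10 %) are found after linear interpolation onto a 1 mm grid —
interval endpoints finer than the voxel pitch imply sub-voxel
interpolation; endpoints sit on the last non-compliant millimetre, and
outermost compliant intervals extend to ±∞ at the equilibrated profile
boundaries.  Isolated 1–2 mm sliver intervals next to the interface are
discretization artifacts of threshold crossing; the summary metric
(`noncompliance_depth`) therefore reports the largest distance from the
interface at which any engine/LS combination still exceeds the threshold,
which is robust to them.

## VOI analysis

Mean doses are arithmetic means over mask voxels; DVHs are cumulative
(fraction of the VOI receiving at least each dose, default bin 0.5 Gy), and
the DVH integral reproduces the mean dose to within half a bin.  The
liver–lung interface surface is the set of voxel faces where the two masks
are 6-adjacent; a voxel is excluded from a remainder VOI when its center
lies within the margin of the nearest face center (KD-tree distances — at
oblique surfaces this voxel-based distance can differ from a contour-based
expansion by sub-voxel amounts).  The sensitivity regression fits the
original VOI mean dose (y) against the remainder mean dose (x) by ordinary
least squares across the cohort and also reports the cohort-mean percent
change.

## Synthetic phantoms

`generate_phantom` builds a liver-dominant "patient": an ellipsoidal liver
(clipped at a horizontal liver–lung interface plane) in soft tissue with
1–3 spherical tumors at uptake ratios 2–6, a lung half-space at 0.26 g/cc
whose lower 12 slabs form the right-lung VOI carrying the lung-shunt
activity, and an inactive lung padding above it so β energy escaping upward
stays on the grid.  Imaging is emulated as PSF blur (default 20 mm FWHM, a
typical post-therapy SPECT resolution) with proportional counts and
optional Poisson noise; the self-calibration step makes the absolute counts
scale irrelevant.  The default cohort is 17 phantoms with 31 tumors in
total, administered activities drawn uniformly from 1.13–5.21 GBq and lung
shunts from 1–20 % (uniform shapes are the package's choice), all driven by
one master seed: a fixed seed reproduces bit-identical volumes and
manifests.

What the phantoms do **not** emulate: attenuation, scatter, collimator
response and reconstruction artifacts, respiratory motion, realistic
anatomy, or noise correlations.  Tests passing on these phantoms therefore
validate the dosimetry and analysis chain — conservation, equilibrium,
engine agreement structure, interface sensitivity direction — not the
quantitative accuracy of any clinical imaging protocol.

## Problem sizes and determinism

Default problem sizes (61³ slab core + margins; 42×42×52 phantoms;
17-phantom cohort) keep a full analysis around a minute on one CPU while
leaving every region of interest several kernel ranges away from grid
effects.  Everything except the optional Poisson noise and the cohort
parameter sampling is deterministic; both are driven by explicit seeds.

## Known limitations

* The bundled DPK is an analytic stand-in, not a Monte Carlo tabulation;
  its range-end tail is approximate (the X90 anchor fixes the dominant
  region).
* The transport engine is not a Monte Carlo: no backscatter or lateral
  scatter redistribution at interfaces, and no bremsstrahlung photon dose
  (β-only, as for all engines here).
* Interface distances are voxel-face based; contour-based margins can
  differ by sub-voxel amounts at oblique surfaces.
* Densities below 0.1·ρ_ref are outside the transport self-term table
  (clamped); β dosimetry in air-like media is out of scope.
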