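# Methods

## Scope and model

The package analyses point-dose IMRT QA in a homogeneous phantom. Its
objects are: an IMRT **plan** (beams → static MLC segments with MU
weights), per-beam 3D **dose grids** on a voxel lattice, a cylindrical
chamber **contour** on that lattice, and scalar chamber
(pseudo-)measurements. Two delivery modes of the same plan are compared:
*rotated* (each beam at its planned gantry angle) and *collapsed* (every
beam delivered from one angle, default 0°, with leaf sequences and MUs
untouched). All plan-complexity scores are functions of leaf positions and
MUs only, so they are identical between modes by construction; the dose
metrics differ because crossfiring from many angles averages each beam's
lateral and depth gradients over the chamber while collapsed delivery adds
them coherently.

## Complexity scores

The plan score is the MU-weighted mean over beams of the MU-weighted mean
over segments of AAV × LSV.

- **Open-leaf criterion.** A leaf pair counts as open when its gap exceeds
  `gap_threshold` (default 0.05 cm). Without a criterion, closed pairs
  parked behind the jaws would dominate the leaf-sequence statistics.
- **LSV.** Per bank, over the N open leaves:
  `Σ_{n=1}^{N−1} (pos_max − |pos_n − pos_{n+1}|) / ((N−1)·pos_max)` with
  `pos_max` the open-leaf position range. A bank with N = 1 or
  `pos_max = 0` is perfectly regular and contributes factor 1 (avoids
  0/0). The adjacent-difference form over N−1 pairs with an absolute value
  is the only self-consistent reading of the published construction.
- **AAV.** Segment aperture area over the beam's maximal per-leaf aperture:
  the denominator uses, per leaf, the maximum left-bank coordinate and the
  minimum right-bank coordinate over the segments of the *same beam*,
  which keeps the score in [0, 1] and composes consistently with the
  per-beam MU weighting. A fully closed segment scores AAV = 0 and
  contributes nothing regardless of LSV.

## Dose metrics

- **DVH convention.** Cumulative DVHs are exact voxel-rank curves (no
  binning). `D_x%` is the largest voxel dose received by at least x% of
  the structure volume, without interpolation — directly testable against
  a descending-sort oracle. `HI = (D2% − D98%)/D_avg` over the chamber.
- **COIN.** The reference isodose RI is the mean chamber dose of the
  delivery mode's total grid. The comparison shell is the chamber dilated
  by 1.5 cm (Euclidean distance between voxel centers, via an exact
  distance transform with per-axis sampling). The shell *includes* the
  chamber: with an annulus the ideal case (isodose exactly covering the
  chamber) would be undefined, whereas here it yields COIN = 1.
- **Beam–chamber intersection.** The clinical determination was visual; the
  quantitative surrogate asks whether any chamber voxel receives at least
  `frac_of_max` (default 0.5) of the beam's reference dose. When the beam
  axis is known (the pipeline passes each beam's gantry angle), the
  reference is the beam's maximum dose in the transverse slab through the
  chamber center rather than the whole-grid maximum: with a whole-grid
  reference, obliquely incident beams in a 30 cm-wide phantom fail the
  test purely through depth attenuation and inverse-square falloff even
  when their aperture is centered on the chamber, which conflates depth
  with a lateral miss and biases rotated deliveries. Without an axis the
  whole-grid maximum is used.
- **Combined uncertainty.** Per-beam Type-A percent uncertainties combine
  as `√(Σ i²)/n` for the n-beam sum; for equal i this is `i/√n`.

## Small-field correction

`k_Qclin` is the double ratio of water-sphere to air-cavity dose in the
clinical and reference fields. In the synthetic pipeline the cavity dose
is surrogated by the mean dose over the chamber cylinder and the
dose-to-water by the mean over a sphere of equal volume (0.65 cc, radius
0.538 cm) at the same point: the two shapes average spatial gradients
differently, so the factor deviates from 1 exactly when the field is
non-uniform across the chamber — the mechanism the correction exists for —
and is computed, never assigned. The reference field is the open
10×10 cm² beam at gantry 0 on the same phantom. Uncertainties on the four
doses, when given, propagate in quadrature (independence assumed; the
correlated-sampling variance reductions of full transport codes are out
of scope). Per-beam factors use per-beam dose quadruples; the plan-level
factor uses the summed-field doses, not an average of per-beam factors.

## Toy dose engine

Per segment, each voxel center is projected along the diverging ray from
the source (gantry rotation about the y axis, isocenter at the chamber
center, SAD 100 cm) onto the isocenter plane; the dose contribution is

    MU × fluence(u, w) × exp(−μ · water_depth) × (SAD / r)²

where the fluence is the aperture indicator of the voxel's leaf pair
smoothed along the leaf-travel direction with a Gaussian penumbra
(σ = 0.3 cm), μ = 0.049 cm⁻¹ is a 6 MV-like effective attenuation
coefficient, `water_depth` is the ray's path length from the phantom
surface, and r the source–voxel distance. The output is scaled so one MU
delivers about 1 cGy near the reference point. The engine is deterministic
and models **no** scatter, buildup, leaf transmission, tongue-and-groove,
or electron transport; it reproduces the geometric structure of composite
deliveries (crossfire averaging, depth gradients, penumbrae), which is
what the metrics respond to — it is not a dosimetric engine, and absolute
dose levels carry no clinical meaning.

MLC geometry: 20 leaf pairs of 0.5 cm width stacked along the rotation
axis (10 cm span), leaf travel perpendicular to it; the field edge along
the leaf-stack direction is sharp.

## Synthetic cohort

`generate_plan` places beams at evenly spaced gantry angles over the full
circle and draws each segment's aperture from a modulation level
m ∈ [0, 1]: center offset ~ U(−3m, 3m) cm, half-width shrink up to 70%·m,
per-leaf jitter ~ m·1.5·N(0,1) cm, and leaf pairs closed with probability
0.3m; segment MUs ~ U(5, 15). m = 0 reproduces a static rectangular field
(MCS exactly 1) and the mean MCS decreases strictly with m (verified over
seeded batches). Defaults mirror the emulated study: 20 patients, 7–19
beams per plan, 6 segments per beam, modulation 0.5 (chosen to give
mid-range plan MCS values around 0.2–0.4, the regime where delivery mode
matters).

Pseudo-measurements are the chamber-contour mean dose of each mode's total
grid with 0.5% Gaussian noise — the order of the output-stability drift a
clinic corrects between QA fields. They emulate a reading already
converted with the reference-field calibration, i.e. *without* the
small-field correction; applying `k_Qclin` should therefore move them
toward the computed water-sphere dose, and the cohort RMS statistics test
exactly that. The per-beam Type-A uncertainty surrogate grows as
`u₀·√(plan-mean/beam-mean)` of the chamber dose (u₀ = 0.3%, capped at 5%),
emulating the poorer statistics of beams that barely hit the cavity.

What passing the synthetic cohort does *not* show: agreement with physical
chamber measurements, real accelerator beam models, chamber perturbation
physics, or TPS dose calculation accuracy. The cohort demonstrates the
analysis machinery and the geometric mechanism of the rotated-vs-collapsed
contrast, not clinical dosimetry.

## Numerical choices

- Grid coordinates are 0-based with half-open voxel extents; masks are
  defined on voxel centers. The default lattice is 100×100×57 voxels
  (the 17 cm extent is covered by 57 voxels of 0.3 cm, within the
  one-voxel tolerance the phantom spec allows).
- Chamber rasterization at 0.3 cm voxels yields 32 voxels (0.864 cc) for
  the 0.65 cc cylinder; DVH metrics on it are coarse but exact under the
  rank convention.
- Segment MU weights from DICOM control points are cumulative-meterset
  differences times the beam meterset; leaf positions of a segment are the
  mean of its two control points (the standard discretization of dynamic
  delivery into step-and-shoot segments). Sub-meterset float round-off is
  absorbed into the last segment so MU invariants hold exactly.
- Dilation uses `distance ≤ margin + 1e−9` to make integer-multiple
  margins inclusive under floating point.
- JSON plan serialization uses Python's repr-based float round-trip, so
  write→read is bit-lossless.
- The collapsed target angle defaults to 0°; it is a configuration choice,
  not a measured convention.

## Problem sizes

The shipped tests and the acceptance script use 20-patient cohorts at the
full default lattice for the end-to-end checks, and a 9×9×9 cm phantom
variant (30³ voxels, chamber at mid-depth — a symmetric lattice that also
serves the opposed-beam symmetry oracle) for unit-level engine tests.

## Known limitations

- The toy engine's missing buildup region makes near-surface dose maximal
  at the entrance voxel; depth-dose shapes are exponential, not clinical.
- Collapsed-vs-rotated intersection fractions are both 1.0 for
  centered synthetic apertures; real plans with off-axis targets produce
  the informative sub-unity fractions.
- `k_Qclin` magnitudes from the shape-averaging surrogate (up to ~8% at
  modulation 0.5) are larger than chamber-physics values for real fields;
  only their structure (growth with HI, mode contrast) is meaningful.
- RTSTRUCT rasterization assigns each planar contour to its nearest grid
  slice; sub-slice contour spacing is not interpolated.
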