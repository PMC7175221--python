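# Methods

This note documents the models, conventions and numerical choices behind
cdsolv, in the order a trajectory flows through the package.

## Topologies and the mass schemes

The parser reads the GROMACS `.top`/`.itp` dialect. Only `[moleculetype]`,
`[atoms]` and `[bonds]` are interpreted; every other section is carried
verbatim, and serialising an unmodified file reproduces the input
byte-identically. A mass edit rewrites only the mass token of the affected
atom lines, preserving the column width and the decimal count of the
original token, so review diffs show nothing but the masses. Multi-molecule
files are supported; the transform applies to one named `[moleculetype]`,
and solvent/ion blocks are never touched.

Polar hydrogens are found from connectivity: an atom whose element
(inferred from the leading letters of its name, after stripping digits) is
H, bonded to exactly one heavy atom whose element is O, N or S. An explicit
name list can override the inference. A hydrogen bonded to two heavy atoms
has no unique mass-transfer partner and is an error, as is an unbonded one.

* **HMR** moves `delta` (default 3 Da) from the heavy partner to the
  hydrogen. The transform refuses to proceed if any heavy atom would end up
  no heavier than a hydrogen bonded to it — the regime where the scheme is
  unusable — and this is an error rather than a warning because the
  constraint is physical, not stylistic. Conservation of total mass is
  exact in floating point (the same `delta` is added and subtracted).
* **H2Q** sets each selected hydrogen to `target_h_mass` (default 4 Da).
  A hydrogen already at or above the target triggers a double-application
  guard. The selector defaults to the polar set; `hydrogens="all"` extends
  it to every hydrogen, which is what the all-atom mass-arithmetic
  comparison uses. The scheme is exposed for any O/N/S-bound hydrogen even
  though only hydroxyls are exercised here.

The bundled reference topologies (united-atom and all-atom six-unit
pyranose macrocycle, dodecyl-sulfate sodium salt) are synthetic stand-ins
built in `cdsolv.synth`: correct stoichiometry (C₃₆H₆₀O₃₀; NaC₁₂H₂₅SO₄),
connectivity, and standard united-atom carbon masses (CH1 13.019, CH2
14.027, CH3 15.035 Da), with hydrogens at a nominal 1 Da so the scheme
deltas are exact integers. Their charges are placeholders; nothing in the
package depends on them.

## Trajectory model and alignment

Coordinates are Angstrom everywhere; MDAnalysis handles GRO/PDB/XTC/TRR
I/O and the nm→Å conversion at the boundary. Boxes must be orthorhombic;
triclinic input is rejected. For lossless synthetic round-trips the
generator writes TRR (XTC's compression quantises at 10⁻³ nm).

The body frame of the complex is defined by the twelve O4 atoms: origin at
their centroid, axis from the CD2 O4-centroid to the CD1 O4-centroid (CD1
is the ring nearer the surfactant head atom; a helper applies that rule
from the first frame), and a roll reference from the axis to the first O4
of CD1, orthogonalised. O4 is the right fit set because those atoms move
least; the large-amplitude O6 motion would contaminate a fit.

* **Bulk alignment** builds a fixed reference from the *first frame*
  (rotated so the body frame coincides with the lab frame, axis along the
  configured target axis, default X) and Kabsch-fits every frame's twelve
  O4 atoms onto it. A fixed single reference rather than a running one
  keeps the map accumulation frame-order independent. Fits are
  unit-weighted (the twelve O4 are equivalent atoms). The proper-rotation
  branch of the SVD solution is always taken; reflections are never
  returned.
* **Interface alignment** is two-stage. Stage 1 rotates the *final* frame
  about the interface normal (z) so the in-plane projection of the body
  axis points along the target axis, keeping the water slab horizontal.
  Stage 2 fits every frame to that structure on the O4 atoms with the
  rotation constrained to be about z (closed-form 2-D Procrustes) plus a
  translation. The constraint is deliberate for both stages: an
  unconstrained rigid fit would tilt the slab and, worse, would pin the
  complex to the reference and erase the very tilt (pitch) and spin (roll)
  signals the orientation analysis must report. Pitch and roll are exactly
  invariant under the constrained fit; yaw after alignment is measured
  relative to the fitted reference heading.

Solvent wrapping moves whole molecules (keyed on the oxygen) by integer
box vectors to the image nearest a centre, never splitting a molecule.
The hydration and hydrogen-bond modules do not require pre-wrapping: they
compute minimum-image distances directly (periodic KD-tree), which is
equivalent and exact.

## Density and dipole maps

A water is attributed to a region iff its **oxygen** is inside — the
standard convention for oxygen-density maps. Binning is half-open
[lo, hi) on every axis with edges on integer multiples of the 0.5 Å
resolution, so bin membership is reproducible and a point on an edge
belongs to exactly one bin.

The slice set is: a central perpendicular slice covering −1.5…+1.5 Å along
the axis, plus 1–4, 4–7, 7–10 and 10–13 Å toward each ring (nine
perpendicular slices in total; the 1–1.5 Å band on each side is
deliberately present in both the central and the first lateral slice), and
one parallel 3 Å slab containing the axis. Shells are thirteen 1 Å coaxial
cylinders covering 0–13 Å, unrolled onto an (arc-length, axial) grid with
the azimuth expressed as φ·r_mid and the bin count chosen to make arc bins
≈0.5 Å wide at mid-radius. φ = 0 is the first lab axis perpendicular to
the body axis, which bulk alignment ties to the body roll reference, so
cylindrical maps are reproducible across runs.

Densities are mean oxygen counts per frame per bin (a conversion to number
density in Å⁻³ by the bin volume is provided but not applied by default —
published maps of this kind are relative). Dipoles are per-bin **vector**
means in Debye (μ = Σqᵢrᵢ, origin-free because the models are net
neutral; 1 e·Å = 4.8032 D). Vector averaging is what makes orientational
sources and sinks visible and lets an isotropic distribution cancel toward
zero. Bins never visited carry NaN, not zero: zero is a physical value
(cancellation) and must remain distinguishable from absence of data. The
accumulation grid covers ±16 Å in-plane/axially by default; the reported
occupancy is the mean number of waters inside that window. Both SPC
(−0.82/+0.41/+0.41 e, OH 1.0 Å, 109.47°; |μ| = 2.27 D) and TIP3P
geometries are built in. Stored dipoles are full 3-vectors; any projection
onto a map plane is a plotting choice.

## Hexagon areas and orientation

Hexagon area projects the six class oxygens of a ring onto their
least-squares plane (SVD of the centred coordinates) and applies the
shoelace formula **in topological ring order**. Angular re-sorting of the
vertices is deliberately avoided: it would silently repair
self-intersecting configurations that should instead surface as area
changes. Collinear or coincident vertices (second singular value ≈ 0) are
an error. Optional smoothing is a boxcar ('valid' mode) with a window of
`smooth_ns` converted to frames.

Orientation follows the aeronautical convention with the interface as the
horizon (normal = z): pitch is the elevation of the body axis out of the
interface plane, positive when the CD1 end points toward the air, in
[−90°, 90°]; yaw is the azimuth of the axis projection, in (−180°, 180°];
roll is the rotation of the roll reference about the axis measured against
a horizon-anchored frame (e₁ = normal orthogonalised to the axis,
e₂ = axis × e₁), unwrapped across frames and reported relative to frame 0
so full turns accumulate. The horizon anchor makes roll invariant to any
rotation of the whole system about the normal, i.e. the same before and
after interface alignment. When the axis is numerically parallel to the
normal, yaw (and the roll anchor) is undefined; the previous value is
carried and the frame flagged. The complex-to-water distance is the
|z|-separation between the O4 centroid and the water centre of mass — the
slab geometry makes the normal component the meaningful one.

## Hydration and frame selection

Ring hydration counts distinct water oxygens within the cutoff of any ring
atom (`any_atom`) or of the ring centroid (`ring_center`), each water at
most once per ring, with minimum-image distances. The KD-tree acceleration
is exact — tests assert set-level equality with an all-pairs O(N²) oracle,
not approximate agreement. Counts are monotone in the cutoff within a
mode; no ordering between modes is asserted because none holds
geometrically.

Minimum-hydration selection interprets "the ring with minimum hydration"
per frame: the argmin over one ring system's six counts claims the frame.
Ties assign the frame to every tied ring — dropping tied frames would bias
each ring's conditioned map — and are reported. Without ties the frame
sets partition the trajectory. No contiguity (minimum-dwell) filter is
applied to the segments; that is a deliberate choice, flagged for
sensitivity analysis.

## Hydrogen bonds

Detection uses the common geometric criterion: donor–acceptor distance
≤ 3.5 Å and hydrogen–donor–acceptor angle ≤ 30°, the documented defaults
of the widely used GROMACS tool (the tool's thresholds, not bespoke ones).
Lifetime is the **continuous** estimate: the mean duration of maximal
uninterrupted bonded runs per donor–acceptor pair, a k-frame run counting
k·Δt. Runs touching a trajectory end are censored — the true dwell is at
least the observed one — and are included at observed length with their
count reported; at realistic run/trajectory length ratios the bias is
negligible, but the count lets a user judge. A `forgive_frames` option can
bridge ruptures up to that many frames; it defaults to 0 (one unbonded
frame breaks a run). An autocorrelation-based estimator would weight long
runs differently; the continuous definition was chosen as the simplest
estimator with an unambiguous generative counterpart (see below), and
absolute lifetimes from other estimators are not comparable number for
number.

## The synthetic generator

The generator produces statistical structure, not dynamics: no
interactions, no energies. Its purpose is parameter recovery — every
analysis is tested by asking it to read back what the generator was told
to produce.

* **Scaffold**: six sites per oxygen class per ring at 60° spacing, radii
  O2 5.0 / O3 5.1 / O4 4.2 / O5 3.9 / O6 3.3 Å and per-class axial offsets
  (hydroxyl rims facing the inter-ring interface, primary rim outward),
  O4 planes 8 Å apart, head atom on the axis 3 Å beyond CD1, polar
  hydrogens 1 Å radially outward from O2/O3/O6. The radii are
  macrocycle-like by construction (the O4 ring of a six-unit pyranose
  macrocycle is ≈4.2 Å); the analyses depend only on labels and
  selections, not on these numbers. Optional O6 modes: azimuthal "petal"
  arcs with opposite handedness in the two rings, and a radial breathing
  oscillation (a pure azimuthal wave leaves hexagon area constant to
  second order, so area-modulation fixtures use breathing).
* **Waters**: rigid three-site SPC geometry so the dipole machinery is
  exercised end to end. Oxygen positions are rejection-sampled against a
  radial (cylindrical, about the body axis) relative-density profile; the
  default layered profile is three 1.5 Å high–low–high bands
  (1.8/0.6/1.5 relative to bulk) starting at the scaffold surface,
  emulating the tight solvation layering around a well-dressed cylindrical
  solute. Dipole directions are von Mises–Fisher about the local radial
  direction with concentration κ (κ = ∞ exactly radial), or isotropic.
  Defaults (1500 waters in a 40 Å box ≈ bulk-density coverage of the first
  shells) were chosen once as representative and are not tuned per test.
* **Trajectories**: per-frame rigid-body pose (random-walk translation and
  rotation), constant-rate roll about the body axis, an optional 90° flip
  of the axis toward the normal at a chosen frame (the
  parallel→perpendicular adsorption event), and either per-frame
  resampling of the water field or a fixed field with Gaussian jitter. The
  interface option carves a dry cap: waters within a radius (default 6 Å)
  of a named ring's centre are removed, emulating the air-exposed ring of
  an adsorbed complex. With a cap the kept-water count is clamped to the
  first frame's so the atom count is constant. All outputs are
  reproducible from (spec, seed).
* **Telegraph process** (for lifetime checks): a discrete-time two-state
  chain with per-frame exit probability Δt/τ, i.e. geometric dwells — the
  discrete-time exponential — with mean exactly τ. This is the well-posed
  discrete counterpart of "exponential dwells sampled every Δt": a
  continuous-time telegraph subsampled at Δt suffers detection and merging
  bias of order 10 % on run-length estimates, which would measure the
  sampling artefact rather than the estimator.

What the generator does **not** emulate: water–water correlations,
hydrogen-bond networks in the solvent, realistic diffusion, box-spanning
interfaces with capillary waves, or coupling between complex motion and
solvent structure. Passing tests therefore demonstrate that the analyses
measure what they claim on known structure — not that a particular force
field reproduces experiment.

## Numerical choices and degenerate inputs

* Kabsch fits reject degenerate (collinear) references via the singular
  values; the determinant correction guarantees a proper rotation.
* Alignment is idempotent to < 10⁻⁹ Å; inter-atomic distances are
  invariant under it (rigid transforms only).
* Roll unwrapping assumes per-frame increments < 180°; fixtures and real
  10 ps-spaced trajectories are far below that.
* Map accumulation is order-independent by construction (pure binning).
* The mass-arithmetic acceptance checks compare at one decimal (±0.1
  percentage point): with exact united-atom masses the polar-hydrogen
  percentage is 5.55 %, printed sources round it to 5.5.
* Problem sizes in tests and the acceptance script (10⁵ water samples for
  density recovery, 10⁵ telegraph frames, 200 oracle frames of up to 2000
  waters, 501-frame roll fixtures) were chosen to put sampling error well
  inside the stated tolerances while keeping the whole suite in seconds.

## Known limitations

* Orthorhombic boxes only; no triclinic support anywhere.
* Interface normal is fixed to z; slabs must be xy-parallel.
* The hydrogen-bond lifetime is a single estimator; ACF-based lifetimes
  from other tools are not numerically comparable.
* Map wrapping assumes solvent was generated or wrapped near the complex;
  maps do not re-wrap after rotation (rotated frames have no exact
  periodic images).
* The CLI `maps` subcommand re-aligns internally rather than trusting a
  previously aligned file, trading a little compute for reproducibility.
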