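# Methods

This package analyzes molecular-dynamics trajectories of cardiac
thin-filament models — F-actin fragments (typically 26 monomers)
decorated with tropomyosin (Tpm) strands and troponin (Tn) complexes —
and estimates the geometric and mechanical observables such
trajectories carry: the genetic-helix parameters of F-actin, the
bending / longitudinal / torsional stiffness of the filament, the
angular and radial mobility of Tpm on the actin surface, the
occupancy of stabilizing actin–Tpm hydrogen bonds, and the coiled-coil
skeleton geometry used when assembling filament models from cryo-EM
fragments.

## Rigid-body removal (frame normalization)

All observables are computed after removing rigid-body motion from
each frame independently:

1. the mass-weighted center of mass (COM) of every actin monomer is
   computed from the component map (all atoms of the monomer's residue
   blocks);
2. the filament axis is fitted through the COMs and rotated onto z,
   with the COM centroid translated to the origin;
3. the frame is rotated about z so that the linear regression of the
   COM azimuth phi on the axial coordinate z has zero intercept.

**Axis fit.** The classical choice — the total-least-squares line,
i.e. the principal axis of the COM point cloud — carries a systematic
tilt on a helix of finite length: unless the filament spans an integer
number of turns, the z-weighted radial unit vectors of the monomers do
not cancel, and the principal axis tips toward that residual.  For a
26-monomer filament with a 166.6-degree step the tilt is ~0.03 rad and
biases d by ~0.05% and phi by ~0.3 degrees.  `normalize_frame`
therefore refines the axis with a fixed-point iteration that
decomposes the COMs into (straight axis) + (quadratic centerline
displacement, the thermal bend) + (constant-radius helical offset):
in the current axis frame the bend estimate is subtracted before
reading each monomer's azimuth, the mean-radius helical offset at
those azimuths is stripped, and a full quadratic (curvature + slope +
offset) is refitted, its linear and constant parts being absorbed into
the axis update.  On an ideal helix the fixed point is the exact
construction axis (recovered to ~1e-13); on a bent frame the
curvature is carried by the quadratic term so the axis does not tilt
with the bend.  Convergence is linear with a rate close to one, so an
Aitken extrapolation along the slow mode is attempted every third
iteration and kept only when it reduces the step residual.  The plain
TLS line remains available as `fit_filament_axis`.

**Azimuth unwrapping.** The genetic helix is left-handed with a step
near -166.6 degrees.  Bending perturbs monomer azimuths by up to tens
of degrees at the filament ends, which can push a step past -180
degrees — where nearest-branch unwrapping would flip it to +~180.
Monomer-azimuth sequences are therefore unwrapped with steps mapped
into (-360, 0], which is correct for any left-handed step
(`unwrap_signed_degrees`).  Long-helix marker sequences (every other
monomer, step ~+27 degrees) and Tpm chains use ordinary nearest-branch
unwrapping.

## Helix parameters

Per frame, d is the mean axial COM spacing and phi the magnitude of
the mean azimuthal step over adjacent monomer pairs, after excluding
`end_exclusion` monomers (default 2) at each end, where fluctuations
are inflated by the artificial cuts.  The apparent period
P = d·pi/(pi − phi) is evaluated by default on the per-frame mean
(d, phi); averaging per-pair periods instead is available
(`period_averaging="per_pair"`, pairs with an instantaneous step
beyond 180 degrees skipped) because published mean
values are consistent with more than one averaging order.  Trajectory summaries
report mean ± SD over all frames and over the second half (by time),
to expose equilibration drifts.

## Bending stiffness (worm-like chain)

Per frame the monomer COMs are projected to the (x,z) and (y,z) planes
and fitted with parabolas x = kx z²/2 + bx, y = ky z²/2 + by.  The
cosine of the angle between z and the parabola tangent at the segment
end, cos a = 1/sqrt(1 + l²(kx² + ky²)), is averaged over frames and
inverted through the worm-like-chain relation <cos a> = exp(−l/xi),
giving the persistence length xi and Kb = xi·kB·T.  The half-length l
is half the trajectory-mean axial extent of the monomers kept after
end exclusion (the natural reading of the otherwise undefined
"half-length of the segment").  The static helical offset of the COMs
aliases only weakly into the quadratic term (adjacent monomers sit
nearly opposite the axis), which we verified by parameter recovery; a
`bend_points="midpoints"` option fits the adjacent-pair midpoints
instead, which trace the centerline with a much smaller ripple.

## Longitudinal and torsional stiffness (equipartition)

The central segment runs between the mean positions of monomers
{5, 6} and {N−5, N−4+1} (i.e. the 5th/6th monomers from either end;
`segment_offset`).  Its axial projection L and endpoint twist Psi
(difference of the endpoint azimuths, each the mean of its two
monomers' unwrapped azimuths, in radians, unwrapped over time) yield

    K = kB·T·<L> / <dL²>,   G = kB·T·<L> / <dPsi²>,

with the variances computed inside a sliding window of `window_ns`
(default 16 ns, i.e. 80 frames at 200 ps; a window covering the whole
series degrades to the plain sample variance) and averaged over
window positions, on the full series and on its second half.

**Twist azimuth reference.**  Measured about the laboratory z-axis,
the twist observable is contaminated by bending: a bend displaces
monomers laterally and shifts their azimuths by (displacement)/r,
which for realistic stiffness is comparable to — or larger than — the
thermal twist signal itself, collapsing G by orders of magnitude (we
measured a ~3-order-of-magnitude error on the synthetic generator).
By default the monomer azimuths entering Psi are therefore measured
about the per-frame fitted parabola centerline
(`azimuth_reference="parabola"`), which decouples twist from bend;
the literal z-axis convention is retained as `"z"`.  The
`segment_endpoint="combined_com"` alternative (azimuth of the
two-monomer combined COM) is exposed but ill-conditioned: on a
two-start helix that point lies ~0.3 nm from the axis.

Window width matters little here because the synthetic generator
draws frames independently; on real MD data with correlated frames
the window bounds the time scale over which variances are collected.

## Tpm profiles

Each long actin pseudo-helix (the odd or even monomers) is reduced,
per frame, to the ordinary-least-squares line of its Lys328-Calpha
marker azimuth on z (markers ordered by z, azimuths unwrapped
monotone).  Angular fluctuation of the helix itself is the RMS over
time of each marker's residual from its own frame's line.  Tpm
residues are measured as the azimuthal deviation of each Calpha from
the paired helix's line (SD and mean over time) and as the radial
distance from the filament axis (mean and SD), indexed both by
residue and by mean axial position.  Per-frame regression (not a
time-averaged reference) is used throughout, so slow global rotations
of the helices do not masquerade as Tpm mobility.

## Hydrogen-bond occupancy

A donor–acceptor pair is bonded when r(D···A) ≤ 0.35 nm and the
smallest H–D···A angle over the donor's hydrogens is ≤ 30 degrees
(the GROMACS `hbond` convention; both thresholds configurable).
Hydrogens are attached to donors geometrically (same residue, within
0.12 nm) because coordinate files carry no bond topology; structures
without hydrogens fall back to the distance-only criterion with a
warning.  Donors default to the side-chain nitrogens of Lys326 and
Lys328 of each actin monomer; acceptors default to all Asp/Glu
side-chain carboxyl oxygens of the monomer's own Tpm strand, because
the conserved acidic Tpm residue list used in the source analyses is
not enumerated — an explicit residue list can be supplied in the
component map, and absolute lifetimes may shift with that choice.
Occupancy is 1 when at least one bond exists in a frame; the lifetime
is its time average, also reported over four equal trajectory
quarters.

## Coiled-coil skeleton operators

The local helix axis at residue i is built from four consecutive
Calpha positions (the TWISTER scheme): the bond-angle bisectors at
residues i and i+1 point from the backbone toward the axis, their
cross product gives the local axis direction, and the chord geometry
gives the local radius and per-residue rise.  One residue at the
start and two at the end carry no skeleton point (the last point is
extrapolated from the final usable bisector).  Chain breaks
(consecutive Calpha beyond 0.45 nm) are rejected.  The residue rise
is reported per chain; the dimer midpoint curve is available
separately.

Rescaling along the skeleton multiplies each residue's arc-length
distance from an anchor residue by the given factor and re-places
every atom preserving its offset in a parallel-transported
tangent/normal/binormal frame, so the cross-section is not distorted.
The extension-factor scan rescales over a factor grid and accepts the
factor whose best-coinciding Calpha (anchor excluded — it coincides
trivially at every factor) is closest, subject to the 0.05 nm
coincidence criterion.  The best-match interval search evaluates the
RMSD over the six Calpha pairs {i−1, i, i+1, j−1, j, j+1} in the
common frame (no superposition) over an explicit candidate set, ties
breaking toward the smallest i, then j.

## Synthetic generator

The generator builds a two-start helical pseudo-filament with
prescribed rise d0 (default 2.75 nm), left-handed step phi0 (default
166.6 degrees), COM ring radius 2.5 nm and 26 monomers.  Each
pseudo-monomer is a rigid group on its own chain: a body atom, a
Lys328-Calpha marker surrogate at 2.7 nm radius, Lys326/Lys328
side-chain-nitrogen donor surrogates with riding hydrogens, and one
balance atom placed so the mass-weighted COM falls exactly on the
ideal helix (so helix-parameter exactness tests are meaningful at
1e-9).

Frames are drawn independently from a single seeded generator:

- a uniform axial strain with Var(L) = kB·T·L0/K_true over the
  central segment (L0 = 16·d0);
- a uniform twist increment with Var(Psi) = kB·T·L0/G_true;
- a parabolic bend with kx, ky ~ Normal(0, 1/(l·xi_true)), calibrated
  through the small-angle expansion 1 − cos a ≈ l²(kx²+ky²)/2 so that
  <1 − cos a> ≈ l/xi_true (exact to <0.1% in the tested regime);
- optional per-atom Gaussian jitter (default 0.02 nm; donor–hydrogen
  pairs move rigidly so covalent geometry survives);
- a uniformly random proper rotation plus a random translation.

Pseudo-Tpm strands are added frame by frame exactly on the paired
long helix's regression line at a prescribed radius, then perturbed
by Gaussian angular/radial noise; flagged monomers receive an
acceptor oxygen placed 0.30 nm from the donor along the N–H bond on a
prescribed frame schedule, giving exact control of hydrogen-bond
occupancy patterns.

What the generator does **not** emulate: temporal autocorrelation
(frames are independent, which makes the sliding-window estimators
window-width-insensitive and isolates estimator correctness from
kinetics), internal monomer flexibility (pseudo-monomers are 7-atom
rigid bodies, not 375-residue actins — the analysis layer sees only
the component-map abstraction), solvent and force-field physics, Tn
geometry, and end effects beyond simple exclusion.  Passing recovery
tests therefore validates the estimators, not the realism of any MD
force field.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| temperature | 300 K | matches the simulated ensembles |
| window_ns | 16 ns | sliding-window width for the equipartition variances (80 frames at 200 ps sampling) |
| end_exclusion | 2 | monomers dropped per end ("a pair from both sides") |
| segment_offset | 5 | central segment between the 5th/6th monomers from each end |
| hbond | 0.35 nm / 30 deg | geometric bond criterion |
| azimuth_reference | parabola | twist azimuths about the bent centerline |
| period_averaging | mean_params | P from per-frame mean (d, phi) |

## Problem sizes

The validation suite and the bundled analysis scripts run the full
study conditions: 26 monomers, 2000 frames at 200 ps spacing,
K = 48 nN, G = 4e-26 N·m², xi = 7 um at 300 K.  Across seeds the
estimators recover K and G within ~7% and xi within ~6% at this size;
errors shrink roughly as 1/sqrt(frames).  Shorter trajectories
(150–400 frames) are used where only exactness or invariance is being
checked.

## Known limitations

- The WLC and equipartition estimators assume equilibrated,
  stationary fluctuations; no attempt is made to detect or correct
  drift beyond reporting second-half statistics.
- Per-pair apparent periods are undefined on frames where bending
  pushes an azimuthal step beyond 180 degrees; such pairs are skipped
  in the per-pair averaging mode.
- PDB output carries 0.001 A coordinate columns, so structure
  round-trips reproduce monomer COMs to ~1e-4 nm, not better.
- The hydrogen-bond acceptor set is a superset heuristic (all Asp/Glu
  oxygens) unless an explicit conserved-residue list is configured.
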