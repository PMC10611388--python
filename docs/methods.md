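# Methods

## The model

`knotpush` simulates a coarse-grained double-stranded DNA molecule as a
bead–spring chain pushed by a piston through an infinitely long implicit
channel, and analyses the topology (knot type, chirality, writhe) of the
confined chain.  All computation uses reduced units: the bead diameter
sigma, the bond length l = 1 sigma, and the thermal energy
epsilon_0 = k_B T are unity.  One sigma corresponds to 2.5 nm of dsDNA; the
reduced time unit tau = 6 pi eta sigma^3 / epsilon_0 is about 74 ns in
water at room temperature and scales linearly with the solvent viscosity.

### Force field

* **Bond stretch** `U_S(r) = K_s (r - r0)^2` with `K_s = 80 epsilon_0/sigma^2`
  and `r0 = 1 sigma`.  The stiffness is deliberately high so that two chain
  segments can never pass through each other under the compressive loads
  reached here: topology changes would otherwise corrupt the knot
  statistics.
* **Angle bend** `U_b(theta) = (K_b/2)(theta - pi)^2` with
  `K_b = 20 epsilon_0/rad^2`.  We adopt the half-prefactor convention
  deliberately: with it, the persistence length of the discrete chain is
  `P ≈ K_b l = 20 sigma` (i.e. 50 nm, the standard dsDNA value), which the
  test suite verifies by direct measurement on equilibrium trajectories.
* **Excluded volume**: the purely repulsive Weeks–Chandler–Andersen form
  `U_ex(r) = 4[(1/r)^12 - (1/r)^6 + 1/4]` for `r < 2^(1/6) sigma`, zero
  beyond.  The constant shift is placed inside the bracket so the potential
  is continuous at the cutoff — a discontinuous force there would destroy
  the integrator's stability.  Directly bonded pairs are excluded from this
  sum by default (the bond length sits on the steep repulsive flank and
  double counting would stiffen bonds); the exclusion is configurable.
* **Piston**: an extra bead of diameter parameter `sigma_P = 100 sigma`
  interacting with chain beads through the same WCA form with contact scale
  `(sigma + sigma_P)/2` (arithmetic mixing), carrying a constant external
  force `F` along −x, and holonomically constrained to the channel axis by
  projecting its y/z position and velocity to zero after every step.

### Channel

The channel is a tube of radius `R_ch` around the helical centerline
`r0(t) = (k t, R_H cos(w t), R_H sin(w t))`, `w = ±1` (left/right winding);
`R_H = 0` gives a cylinder.  One helical turn spans `d_H = 2 pi k` along
the axis.  The default geometry sets `R_H = R_ch/3` (the lower end of the
range where chiral confinement effects are strongest) and `k = D/(2 pi)`
(one helical turn per diameter), with confinement strength expressed as
`D/P` for `P = 20 sigma`.  The wall is implicit: each bead
feels a WCA repulsion of the *gap* `g = R_ch − d(bead, centerline)`, with
wall length scale 1 sigma — the same functional form as the bead–bead
exclusion, applied to the gap coordinate.  A bead with `g ≤ 0` aborts the
run with a diagnostic (this never happens in a stable run).

The point-to-helix distance has no closed form.  The library routine uses
multi-start safeguarded Newton iteration on the stationarity condition
(starts every half turn within ±2 turns of the query's axial position,
Newton steps bisected into a shrinking bracket); the test suite checks it
against a dense-grid global search to 1e-6 sigma.  Inside the integrator
the minimiser is warm-started per bead from the previous step (beads move
~1e-3 sigma per step, so 3 Newton iterations suffice) and the two
neighbouring helix branches are re-examined every 25 steps, so branch
switches near the tube overlap region cannot go unnoticed.

### Dynamics

The Langevin equation
`m r'' = −grad U − gamma m r' + sqrt(2 epsilon_0 m gamma) R(t) (+ F_ext)`
is integrated with the BAOAB splitting at `dt = 0.01 tau`; BAOAB was chosen
over Euler-type schemes because it stays accurate with the stiff `K_s = 80`
bonds at this step size.  Friction and mass are `gamma = m = 1` for chain
beads.  For the piston, Stokes drag scales with particle size, so the
default piston friction is `gamma_P = (sigma_P/sigma) gamma = 100`; with a
unit-friction piston the pushing velocities at the forces studied would be
an order of magnitude above the experimental regime the model targets
(both settings are configurable, and only trends — not absolute
velocities — are meaningful at scaled-down problem sizes anyway).

A pushing run starts from a straight chain on the axis at `x = 1..N` with
the piston at contact distance + 1 sigma beyond the high-x end, draws
Maxwell–Boltzmann velocities, pre-equilibrates with the external force off,
then runs production with the force on, sampling frames on a fixed stride.
The seeded generator drives every random number, so a (config, seed) pair
reproduces a trajectory bit-for-bit on one platform.

### Polymer metrics

The primary compaction observable is the **span**: the extent of the chain
along the channel axis, `S = max_i x_i − min_i x_i`, which suppresses
chain-end noise relative to 3D extent measures.  Steady-state spans are
averaged over the last half of production frames.  The compression-scaling
analysis fits the slope of `log(F D)` against `log(S)`; in the de Gennes
compression regime the expected exponent is −9/4.  Radial distributions
are reported as normalized frequency per bin (no annulus-area correction);
axial distributions measure bead offsets from the piston face with the push
direction positive.  The helical-turn-periodized heatmap bins
`(x mod d_H, signed transverse coordinate)` in a frame co-rotated by
`−w x/k` about the axis, which unwinds the helix so the groove sits still
at transverse +R_H; this particular unwinding is this package's own
construction.

The persistence length is measured from the bond-direction correlation
`<u_i · u_(i+s)> = exp(−s l / P)` by a log-space fit over lags `s ≤ 6`.
The window is deliberately short: beyond `s ≈ P/(2 l)` the measured
correlations of a self-avoiding chain decay *slower* than exponentially
(excluded-volume swelling) and plateau near 0.3 for an N = 100 chain, so
longer windows inflate P far above the bending-rigidity value that
controls confinement physics.

## Topology analysis

Knots are defined on closed curves.  A frame is typed only when its
end-to-end distance is below the **ligation distance** (default 10 sigma,
the scale of frame-to-frame end-distance fluctuations); this keeps the
closure from injecting entanglements of its own.  Accepted frames are
closed minimally-interferingly: both termini extend radially away from the
chain centroid to a sphere of 3× the maximal centroid distance and are
joined along that sphere.  The closure interior must clear the chain
interior by 0.1 sigma (attachment regions excluded); blocked radial
directions are nudged away from nearby beads, and a frame whose closure
still fails is skipped and logged rather than mistyped.

The closed curve is projected along several seeded directions; each
projection is validated as generic (transverse crossings away from
vertices, distinct depths) and otherwise redrawn.  Diagrams are reduced by
repeated Reidemeister I and II moves, and the smallest diagram over the
projections is kept.  The Jones polynomial is evaluated through the
Kauffman bracket state sum (exact integer arithmetic over all 2^c
smoothings with union-find loop counting), normalised by
`(−A)^(−3w)` and the substitution `A = t^(−1/4)`.  Diagrams still above 22
crossings after reduction are reported as the unidentified bucket "?" —
the state sum would be exact but wasteful there, and such frames are rare
and complex enough that typing them adds nothing at the problem sizes used.
A second, structurally independent implementation (recursive skein
expansion) cross-checks the state sum in the tests, and projection
invariance of the polynomial is itself a test.

Identification matches the polynomial (and its `t -> 1/t` mirror) against
the bundled table.  The table is generated and verified by this package's
own pipeline from constructions whose knot type is provable: all fourteen
prime knots up to 7 crossings plus 8_1, 9_1 and 9_2 as rational (2-bridge)
4-plats assembled from their continued fractions — each checked against
its determinant `|V(−1)|` (the continued-fraction numerator) and the
Kauffman–Murasugi span identity (Jones span = crossing number for reduced
alternating diagrams), a certificate that is unique within this set — and
the torus knot 8_19 from its explicit parametrisation.  Chiral knots are
stored in their positive-writhe form, labelled right-handed; a mirror
match therefore means a left-handed knot.  Handedness is tabulated up to
9 crossings; beyond that the package reports "undetermined".  Knots absent
from the table (including composites, whose product polynomials never
match a prime entry) fall into "?".  The census table (names and
amphichiral/torus/twist flags for all 801 prime knots to 11 crossings) is
complete and used for group statistics; identification coverage above 7
crossings is intentionally sparse, which matters little in practice
because compressed-chain knots at these chain lengths are dominated by
3_1, 4_1, 5_1 and 5_2.

The **writhe** of a frame is the Gauss double integral of the open chain,
evaluated exactly as the sum of analytic solid-angle contributions over
all non-adjacent segment pairs; its sign convention matches crossing signs
(a right-handed trefoil has Wr ≈ +3.4), and the centerline of a
right-winding channel has positive writhe.  **Equichiral** knots are
identified knots whose handedness matches the channel winding sign;
knotting probabilities, crossing-number spectra and group frequencies are
reported with explicit denominators (typed frames), since ligation
rejects most frames of an extended chain.

## Synthetic fixtures

Test fixtures are generated, never stored: torus knots `T(p,q)` and the
figure-eight knot from standard parametrisations (chirality
self-normalised against the computed writhe sign, so a fixture's label can
never disagree with its geometry), rational knots as 4-plats with the
alternating over/under pattern built into the 3D scaffold, equilateral
random rings (random unit steps alternately recentred and renormalised to
closure), and single-fold hairpin chains for the metrics tests.  These
fixtures exercise every ground truth the analysis relies on, but they are
idealised: simulation frames have thermal roughness, near-contacts at the
excluded-volume scale and piston-compressed density gradients that no
fixture reproduces, so fixture-based tests validate the *operators*
(projection, bracket, identification, writhe), not the sampling statistics
of real pushing runs — those are exercised by the scaled-down simulation
studies.

## Problem sizes and numerical choices

Full-scale production (N = 300, 1e7 pre-equilibration + 1e9 steps, ten
replicas per parameter point) is supported through the configuration
system but is a multi-week single-CPU workload.  The bundled studies use
deliberately scaled-down protocols chosen to reach their respective steady
states:

* compression scaling: N = 100 in a D/P = 1 cylinder, forces
  {0.5, 1, 2, 5}, 1e6–8e6 production steps and three to five seeds per
  force (weak pushes converge slowly and their steady spans fluctuate on
  5e5-step timescales, so they get the longest runs and the extra seeds;
  unit piston friction so every force reaches its steady span within the
  budget), spans averaged over the last half.  At this chain length the
  chain is only five persistence lengths long, so the measured exponent
  sits near the shallow end of the compression-scaling band;
* chirality: N = 150 in D/P = 1 helical channels of both handednesses
  and a cylinder control, F = 2, 2.5e6 production steps, several seeds per
  geometry, writhe averaged over the steady-state last half;
* persistence: N = 100 free chain, 1e6 steps.

A caveat the chirality numbers force on any reader: at these scaled-down
ensembles the chiral writhe bias at F = 2 is small compared with the
run-to-run writhe fluctuation (per-run standard deviation near 1.2), so
the *sign* of the pooled mean writhe at F = 2 is not a reliable statistic
at a handful of seeds.  Under stronger compression the signal strengthens
but remains noisy: at F = 5, pooling nine seeds per handedness in our
runs gives mean writhe near +0.5 for right-winding and −0.5 for
left-winding channels, with identified knots equichiral in about 63% of
cases — directionally consistent with a channel-handedness effect, with
confidence limited by the ensemble size.  The acceptance script reports
the chirality statistics at both forces.

Tolerances: helix-distance Newton converges to |f'| < 1e-13 (distance
error << 1e-6 sigma); all analytic gradients match central finite
differences to 1e-6 relative; diagram genericity margins are 1e-9 of the
largest projected segment; the Kauffman state sum is exact integer
arithmetic.  Degenerate inputs (zero-length bonds, escaped beads,
non-generic projections, unsatisfiable closures) raise typed errors with
context rather than returning silently wrong values.

## Known limitations

* No hydrodynamic interactions (free-draining Langevin friction); absolute
  piston velocities depend on the friction convention and only force
  trends are comparable across conventions.
* Knot identification above 7 crossings covers only the torus/twist
  families bundled; other 8–9 crossing knots report "?".
* No knot localisation along the chain, no knotoid (open-curve) formalism,
  no composite-knot decomposition.
* R1/R2 reduction does not always reach minimal diagrams (R3 is not
  applied); the multi-projection minimum compensates in practice, and a
  non-minimal diagram only costs state-sum time, never correctness.
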