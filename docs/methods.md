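# Methods

This note documents the models behind `prochir`, the choices that were
genuinely open, and what the synthetic study conditions do and do not
establish about real molecules.

## The physical picture

cis-Stilbene and cis-stiff-stilbene exist as two helically twisted
conformers, P (right-handed, ethylenic twist tau > 0) and M (left-handed,
tau < 0). On the ground state the helical-inversion barrier is small
(1.6 and 4.9 kcal/mol respectively), so the conformers racemize thermally
and the compounds behave as achiral. On S1 the inversion barrier rises to
19 and 13 kcal/mol while the surface becomes steeply sloped along the
ethylenic twist toward the S1/S0 conical-intersection region at
tau = +-90 deg. The consequence is *chirality stiffening by excitation*:
each enantiomer, once excited, is trapped in its helical basin and
photoisomerizes unidirectionally — P clockwise toward +90 deg, M
anticlockwise toward -90 deg — and the chiral photocyclization product
(4a,4b-dihydrophenanthrene, DHP) inherits that sense: S,S from P, R,R
from M. Coupling this to the enantioselective absorption of circularly
polarized light gives a photoresolution scheme whose photostationary
enantiomeric excess is the closed-form expression evaluated by the
kinetics module.

## Model surface (module `pes`)

The ab initio surfaces are replaced by an analytic two-state diabatic
model in reduced coordinates (tau = ethylenic twist, phi = helicity/
phenyl-rotation coordinate):

    H11 = A1 sin^2(tau) + B1 cos^2(phi) - c1 sin(tau) sin(phi)
    H22 = C2 + A2 cos^2(tau) + B2 cos^2(phi)
    H12 = k cos(tau) [G(tau - pi/2) + G(tau + pi/2)]

with G a Gaussian of width `coupling_width` and B2 = B1. Only the
*topography* of the real system is published — well/saddle energetics and
the location of the intersection — so any smooth form reproducing them is
admissible; this one was chosen because its calibration is closed-form:

* A2 = S1 inversion barrier (the planar saddle at (0, +-pi/2) is exact);
* A1 = (dE_vert - A2 cos^2 tau0)/(1 - sin tau0)^2, which places the
  diabatic degeneracy exactly at (+-pi/2, +-pi/2);
* c1 = 2 A1 sin tau0 puts the P well exactly at (tau0, pi/2);
* B1 = S0 barrier - A1 sin^2 tau0 makes the ground-state inversion saddle
  at the origin exact (the saddle is reached by phi motion, the S1 saddle
  by tau motion through planarity, mirroring the published mechanism).

H12 vanishes *linearly* at tau = +-pi/2, so the degeneracies are isolated
conical intersections (the gap is zero only there) rather than avoided
seams; the adiabatic coupling diverges at the point and is capped at
`nacv_cap` (default 50 rad^-1) for integrability. Everything is exactly
mirror-symmetric under (tau, phi) -> (-tau, -phi) in floating point,
which the mirror-swarm tests exploit.

Free calibration inputs with no published value, chosen once: the well
twist tau0 (8 deg stilbene, 12 deg stiff-stilbene — small helical twists
consistent with nearly planar cis minima), the vertical gap dE_vert
(70 kcal/mol; a reduced-coordinate effective gap, deliberately below the
gas-phase vertical excitation since the 2D model absorbs relaxation along
all discarded coordinates), and the reduced inertias (167 and
250 amu A^2), set so that the S1 well frequencies are ~100 cm^-1 and the
Franck-Condon-to-intersection passage takes a few hundred femtoseconds
(sub-picosecond, as observed). Feasibility requires
A1 sin^2(tau0) < barrier_S0; the constructor rejects infeasible
combinations.

An auxiliary `LinearCrossingSurface` (linear diabats, constant coupling)
provides the exactly solvable crossing used to validate the hopping
algorithm.

## Wigner sampling (module `wigner`)

Standard harmonic analysis: mass-weighting, Eckart projection of
translations/rotations (zero-mode tolerance 5 cm^-1; an imaginary
retained frequency raises an error), diagonalization. The 0 K Wigner
function of each retained mode is a Gaussian product with
Var(Q) = hbar/2w and Var(P) = hbar w/2 in mass-weighted coordinates;
positions and momenta are drawn independently with numpy's PCG64
generator (seed mandatory) and back-transformed. Subselection of the
30-of-500 initial conditions is uniform without replacement — the
published protocol says only "randomly selected", and uniform sampling is
the natural reading. Finite temperature is out of scope.

## Surface hopping (module `dynamics`)

Fewest-switches surface hopping replaces the multiple-spawning dynamics
of the source study: the observable reproduced here (rotational
directionality of the twist angle) is a classical-path quantity, and
spawning adds no testable content at this scale. Details:

* velocity-Verlet nuclear steps (default dt = 0.05 fs, horizon 1.4 ps);
* electronic amplitudes in phase-factored form c_k = a_k exp(-i Theta_k)
  with the dynamical phase integrated exactly for linearly interpolated
  energies; RK4 for the residual coupling term. Away from the coupling
  region the right-hand side vanishes, so the norm is conserved to
  ~1e-14 over a full trajectory (tolerance asserted: 1e-6);
* 10x electronic substepping when the gap falls below 1 kcal/mol;
* hops drawn per substep from the standard fewest-switches probability;
  momentum rescaling along the nonadiabatic coupling vector conserves
  total energy to < 1e-8 at every allowed hop; frustrated hops default to
  "ignore" (velocity kept), with "reflect" available — the source gives
  no guidance, and none of the reported observables is sensitive because
  frustrated hops essentially never occur on the model surface;
* optional energy-based decoherence damping (off by default; the
  single-passage validation below is run without it);
* trajectories whose energy drifts beyond ~1 kcal/mol per ps between hops
  are flagged invalid, never silently kept;
* a ground-state trajectory stops on leaving |tau| >= pi/2.

The Landau-Zener validation fires trajectories through the linear
crossing at v ~ 1 rad/fs and compares the fraction switching adiabats
with exp(-2 pi Gamma). Two numerical points matter: the passage must
extend ~1 length unit beyond the crossing, because the adiabatic-basis
coherence keeps oscillating there and the back-hops it drives are part of
the fewest-switches balance (truncating them biases the fraction by
+0.4% absolute); and the closed form is evaluated with the velocity
measured at the crossing. With both, 1e4 trajectories agree with the
closed form to ~1 Monte-Carlo sigma, and the underlying amplitude
transfer matches it to ~1e-4.

A dynamical remark: P-well trajectories that cross the planar S1 ridge
with large negative momentum (a ~1-3% Wigner tail) do not continue to
-90 deg; with their phenyls still in the P arrangement (phi near +pi/2)
the M-side funnel is closed — they bounce off the adiabatic wall where
the diabats cross and eventually exit clockwise. Unidirectionality on
this surface is therefore even stricter than the ridge-crossing estimate
suggests, at the cost of occasional ~1.3 ps stragglers (hence the 1.4 ps
default horizon).

## Trajectory analysis (module `analysis`)

Signed dihedrals follow the IUPAC convention; the twist angle is the
*circular* mean of the two central-bond dihedrals (so 179/-179 deg
average to 180, not 0). Helicity is sign(tau) with a 1 deg dead zone;
P/M labels for Cartesian input via phenyl torsions are not implemented
(the sign(tau) reading is consistent with the published figures but is an
interpretation). Photoproduct thresholds — cis below 60 deg, trans above
120 deg, unresolved between — are symmetric about the 90 deg funnel; the
source publishes none. Because the stop criterion halts ground-state
trajectories right at |tau| = pi/2, model-surface product counts land
mostly in "unresolved"; the cis/trans split on S0 after the hop is not an
observable this surface is calibrated to reproduce (the published
branching ratio requires the quantum-chemical surfaces and is out of
scope). DHP formation is *not* a coordinate of the model surface — the
cyclization channel enters only through the kinetic module; a distance
criterion (C4a-C4b < 1.8 A) is provided for external Cartesian
trajectories but is untested against reference data.

## Chiroptics (module `chiroptics`)

Spectra are sums of Gaussians at (shifted) excitation energies, weighted
by dipole strength for eps and by 4x rotatory strength for delta-eps, so
that the single-band dissymmetry equals the per-transition Kuhn factor
g = 4R/D exactly (identical centers and widths for the eps and delta-eps
bands make the shape factors cancel). Absolute extinction prefactors are
left symbolic: all spectra are relative, as in the simulated spectra this
mimics. Both width conventions are supported — FWHM f and 1/e half-width
w, f = 2 sqrt(ln 2) w, interconverted exactly. g is reported as undefined
(NaN), never zero, where eps falls below 1e-6 of its maximum. Note the
Kuhn factor is defined here as rotatory over dipole strength (x4), the
standard convention; the source text's parenthetical inverts the ratio,
which is read as a typographical slip. The mapping of g onto the kinetic
excitation asymmetry is discussed below.

## Photostationary kinetics (module `kinetics`)

Five species {M, P, T, RR, SS} with first-order effective rates; under
r-CPL every photoexcitation rate out of M and out of R,R-DHP is scaled by
(1 + g) and out of P / S,S-DHP by (1 - g). This (1 +- g) convention is
the unique one under which the scheme's asymptotic steady states
reproduce the published closed form (limits |g_DHP| and
|g_DHP - g_stil|/(1 - g_stil g_DHP)); the physically motivated
(1 +- g/2) variant is available as `convention="kuhn"` for sensitivity
analysis. trans-stilbene is achiral and feeds both helices at k_tc/2.
The cyclization branching k_cD/k_ct defaults to 4/52 after the published
photoproduct ratio; the tests verify it does not move the ee in either
asymptotic limit. The "comparable" regime is evaluated at k_ct = k_rac
exactly, the source giving no ratio.

Steady states come from two independent routes — SVD null space, and
matrix-exponential propagation of the stiff linear ODE with time doubling
until the residual vanishes — which agree to ~1e-11 and conserve total
concentration to 1e-10 relative. The five-species scheme's exact steady
state is

    ee_scheme = [k_ct g_D (1 - g_s^2) + 2 k_rac (g_D - g_s)]
                / [k_ct (1 - g_s^2) + 2 k_rac (1 - g_s g_D)]

which differs from the published closed form — (1 - g_s) where the scheme
has (1 - g_s^2) — at second order in g. The derivation behind the
published form is in supplementary material not available here, so the
package implements the published expression verbatim in
`ee_closed_form`, exposes the scheme result independently, and documents
the O(g^2) residual rather than forcing agreement; both coincide in the
two asymptotic limits and to within 10 g^2 everywhere tested.

## Synthetic data and what passing means

`fixtures.make_fixtures(seed)` generates all study inputs: mirror-pair
two-band transition tables (equal D, opposite R, Kuhn factors ~0.005 to
0.008 in magnitude, inside the |g| < 0.01 bound typical of closed-shell
organics), anisotropy curves with a DHP-like sign change inside the
230-350 nm window, toy Hessians with known spectra, and dihedral test
geometries. The synthetic conditions reproduce the *structure* of the
real problem — mirror antisymmetry, magnitudes, band overlap, sign
change — but not the actual stilbene/DHP spectra; consequently the
wavelength-scanned ee maxima computed here (~0.9-1.4% for |g| up to
0.008) characterize the synthetic curves, not the molecule. Reproducing
the published ~0.23%/~0.25% maxima requires the study's deposited
g(lambda) tables; the scan machinery accepts them as CSV
(`data/external/g_stilbene.csv`, `data/external/g_dhp.csv`) and the
corresponding acceptance test states exactly that dependency.

## Problem sizes and numerical settings

Defaults used by the tests and the acceptance script: Wigner moments at
n = 1e5 (3-standard-error bands); directionality swarm of 100
trajectories from 500 Wigner samples at dt = 0.05 fs; Landau-Zener
validation with 1e4 passages at dt = 0.008 fs; steady-state
cross-validation over 1000 random rate/anisotropy draws; dt-convergence
of the swarm clockwise fraction checked at n = 500 against the binomial
standard error. Spectra use grids of 2-3 meV spacing so that measured
FWHMs are grid-limited.

## Known limitations

* Two reduced coordinates; no cyclization coordinate, no 3N-dimensional
  dynamics, no ab initio energetics; the published excited-state
  branching ratio is intentionally not reproduced.
* Surface hopping, not multiple spawning: no coupled-trajectory
  coherences; single-passage statistics are validated, long-time
  coherence effects are not.
* The trans region of the model surface mirrors the cis region (the
  trigonometric form is symmetric about tau = 90 deg), so post-funnel
  ground-state dynamics is qualitative only.
* Kinetics uses effective first-order rates; photon flux and quantum
  yields are absorbed into the constants, so only rate *ratios* matter.
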