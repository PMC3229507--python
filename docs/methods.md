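# Methods

`ionpore` analyzes ion permeation through wide membrane channels whose
selectivity is set by fixed charges lining the pore, and how that
selectivity fades as the bulk salt concentration rises and screens those
charges. The package couples a Brownian-dynamics (BD) trajectory generator
to the analyses a permeation study needs: occupancy and translocation
statistics, density-inversion free-energy profiles, continuum
electrostatics, solution-structure profiles, reversal-potential models and
alignment conservation scoring. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## The Brownian-dynamics channel model

The generator (`ionpore.synthetic`) propagates two monovalent species
(tags `cation`, `anion`) with the overdamped Euler-Maruyama scheme

    x(t+dt) = x(t) + D f(x) dt + sqrt(2 D dt) N(0,1),

forces `f = -grad(U/kT)` in 1/A. There is no hydrodynamic coupling and no
explicit water: analyses that need solvent structure (dipole orientation)
run on synthetic dipole-carrier ensembles with a stated orientation law
instead (see below).

The interaction model is deliberately minimal:

* **Screened Coulomb (Yukawa):** `U/kT = q1 q2 l_B exp(-r/lambda)/r`, both
  ion-ion and ion-fixed-charge, with the Bjerrum length `l_B(T, eps)` and
  `lambda` the Debye length of the bulk concentration
  (`kappa^2 = 8 pi l_B N_A C` for a 1:1 salt; 9.6 A at 0.1 M, 3.0 A at
  1 M, 298 K, eps 78.5). This builds the concentration dependence of the
  fixed-charge reach directly into the dynamics.
* **Soft core:** `(sigma/r)^12` with contact radius `sigma = 2.5 A`
  (force clamped below `0.6 sigma`); applied between all particle pairs
  and between ions and fixed charges.
* **Geometry:** a membrane slab of half-thickness 15 A centered at z = 0,
  pierced by a cylindrical pore of radius 9 A on the z axis, in a
  34 x 34 x 72 A periodic box. The wall reflects; the reservoirs on the
  two sides connect through the pore and through the periodic z boundary
  (crossings of the latter are recognized and never counted as pore
  events). Default fixed charges are two rings of +0.5 e to +0.75 e point
  charges (total +4 to +6 e) at z = +/-5 A, radius 6.5 A, standing in for
  the basic residues that line an anion-selective pore; a net charge of a
  few +e matches the positive excess such channels carry.
* **Defaults:** dt = 0.5 ps (per-step RMS displacement ~0.45 A, well
  under the contact radius; a `StabilityWarning` fires when it is not),
  D_K = 0.196 and D_Cl = 0.203 A^2/ps (experimental bulk values), T =
  300 K. Particle numbers follow `C_bulk x N_A x V_box`, enforced within
  10% unless a deliberately non-physical ensemble is requested.
* **Initial placement:** uniform rejection sampling outside the wall and
  outside the contact radius of anything already placed, capped at 1e4
  retries per particle (`PackingError` beyond).
* **Determinism:** a single `numpy` PCG64 generator seeded from the run
  seed; identical seed and parameters give bit-identical trajectories.

Internal units are angstrom, picosecond and kT. kcal/mol appears only at
reporting boundaries with RT(300 K) = 0.59616 kcal/mol; reversal
potentials are in mV.

## Permeation statistics

The pore slab is the open interval -15 < z < 15 A (points on a boundary
are outside). Occupancy is the per-frame count of a species in the slab
(optionally restricted to the lumen radius), with population-convention
standard deviations. A translocation event is one complete directed
traversal — from beyond one boundary to beyond the other — detected by a
per-particle state machine whose entry time is the last frame outside the
entry boundary and whose exit time is the first frame beyond the far one;
retreats and incomplete re-entries produce nothing. Event durations use
sample-convention standard deviations, and a single event reports no
standard deviation at all. Ratios (anion/cation events, anion/cation
occupancy) carry an explicit flag instead of crashing when the denominator
is zero.

## Free-energy profiles from densities

For species i, `dG_i(z) = -RT ln(C_i(z) / C_bulk)` on 1 A bins (matching
the PB grid spacing), and the same estimator per voxel on a 3D grid. The
bulk concentration is measured from a bulk slab of the same trajectory
(default |z| > 25 A, which must not overlap the pore slab) or taken from
metadata by flag, because a trajectory's realized bulk density can differ
from its nominal concentration when the pore region is enriched.
Zero-count bins are masked, never clamped and never given pseudo-counts:
unvisited regions report "no information" rather than a fabricated
barrier. The analysis cross-section is the lumen cylinder inside the slab
and the full box cross-section outside; with no lumen radius configured
the full cross-section is used everywhere.

3D-to-1D reduction defaults to the arithmetic mean over valid voxels per
constant-z layer; a Boltzmann-weighted mode
(`-RT ln<exp(-dG/RT)>`) is available since it weights voxels the way the
ion population does. Layers with no valid voxel stay masked.

Residues shaping the low-energy regions are identified by taking grid
points with values within 1% of the minimum and selecting residues whose
side-chain N/O atoms lie strictly within 4 A of any such point. "Within
1% of the lowest values" is ill-defined when energies change sign, so the
default window is `G_min + 0.01 (G_max - G_min)` (well defined for any
sign) with the literal `G_min + 0.01 |G_min|` selectable.

## Continuum electrostatics

`solve_lpb` discretizes the linearized Poisson-Boltzmann equation
`div(eps grad phi) - eps_w kappa^2 lambda phi = -4 pi k_c rho` with
node-centered dielectrics, harmonic-mean edge values, trilinear charge
assignment and red-black SOR (relaxation factor `2/(1 + sin(pi/n))`).
Dirichlet boundaries come from a Debye-Hueckel monopole superposition,
which also serves as the initial guess; successive focusing interpolates
a parent solution onto finer-grid boundaries, with levels shrinking
geometrically from the outer extent to the final spacing. Convergence is
a maximum update below tolerance (default 1e-4 kcal/(mol e)); exceeding
the iteration cap raises with the final residual. The ion-accessibility
mask `lambda` is 1 only in water-labeled regions by default and can be
overridden (e.g. to zero out screening inside a lumen, a choice the
three-dielectric model itself does not settle).

The membrane model is three dielectrics: protein 4 (any node inside an
atom sphere), hydrophobic membrane core 2 (|z| < 12.5 A, i.e. a 25 A
slab, optionally excluding a lumen cylinder), water and headgroups 80.
Energies use `k_c = 332.06 kcal A/(mol e^2)`.

Transfer energies follow the two-solve decomposition
`dG(p) = q phi_static(p) + [E_self(p; environment) - E_self(bulk water)]`,
with the probe placed exactly on solver nodes so the grid self-energy
artifact cancels between the environment and the uniform-water reference.
Sample points within (vdW + probe radius) of an atom are removed, mirroring
clash removal on a sampling grid. Verified oracles: Coulomb and
Debye-Hueckel potentials to 2-3% mid-range at 0.5 A spacing, the Born
solvation energy of a 2 A ion to 2% at 0.25 A spacing, transfer energy
identically zero in homogeneous water, exact linearity in the charges.

Field maps average, over frames, the exact Poisson solution for
Gaussian-smeared charges (`phi = k_c q erf(r / sqrt2 sigma) / r`,
default smearing 1 A); the stored field is the negative finite-difference
gradient of the averaged potential. This is the same model a smeared-
charge mesh solver evaluates, without mesh periodicity artifacts.

## Solution structure

RDFs use minimum-image shell histograms normalized by ideal-gas shell
counts, with `r_max` capped at half the smallest box length; coordination
numbers are running integrals of the histogram. Cation-anion pair classes
default to contact pairs (CIP) up to 3.95 A and solvent-separated pairs
(SSIP) up to 6.37 A — the first and second minima of a 1 M KCl solution
RDF — with the contact boundary inclusive; thresholds can instead be
derived from a user RDF via its extrema (3-point smoothing, binned-curve
resolution). A cation is paired when it has at least one partner within
the SSIP limit, counted once. Pairing, solvation and dipole profiles are
per-z-bin time averages.

Dipole-orientation analyses run on synthetic dipole carriers whose
cos(theta) is Boltzmann-distributed in an imposed z field with energy
`-pE cos(theta)`; the stationary mean is the Langevin function L(pE/kT),
which is the analytic oracle the generator is tested against. This keeps
the orientation pipeline testable without any water model; it does not
claim to reproduce hydrogen-bonded water structure.

## Reversal-potential models

For a symmetric monovalent salt, GHK:
`E = (RT/F) ln[(P_C C_trans + P_A C_cis)/(P_C C_cis + P_A C_trans)]`, and
Planck (electroneutral constrained liquid junction):
`E = (RT/F) (D_C - D_A)/(D_C + D_A) ln(C_trans/C_cis)`. The sign
convention is cis relative to the grounded trans side, so anion
preference with trans = 2 x cis gives E < 0. Permeabilities are always
named per ion (never a bare ratio) to keep the orientation of the
permeability ratio unambiguous. `invert_ghk` solves the GHK form for
P_anion/P_cation in closed form and rejects potentials outside the
attainable band +/-(RT/F) ln(ratio). Both models depend only on the
concentration ratio — their analytic ionic-strength invariance at fixed
ratio (checked to 1e-9 mV) is exactly why a measured ionic-strength
dependence at fixed ratio indicates unscreened fixed charges rather than
neutral-pore diffusion. RT/F uses CODATA constants; default 298.15 K.

## Conservation scoring

Columns are scored against a reference sequence whose numbering skips its
own gaps (an audit map from reference position to alignment column is
available). Four physicochemical classes partition the 20 amino acids
(negative D/E; positive R/K; polar T/W/S/N/Q/Y/C/H; other
A/G/I/L/M/P/V/F; asserted at import). Gaps are excluded from class
fractions and reported separately, so fractions sum to one only together
with the gap fraction. A column is conserved when the reference residue
exceeds 90% strictly, functionally conserved when its class does; the
"functionally conserved" formalization (own-class fraction over the same
threshold) is this package's definition of a phrase that is used in the
field without a formula. Net charge is the pH-7 standard-protonation
count (D/E -1, R/K +1), with unknown letters counted as 0 under a
warning.

## Problem sizes used in tests and the acceptance script

Simulation sizes were chosen so each check has the statistics it needs:
the free-energy well recovery uses 150 non-interacting anions for 4000
recorded frames (600 000 frame-particle samples) in a box whose
reservoirs are large relative to the well, because the dominant error is
the slow exchange fluctuation between the well and the bulk region that
sets the measured C_bulk, not per-bin shot noise; the screening scan runs
3 seeds x 4 concentrations
(0.1-1.2 M) with run lengths scaled inversely with concentration so the
sparse low-salt reservoirs are sampled as well as the crowded ones; PB
oracles use 65^3-97^3 grids at 0.25-0.5 A spacing. The translocation
detector is validated against an exhaustive region-labeling oracle on
1000 random walks.

## Known limitations

* The BD model has implicit solvent, point-like ions and a rigid,
  idealized wall: it reproduces the *mechanism* under study
  (fixed-charge attraction, its Debye screening, mass-action ion
  pairing) but not absolute occupancies, passage times or conductances of
  any real channel. Passing tests show the estimators are correct and the
  screening physics is present, not that a specific protein is modeled.
* The linearized PB solver omits nonlinear saturation; near multivalent
  or densely charged sites the linear approximation overestimates
  screening response.
* The field map is non-periodic by construction; long-range periodic
  images are absent (negligible for the pore-scale maps it serves).
* The event detector assumes frame spacing fine enough that a particle
  cannot skip the slab in one step; it warns otherwise.
* Free-energy profiles need sampling everywhere they report: masked bins
  in poorly sampled regions are the intended behavior, and barrier tops
  converge last.
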