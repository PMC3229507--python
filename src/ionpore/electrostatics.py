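"""Continuum electrostatics: linearized Poisson-Boltzmann on a grid,
ion-transfer free energies, and time-averaged electric-field maps.

The solver discretizes::

    div( eps grad(phi) ) - eps_w kappa^2 lambda(r) phi = -4 pi k_c rho

on a uniform grid with harmonic-mean edge dielectrics and red-black SOR.
``lambda`` is the ion-accessibility mask (1 in water-labeled regions, 0 in
protein and membrane core); potentials are in kcal/(mol e), charges in e,
k_c = 332.06 kcal A/(mol e^2). The membrane model follows a
three-dielectric picture: water and lipid headgroups at eps 80, protein at
4, a 25 A hydrophobic core slab at 2.

Field maps are the time average over frames of the exact solution of the
Poisson equation for Gaussian-smeared point charges (the smeared-charge
potential is analytic, erf(r / sqrt(2) sigma) / r), with the field taken
as the negative gradient of the stored potential grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from scipy.special import erf

from .constants import COULOMB_KCAL, MOLAR_TO_PER_A3, bjerrum_length
from .errors import (
    ConfigurationError,
    ConvergenceError,
    EmptyInputError,
    InvalidParameterError,
)
from .grids import Grid3D
from .trajectory import Trajectory

LABEL_WATER, LABEL_PROTEIN, LABEL_CORE = 0, 1, 2


@dataclass
class DielectricMap:
    """Node-based relative-dielectric map with region labels."""

    eps: Grid3D
    labels: np.ndarray           # int array, LABEL_* per node
    eps_water: float = 80.0
    slab_half: float = 12.5

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != self.eps.shape:
            raise InvalidParameterError("labels shape must match eps grid")


@dataclass
class PBOptions:
    """Solver controls; spacings in angstrom, ionic strength in mol/L."""

    ionic_strength: float = 0.0
    temperature: float = 300.0
    tol: float = 1e-4
    max_iter: int = 20000
    omega: float | None = None
    outer_extent: float = 120.0
    levels: int = 2
    final_spacing: float = 0.8
    nodes_per_level: int = 65
    probe_charge: float = -1.0
    probe_radius: float = 2.0

    def __post_init__(self):
        if self.tol <= 0:
            raise InvalidParameterError("tolerance must be > 0")
        if self.final_spacing <= 0:
            raise InvalidParameterError("final spacing must be > 0")
        final_extent = self.final_spacing * (self.nodes_per_level - 1)
        if final_extent > self.outer_extent:
            raise InvalidParameterError("final grid extent exceeds the outer extent")


def kappa_from_ionic_strength(
    ionic_strength: float, temperature: float = 300.0, eps_water: float = 80.0
) -> float:
    """Inverse Debye length (1/A) for a 1:1 salt at the given conditions."""
    if ionic_strength <= 0:
        return 0.0
    lb = bjerrum_length(temperature, eps_water)
    return float(np.sqrt(8.0 * np.pi * lb * ionic_strength * MOLAR_TO_PER_A3))


def uniform_dielectric_map(
    origin, spacing: float, shape, eps: float = 80.0
) -> DielectricMap:
    """A homogeneous map (all water), e.g. the bulk solvation reference."""
    values = np.full(shape, float(eps))
    grid = Grid3D(origin=origin, spacing=spacing, values=values)
    return DielectricMap(
        eps=grid, labels=np.zeros(shape, dtype=np.int8), eps_water=eps
    )


def build_dielectric_map(
    atom_coords,
    atom_radii,
    origin,
    spacing: float,
    shape,
    slab_half: float = 12.5,
    pore_radius: float | None = None,
    eps_water: float = 80.0,
    eps_protein: float = 4.0,
    eps_core: float = 2.0,
) -> DielectricMap:
    """Three-dielectric membrane/protein map on grid nodes.

    Nodes inside any atom sphere are protein (eps 4); otherwise nodes with
    |z| < slab_half (optionally outside a lumen cylinder of ``pore_radius``)
    are hydrophobic core (eps 2); everything else is water/headgroup
    (eps 80). An empty structure yields a pure membrane/water map.
    """
    import warnings

    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(s) for s in shape)
    atom_coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
    atom_radii = np.asarray(atom_radii, dtype=float).reshape(-1)
    if len(atom_coords) == 0:
        warnings.warn("empty structure: building a pure membrane/water map")

    labels = np.full(shape, LABEL_WATER, dtype=np.int8)
    xs = origin[0] + spacing * np.arange(shape[0])
    ys = origin[1] + spacing * np.arange(shape[1])
    zs = origin[2] + spacing * np.arange(shape[2])
    zz = zs[None, None, :]
    in_slab = np.broadcast_to(np.abs(zz) < slab_half, shape)
    if pore_radius is not None:
        rho2 = xs[:, None, None] ** 2 + ys[None, :, None] ** 2
        in_slab = in_slab & np.broadcast_to(rho2 > pore_radius**2, shape)
    labels[in_slab] = LABEL_CORE

    for xyz, r in zip(atom_coords, atom_radii):
        lo = np.maximum(np.ceil((xyz - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.floor((xyz + r - origin) / spacing).astype(int), np.array(shape) - 1)
        if np.any(lo > hi):
            continue
        sx = xs[lo[0]:hi[0] + 1] - xyz[0]
        sy = ys[lo[1]:hi[1] + 1] - xyz[1]
        sz = zs[lo[2]:hi[2] + 1] - xyz[2]
        d2 = sx[:, None, None] ** 2 + sy[None, :, None] ** 2 + sz[None, None, :] ** 2
        sub = labels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub[d2 <= r**2] = LABEL_PROTEIN

    eps_values = np.choose(labels, [eps_water, eps_protein, eps_core])
    grid = Grid3D(origin=origin, spacing=spacing, values=eps_values.astype(float))
    return DielectricMap(eps=grid, labels=labels, eps_water=eps_water, slab_half=slab_half)


# -- solver ----------------------------------------------------------------

def _assign_charges(origin, spacing, shape, charges) -> np.ndarray:
    """Trilinear (cloud-in-cell) assignment of point charges to nodes."""
    q = np.zeros(shape)
    for pos, qv in charges:
        f = (np.asarray(pos, dtype=float) - origin) / spacing
        i0 = np.floor(f).astype(int)
        if np.any(i0 < 0) or np.any(i0 + 1 > np.array(shape) - 1):
            raise ConfigurationError(f"charge at {pos} lies outside the grid")
        w = f - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wgt = (
                        (w[0] if dx else 1 - w[0])
                        * (w[1] if dy else 1 - w[1])
                        * (w[2] if dz else 1 - w[2])
                    )
                    q[i0[0] + dx, i0[1] + dy, i0[2] + dz] += qv * wgt
    return q


def _dh_potential(points: np.ndarray, charges, kappa: float, eps: float) -> np.ndarray:
    """Debye-Hueckel monopole superposition (boundary model / initial guess)."""
    out = np.zeros(len(points))
    for pos, qv in charges:
        r = np.linalg.norm(points - np.asarray(pos, dtype=float), axis=1)
        r = np.maximum(r, 1e-6)
        out += COULOMB_KCAL * qv * np.exp(-kappa * r) / (eps * r)
    return out


def solve_lpb(
    diel: DielectricMap,
    charges,
    options: PBOptions | None = None,
    boundary_values: np.ndarray | None = None,
    lambda_mask: np.ndarray | None = None,
) -> Grid3D:
    """Solve the linearized PB equation on the map's grid.

    ``charges`` is a list of (position, charge/e) pairs. The Dirichlet
    boundary is a Debye-Hueckel monopole superposition unless
    ``boundary_values`` (a full-shape array, used on the faces) is given,
    e.g. interpolated from a coarser focusing level. ``lambda_mask``
    overrides the ion-accessibility mask (default: water-labeled nodes),
    exposing e.g. a kappa = 0 pore lumen.
    """
    opts = options or PBOptions()
    grid = diel.eps
    h = grid.spacing
    shape = grid.shape
    eps = grid.values
    kappa = kappa_from_ionic_strength(opts.ionic_strength, opts.temperature, diel.eps_water)
    lam = (diel.labels == LABEL_WATER) if lambda_mask is None else np.asarray(lambda_mask, bool)
    kap2h2 = diel.eps_water * kappa**2 * lam * h**2

    qgrid = _assign_charges(grid.origin, h, shape, charges)
    b = 4.0 * np.pi * COULOMB_KCAL * qgrid / h

    # boundary dielectric for the monopole model: corner value of the map
    eps_b = float(eps[0, 0, 0])
    if boundary_values is not None:
        phi = np.array(boundary_values, dtype=float)
        if phi.shape != shape:
            raise ConfigurationError("boundary_values shape must match the grid")
    else:
        phi = _dh_potential(grid.points(), charges, kappa, eps_b).reshape(shape)

    # harmonic-mean edge dielectrics
    ex = 2.0 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:])
    ey = 2.0 * eps[:, :-1] * eps[:, 1:] / (eps[:, :-1] + eps[:, 1:])
    ez = 2.0 * eps[:, :, :-1] * eps[:, :, 1:] / (eps[:, :, :-1] + eps[:, :, 1:])

    I = slice(1, -1)
    exm, exp_ = ex[:-1, I, I], ex[1:, I, I]
    eym = ey[I, :-1, I]
    eyp = ey[I, 1:, I]
    ezm = ez[I, I, :-1]
    ezp = ez[I, I, 1:]
    diag = exm + exp_ + eym + eyp + ezm + ezp + kap2h2[I, I, I]
    b_int = b[I, I, I]

    ii, jj, kk = np.indices(tuple(s - 2 for s in shape))
    red = (ii + jj + kk) % 2 == 0
    black = ~red

    n_max = max(shape)
    omega = opts.omega or 2.0 / (1.0 + np.sin(np.pi / n_max))

    phi_int = phi[I, I, I]
    last_delta = np.inf
    for it in range(opts.max_iter):
        last_delta = 0.0
        for color in (red, black):
            s = (
                exm * phi[:-2, I, I]
                + exp_ * phi[2:, I, I]
                + eym * phi[I, :-2, I]
                + eyp * phi[I, 2:, I]
                + ezm * phi[I, I, :-2]
                + ezp * phi[I, I, 2:]
            )
            upd = omega * ((s + b_int) / diag - phi_int)
            phi_int[color] += upd[color]
            last_delta = max(last_delta, float(np.abs(upd[color]).max(initial=0.0)))
        if last_delta < opts.tol:
            break
    else:
        raise ConvergenceError(
            f"LPB solver did not reach tol={opts.tol} in {opts.max_iter} "
            f"iterations (last max update {last_delta:.3e})",
            residual=last_delta,
        )
    return Grid3D(
        origin=grid.origin,
        spacing=h,
        values=phi,
        meta={"iterations": it + 1, "residual": last_delta, "kappa": kappa,
              "kind": "potential"},
    )


def solve_lpb_focused(
    make_map,
    charges,
    options: PBOptions,
    center=(0.0, 0.0, 0.0),
):
    """Successive-focusing LPB solve.

    ``make_map(origin, spacing, shape) -> DielectricMap`` builds the map at
    each level. Levels run from ``outer_extent`` down to the final grid
    (``nodes_per_level`` nodes at ``final_spacing``), shrinking the extent
    geometrically; each finer level takes Dirichlet boundaries interpolated
    from the parent solution. Returns the finest-level potential Grid3D.
    """
    center = np.asarray(center, dtype=float)
    n = options.nodes_per_level
    final_extent = options.final_spacing * (n - 1)
    extents = np.geomspace(options.outer_extent, final_extent, options.levels + 1)
    phi_parent: Grid3D | None = None
    for ext in extents:
        spacing = ext / (n - 1)
        origin = center - ext / 2.0
        diel = make_map(origin, spacing, (n, n, n))
        if phi_parent is None:
            phi = solve_lpb(diel, charges, options)
        else:
            interp = RegularGridInterpolator(
                tuple(phi_parent.axis_coords(a) for a in range(3)),
                phi_parent.values,
                bounds_error=False,
                fill_value=None,
            )
            bvals = interp(
                Grid3D(origin, spacing, np.zeros((n, n, n))).points()
            ).reshape(n, n, n)
            phi = solve_lpb(diel, charges, options, boundary_values=bvals)
        phi_parent = phi
    return phi_parent


# -- transfer energies -----------------------------------------------------

def transfer_energy_grid(
    diel: DielectricMap,
    static_charges,
    sample_origin,
    sample_spacing: float,
    sample_shape,
    options: PBOptions | None = None,
    probe_charge: float | None = None,
    probe_radius: float | None = None,
    atom_coords=None,
    atom_radii=None,
) -> Grid3D:
    """Ion-transfer free energy on a sample grid inside an environment map.

    Per sample point p (snapped to the nearest solver node)::

        dG(p) = q phi_static(p) + [ E_self(p; env) - E_self(bulk water) ]

    where phi_static is the LPB potential of the fixed charges in the
    environment and E_self = q phi_probe(p) / 2 from a solve with only the
    probe charge; the bulk reference is one solve in a uniform-water map of
    identical geometry, so the grid self-energy artifact cancels. Sample
    points within (atom vdW radius + probe radius) of any atom clash and
    are masked, as are points outside the solver grid.
    """
    opts = options or PBOptions()
    qp = opts.probe_charge if probe_charge is None else probe_charge
    rp = opts.probe_radius if probe_radius is None else probe_radius
    sample_origin = np.asarray(sample_origin, dtype=float)
    sample_shape = tuple(int(s) for s in sample_shape)

    grid = diel.eps
    h = grid.spacing
    if static_charges:
        phi_static = solve_lpb(diel, static_charges, opts).values
    else:
        phi_static = np.zeros(grid.shape)

    bulk = uniform_dielectric_map(grid.origin, h, grid.shape, eps=diel.eps_water)
    center_node = tuple(s // 2 for s in grid.shape)
    center_pos = grid.origin + h * np.asarray(center_node)
    phi_b = solve_lpb(bulk, [(center_pos, qp)], opts).values
    e_bulk = 0.5 * qp * phi_b[center_node]

    tree = None
    if atom_coords is not None and len(np.atleast_2d(atom_coords)):
        atom_coords = np.asarray(atom_coords, dtype=float).reshape(-1, 3)
        atom_radii = np.asarray(atom_radii, dtype=float).reshape(-1)
        tree = cKDTree(atom_coords)

    values = np.full(sample_shape, np.nan)
    mask = np.zeros(sample_shape, dtype=bool)
    for idx in np.ndindex(sample_shape):
        p = sample_origin + sample_spacing * np.asarray(idx)
        node = np.round((p - grid.origin) / h).astype(int)
        if np.any(node < 1) or np.any(node > np.array(grid.shape) - 2):
            continue
        if tree is not None:
            near = tree.query_ball_point(p, r=float(atom_radii.max()) + rp)
            if any(np.linalg.norm(atom_coords[a] - p) < atom_radii[a] + rp for a in near):
                continue
        node_pos = grid.origin + h * node
        phi_p = solve_lpb(diel, [(node_pos, qp)], opts).values
        e_env = 0.5 * qp * phi_p[tuple(node)]
        values[idx] = qp * phi_static[tuple(node)] + (e_env - e_bulk)
        mask[idx] = True
    return Grid3D(
        origin=sample_origin,
        spacing=sample_spacing,
        values=values,
        mask=mask,
        meta={"probe_charge": qp, "probe_radius": rp, "kind": "transfer_energy"},
    )


# -- field maps ------------------------------------------------------------

@dataclass
class FieldMap:
    """Time-averaged electric field on a grid.

    ``vectors`` holds -grad(phi) in kcal/(mol A e); ``magnitude`` its norm.
    """

    potential: Grid3D
    vectors: np.ndarray
    magnitude: Grid3D


DEFAULT_SPECIES_CHARGE = {"cation": 1.0, "anion": -1.0}


def _smeared_potential(points: np.ndarray, charges, sigma: float, eps: float) -> np.ndarray:
    """Exact Poisson potential of Gaussian charges of width sigma."""
    out = np.zeros(len(points))
    pref = COULOMB_KCAL / eps
    for pos, qv in charges:
        r = np.linalg.norm(points - np.asarray(pos, dtype=float), axis=1)
        small = r < 1e-9
        rs = np.where(small, 1.0, r)
        v = erf(rs / (np.sqrt(2.0) * sigma)) / rs
        v[small] = np.sqrt(2.0 / np.pi) / sigma
        out += pref * qv * v
    return out


def average_field_map(
    source,
    origin,
    spacing: float,
    shape,
    smoothing: float = 1.0,
    dielectric: float = 1.0,
    species_charge: dict | None = None,
) -> FieldMap:
    """Time-averaged smeared-charge field map (PMEPot-style).

    ``source`` is a Trajectory (charged species taken per frame) or a
    static list of (position, charge) pairs. Each frame's potential is the
    exact solution of the Poisson equation for charges smeared with a
    Gaussian of width ``smoothing``; the frame-averaged potential is stored
    and the field is its negative finite-difference gradient.
    """
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(s) for s in shape)
    pts = Grid3D(origin, spacing, np.zeros(shape)).points()
    chmap = species_charge or DEFAULT_SPECIES_CHARGE

    if isinstance(source, Trajectory):
        if source.n_frames == 0:
            raise EmptyInputError("cannot average a field over zero frames")
        qs = np.asarray([chmap.get(sp, 0.0) for sp in source.species])
        charged = np.nonzero(qs != 0.0)[0]
        acc = np.zeros(len(pts))
        for f in range(source.n_frames):
            frame_charges = [
                (source.positions[f, p], qs[p]) for p in charged
            ]
            acc += _smeared_potential(pts, frame_charges, smoothing, dielectric)
        phi = acc / source.n_frames
    else:
        phi = _smeared_potential(pts, list(source), smoothing, dielectric)

    phi = phi.reshape(shape)
    grads = np.gradient(phi, spacing)
    vectors = -np.stack(grads, axis=-1)
    magnitude = np.linalg.norm(vectors, axis=-1)
    pot = Grid3D(origin, spacing, phi, meta={"smoothing": smoothing, "kind": "potential"})
    mag = Grid3D(origin, spacing, magnitude, meta={"kind": "field_magnitude"})
    return FieldMap(potential=pot, vectors=vectors, magnitude=mag)
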