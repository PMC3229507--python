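"""Brownian-dynamics ion trajectories in a model membrane channel.

The generator emulates the study conditions of an equilibrium KCl/channel
simulation: two monovalent species with distinct diffusion coefficients, a
membrane slab pierced by a cylindrical pore on the z axis, fixed positive
pore-lining charges whose electrostatic reach shrinks with bulk
concentration (Debye screening), screened ion-ion interactions, and bulk
reservoirs on both sides connected through the pore only.

Dynamics are overdamped Euler-Maruyama Langevin steps::

    x(t+dt) = x(t) + D f(x) dt + sqrt(2 D dt) N(0, 1)

with forces f = -grad(U/kT) in 1/A. Interactions use the Yukawa form
``q1 q2 l_B exp(-r/lambda)/r`` (in kT) plus a soft-core ``(sigma/r)^12``
repulsion; the membrane is a reflecting wall outside the pore cylinder and
the box is periodic in x, y, z. Internal units: angstrom, picosecond, kT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import MOLAR_TO_PER_A3, bjerrum_length
from .errors import (
    InvalidParameterError,
    PackingError,
    StabilityWarning,
)
from .trajectory import Trajectory, minimum_image

#: formal charge per species tag, elementary units
SPECIES_CHARGE = {"cation": 1.0, "anion": -1.0, "dipole": 0.0, "other": 0.0}


def debye_length(c_bulk: float, temperature: float = 298.0, dielectric: float = 78.5) -> float:
    """Debye screening length (A) of a fully dissociated 1:1 salt.

    kappa^2 = 8 pi l_B N_A C with the Bjerrum length l_B evaluated at the
    given temperature and relative permittivity; C in mol/L.
    """
    if c_bulk <= 0 or temperature <= 0 or dielectric <= 0:
        raise InvalidParameterError("debye_length arguments must all be > 0")
    lb = bjerrum_length(temperature, dielectric)
    kappa2 = 8.0 * np.pi * lb * c_bulk * MOLAR_TO_PER_A3
    return 1.0 / np.sqrt(kappa2)


@dataclass
class ChannelSystem:
    """Membrane slab + cylindrical pore geometry with fixed point charges.

    The slab is centered at z = 0 with half-thickness ``slab_half``; the
    pore is a cylinder of radius ``pore_radius`` on the z axis. Fixed
    charges are (position, charge/e) pairs, typically rings lining the pore
    that emulate the basic residues of an anion-selective channel wall.
    """

    box: tuple[float, float, float] = (34.0, 34.0, 72.0)
    slab_half: float = 15.0
    pore_radius: float = 9.0
    fixed_charges: list = field(default_factory=list)
    dielectric: float = 78.5
    temperature: float = 300.0

    def __post_init__(self):
        self.box = tuple(float(v) for v in self.box)
        if any(v <= 0 for v in self.box):
            raise InvalidParameterError("box lengths must be > 0")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be > 0")
        if self.slab_half < 0 or 2 * self.slab_half >= self.box[2]:
            raise InvalidParameterError("membrane slab must fit inside the box")
        if self.slab_half > 0:
            if self.pore_radius <= 0 or self.pore_radius >= min(self.box[0], self.box[1]) / 2:
                raise InvalidParameterError("pore radius must be positive and smaller than the lateral half-box")

    @property
    def charge_positions(self) -> np.ndarray:
        if not self.fixed_charges:
            return np.zeros((0, 3))
        return np.asarray([p for p, _ in self.fixed_charges], dtype=float)

    @property
    def charge_values(self) -> np.ndarray:
        return np.asarray([q for _, q in self.fixed_charges], dtype=float)


@dataclass
class BDParams:
    """Propagation parameters for :func:`run_bd`.

    ``kappa_inv`` defaults to the Debye length of ``c_bulk`` at the system
    temperature/dielectric; ``seed`` makes runs bit-for-bit reproducible.
    """

    dt: float = 0.5                      # ps
    diffusion: dict = field(default_factory=lambda: {"cation": 0.196, "anion": 0.203})
    c_bulk: float = 0.1                  # mol/L
    kappa_inv: float | None = None       # A
    contact_radius: float = 2.5          # A (soft-core sigma)
    n_steps: int = 10000
    n_equil: int = 0
    stride: int = 10
    seed: int = 0
    ion_ion: bool = True
    wrap: bool = True
    strict_stability: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidParameterError("time step must be > 0")
        if any(d <= 0 for d in self.diffusion.values()):
            raise InvalidParameterError("diffusion coefficients must be > 0")
        if self.kappa_inv is not None and self.kappa_inv <= 0:
            raise InvalidParameterError("Debye length must be > 0")
        if self.c_bulk <= 0:
            raise InvalidParameterError("bulk concentration must be > 0")


@dataclass
class GaussianWell:
    """External potential U(z) = depth_kt * exp(-(z-center)^2 / (2 sigma^2))."""

    depth_kt: float
    center: float = 0.0
    sigma: float = 3.0

    def energy(self, z):
        return self.depth_kt * np.exp(-((z - self.center) ** 2) / (2.0 * self.sigma**2))

    def force(self, z):
        # f = -dU/dz
        return (
            self.depth_kt
            * (z - self.center)
            / self.sigma**2
            * np.exp(-((z - self.center) ** 2) / (2.0 * self.sigma**2))
        )


def fixed_charge_ring(n: int, radius: float, z: float, q_each: float, phase: float = 0.0) -> list:
    """A ring of n point charges of q_each at the given radius and height."""
    angles = phase + 2.0 * np.pi * np.arange(n) / n
    return [
        (np.array([radius * np.cos(a), radius * np.sin(a), z]), q_each) for a in angles
    ]


def default_pore_charges(total_charge: float = 4.0) -> list:
    """Two rings of positive charges lining the pore wall (z = +/-5 A).

    Stand-in for the basic residues that give the channel its anion
    preference; the default +4 e total is of the order of the net positive
    excess of the modeled pore.
    """
    per_ring = total_charge / 2.0
    return fixed_charge_ring(4, 6.5, -5.0, per_ring / 4.0) + fixed_charge_ring(
        4, 6.5, 5.0, per_ring / 4.0, phase=np.pi / 4
    )


# -- propagation ----------------------------------------------------------

def _forbidden(pos: np.ndarray, slab_half: float, pore_radius: float) -> np.ndarray:
    """Mask of positions inside the membrane wall (slab minus pore)."""
    if slab_half <= 0:
        return np.zeros(len(pos), dtype=bool)
    rho2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
    return (np.abs(pos[:, 2]) < slab_half) & (rho2 > pore_radius**2)


def _place_particles(
    rng, n: int, system: ChannelSystem, sigma: float, max_retry: int = 10000
) -> np.ndarray:
    box = np.asarray(system.box)
    placed = np.zeros((0, 3))
    fc = system.charge_positions
    out = []
    for _ in range(n):
        for attempt in range(max_retry):
            p = (rng.random(3) - 0.5) * box
            if _forbidden(p[None, :], system.slab_half, system.pore_radius)[0]:
                continue
            obstacles = placed if len(fc) == 0 else np.vstack([placed, fc]) if len(placed) else fc
            if len(obstacles):
                d = minimum_image(obstacles - p, box)
                if np.any((d**2).sum(axis=1) < sigma**2):
                    continue
            out.append(p)
            placed = np.asarray(out)
            break
        else:
            raise PackingError(
                f"could not place particle {len(out)} after {max_retry} attempts"
            )
    return np.asarray(out)


def _pair_force(pos, charges, box, lb, lam, sigma, ion_ion):
    """Forces (kT/A) from ion-ion Yukawa + soft-core interactions."""
    d = pos[:, None, :] - pos[None, :, :]
    d = minimum_image(d, box)
    r2 = (d**2).sum(axis=-1)
    np.fill_diagonal(r2, np.inf)
    r = np.sqrt(r2)
    rc = np.maximum(r, 0.6 * sigma)
    fmag = 12.0 * sigma**12 / rc**13
    if ion_ion:
        a = np.outer(charges, charges) * lb
        fmag = fmag + a * np.exp(-r / lam) * (1.0 / r2 + 1.0 / (lam * r))
    with np.errstate(invalid="ignore"):
        fvec = (fmag / r)[:, :, None] * d
    fvec[~np.isfinite(fvec)] = 0.0
    return fvec.sum(axis=1)


def _external_force(pos, charges, fc_pos, fc_q, box, lb, lam, sigma):
    """Forces (kT/A) from the fixed channel charges (Yukawa + soft core)."""
    if len(fc_pos) == 0:
        return np.zeros_like(pos)
    d = pos[:, None, :] - fc_pos[None, :, :]
    d = minimum_image(d, box)
    r2 = (d**2).sum(axis=-1)
    r = np.sqrt(r2)
    rc = np.maximum(r, 0.6 * sigma)
    a = charges[:, None] * fc_q[None, :] * lb
    fmag = 12.0 * sigma**12 / rc**13 + a * np.exp(-r / lam) * (1.0 / r2 + 1.0 / (lam * r))
    fvec = (fmag / r)[:, :, None] * d
    fvec[~np.isfinite(fvec)] = 0.0
    return fvec.sum(axis=1)


def _apply_walls(old, new, slab_half, pore_radius):
    """Reflect proposed moves off the membrane wall; reject unresolvable ones."""
    if slab_half <= 0:
        return new
    bad = _forbidden(new, slab_half, pore_radius)
    if not np.any(bad):
        return new
    idx = np.nonzero(bad)[0]
    for i in idx:
        zo = old[i, 2]
        if abs(zo) >= slab_half:
            # came from a reservoir: reflect off the nearest slab face
            s = 1.0 if zo >= 0 else -1.0
            new[i, 2] = s * 2.0 * slab_half - new[i, 2]
        else:
            # was inside the pore: reflect off the cylinder wall
            rho = np.hypot(new[i, 0], new[i, 1])
            target = 2.0 * pore_radius - rho
            if target > 0.1 * pore_radius:
                new[i, 0] *= target / rho
                new[i, 1] *= target / rho
    still = _forbidden(new, slab_half, pore_radius)
    new[still] = old[still]
    return new


def expected_counts(system: ChannelSystem, c_bulk: float) -> float:
    """Ideal per-species particle number for c_bulk over the full box volume."""
    v = system.box[0] * system.box[1] * system.box[2]
    return c_bulk * MOLAR_TO_PER_A3 * v


def run_bd(
    system: ChannelSystem,
    params: BDParams,
    counts: dict,
    external: dict | None = None,
    check_counts: bool = True,
) -> Trajectory:
    """Propagate ions and return the sampled trajectory.

    Parameters
    ----------
    counts : dict
        Particle number per species tag, e.g. ``{"cation": 20, "anion": 20}``.
    external : dict, optional
        Per-species external potential objects with ``force(z)`` methods
        (e.g. :class:`GaussianWell`) added to the channel forces.
    check_counts : bool
        Enforce that ionic counts match ``params.c_bulk`` and the box volume
        within 10% (disable for deliberately non-physical test ensembles).
    """
    box = np.asarray(system.box)
    sigma = params.contact_radius
    if check_counts:
        n_exp = expected_counts(system, params.c_bulk)
        for sp in ("cation", "anion"):
            if sp in counts and abs(counts[sp] - n_exp) > 0.1 * max(n_exp, 1.0):
                raise InvalidParameterError(
                    f"{sp} count {counts[sp]} inconsistent with c_bulk "
                    f"{params.c_bulk} M (expected ~{n_exp:.1f})"
                )
    dmax = max(params.diffusion.get(sp, 0.2) for sp in counts)
    rms_step = np.sqrt(2.0 * dmax * params.dt)
    if rms_step > sigma:
        msg = (
            f"per-step RMS displacement {rms_step:.2f} A exceeds the contact "
            f"radius {sigma:.2f} A"
        )
        if params.strict_stability:
            raise InvalidParameterError(msg)
        warnings.warn(msg, StabilityWarning)

    species = np.concatenate(
        [np.full(counts[sp], sp, dtype="U16") for sp in sorted(counts)]
    )
    n = len(species)
    charges = np.asarray([SPECIES_CHARGE[sp] for sp in species])
    dcoef = np.asarray([params.diffusion.get(sp, 0.2) for sp in species])

    rng = np.random.default_rng(params.seed)
    pos = _place_particles(rng, n, system, sigma)

    lb = bjerrum_length(system.temperature, system.dielectric)
    lam = params.kappa_inv
    if lam is None:
        lam = debye_length(params.c_bulk, system.temperature, system.dielectric)
    fc_pos, fc_q = system.charge_positions, system.charge_values

    ext_species = sorted(external) if external else []
    sp_masks = {sp: species == sp for sp in ext_species}

    n_record = params.n_steps // params.stride + 1
    out = np.empty((n_record, n, 3))
    times = np.empty(n_record)
    k = 0
    total = params.n_equil + params.n_steps
    amp = np.sqrt(2.0 * dcoef * params.dt)[:, None]
    mob = (dcoef * params.dt)[:, None]
    for step in range(total + 1):
        rec_step = step - params.n_equil
        if rec_step >= 0 and rec_step % params.stride == 0 and k < n_record:
            out[k] = pos
            times[k] = rec_step * params.dt
            k += 1
        if step == total:
            break
        f = _external_force(pos, charges, fc_pos, fc_q, box, lb, lam, sigma)
        if n > 1 and params.ion_ion:
            # ion_ion gates all ion-ion terms (Yukawa and soft core); the
            # fixed-charge interaction above always keeps its soft core
            f += _pair_force(pos, charges, box, lb, lam, sigma, True)
        for sp in ext_species:
            m = sp_masks[sp]
            f[m, 2] += external[sp].force(pos[m, 2])
        # cap the deterministic drift at 1 A/step for numerical safety
        drift = mob * f
        norm = np.linalg.norm(drift, axis=1, keepdims=True)
        np.divide(drift, norm, out=drift, where=norm > 1.0)
        new = pos + drift + amp * rng.standard_normal((n, 3))
        new = _apply_walls(pos, new, system.slab_half, system.pore_radius)
        if params.wrap:
            new = new - box * np.round(new / box)
        pos = new

    return Trajectory(
        times=times[:k],
        ids=np.arange(n),
        species=species,
        positions=out[:k],
        box=box,
        temperature=system.temperature,
        c_bulk=params.c_bulk,
        diffusion=dict(params.diffusion),
    )


def selectivity_scan(
    concentrations=(0.1, 0.4, 0.8, 1.2),
    seeds=(1, 2, 3),
    total_charge: float = 6.0,
    base_steps: int = 20000,
    dt: float = 0.5,
    pore=None,
) -> dict:
    """Pore anion/cation occupancy ratio over a bulk-concentration scan.

    One BD run per (seed, concentration) with identical geometry and fixed
    charges; particle numbers follow the concentration and run lengths
    scale inversely with it so the sparse low-concentration reservoirs are
    sampled as well as the crowded ones. Returns
    ``{seed: {c: (ratio, n_anion, n_cation)}}``.
    """
    from .permeation import count_occupancy
    from .trajectory import PoreGeometry

    pore = pore or PoreGeometry(-15.0, 15.0)
    out: dict = {}
    for seed in seeds:
        out[seed] = {}
        for c in concentrations:
            system = ChannelSystem(fixed_charges=default_pore_charges(total_charge))
            n = int(round(expected_counts(system, c)))
            n_steps = int(base_steps * max(1.0, 0.8 / c))
            params = BDParams(
                dt=dt, n_steps=n_steps, n_equil=max(3000, n_steps // 8),
                stride=20, seed=seed, c_bulk=c,
            )
            traj = run_bd(system, params, {"cation": n, "anion": n})
            oa = count_occupancy(traj, pore, "anion")
            oc = count_occupancy(traj, pore, "cation")
            ratio = oa.mean / oc.mean if oc.mean > 0 else np.inf
            out[seed][c] = (ratio, oa.mean, oc.mean)
    return out


# -- analytic sampling generators (fixtures without dynamics) -------------

def ideal_gas_trajectory(
    n: int,
    n_frames: int,
    box=(30.0, 30.0, 60.0),
    seed: int = 0,
    species: str = "anion",
    temperature: float = 300.0,
    c_bulk: float | None = None,
    dt: float = 1.0,
) -> Trajectory:
    """Uncorrelated uniform positions per frame (exact ideal gas)."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    pos = (rng.random((n_frames, n, 3)) - 0.5) * box
    if c_bulk is None:
        c_bulk = n / (box.prod() * MOLAR_TO_PER_A3)
    return Trajectory(
        times=dt * np.arange(n_frames),
        ids=np.arange(n),
        species=np.full(n, species, dtype="U16"),
        positions=pos,
        box=box,
        temperature=temperature,
        c_bulk=c_bulk,
    )


def boltzmann_z_trajectory(
    n: int,
    n_frames: int,
    u_of_z,
    box=(30.0, 30.0, 60.0),
    seed: int = 0,
    species: str = "anion",
    temperature: float = 300.0,
) -> Trajectory:
    """Frames sampled exactly from p(z) ~ exp(-U(z)/kT), uniform in x, y.

    ``u_of_z`` takes z (A) and returns energy in kT. Used as the Boltzmann
    oracle for density-inversion analyses.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    nsamp = n * n_frames
    zs = np.empty(0)
    umin_ref = None
    while len(zs) < nsamp:
        cand = (rng.random(2 * nsamp) - 0.5) * box[2]
        u = np.asarray(u_of_z(cand), dtype=float)
        if umin_ref is None:
            umin_ref = u.min()
        acc = rng.random(len(cand)) < np.exp(-(u - umin_ref))
        zs = np.concatenate([zs, cand[acc]])
    zs = zs[:nsamp].reshape(n_frames, n)
    xy = (rng.random((n_frames, n, 2)) - 0.5) * box[:2]
    pos = np.concatenate([xy, zs[:, :, None]], axis=2)
    return Trajectory(
        times=np.arange(n_frames, dtype=float),
        ids=np.arange(n),
        species=np.full(n, species, dtype="U16"),
        positions=pos,
        box=box,
        temperature=temperature,
    )


def dipole_ensemble(
    n: int,
    n_frames: int,
    box=(30.0, 30.0, 60.0),
    alignment=0.0,
    seed: int = 0,
    temperature: float = 300.0,
) -> Trajectory:
    """Dipole carriers with cos(theta) Boltzmann-distributed in a z field.

    ``alignment`` is pE/kT, either a scalar or a callable of z; the
    stationary density of orientations is exp(alignment * cos theta), whose
    mean is the Langevin function L(alignment). alignment = 0 is isotropic.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    pos = (rng.random((n_frames, n, 3)) - 0.5) * box
    a = alignment(pos[:, :, 2]) if callable(alignment) else np.full((n_frames, n), float(alignment))
    u = rng.random((n_frames, n))
    with np.errstate(over="ignore"):
        cos = np.where(
            np.abs(a) < 1e-12,
            2.0 * u - 1.0,
            np.log(np.exp(-np.abs(a)) + u * (np.exp(np.abs(a)) - np.exp(-np.abs(a))))
            / np.where(np.abs(a) < 1e-12, 1.0, np.abs(a)),
        )
    cos = np.clip(np.sign(a + (np.abs(a) < 1e-12)) * cos, -1.0, 1.0)
    phi = 2.0 * np.pi * rng.random((n_frames, n))
    sin = np.sqrt(np.clip(1.0 - cos**2, 0.0, 1.0))
    dip = np.stack([sin * np.cos(phi), sin * np.sin(phi), cos], axis=-1)
    return Trajectory(
        times=np.arange(n_frames, dtype=float),
        ids=np.arange(n),
        species=np.full(n, "dipole", dtype="U16"),
        positions=pos,
        box=box,
        dipoles=dip,
        temperature=temperature,
    )


def toy_channel_structure(
    n_residues: int = 8,
    ring_radius: float = 11.0,
    nz_radius: float = 8.0,
    z_positions=(-5.0, 5.0),
):
    """A synthetic minimal channel structure for PB / residue-identification
    stages: rings of lysine-like residues whose side-chain NZ atoms line the
    pore lumen. Returns a Bio.PDB Structure (chain A, residues LYS).

    This is a synthetic stand-in geometry, not any deposited structure.
    """
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("toy")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    resid = 0
    for z in z_positions:
        for i in range(n_residues):
            resid += 1
            ang = 2.0 * np.pi * i / n_residues + (0.3 if z > 0 else 0.0)
            ca = np.array([ring_radius * np.cos(ang), ring_radius * np.sin(ang), z])
            nz = np.array([nz_radius * np.cos(ang), nz_radius * np.sin(ang), z])
            sb.init_residue("LYS", " ", resid, " ")
            sb.init_atom("N", ca + [0.0, 0.0, 1.2], 0.0, 1.0, " ", " N", element="N")
            sb.init_atom("CA", ca, 0.0, 1.0, " ", " CA", element="C")
            sb.init_atom("C", ca + [1.2, 0.0, 0.0], 0.0, 1.0, " ", " C", element="C")
            sb.init_atom("O", ca + [1.2, 0.0, 1.1], 0.0, 1.0, " ", " O", element="O")
            sb.init_atom("NZ", nz, 0.0, 1.0, " ", " NZ", element="N")
    return sb.get_structure()
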