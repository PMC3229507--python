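"""Concentration-based free-energy profiles in 1D and 3D.

The estimator inverts time-averaged ion densities::

    dG_i(z) = -RT ln( C_i(z) / C_bulk )

with C_i the local concentration of species i and C_bulk taken either from
a bulk slab of the same trajectory (default) or from the trajectory
metadata. Zero-count bins are masked, never clamped: the estimator reports
where it has no information instead of fabricating barrier heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MOLAR_TO_PER_A3, rt_kcal
from .errors import ConfigurationError, EmptyInputError, InvalidParameterError
from .grids import Grid3D
from .trajectory import Trajectory


@dataclass
class Profile1D:
    """Binned 1D profile along z: concentrations, free energies, counts."""

    z_centers: np.ndarray
    free_energy: np.ndarray          # kcal/mol, NaN on masked bins
    mask: np.ndarray                 # True where sampled
    counts: np.ndarray               # mean per-frame raw counts
    concentration: np.ndarray | None = None   # mol/L
    species: str = ""
    c_bulk: float | None = None
    temperature: float = 300.0
    meta: dict = field(default_factory=dict)

    def minimum(self) -> tuple[float, float]:
        """(z, dG) of the lowest valid free-energy bin."""
        vals = np.where(self.mask, self.free_energy, np.inf)
        i = int(np.argmin(vals))
        return float(self.z_centers[i]), float(self.free_energy[i])


def _resolve_rt(traj: Trajectory, temperature: float | None) -> tuple[float, float]:
    t = traj.temperature if temperature is None else temperature
    return t, rt_kcal(t)


def _bulk_concentration(
    traj: Trajectory, idx: np.ndarray, bulk_zmin: float
) -> float:
    lx, ly, lz = traj.box
    if bulk_zmin >= lz / 2.0:
        raise ConfigurationError(
            f"bulk region |z| > {bulk_zmin} A is empty for a box of Lz = {lz} A"
        )
    z = traj.z()[:, idx]
    n_bulk = float((np.abs(z) > bulk_zmin).sum()) / traj.n_frames
    v_bulk = lx * ly * (lz - 2.0 * bulk_zmin)
    return n_bulk / (v_bulk * MOLAR_TO_PER_A3)


def pmf_1d(
    traj: Trajectory,
    species: str,
    bin_width: float = 1.0,
    bulk_zmin: float = 25.0,
    lumen_radius: float | None = None,
    slab_half: float | None = None,
    c_bulk_source: str = "measured",
    temperature: float | None = None,
) -> Profile1D:
    """1D free-energy profile of one species along the pore axis.

    The analysis cross-section is the lumen cylinder (``lumen_radius``)
    for bins whose centers lie inside |z| < ``slab_half`` and the full box
    cross-section elsewhere; with ``lumen_radius=None`` the full box is
    used everywhere. ``c_bulk_source`` is ``measured`` (bulk slab
    |z| > bulk_zmin of this trajectory) or ``metadata``.
    """
    if traj.n_frames == 0:
        raise EmptyInputError("cannot compute a profile from an empty trajectory")
    idx = traj.species_index(species)
    if len(idx) == 0:
        raise EmptyInputError(f"trajectory holds no {species!r} particles")
    if bin_width <= 0:
        raise InvalidParameterError("bin width must be > 0")
    lx, ly, lz = traj.box
    if slab_half is not None and bulk_zmin < slab_half:
        raise ConfigurationError("bulk region overlaps the pore slab")
    t, rt = _resolve_rt(traj, temperature)

    n_bins = int(round(lz / bin_width))
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    z = traj.z()[:, idx]
    pos = traj.positions[:, idx, :]
    sel = np.ones(z.shape, dtype=bool)
    in_lumen_bin = np.zeros(n_bins, dtype=bool)
    if lumen_radius is not None:
        half = slab_half if slab_half is not None else np.inf
        in_lumen_bin = np.abs(centers) < half
        rho2 = pos[:, :, 0] ** 2 + pos[:, :, 1] ** 2
        in_slab = np.abs(z) < half
        sel = ~in_slab | (rho2 < lumen_radius**2)

    counts = np.histogram(z[sel], bins=edges)[0].astype(float) / traj.n_frames
    volumes = np.where(
        in_lumen_bin, np.pi * (lumen_radius or 1.0) ** 2 * bin_width, lx * ly * bin_width
    )
    conc = counts / (volumes * MOLAR_TO_PER_A3)

    if c_bulk_source == "metadata":
        if traj.c_bulk is None:
            raise ConfigurationError("trajectory metadata holds no c_bulk")
        c_bulk = float(traj.c_bulk)
    elif c_bulk_source == "measured":
        c_bulk = _bulk_concentration(traj, idx, bulk_zmin)
        if c_bulk <= 0:
            raise ConfigurationError("no particles found in the bulk region")
    else:
        raise ConfigurationError(f"unknown c_bulk_source {c_bulk_source!r}")

    mask = counts > 0
    dg = np.full(n_bins, np.nan)
    dg[mask] = -rt * np.log(conc[mask] / c_bulk)
    return Profile1D(
        z_centers=centers,
        free_energy=dg,
        mask=mask,
        counts=counts,
        concentration=conc,
        species=species,
        c_bulk=c_bulk,
        temperature=t,
        meta={"bin_width": bin_width, "bulk_zmin": bulk_zmin, "lumen_radius": lumen_radius},
    )


def pmf_3d(
    traj: Trajectory,
    species: str,
    origin,
    spacing: float,
    shape: tuple[int, int, int],
    c_bulk_source: str = "measured",
    bulk_zmin: float = 25.0,
    temperature: float | None = None,
) -> Grid3D:
    """Per-voxel free energy on a 3D grid; origin is the first voxel center.

    Voxels never visited are masked (no -inf/NaN leaks into valid values).
    """
    if traj.n_frames == 0:
        raise EmptyInputError("cannot compute a profile from an empty trajectory")
    idx = traj.species_index(species)
    if len(idx) == 0:
        raise EmptyInputError(f"trajectory holds no {species!r} particles")
    if spacing <= 0:
        raise InvalidParameterError("grid spacing must be > 0")
    origin = np.asarray(origin, dtype=float)
    t, rt = _resolve_rt(traj, temperature)

    edges = [
        origin[a] - spacing / 2.0 + spacing * np.arange(shape[a] + 1) for a in range(3)
    ]
    pos = traj.positions[:, idx, :].reshape(-1, 3)
    counts = np.histogramdd(pos, bins=edges)[0] / traj.n_frames
    conc = counts / (spacing**3 * MOLAR_TO_PER_A3)

    if c_bulk_source == "metadata":
        if traj.c_bulk is None:
            raise ConfigurationError("trajectory metadata holds no c_bulk")
        c_bulk = float(traj.c_bulk)
    else:
        c_bulk = _bulk_concentration(traj, idx, bulk_zmin)
        if c_bulk <= 0:
            raise ConfigurationError("no particles found in the bulk region")

    mask = counts > 0
    vals = np.full(shape, np.nan)
    vals[mask] = -rt * np.log(conc[mask] / c_bulk)
    return Grid3D(
        origin=origin,
        spacing=spacing,
        values=vals,
        mask=mask,
        meta={"species": species, "c_bulk": c_bulk, "temperature": t,
              "counts_per_frame": counts, "kind": "free_energy"},
    )


def reduce_3d_to_1d(
    grid: Grid3D, mode: str = "mean", temperature: float | None = None
) -> Profile1D:
    """Collapse a 3D energy grid to a z profile.

    ``mean``: arithmetic mean of valid voxels per z layer (the direct
    constant-z averaging procedure). ``boltzmann``: -RT ln< exp(-G/RT) >,
    which weights low-energy voxels the way an ion population does.
    Layers with no valid voxel are masked.
    """
    t = float(grid.meta.get("temperature", 300.0)) if temperature is None else temperature
    rt = rt_kcal(t)
    nz = grid.shape[2]
    out = np.full(nz, np.nan)
    mask = np.zeros(nz, dtype=bool)
    counts = np.zeros(nz)
    for k in range(nz):
        m = grid.mask[:, :, k]
        if not np.any(m):
            continue
        vals = grid.values[:, :, k][m]
        if mode == "mean":
            out[k] = vals.mean()
        elif mode == "boltzmann":
            out[k] = -rt * np.log(np.mean(np.exp(-vals / rt)))
        else:
            raise ConfigurationError(f"unknown reduction mode {mode!r}")
        mask[k] = True
        counts[k] = m.sum()
    return Profile1D(
        z_centers=grid.axis_coords(2),
        free_energy=out,
        mask=mask,
        counts=counts,
        species=str(grid.meta.get("species", "")),
        c_bulk=grid.meta.get("c_bulk"),
        temperature=t,
        meta={"mode": mode},
    )


# -- residue identification ------------------------------------------------

_BACKBONE = {"N", "O", "OXT"}


def _side_chain_no_atoms(structure):
    """(coords, labels) of side-chain N/O atoms of a Bio.PDB entity."""
    coords, labels = [], []
    for atom in structure.get_atoms():
        if atom.element not in ("N", "O"):
            continue
        if atom.get_name() in _BACKBONE:
            continue
        res = atom.get_parent()
        het, resseq, _ = res.get_id()
        if het.strip():
            continue
        chain = res.get_parent().get_id()
        coords.append(atom.get_coord())
        labels.append((chain, int(resseq), res.get_resname()))
    return np.asarray(coords, dtype=float), labels


@dataclass
class ResidueHit:
    """A residue whose side-chain N/O approaches a low-energy grid point."""

    chain: str
    resseq: int
    resname: str
    min_distance: float
    nearest_energy: float


def identify_low_energy_residues(
    grid: Grid3D,
    structure,
    window_fraction: float = 0.01,
    cutoff: float = 4.0,
    window_mode: str = "range",
) -> list[ResidueHit]:
    """Residues with side-chain N/O within ``cutoff`` of low-energy points.

    The low-energy point set contains valid grid points with values within
    ``window_fraction`` of the minimum: in ``range`` mode values
    <= G_min + f (G_max - G_min) (well defined for any sign of G), in
    ``abs_min`` mode <= G_min + f |G_min|. The distance comparison is a
    strict inequality. ``structure`` is a Bio.PDB entity or a PDB path.
    """
    import warnings as _w

    if isinstance(structure, (str, bytes)) or hasattr(structure, "__fspath__"):
        from Bio.PDB import PDBParser

        structure = PDBParser(QUIET=True).get_structure("s", structure)
    if not np.any(grid.mask):
        raise EmptyInputError("grid has no valid points")
    vals = grid.values[grid.mask]
    gmin, gmax = float(vals.min()), float(vals.max())
    if window_mode == "range":
        thresh = gmin + window_fraction * (gmax - gmin)
    elif window_mode == "abs_min":
        thresh = gmin + window_fraction * abs(gmin)
    else:
        raise ConfigurationError(f"unknown window_mode {window_mode!r}")
    pts = grid.points()[grid.mask.ravel()]
    low = vals <= thresh
    low_pts, low_vals = pts[low], vals[low]

    coords, labels = _side_chain_no_atoms(structure)
    if len(coords) == 0:
        _w.warn("structure has no side-chain N/O atoms; no residues selected")
        return []
    hits: dict[tuple, ResidueHit] = {}
    for xyz, lab in zip(coords, labels):
        d = np.linalg.norm(low_pts - xyz, axis=1)
        i = int(np.argmin(d))
        if lab not in hits or d[i] < hits[lab].min_distance:
            hits[lab] = ResidueHit(lab[0], lab[1], lab[2], float(d[i]), float(low_vals[i]))
    out = [h for h in hits.values() if h.min_distance < cutoff]
    out.sort(key=lambda h: (h.chain, h.resseq))
    return out
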