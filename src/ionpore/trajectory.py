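"""Trajectory data model and native columnar text I/O.

The native format (version 1) is a self-describing text file::

    # ionpore-trajectory 1
    # box 40.0000 40.0000 80.0000
    # temperature 300.0
    # c_bulk 1.0
    # diffusion anion 0.203
    # dipoles 0
    frame 0.0000
    <id> <species> <x> <y> <z> [<ux> <uy> <uz>]
    ...
    frame 0.5000
    ...

Positions are written with 4 decimals (lossless round trip to 1e-4 A),
dipole components with 6. Species tags are ``cation``, ``anion``,
``dipole`` (a dipole-carrier such as a water stand-in) and ``other``.
The pore axis is z with the membrane midplane at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, TrajectoryFormatError

FORMAT_VERSION = 1
SPECIES_TAGS = ("cation", "anion", "dipole", "other")


@dataclass
class PoreGeometry:
    """Pore slab along the z axis: z_lower < z < z_upper, optional lumen radius."""

    z_lower: float = -15.0
    z_upper: float = 15.0
    radius: float | None = None

    def __post_init__(self):
        if not self.z_lower < self.z_upper:
            raise InvalidParameterError("pore requires z_lower < z_upper")
        if self.radius is not None and self.radius <= 0:
            raise InvalidParameterError("pore lumen radius must be > 0")

    @property
    def width(self) -> float:
        return self.z_upper - self.z_lower


@dataclass
class Trajectory:
    """Time-ordered frames of typed particles in a periodic box.

    Attributes
    ----------
    times : (n_frames,) array, ps, strictly increasing
    ids : (n_particles,) int array, stable across frames
    species : (n_particles,) str array over SPECIES_TAGS
    positions : (n_frames, n_particles, 3) array, angstrom
    box : (3,) array, angstrom
    dipoles : optional (n_frames, n_particles, 3) array of unit vectors
        (NaN rows for particles that carry no dipole)
    temperature : K
    c_bulk : bulk salt concentration the system was set up at, mol/L (optional)
    diffusion : per-species diffusion coefficients, A^2/ps (optional)
    """

    times: np.ndarray
    ids: np.ndarray
    species: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    dipoles: np.ndarray | None = None
    temperature: float = 300.0
    c_bulk: float | None = None
    diffusion: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=int)
        self.species = np.asarray(self.species, dtype="U16")
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        nf, np_, _ = self.positions.shape if self.positions.ndim == 3 else (0, 0, 0)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryFormatError("positions must have shape (n_frames, n_particles, 3)")
        if self.times.shape != (nf,):
            raise TrajectoryFormatError("times length does not match frame count")
        if nf > 1 and not np.all(np.diff(self.times) > 0):
            bad = int(np.argmin(np.diff(self.times) > 0))
            raise TrajectoryFormatError(f"frame times not strictly increasing at frame {bad + 1}")
        if self.ids.shape != (np_,) or self.species.shape != (np_,):
            raise TrajectoryFormatError("ids/species length does not match particle count")
        if len(set(self.ids.tolist())) != np_:
            raise TrajectoryFormatError("particle ids must be unique")
        unknown = set(self.species.tolist()) - set(SPECIES_TAGS)
        if unknown:
            raise TrajectoryFormatError(f"unknown species tag(s): {sorted(unknown)}")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryFormatError("positions must be finite")
        if np.any(self.box <= 0):
            raise InvalidParameterError("box lengths must be > 0")
        if self.dipoles is not None:
            self.dipoles = np.asarray(self.dipoles, dtype=float)
            if self.dipoles.shape != self.positions.shape:
                raise TrajectoryFormatError("dipoles must match positions shape")
            norms = np.linalg.norm(self.dipoles, axis=-1)
            present = np.isfinite(norms)
            if np.any(np.abs(norms[present] - 1.0) > 1e-3):
                raise TrajectoryFormatError("dipole vectors must be unit-norm where present")

    # -- convenience ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def species_index(self, species: str) -> np.ndarray:
        """Indices of all particles of one species."""
        return np.nonzero(self.species == species)[0]

    def z(self) -> np.ndarray:
        """(n_frames, n_particles) z coordinates."""
        return self.positions[:, :, 2]


# -- native format I/O ----------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory in the native columnar text format (version 1)."""
    traj.validate()
    has_dip = traj.dipoles is not None
    with open(path, "w") as fh:
        fh.write(f"# ionpore-trajectory {FORMAT_VERSION}\n")
        fh.write("# box %.4f %.4f %.4f\n" % tuple(traj.box))
        fh.write(f"# temperature {float(traj.temperature)!r}\n")
        if traj.c_bulk is not None:
            fh.write(f"# c_bulk {float(traj.c_bulk)!r}\n")
        for sp, d in sorted(traj.diffusion.items()):
            fh.write(f"# diffusion {sp} {float(d)!r}\n")
        fh.write(f"# dipoles {int(has_dip)}\n")
        for f in range(traj.n_frames):
            fh.write("frame %.4f\n" % traj.times[f])
            for p in range(traj.n_particles):
                x, y, z = traj.positions[f, p]
                line = f"{traj.ids[p]} {traj.species[p]} {x:.4f} {y:.4f} {z:.4f}"
                if has_dip:
                    u = traj.dipoles[f, p]
                    line += " %.6f %.6f %.6f" % tuple(u)
                fh.write(line + "\n")


def read_trajectory(path, format: str = "native") -> Trajectory:
    """Read a trajectory file; ``format`` is ``native`` or an MDAnalysis tag.

    Non-native formats are delegated to :func:`from_mdanalysis` and require
    the optional MDAnalysis dependency.
    """
    if format != "native":
        import MDAnalysis as mda

        return from_mdanalysis(mda.Universe(path, format=format))
    header: dict = {"diffusion": {}}
    times: list[float] = []
    frames: list[list] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("# ionpore-trajectory"):
        raise TrajectoryFormatError(f"{path}: missing ionpore-trajectory header")
    i = 1
    while i < len(lines) and lines[i].startswith("#"):
        parts = lines[i][1:].split()
        key = parts[0]
        if key == "box":
            header["box"] = [float(v) for v in parts[1:4]]
        elif key == "temperature":
            header["temperature"] = float(parts[1])
        elif key == "c_bulk":
            header["c_bulk"] = float(parts[1])
        elif key == "diffusion":
            header["diffusion"][parts[1]] = float(parts[2])
        elif key == "dipoles":
            header["dipoles"] = bool(int(parts[1]))
        i += 1
    if "box" not in header:
        raise TrajectoryFormatError(f"{path}: header lacks box line")
    has_dip = header.get("dipoles", False)
    current: list | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.startswith("frame"):
            t = float(line.split()[1])
            if times and t <= times[-1]:
                raise TrajectoryFormatError(
                    f"{path}: frame time {t} at line {lineno + 1} not strictly increasing"
                )
            times.append(t)
            current = []
            frames.append(current)
        else:
            if current is None:
                raise TrajectoryFormatError(f"{path}: particle record before first frame at line {lineno + 1}")
            parts = line.split()
            nfield = 8 if has_dip else 5
            if len(parts) != nfield:
                raise TrajectoryFormatError(f"{path}: expected {nfield} fields at line {lineno + 1}")
            pid, sp = int(parts[0]), parts[1]
            if sp not in SPECIES_TAGS:
                raise TrajectoryFormatError(f"{path}: unknown species tag {sp!r} at line {lineno + 1}")
            rec = [pid, sp] + [float(v) for v in parts[2:]]
            current.append(rec)

    n_frames = len(times)
    if n_frames == 0:
        return Trajectory(
            times=np.zeros(0), ids=np.zeros(0, int), species=np.zeros(0, "U16"),
            positions=np.zeros((0, 0, 3)), box=np.asarray(header["box"]),
            dipoles=None, temperature=header.get("temperature", 300.0),
            c_bulk=header.get("c_bulk"), diffusion=header["diffusion"],
        )
    ref = [(r[0], r[1]) for r in frames[0]]
    order = {pid: k for k, (pid, _) in enumerate(ref)}
    n_particles = len(ref)
    positions = np.empty((n_frames, n_particles, 3))
    dipoles = np.full((n_frames, n_particles, 3), np.nan) if has_dip else None
    for f, recs in enumerate(frames):
        seen = [(r[0], r[1]) for r in recs]
        if sorted(pid for pid, _ in seen) != sorted(pid for pid, _ in ref):
            raise TrajectoryFormatError(f"{path}: particle id set differs in frame {f}")
        for r in recs:
            k = order[r[0]]
            positions[f, k] = r[2:5]
            if has_dip:
                dipoles[f, k] = r[5:8]
    return Trajectory(
        times=np.asarray(times),
        ids=np.asarray([pid for pid, _ in ref]),
        species=np.asarray([sp for _, sp in ref]),
        positions=positions,
        box=np.asarray(header["box"]),
        dipoles=dipoles,
        temperature=header.get("temperature", 300.0),
        c_bulk=header.get("c_bulk"),
        diffusion=header["diffusion"],
    )


def from_mdanalysis(universe) -> Trajectory:
    """Convenience adapter from an MDAnalysis Universe (ions only).

    Atoms named K/NA/CS map to ``cation``, CL/BR/I to ``anion``, everything
    else to ``other``. Never required by the analyses in this package.
    """
    cat = {"K", "NA", "CS", "K+", "NA+"}
    an = {"CL", "BR", "I", "CL-"}
    names = [a.name.upper() for a in universe.atoms]
    species = np.asarray(
        ["cation" if n in cat else "anion" if n in an else "other" for n in names]
    )
    times, positions = [], []
    for ts in universe.trajectory:
        times.append(float(ts.time))
        positions.append(universe.atoms.positions.copy())
    return Trajectory(
        times=np.asarray(times),
        ids=np.arange(len(names)),
        species=species,
        positions=np.asarray(positions, dtype=float),
        box=np.asarray(universe.dimensions[:3], dtype=float),
    )


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return delta - box * np.round(delta / box)
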