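"""Occupancy, translocation-event and ratio statistics for a pore slab.

Conventions (documented and fixed):

* the pore slab is the open interval z_lower < z < z_upper; points exactly
  on a boundary count as outside;
* a translocation event is one complete directed traversal of the slab,
  from beyond one boundary to beyond the other; retreats and incomplete
  re-entries produce no event;
* occupancy standard deviations use the population convention (divide by
  N frames), passage-time standard deviations the sample convention (N-1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, InvalidParameterError, SkipWarning
from .trajectory import PoreGeometry, Trajectory


@dataclass
class OccupancyStats:
    """Time-averaged particle count of one species inside the pore."""

    species: str
    mean: float
    std: float
    n_frames: int
    per_frame: np.ndarray | None = None


@dataclass
class TranslocationEvent:
    """One directed crossing of the pore slab by one particle."""

    particle_id: int
    species: str
    direction: str        # "up": z_lower -> z_upper, "down": reverse
    entry_time: float     # ps, last frame beyond the entry boundary
    exit_time: float      # ps, first frame beyond the far boundary

    @property
    def duration(self) -> float:
        return self.exit_time - self.entry_time


@dataclass
class Ratio:
    """A ratio with a definedness flag instead of a division crash.

    flag is "ok", "unbounded" (x/0 with x > 0) or "undefined" (0/0).
    """

    value: float
    flag: str = "ok"

    @property
    def defined(self) -> bool:
        return self.flag == "ok"


@dataclass
class PassageTimeStats:
    """Mean passage duration (ps); std is None when only one event exists."""

    species: str
    mean: float | None
    std: float | None
    n_events: int


def _inside(traj: Trajectory, pore: PoreGeometry) -> np.ndarray:
    """(n_frames, n_particles) mask of positions strictly inside the pore."""
    z = traj.z()
    mask = (z > pore.z_lower) & (z < pore.z_upper)
    if pore.radius is not None:
        rho2 = traj.positions[:, :, 0] ** 2 + traj.positions[:, :, 1] ** 2
        mask &= rho2 < pore.radius**2
    return mask


def count_occupancy(
    traj: Trajectory, pore: PoreGeometry, species: str, keep_per_frame: bool = False
) -> OccupancyStats:
    """Per-frame count of species particles inside the pore, mean and std."""
    if traj.n_frames == 0:
        raise EmptyInputError("cannot compute occupancy of an empty trajectory")
    idx = traj.species_index(species)
    counts = _inside(traj, pore)[:, idx].sum(axis=1).astype(float)
    return OccupancyStats(
        species=species,
        mean=float(counts.mean()),
        std=float(counts.std()),  # population convention
        n_frames=traj.n_frames,
        per_frame=counts if keep_per_frame else None,
    )


def detect_translocations(
    traj: Trajectory, pore: PoreGeometry, warn_skips: bool = True
) -> list[TranslocationEvent]:
    """Detect completed directed crossings of the pore slab.

    Jumps larger than half the box along z are treated as periodic wraps
    (the particle moved between reservoirs through the periodic boundary)
    and reset the crossing state without producing an event. Jumps larger
    than the slab width that are not wraps trigger a SkipWarning since the
    frame spacing then allows slab-skipping.
    """
    if traj.n_frames == 0:
        raise EmptyInputError("cannot detect translocations in an empty trajectory")
    z = traj.z()
    lz = traj.box[2]
    events: list[TranslocationEvent] = []
    warned = False
    # region: -1 below slab, 0 inside, +1 above
    region = np.where(z <= pore.z_lower, -1, np.where(z >= pore.z_upper, 1, 0))
    dz = np.abs(np.diff(z, axis=0))
    wrap = dz > lz / 2.0
    if warn_skips and np.any((dz > pore.width) & ~wrap) and not warned:
        warnings.warn(
            "per-step |dz| exceeds the slab width; crossings may be skipped",
            SkipWarning,
        )
        warned = True
    for p in range(traj.n_particles):
        side = int(region[0, p]) if region[0, p] != 0 else 0
        side_idx = 0
        for f in range(1, traj.n_frames):
            if wrap[f - 1, p]:
                side = int(region[f, p])
                side_idx = f
                continue
            r = int(region[f, p])
            if r == 0:
                continue
            if side == 0:
                side, side_idx = r, f
            elif r == side:
                side_idx = f
            else:
                events.append(
                    TranslocationEvent(
                        particle_id=int(traj.ids[p]),
                        species=str(traj.species[p]),
                        direction="up" if r == 1 else "down",
                        entry_time=float(traj.times[side_idx]),
                        exit_time=float(traj.times[f]),
                    )
                )
                side, side_idx = r, f
    events.sort(key=lambda e: (e.exit_time, e.particle_id))
    return events


def permeation_ratio(n_anion_events: int, n_cation_events: int) -> Ratio:
    """Anion translocation events / cation translocation events."""
    if n_anion_events < 0 or n_cation_events < 0:
        raise InvalidParameterError("event counts must be >= 0")
    if n_cation_events == 0:
        if n_anion_events == 0:
            return Ratio(math.nan, "undefined")
        return Ratio(math.inf, "unbounded")
    return Ratio(n_anion_events / n_cation_events)


def occupancy_ratio(anion: OccupancyStats, cation: OccupancyStats) -> Ratio:
    """Time-averaged anion count / cation count inside the pore."""
    if cation.mean == 0:
        if anion.mean == 0:
            return Ratio(math.nan, "undefined")
        return Ratio(math.inf, "unbounded")
    return Ratio(anion.mean / cation.mean)


def passage_time_stats(
    events: list[TranslocationEvent], species: str
) -> PassageTimeStats:
    """Mean +/- sample std of passage durations for one species."""
    durations = [e.duration for e in events if e.species == species]
    n = len(durations)
    if n == 0:
        return PassageTimeStats(species, None, None, 0)
    mean = float(np.mean(durations))
    std = float(np.std(durations, ddof=1)) if n > 1 else None
    return PassageTimeStats(species, mean, std, n)


def partition_coefficient(stats: OccupancyStats, c_bulk: float) -> float:
    """Pore occupancy relative to the bulk concentration, N_pore/[salt]."""
    if c_bulk <= 0:
        raise InvalidParameterError("bulk concentration must be > 0")
    return stats.mean / c_bulk
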