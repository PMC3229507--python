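"""Solution-structure analyses: RDFs, coordination numbers, contact /
solvent-separated ion-pair classification, pairing and solvation profiles
along the pore axis, and dipole-orientation profiles.

Distances use the minimum-image convention throughout. The default
cation-anion pair thresholds (contact pair up to 3.95 A, solvent-separated
pair up to 6.37 A) are the first/second RDF minima of a 1 M KCl solution;
``find_rdf_extrema`` derives thresholds from a user RDF instead. The
contact boundary is inclusive (d <= CIP max is a contact pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmax, argrelmin

from .errors import ConfigurationError, EmptyInputError, InvalidParameterError
from .trajectory import Trajectory, minimum_image


@dataclass
class RDFResult:
    """Radial distribution function and running coordination number."""

    r_centers: np.ndarray
    g: np.ndarray
    coordination: np.ndarray       # N(r), density-weighted running integral
    pair: tuple[str, str]
    density: float                 # neighbor-species number density (1/A^3)
    meta: dict = field(default_factory=dict)


@dataclass
class PairThresholds:
    """CIP/SSIP distance limits (A); defaults from a 1 M KCl solution RDF."""

    cip_max: float = 3.95
    ssip_max: float = 6.37

    def __post_init__(self):
        if not 0 < self.cip_max < self.ssip_max:
            raise InvalidParameterError("thresholds require 0 < CIP max < SSIP max")


DEFAULT_THRESHOLDS = PairThresholds()


def rdf(
    traj: Trajectory,
    pair: tuple[str, str],
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RDFResult:
    """Shell-histogram RDF between two species with ideal-gas normalization.

    ``r_max`` must not exceed half the smallest box length (minimum-image
    validity); it defaults to that limit.
    """
    if traj.n_frames == 0:
        raise EmptyInputError("cannot compute an RDF from an empty trajectory")
    half_min = float(min(traj.box)) / 2.0
    if r_max is None:
        r_max = half_min
    if r_max > half_min + 1e-9:
        raise ConfigurationError(
            f"r_max {r_max} exceeds half the smallest box length {half_min}"
        )
    sp_a, sp_b = pair
    ia = traj.species_index(sp_a)
    ib = traj.species_index(sp_b)
    if len(ia) == 0 or len(ib) == 0:
        raise EmptyInputError(f"trajectory lacks particles of pair {pair}")
    same = sp_a == sp_b
    box = traj.box
    volume = float(np.prod(box))
    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    hist = np.zeros(n_bins)
    for f in range(traj.n_frames):
        d = traj.positions[f, ia][:, None, :] - traj.positions[f, ib][None, :, :]
        d = minimum_image(d, box)
        r = np.sqrt((d**2).sum(axis=-1))
        if same:
            iu = np.triu_indices(len(ia), k=1)
            r = r[iu]
            r = np.concatenate([r, r])  # both orderings, as in the distinct case
        hist += np.histogram(r[r < r_max], bins=edges)[0]
    hist /= traj.n_frames

    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_b_eff = len(ib) - 1 if same else len(ib)
    rho_b = n_b_eff / volume
    g = hist / (len(ia) * rho_b * shell)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = len(ib) / volume if not same else (len(ib) - 1) / volume
    coordination = np.cumsum(hist) / len(ia)
    return RDFResult(
        r_centers=centers,
        g=g,
        coordination=coordination,
        pair=(sp_a, sp_b),
        density=density,
        meta={"bin_width": bin_width, "r_max": r_max,
              "n_a": len(ia), "n_b": len(ib)},
    )


@dataclass
class RDFExtrema:
    """Locations on the binned curve; fields are None when not found."""

    first_peak: float | None
    first_minimum: float | None
    second_minimum: float | None

    @property
    def found(self) -> bool:
        return self.first_peak is not None and self.first_minimum is not None


def find_rdf_extrema(result: RDFResult, smooth: bool = True) -> RDFExtrema:
    """First peak and the first/second minima of a binned g(r).

    Optionally applies a 3-point moving average before locating extrema;
    monotone curves yield a not-found result.
    """
    g = result.g
    if smooth and len(g) >= 3:
        g = np.convolve(g, np.ones(3) / 3.0, mode="same")
    maxima = argrelmax(g)[0]
    minima = argrelmin(g)[0]
    if len(maxima) == 0:
        return RDFExtrema(None, None, None)
    p1 = maxima[0]
    after_p1 = minima[minima > p1]
    if len(after_p1) == 0:
        return RDFExtrema(float(result.r_centers[p1]), None, None)
    m1 = after_p1[0]
    # second minimum: next minimum past the next peak
    later_peaks = maxima[maxima > m1]
    m2 = None
    if len(later_peaks):
        after_p2 = minima[minima > later_peaks[0]]
        if len(after_p2):
            m2 = after_p2[0]
    return RDFExtrema(
        float(result.r_centers[p1]),
        float(result.r_centers[m1]),
        float(result.r_centers[m2]) if m2 is not None else None,
    )


def thresholds_from_rdf(result: RDFResult, smooth: bool = True) -> PairThresholds:
    """PairThresholds from the first/second minima of a cation-anion RDF."""
    ext = find_rdf_extrema(result, smooth=smooth)
    if ext.first_minimum is None or ext.second_minimum is None:
        raise ConfigurationError("RDF lacks the two minima needed for thresholds")
    return PairThresholds(cip_max=ext.first_minimum, ssip_max=ext.second_minimum)


@dataclass
class PairClassification:
    """Per-cation partner counts for one frame."""

    n_cip: np.ndarray       # contact partners per cation
    n_ssip: np.ndarray      # solvent-separated partners per cation
    paired: np.ndarray      # bool, >= 1 partner of either class

    @property
    def n_paired(self) -> int:
        return int(self.paired.sum())

    @property
    def n_unpaired(self) -> int:
        return int((~self.paired).sum())


def classify_ion_pairs(
    cation_pos: np.ndarray,
    anion_pos: np.ndarray,
    box,
    thresholds: PairThresholds = DEFAULT_THRESHOLDS,
) -> PairClassification:
    """Label every cation-anion distance as CIP, SSIP or unpaired.

    A cation counts as paired when it has at least one partner within the
    SSIP limit (pairs are counted once per cation, not per partner).
    """
    cation_pos = np.atleast_2d(cation_pos)
    anion_pos = np.atleast_2d(anion_pos)
    box = np.asarray(box, dtype=float)
    if len(anion_pos) == 0 or anion_pos.size == 0:
        n = len(cation_pos)
        zero = np.zeros(n, dtype=int)
        return PairClassification(zero, zero.copy(), np.zeros(n, dtype=bool))
    d = cation_pos[:, None, :] - anion_pos[None, :, :]
    d = minimum_image(d, box)
    r = np.sqrt((d**2).sum(axis=-1))
    cip = r <= thresholds.cip_max
    ssip = (r > thresholds.cip_max) & (r <= thresholds.ssip_max)
    n_cip = cip.sum(axis=1).astype(int)
    n_ssip = ssip.sum(axis=1).astype(int)
    return PairClassification(n_cip, n_ssip, (n_cip + n_ssip) > 0)


@dataclass
class ZProfile:
    """A per-z-bin time-averaged quantity."""

    z_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray         # denominator per bin (frame-particle samples)
    meta: dict = field(default_factory=dict)


def _z_edges(box, bin_width: float) -> np.ndarray:
    lz = float(box[2])
    n_bins = int(round(lz / bin_width))
    return np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)


def pairing_profile(
    traj: Trajectory,
    thresholds: PairThresholds = DEFAULT_THRESHOLDS,
    bin_width: float = 2.0,
) -> ZProfile:
    """Paired-cation fraction (and count) per z bin, time averaged."""
    ic = traj.species_index("cation")
    ia = traj.species_index("anion")
    edges = _z_edges(traj.box, bin_width)
    n_bins = len(edges) - 1
    paired_sum = np.zeros(n_bins)
    total = np.zeros(n_bins)
    for f in range(traj.n_frames):
        cl = classify_ion_pairs(
            traj.positions[f, ic], traj.positions[f, ia], traj.box, thresholds
        )
        z = traj.positions[f, ic, 2]
        idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
        np.add.at(total, idx, 1.0)
        np.add.at(paired_sum, idx, cl.paired.astype(float))
    frac = np.divide(paired_sum, total, out=np.zeros(n_bins), where=total > 0)
    return ZProfile(
        z_centers=0.5 * (edges[:-1] + edges[1:]),
        values=frac,
        counts=total,
        meta={"paired_per_frame": paired_sum / traj.n_frames, "bin_width": bin_width},
    )


def solvation_count(
    traj: Trajectory,
    center_species: str,
    neighbor_species: str,
    cutoff: float,
    bin_width: float = 2.0,
) -> ZProfile:
    """Mean neighbor count within ``cutoff`` per z bin of the center species."""
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be > 0")
    ic = traj.species_index(center_species)
    inb = traj.species_index(neighbor_species)
    edges = _z_edges(traj.box, bin_width)
    n_bins = len(edges) - 1
    acc = np.zeros(n_bins)
    total = np.zeros(n_bins)
    same = center_species == neighbor_species
    for f in range(traj.n_frames):
        z = traj.positions[f, ic, 2]
        idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
        if len(inb):
            d = traj.positions[f, ic][:, None, :] - traj.positions[f, inb][None, :, :]
            d = minimum_image(d, traj.box)
            r2 = (d**2).sum(axis=-1)
            counts = (r2 < cutoff**2).sum(axis=1).astype(float)
            if same:
                counts -= 1.0  # self distance
        else:
            counts = np.zeros(len(ic))
        np.add.at(total, idx, 1.0)
        np.add.at(acc, idx, counts)
    mean = np.divide(acc, total, out=np.zeros(n_bins), where=total > 0)
    return ZProfile(
        z_centers=0.5 * (edges[:-1] + edges[1:]),
        values=mean,
        counts=total,
        meta={"cutoff": cutoff, "bin_width": bin_width},
    )


@dataclass
class DipoleProfile:
    """Mean cos(theta) against +z per bin, plus per-bin orientation histograms."""

    z_centers: np.ndarray
    mean_cos: np.ndarray
    counts: np.ndarray
    cos_edges: np.ndarray
    histograms: np.ndarray      # (n_z_bins, n_cos_bins), row-normalized


def dipole_orientation_profile(
    traj: Trajectory, bin_width: float = 2.0, n_cos_bins: int = 20
) -> DipoleProfile:
    """Orientation statistics of dipole carriers along the pore axis."""
    idx = traj.species_index("dipole")
    if traj.dipoles is None or len(idx) == 0:
        raise EmptyInputError("trajectory carries no dipole vectors")
    edges = _z_edges(traj.box, bin_width)
    n_bins = len(edges) - 1
    cos_edges = np.linspace(-1.0, 1.0, n_cos_bins + 1)
    z = traj.positions[:, idx, 2].ravel()
    cos = traj.dipoles[:, idx, 2].ravel()
    ok = np.isfinite(cos)
    z, cos = z[ok], cos[ok]
    bins = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    sums = np.zeros(n_bins)
    total = np.zeros(n_bins)
    np.add.at(sums, bins, cos)
    np.add.at(total, bins, 1.0)
    hist = np.zeros((n_bins, n_cos_bins))
    for b in range(n_bins):
        sel = bins == b
        if np.any(sel):
            h = np.histogram(cos[sel], bins=cos_edges)[0].astype(float)
            hist[b] = h / h.sum()
    mean = np.divide(sums, total, out=np.zeros(n_bins), where=total > 0)
    return DipoleProfile(
        z_centers=0.5 * (edges[:-1] + edges[1:]),
        mean_cos=mean,
        counts=total,
        cos_edges=cos_edges,
        histograms=hist,
    )


def langevin(x):
    """Langevin function L(x) = coth(x) - 1/x (mean cos theta at pE/kT = x)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    xs = np.where(small, 1.0, x)
    out = 1.0 / np.tanh(xs) - 1.0 / xs
    return np.where(small, x / 3.0, out)
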