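"""Closed-form reversal-potential models for a symmetric monovalent salt.

Sign convention: potentials are reported in mV for the cis compartment
relative to the grounded trans compartment. Anion preference
(P_A > P_C) with trans concentration above cis gives a negative reversal
potential (anion-selective channel).

GHK (constant-field) model::

    E = (RT/F) ln[ (P_C C_trans + P_A C_cis) / (P_C C_cis + P_A C_trans) ]

Planck (constrained liquid-junction, electroneutral) model::

    E = (RT/F) (D_C - D_A)/(D_C + D_A) ln(C_trans / C_cis)

Both depend only on the concentration ratio, never on the ionic strength
at fixed ratio: a charged pore whose measured reversal potential varies
with ionic strength at constant ratio is therefore not behaving as the
neutral channel these models describe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import rt_over_f_mv
from .errors import ConfigurationError, InvalidParameterError


@dataclass
class SolutionPair:
    """Salt concentrations (mol/L) of the trans and cis compartments."""

    c_trans: float
    c_cis: float

    def __post_init__(self):
        if self.c_trans <= 0 or self.c_cis <= 0:
            raise InvalidParameterError("compartment concentrations must be > 0")

    @property
    def ratio(self) -> float:
        return self.c_trans / self.c_cis


@dataclass
class TransportParams:
    """Named permeabilities and diffusion coefficients.

    Permeabilities are stored by ion, never as a bare ratio, so no
    orientation ambiguity (anion/cation vs cation/anion) can creep in.
    Units cancel inside each model; only the ratios matter.
    """

    p_cation: float = 1.0
    p_anion: float = 1.0
    d_cation: float = 1.0
    d_anion: float = 1.0
    temperature: float = 298.15

    def __post_init__(self):
        for name in ("p_cation", "p_anion", "d_cation", "d_anion", "temperature"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def alpha_anion_over_cation(self) -> float:
        return self.p_anion / self.p_cation


def ghk_reversal(params: TransportParams, solutions: SolutionPair) -> float:
    """GHK reversal potential in mV (cis relative to grounded trans)."""
    num = params.p_cation * solutions.c_trans + params.p_anion * solutions.c_cis
    den = params.p_cation * solutions.c_cis + params.p_anion * solutions.c_trans
    return rt_over_f_mv(params.temperature) * math.log(num / den)


def planck_reversal(params: TransportParams, solutions: SolutionPair) -> float:
    """Planck (constrained liquid-junction) potential in mV."""
    dsum = params.d_cation + params.d_anion
    factor = (params.d_cation - params.d_anion) / dsum
    return rt_over_f_mv(params.temperature) * factor * math.log(solutions.ratio)


def invert_ghk(
    potential_mv: float, solutions: SolutionPair, temperature: float = 298.15
) -> float:
    """Permeability ratio P_anion/P_cation solving the GHK equation.

    The potential must lie strictly inside the attainable band
    (+/- (RT/F) ln ratio); outside it no positive ratio exists.
    """
    rtf = rt_over_f_mv(temperature)
    x = math.exp(potential_mv / rtf)
    ct, cc = solutions.c_trans, solutions.c_cis
    # E = rtf ln[(Pc ct + Pa cc)/(Pc cc + Pa ct)] with alpha = Pa/Pc:
    # ct + alpha cc = x (cc + alpha ct)  =>  alpha = (ct - x cc)/(x ct - cc)
    num = ct - x * cc
    den = x * ct - cc
    if num <= 0 or den <= 0:
        bound = rtf * abs(math.log(solutions.ratio))
        raise InvalidParameterError(
            f"potential {potential_mv:.3f} mV outside the attainable GHK band "
            f"(+/-{bound:.3f} mV) for concentration ratio {solutions.ratio:.3f}"
        )
    return num / den


def ionic_strength_scan(
    model: str,
    params: TransportParams,
    ratio: float,
    trans_concentrations,
) -> list[float]:
    """Model reversal potentials over trans concentrations at fixed ratio.

    ``model`` is ``ghk`` or ``planck``; cis = trans / ratio for every entry.
    """
    if ratio <= 0:
        raise ConfigurationError("concentration ratio must be > 0")
    fn = {"ghk": ghk_reversal, "planck": planck_reversal}.get(model)
    if fn is None:
        raise ConfigurationError(f"unknown model tag {model!r}")
    out = []
    for ct in trans_concentrations:
        pair = SolutionPair(c_trans=float(ct), c_cis=float(ct) / ratio)
        if abs(pair.ratio - ratio) > 1e-9 * ratio:
            raise ConfigurationError("inconsistent concentration ratio in scan")
        out.append(fn(params, pair))
    return out
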