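"""State, rate laws and ODE right-hand side of the HSR network.

The network senses heat through Arrhenius-law denaturation of functional
protein P into the misfolded form P#.  Misfolded protein activates a stress
kinase (SK -> SK*) through Hill kinetics; SK* phosphorylates the heat shock
factor (HSF -> HSF*) with Michaelis-Menten kinetics.  Both HSF forms bind the
generic heat-shock gene locus G, but only the HSF*-bound locus transcribes the
two mRNAs (for HSF itself and for the heat shock protein HP); the HSF-bound
locus blocks transcription.  HP refolds P# back to P, closing the loop.  All
remaining steps follow mass action kinetics.

Three moiety pools are conserved exactly: P + P#, SK + SK*, and
G + HSF*G + HSFG.  The HSF pool is open (synthesis and first-order decay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .params import GAS_CONSTANT, RateParameters

#: Species names, fixing the layout of state vectors throughout the package.
SPECIES: tuple[str, ...] = (
    "P", "Pm", "SK", "SKa", "F", "Fa", "G", "FG", "FaG", "mF", "mH", "H",
)
N_SPECIES = len(SPECIES)
_IDX = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class HSRState:
    """Concentrations of the 12 dynamic species (mM).

    P / Pm: functional and misfolded protein; SK / SKa: inactive and active
    stress kinase; F / Fa: unphosphorylated and phosphorylated HSF;
    G / FG / FaG: free gene locus, locus bound by inactive HSF, locus bound
    by active HSF*; mF / mH: mRNA of HSF and of HP; H: heat shock protein.
    """

    P: float
    Pm: float
    SK: float
    SKa: float
    F: float
    Fa: float
    G: float
    FG: float
    FaG: float
    mF: float
    mH: float
    H: float

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"species {name} must be non-negative, "
                                 f"got {getattr(self, name)!r}")
        for label, total in (("P + Pm", self.P + self.Pm),
                             ("SK + SKa", self.SK + self.SKa),
                             ("G + FG + FaG", self.G + self.FG + self.FaG)):
            if not total > 0:
                raise ValueError(f"conserved pool {label} must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "HSRState":
        return cls(**{name: float(y[i]) for i, name in enumerate(SPECIES)})

    @property
    def misfolded_fraction(self) -> float:
        return self.Pm / (self.P + self.Pm)

    @property
    def active_kinase_fraction(self) -> float:
        return self.SKa / (self.SK + self.SKa)


class RateVector(NamedTuple):
    """One non-negative flux per reaction (mM s^-1)."""

    denaturation: float        # v'_P : P  -> P#,  Arrhenius in T
    refolding: float           # v_P  : P# -> P,   chaperone-assisted
    sk_activation: float       # SK  -> SK*, Hill in P#
    sk_deactivation: float     # SK* -> SK
    phosphorylation: float     # v'_F : F -> F*, Michaelis-Menten in F, by SK*
    dephosphorylation: float   # v_F  : F* -> F
    fag_binding: float         # F* + G -> F*G
    fag_unbinding: float       # F*G -> F* + G
    fg_binding: float          # F + G -> FG
    fg_unbinding: float        # FG -> F + G
    transcription_mF: float    # F*G -> F*G + mF
    transcription_mH: float    # F*G -> F*G + mH
    translation_F: float       # mF -> mF + F
    translation_H: float       # mH -> mH + H
    degradation_mF: float
    degradation_mH: float
    degradation_F: float
    degradation_H: float


def arrhenius_factor(T: float, params: RateParameters) -> float:
    """Temperature-dependent denaturation rate ω_TP(T) in s^-1.

    Uses the reference-anchored form
    ``k_TP * exp(-(E_A/R) * (1/T - 1/T_ref))``, so ``k_TP`` is the
    denaturation rate at ``T_ref`` and the factor increases monotonically
    with temperature.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError(f"temperature must be positive (K), got {T}")
    out = params.k_TP * np.exp(-(params.E_A / GAS_CONSTANT)
                               * (1.0 / T - 1.0 / params.T_ref))
    return float(out) if out.ndim == 0 else out


def hill_activation(Pm: float, params: RateParameters) -> float:
    """Hill activation ω_PS = Pm^m / (P0^m + Pm^m), in [0, 1)."""
    Pm = np.asarray(Pm, dtype=float)
    if np.any(Pm < 0):
        raise ValueError(f"misfolded protein concentration must be >= 0, got {Pm}")
    num = Pm ** params.m
    out = num / (params.P0 ** params.m + num)
    return float(out) if out.ndim == 0 else out


def phosphorylation_rate(SKa: float, F: float, params: RateParameters) -> float:
    """Michaelis-Menten HSF phosphorylation flux ν'_F = kp_F·SK*·F/(K_F+F)."""
    if SKa < 0 or F < 0:
        raise ValueError(f"concentrations must be >= 0, got SKa={SKa}, F={F}")
    return params.kp_F * SKa * F / (params.K_F + F)


def reaction_rates(state: HSRState, T: float,
                   params: RateParameters) -> RateVector:
    """Evaluate every reaction flux at the given state and temperature."""
    return RateVector(*_fluxes(state.to_array(), T, params))


def _fluxes(y, T: float, p: RateParameters):
    """Flux tuple from a raw state array; shared by rhs and reaction_rates."""
    P, Pm, SK, SKa, F, Fa, G, FG, FaG, mF, mH, H = y
    omega_TP = p.k_TP * math.exp(-(p.E_A / GAS_CONSTANT)
                                 * (1.0 / T - 1.0 / p.T_ref))
    pm_m = Pm ** p.m if Pm > 0 else 0.0
    omega_PS = pm_m / (p.P0 ** p.m + pm_m)
    return (
        omega_TP * P,                     # denaturation
        p.k_P * H * Pm,                   # refolding
        p.k_S * omega_PS * SK,            # sk_activation
        p.kp_S * SKa,                     # sk_deactivation
        p.kp_F * SKa * F / (p.K_F + F),   # phosphorylation
        p.k_F * Fa,                       # dephosphorylation
        p.k_FaG * Fa * G,                 # fag_binding
        p.kp_FaG * FaG,                   # fag_unbinding
        p.k_FG * F * G,                   # fg_binding
        p.kp_FG * FG,                     # fg_unbinding
        p.pi_mF * FaG,                    # transcription_mF
        p.pi_mH * FaG,                    # transcription_mH
        p.pi_F * mF,                      # translation_F
        p.pi_H * mH,                      # translation_H
        p.eta_mF * mF,                    # degradation_mF
        p.eta_mH * mH,                    # degradation_mH
        p.eta_F * F,                      # degradation_F
        p.eta_H * H,                      # degradation_H
    )


def rhs_array(t: float, y: np.ndarray, params: RateParameters,
              temperature_of_t) -> np.ndarray:
    """ODE right-hand side on a raw state array.

    ``temperature_of_t`` maps time (s) to temperature (K).  The stoichiometry
    cancels exactly over each conserved pool: dP+dPm, dSK+dSKa and
    dG+dFG+dFaG are identically zero.
    """
    (v_den, v_ref, v_act, v_dea, v_pho, v_dep, v_abind, v_aunb,
     v_ibind, v_iunb, tr_mF, tr_mH, tl_F, tl_H,
     dg_mF, dg_mH, dg_F, dg_H) = _fluxes(y, temperature_of_t(t), params)
    d_fg = v_ibind - v_iunb
    d_fag = v_abind - v_aunb
    return np.array([
        -v_den + v_ref,                                   # P
        v_den - v_ref,                                    # Pm
        -v_act + v_dea,                                   # SK
        v_act - v_dea,                                    # SKa
        -v_pho + v_dep - v_ibind + v_iunb + tl_F - dg_F,  # F
        v_pho - v_dep - v_abind + v_aunb,                 # Fa
        -(d_fg + d_fag),                                  # G (exact pool closure)
        d_fg,                                             # FG
        d_fag,                                            # FaG
        tr_mF - dg_mF,                                    # mF
        tr_mH - dg_mH,                                    # mH
        tl_H - dg_H,                                      # H
    ])


def rhs(t: float, state: HSRState, protocol,
        params: RateParameters) -> np.ndarray:
    """Time derivative of the state under a temperature protocol.

    Returns the derivative as an array in :data:`SPECIES` order.
    """
    return rhs_array(t, state.to_array(), params, protocol.temperature_at)


def species_index(name: str) -> int:
    """Position of a species name in the state vector."""
    return _IDX[name]
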