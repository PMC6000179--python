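"""Rate parameters of the heat shock response network.

Concentrations are expressed in mM (the three conserved pools — protein,
stress kinase and gene — are normalized to 1 mM each by default), time in
seconds and temperature in Kelvin internally.  The mRNA and heat-shock-protein
species are carried in the same nominal mM units; their absolute scale is
arbitrary because all comparisons with data are made on max-normalized curves.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1

#: The kinetic rate constants explored by the calibration machinery.  The
#: regulatory/thermodynamic parameters (m, P0, E_A, T_ref) and the conserved
#: pool totals are held fixed by default.
KINETIC_CONSTANTS: tuple[str, ...] = (
    "k_TP", "k_P", "k_S", "kp_S", "kp_F", "K_F", "k_F",
    "k_FaG", "kp_FaG", "k_FG", "kp_FG",
    "pi_mF", "pi_mH", "pi_F", "pi_H",
    "eta_mF", "eta_mH", "eta_F", "eta_H",
)


@dataclass(frozen=True)
class RateParameters:
    """All rate constants and regulatory parameters of the HSR model.

    Attributes
    ----------
    k_TP:
        Protein denaturation rate at the reference temperature (s^-1).
    E_A:
        Arrhenius activation energy of denaturation (J mol^-1).
    T_ref:
        Reference temperature anchoring the Arrhenius law (K).
    k_P:
        Chaperone-mediated refolding rate constant (mM^-1 s^-1).
    k_S, kp_S:
        Stress-kinase activation / deactivation rate constants (s^-1).
    m, P0:
        Hill coefficient (dimensionless) and half-activation threshold (mM)
        of kinase activation by misfolded protein.
    kp_F, K_F:
        Catalytic constant (s^-1) and Michaelis constant (mM) of HSF
        phosphorylation by the active kinase.
    k_F:
        HSF* dephosphorylation rate constant (s^-1).
    k_FaG, kp_FaG:
        Association (mM^-1 s^-1) / dissociation (s^-1) of active HSF* with
        the gene locus.
    k_FG, kp_FG:
        Association / dissociation of inactive HSF with the gene locus.
    pi_mF, pi_mH:
        Transcription rate constants from the HSF*-bound gene (s^-1).
    pi_F, pi_H:
        Translation rate constants (s^-1).
    eta_mF, eta_mH, eta_F, eta_H:
        First-order degradation rate constants (s^-1).
    total_P, total_SK, total_G:
        Conserved pool totals (mM); configuration, not kinetics.
    """

    k_TP: float
    E_A: float
    T_ref: float
    k_P: float
    k_S: float
    kp_S: float
    m: float
    P0: float
    kp_F: float
    K_F: float
    k_F: float
    k_FaG: float
    kp_FaG: float
    k_FG: float
    kp_FG: float
    pi_mF: float
    pi_mH: float
    pi_F: float
    pi_H: float
    eta_mF: float
    eta_mH: float
    eta_F: float
    eta_H: float
    total_P: float = 1.0
    total_SK: float = 1.0
    total_G: float = 1.0

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not (value > 0):
                raise ValueError(f"parameter {field.name} must be strictly "
                                 f"positive, got {value!r}")
        if self.m < 1:
            raise ValueError(f"Hill coefficient m must be >= 1, got {self.m}")
        if not (270.0 <= self.T_ref <= 330.0):
            raise ValueError(f"T_ref must lie in [270, 330] K, got {self.T_ref}")

    def replace(self, **changes: float) -> "RateParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def scaled(self, **factors: float) -> "RateParameters":
        """Return a copy with the named parameters multiplied by factors."""
        changes = {name: getattr(self, name) * f for name, f in factors.items()}
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


_FIELD_NAMES = tuple(f.name for f in dataclasses.fields(RateParameters))


def load_parameters(path: str | Path) -> RateParameters:
    """Read a flat ``key = value`` parameter file.

    Lines starting with ``#`` and inline ``#`` comments are ignored.  The
    file must define every parameter exactly once; unknown keys are an error.
    """
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, rhs = line.partition("=")
        key = key.strip()
        if key not in _FIELD_NAMES:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key in values:
            raise ValueError(f"{path}:{lineno}: duplicate parameter {key!r}")
        values[key] = float(rhs.strip())
    missing = [n for n in _FIELD_NAMES
               if n not in values and n not in ("total_P", "total_SK", "total_G")]
    if missing:
        raise ValueError(f"{path}: missing parameters: {', '.join(missing)}")
    return RateParameters(**values)


def save_parameters(params: RateParameters, path: str | Path,
                    header: str = "") -> None:
    """Write a parameter file readable by :func:`load_parameters`."""
    lines = []
    if header:
        lines.extend(f"# {line}" for line in header.splitlines())
    for name in _FIELD_NAMES:
        lines.append(f"{name} = {getattr(params, name)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _bundled(name: str) -> RateParameters:
    ref = importlib.resources.files("hsrsim.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return load_parameters(path)


def final_parameters() -> RateParameters:
    """The calibrated parameter set used for all simulation experiments."""
    return _bundled("final.txt")


def fiducial_parameters() -> RateParameters:
    """The manually tuned starting point of the calibration."""
    return _bundled("fiducial.txt")
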