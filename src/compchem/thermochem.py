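"""Ideal-gas rigid-rotor harmonic-oscillator (RRHO) thermochemistry.

Given an optimized geometry and harmonic vibrational wavenumbers — for
example the finalization blocks of a two-job (geometry optimization +
frequency analysis) CompChem document — this module computes the standard
statistical-mechanics gas-phase properties:

* translational: Sackur-Tetrode entropy, Cv = 3/2 R, H contribution
  5/2 RT (the ideal-gas PV = RT term is booked under translation);
* rotational: classical rigid rotor divided by the external symmetry
  number sigma; linear molecules use the single-moment formula;
* vibrational: an independent harmonic oscillator per mode, with
  vibrational temperature theta = h c nu / k; by default H - H(0) is
  referenced to the ground vibrational state (zero-point energy excluded;
  ``include_zpe=True`` adds R * theta / 2 per mode);
* electronic: R ln g entropy only, for a degeneracy-g ground state.

Cp = Cv + R holds identically (ideal gas). Physical constants are CODATA
values taken from :mod:`scipy.constants`; atomic masses are standard
atomic weights from a bundled table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import constants as const

from .model import COMPCHEM_DICT_NS, CompChemDocument, SemanticError

__all__ = [
    "R_GAS",
    "ATOMIC_MASSES",
    "atomic_mass",
    "classify_linearity",
    "ThermoInput",
    "MotionContribution",
    "ThermoResult",
    "compute_thermo",
    "thermo_from_document",
    "UnsupportedDocumentError",
]

R_GAS = const.R  # J mol^-1 K^-1
_KB = const.k
_H = const.h
_C_CM = const.c * 100.0  # speed of light in cm s^-1
_AMU = const.atomic_mass
_NA = const.N_A

#: Standard atomic weights (amu), most-abundant-isotope-weighted.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.0983,
    "Ca": 40.078, "Sc": 44.955908, "Ti": 47.867, "V": 50.9415, "Cr": 51.9961,
    "Mn": 54.938044, "Fe": 55.845, "Co": 58.933194, "Ni": 58.6934,
    "Cu": 63.546, "Zn": 65.38, "Br": 79.904, "I": 126.90447,
}


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise SemanticError(f"no atomic mass tabulated for element {element!r}") from None


class UnsupportedDocumentError(ValueError):
    """The document lacks the data the RRHO treatment needs."""


# ---------------------------------------------------------------------------
# Geometry classification

#: A principal moment below this (amu Angstrom^2) is treated as zero.
LINEARITY_TOLERANCE = 1e-10


def principal_moments(masses, coordinates) -> np.ndarray:
    """Principal moments of inertia in amu Angstrom^2, ascending."""
    m = np.asarray(masses, float)
    x = np.asarray(coordinates, float).reshape(len(m), 3)
    x = x - np.average(x, axis=0, weights=m)
    tensor = np.zeros((3, 3))
    for mi, ri in zip(m, x):
        tensor += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    return np.sort(np.linalg.eigvalsh(tensor))


def classify_linearity(masses, coordinates) -> str:
    """Classify a geometry as ``atom``, ``linear`` or ``nonlinear`` from its
    principal moments of inertia."""
    if len(np.atleast_1d(masses)) == 1:
        return "atom"
    moments = principal_moments(masses, coordinates)
    if moments[-1] < LINEARITY_TOLERANCE:
        return "atom"
    if moments[0] < LINEARITY_TOLERANCE:
        return "linear"
    return "nonlinear"


# ---------------------------------------------------------------------------
# Inputs and results

@dataclass
class ThermoInput:
    """Masses in amu, coordinates in Angstrom, frequencies in cm^-1;
    temperature in K, pressure in Pa; sigma is the external rotational
    symmetry number and g the electronic ground-state degeneracy."""

    masses: np.ndarray
    coordinates: np.ndarray
    frequencies: np.ndarray
    temperature: float = 298.15
    pressure: float = 101325.0
    sigma: int = 1
    degeneracy: int = 1
    include_zpe: bool = False

    def __post_init__(self):
        self.masses = np.asarray(self.masses, float)
        self.coordinates = np.asarray(self.coordinates, float).reshape(
            len(self.masses), 3
        )
        self.frequencies = np.asarray(self.frequencies, float)
        if self.temperature <= 0 or self.pressure <= 0:
            raise SemanticError("temperature and pressure must be positive")
        if self.sigma < 1 or self.degeneracy < 1:
            raise SemanticError("sigma and degeneracy must be positive integers")
        bad = np.nonzero(self.frequencies <= 0)[0]
        if bad.size:
            raise SemanticError(
                f"non-positive frequency at mode index {int(bad[0])}; imaginary "
                "modes (transition states) are out of scope"
            )
        shape = self.shape
        if shape != "atom":
            n = len(self.masses)
            expected = 3 * n - (5 if shape == "linear" else 6)
            if len(self.frequencies) != max(0, expected):
                raise SemanticError(
                    f"{shape} molecule with {n} atoms needs {expected} "
                    f"frequencies, got {len(self.frequencies)}"
                )
        elif len(self.frequencies):
            raise SemanticError("an atom has no vibrational modes")

    @property
    def shape(self) -> str:
        return classify_linearity(self.masses, self.coordinates)


@dataclass
class MotionContribution:
    """One motion's share: S and Cv/Cp in J mol^-1 K^-1, H in kJ mol^-1."""

    S: float = 0.0
    H: float = 0.0
    Cv: float = 0.0
    Cp: float = 0.0


@dataclass
class ThermoResult:
    temperature: float
    pressure: float
    S: float
    H: float
    Cv: float
    Cp: float
    by_motion: dict[str, MotionContribution] = field(default_factory=dict)
    mode_S: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mode_Cv: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mode_H: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# Contributions

def translational(mass_amu: float, T: float, P: float) -> MotionContribution:
    """Sackur-Tetrode translation for one mole of ideal gas."""
    m = mass_amu * _AMU
    q = (2.0 * math.pi * m * _KB * T / _H**2) ** 1.5 * (_KB * T / P)
    S = R_GAS * (math.log(q) + 2.5)
    return MotionContribution(
        S=S, H=2.5 * R_GAS * T / 1000.0, Cv=1.5 * R_GAS, Cp=2.5 * R_GAS
    )


def rotational(
    masses, coordinates, T: float, sigma: int
) -> MotionContribution:
    shape = classify_linearity(masses, coordinates)
    if shape == "atom":
        return MotionContribution()
    moments = principal_moments(masses, coordinates) * _AMU * 1e-20  # kg m^2
    if shape == "linear":
        theta = _H**2 / (8.0 * math.pi**2 * _KB * moments[-1])
        q = T / (sigma * theta)
        return MotionContribution(
            S=R_GAS * (math.log(q) + 1.0),
            H=R_GAS * T / 1000.0,
            Cv=R_GAS,
            Cp=R_GAS,
        )
    thetas = _H**2 / (8.0 * math.pi**2 * _KB * moments)
    q = math.sqrt(math.pi) / sigma * math.sqrt(T**3 / np.prod(thetas))
    return MotionContribution(
        S=R_GAS * (math.log(q) + 1.5),
        H=1.5 * R_GAS * T / 1000.0,
        Cv=1.5 * R_GAS,
        Cp=1.5 * R_GAS,
    )


def vibrational_mode(nu_cm: float, T: float, include_zpe: bool = False):
    """Per-mode harmonic S, H, Cv; returns (S, H, Cv) in SI molar units
    (H in kJ mol^-1)."""
    theta = _H * _C_CM * nu_cm / _KB  # vibrational temperature, K
    u = theta / T
    expm1 = math.expm1(u)
    S = R_GAS * (u / expm1 - math.log1p(-math.exp(-u))) if u < 700 else 0.0
    E = R_GAS * theta / expm1 if u < 700 else 0.0
    if include_zpe:
        E += 0.5 * R_GAS * theta
    Cv = R_GAS * u**2 * math.exp(u) / expm1**2 if u < 350 else 0.0
    return S, E / 1000.0, Cv


def electronic(g: int) -> MotionContribution:
    S = R_GAS * math.log(g)
    return MotionContribution(S=S)


def compute_thermo(inp: ThermoInput) -> ThermoResult:
    """Total S, H - H(0), Cp and Cv with per-motion and per-mode breakdowns.

    The motion-wise contributions sum to the totals exactly; Cp = Cv + R by
    construction, with the +R booked under translation.
    """
    T, P = inp.temperature, inp.pressure
    trans = translational(float(inp.masses.sum()), T, P)
    rot = rotational(inp.masses, inp.coordinates, T, inp.sigma)
    mode_S = np.zeros(len(inp.frequencies))
    mode_H = np.zeros(len(inp.frequencies))
    mode_Cv = np.zeros(len(inp.frequencies))
    for i, nu in enumerate(inp.frequencies):
        mode_S[i], mode_H[i], mode_Cv[i] = vibrational_mode(
            float(nu), T, inp.include_zpe
        )
    vib = MotionContribution(
        S=float(mode_S.sum()),
        H=float(mode_H.sum()),
        Cv=float(mode_Cv.sum()),
        Cp=float(mode_Cv.sum()),
    )
    elec = electronic(inp.degeneracy)
    by_motion = {
        "translational": trans,
        "rotational": rot,
        "vibrational": vib,
        "electronic": elec,
    }
    total = {
        k: sum(getattr(c, k) for c in by_motion.values())
        for k in ("S", "H", "Cv", "Cp")
    }
    return ThermoResult(
        temperature=T,
        pressure=P,
        S=total["S"],
        H=total["H"],
        Cv=total["Cv"],
        Cp=total["Cp"],
        by_motion=by_motion,
        mode_S=mode_S,
        mode_Cv=mode_Cv,
        mode_H=mode_H,
    )


# ---------------------------------------------------------------------------
# Document front end

def _find_frequencies(doc: CompChemDocument):
    for jl in doc.jobLists:
        for job in jl.jobs:
            if job.finalization is None:
                continue
            for prop in job.finalization.properties or []:
                ref = prop.dictRef
                if ref.pair == (COMPCHEM_DICT_NS, "frequencies"):
                    return [float(v) for v in prop.value.values]
    return None


def _final_molecule(doc: CompChemDocument):
    mol = None
    for jl in doc.jobLists:
        for job in jl.jobs:
            if job.finalization is not None and job.finalization.molecule is not None:
                mol = job.finalization.molecule
    return mol


def thermo_from_document(
    doc: CompChemDocument,
    temperature: float = 298.15,
    pressure: float = 101325.0,
    sigma: int = 1,
    degeneracy: int = 1,
    include_zpe: bool = False,
) -> ThermoResult:
    """RRHO properties from a CompChem document holding an optimized
    geometry (last finalization molecule) and a frequencies property.

    The document must validate with zero ERROR findings.
    """
    from .validator import validate

    report = validate(doc)
    if not report.valid:
        raise UnsupportedDocumentError(
            "document fails convention validation:\n" + report.summary()
        )
    freqs = _find_frequencies(doc)
    if freqs is None:
        raise UnsupportedDocumentError(
            "no frequencies property found; run a frequency-analysis job first"
        )
    mol = _final_molecule(doc)
    if mol is None or not mol.atoms:
        raise UnsupportedDocumentError(
            "no finalization molecule with Cartesian coordinates found"
        )
    masses = np.array([atomic_mass(a.element) for a in mol.atoms])
    coords = np.array([[a.x, a.y, a.z] for a in mol.atoms])
    inp = ThermoInput(
        masses=masses,
        coordinates=coords,
        frequencies=np.asarray(freqs),
        temperature=temperature,
        pressure=pressure,
        sigma=sigma,
        degeneracy=degeneracy,
        include_zpe=include_zpe,
    )
    return compute_thermo(inp)
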