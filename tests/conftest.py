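import math

import numpy as np
import pytest

from compchem.fixtures import conforming_document
from compchem.model import ZMatrix, ZMatrixRow


@pytest.fixture()
def reference_doc():
    return conforming_document()


@pytest.fixture()
def registry():
    from compchem.dictionary import builtin_registry

    return builtin_registry()


def random_zmatrix(rng: np.random.Generator, n_atoms: int) -> ZMatrix:
    """A valid random z-matrix: lengths in [0.5, 3.0] Angstrom, angles in
    [15, 165] degrees, torsions in (-180, 180]."""
    rows = []
    for k in range(1, n_atoms + 1):
        row = ZMatrixRow(element="C")
        if k >= 2:
            row.length = float(rng.uniform(0.5, 3.0))
            refs = [int(rng.integers(1, k))]
        if k >= 3:
            row.angle = float(rng.uniform(15.0, 165.0))
            choices = [i for i in range(1, k) if i not in refs]
            refs.append(int(rng.choice(choices)))
        if k >= 4:
            row.torsion = float(rng.uniform(-179.999, 180.0))
            choices = [i for i in range(1, k) if i not in refs]
            refs.append(int(rng.choice(choices)))
        if k >= 2:
            row.refs = tuple(refs)
        rows.append(row)
    return ZMatrix(rows=rows)


# -- independent brute-force thermochemistry oracle -------------------------
# CODATA constants restated here on purpose, so the oracle shares nothing
# with the implementation under test.
_KB = 1.380649e-23
_H = 6.62607015e-34
_NA = 6.02214076e23
_R = _KB * _NA
_C_CM = 2.99792458e10
_AMU = 1.66053906892e-27


def oracle_vibrational(freqs_cm, T, n_levels=10_000):
    """Per-mode S, H(kJ/mol), Cv by direct Boltzmann summation over the
    first ``n_levels`` harmonic levels (ZPE-referenced)."""
    S = H = Cv = 0.0
    for nu in freqs_cm:
        theta = _H * _C_CM * nu / _KB
        u = theta / T
        n = np.arange(n_levels)
        w = np.exp(-n * u)
        q = w.sum()
        mean_n = (n * w).sum() / q
        mean_n2 = (n * n * w).sum() / q
        U = _R * theta * mean_n
        S += U / T + _R * math.log(q)
        H += U / 1000.0
        Cv += _R * u * u * (mean_n2 - mean_n**2)
    return S, H, Cv


def oracle_sackur_tetrode(mass_amu, T, P):
    m = mass_amu * _AMU
    q = (2.0 * math.pi * m * _KB * T / _H**2) ** 1.5 * _KB * T / P
    return _R * (math.log(q) + 2.5)


def oracle_rotational(masses_amu, coords_ang, T, sigma):
    """Classical rigid-rotor S by explicit inertia-tensor evaluation."""
    m = np.asarray(masses_amu, float)
    x = np.asarray(coords_ang, float) - np.average(
        np.asarray(coords_ang, float), axis=0, weights=m
    )
    I = np.zeros((3, 3))
    for mi, ri in zip(m, x):
        I += mi * (ri @ ri * np.eye(3) - np.outer(ri, ri))
    moments = np.sort(np.linalg.eigvalsh(I)) * _AMU * 1e-20
    if moments[-1] < 1e-50:
        return 0.0, 0.0, 0.0
    if moments[0] / moments[-1] < 1e-8:
        theta = _H**2 / (8 * math.pi**2 * _KB * moments[-1])
        return _R * (math.log(T / (sigma * theta)) + 1.0), _R * T / 1000.0, _R
    thetas = _H**2 / (8 * math.pi**2 * _KB * moments)
    q = math.sqrt(math.pi) / sigma * math.sqrt(T**3 / np.prod(thetas))
    return _R * (math.log(q) + 1.5), 1.5 * _R * T / 1000.0, 1.5 * _R
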