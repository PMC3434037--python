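"""RRHO thermochemistry: closed-form agreement, thermodynamic identities,
limits and the document front end."""

import math

import numpy as np
import pytest

from conftest import (
    oracle_rotational,
    oracle_sackur_tetrode,
    oracle_vibrational,
)
from compchem.logfile import generate_log, parse_log, random_spec
from compchem.model import SemanticError
from compchem.thermochem import (
    R_GAS,
    ThermoInput,
    UnsupportedDocumentError,
    atomic_mass,
    classify_linearity,
    compute_thermo,
    thermo_from_document,
)
from test_logfile import two_job_tio2_spec


def make_input(**kw):
    defaults = dict(
        masses=[15.999, 1.008, 1.008],
        coordinates=[[0.0, 0.0, 0.0], [0.0, 0.0, 0.96], [0.93, 0.0, -0.24]],
        frequencies=[1603.5, 3817.2, 3922.6],
        sigma=2,
    )
    defaults.update(kw)
    return ThermoInput(**defaults)


class TestClassifyLinearity:
    def test_atom(self):
        assert classify_linearity([39.948], [[0, 0, 0]]) == "atom"

    def test_diatomic_is_linear(self):
        assert classify_linearity(
            [12.011, 15.999], [[0, 0, 0], [0, 0, 1.13]]
        ) == "linear"

    def test_co2_is_linear(self):
        coords = [[0, 0, -1.16], [0, 0, 0], [0, 0, 1.16]]
        assert classify_linearity([15.999, 12.011, 15.999], coords) == "linear"

    def test_water_is_nonlinear(self):
        assert make_input().shape == "nonlinear"


class TestTranslation:
    def test_argon_sackur_tetrode_closed_form(self):
        inp = ThermoInput(
            masses=[39.948], coordinates=[[0, 0, 0]], frequencies=[], pressure=1e5
        )
        res = compute_thermo(inp)
        expected = oracle_sackur_tetrode(39.948, 298.15, 1e5)
        assert res.S == pytest.approx(expected, rel=1e-9)
        # the textbook standard entropy of argon at 1 bar
        assert res.S == pytest.approx(154.846, abs=5e-4)

    def test_degeneracy_adds_r_ln_g(self):
        base = compute_thermo(
            ThermoInput(masses=[15.999], coordinates=[[0, 0, 0]], frequencies=[])
        )
        triplet = compute_thermo(
            ThermoInput(
                masses=[15.999], coordinates=[[0, 0, 0]], frequencies=[], degeneracy=3
            )
        )
        assert triplet.S - base.S == pytest.approx(R_GAS * math.log(3), rel=1e-12)


class TestIdentitiesAndLimits:
    def test_cp_minus_cv_is_r(self):
        for inp in (
            make_input(),
            ThermoInput(masses=[39.948], coordinates=[[0, 0, 0]], frequencies=[]),
            make_input(temperature=50.0),
        ):
            res = compute_thermo(inp)
            assert res.Cp - res.Cv == pytest.approx(R_GAS, rel=1e-12)

    def test_breakdown_sums_to_totals(self):
        res = compute_thermo(make_input())
        for attr in ("S", "H", "Cv", "Cp"):
            total = sum(getattr(c, attr) for c in res.by_motion.values())
            assert getattr(res, attr) == pytest.approx(total, rel=1e-9)

    def test_high_temperature_mode_cv_approaches_r(self):
        # T = 100x the vibrational temperature: classical equipartition
        nu = 1000.0
        theta = 6.62607015e-34 * 2.99792458e10 * nu / 1.380649e-23
        res = compute_thermo(
            make_input(frequencies=[nu, nu, nu], temperature=100.0 * theta)
        )
        for cv in res.mode_Cv:
            assert cv == pytest.approx(R_GAS, rel=0.01)

    def test_stiff_mode_contributions_vanish(self):
        res = compute_thermo(make_input(frequencies=[30000.0, 30000.0, 30000.0]))
        assert res.by_motion["vibrational"].S == pytest.approx(0.0, abs=1e-12)
        assert res.by_motion["vibrational"].Cv == pytest.approx(0.0, abs=1e-12)
        assert res.by_motion["vibrational"].H == pytest.approx(0.0, abs=1e-12)

    def test_mode_cv_bounded_by_equipartition(self):
        res = compute_thermo(make_input())
        assert np.all(res.mode_Cv > 0) and np.all(res.mode_Cv < R_GAS)

    def test_entropy_increases_with_temperature(self):
        temps = [100.0, 200.0, 298.15, 500.0, 1000.0]
        entropies = [
            compute_thermo(make_input(temperature=t)).S for t in temps
        ]
        assert all(a < b for a, b in zip(entropies, entropies[1:]))

    def test_zpe_flag_shifts_enthalpy_by_half_r_theta(self):
        without = compute_thermo(make_input())
        with_zpe = compute_thermo(make_input(include_zpe=True))
        thetas = [
            6.62607015e-34 * 2.99792458e10 * nu / 1.380649e-23
            for nu in (1603.5, 3817.2, 3922.6)
        ]
        expected = sum(0.5 * R_GAS * t for t in thetas) / 1000.0
        assert with_zpe.H - without.H == pytest.approx(expected, rel=1e-9)


class TestInputValidation:
    def test_imaginary_mode_rejected_with_index(self):
        with pytest.raises(SemanticError, match="index 1"):
            make_input(frequencies=[1603.5, -100.0, 3922.6])

    def test_wrong_mode_count_rejected(self):
        with pytest.raises(SemanticError, match="needs 3"):
            make_input(frequencies=[1603.5])


class TestOracleEquivalence:
    def test_agreement_with_level_summation_on_random_molecules(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 20:
            spec = random_spec(rng)
            if "freq" not in spec.jobs or not spec.frequencies:
                continue
            masses = [atomic_mass(e) for e in spec.elements]
            inp = ThermoInput(
                masses=masses,
                coordinates=spec.coordinates,
                frequencies=spec.frequencies,
                sigma=1,
            )
            res = compute_thermo(inp)
            sv, hv, cvv = oracle_vibrational(spec.frequencies, 298.15)
            st = oracle_sackur_tetrode(sum(masses), 298.15, 101325.0)
            sr, hr, cvr = oracle_rotational(masses, spec.coordinates, 298.15, 1)
            assert res.S == pytest.approx(st + sr + sv, rel=1e-6)
            assert res.Cv == pytest.approx(1.5 * R_GAS + cvr + cvv, rel=1e-6)
            assert res.H == pytest.approx(
                2.5 * R_GAS * 298.15 / 1000.0 + hr + hv, rel=1e-6
            )
            checked += 1


class TestDocumentFrontEnd:
    def test_two_job_document_uses_three_modes(self):
        doc = parse_log(generate_log(two_job_tio2_spec()))
        res = thermo_from_document(doc, sigma=2)
        assert len(res.mode_Cv) == 3

    def test_document_result_matches_raw_values_exactly(self):
        spec = two_job_tio2_spec()
        doc = parse_log(generate_log(spec))
        via_doc = thermo_from_document(doc, sigma=2)
        direct = compute_thermo(
            ThermoInput(
                masses=[atomic_mass(e) for e in spec.elements],
                coordinates=spec.coordinates,
                frequencies=spec.frequencies,
                sigma=2,
            )
        )
        assert (via_doc.S, via_doc.H, via_doc.Cp, via_doc.Cv) == (
            direct.S, direct.H, direct.Cp, direct.Cv,
        )

    def test_opt_only_document_unsupported(self):
        spec = two_job_tio2_spec()
        spec.jobs, spec.scf_energies, spec.frequencies = ["opt"], [-924.5], []
        doc = parse_log(generate_log(spec))
        with pytest.raises(UnsupportedDocumentError, match="frequencies"):
            thermo_from_document(doc)

    def test_invalid_document_refused_with_report(self):
        doc = parse_log(generate_log(two_job_tio2_spec()))
        doc.jobLists[0].jobs[0].initialization.molecule.conventionRef = None
        with pytest.raises(UnsupportedDocumentError, match="I1b"):
            thermo_from_document(doc)
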