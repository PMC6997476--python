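"""Partition functions, populations, and the multi-structural sums."""

import numpy as np
import pytest

from torsearch.constants import KB_KCALMOL, WAVENUMBER_TO_KCALMOL
from torsearch.msthermo import (
    ConformerThermo,
    ThermoInput,
    chi,
    gibbs_free_energies,
    min_conformers_for_fraction,
    one_well_input,
    q_ho,
    q_ms,
    q_mst,
    q_qh,
    q_rot,
    ratio_report,
    thermo_table,
    zpe_ho,
)


def random_ensemble(rng, n=5, nu=9, temps=(300.0, 1000.0), lam=0.951):
    confs = [ConformerThermo(
        energy_U=float(rng.uniform(0, 4)),
        frequencies=rng.uniform(100, 3200, nu),
        inertia=rng.uniform(5, 200, 3),
        sigma_rot=int(rng.integers(1, 4)),
        weight_w=int(rng.integers(1, 3)),
        label=str(j),
        provenance="systematic" if j % 2 == 0 else "stochastic-0",
    ) for j in range(n)]
    return ThermoInput(confs, np.array(temps), lam)


class TestQRot:
    def test_sigma_halves(self):
        I = [10.0, 20.0, 30.0]
        assert q_rot(I, 2, 300.0) == pytest.approx(q_rot(I, 1, 300.0) / 2.0)

    def test_moment_scaling(self):
        I = np.array([10.0, 20.0, 30.0])
        assert q_rot(4 * I, 1, 500.0) == pytest.approx(8.0 * q_rot(I, 1, 500.0))

    def test_hand_checked_value(self):
        # sqrt(pi)/sigma * prod_i sqrt(8 pi^2 I_i kB T / h^2), evaluated
        # independently with CODATA constants for I=(10,20,30) amu A^2, 300 K
        assert q_rot([10.0, 20.0, 30.0], 1, 300.0) == pytest.approx(5972.3813, rel=1e-6)

    def test_linear_molecule_unsupported(self):
        with pytest.raises(ValueError, match="nonlinear"):
            q_rot([0.0, 10.0, 10.0], 1, 300.0)


class TestVibrational:
    def test_zpe_unit_conversion(self):
        # 1000 cm^-1 mode: ZPE 500 cm^-1 = 1.4296 kcal/mol
        assert zpe_ho([1000.0]) == pytest.approx(500.0 * WAVENUMBER_TO_KCALMOL)
        assert zpe_ho([1000.0]) == pytest.approx(1.4296, abs=2e-4)

    def test_zpe_additivity_and_empty(self):
        assert zpe_ho([800.0, 800.0]) == pytest.approx(2 * zpe_ho([800.0]))
        assert zpe_ho([]) == 0.0

    def test_low_temperature_limit(self):
        qt, _ = q_ho([1200.0], 10.0)
        assert qt == pytest.approx(1.0, abs=1e-12)

    def test_high_temperature_limit(self):
        nu = 1000.0
        beta_hw = 0.01
        T = nu * WAVENUMBER_TO_KCALMOL / (KB_KCALMOL * beta_hw)
        qt, _ = q_ho([nu], T)
        assert qt == pytest.approx(1.0 / beta_hw, rel=0.01)

    def test_mode_factorization(self):
        q2, _ = q_ho([700.0, 1500.0], 400.0)
        assert q2 == pytest.approx(q_ho([700.0], 400.0)[0] * q_ho([1500.0], 400.0)[0])

    def test_qh_is_ho_of_scaled_modes(self):
        qt, e = q_qh([1000.0], 0.951, 350.0)
        qt2, e2 = q_ho([951.0], 350.0)
        assert qt == pytest.approx(qt2) and e == pytest.approx(e2)

    def test_qh_zpe_scales_exactly(self):
        freqs = [500.0, 1500.0, 3000.0]
        assert q_qh(freqs, 0.951, 298.0)[1] == pytest.approx(0.951 * zpe_ho(freqs))

    def test_lambda_one_collapse(self, rng):
        inp = random_ensemble(rng, lam=1.0)
        assert np.allclose(q_ms(inp, "QH"), q_ms(inp, "HO"), rtol=1e-12)


class TestMultiStructural:
    def test_single_conformer_is_one_well(self):
        c = ConformerThermo(0.0, [1000.0, 2000.0], [10.0, 20.0, 30.0], 1, 1)
        inp = ThermoInput([c], [300.0])
        qt, ezpe = q_qh(c.frequencies, 1.0, 300.0)
        expected = q_rot(c.inertia, 1, 300.0) * qt * np.exp(-ezpe / (KB_KCALMOL * 300.0))
        assert q_ms(inp, "QH")[0] == pytest.approx(expected, rel=1e-12)

    def test_weight_two_equals_explicit_duplication(self, rng):
        """The weighted sum over non-enantiomeric structures equals the plain
        sum with every enantiomer pair expanded (100 random ensembles)."""
        for _ in range(100):
            inp = random_ensemble(rng, n=int(rng.integers(2, 7)))
            expanded = []
            for c in inp.conformers:
                for _ in range(c.weight_w):
                    expanded.append(ConformerThermo(c.energy_U, c.frequencies.copy(),
                                                    c.inertia.copy(), c.sigma_rot, 1))
            q_w = q_ms(inp, "QH")
            q_e = q_ms(ThermoInput(expanded, inp.temperatures, inp.lambda_zpe), "QH")
            assert np.allclose(q_w, q_e, rtol=1e-12)

    def test_boltzmann_suppression(self):
        base = ConformerThermo(0.0, [1000.0], [10.0, 20.0, 30.0])
        high = ConformerThermo(60.0, [1000.0], [10.0, 20.0, 30.0])  # ~e^-100 at 300 K
        q1 = q_ms(ThermoInput([ConformerThermo(0.0, [1000.0], [10, 20, 30])], [300.0]), "QH")
        q2 = q_ms(ThermoInput([base, high], [300.0]), "QH")
        assert q2[0] == pytest.approx(q1[0], rel=1e-12)


class TestMST:
    def test_all_unity_factors_collapse_to_qh(self, rng):
        inp = random_ensemble(rng)
        f = [np.ones(3) for _ in inp.conformers]
        assert np.allclose(q_mst(inp, f), q_ms(inp, "QH"), rtol=1e-12)

    def test_constant_factor_scales_globally(self, rng):
        inp = random_ensemble(rng)
        c, t = 1.7, 3
        f = [np.full(t, c) for _ in inp.conformers]
        assert np.allclose(q_mst(inp, f), c ** t * q_ms(inp, "QH"), rtol=1e-12)

    def test_factor_locality(self, rng):
        from torsearch.msthermo import _log_conformer_term

        inp = random_ensemble(rng, n=3, temps=(500.0,))
        f = [np.ones(2) for _ in inp.conformers]
        q0 = q_mst(inp, f)
        f[1][0] = 2.0
        q1 = q_mst(inp, f)
        # doubling one torsional factor of one conformer adds exactly that
        # conformer's base term once more
        term = np.exp(_log_conformer_term(inp.conformers[1], 500.0, inp.lambda_zpe))
        assert q1[0] - q0[0] == pytest.approx(term, rel=1e-9)

    def test_factor_count_mismatch(self, rng):
        inp = random_ensemble(rng, n=2)
        with pytest.raises(ValueError, match="per conformer"):
            q_mst(inp, [np.ones(2)])


class TestPopulations:
    def test_normalization_exact(self, rng):
        for _ in range(20):
            inp = random_ensemble(rng, n=int(rng.integers(1, 9)))
            for T in (100.0, 300.0, 2500.0):
                assert abs(chi(inp, T).sum() - 1.0) < 1e-12

    def test_identical_conformers_split_evenly(self):
        c = dict(energy_U=0.0, frequencies=[900.0, 1800.0], inertia=[15.0, 25.0, 35.0])
        inp = ThermoInput([ConformerThermo(**c), ConformerThermo(**c)], [400.0])
        assert np.allclose(chi(inp, 400.0), [0.5, 0.5])

    def test_single_conformer_is_unity(self):
        inp = ThermoInput([ConformerThermo(0.0, [1000.0], [10, 20, 30])], [300.0])
        assert chi(inp, 300.0)[0] == pytest.approx(1.0)

    def test_lower_free_energy_more_populated(self, rng):
        inp = random_ensemble(rng, n=6, temps=(700.0,))
        g = gibbs_free_energies(inp, 700.0)
        x = chi(inp, 700.0)
        # compare on equal weights only
        w1 = [j for j, c in enumerate(inp.conformers) if c.weight_w == 1]
        for a in w1:
            for b in w1:
                if g[a] < g[b]:
                    assert x[a] > x[b]


class TestMinimumConformerSet:
    def _uniform_input(self, us):
        confs = [ConformerThermo(u, [1000.0], [10.0, 20.0, 30.0], label=str(i),
                                 provenance="systematic")
                 for i, u in enumerate(us)]
        return ThermoInput(confs, [300.0])

    def test_single_conformer(self):
        assert min_conformers_for_fraction(self._uniform_input([0.0]), 300.0, 0.9)["m"] == 1

    def test_threshold_crossings(self):
        # chi = (0.5, 0.3, 0.2) engineered through energy gaps
        kt = KB_KCALMOL * 300.0
        us = [0.0, -kt * np.log(0.3 / 0.5), -kt * np.log(0.2 / 0.5)]
        inp = self._uniform_input(us)
        assert np.allclose(chi(inp, 300.0), [0.5, 0.3, 0.2], atol=1e-9)
        assert min_conformers_for_fraction(inp, 300.0, 0.9)["m"] == 3
        us = [0.0, -kt * np.log(0.35 / 0.6), -kt * np.log(0.05 / 0.6)]
        inp = self._uniform_input(us)
        assert min_conformers_for_fraction(inp, 300.0, 0.9)["m"] == 2

    def test_provenance_split(self, rng):
        inp = random_ensemble(rng, n=6)
        r = min_conformers_for_fraction(inp, 1000.0, 0.9)
        assert r["m"] == r["systematic"] + r["stochastic"]
        assert 1 <= r["m"] <= 6


class TestRatios:
    def test_single_conformer_all_ratios_one(self):
        inp = ThermoInput([ConformerThermo(0.0, [1000.0], [10, 20, 30], weight_w=1)], [300.0, 900.0])
        rep = ratio_report(inp)
        assert np.allclose(rep["MSQH_over_1WQH"], 1.0)
        assert np.allclose(rep["MSTC_over_1WQH"], 1.0)

    def test_ms_over_1w_at_least_one(self, rng):
        for _ in range(10):
            inp = random_ensemble(rng, n=int(rng.integers(1, 6)))
            rep = ratio_report(inp)
            assert np.all(rep["MSQH_over_1WQH"] >= 1.0 - 1e-12)

    def test_adding_a_conformer_increases_ratio(self, rng):
        inp = random_ensemble(rng, n=3, temps=(600.0,))
        rep3 = ratio_report(inp)
        bigger = ThermoInput(inp.conformers + [ConformerThermo(
            1.0, inp.conformers[0].frequencies.copy(), inp.conformers[0].inertia.copy())],
            inp.temperatures, inp.lambda_zpe)
        rep4 = ratio_report(bigger)
        assert rep4["MSQH_over_1WQH"].iloc[0] > rep3["MSQH_over_1WQH"].iloc[0]

    def test_two_level_high_temperature_limit(self):
        """Two identical wells separated by dU: the MS/1W ratio rises with T
        toward the multiplicity limit 1 + exp(-beta dU) -> 2."""
        freqs, I = [1000.0, 2000.0], [10.0, 20.0, 30.0]
        dU = 1.0
        temps = np.array([100.0, 500.0, 2000.0, 10000.0])
        inp = ThermoInput([ConformerThermo(0.0, freqs, I), ConformerThermo(dU, freqs, I)], temps)
        ratio = ratio_report(inp)["MSQH_over_1WQH"].to_numpy()
        closed_form = 1.0 + np.exp(-dU / (KB_KCALMOL * temps))
        assert np.allclose(ratio, closed_form, rtol=1e-9)
        assert np.all(np.diff(ratio) > 0)

    def test_one_well_selects_global_minimum_with_unit_weight(self, rng):
        inp = random_ensemble(rng)
        ow = one_well_input(inp)
        assert len(ow.conformers) == 1
        assert ow.conformers[0].weight_w == 1
        assert ow.conformers[0].energy_U == 0.0


def test_thermo_table_shape(rng):
    inp = random_ensemble(rng, n=3, temps=(300.0, 1000.0))
    df = thermo_table(inp)
    assert len(df) == 6
    for col in ("Q_rot", "Q_QH_tilde", "chi", "G"):
        assert col in df.columns
    assert df.groupby("T")["chi"].sum().round(12).eq(1.0).all()
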