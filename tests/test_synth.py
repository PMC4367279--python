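"""Synthetic-data generators: determinism, structure, round trips."""
import numpy as np
import pytest

from fibrilstack.cd import unmix_cd
from fibrilstack.darr import classify_residue
from fibrilstack.errors import DomainError
from fibrilstack.synth import (
    gen_cd_series,
    gen_dephasing,
    gen_emission_series,
    gen_hairpin_shift_table,
    gen_tht,
)
from fibrilstack.tht import fit_tht
from fibrilstack.trp import fit_fixed_components

SEGMENTATION = [("coil", 1, 2), ("sheet", 3, 5), ("turn", 6, 6), ("sheet", 7, 8)]


class TestDeterminism:
    def test_tht_same_seed_identical(self):
        a = gen_tht(0.0, 700.0, 28.0, 0.8, sigma=5.0, seed=17)
        b = gen_tht(0.0, 700.0, 28.0, 0.8, sigma=5.0, seed=17)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_tht_different_seed_differs(self):
        a = gen_tht(0.0, 700.0, 28.0, 0.8, sigma=5.0, seed=17)
        b = gen_tht(0.0, 700.0, 28.0, 0.8, sigma=5.0, seed=18)
        assert not np.array_equal(a.signal, b.signal)

    def test_dephasing_seeded(self):
        t = np.arange(2.0, 12.1, 1.0)
        a = gen_dephasing(3.8, 0.25, t, sigma=0.05, seed=5)
        b = gen_dephasing(3.8, 0.25, t, sigma=0.05, seed=5)
        np.testing.assert_array_equal(a.s_ratio, b.s_ratio)

    def test_cd_series_seeded(self):
        a = gen_cd_series([0.0, 20.0, 40.0], sigma=0.5, seed=9)
        b = gen_cd_series([0.0, 20.0, 40.0], sigma=0.5, seed=9)
        for (_, sa), (_, sb) in zip(a, b):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)


class TestGenTht:
    def test_noiseless_sigmoid_recovered_by_fit(self):
        trace = gen_tht(10.0, 500.0, 25.0, 1.5)
        fit = fit_tht(trace)
        assert fit.a == pytest.approx(500.0, rel=1e-4)
        assert fit.tau == pytest.approx(1.5, rel=1e-4)

    def test_hump_near_inflection_warns(self):
        with pytest.warns(UserWarning, match="fit window"):
            gen_tht(0.0, 500.0, 25.0, 1.5, hump=(24.0, 5.0, 50.0))

    def test_hump_with_late_window_recovers_main_phase(self):
        trace = gen_tht(0.0, 500.0, 30.0, 1.0, hump=(8.0, 4.0, 100.0))
        fit = fit_tht(trace, fit_window=(15.0, None))
        assert fit.rate == pytest.approx(1.0, rel=0.01)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(DomainError):
            gen_tht(0.0, 500.0, 25.0, 0.0)


class TestGenEmission:
    def test_initial_spectrum_is_single_red_component(self):
        series = gen_emission_series(times=[0.0], t_inflection=35.0, tau=2.0)
        res = fit_fixed_components(series[0][1], ((359.0, 60.0), (327.0, 40.0)))
        assert res.fractions[0] == pytest.approx(1.0, abs=1e-6)

    def test_trajectory_recovered_by_deconvolution(self):
        times = np.arange(0.0, 50.1, 5.0)
        series = gen_emission_series(times=times, t_inflection=35.0, tau=2.0)
        for t, spec in series:
            res = fit_fixed_components(spec, ((359.0, 60.0), (327.0, 40.0)))
            expected = 1.0 / (1.0 + np.exp(-(t - 35.0) / 2.0))
            assert res.fractions[1] == pytest.approx(expected, abs=0.02)

    def test_zero_intensity_rejected(self):
        with pytest.raises(DomainError):
            gen_emission_series(times=[0.0], total_intensity=0.0)

    def test_narrow_grid_rejected(self):
        with pytest.raises(DomainError):
            gen_emission_series(times=[0.0], grid=np.arange(320.0, 380.0))


class TestGenCD:
    def test_endpoint_composition_recovered(self, cd_basis):
        series = gen_cd_series([100.0], t_inflection=20.0, tau=2.0, basis=cd_basis)
        res = unmix_cd(series[0][1], cd_basis)
        assert res.fractions["sheet"] == pytest.approx(0.65, abs=1e-3)
        assert res.fractions["coil"] == pytest.approx(0.35, abs=1e-3)

    def test_initial_state_is_helical(self, cd_basis):
        series = gen_cd_series([0.0], t_inflection=20.0, tau=2.0, basis=cd_basis)
        res = unmix_cd(series[0][1], cd_basis)
        assert res.fractions["helix"] == pytest.approx(1.0, abs=1e-3)

    def test_invalid_end_fractions_rejected(self):
        with pytest.raises(DomainError):
            gen_cd_series([0.0], end_fractions={"sheet": 0.7, "coil": 0.7})


class TestGenDephasing:
    def test_zero_sigma_is_exact_model(self):
        t = np.arange(2.0, 12.1, 1.0)
        from fibrilstack.redor import simulate_fsr_curve
        clean = simulate_fsr_curve(3.8, t, 0.25)
        gen = gen_dephasing(3.8, 0.25, t, sigma=0.0)
        np.testing.assert_array_equal(gen.s_ratio, clean.s_ratio)

    def test_noise_sigma_recorded(self):
        curve = gen_dephasing(3.8, 0.25, np.arange(2.0, 12.1, 1.0), sigma=0.05)
        assert curve.noise_sigma == 0.05

    def test_negative_times_rejected(self):
        with pytest.raises(DomainError):
            gen_dephasing(3.8, 0.25, [-1.0, 2.0])


class TestGenHairpin:
    def test_zero_jitter_is_deterministic_prediction(self):
        a = gen_hairpin_shift_table("NFGSVQFV", SEGMENTATION)
        b = gen_hairpin_shift_table("NFGSVQFV", SEGMENTATION, seed=99)
        assert [(e.number, e.atom, e.shift) for e in a] == \
               [(e.number, e.atom, e.shift) for e in b]

    def test_sheet_span_residues_classify_as_sheet(self):
        table = gen_hairpin_shift_table("NFGSVQFV", SEGMENTATION,
                                        jitter_sigma=0.5, seed=4)
        for number in (3, 4, 5, 7, 8):
            obs = {e.atom: e.shift for e in table
                   if e.number == number and e.atom in ("C'", "CA", "CB")}
            residue = next(e.residue for e in table if e.number == number)
            assert classify_residue(obs, residue) == "sheet"

    def test_turn_span_takes_coil_values(self):
        table = gen_hairpin_shift_table("NFGSVQFV", SEGMENTATION)
        coil = gen_hairpin_shift_table("NFGSVQFV", [("coil", 1, 8)])
        for e in table:
            if e.number == 6:
                assert e.shift == coil.get(6, e.atom).shift

    def test_incomplete_segmentation_rejected(self):
        with pytest.raises(DomainError):
            gen_hairpin_shift_table("NFGSVQFV", [("coil", 1, 5)])
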