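"""15N relaxation fits, spectral densities and model-free analysis."""

import numpy as np
import pytest

from hmgdyn import synthetic
from hmgdyn.constants import GAMMA_H, GAMMA_N, PhysicalConstants
from hmgdyn.modelfree import (
    DiffusionTensor,
    RelaxationRates,
    anisotropy_diagnostic,
    compute_noe,
    estimate_diffusion_tensor,
    fit_decay,
    modelfree_fit,
    predict_rates,
    spectral_density,
)

CONST600 = PhysicalConstants(field_mhz=600.0)
ISO925 = DiffusionTensor("isotropic", 9.25e-9)


def literal_spectral_density(omega, s2, tau, te):
    """Independent literal transcription of the model-free J(w)."""
    term = s2 * tau / (1.0 + (omega * tau) ** 2)
    if te > 0 and s2 < 1:
        tp = 1.0 / (1.0 / tau + 1.0 / te)
        term += (1.0 - s2) * tp / (1.0 + (omega * tp) ** 2)
    return (2.0 / 5.0) * term


def literal_rates(s2, tau_m, te, rex, const):
    """Independent literal transcription of the dipolar+CSA rate equations."""
    wh, wn = const.omega_h, const.omega_n
    d2 = const.d_dipolar**2
    c2 = const.c_csa**2
    j = lambda w: literal_spectral_density(abs(w), s2, tau_m, te)
    r1 = d2 / 4 * (j(wh - wn) + 3 * j(wn) + 6 * j(wh + wn)) + c2 * j(wn)
    r2 = (d2 / 8 * (4 * j(0) + j(wh - wn) + 3 * j(wn) + 6 * j(wh) + 6 * j(wh + wn))
          + c2 / 6 * (4 * j(0) + 3 * j(wn)) + rex)
    noe = 1 + (GAMMA_H / GAMMA_N) * (d2 / 4) * (6 * j(wh + wn) - j(wh - wn)) / r1
    return r1, r2, noe


class TestDecayFit:
    def test_two_point_closed_form(self):
        rate, i0, *_ = fit_decay([0.0, np.log(2) / 10.0], [1.0, 0.5])
        assert rate == pytest.approx(10.0, rel=1e-12)
        assert i0 == pytest.approx(1.0, rel=1e-12)

    def test_noiseless_round_trip_on_measured_delay_grid(self):
        t = synthetic.R1_DELAYS
        y = 2.5 * np.exp(-1.4 * t)
        rate, i0, *_ = fit_decay(t, y)
        assert rate == pytest.approx(1.4, rel=1e-9)
        assert i0 == pytest.approx(2.5, rel=1e-9)

    def test_constant_intensities_give_zero_rate(self):
        rate, *_ = fit_decay([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        assert rate == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            fit_decay([0.1, 0.2, 0.3], [1.0, -0.5, 0.2])


class TestNoe:
    @pytest.mark.parametrize("ratio", [1.0, 0.8])
    def test_ratio(self, ratio):
        noe, _ = compute_noe(ratio * 2.0, 2.0)
        assert noe == pytest.approx(ratio)

    def test_error_propagation_in_quadrature(self):
        # equal 5% relative errors on both peaks -> ~7.07% on the ratio
        noe, err = compute_noe(0.8, 1.0, sigma_sat=0.04, sigma_0=0.05)
        assert err / noe == pytest.approx(np.sqrt(2) * 0.05, rel=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_noe(1.0, 0.0)


class TestSpectralDensity:
    def test_rigid_single_lorentzian(self):
        tau = 9.25e-9
        w = 2 * np.pi * 60.8e6
        expected = 0.4 * tau / (1 + (w * tau) ** 2)
        assert spectral_density(w, 1.0, tau) == pytest.approx(expected, rel=1e-12)

    def test_zero_frequency_rigid(self):
        assert spectral_density(0.0, 1.0, 9.25e-9) == pytest.approx(0.4 * 9.25e-9)

    def test_dual_implementation_agreement(self):
        w = abs(CONST600.omega_n)
        mine = spectral_density(w, 0.8, 9.25e-9, 50e-12)
        literal = literal_spectral_density(w, 0.8, 9.25e-9, 50e-12)
        assert mine == pytest.approx(literal, rel=1e-10)

    def test_invalid_order_parameter(self):
        with pytest.raises(ValueError):
            spectral_density(0.0, 1.2, 9e-9)


class TestPredictRates:
    def test_dual_implementation_agreement(self):
        for s2, te, rex in [(1.0, 0.0, 0.0), (0.8, 50e-12, 0.0), (0.6, 200e-12, 3.0)]:
            mine = predict_rates(s2, ISO925, CONST600, te=te, rex=rex)
            literal = literal_rates(s2, 9.25e-9, te, rex, CONST600)
            assert np.allclose(mine, literal, rtol=1e-10)

    def test_r2_over_r1_monotone_in_tau_m(self):
        ratios = []
        for tau in (5e-9, 10e-9, 15e-9):
            r1, r2, _ = predict_rates(1.0, DiffusionTensor("isotropic", tau), CONST600)
            ratios.append(r2 / r1)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_rigid_noe_in_plausible_bracket(self):
        _, _, noe = predict_rates(1.0, ISO925, CONST600)
        assert 0.6 < noe < 0.87

    def test_rex_strictly_additive_to_r2(self):
        base = predict_rates(0.85, ISO925, CONST600)
        with_rex = predict_rates(0.85, ISO925, CONST600, rex=5.0)
        assert with_rex[1] - base[1] == pytest.approx(5.0, abs=1e-12)
        assert with_rex[0] == pytest.approx(base[0])
        assert with_rex[2] == pytest.approx(base[2])


class TestAnisotropyDiagnostic:
    def test_product_and_ratio(self):
        rates = RelaxationRates(np.array([1]), np.array([1.5]), np.array([15.0]),
                                np.array([0.8]))
        diag = anisotropy_diagnostic(rates)
        assert diag["r1r2"][0] == pytest.approx(22.5)
        assert diag["r2_over_r1"][0] == pytest.approx(10.0)

    def test_rex_elevates_both_flexibility_depresses_both(self):
        base = predict_rates(0.85, ISO925, CONST600)
        rexy = predict_rates(0.85, ISO925, CONST600, rex=5.0)
        flex = predict_rates(0.3, ISO925, CONST600, te=500e-12)
        assert rexy[0] * rexy[1] > base[0] * base[1]
        assert rexy[1] / rexy[0] > base[1] / base[0]
        assert flex[0] * flex[1] < base[0] * base[1]
        assert flex[1] / flex[0] < base[1] / base[0]


class TestDiffusionTensor:
    def _rates_from(self, tensor, vecs, noise, seed):
        residues = sorted(vecs)
        params = {r: {"s2": 0.85} for r in residues}
        ds = synthetic.gen_relaxation_data(params, tensor, noise=0.0, seed=seed,
                                           nh_vectors=vecs)
        rng = np.random.default_rng(seed)
        r1 = ds.rates_true["r1"].to_numpy() * (1 + noise * rng.standard_normal(len(residues)))
        r2 = ds.rates_true["r2"].to_numpy() * (1 + noise * rng.standard_normal(len(residues)))
        return RelaxationRates(ds.residues, r1, r2, ds.rates_true["noe"].to_numpy())

    def test_isotropic_round_trip(self, toy_structure, toy_nh_vectors):
        rates = self._rates_from(DiffusionTensor("isotropic", 9.3e-9),
                                 toy_nh_vectors, 0.005, 1)
        est = estimate_diffusion_tensor(rates, toy_structure)
        assert est.model == "isotropic"
        assert est.tau_m == pytest.approx(9.3e-9, abs=0.1e-9)

    def test_axial_selected_and_ratio_recovered(self, toy_structure, toy_nh_vectors):
        truth = DiffusionTensor("axial", 9.3e-9, ratio=1.3, theta=0.4, phi=1.0)
        rates = self._rates_from(truth, toy_nh_vectors, 0.002, 2)
        est = estimate_diffusion_tensor(rates, toy_structure)
        assert est.model == "axial"
        assert est.stats["p_iso_vs_axial"] < 0.05
        assert est.ratio == pytest.approx(1.3, rel=0.10)

    def test_shuffled_vectors_destroy_orientation_dependence(self, toy_structure,
                                                             toy_nh_vectors):
        truth = DiffusionTensor("axial", 9.3e-9, ratio=1.3, theta=0.4, phi=1.0)
        rng = np.random.default_rng(3)
        fake = {r: v / np.linalg.norm(v)
                for r, v in ((r, rng.standard_normal(3)) for r in toy_nh_vectors)}
        rates = self._rates_from(truth, fake, 0.005, 3)
        est = estimate_diffusion_tensor(rates, toy_structure)
        assert est.model == "isotropic"

    def test_too_few_residues_rejected(self, toy_structure):
        rates = RelaxationRates(np.arange(1, 5), np.full(4, 1.4), np.full(4, 13.0),
                                np.full(4, 0.8))
        with pytest.raises(ValueError):
            estimate_diffusion_tensor(rates, toy_structure)


class TestModelFreeFit:
    def test_rigid_residue_selects_simplest_model(self):
        params = {1: {"s2": 0.85}}
        ds = synthetic.gen_relaxation_data(params, ISO925, noise=0.0, seed=0)
        rates = RelaxationRates(ds.residues,
                                ds.rates_true["r1"].to_numpy(),
                                ds.rates_true["r2"].to_numpy(),
                                ds.rates_true["noe"].to_numpy())
        out = modelfree_fit(rates, ISO925, CONST600, n_bootstrap=50, rng=0)[0]
        assert out.model == 1
        assert out.s2 == pytest.approx(0.85, abs=1e-4)

    def test_rex_residue_detected_and_recovered(self):
        params = {1: {"s2": 0.85, "rex": 4.0}}
        ds = synthetic.gen_relaxation_data(params, ISO925, noise=0.0, seed=3)
        rates = RelaxationRates(ds.residues,
                                ds.rates_true["r1"].to_numpy(),
                                ds.rates_true["r2"].to_numpy(),
                                ds.rates_true["noe"].to_numpy())
        out = modelfree_fit(rates, ISO925, CONST600, n_bootstrap=50, rng=1)[0]
        assert out.model in (3, 4)
        assert out.rex == pytest.approx(4.0, rel=0.30)

    def test_monte_carlo_s2_recovery(self):
        # 0.85-S2 residues at 3% noise: model 1 chosen and S2 within 0.03
        # in >= 90% of realizations
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            params = {1: {"s2": 0.85}}
            ds = synthetic.gen_relaxation_data(params, ISO925, noise=0.03, seed=seed)
            rates = RelaxationRates(ds.residues,
                                    ds.rates_true["r1"].to_numpy() * 1.0,
                                    ds.rates_true["r2"].to_numpy() * 1.0,
                                    ds.noe["noe"].to_numpy())
            out = modelfree_fit(rates, ISO925, CONST600, n_bootstrap=30, rng=seed)[0]
            if out.model == 1 and abs(out.s2 - 0.85) <= 0.03:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_selection_never_prefers_larger_nested_model(self):
        # when model 1 already passes goodness-of-fit, no extension is chosen
        params = {i: {"s2": s} for i, s in enumerate((0.95, 0.85, 0.7), start=1)}
        ds = synthetic.gen_relaxation_data(params, ISO925, noise=0.0, seed=5)
        rates = RelaxationRates(ds.residues,
                                ds.rates_true["r1"].to_numpy(),
                                ds.rates_true["r2"].to_numpy(),
                                ds.rates_true["noe"].to_numpy())
        for out in modelfree_fit(rates, ISO925, CONST600, n_bootstrap=50, rng=2):
            assert out.model == 1
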