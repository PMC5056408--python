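"""Two-term Ogden model: identities, closed forms, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctfm.material import (OgdenMaterial, StressStrainCurve, SUBSTRATE_9_10,
                           fit_ogden, initial_youngs_modulus,
                           nominal_stress_equibiaxial,
                           nominal_stress_uniaxial, strain_energy)


class TestStrainEnergy:
    def test_zero_at_identity(self):
        assert strain_energy(SUBSTRATE_9_10, 1.0, 1.0, 1.0) == 0.0

    def test_one_term_alpha2_reduces_to_neo_hookean(self):
        """mu, alpha = 2 gives W = mu/2 (I1 - 3) at J = 1."""
        mat = OgdenMaterial(mu1=3.0, alpha1=2.0, mu2=0.0, alpha2=1.0, nu=0.49)
        l1, l2 = 1.7, 0.9
        l3 = 1.0 / (l1 * l2)
        I1 = l1 ** 2 + l2 ** 2 + l3 ** 2
        assert strain_energy(mat, l1, l2, l3) == pytest.approx(
            3.0 / 2.0 * (I1 - 3.0), rel=1e-12)

    def test_work_energy_consistency_uniaxial(self):
        """W along the incompressible uniaxial path equals the integral of
        the nominal stress (trapezoid quadrature oracle)."""
        mat = SUBSTRATE_9_10
        lam = np.linspace(1.0, 1.5, 20001)
        P = nominal_stress_uniaxial(mat, lam)
        work = np.trapezoid(P, lam)
        W = strain_energy(mat, 1.5, 1.5 ** -0.5, 1.5 ** -0.5)
        assert W == pytest.approx(work, rel=1e-6)

    def test_zero_alpha_rejected(self):
        with pytest.raises(ValueError):
            OgdenMaterial(mu1=1.0, alpha1=0.0)


class TestNominalStress:
    def test_zero_at_unit_stretch(self):
        assert nominal_stress_uniaxial(SUBSTRATE_9_10, 1.0) == 0.0
        assert nominal_stress_equibiaxial(SUBSTRATE_9_10, 1.0) == 0.0

    def test_small_strain_slope_is_three_mu0(self):
        mat = SUBSTRATE_9_10
        h = 1e-6
        slope = (nominal_stress_uniaxial(mat, 1 + h)
                 - nominal_stress_uniaxial(mat, 1 - h)) / (2 * h)
        assert slope == pytest.approx(3.0 * mat.mu0, rel=1e-6)
        assert 3.0 * mat.mu0 == pytest.approx(12.72, abs=0.005)

    def test_equibiaxial_stiffer_than_uniaxial(self):
        lam = np.linspace(1.05, 2.75, 30)
        assert np.all(nominal_stress_equibiaxial(SUBSTRATE_9_10, lam)
                      > nominal_stress_uniaxial(SUBSTRATE_9_10, lam))

    def test_monotone_increasing_on_test_range(self):
        lam = np.linspace(1.0, 2.75, 200)
        P = nominal_stress_uniaxial(SUBSTRATE_9_10, lam)
        assert np.all(np.diff(P) > 0)

    @pytest.mark.parametrize("mode,path", [
        ("uniaxial", lambda l: (l, l ** -0.5, l ** -0.5)),
        ("equibiaxial", lambda l: (l, l, l ** -2.0)),
    ])
    def test_stress_equals_energy_derivative(self, mode, path):
        """Closed-form P equals dW/dlambda along the matching J=1 path."""
        mat = SUBSTRATE_9_10
        fn = (nominal_stress_uniaxial if mode == "uniaxial"
              else nominal_stress_equibiaxial)
        for lam in (1.1, 1.6, 2.4):
            h = 1e-6
            dW = (strain_energy(mat, *path(lam + h))
                  - strain_energy(mat, *path(lam - h))) / (2 * h)
            factor = 1.0 if mode == "uniaxial" else 2.0
            assert fn(mat, lam) == pytest.approx(dW / factor, rel=1e-6)

    def test_negative_stretch_rejected(self):
        with pytest.raises(ValueError):
            nominal_stress_uniaxial(SUBSTRATE_9_10, -0.5)


class TestYoungsModulus:
    def test_calibrated_substrate_matches_measured_modulus(self):
        assert initial_youngs_modulus(SUBSTRATE_9_10) == pytest.approx(
            12.6352, abs=1e-4)

    def test_incompressible_one_term(self):
        mat = OgdenMaterial(mu1=1.0, alpha1=2.0, mu2=0.0, alpha2=1.0,
                            nu=0.4999)
        assert initial_youngs_modulus(mat) == pytest.approx(3.0, rel=1e-3)

    def test_term_order_symmetry(self):
        a = OgdenMaterial(mu1=4.073, alpha1=2.132, mu2=0.167, alpha2=-0.6)
        b = OgdenMaterial(mu1=0.167, alpha1=-0.6, mu2=4.073, alpha2=2.132)
        assert initial_youngs_modulus(a) == initial_youngs_modulus(b)

    @settings(deadline=None, max_examples=25)
    @given(mu1=st.floats(0.5, 10), mu2=st.floats(0.01, 1),
           a1=st.floats(0.5, 4), a2=st.floats(-3, -0.1))
    def test_modulus_consistent_with_uniaxial_slope(self, mu1, mu2, a1, a2):
        mat = OgdenMaterial(mu1=mu1, alpha1=a1, mu2=mu2, alpha2=a2, nu=0.5 - 1e-9)
        h = 1e-6
        slope = (nominal_stress_uniaxial(mat, 1 + h)
                 - nominal_stress_uniaxial(mat, 1 - h)) / (2 * h)
        assert slope == pytest.approx(initial_youngs_modulus(mat), rel=1e-4)


class TestFit:
    @pytest.fixture()
    def truth_curves(self):
        lam = np.linspace(1.0, 2.75, 40)
        return [StressStrainCurve(lam=lam,
                                  P=nominal_stress_uniaxial(SUBSTRATE_9_10,
                                                            lam),
                                  mode="uniaxial"),
                StressStrainCurve(lam=lam,
                                  P=nominal_stress_equibiaxial(SUBSTRATE_9_10,
                                                               lam),
                                  mode="equibiaxial")]

    def test_parameter_recovery_within_1pc(self, truth_curves):
        fit = fit_ogden(truth_curves)
        got = sorted([(fit.material.mu1, fit.material.alpha1),
                      (fit.material.mu2, fit.material.alpha2)])
        want = sorted([(4.073, 2.132), (0.167, -0.600)])
        for (mg, ag), (mw, aw) in zip(got, want):
            assert mg == pytest.approx(mw, rel=0.01)
            assert ag == pytest.approx(aw, rel=0.01)

    def test_modulus_robust_to_2pc_stress_noise(self, truth_curves, rng):
        noisy = [StressStrainCurve(
            lam=c.lam, P=c.P * (1 + rng.normal(0, 0.02, len(c.P))),
            mode=c.mode) for c in truth_curves]
        fit = fit_ogden(noisy)
        assert initial_youngs_modulus(fit.material) == pytest.approx(
            12.6352, rel=0.05)

    def test_nested_one_term_material_reproduced(self):
        mat = OgdenMaterial(mu1=2.0, alpha1=2.0, mu2=0.0, alpha2=1.0)
        lam = np.linspace(1.0, 2.0, 30)
        curves = [StressStrainCurve(lam=lam,
                                    P=nominal_stress_uniaxial(mat, lam),
                                    mode="uniaxial")]
        fit = fit_ogden(curves)
        assert fit.residual_rms < 1e-4 * nominal_stress_uniaxial(mat, 2.0)

    def test_rank_deficient_data_rejected(self):
        c = StressStrainCurve(lam=np.array([1.5, 1.5, 1.5, 1.5]),
                              P=np.array([1.0, 1.0, 1.0, 1.0]),
                              mode="uniaxial")
        with pytest.raises(ValueError):
            fit_ogden([c])
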