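"""Ball-and-stick forward model and orientation statistics."""

import numpy as np
import pytest
from scipy.integrate import quad

from pmdwi import (
    DirectionScheme,
    FiberCompartmentModel,
    beff,
    cone_of_uncertainty,
    predict_voxel_signals,
)
from pmdwi.ballstick import SSFPSignalTable, mean_direction
from pmdwi.signals import ssfp_echo


def _model(f=0.7, v=(0, 0, 1.0), d=0.08e-3):
    v = np.asarray(v, float)
    return FiberCompartmentModel(S0=100.0, d=d, fractions=(f,),
                                 directions=(v / np.linalg.norm(v))[None, :])


class TestModelInvariants:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="sum"):
            FiberCompartmentModel(S0=1, d=1e-3, fractions=(0.6, 0.6),
                                  directions=np.eye(3)[:2])
        with pytest.raises(ValueError, match="fraction"):
            _model(f=1.2)

    def test_unit_directions_required(self):
        with pytest.raises(ValueError, match="unit norm"):
            FiberCompartmentModel(S0=1, d=1e-3, fractions=(0.5,),
                                  directions=np.array([[0, 0, 2.0]]))


class TestSEForward:
    def test_parallel_direction_collapses_to_monoexponential(self, se_proto):
        sch = DirectionScheme(vectors=np.array([[0, 0, 1.0]]))
        m = _model()
        sig = predict_voxel_signals(m, se_proto, sch)
        assert sig[0] == pytest.approx(100 * np.exp(-4500 * m.d), rel=1e-12)

    def test_perpendicular_direction_spares_the_stick(self, se_proto):
        sch = DirectionScheme(vectors=np.array([[1.0, 0, 0]]))
        sig = predict_voxel_signals(_model(), se_proto, sch)
        expect = 100 * (0.3 * np.exp(-4500 * 0.08e-3) + 0.7)
        assert sig[0] == pytest.approx(expect, rel=1e-12)

    def test_lowb_volumes_unattenuated(self, se_proto):
        sch = DirectionScheme(vectors=np.array([[1.0, 0, 0]]), n_lowb=2)
        sig = predict_voxel_signals(_model(), se_proto, sch)
        assert sig[0] == sig[1] == pytest.approx(100.0)


class TestSSFPForward:
    def test_ball_attenuation_consistent_with_beff(self, ssfp_hi, ssfp_lo, tissue):
        # the isotropic compartment's attenuation at d = tissue D must match
        # exp(-b_eff d) (this is the definition of b_eff)
        sch = DirectionScheme(vectors=np.array([[0, 0, 1.0]]))
        m0 = _model(f=0.0)
        sig = predict_voxel_signals(m0, ssfp_hi, sch, ssfp_lo)
        tbl = SSFPSignalTable(ssfp_hi, 400, 45)
        ratio = sig[0] / (100 * tbl(0.0))
        assert ratio == pytest.approx(np.exp(-beff(ssfp_hi, tissue) * m0.d), rel=0.05)

    def test_spline_table_matches_direct_solve(self, ssfp_hi):
        tbl = SSFPSignalTable(ssfp_hi, 400, 45)
        for D in np.linspace(1e-5, 3.5e-3, 17):
            direct = ssfp_echo(42, 37, 16.7, 38, 400, 45, D)
            assert tbl(D) == pytest.approx(direct, rel=1e-4)

    def test_signal_length_mismatch_rejected(self, ssfp_hi, dirs54):
        from pmdwi import BallStickModel

        sch = DirectionScheme(vectors=dirs54.vectors, n_lowb=30)
        with pytest.raises(ValueError, match="does not match"):
            BallStickModel(np.ones(10), sch, ssfp_hi)


class TestConeOfUncertainty:
    def test_identical_draws_zero_cone(self):
        dirs = np.tile([0, 0, 1.0], (30, 1))
        assert cone_of_uncertainty(dirs) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_sphere_quantile(self):
        # uniform axes: P(angle < a) = 1 - cos a, so the 95% angle is
        # arccos(0.05) = 87.13 deg; cross-checked by brute-force sampling
        rng = np.random.default_rng(0)
        v = rng.standard_normal((200_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert cone_of_uncertainty(v) == pytest.approx(np.degrees(np.arccos(0.05)), abs=0.3)

    def test_watson_quantile_matches_quadrature(self):
        # Watson(kappa) axes about +z via rejection sampling
        kappa = 20.0
        rng = np.random.default_rng(1)
        draws = []
        while len(draws) < 30_000:
            c = rng.uniform(-1, 1, 50_000)
            keep = rng.random(50_000) < np.exp(kappa * (c**2 - 1))
            draws.extend(c[keep])
        c = np.abs(np.array(draws[:30_000]))
        ph = rng.uniform(0, 2 * np.pi, len(c))
        s = np.sqrt(1 - c**2)
        v = np.stack([s * np.cos(ph), s * np.sin(ph), c], axis=1)
        # numerically integrate the angle CDF for the 95% quantile
        pdf = lambda th: np.exp(kappa * np.cos(th) ** 2) * np.sin(th)
        norm = quad(pdf, 0, np.pi / 2)[0]
        from scipy.optimize import brentq

        q95 = brentq(lambda th: quad(pdf, 0, th)[0] / norm - 0.95, 1e-3, np.pi / 2)
        assert cone_of_uncertainty(v) == pytest.approx(np.degrees(q95), rel=0.02)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError, match=">= 20"):
            cone_of_uncertainty(np.tile([0, 0, 1.0], (5, 1)))

    def test_mean_direction_antipodal_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((500, 3)) * 0.05 + [0, 0, 1.0]
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        signs = rng.choice([-1.0, 1.0], size=(500, 1))
        mu = mean_direction(v * signs)
        assert abs(mu @ [0, 0, 1.0]) > 0.999
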