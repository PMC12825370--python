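import numpy as np
import pytest

from xrrfilm import (
    InterfaceModel,
    ReflectivityCurve,
    Slab,
    critical_qz,
    fresnel,
    normalize_to_fresnel,
    parratt_reflectivity,
    qz_from_alpha,
)
from xrrfilm.reflectivity import alpha_from_qz, denormalize_from_fresnel

from oracles import oracle_reflectivity

WATER = 0.334
LAMBDA = 1.28


def first_local_minimum(qz: np.ndarray, y: np.ndarray, q_start: float) -> float:
    """qz of the first interior local minimum of y above q_start."""
    sel = qz > q_start
    q, v = qz[sel], y[sel]
    interior = np.flatnonzero((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:]))
    assert interior.size, "no local minimum found"
    return float(q[interior[0] + 1])


class TestGeometry:
    def test_qz_zero_at_grazing(self):
        assert qz_from_alpha(0.0, LAMBDA) == 0.0

    def test_qz_at_normal_incidence(self):
        assert qz_from_alpha(np.pi / 2, LAMBDA) == pytest.approx(4 * np.pi / 1.28)

    def test_alpha_qz_round_trip(self):
        alpha = alpha_from_qz(0.6, LAMBDA)
        assert qz_from_alpha(alpha, LAMBDA) == pytest.approx(0.6, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            qz_from_alpha(-0.1, LAMBDA)
        with pytest.raises(ValueError):
            qz_from_alpha(0.1, -1.0)


class TestFresnel:
    def test_critical_qz_of_water(self):
        # 4 sqrt(pi r_e 0.334) with r_e = 2.8179403e-5 Å
        assert critical_qz(WATER) == pytest.approx(0.0217507, rel=1e-5)

    def test_total_reflection_below_qc(self):
        qc = critical_qz(WATER)
        assert fresnel(0.5 * qc, WATER) == pytest.approx(1.0, abs=1e-14)

    def test_high_q_asymptote(self):
        """R_F -> (q_c / 2 q)^4 far above the critical edge."""
        qc = critical_qz(WATER)
        q = 20 * qc
        assert fresnel(q, WATER) == pytest.approx((qc / (2 * q)) ** 4, rel=0.01)


class TestParratt:
    def test_empty_stack_recovers_fresnel(self, qz_grid):
        r = parratt_reflectivity(InterfaceModel(), qz_grid).r
        np.testing.assert_allclose(r, fresnel(qz_grid, WATER), atol=1e-12)

    def test_contrast_free_slab_recovers_fresnel(self, qz_grid):
        """A sharp slab at the subphase density is invisible."""
        m = InterfaceModel(slabs=(Slab(20.0, WATER, sigma=0.0),))
        r = parratt_reflectivity(m, qz_grid, use_slicing=False).r
        np.testing.assert_allclose(r, fresnel(qz_grid, WATER), atol=1e-9)

    def test_energy_bound(self, oa_model, qz_grid):
        qz = np.concatenate([np.linspace(0.002, 0.0159, 30), qz_grid])
        for use_slicing in (False, True):
            r = parratt_reflectivity(oa_model, qz, use_slicing=use_slicing).r
            assert np.all(r >= 0)
            assert np.all(r <= 1 + 1e-9)

    def test_matches_slicing_oracle_on_random_stacks(self, qz_grid):
        """Parratt + Névot–Croce vs an independent Abelès fine-slicing matrix
        calculation, over stacks with capillary-scale roughness."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            n = rng.integers(1, 4)
            d = rng.uniform(8, 40, n)
            rho = rng.uniform(0.1, 0.5, n)
            sigma = float(rng.uniform(1.0, 3.0))
            m = InterfaceModel(
                slabs=tuple(Slab(di, ri) for di, ri in zip(d, rho)),
                shared_sigma=sigma,
            )
            r = parratt_reflectivity(m, qz_grid, use_slicing=False).r
            r_ref = oracle_reflectivity(m, qz_grid, width=0.1)
            worst = max(worst, np.max(np.abs(r - r_ref) / r_ref))
        assert worst <= 5e-3

    def test_slicing_fallback_matches_oracle(self, oa_model, qz_grid):
        """Roughness comparable to the thinnest slab triggers fine slicing."""
        assert oa_model.interface_sigmas.max() > 5.025 / 2  # fallback engaged
        r = parratt_reflectivity(oa_model, qz_grid).r
        r_ref = oracle_reflectivity(oa_model, qz_grid, width=0.05)
        assert np.max(np.abs(r - r_ref) / r_ref) <= 5e-3

    def test_thicker_film_compresses_fringes(self, qz_grid):
        """The first fringe minimum of R/R_F moves to lower qz as thickness grows."""
        minima = []
        for extra in (0.0, 2.0, 4.0):
            m = InterfaceModel(
                slabs=(Slab(10.63 + extra, 0.312), Slab(5.025, 0.350)),
                shared_sigma=1.0,
            )
            curve = parratt_reflectivity(m, qz_grid, use_slicing=False)
            rrf = normalize_to_fresnel(curve, m).r
            minima.append(first_local_minimum(qz_grid, rrf, 0.1))
        assert minima[0] > minima[1] > minima[2]

    def test_invalid_qz_rejected(self, oa_model):
        with pytest.raises(ValueError):
            parratt_reflectivity(oa_model, np.array([-0.1, 0.2]))


class TestNormalization:
    def test_bare_interface_normalizes_to_unity(self, qz_grid):
        m = InterfaceModel()
        curve = parratt_reflectivity(m, qz_grid)
        flat = normalize_to_fresnel(curve, m)
        np.testing.assert_allclose(flat.r, 1.0, atol=1e-12)

    def test_normalize_denormalize_round_trip(self, oa_model, qz_grid):
        curve = parratt_reflectivity(oa_model, qz_grid)
        back = denormalize_from_fresnel(normalize_to_fresnel(curve, oa_model),
                                        oa_model)
        np.testing.assert_allclose(back.r, curve.r, rtol=1e-12)

    def test_double_normalization_rejected(self, oa_model, qz_grid):
        curve = normalize_to_fresnel(parratt_reflectivity(oa_model, qz_grid),
                                     oa_model)
        with pytest.raises(ValueError):
            normalize_to_fresnel(curve, oa_model)

    def test_first_fringe_minimum_tracks_total_thickness(self, qz_grid):
        """R/R_F oscillates about 1 with fringe period ~ 2 pi / total thickness.

        At low roughness the fringes survive to high qz; at the fitted
        capillary roughness of ~3.6 Å the damping wipes them out.
        """
        m = InterfaceModel(slabs=(Slab(10.63, 0.312), Slab(5.025, 0.350)),
                           shared_sigma=0.5)
        rrf = normalize_to_fresnel(
            parratt_reflectivity(m, qz_grid, use_slicing=False), m
        ).r
        q_min = first_local_minimum(qz_grid, rrf, 0.1)
        assert q_min == pytest.approx(2 * np.pi / (10.63 + 5.025), rel=0.15)
        assert rrf[(qz_grid > 0.08)].max() > 1.0


class TestCurveValidation:
    def test_non_monotone_qz_rejected(self):
        with pytest.raises(ValueError):
            ReflectivityCurve(qz=np.array([0.1, 0.05]), r=np.array([1.0, 1.0]))

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            ReflectivityCurve(qz=np.array([0.1, 0.2]), r=np.array([1.0, -1.0]))
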