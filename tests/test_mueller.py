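"""Retarder forward model, simulated polarimetry and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polsing import (
    AnisotropyMap,
    IntensityStack,
    MuellerImage,
    OpticalParams,
    compute_invariants,
    mm_from_anisotropy,
    mm_from_stokes,
    phase_from_optics,
    simulate_intensities,
    stokes_from_intensities,
)


def rotation_mueller(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1, 0, 0, 0], [0, c, -s, 0], [0, s, c, 0], [0, 0, 0, 1.0]])


def linear_retarder(delta):
    c, s = np.cos(delta), np.sin(delta)
    return np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, c, s], [0, 0, -s, c]])


class TestPhaseFromOptics:
    @pytest.mark.parametrize(
        "wavelength,dn,thickness,expected",
        [
            (633e-9, 0.0, 20e-6, 0.0),                 # no birefringence
            (633e-9, 1.0, 633e-9 / 2, np.pi),          # half-wave condition
            (633e-9, 1.5e-3, 20e-6, 0.2977812941791273),
        ],
    )
    def test_values(self, wavelength, dn, thickness, expected):
        delta = phase_from_optics(OpticalParams(wavelength, dn, thickness))
        assert delta == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("kw", [
        {"wavelength": -633e-9, "birefringence": 1e-3, "thickness": 20e-6},
        {"wavelength": 633e-9, "birefringence": 1e-3, "thickness": 0.0},
        {"wavelength": 633e-9, "birefringence": -1e-3, "thickness": 20e-6},
    ])
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            OpticalParams(**kw)


class TestMmFromAnisotropy:
    def test_zero_delta_gives_identity(self, rng):
        amap = AnisotropyMap(rng.uniform(0, np.pi, (5, 7)), np.zeros((5, 7)))
        mm = mm_from_anisotropy(amap)
        assert np.allclose(mm.elements, np.eye(4), atol=1e-14)

    def test_circular_singularity_at_diagonal_axis(self):
        # at rho = +pi/4, delta = +pi/2 both f22 and f44 vanish
        amap = AnisotropyMap(np.full((1, 1), np.pi / 4), np.full((1, 1), np.pi / 2))
        mm = mm_from_anisotropy(amap)
        assert mm.element(2, 2)[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert mm.element(4, 4)[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_rotated_retarder_composition(self, random_map):
        amap = random_map((4, 6))
        mm = mm_from_anisotropy(amap)
        for i in range(4):
            for j in range(6):
                expected = (
                    rotation_mueller(2 * amap.rho[i, j])
                    @ linear_retarder(amap.delta[i, j])
                    @ rotation_mueller(-2 * amap.rho[i, j])
                )
                np.testing.assert_allclose(mm.elements[i, j], expected, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(rho=st.floats(0, np.pi), delta=st.floats(0, 2 * np.pi))
    def test_retarder_block_is_rotation(self, rho, delta):
        mm = mm_from_anisotropy(
            AnisotropyMap(np.full((1, 1), rho), np.full((1, 1), delta))
        )
        block = mm.elements[0, 0, 1:, 1:]
        np.testing.assert_allclose(block @ block.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(block) == pytest.approx(1.0, abs=1e-10)

    def test_azimuth_pi_periodicity(self, rng):
        rho = rng.uniform(0, np.pi, (4, 4))
        delta = rng.uniform(0, 2 * np.pi, (4, 4))
        mm1 = mm_from_anisotropy(AnisotropyMap(rho, delta))
        mm2 = mm_from_anisotropy(AnisotropyMap(rho + np.pi, delta))
        np.testing.assert_allclose(mm1.elements, mm2.elements, atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            AnisotropyMap(np.zeros((3, 3)), np.zeros((3, 4)))


class TestSimulateIntensities:
    def test_identity_medium_linear_probe(self):
        mm = MuellerImage(np.tile(np.eye(4), (1, 1, 1, 1)))
        stack = simulate_intensities(mm)
        i = stack.intensities[0, 0, 0]  # illumination 0 deg
        np.testing.assert_allclose(i, [1.0, 0.5, 0.0, 0.5, 0.5, 0.5], atol=1e-14)

    def test_identity_medium_circular_probe(self):
        mm = MuellerImage(np.tile(np.eye(4), (1, 1, 1, 1)))
        i = simulate_intensities(mm).intensities[0, 0, 3]  # circular illumination
        # order: 0, 45, 90, 135, R, L
        np.testing.assert_allclose(i, [0.5, 0.5, 0.5, 0.5, 1.0, 0.0], atol=1e-14)

    def test_matches_stokes_mueller_algebra(self, random_map):
        mm = mm_from_anisotropy(random_map((3, 3)))
        stack = simulate_intensities(mm, noise_sd=0.0)
        probes = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [1, -1, 0, 0], [1, 0, 0, 1.0]])
        analyzers = np.array(
            [[1, 1, 0, 0], [1, 0, 1, 0], [1, -1, 0, 0],
             [1, 0, -1, 0], [1, 0, 0, 1], [1, 0, 0, -1.0]]
        )
        for i in range(3):
            for j in range(3):
                for p, sp in enumerate(probes):
                    s_out = mm.elements[i, j] @ sp
                    for q, aq in enumerate(analyzers):
                        assert stack.intensities[i, j, p, q] == pytest.approx(
                            0.5 * aq @ s_out, abs=1e-12
                        )

    def test_negative_noise_rejected(self):
        mm = MuellerImage(np.tile(np.eye(4), (1, 1, 1, 1)))
        with pytest.raises(ValueError):
            simulate_intensities(mm, noise_sd=-0.1)

    def test_noise_seeded_reproducible(self, random_map):
        mm = mm_from_anisotropy(random_map((4, 4)))
        a = simulate_intensities(mm, noise_sd=0.01, seed=42)
        b = simulate_intensities(mm, noise_sd=0.01, seed=42)
        np.testing.assert_array_equal(a.intensities, b.intensities)


class TestStokesReconstruction:
    def test_linear_zero_state(self):
        inten = np.zeros((1, 1, 4, 6))
        inten[0, 0, :, :] = [1.0, 0.5, 0.0, 0.5, 0.5, 0.5]
        sv = stokes_from_intensities(IntensityStack(inten)).stokes
        np.testing.assert_allclose(sv[0, 0, 0], [1, 1, 0, 0], atol=1e-14)

    def test_right_circular_state(self):
        inten = np.zeros((1, 1, 4, 6))
        inten[0, 0, :, :] = [0.5, 0.5, 0.5, 0.5, 1.0, 0.0]
        sv = stokes_from_intensities(IntensityStack(inten)).stokes
        np.testing.assert_allclose(sv[0, 0, 0], [1, 0, 0, 1], atol=1e-14)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            IntensityStack(np.full((1, 1, 4, 6), -1.0))

    def test_recovers_output_stokes_of_retarder(self, random_map):
        mm = mm_from_anisotropy(random_map((4, 5)))
        sv = stokes_from_intensities(simulate_intensities(mm)).stokes
        probes = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [1, -1, 0, 0], [1, 0, 0, 1.0]])
        expected = np.einsum("hwik,pk->hwpi", mm.elements, probes)
        np.testing.assert_allclose(sv, expected, atol=1e-12)


class TestMmFromStokes:
    def test_identity_round_trip(self):
        mm = MuellerImage(np.tile(np.eye(4), (2, 2, 1, 1)))
        rec = mm_from_stokes(stokes_from_intensities(simulate_intensities(mm)))
        np.testing.assert_allclose(rec.elements, mm.elements, atol=1e-12)

    def test_full_round_trip_random_retarder(self, random_map):
        mm = mm_from_anisotropy(random_map((32, 32)))
        rec = mm_from_stokes(stokes_from_intensities(simulate_intensities(mm)))
        np.testing.assert_allclose(rec.elements, mm.elements, atol=1e-10)

    def test_f12_combination_formula(self, random_map):
        mm = mm_from_anisotropy(random_map((3, 3)))
        stokes = stokes_from_intensities(simulate_intensities(mm))
        rec = mm_from_stokes(stokes)
        sv = stokes.stokes
        f12 = 0.5 * (sv[:, :, 0, 0] - sv[:, :, 2, 0])  # 0.5*(SV1^0 - SV1^90)
        np.testing.assert_allclose(rec.element(1, 2), f12, atol=1e-12)

    def test_dark_pixels_flagged_invalid(self):
        stack = IntensityStack(np.zeros((2, 2, 4, 6)))
        rec = mm_from_stokes(stokes_from_intensities(stack))
        assert rec.invalid is not None and rec.invalid.all()


class TestInvariants:
    def test_l_point_values_at_zero_delta(self, rng):
        amap = AnisotropyMap(rng.uniform(0, np.pi, (4, 4)), np.zeros((4, 4)))
        inv = compute_invariants(mm_from_anisotropy(amap))
        np.testing.assert_allclose(inv.F2233, 1.0, atol=1e-14)
        np.testing.assert_allclose(inv.F4243, 0.0, atol=1e-14)

    def test_c_point_value_at_quarter_wave(self, rng):
        amap = AnisotropyMap(
            rng.uniform(0, np.pi, (4, 4)), np.full((4, 4), np.pi / 2)
        )
        inv = compute_invariants(mm_from_anisotropy(amap))
        np.testing.assert_allclose(inv.f44, 0.0, atol=1e-14)

    def test_analytic_identities(self, random_map):
        amap = random_map((16, 16))
        inv = compute_invariants(mm_from_anisotropy(amap))
        np.testing.assert_allclose(inv.F2233, inv.f44, atol=1e-12)
        np.testing.assert_allclose(inv.F2434, inv.F4243, atol=1e-12)
        np.testing.assert_allclose(inv.f44, np.cos(amap.delta), atol=1e-12)
        np.testing.assert_allclose(inv.F4243, np.abs(np.sin(amap.delta)), atol=1e-12)
        np.testing.assert_allclose(inv.f44**2 + inv.F4243**2, 1.0, atol=1e-10)

    def test_unknown_invariant_name(self, random_map):
        inv = compute_invariants(mm_from_anisotropy(random_map((2, 2))))
        with pytest.raises(KeyError):
            inv.get("f99")
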