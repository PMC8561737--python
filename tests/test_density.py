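"""Density simulation, radial profiles, correlations and d99."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import fft as sp_fft

from saptfit.density import (
    compute_d99,
    lowpass_filter,
    radial_profile,
    real_space_cc,
    simulate_density,
)
from saptfit.structures_io import Atom, AtomicModel, Chain, DensityMap, Residue
from saptfit.synthetic import make_toy_subunit


def _single_atom_model(pos=(0.0, 0.0, 0.0), element="C"):
    return AtomicModel(
        [Chain("A", [Residue(1, "ALA", [Atom("CA", element, np.array(pos))])])]
    )


def _radial_power(density_map):
    """Spherically binned power spectrum (oracle for frequency content)."""
    data = density_map.data.astype(float)
    f = sp_fft.fftn(data)
    power = np.abs(f) ** 2
    freqs = [
        sp_fft.fftfreq(n, d=v) for n, v in zip(data.shape, density_map.voxel_size)
    ]
    sx, sy, sz = np.meshgrid(*freqs, indexing="ij")
    s = np.sqrt(sx**2 + sy**2 + sz**2)
    return s.ravel(), power.ravel()


class TestSimulateDensity:
    def test_single_atom_spherical_and_monotone(self):
        m = simulate_density(_single_atom_model(), 6.0, voxel_size=1.0)
        peak_idx = np.unravel_index(np.argmax(m.data), m.shape)
        peak_world = m.index_to_world(np.array(peak_idx))
        assert np.allclose(peak_world, 0.0, atol=1.0)
        prof = radial_profile(m, (0, 0, 0), 6.0, 8)
        assert np.all(np.diff(prof.values) < 0)

    def test_linearity_two_atoms(self):
        one = simulate_density(_single_atom_model(), 6.0, voxel_size=1.0)
        two_model = AtomicModel(
            [
                Chain(
                    "A",
                    [
                        Residue(1, "ALA", [Atom("CA", "C", np.array([0.0, 0, 0]))]),
                        Residue(2, "ALA", [Atom("CA", "C", np.array([0.0, 0, 0]))]),
                    ],
                )
            ]
        )
        two = simulate_density(two_model, 6.0, grid=one)
        assert two.data.sum() == pytest.approx(2 * one.data.sum(), rel=1e-6)

    def test_integral_proportional_to_atomic_number(self):
        c = simulate_density(_single_atom_model(element="C"), 6.0, voxel_size=1.0)
        o = simulate_density(_single_atom_model(element="O"), 6.0, grid=c)
        assert o.data.sum() / c.data.sum() == pytest.approx(8 / 6, rel=1e-6)

    def test_lower_resolution_suppresses_high_frequencies(self):
        """8 Å map of a 20-residue model has less power beyond 1/8 Å⁻¹ than 4 Å."""
        model = make_toy_subunit(20, seed=3)
        grid = simulate_density(model, 4.0, voxel_size=1.5, pad=8.0)
        m4 = grid
        m8 = simulate_density(model, 8.0, grid=grid)
        for m in (m4, m8):
            assert m.shape == grid.shape
        s4, p4 = _radial_power(m4)
        s8, p8 = _radial_power(m8)
        hi = s4 > 1.0 / 8.0
        frac4 = p4[hi].sum() / p4.sum()
        frac8 = p8[hi].sum() / p8.sum()
        assert frac8 < frac4

    def test_rotation_equivariance(self):
        """Simulating a rotated model equals rotating the simulated map.

        A +90° lattice rotation about the grid center permutes voxels
        exactly, so the two maps must agree to floating-point precision.
        """
        model = make_toy_subunit(20, seed=3)
        com = model.center_of_mass()
        rot90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        rotated = model.transformed(rot90, com - rot90 @ com)
        n, vox = 49, 1.5
        origin = com - (n - 1) / 2 * vox
        grid = DensityMap(np.zeros((n, n, n), dtype=np.float32), vox, origin)
        a = simulate_density(model, 6.0, grid=grid)
        b = simulate_density(rotated, 6.0, grid=grid)
        a_rot = np.rot90(a.data, k=1, axes=(0, 1))
        assert np.abs(a_rot - b.data).max() / np.abs(a.data).max() < 1e-6

    def test_model_outside_grid_rejected(self):
        grid = DensityMap(np.zeros((8, 8, 8)), 1.0, (100.0, 100.0, 100.0))
        with pytest.raises(ValueError, match="outside"):
            simulate_density(_single_atom_model(), 4.0, grid=grid)


class TestRadialProfile:
    def test_uniform_map(self):
        m = DensityMap(np.full((24, 24, 24), 3.7), 1.0, (0, 0, 0))
        prof = radial_profile(m, (12, 12, 12), 8.0, 6)
        assert np.allclose(prof.values, 3.7, atol=1e-9)

    def test_lattice_rotation_invariance(self):
        """90° lattice rotations about the center leave the profile unchanged.

        Lattice rotations permute voxels exactly, so the residual is pure
        spherical quadrature error, driven below 1e-3 by dense sampling.
        """
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(rng.normal(size=(25, 25, 25)), 2.0)
        m = DensityMap(data, 1.0, (0, 0, 0))
        center = (12.0, 12.0, 12.0)
        base = radial_profile(m, center, 10.0, 8, points_per_shell=5000)
        rot = DensityMap(np.rot90(data, axes=(0, 1)).copy(), 1.0, (0, 0, 0))
        prof = radial_profile(rot, center, 10.0, 8, points_per_shell=5000)
        scale = np.abs(base.values).max()
        assert np.abs(base.values - prof.values).max() / scale < 1e-3

    def test_gaussian_blob_closed_form(self):
        """Profile of exp(-r²/2σ²), σ=4 Å matches the analytic form per shell."""
        sigma = 4.0
        n = 65
        ax = np.arange(n) * 0.5
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        c = ax[n // 2]
        r2 = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2
        m = DensityMap(np.exp(-r2 / (2 * sigma**2)), 0.5, (0, 0, 0))
        prof = radial_profile(m, (c, c, c), 12.0, 10)
        expected = np.exp(-(prof.shell_radii**2) / (2 * sigma**2))
        assert np.all(np.abs(prof.values / expected - 1) < 0.02)

    def test_center_outside_grid_rejected(self):
        m = DensityMap(np.zeros((8, 8, 8)), 1.0, (0, 0, 0))
        with pytest.raises(ValueError):
            radial_profile(m, (100, 100, 100), 4.0, 4)


class TestRealSpaceCC:
    def test_self_correlation_is_one(self, single_copy_case):
        m = single_copy_case["map"]
        assert real_space_cc(m, m) == pytest.approx(1.0)

    def test_negated_map_is_minus_one(self, single_copy_case):
        m = single_copy_case["map"]
        neg = DensityMap(-m.data, m.voxel_size, m.origin)
        assert real_space_cc(m, neg) == pytest.approx(-1.0)

    def test_matches_explicit_formula_with_noise(self, single_copy_case):
        m = single_copy_case["map"]
        rng = np.random.default_rng(1)
        noisy = DensityMap(
            m.data + rng.normal(scale=0.5 * m.data.std(), size=m.shape),
            m.voxel_size,
            m.origin,
        )
        got = real_space_cc(m, noisy)
        x = m.data.astype(float).ravel()
        y = noisy.data.astype(float).ravel()
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_affine_rescaling_invariance(self, single_copy_case):
        m = single_copy_case["map"]
        scaled = DensityMap(2.5 * m.data + 7.0, m.voxel_size, m.origin)
        assert real_space_cc(m, scaled) == pytest.approx(1.0, abs=1e-6)

    def test_local_mask_uses_model_atoms(self, single_copy_case):
        m = single_copy_case["map"]
        cc = real_space_cc(m, m, mask="local", model=single_copy_case["placed"])
        assert cc == pytest.approx(1.0)

    def test_degenerate_mask_rejected(self, single_copy_case):
        m = single_copy_case["map"]
        mask = np.zeros(m.shape, dtype=bool)
        mask[0, 0, :5] = True
        with pytest.raises(ValueError, match="degenerate"):
            real_space_cc(m, m, mask=mask)


class TestD99:
    def test_lowpass_filtered_map(self):
        """d99 of a map low-pass filtered at 8 Å sits in [7, 10] Å."""
        rng = np.random.default_rng(0)
        noise = DensityMap(rng.normal(size=(48, 48, 48)), 1.0, (0, 0, 0))
        lp = lowpass_filter(noise, 8.0)
        assert 7.0 <= compute_d99(lp) <= 10.0

    def test_white_noise_hits_nyquist(self):
        rng = np.random.default_rng(1)
        m = DensityMap(rng.normal(size=(40, 40, 40)), 1.2, (0, 0, 0))
        d99 = compute_d99(m)
        # ~2 voxels (Nyquist), within one Fourier shell of the 40-point grid
        assert abs(d99 - 2.4) < 2.4 / 0.99 - 2.4 + 0.2

    def test_scale_invariance(self, single_copy_case):
        m = single_copy_case["map"]
        scaled = DensityMap(37.5 * m.data, m.voxel_size, m.origin)
        assert compute_d99(scaled) == pytest.approx(compute_d99(m), rel=1e-9)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            compute_d99(DensityMap(np.full((8, 8, 8), 2.0), 1.0, (0, 0, 0)))
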