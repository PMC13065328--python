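"""Surrogate constructions: gradients, injection, reversal, sparsification."""

import numpy as np
import pandas as pd
import pytest

from phasefield.decomposition import complex_svd
from phasefield.spectral_phase import PhaseMatrix
from phasefield.surrogates import (
    SurrogateSpec,
    inject,
    load_average_reference,
    reverse_singular_weights,
    sf_grid,
    sparsify,
    spherical_gradient_basis,
    surrogate_timeseries,
)


def test_sf_grid_has_fourteen_steps_from_two_to_sixteen():
    g = sf_grid()
    assert len(g) == 14
    assert g[0] == 2.0 and g[-1] == 16.0


class TestSphericalGradientBasis:
    def test_vanishing_sf_gives_constant_phase(self, noise_subject):
        spec = SurrogateSpec(sf=1e-9)
        basis = spherical_gradient_basis(noise_subject.mesh, noise_subject.points, spec)
        np.testing.assert_allclose(basis, basis[0], atol=1e-6)

    def test_phases_track_arc_length_on_a_great_circle(self, mesh):
        # synthetic contacts along the anterior-posterior great circle of the
        # left shell: phase must advance at 2*pi*sf per meter of arc
        from phasefield.cortical_geometry import project_to_surface

        sub, _ = mesh.submesh("left")
        center = np.asarray(sub.vertices).mean(axis=0)
        angles = np.linspace(0.3, 2.0, 9)
        pts3d = center + 0.07 * np.column_stack(
            [np.zeros_like(angles), np.cos(angles), np.sin(angles)]
        )
        pts = project_to_surface(pts3d, np.full(9, "left"), mesh, max_dist=np.inf)
        spec = SurrogateSpec(sf=4.0)
        basis = spherical_gradient_basis(mesh, pts, spec)
        omega = -np.angle(basis)
        d_omega = np.angle(np.exp(1j * np.diff(np.unwrap(omega))))
        # arc between successive contacts ~ R * d(angle); mild tolerance for
        # the radial projection of the distorted shell
        arc = 0.07 * np.diff(angles)
        np.testing.assert_allclose(np.abs(d_omega), 2 * np.pi * 4.0 * arc, rtol=0.15)

    def test_aliased_sf_warns(self, noise_subject):
        with pytest.warns(UserWarning, match="alias"):
            spherical_gradient_basis(
                noise_subject.mesh, noise_subject.points, SurrogateSpec(sf=200.0)
            )


class TestSurrogateTimeseries:
    def test_constant_rsv_gives_static_field(self):
        basis = np.exp(1j * np.linspace(-2, 2, 8))
        out = surrogate_timeseries(basis, np.ones(30, dtype=complex))
        np.testing.assert_allclose(out, np.tile(basis[:, None], (1, 30)), atol=1e-12)

    def test_double_reversal_and_conjugation_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        assert np.allclose(np.conj(np.conj(v[::-1])[::-1]), v)

    def test_construction_is_rank_one(self):
        rng = np.random.default_rng(1)
        basis = np.exp(1j * rng.uniform(-np.pi, np.pi, 12))
        v = rng.standard_normal(80) + 1j * rng.standard_normal(80)
        out = surrogate_timeseries(basis, v)
        s = np.linalg.svd(out, compute_uv=False)
        assert s[1] < 1e-10 * s[0]


class TestInject:
    def phase(self, values):
        return PhaseMatrix(values=values, center_freq=8.0, fs=500.0)

    def test_zero_weight_returns_input(self):
        rng = np.random.default_rng(2)
        vals = np.exp(1j * rng.uniform(-np.pi, np.pi, (5, 40)))
        pm = self.phase(vals)
        out = inject(pm, np.exp(1j * rng.uniform(-np.pi, np.pi, (5, 40))), 0.0)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_large_weight_converges_to_surrogate(self):
        rng = np.random.default_rng(3)
        vals = np.exp(1j * rng.uniform(-np.pi, np.pi, (5, 40)))
        sur = np.exp(1j * rng.uniform(-np.pi, np.pi, (5, 40)))
        out = inject(self.phase(vals), sur, 1e9)
        np.testing.assert_allclose(out.values, sur, atol=1e-6)

    def test_equal_weights_bisect_the_angle(self):
        vals = np.array([[1.0 + 0j]])
        sur = np.array([[np.exp(1j * np.pi / 2)]])
        out = inject(self.phase(vals), sur, 1.0)
        assert np.angle(out.values[0, 0]) == pytest.approx(np.pi / 4)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            inject(self.phase(np.ones((2, 3), complex)), np.ones((3, 2), complex), 1.0)


class TestReverseSingularWeights:
    def test_single_weight_reversal_is_identity(self):
        rng = np.random.default_rng(4)
        vals = np.exp(1j * rng.uniform(-np.pi, np.pi, (10, 60)))
        svd = complex_svd(vals, rank=5)
        out = reverse_singular_weights(svd, n=1)
        recon = (svd.lsv * svd.singular_values[None, :]) @ svd.rsv.conj().T
        np.testing.assert_allclose(out.values, recon / np.abs(recon), atol=1e-10)

    def test_double_reversal_restores_the_reconstruction(self):
        from phasefield.decomposition import reconstruct

        rng = np.random.default_rng(5)
        vals = np.exp(1j * rng.uniform(-np.pi, np.pi, (10, 60)))
        svd = complex_svd(vals, rank=6)
        w = svd.singular_values.copy()
        w[:6] = w[:6][::-1]
        w[:6] = w[:6][::-1]
        np.testing.assert_allclose(reconstruct(svd, w), reconstruct(svd), atol=1e-12)
        # a single reversal genuinely changes the field
        once = reverse_singular_weights(svd, n=6)
        assert not np.allclose(once.values, vals / np.abs(vals))

    def test_reversing_more_than_rank_raises(self):
        rng = np.random.default_rng(6)
        svd = complex_svd(np.exp(1j * rng.uniform(size=(5, 20))), rank=3)
        with pytest.raises(ValueError):
            reverse_singular_weights(svd, n=4)


class TestSparsify:
    def contacts(self, n, hemis=("left", "right")):
        return pd.DataFrame(
            {
                "id": [f"c{i}" for i in range(n)],
                "x": np.zeros(n),
                "y": np.zeros(n),
                "z": np.zeros(n),
                "label": ["gray"] * n,
                "hemisphere": [hemis[i % len(hemis)] for i in range(n)],
            }
        )

    def test_one_third_of_151_is_51(self):
        _, sub, keep = sparsify(None, self.contacts(151), 1.0 / 3.0, seed=0)
        assert len(keep) == 51

    def test_keep_fraction_one_is_identity(self):
        df = self.contacts(20)
        _, sub, keep = sparsify(None, df, 1.0, seed=0)
        assert len(keep) == 20
        np.testing.assert_array_equal(keep, np.arange(20))

    def test_different_seeds_differ_but_sizes_match(self):
        df = self.contacts(60)
        _, _, k1 = sparsify(None, df, 1.0 / 3.0, seed=1)
        _, _, k2 = sparsify(None, df, 1.0 / 3.0, seed=2)
        assert len(k1) == len(k2)
        assert not np.array_equal(k1, k2)

    def test_too_few_survivors_raises(self):
        df = self.contacts(9, hemis=("left",) * 8 + ("right",))
        with pytest.raises(ValueError, match="retains"):
            sparsify(None, df, 1.0 / 3.0, seed=0)


class TestLoadAverageReference:
    def test_zero_weight_is_identity(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((6, 100))
        np.testing.assert_array_equal(load_average_reference(x, 0.0), x)

    def test_weight_one_on_zero_mean_data_is_identity(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((6, 100))
        x = x - x.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(load_average_reference(x, 1.0), x, atol=1e-12)

    def test_negative_weight_raises(self):
        with pytest.raises(ValueError):
            load_average_reference(np.zeros((2, 3)), -1.0)
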