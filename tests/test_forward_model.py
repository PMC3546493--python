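"""Forward-operator construction: entry formula, adjointness, geometry."""

import numpy as np
import pytest

from cspat import (
    FrequencySampling,
    ImageGrid,
    MeasurementVector,
    SensorGeometry,
    StackedOperatorSystem,
    WaveletTransform,
    apply_adjoint,
    apply_forward,
    build_forward_matrix,
    to_stacked_real,
)
from cspat.forward_model import GeometryError


class TestImageGrid:
    def test_pixel_size_and_symmetry(self):
        grid = ImageGrid(nx=128, ny=128, fov_mm=30.0)
        assert grid.pixel_size_mm == 30.0 / 128
        centers = grid.pixel_centers()
        assert centers.shape == (128 * 128, 2)
        np.testing.assert_allclose(centers.sum(axis=0), 0.0, atol=1e-9)

    def test_row_major_y_then_x(self):
        grid = ImageGrid(nx=3, ny=2, fov_mm=3.0)
        centers = grid.pixel_centers()
        # first row of pixels shares the lowest y; x increases fastest
        assert centers[0, 1] == centers[1, 1] == centers[2, 1]
        assert centers[0, 0] < centers[1, 0] < centers[2, 0]
        assert centers[0, 1] < centers[3, 1]

    def test_invalid(self):
        with pytest.raises(ValueError):
            ImageGrid(nx=0)


class TestSensorGeometry:
    def test_arc_placement(self):
        geo = SensorGeometry(radius_mm=30.0, span_deg=90.0, count=5)
        pos = geo.positions
        np.testing.assert_allclose(np.hypot(pos[:, 0], pos[:, 1]), 30.0)
        np.testing.assert_allclose(geo.angles_deg, [0, 22.5, 45, 67.5, 90])

    def test_single_sensor(self):
        geo = SensorGeometry(count=1)
        assert geo.positions.shape == (1, 2)


class TestFrequencySampling:
    def test_within_window_and_deterministic(self):
        fs = FrequencySampling(seed=3)
        t1, t2 = fs.draw(10), fs.draw(10)
        np.testing.assert_array_equal(t1, t2)
        assert t1.shape == (10, 64)
        assert t1.min() >= 0.2 and t1.max() <= 2.5
        # without replacement within each angle
        for row in t1:
            assert len(np.unique(row)) == 64

    def test_independent_across_angles(self):
        t = FrequencySampling(seed=0).draw(8)
        assert any(not np.array_equal(t[0], t[i]) for i in range(1, 8))

    def test_per_angle_exceeds_grid(self):
        with pytest.raises(ValueError):
            FrequencySampling(grid_size=16, per_angle=32)


class TestBuildForwardMatrix:
    def test_single_pixel_entry_formula(self):
        # one pixel at the origin, sensor at distance 1 mm, k = 1 rad/mm
        grid = ImageGrid(nx=1, ny=1, fov_mm=0.1)
        sensors = SensorGeometry(radius_mm=1.0, span_deg=0.0, count=1)
        c = 1.0
        f = c / (2 * np.pi)  # so that k = 2 pi f / c = 1
        freqs = FrequencySampling(grid_size=1, f_min_mhz=f, f_max_mhz=f,
                                  per_angle=1)
        op = build_forward_matrix(grid, sensors, freqs, c=c, dtype=np.complex128)
        expected = -1j * np.exp(1j * 1.0) / 1.0
        assert op.matrix.shape == (1, 1)
        np.testing.assert_allclose(op.matrix[0, 0], expected, rtol=1e-12)
        assert abs(abs(op.matrix[0, 0]) - 1.0) < 1e-12

    def test_modulus_law(self, small_grid):
        """|entry| = c * k_n / distance, exhaustively on a small build."""
        sensors = SensorGeometry(radius_mm=25.0, count=3)
        freqs = FrequencySampling(grid_size=16, per_angle=4, seed=1)
        c = 1.5
        op = build_forward_matrix(small_grid, sensors, freqs, c=c,
                                  dtype=np.complex128)
        pix = small_grid.pixel_centers()
        for m in range(3):
            for n in range(4):
                k = 2 * np.pi * op.freq_table_mhz[m, n] / c
                d = np.hypot(*(sensors.positions[m] - pix).T)
                np.testing.assert_allclose(
                    np.abs(op.matrix[m * 4 + n]), c * k / d, rtol=1e-12
                )

    def test_default_protocol_shape(self):
        grid = ImageGrid(nx=32, ny=32)
        op = build_forward_matrix(
            grid,
            SensorGeometry(count=5),
            FrequencySampling(per_angle=64),
        )
        assert op.shape == (5 * 64, 32 * 32)

    def test_sensor_inside_fov_rejected(self):
        grid = ImageGrid(nx=8, ny=8, fov_mm=30.0)
        with pytest.raises(GeometryError):
            build_forward_matrix(
                grid, SensorGeometry(radius_mm=10.0, count=2),
                FrequencySampling(per_angle=2),
            )

    def test_seed_determinism_bitwise(self, small_grid):
        kw = dict(
            sensors=SensorGeometry(radius_mm=25.0, count=4),
            freqs=FrequencySampling(per_angle=8, seed=11),
        )
        a = build_forward_matrix(small_grid, kw["sensors"], kw["freqs"])
        b = build_forward_matrix(small_grid, kw["sensors"], kw["freqs"])
        assert np.array_equal(a.matrix, b.matrix)


class TestApply:
    def test_zero_and_linearity(self, small_operator):
        op = small_operator
        z = apply_forward(op, np.zeros(op.grid.shape))
        assert not np.any(z.values)
        rng = np.random.default_rng(0)
        x1, x2 = rng.random(op.grid.shape), rng.random(op.grid.shape)
        np.testing.assert_allclose(
            apply_forward(op, x1 + x2).values,
            apply_forward(op, x1).values + apply_forward(op, x2).values,
            rtol=1e-12,
        )

    def test_unit_pixel_is_column(self, small_operator):
        op = small_operator
        e = np.zeros(op.grid.n_pixels)
        e[5] = 1.0
        np.testing.assert_allclose(
            apply_forward(op, e.reshape(op.grid.shape)).values,
            op.matrix[:, 5], rtol=1e-12,
        )

    def test_shape_mismatch(self, small_operator):
        with pytest.raises(ValueError):
            apply_forward(small_operator, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            apply_adjoint(small_operator, np.zeros(99))

    def test_adjoint_identity(self, small_operator):
        """<Ax, y> = <x, A^H y> to 1e-10 relative on random vectors."""
        op = small_operator
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.standard_normal(op.grid.n_pixels)
            y = rng.standard_normal(op.n_rows) + 1j * rng.standard_normal(op.n_rows)
            lhs = np.vdot(y, op.apply(x))
            rhs = np.vdot(op.adjoint(y), x)
            assert abs(lhs - rhs) / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-10

    def test_backprojection_peaks_at_source_full_view(self):
        """Phi^H Phi x localises a point source under 360-degree coverage."""
        grid = ImageGrid(nx=8, ny=8, fov_mm=16.0)
        op = build_forward_matrix(
            grid,
            SensorGeometry(radius_mm=30.0, span_deg=360.0, count=64),
            FrequencySampling(grid_size=32, per_angle=16, seed=5),
            dtype=np.complex128,
        )
        x = np.zeros(64)
        src = 27
        x[src] = 1.0
        bp = np.abs(op.adjoint(op.apply(x)))
        peak = np.argmax(bp)
        pr, pc = divmod(peak, 8)
        sr, sc = divmod(src, 8)
        assert abs(pr - sr) <= 1 and abs(pc - sc) <= 1


class TestStackedReal:
    def test_explicit_example(self):
        s = to_stacked_real(np.array([[1j]]), np.array([1j]))
        np.testing.assert_array_equal(s.matrix, [[0.0], [1.0]])
        np.testing.assert_array_equal(s.y, [0.0, 1.0])

    def test_norm_preservation_and_roundtrip(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((5, 7)) + 1j * rng.standard_normal((5, 7))
        y = rng.standard_normal(5) + 1j * rng.standard_normal(5)
        s = to_stacked_real(A, y)
        v = rng.standard_normal(7)
        np.testing.assert_allclose(
            np.linalg.norm(s.matvec(v)), np.linalg.norm(A @ v), rtol=1e-12
        )
        # transpose-product identity
        u = rng.standard_normal(10)
        np.testing.assert_allclose(
            s.rmatvec(u), (A.conj().T @ (u[:5] + 1j * u[5:])).real, rtol=1e-12
        )
        A2, y2 = s.to_complex()
        np.testing.assert_array_equal(A2, A)
        np.testing.assert_array_equal(y2, y)

    def test_implicit_matches_dense_stacking(self, small_operator):
        """Matrix-free stacked system equals the dense stacked matrix."""
        op = small_operator
        tr = WaveletTransform(op.grid.shape, levels=1)
        system = StackedOperatorSystem(op, tr)
        rng = np.random.default_rng(8)
        v = rng.standard_normal(op.grid.n_pixels)
        u = rng.standard_normal(2 * op.n_rows)
        # dense reference: Phi times synthesis matrix, then stacked
        syn = np.column_stack(
            [tr.synthesis(e) .ravel() for e in np.eye(op.grid.n_pixels)]
        )
        dense = to_stacked_real(op.matrix @ syn, op.apply(np.zeros(op.grid.shape)))
        np.testing.assert_allclose(system.matvec(v), dense.matrix @ v, atol=1e-9)
        np.testing.assert_allclose(system.rmatvec(u), dense.matrix.T @ u, atol=1e-9)


def test_conditioning_improves_with_rows(small_grid):
    """Appending sensor rows never decreases sigma_min (tall system)."""
    op = build_forward_matrix(
        small_grid,
        SensorGeometry(radius_mm=25.0, count=8),
        FrequencySampling(grid_size=16, per_angle=5, seed=2),
        dtype=np.complex128,
    )
    M = op.matrix / np.linalg.norm(op.matrix, axis=1, keepdims=True)
    sigmas = [
        np.linalg.svd(M[: 4 * 5], compute_uv=False)[-1],
        np.linalg.svd(M[: 6 * 5], compute_uv=False)[-1],
        np.linalg.svd(M, compute_uv=False)[-1],
    ]
    assert sigmas[0] <= sigmas[1] + 1e-12 <= sigmas[2] + 2e-12
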