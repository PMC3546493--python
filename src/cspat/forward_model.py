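"""Temporal-frequency-domain forward model for limited-view circular PAT.

In photoacoustic tomography a short laser pulse deposits an absorbed
optical energy density ``A(r)`` in tissue; the resulting acoustic pressure
is recorded by ultrasound detectors placed on an arc around the sample.
After Fourier transforming in time, the pressure spectrum sampled by a
point detector at position ``r_m`` and wavenumber ``k_n = 2*pi*f_n / c`` is a
superposition of outgoing spherical waves from every image pixel, which
discretises to the complex projection matrix

    Phi[(m, n), (i, j)] = -1j * c * k_n * exp(1j * k_n * d) / d,
    d = |r_m - r_ij|,

acting on the flattened image ``x``: ``y = Phi @ x``.  The physical
prefactor (volume expansion coefficient over specific heat) is fixed at 1,
so reconstructions are defined up to a global positive scale shared with
the simulated measurements.

Units are mm and microseconds throughout; frequencies are in MHz, so the
sound speed default ``c = 1.5`` mm/us corresponds to 1500 m/s in soft
tissue and wavenumbers come out in rad/mm.

The measurement geometry is *limited view*: sensors cover only an arc
(90 degrees by default) of the circle, and at every sensor only a random
subset of temporal frequencies inside a band-limited window is kept --
the compressed-sensing acquisition the reconstruction modules undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "GeometryError",
    "ImageGrid",
    "SensorGeometry",
    "FrequencySampling",
    "ForwardOperator",
    "MeasurementVector",
    "StackedRealSystem",
    "StackedOperatorSystem",
    "WhitenedOperator",
    "whiten_operator",
    "build_forward_matrix",
    "apply_forward",
    "apply_adjoint",
    "to_stacked_real",
]


class GeometryError(ValueError):
    """Raised when sensors and image grid are geometrically incompatible."""


@dataclass(frozen=True)
class ImageGrid:
    """Square-pixel Cartesian image grid centred on the origin.

    Pixels are indexed row-major with the row index running along *y*
    (increasing upward in physical space) and the column index along *x*;
    the flat pixel index of (row i, col j) is ``i * nx + j``.
    """

    nx: int = 128
    ny: int = 128
    fov_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("pixel counts must be positive")
        if self.fov_mm <= 0:
            raise ValueError("field of view must be positive")

    @property
    def pixel_size_mm(self) -> float:
        return self.fov_mm / self.nx

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def x_mm(self) -> np.ndarray:
        """Pixel-centre x coordinates, symmetric about 0."""
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pixel_size_mm

    @property
    def y_mm(self) -> np.ndarray:
        """Pixel-centre y coordinates, symmetric about 0."""
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.pixel_size_mm

    @property
    def half_diagonal_mm(self) -> float:
        """Distance from the origin to a field-of-view corner."""
        return 0.5 * float(np.hypot(self.nx, self.ny)) * self.pixel_size_mm

    def pixel_centers(self) -> np.ndarray:
        """(n_pixels, 2) array of (x, y) centres in flat row-major order."""
        xx, yy = np.meshgrid(self.x_mm, self.y_mm)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass(frozen=True)
class SensorGeometry:
    """Point detectors equally spaced on a circular arc.

    Angles are measured counter-clockwise from the +x axis; the arc
    ``[start_deg, start_deg + span_deg]`` includes both endpoints.
    """

    radius_mm: float = 30.0
    span_deg: float = 90.0
    count: int = 40
    start_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("need at least one sensor")
        if self.radius_mm <= 0:
            raise ValueError("sensor radius must be positive")
        if self.span_deg < 0:
            raise ValueError("angular span must be nonnegative")

    @property
    def angles_deg(self) -> np.ndarray:
        if self.count == 1:
            return np.array([self.start_deg])
        return self.start_deg + np.linspace(0.0, self.span_deg, self.count)

    @property
    def positions(self) -> np.ndarray:
        """(count, 2) array of sensor (x, y) positions in mm."""
        ang = np.deg2rad(self.angles_deg)
        return self.radius_mm * np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass(frozen=True)
class FrequencySampling:
    """Random per-angle frequency selection from a candidate grid.

    ``grid_size`` equally spaced candidate frequencies span
    ``[f_min_mhz, f_max_mhz]`` inclusive; each sensor keeps ``per_angle``
    of them, drawn without replacement and independently per angle from a
    single RNG stream seeded with ``seed``.
    """

    grid_size: int = 128
    f_min_mhz: float = 0.2
    f_max_mhz: float = 2.5
    per_angle: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 1 or self.per_angle < 1:
            raise ValueError("grid_size and per_angle must be >= 1")
        if self.per_angle > self.grid_size:
            raise ValueError("cannot draw more frequencies than the grid holds")
        if not (0 < self.f_min_mhz <= self.f_max_mhz):
            raise ValueError("need 0 < f_min_mhz <= f_max_mhz")

    @property
    def candidate_frequencies_mhz(self) -> np.ndarray:
        if self.grid_size == 1:
            return np.array([0.5 * (self.f_min_mhz + self.f_max_mhz)])
        return np.linspace(self.f_min_mhz, self.f_max_mhz, self.grid_size)

    def draw(self, n_angles: int) -> np.ndarray:
        """(n_angles, per_angle) table of selected frequencies in MHz.

        Each row is sorted ascending; identical seeds give identical tables.
        """
        rng = np.random.default_rng(self.seed)
        cand = self.candidate_frequencies_mhz
        table = np.empty((n_angles, self.per_angle))
        for m in range(n_angles):
            idx = rng.choice(self.grid_size, size=self.per_angle, replace=False)
            table[m] = cand[np.sort(idx)]
        return table


@dataclass(frozen=True)
class MeasurementVector:
    """Complex frequency-domain pressure samples with provenance.

    ``values[m * per_angle + n]`` is the sample at sensor ``m`` and the
    ``n``-th of its selected frequencies.
    """

    values: np.ndarray
    snr_db: float | None = None
    noise_seed: int | None = None

    @property
    def clean(self) -> bool:
        return self.snr_db is None

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ForwardOperator:
    """Dense complex projection matrix plus the geometry that built it.

    Row ``m * per_angle + n`` maps to (sensor m, selected frequency n);
    column order follows :meth:`ImageGrid.pixel_centers`.
    """

    matrix: np.ndarray
    grid: ImageGrid
    sensors: SensorGeometry
    sampling: FrequencySampling
    freq_table_mhz: np.ndarray
    c: float = 1.5

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def apply(self, image: np.ndarray) -> np.ndarray:
        """``Phi @ x`` on a flattened or 2-D image."""
        x = np.asarray(image)
        if x.ndim == 2:
            if x.shape != self.grid.shape:
                raise ValueError(
                    f"image shape {x.shape} does not match grid {self.grid.shape}"
                )
            x = x.ravel()
        elif x.shape != (self.grid.n_pixels,):
            raise ValueError("flat image length does not match the grid")
        # match the matrix dtype: mixed-precision matmul would upcast (and
        # silently copy) the large operator
        return self.matrix @ x.astype(self.matrix.dtype, copy=False)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """``Phi^H @ y`` as a flat complex image-domain vector."""
        y = np.asarray(y)
        if y.shape != (self.n_rows,):
            raise ValueError(
                f"measurement length {y.shape} does not match {self.n_rows} rows"
            )
        # (y^H Phi)^H keeps the product cache-friendly for C-ordered Phi.
        y = y.astype(self.matrix.dtype, copy=False)
        return np.conj(np.conj(y) @ self.matrix)


def build_forward_matrix(
    grid: ImageGrid,
    sensors: SensorGeometry,
    freqs: FrequencySampling,
    c: float = 1.5,
    dtype: np.dtype | type = np.complex64,
) -> ForwardOperator:
    """Assemble the frequency-domain projection matrix for a geometry.

    Parameters
    ----------
    c
        Sound speed in mm/us (default 1.5, i.e. 1500 m/s).
    dtype
        ``complex64`` by default (the 2560x16384 full protocol stays under
        a gigabyte); pass ``complex128`` for high-precision small builds.
        Entries are always computed in double precision before casting.
    """
    if c <= 0:
        raise ValueError("sound speed must be positive")
    if sensors.radius_mm <= grid.half_diagonal_mm:
        raise GeometryError(
            f"sensor radius {sensors.radius_mm} mm must exceed the field-of-view "
            f"half-diagonal {grid.half_diagonal_mm:.2f} mm"
        )
    table = freqs.draw(sensors.count)
    pix = grid.pixel_centers()
    pos = sensors.positions
    n_rows = sensors.count * freqs.per_angle
    matrix = np.empty((n_rows, grid.n_pixels), dtype=dtype)
    k_table = 2.0 * np.pi * table / c  # rad/mm
    for m in range(sensors.count):
        d = np.hypot(pix[:, 0] - pos[m, 0], pix[:, 1] - pos[m, 1])
        k = k_table[m][:, None]
        block = (-1j * c) * k * np.exp(1j * k * d[None, :]) / d[None, :]
        matrix[m * freqs.per_angle : (m + 1) * freqs.per_angle] = block
    if not np.all(np.isfinite(matrix)):
        raise GeometryError("non-finite operator entries (sensor on a pixel?)")
    return ForwardOperator(
        matrix=matrix,
        grid=grid,
        sensors=sensors,
        sampling=freqs,
        freq_table_mhz=table,
        c=c,
    )


def apply_forward(op: ForwardOperator, image: np.ndarray | Any) -> MeasurementVector:
    """Simulate clean measurements ``y = Phi x`` for an image or Phantom."""
    img = getattr(image, "image", image)
    return MeasurementVector(values=op.apply(np.asarray(img, dtype=float)))


def apply_adjoint(op: ForwardOperator, y: MeasurementVector | np.ndarray) -> np.ndarray:
    """``Phi^H y``; the backprojection-like image-domain correlate of y."""
    values = y.values if isinstance(y, MeasurementVector) else np.asarray(y)
    return op.adjoint(values)


@dataclass(frozen=True)
class StackedRealSystem:
    """Real-valued stacking of a complex linear system.

    ``matrix = [[Re A], [Im A]]`` and ``y = [Re b, Im b]`` so that for any
    real coefficient vector ``v``, ``norm(matrix @ v) == abs(A @ v)`` and
    ``matrix.T @ u == Re(A^H (u_re + 1j u_im))``.  Keeps the L1 solvers in
    real arithmetic while fitting complex frequency-domain data.
    """

    matrix: np.ndarray
    y: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ v

    def rmatvec(self, u: np.ndarray) -> np.ndarray:
        return self.matrix.T @ u

    def to_complex(self) -> tuple[np.ndarray, np.ndarray]:
        """Recombine the stacked halves into the original complex system."""
        m = self.matrix.shape[0] // 2
        return (
            self.matrix[:m] + 1j * self.matrix[m:],
            self.y[:m] + 1j * self.y[m:],
        )


def to_stacked_real(A: np.ndarray, y: np.ndarray) -> StackedRealSystem:
    """Stack a complex matrix/vector pair into an equivalent real system."""
    A = np.atleast_2d(np.asarray(A))
    y = np.asarray(y)
    if y.shape != (A.shape[0],):
        raise ValueError("matrix rows and measurement length differ")
    return StackedRealSystem(
        matrix=np.concatenate([A.real, A.imag], axis=0),
        y=np.concatenate([y.real, y.imag]),
    )


@dataclass(frozen=True)
class WhitenedOperator:
    """Row-orthonormalised (whitened) view of a forward operator.

    Left-preconditioning with ``(Phi Phi^H + eps I)^{-1/2}`` (computed via
    Cholesky) makes the measurement rows near-orthonormal.  For noiseless
    data the equation set -- and hence the basis-pursuit solution -- is
    unchanged, while first-order L1 solvers converge in tens rather than
    thousands of iterations: the raw frequency-domain rows are strongly
    correlated (nearby frequencies at one sensor see almost the same
    image), which otherwise makes the augmented-Lagrangian dual crawl.
    """

    matrix: np.ndarray
    grid: ImageGrid
    chol_factor: np.ndarray
    eps: float

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def apply(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image)
        if x.ndim == 2:
            x = x.ravel()
        return self.matrix @ x.astype(self.matrix.dtype, copy=False)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y).astype(self.matrix.dtype, copy=False)
        return np.conj(np.conj(y) @ self.matrix)

    def whiten_measurement(self, y: MeasurementVector | np.ndarray) -> np.ndarray:
        from scipy.linalg import solve_triangular

        values = y.values if isinstance(y, MeasurementVector) else np.asarray(y)
        return solve_triangular(
            self.chol_factor, values.astype(np.complex128), lower=True
        )

    def noise_gain(self, n_probes: int = 8, seed: int = 0) -> float:
        """Stochastic estimate of ``||L^{-1}||_F^2``.

        White measurement noise of per-component variance ``sigma^2`` has
        expected power ``2 sigma^2 * noise_gain()`` after whitening; used
        to convert a nominal measurement SNR into the effective SNR of
        the whitened system.
        """
        from scipy.linalg import solve_triangular

        rng = np.random.default_rng(seed)
        m = self.n_rows
        total = 0.0
        for _ in range(n_probes):
            z = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / np.sqrt(2)
            w = solve_triangular(self.chol_factor, z, lower=True)
            total += float(np.vdot(w, w).real)
        return total / n_probes


def whiten_operator(op: ForwardOperator, eps: float = 1e-10) -> WhitenedOperator:
    """Build the row-whitened operator ``L^{-1} Phi`` with ``L L^H = Phi
    Phi^H + eps * mean(diag) * I``.

    ``eps`` regularises the rank-deficient Gram (limited view and band
    limits leave near-null measurement directions).  The dense triangular
    solve runs blockwise to bound peak memory; the result is stored in
    single precision like the default operator build.
    """
    from scipy.linalg import cholesky, solve_triangular

    m = op.n_rows
    block = 2048
    # accumulate the Gram in double precision blockwise: the eigenvalue
    # spread exceeds single-precision resolution
    gram = np.zeros((m, m), dtype=np.complex128)
    for j in range(0, op.grid.n_pixels, block):
        cols = op.matrix[:, j : j + block].astype(np.complex128)
        gram += cols @ cols.conj().T
    shift = eps * float(np.mean(gram.diagonal().real))
    gram[np.diag_indices_from(gram)] += shift
    L = cholesky(gram, lower=True)
    white = np.empty((m, op.grid.n_pixels), dtype=np.complex64)
    for j in range(0, op.grid.n_pixels, block):
        cols = op.matrix[:, j : j + block].astype(np.complex128)
        white[:, j : j + block] = solve_triangular(L, cols, lower=True)
    return WhitenedOperator(matrix=white, grid=op.grid, chol_factor=L, eps=eps)


class StackedOperatorSystem:
    """Matrix-implicit stacked-real view of ``Phi Psi^{-1}``.

    Presents the ``shape`` / ``matvec`` / ``rmatvec`` interface of
    :class:`StackedRealSystem` without forming the doubled real matrix:
    the complex operator is applied directly and real/imaginary parts are
    concatenated.  ``transform`` supplies the orthonormal sparsifier
    (``analysis`` / ``synthesis``); ``None`` means pixel-domain identity.
    """

    def __init__(self, op: ForwardOperator, transform: Any | None = None) -> None:
        self.op = op
        self.transform = transform
        self.shape = (2 * op.n_rows, op.grid.n_pixels)

    def matvec(self, theta: np.ndarray) -> np.ndarray:
        if self.transform is not None:
            x = self.transform.synthesis(theta).ravel()
        else:
            x = np.asarray(theta, dtype=float)
        w = self.op.apply(x)
        return np.concatenate([w.real, w.imag]).astype(float)

    def rmatvec(self, u: np.ndarray) -> np.ndarray:
        m = self.op.n_rows
        w = u[:m] + 1j * u[m:]
        z = self.op.adjoint(w).real
        if self.transform is not None:
            return self.transform.analysis(z.reshape(self.op.grid.shape))
        return z

    def stack_measurement(self, y: MeasurementVector | np.ndarray) -> np.ndarray:
        values = y.values if isinstance(y, MeasurementVector) else np.asarray(y)
        return np.concatenate([values.real, values.imag]).astype(float)
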