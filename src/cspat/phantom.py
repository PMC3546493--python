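"""Sparse disk phantoms and measurement-noise injection.

The simulation phantom is a handful of compact circular absorbers on an
otherwise empty field of view -- the classic sparse target used to probe
limited-view compressed-sensing recovery.  Disks keep the ground truth
analytic (centres, radii, intensities are recorded alongside the image)
and the phantom sparse both in the pixel domain and under wavelets.
Intensities are affinely rescaled to [0, 1] before measurements are
simulated.

Measurement noise is white complex Gaussian at a prescribed vector-level
SNR: the noise power budget ``||y||^2 / 10^(SNR_dB/10)`` is split equally
between the real and imaginary parts of every sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward_model import ImageGrid, MeasurementVector

__all__ = [
    "DegenerateInputError",
    "Phantom",
    "NoiseSpec",
    "make_disk_phantom",
    "rescale_unit",
    "add_white_gaussian_noise",
]


class DegenerateInputError(ValueError):
    """Raised for inputs with no usable signal (constant image, zero y)."""


@dataclass(frozen=True)
class Phantom:
    """Ground-truth absorbed-energy image with its analytic descriptor."""

    image: np.ndarray
    absorbers: tuple[dict, ...]
    seed: int
    grid: ImageGrid

    @property
    def support_fraction(self) -> float:
        return float(np.count_nonzero(self.image)) / self.image.size


@dataclass(frozen=True)
class NoiseSpec:
    """White Gaussian measurement noise at a target SNR.

    ``snr_db = None`` is the noiseless sentinel: measurements pass through
    untouched.
    """

    snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite (use None for noiseless)")


def rescale_unit(image: np.ndarray) -> np.ndarray:
    """Affine map of intensities onto [0, 1] (min -> 0, max -> 1)."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise DegenerateInputError("constant image cannot be rescaled to [0, 1]")
    return (image - lo) / (hi - lo)


def make_disk_phantom(
    grid: ImageGrid,
    n_disks: int = 5,
    radius_range_mm: tuple[float, float] = (0.5, 1.5),
    intensity_range: tuple[float, float] = (0.4, 1.0),
    seed: int = 0,
    margin_mm: float | None = None,
) -> Phantom:
    """Draw ``n_disks`` circular absorbers at seeded random positions.

    Disk centres are uniform over the field of view shrunk by
    ``margin_mm`` (default: the largest radius plus one pixel) so every
    absorber lies fully inside the image.  Overlapping disks take the
    maximum intensity; the final image is rescaled to [0, 1].
    """
    if n_disks < 1:
        raise ValueError("need at least one disk")
    r_lo, r_hi = radius_range_mm
    if not (0 < r_lo <= r_hi):
        raise ValueError("radius range must satisfy 0 < lo <= hi")
    if margin_mm is None:
        margin_mm = r_hi + grid.pixel_size_mm
    half_x = grid.nx * grid.pixel_size_mm / 2 - margin_mm
    half_y = grid.ny * grid.pixel_size_mm / 2 - margin_mm
    if half_x <= 0 or half_y <= 0:
        raise ValueError("disk radii too large for the field of view")

    rng = np.random.default_rng(seed)
    xx, yy = np.meshgrid(grid.x_mm, grid.y_mm)
    image = np.zeros(grid.shape)
    absorbers = []
    for _ in range(n_disks):
        cx = rng.uniform(-half_x, half_x)
        cy = rng.uniform(-half_y, half_y)
        radius = rng.uniform(r_lo, r_hi)
        intensity = rng.uniform(*intensity_range)
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        image[mask] = np.maximum(image[mask], intensity)
        absorbers.append(
            {
                "center_mm": [float(cx), float(cy)],
                "radius_mm": float(radius),
                "intensity": float(intensity),
            }
        )
    image = rescale_unit(image)
    return Phantom(image=image, absorbers=tuple(absorbers), seed=seed, grid=grid)


def add_white_gaussian_noise(
    y: MeasurementVector, spec: NoiseSpec
) -> MeasurementVector:
    """Corrupt measurements with white Gaussian noise at ``spec.snr_db``.

    The per-component standard deviation is chosen so the expected total
    noise power satisfies ``10 log10(||y||^2 / E||n||^2) = snr_db`` over
    the whole complex vector.
    """
    if spec.snr_db is None:
        return y
    values = y.values
    power = float(np.vdot(values, values).real)
    if power == 0.0:
        raise DegenerateInputError("cannot set an SNR on a zero measurement vector")
    n = len(values)
    sigma = np.sqrt(power * 10.0 ** (-spec.snr_db / 10.0) / (2 * n))
    rng = np.random.default_rng(spec.seed)
    noise = sigma * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return MeasurementVector(
        values=values + noise, snr_db=spec.snr_db, noise_seed=spec.seed
    )
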