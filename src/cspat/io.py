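"""Persistence: HDF5 measurement containers, image files, JSON configs.

The HDF5 container stores the forward operator (real/imag parts), the
sensor/frequency geometry that built it, the sound speed and the seed, so
a reconstruction can be re-run from the file alone.  Phantoms and
reconstructions are written as 16-bit TIFFs with a JSON sidecar carrying
the analytic descriptor and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .forward_model import (
    ForwardOperator,
    FrequencySampling,
    ImageGrid,
    MeasurementVector,
    SensorGeometry,
)
from .phantom import Phantom

__all__ = [
    "save_measurements",
    "load_measurements",
    "write_image",
    "read_image",
    "save_phantom",
    "load_phantom",
    "grid_from_config",
    "sensors_from_config",
    "sampling_from_config",
    "load_config",
]


def save_measurements(
    path: str | Path, op: ForwardOperator, y: MeasurementVector
) -> None:
    """Write operator + measurements (+ provenance) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix_real", data=op.matrix.real)
        f.create_dataset("matrix_imag", data=op.matrix.imag)
        f.create_dataset("sensor_positions_mm", data=op.sensors.positions)
        f.create_dataset("frequency_table_mhz", data=op.freq_table_mhz)
        f.create_dataset("y_real", data=y.values.real)
        f.create_dataset("y_imag", data=y.values.imag)
        f.attrs["c_mm_per_us"] = op.c
        f.attrs["nx"] = op.grid.nx
        f.attrs["ny"] = op.grid.ny
        f.attrs["fov_mm"] = op.grid.fov_mm
        f.attrs["sensor_radius_mm"] = op.sensors.radius_mm
        f.attrs["span_deg"] = op.sensors.span_deg
        f.attrs["sensor_count"] = op.sensors.count
        f.attrs["start_deg"] = op.sensors.start_deg
        for key in ("grid_size", "f_min_mhz", "f_max_mhz", "per_angle", "seed"):
            f.attrs[f"sampling_{key}"] = getattr(op.sampling, key)
        f.attrs["snr_db"] = np.nan if y.snr_db is None else y.snr_db
        f.attrs["noise_seed"] = -1 if y.noise_seed is None else y.noise_seed


def load_measurements(path: str | Path) -> tuple[ForwardOperator, MeasurementVector]:
    with h5py.File(path, "r") as f:
        matrix = f["matrix_real"][...] + 1j * f["matrix_imag"][...]
        grid = ImageGrid(
            nx=int(f.attrs["nx"]), ny=int(f.attrs["ny"]),
            fov_mm=float(f.attrs["fov_mm"]),
        )
        sensors = SensorGeometry(
            radius_mm=float(f.attrs["sensor_radius_mm"]),
            span_deg=float(f.attrs["span_deg"]),
            count=int(f.attrs["sensor_count"]),
            start_deg=float(f.attrs["start_deg"]),
        )
        sampling = FrequencySampling(
            grid_size=int(f.attrs["sampling_grid_size"]),
            f_min_mhz=float(f.attrs["sampling_f_min_mhz"]),
            f_max_mhz=float(f.attrs["sampling_f_max_mhz"]),
            per_angle=int(f.attrs["sampling_per_angle"]),
            seed=int(f.attrs["sampling_seed"]),
        )
        op = ForwardOperator(
            matrix=matrix, grid=grid, sensors=sensors, sampling=sampling,
            freq_table_mhz=f["frequency_table_mhz"][...],
            c=float(f.attrs["c_mm_per_us"]),
        )
        snr = float(f.attrs["snr_db"])
        noise_seed = int(f.attrs["noise_seed"])
        y = MeasurementVector(
            values=f["y_real"][...] + 1j * f["y_imag"][...],
            snr_db=None if np.isnan(snr) else snr,
            noise_seed=None if noise_seed < 0 else noise_seed,
        )
    return op, y


def write_image(path: str | Path, image: np.ndarray) -> None:
    """16-bit TIFF; intensities are linearly mapped from [0, 1]."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    tifffile.imwrite(path, np.round(arr * 65535).astype(np.uint16))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float) / 65535.0


def save_phantom(path: str | Path, phantom: Phantom) -> None:
    """TIFF image + ``.json`` sidecar with absorbers, seed and grid."""
    path = Path(path)
    write_image(path, phantom.image)
    sidecar = {
        "absorbers": list(phantom.absorbers),
        "seed": phantom.seed,
        "grid": {"nx": phantom.grid.nx, "ny": phantom.grid.ny,
                 "fov_mm": phantom.grid.fov_mm},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path: str | Path) -> Phantom:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Phantom(
        image=read_image(path),
        absorbers=tuple(meta["absorbers"]),
        seed=meta["seed"],
        grid=ImageGrid(**meta["grid"]),
    )


def load_config(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def grid_from_config(cfg: dict) -> ImageGrid:
    return ImageGrid(**cfg.get("grid", {}))


def sensors_from_config(cfg: dict) -> SensorGeometry:
    return SensorGeometry(**cfg.get("sensors", {}))


def sampling_from_config(cfg: dict) -> FrequencySampling:
    return FrequencySampling(**cfg.get("sampling", {}))
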