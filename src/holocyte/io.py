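"""Shared file I/O: OPD maps/stacks and holograms with sampling metadata.

Arrays travel as multi-page TIFF (32-bit float, shaped metadata in the
image description) or HDF5 (dataset ``data`` with attributes). The
required metadata keys are ``pixel_pitch_um`` and ``wavelength_nm``, plus
``frame_rate_hz`` for time stacks; readers fail loudly, naming any missing
key. Holograms are written as 16-bit grayscale TIFF with a YAML sidecar
carrying the optical configuration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .forward import Hologram, NoiseModel, OpticalConfig

__all__ = [
    "REQUIRED_KEYS",
    "write_image_stack",
    "read_image_stack",
    "write_hologram",
    "read_hologram",
]

REQUIRED_KEYS = ("pixel_pitch_um", "wavelength_nm")
STACK_KEYS = REQUIRED_KEYS + ("frame_rate_hz",)


def _required_for(data: np.ndarray) -> tuple[str, ...]:
    return STACK_KEYS if data.ndim == 3 else REQUIRED_KEYS


def _check_metadata(meta: dict, data: np.ndarray) -> dict:
    missing = [k for k in _required_for(data) if k not in meta or meta[k] is None]
    if missing:
        raise KeyError(f"missing required metadata keys: {missing}")
    return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in meta.items()}


def write_image_stack(path: str | Path, data: np.ndarray, metadata: dict) -> Path:
    """Write a 2-D map or 3-D stack with metadata; format from the suffix."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (2, 3):
        raise ValueError("data must be 2-D or 3-D")
    metadata = _check_metadata(metadata, data)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data.astype(np.float32), metadata=metadata)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("data", data=data)
            for k, v in metadata.items():
                ds.attrs[k] = v
    else:
        raise ValueError(f"unsupported format {path.suffix!r}")
    return path


def read_image_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a map/stack and its metadata; validates shapes and keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                bad = next(
                    i for i, p in enumerate(tif.pages)
                    if p.shape != tif.pages[0].shape
                )
                raise ValueError(f"inconsistent frame shape at page {bad}")
            data = tif.asarray()
            meta = dict(tif.shaped_metadata[0]) if tif.shaped_metadata else {}
        meta.pop("shape", None)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["data"]
            data = ds[...]
            meta = {k: v for k, v in ds.attrs.items()}
    else:
        raise ValueError(f"unsupported format {path.suffix!r}")
    data = np.asarray(data, dtype=float)
    meta = _check_metadata(meta, data)
    return data, meta


def write_hologram(path: str | Path, holo: Hologram) -> Path:
    """16-bit grayscale TIFF plus a YAML sidecar with the optical config."""
    path = Path(path)
    peak = float(holo.data.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    tifffile.imwrite(path, np.round(holo.data * scale).astype(np.uint16))
    cfg = dataclasses.asdict(holo.config)
    if cfg.get("noise_model") is not None:
        cfg["noise_model"] = dataclasses.asdict(holo.config.noise_model)
    sidecar = {
        "optical_config": cfg,
        "intensity_scale": scale,
        "clipped_px": holo.clipped_px,
        "noise_seed": holo.noise_seed,
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
    return path


def read_hologram(path: str | Path) -> Hologram:
    """Read a hologram TIFF + YAML sidecar back into a :class:`Hologram`."""
    path = Path(path)
    sidecar_path = path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing YAML sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = yaml.safe_load(fh)
    cfg_dict = dict(sidecar["optical_config"])
    nm = cfg_dict.pop("noise_model", None)
    cfg = OpticalConfig(
        **cfg_dict, noise_model=NoiseModel(**nm) if nm else None
    )
    data = tifffile.imread(path).astype(float) / float(sidecar["intensity_scale"])
    return Hologram(
        data, cfg,
        clipped_px=int(sidecar.get("clipped_px", 0)),
        noise_seed=sidecar.get("noise_seed"),
    )
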