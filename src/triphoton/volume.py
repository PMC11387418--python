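"""Volumetric image container and TIFF/OME-TIFF I/O.

The package-wide axis convention is ``(t, z, y, x)`` for time-lapse data and
``(z, y, x)`` for single stacks.  ``y`` is the scan (line) axis: one row of a
z-slice is one detector line, which is why the structured-noise tools index
rows as ``(z, y)`` and operate along ``x``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNELS = ("mGFP", "THG", "label", "probability")

_SUPPORTED_DTYPES = (
    np.dtype("float32"),
    np.dtype("float64"),
    np.dtype("uint8"),
    np.dtype("uint16"),
    np.dtype("uint32"),
)


@dataclass
class Volume:
    """A 3D ``(z, y, x)`` or 4D ``(t, z, y, x)`` intensity grid with metadata.

    Parameters
    ----------
    data:
        Intensity grid, float or unsigned integer.
    voxel_size_um:
        Physical voxel size ``(z, y, x)`` in micrometres; all entries > 0.
    channel:
        One of ``{"mGFP", "THG", "label", "probability"}``.
    provenance:
        Append-only log of operations applied to this volume, each entry a
        ``{"op": name, **parameters}`` mapping.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = "THG"
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"Volume data must be 3D (z,y,x) or 4D (t,z,y,x), got {self.data.ndim}D"
            )
        if self.data.dtype not in _SUPPORTED_DTYPES:
            raise ValueError(
                f"unsupported dtype {self.data.dtype}; use float32/float64 or "
                "an unsigned integer type"
            )
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive floats, got {vs}")
        self.voxel_size_um = vs
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def is_timelapse(self) -> bool:
        return self.data.ndim == 4

    def log(self, op: str, **params) -> "Volume":
        """Append an operation record to the provenance log (in place)."""
        self.provenance.append({"op": op, **params})
        return self

    def with_data(self, data: np.ndarray, op: str | None = None, **params) -> "Volume":
        """Return a new Volume sharing metadata, with ``data`` replaced."""
        out = Volume(
            data=data,
            voxel_size_um=self.voxel_size_um,
            channel=self.channel,
            provenance=list(self.provenance),
        )
        if op is not None:
            out.log(op, **params)
        return out


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF plus a JSON metadata sidecar.

    The sidecar records voxel size, channel tag and the provenance log, so a
    written volume round-trips losslessly through :func:`read_volume`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    zsize, ysize, xsize = vol.voxel_size_um
    tifffile.imwrite(
        path,
        vol.data,
        metadata={
            "axes": "TZYX" if vol.is_timelapse else "ZYX",
            "PhysicalSizeZ": zsize,
            "PhysicalSizeY": ysize,
            "PhysicalSizeX": xsize,
        },
    )
    sidecar = {
        "voxel_size_um": list(vol.voxel_size_um),
        "channel": vol.channel,
        "shape": list(vol.data.shape),
        "dtype": str(vol.data.dtype),
        "provenance": vol.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_volume(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channel: str | None = None,
) -> Volume:
    """Read a TIFF/OME-TIFF volume.

    Voxel size is taken from (in order of priority) the ``voxel_size_um``
    argument, the JSON sidecar written by :func:`write_volume`, or OME
    ``PhysicalSize*`` metadata.  If none is available an error instructs the
    caller to pass the size explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ome_vs = _ome_voxel_size(tf)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"could not read TIFF file {path}: {exc}") from exc
    if data.dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {data.dtype} in {path}")

    sidecar = None
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())

    vs = voxel_size_um
    if vs is None and sidecar is not None:
        vs = tuple(sidecar["voxel_size_um"])
    if vs is None:
        vs = ome_vs
    if vs is None:
        raise ValueError(
            f"no voxel size found for {path}: pass voxel_size_um= (or use the "
            "--voxel-size flag on the command line)"
        )
    ch = channel
    if ch is None and sidecar is not None:
        ch = sidecar.get("channel")
    if ch is None:
        ch = "THG"
    prov = sidecar.get("provenance", []) if sidecar is not None else []
    return Volume(data=data, voxel_size_um=vs, channel=ch, provenance=prov)


def _ome_voxel_size(tf: "tifffile.TiffFile"):
    meta = None
    if tf.shaped_metadata:
        meta = tf.shaped_metadata[0]
    elif tf.imagej_metadata:
        meta = tf.imagej_metadata
    if meta is None and tf.ome_metadata:
        import re

        m = {}
        for ax in "ZYX":
            hit = re.search(rf'PhysicalSize{ax}="([0-9.eE+-]+)"', tf.ome_metadata)
            if hit:
                m[f"PhysicalSize{ax}"] = float(hit.group(1))
        meta = m
    if not meta:
        return None
    try:
        return (
            float(meta["PhysicalSizeZ"]),
            float(meta["PhysicalSizeY"]),
            float(meta["PhysicalSizeX"]),
        )
    except (KeyError, TypeError):
        return None


def as_array(vol) -> np.ndarray:
    """Accept a Volume or a bare ndarray and return the ndarray view."""
    if isinstance(vol, Volume):
        return vol.data
    return np.asarray(vol)
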