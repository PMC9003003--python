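"""Volume data model, axis conventions, reslicing and TIFF I/O.

Index semantics throughout the package:

* ``OCTVolume4D.data[x, y, t, z]`` — x: A-scan index within a B-scan,
  y: depth sample, t: repeat frame at the same position, z: B-scan index.
* ``Volume3D.data[x, y, z]`` — t reduced away (single frame or composite).
* ``EnFaceStack.data[x, z, y]`` — C-scan order: each ``[:, :, j]`` slice is
  an en-face plane at depth j.

Coordinates are 0-based with half-open extents. On disk a volume is a
multi-page grayscale TIFF (one page per B-scan, repeat frames interleaved
fastest) plus an optional JSON sidecar carrying voxel spacing and layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "OCTVolume4D",
    "Volume3D",
    "EnFaceStack",
    "TiffLayout",
    "read_volume",
    "write_stack",
    "reslice_to_enface",
    "reslice_from_enface",
    "reslice_virtual_bscan",
]

_PROVENANCES = ("raw_single_frame", "mean_composite", "stdev_composite")


def _check_spacing(dx: float, dy: float, dz: float) -> None:
    if not (dx > 0 and dy > 0 and dz > 0):
        raise ValueError(f"voxel spacing must be positive, got dx={dx}, dy={dy}, dz={dz}")


@dataclass
class OCTVolume4D:
    """Raw intensity cube indexed ``[x, y, t, z]`` with spacing metadata.

    ``data`` is real intensity unless ``is_complex`` is set, in which case it
    is a complex-valued array whose squared magnitude is the intensity.
    """

    data: np.ndarray
    dx: float = 1.4
    dy: float = 1.9
    dz: float = 1.4
    bit_depth: int = 8
    is_complex: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D [x,y,t,z] data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all four extents must be >= 1")
        _check_spacing(self.dx, self.dy, self.dz)
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.is_complex != np.iscomplexobj(self.data):
            raise ValueError("is_complex flag inconsistent with data dtype")
        if not self.is_complex:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < 0:
                raise ValueError("intensities must be non-negative")
            if np.issubdtype(self.data.dtype, np.integer) and hi > 2 ** self.bit_depth - 1:
                raise ValueError(
                    f"intensity {hi} exceeds {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def intensity(self) -> "OCTVolume4D":
        """Squared-magnitude intensity of a complex volume (identity if real)."""
        if not self.is_complex:
            return self
        return replace(self, data=np.abs(self.data) ** 2, is_complex=False)


@dataclass
class Volume3D:
    """Frame-reduced cube indexed ``[x, y, z]``."""

    data: np.ndarray
    dx: float = 1.4
    dy: float = 1.9
    dz: float = 1.4
    provenance: str = "raw_single_frame"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D [x,y,z] data, got ndim={self.data.ndim}")
        _check_spacing(self.dx, self.dy, self.dz)
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class EnFaceStack:
    """C-scan cube indexed ``[x, z, y]``; slice index along the last axis is depth."""

    data: np.ndarray
    dx: float = 1.4
    dy: float = 1.9
    dz: float = 1.4
    provenance: str = "raw_single_frame"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D [x,z,y] data, got ndim={self.data.ndim}")
        _check_spacing(self.dx, self.dy, self.dz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        """Number of en-face (depth) slices."""
        return self.data.shape[2]

    def slice(self, j: int) -> np.ndarray:
        """En-face plane at depth index ``j`` (a ``[x, z]`` view)."""
        return self.data[:, :, j]


@dataclass
class TiffLayout:
    """Page ordering of a multi-page TIFF: z-major, t interleaved fastest.

    Page ``p`` holds frame ``t = p % n_frames`` of B-scan ``z = p // n_frames``
    and is stored as a ``[y, x]`` image (rows are depth).
    """

    n_frames: int = 1
    dx: float = 1.4
    dy: float = 1.9
    dz: float = 1.4
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def layout_from_sidecar(path: str | Path) -> TiffLayout | None:
    """Load a :class:`TiffLayout` from ``<path>.json`` if present."""
    sc = _sidecar_path(Path(path))
    if not sc.exists():
        return None
    meta = json.loads(sc.read_text())
    return TiffLayout(
        n_frames=int(meta.get("n_frames_t", 1)),
        dx=float(meta.get("dx_um", 1.4)),
        dy=float(meta.get("dy_um", 1.9)),
        dz=float(meta.get("dz_um", 1.4)),
        bit_depth=meta.get("bit_depth"),
    )


def read_volume(path: str | Path, layout: TiffLayout | None = None) -> OCTVolume4D:
    """Read a multi-page grayscale TIFF into an ``[x, y, t, z]`` volume.

    ``layout`` defaults to the JSON sidecar next to ``path``, else a
    single-frame layout. Two-channel float pages (real, imaginary) produce a
    complex volume.
    """
    path = Path(path)
    if layout is None:
        layout = layout_from_sidecar(path) or TiffLayout()
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    is_complex = False
    if pages.ndim == 4:
        if pages.shape[1] != 2:
            raise ValueError(f"expected 2-channel complex pages, got shape {pages.shape}")
        pages = pages[:, 0].astype(np.float64) + 1j * pages[:, 1].astype(np.float64)
        is_complex = True
    elif pages.ndim != 3:
        raise ValueError(f"unsupported TIFF shape {pages.shape}")
    n_pages = pages.shape[0]
    if n_pages % layout.n_frames != 0:
        raise ValueError(
            f"page count {n_pages} not divisible by n_frames={layout.n_frames}"
        )
    n_z = n_pages // layout.n_frames
    # [z, t, y, x] -> [x, y, t, z]
    data = pages.reshape(n_z, layout.n_frames, *pages.shape[1:]).transpose(3, 2, 1, 0)
    if layout.bit_depth is not None:
        bit_depth = int(layout.bit_depth)
    elif pages.dtype == np.uint16:
        bit_depth = 16
    else:
        bit_depth = 8
    return OCTVolume4D(
        data=data, dx=layout.dx, dy=layout.dy, dz=layout.dz,
        bit_depth=bit_depth, is_complex=is_complex,
    )


def write_stack(stack: "EnFaceStack | Volume3D | OCTVolume4D", path: str | Path) -> None:
    """Write a volume as a multi-page TIFF, one page per leading slice.

    * ``Volume3D`` — one ``[y, x]`` page per z (B-scan order).
    * ``EnFaceStack`` — one ``[z, x]`` page per depth slice.
    * ``OCTVolume4D`` — B-scan pages with t interleaved (:class:`TiffLayout`
      order); complex volumes are written as 2-channel float pages.

    A JSON sidecar with spacing/layout is written next to the TIFF. Integer
    data round-trips bit-exactly through :func:`read_volume`.
    """
    path = Path(path)
    n_frames = 1
    if isinstance(stack, OCTVolume4D):
        n_frames = stack.n_frames
        # [x, y, t, z] -> [z, t, y, x] -> pages
        pages = stack.data.transpose(3, 2, 1, 0)
        pages = pages.reshape(-1, *pages.shape[2:])
        bit_depth = stack.bit_depth
        if stack.is_complex:
            pages = np.stack([pages.real, pages.imag], axis=1).astype(np.float32)
    elif isinstance(stack, Volume3D):
        pages = stack.data.transpose(2, 1, 0)  # [z, y, x]
        bit_depth = 16 if pages.dtype == np.uint16 else 8
    elif isinstance(stack, EnFaceStack):
        pages = stack.data.transpose(2, 1, 0)  # [y, z, x]
        bit_depth = 16 if pages.dtype == np.uint16 else 8
    else:
        raise TypeError(f"cannot write object of type {type(stack).__name__}")
    tifffile.imwrite(path, pages)
    meta = {
        "dx_um": stack.dx, "dy_um": stack.dy, "dz_um": stack.dz,
        "n_frames_t": n_frames, "bit_depth": bit_depth,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def reslice_to_enface(v: Volume3D) -> EnFaceStack:
    """Reslice ``[x, y, z]`` to C-scan order ``[x, z, y]``.

    Pure axis permutation — no interpolation, voxel values preserved exactly.
    """
    return EnFaceStack(
        data=v.data.transpose(0, 2, 1),
        dx=v.dx, dy=v.dy, dz=v.dz, provenance=v.provenance,
    )


def reslice_from_enface(s: EnFaceStack) -> Volume3D:
    """Inverse of :func:`reslice_to_enface`."""
    return Volume3D(
        data=s.data.transpose(0, 2, 1),
        dx=s.dx, dy=s.dy, dz=s.dz, provenance=s.provenance,
    )


def reslice_virtual_bscan(v: Volume3D) -> np.ndarray:
    """Virtual B-scan view ``[z, y, x]`` of an ``[x, y, z]`` volume."""
    return v.data.transpose(2, 1, 0)
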