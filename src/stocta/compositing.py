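"""Frame compositing over t and slab/depth projections.

Compositing reduces the repeat-frame axis by arithmetic mean (structure
preserving) or standard deviation (flow selective; sample convention,
divisor t-1). Projections reduce depth ranges of an en-face stack into 2D
images, optionally color-coding the depth of the brightest voxel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from matplotlib import colors as mcolors

from stocta.volume import EnFaceStack, OCTVolume4D, Volume3D

__all__ = [
    "SlabSpec",
    "composite_frames",
    "project_slab",
    "project_depth_colormap",
    "consecutive_slabs",
    "fire_colormap",
]

_COMPOSITE_PROVENANCE = {
    "single": "raw_single_frame",
    "mean": "mean_composite",
    "stdev": "stdev_composite",
}


@dataclass
class SlabSpec:
    """A depth slab: start slice, physical thickness and reduction method.

    The slab covers ``max(1, floor(thickness_um / dy))`` consecutive depth
    slices starting at ``start_slice``.
    """

    start_slice: int = 0
    thickness_um: float = 60.0
    method: str = "max"

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be positive")
        if self.start_slice < 0:
            raise ValueError("start_slice must be >= 0")
        if self.method not in ("max", "mean", "stdev"):
            raise ValueError(f"unknown projection method {self.method!r}")

    def n_slices(self, dy: float) -> int:
        return max(1, int(self.thickness_um / dy))


def composite_frames(v: OCTVolume4D, method: str = "stdev") -> Volume3D:
    """Reduce the t axis of an ``[x, y, t, z]`` volume to ``[x, y, z]``.

    ``single`` takes frame 0; ``mean`` and ``stdev`` reduce over t per voxel.
    Standard deviation uses the sample convention (divisor t-1) and requires
    t >= 2.
    """
    if method not in _COMPOSITE_PROVENANCE:
        raise ValueError(f"unknown compositing method {method!r}")
    data = v.data
    if v.is_complex:
        data = np.abs(data) ** 2
    if method == "single":
        out = data[:, :, 0, :].astype(np.float64)
    elif method == "mean":
        out = data.mean(axis=2, dtype=np.float64)
    else:
        if v.n_frames < 2:
            raise ValueError("stdev compositing requires t >= 2 frames")
        # subtract frame 0 first (std is shift-invariant): voxels frozen
        # across t come out exactly zero
        rel = data.astype(np.float64) - data[:, :, :1, :]
        out = rel.std(axis=2, ddof=1)
    return Volume3D(
        data=out, dx=v.dx, dy=v.dy, dz=v.dz,
        provenance=_COMPOSITE_PROVENANCE[method],
    )


def _slab_block(s: EnFaceStack, spec: SlabSpec) -> np.ndarray:
    n = spec.n_slices(s.dy)
    if spec.start_slice >= s.n_slices:
        raise ValueError(
            f"slab start {spec.start_slice} beyond stack depth {s.n_slices}"
        )
    stop = min(spec.start_slice + n, s.n_slices)
    return s.data[:, :, spec.start_slice:stop]


def project_slab(s: EnFaceStack, spec: SlabSpec) -> np.ndarray:
    """Project a depth slab of an en-face stack to a 2D ``[x, z]`` image."""
    block = _slab_block(s, spec).astype(np.float64)
    if spec.method == "max":
        return block.max(axis=2)
    if spec.method == "mean":
        return block.mean(axis=2)
    if block.shape[2] < 2:
        raise ValueError("stdev projection needs a slab of >= 2 slices")
    return block.std(axis=2, ddof=1)


def fire_colormap() -> mcolors.Colormap:
    """Black -> blue -> red -> yellow -> white depth LUT."""
    stops = [(0, 0, 0), (0, 0, 1), (1, 0, 0), (1, 1, 0), (1, 1, 1)]
    return mcolors.LinearSegmentedColormap.from_list("fire_depth", stops)


def project_depth_colormap(
    s: EnFaceStack,
    spec: SlabSpec,
    colormap: mcolors.Colormap | None = None,
) -> np.ndarray:
    """Color-coded depth projection of a slab.

    Per pixel: the relative depth of the maximal intensity within the slab
    selects the hue (0 = top of slab, 1 = bottom); brightness is scaled by
    that maximal intensity. Returns an ``[x, z, 3]`` float RGB image in [0, 1].
    """
    if colormap is None:
        colormap = fire_colormap()
    block = _slab_block(s, spec).astype(np.float64)
    n = block.shape[2]
    arg = block.argmax(axis=2)
    peak = block.max(axis=2)
    rel_depth = arg / max(n - 1, 1)
    rgb = np.asarray(colormap(rel_depth))[..., :3]
    vmax = peak.max()
    brightness = peak / vmax if vmax > 0 else np.zeros_like(peak)
    return rgb * brightness[..., None]


def consecutive_slabs(
    s: EnFaceStack,
    start_slice: int = 0,
    thickness_um: float = 60.0,
    method: str = "max",
) -> Iterator[tuple[np.ndarray, SlabSpec, bool]]:
    """Non-overlapping slab projections from ``start_slice`` to the stack end.

    Yields ``(image, spec, is_partial)``; the final slab may cover fewer
    slices than the nominal thickness and is then flagged partial.
    """
    if start_slice >= s.n_slices:
        raise ValueError(f"start slice {start_slice} beyond stack depth {s.n_slices}")
    n = SlabSpec(0, thickness_um, method).n_slices(s.dy)
    start = start_slice
    while start < s.n_slices:
        spec = SlabSpec(start_slice=start, thickness_um=thickness_um, method=method)
        partial = start + n > s.n_slices
        yield project_slab(s, spec), spec, partial
        start += n
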