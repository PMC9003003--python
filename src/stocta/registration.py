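"""Rigid registration of repeat frames and B-scans against bulk motion.

Translation is estimated by Fourier phase cross-correlation with sub-voxel
upsampling; an optional rotation stage does a coarse grid search over small
angles. Sub-voxel shifts are applied by linear interpolation with zero fill
outside the field of view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _sk_rotate

from stocta.volume import OCTVolume4D

__all__ = ["RigidTransform", "estimate_rigid", "register_volume", "apply_rigid"]


@dataclass(frozen=True)
class RigidTransform:
    """In-plane displacement (rows, cols of the frame) plus optional rotation."""

    shift_x: float = 0.0
    shift_y: float = 0.0
    rotation: float = 0.0  # radians

    def __post_init__(self) -> None:
        if not np.isfinite([self.shift_x, self.shift_y, self.rotation]).all():
            raise ValueError("transform parameters must be finite")

    @property
    def is_identity(self) -> bool:
        return self.shift_x == 0.0 and self.shift_y == 0.0 and self.rotation == 0.0


def estimate_rigid(
    reference: np.ndarray,
    moving: np.ndarray,
    allow_rotation: bool = False,
    upsample_factor: int = 20,
    max_rotation: float = 0.05,
) -> RigidTransform:
    """Estimate the transform mapping ``moving`` onto ``reference``.

    Frames are 2D ``[x, y]`` grids of equal extent. Deterministic: a fixed
    input pair always yields the same transform. Degenerate (constant)
    frames yield the identity with a warning.
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError(
            f"frame extents differ: {reference.shape} vs {moving.shape}"
        )
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        warnings.warn("constant frame: returning identity transform", stacklevel=2)
        return RigidTransform()

    best_angle = 0.0
    if allow_rotation:
        angles = np.linspace(-max_rotation, max_rotation, 11)
        best_err = np.inf
        for ang in angles:
            rot = _rotate(moving, ang)
            shift, err, _ = phase_cross_correlation(
                reference, rot, upsample_factor=upsample_factor, normalization=None
            )
            if err < best_err:
                best_err, best_angle = err, float(ang)
        moving_eval = _rotate(moving, best_angle)
    else:
        moving_eval = moving
    shift, _, _ = phase_cross_correlation(
        reference, moving_eval, upsample_factor=upsample_factor, normalization=None
    )
    sx, sy = float(shift[0]), float(shift[1])
    half = max(reference.shape) / 2
    if abs(sx) > half or abs(sy) > half:
        warnings.warn("estimated shift exceeds half the frame extent", stacklevel=2)
    return RigidTransform(shift_x=sx, shift_y=sy, rotation=best_angle)


def _rotate(frame: np.ndarray, angle_rad: float) -> np.ndarray:
    if angle_rad == 0.0:
        return frame
    return _sk_rotate(frame, np.degrees(angle_rad), preserve_range=True, order=1)


def apply_rigid(frame: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Apply a transform to a 2D frame (linear interpolation, zero fill)."""
    out = np.asarray(frame, dtype=np.float64)
    if t.rotation != 0.0:
        out = _rotate(out, t.rotation)
    if t.shift_x != 0.0 or t.shift_y != 0.0:
        out = ndimage.shift(out, (t.shift_x, t.shift_y), order=1, mode="constant", cval=0.0)
    return out


def register_volume(
    v: OCTVolume4D,
    mode: str = "both",
    allow_rotation: bool = False,
    return_transforms: bool = False,
):
    """Align repeat frames (``across_t``), averaged B-scans (``across_z``) or both.

    ``across_t``: within each B-scan position, frames t>=1 are aligned to
    frame 0. ``across_z``: the t-mean of each B-scan is aligned to the t-mean
    of its predecessor; the accumulated shift is applied to every frame of
    that position. Out-of-bounds regions are zero-filled.

    Returns the registered volume (float data), and when
    ``return_transforms`` is set also a dict with per-(z, t) and per-z
    transforms.
    """
    if mode not in ("across_t", "across_z", "both", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    data = v.data.astype(np.float64).copy()
    nx, ny, nt, nz = data.shape
    t_transforms: dict[tuple[int, int], RigidTransform] = {}
    z_transforms: dict[int, RigidTransform] = {}

    if mode in ("across_t", "both") and nt > 1:
        for z in range(nz):
            ref = data[:, :, 0, z]
            for t in range(1, nt):
                tr = estimate_rigid(ref, data[:, :, t, z], allow_rotation=allow_rotation)
                t_transforms[(z, t)] = tr
                if not tr.is_identity:
                    data[:, :, t, z] = apply_rigid(data[:, :, t, z], tr)

    if mode in ("across_z", "both") and nz > 1:
        prev = data[:, :, :, 0].mean(axis=2)
        for z in range(1, nz):
            cur = data[:, :, :, z].mean(axis=2)
            # prev is already registered, so the estimate is the full correction
            tr = estimate_rigid(prev, cur, allow_rotation=allow_rotation)
            z_transforms[z] = tr
            if not tr.is_identity:
                for t in range(nt):
                    data[:, :, t, z] = apply_rigid(data[:, :, t, z], tr)
            prev = data[:, :, :, z].mean(axis=2)

    out = OCTVolume4D(
        data=np.clip(data, 0, None), dx=v.dx, dy=v.dy, dz=v.dz,
        bit_depth=v.bit_depth, is_complex=False,
    )
    if return_transforms:
        return out, {"across_t": t_transforms, "across_z": z_transforms}
    return out


def transforms_to_csv(z_transforms: dict[int, RigidTransform]) -> str:
    """Serialize per-B-scan transforms as CSV (z_index, shift_x, shift_y, rotation)."""
    lines = ["z_index,shift_x,shift_y,rotation"]
    for z in sorted(z_transforms):
        t = z_transforms[z]
        lines.append(f"{z},{t.shift_x:.6g},{t.shift_y:.6g},{t.rotation:.6g}")
    return "\n".join(lines) + "\n"
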