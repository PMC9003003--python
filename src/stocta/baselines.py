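"""Reference OCTA contrasts: speckle variance, phase variance, complex
differential variance.

Phase variance and complex differential variance require complex-valued
input; intensity-only volumes are rejected rather than approximated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from stocta.volume import OCTVolume4D, Volume3D

__all__ = [
    "ComplexVolume4D",
    "speckle_variance",
    "phase_variance",
    "complex_differential_variance",
]


@dataclass
class ComplexVolume4D:
    """Complex OCT field indexed ``[x, y, t, z]``."""

    data: np.ndarray
    dx: float = 1.4
    dy: float = 1.9
    dz: float = 1.4

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 4:
            raise ValueError("expected 4D [x,y,t,z] complex data")
        if not np.isfinite(self.data).all():
            raise ValueError("complex field must be finite")

    @classmethod
    def from_volume(cls, v: OCTVolume4D) -> "ComplexVolume4D":
        if not v.is_complex:
            raise ValueError(
                "phase-based baselines need complex input; intensity-only "
                "volumes are not supported"
            )
        return cls(data=v.data, dx=v.dx, dy=v.dy, dz=v.dz)

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2


def speckle_variance(v: OCTVolume4D) -> Volume3D:
    """Per-voxel inter-frame intensity variance (population convention)."""
    if v.n_frames < 2:
        raise ValueError("speckle variance requires t >= 2 frames")
    data = v.data
    if v.is_complex:
        data = np.abs(data) ** 2
    sv = data.astype(np.float64).var(axis=2, ddof=0)
    return Volume3D(data=sv, dx=v.dx, dy=v.dy, dz=v.dz, provenance="stdev_composite")


def _frame_pairs_phase_diff(data: np.ndarray) -> np.ndarray:
    """Bulk-corrected phase differences between consecutive frames.

    Returns an array of shape [x, y, t-1, z], each value wrapped to
    (-pi, pi]. Bulk motion is removed by subtracting the per-(frame pair, z)
    median phase difference before re-wrapping.
    """
    phase = np.angle(data)
    diff = np.diff(phase, axis=2)
    diff = np.angle(np.exp(1j * diff))  # wrap to (-pi, pi]
    bulk = np.median(diff, axis=(0, 1), keepdims=True)
    return np.angle(np.exp(1j * (diff - bulk)))


def phase_variance(v: "ComplexVolume4D | OCTVolume4D") -> Volume3D:
    """Variance over t of bulk-corrected consecutive-frame phase differences."""
    if isinstance(v, OCTVolume4D):
        v = ComplexVolume4D.from_volume(v)
    if v.n_frames < 2:
        raise ValueError("phase variance requires t >= 2 frames")
    diff = _frame_pairs_phase_diff(v.data)
    pv = np.mean(diff ** 2, axis=2)
    return Volume3D(data=pv, dx=v.dx, dy=v.dy, dz=v.dz, provenance="stdev_composite")


def complex_differential_variance(
    v: "ComplexVolume4D | OCTVolume4D", window: int = 5
) -> Volume3D:
    """Complex differential variance with an axial (y) smoothing window.

    CDV = 1 - |sum_t w * A_t conj(A_{t+1})| / sum_t w * (|A_t|^2 + |A_{t+1}|^2)/2,
    with ``w`` a Gaussian-weighted window along depth. Bounded in [0, 1]:
    0 for identical frames, approaching 1 for decorrelated speckle.
    """
    if isinstance(v, OCTVolume4D):
        v = ComplexVolume4D.from_volume(v)
    if v.n_frames < 2:
        raise ValueError("CDV requires t >= 2 frames")
    if window < 1:
        raise ValueError("window must be >= 1")
    a = v.data
    cross = (a[:, :, :-1, :] * np.conj(a[:, :, 1:, :])).sum(axis=2)
    power = 0.5 * (np.abs(a[:, :, :-1, :]) ** 2 + np.abs(a[:, :, 1:, :]) ** 2).sum(axis=2)
    if window > 1:
        sigma = window / 4.0
        kw = {"mode": "reflect"}
        cross = (
            ndimage.gaussian_filter1d(cross.real, sigma, axis=1, **kw)
            + 1j * ndimage.gaussian_filter1d(cross.imag, sigma, axis=1, **kw)
        )
        power = ndimage.gaussian_filter1d(power, sigma, axis=1, **kw)
    with np.errstate(invalid="ignore", divide="ignore"):
        cdv = 1.0 - np.abs(cross) / power
    cdv = np.nan_to_num(cdv, nan=0.0)
    return Volume3D(
        data=np.clip(cdv, 0.0, 1.0), dx=v.dx, dy=v.dy, dz=v.dz,
        provenance="stdev_composite",
    )
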