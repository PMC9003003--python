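"""The six-step 2.5D en-face vessel enhancement.

Each en-face slice (an ``[x, z]`` plane) passes through, in order:

1. constant background offset subtraction (clamped at zero),
2. Fourier bandpass with horizontal-stripe suppression,
3. smoothing (2D Gaussian, or a 3D median spanning adjacent slices),
4. oriented ridge enhancement with a bank of notched third-derivative
   Gaussian kernels,
5. median filtering to suppress isolated ridge-detection errors,
6. rolling-ball background subtraction.

"Horizontal" stripes are the bulk-motion bands: structures constant along
x and varying along the B-scan index z. All computation is in floating
point; quantization happens only on export. The pipeline is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from stocta.volume import EnFaceStack

__all__ = [
    "PipelineConfig",
    "G3Kernel",
    "STEP_NAMES",
    "estimate_background_rms",
    "subtract_offset",
    "fft_bandpass",
    "smooth",
    "build_g3_bank",
    "ridge_enhance",
    "median_suppress",
    "rollingball_subtract",
    "enhance_slice",
    "enhance_stack",
]

#: Checkpoint labels: the input plus the six processing steps.
STEP_NAMES = (
    "input",
    "offset_subtracted",
    "bandpassed",
    "smoothed",
    "ridge_enhanced",
    "median_filtered",
    "background_subtracted",
)


@dataclass
class PipelineConfig:
    """Tunable parameters of the six-step algorithm.

    Defaults follow the 8-bit retina configuration: background RMS offset 20,
    bandpass scales 40/3 voxels with horizontal stripe suppression, Gaussian
    sigma 2 and 9 kernel orientations.
    """

    rms_offset: float = 20.0
    bandpass_large: float = 40.0
    bandpass_small: float = 3.0
    suppress_stripes: str = "horizontal"
    gaussian_sigma: float = 2.0
    smoothing_mode: str = "gaussian_2d"
    median_3d_window: tuple[int, int, int] = (5, 5, 3)
    n_orientations: int = 9
    kernel_halfwidth: int | None = None
    kernel_elongation: float = 2.0
    notch_width: float = 1.0
    median_radius: int = 1
    rollingball_radius: float = 25.0

    def __post_init__(self) -> None:
        if self.bandpass_large <= self.bandpass_small:
            raise ValueError("bandpass_large must exceed bandpass_small")
        if self.bandpass_small <= 0:
            raise ValueError("bandpass scales must be positive")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")
        if self.median_radius < 1:
            raise ValueError("median_radius must be >= 1")
        if self.rollingball_radius <= 0:
            raise ValueError("rollingball_radius must be positive")
        if self.suppress_stripes not in ("horizontal", "none"):
            raise ValueError(f"unknown stripe mode {self.suppress_stripes!r}")
        if self.smoothing_mode not in ("gaussian_2d", "median_3d"):
            raise ValueError(f"unknown smoothing mode {self.smoothing_mode!r}")
        if self.rms_offset < 0:
            raise ValueError("rms_offset must be >= 0")
        self.median_3d_window = tuple(int(w) for w in self.median_3d_window)
        if len(self.median_3d_window) != 3 or min(self.median_3d_window) < 1:
            raise ValueError("median_3d_window must be three positive ints")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["median_3d_window"] = list(self.median_3d_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config fields: {sorted(extra)}")
        return cls(**d)


@dataclass(frozen=True)
class G3Kernel:
    """One oriented ridge kernel: zero-sum, finite support, central notch."""

    weights: np.ndarray
    orientation: float  # radians, vessel-axis angle from the x array axis
    sigma: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        tol = 1e-6 * np.abs(w).max()
        if abs(w.sum()) > tol:
            raise ValueError("kernel weights must sum to zero")


def estimate_background_rms(
    s: "EnFaceStack | np.ndarray", background_region: np.ndarray | None = None
) -> float:
    """Root-mean-square intensity of the non-tissue background.

    With no explicit mask the darkest decile of voxels is used.
    """
    data = s.data if isinstance(s, EnFaceStack) else np.asarray(s)
    data = data.astype(np.float64)
    if background_region is not None:
        region = np.asarray(background_region, dtype=bool)
        if region.shape != data.shape:
            raise ValueError("background mask shape mismatch")
        vals = data[region]
        if vals.size == 0:
            raise ValueError("background region is empty")
    else:
        cutoff = np.quantile(data, 0.1)
        vals = data[data <= cutoff]
    return float(np.sqrt(np.mean(vals ** 2)))


def subtract_offset(slice_: np.ndarray, offset: float) -> np.ndarray:
    """``max(value - offset, 0)`` elementwise."""
    return np.clip(np.asarray(slice_, dtype=np.float64) - offset, 0.0, None)


def fft_bandpass(
    slice_: np.ndarray,
    large: float = 40.0,
    small: float = 3.0,
    suppress: str = "horizontal",
    stripe_tolerance: float = 0.05,
) -> np.ndarray:
    """Fourier bandpass keeping structure between ``small`` and ``large`` voxels.

    Gaussian roll-offs attenuate features larger than ``large`` and smaller
    than ``small``. With ``suppress='horizontal'``, a Gaussian angular notch
    additionally removes energy in a narrow band around the stripe axis
    (structures constant along x, varying along z — bulk-motion banding).
    The output mean is restored to the input mean.
    """
    if large <= small:
        raise ValueError("large scale must exceed small scale")
    if suppress not in ("horizontal", "none"):
        raise ValueError(f"unknown stripe mode {suppress!r}")
    img = np.asarray(slice_, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 4:
        raise ValueError("slice must be 2D with extents >= 4")
    nx, nz = img.shape
    fx = np.fft.fftfreq(nx)[:, None]
    fz = np.fft.fftfreq(nz)[None, :]
    r2 = fx ** 2 + fz ** 2
    ln2 = math.log(2.0)
    # half-power points at feature sizes `small` and `large`
    keep_small = np.exp(-ln2 * (small ** 2) * r2)
    keep_large = 1.0 - np.exp(-ln2 * (large ** 2) * r2)
    h = keep_small * keep_large
    if suppress == "horizontal":
        with np.errstate(invalid="ignore", divide="ignore"):
            ang = np.abs(fx) / np.sqrt(r2)
        ang[0, 0] = 1.0
        h *= 1.0 - np.exp(-((ang / stripe_tolerance) ** 2))
    out = np.fft.ifft2(np.fft.fft2(img) * h).real
    return out + (img.mean() - out.mean())


def smooth(
    data: np.ndarray, cfg: PipelineConfig | None = None
) -> np.ndarray:
    """Continuity smoothing: per-slice 2D Gaussian or cross-slice 3D median.

    2D input is smoothed with a Gaussian of ``cfg.gaussian_sigma``
    (``median_3d`` needs the full stack). 3D input (en-face order [x, z, y])
    is smoothed slice-wise in gaussian mode or with the configured 3D median
    window, whose third extent spans adjacent en-face slices.
    """
    cfg = cfg or PipelineConfig()
    arr = np.asarray(data, dtype=np.float64)
    if cfg.smoothing_mode == "gaussian_2d":
        if arr.ndim == 2:
            return ndimage.gaussian_filter(arr, cfg.gaussian_sigma, mode="reflect")
        if arr.ndim == 3:
            return ndimage.gaussian_filter(
                arr, (cfg.gaussian_sigma, cfg.gaussian_sigma, 0), mode="reflect"
            )
        raise ValueError("expected 2D or 3D input")
    if arr.ndim == 2:
        win = cfg.median_3d_window[:2]
        return ndimage.median_filter(arr, size=win, mode="reflect")
    if arr.ndim == 3:
        return ndimage.median_filter(arr, size=cfg.median_3d_window, mode="reflect")
    raise ValueError("expected 2D or 3D input")


def _g3_profile(u: np.ndarray, sigma: float) -> np.ndarray:
    # even-symmetrized third-derivative-of-Gaussian magnitude profile:
    # positive side lobes flanking the (notched) center, negative outer lobes
    a = np.abs(u)
    return (3 * a / sigma ** 4 - a ** 3 / sigma ** 6) * np.exp(-(a ** 2) / (2 * sigma ** 2))


def build_g3_bank(cfg: PipelineConfig | None = None) -> list[G3Kernel]:
    """Oriented ridge kernels at equally spaced angles in [0, 180).

    Each kernel is a third-derivative-of-Gaussian profile taken across the
    vessel axis, Gaussian-tapered along it, truncated to a finite disc with
    zero padding, with a ``notch_width`` strip of zeros along the vessel axis
    through the center. Weights are normalized to zero sum and unit L2 norm.
    """
    cfg = cfg or PipelineConfig()
    sigma = cfg.gaussian_sigma
    half = cfg.kernel_halfwidth or int(math.ceil(3 * sigma * cfg.kernel_elongation))
    coords = np.arange(-half, half + 1, dtype=np.float64)
    ii, jj = np.meshgrid(coords, coords, indexing="ij")
    kernels = []
    for k in range(cfg.n_orientations):
        theta = k * math.pi / cfg.n_orientations
        c, s = math.cos(theta), math.sin(theta)
        # snap to exact axis alignment so boundary masks stay symmetric
        c = 0.0 if abs(c) < 1e-12 else c
        s = 0.0 if abs(s) < 1e-12 else s
        along = ii * c + jj * s
        across = -ii * s + jj * c
        w = _g3_profile(across, sigma)
        w *= np.exp(-(along ** 2) / (2 * (cfg.kernel_elongation * sigma) ** 2))
        support = np.sqrt(ii ** 2 + jj ** 2) <= half  # zero-padded truncation
        w[~support] = 0.0
        notch = np.abs(across) <= cfg.notch_width / 2.0  # central notch
        w[notch] = 0.0
        live = support & ~notch
        w[live] -= w[live].mean()  # zero DC response, notch stays zero
        # equalize gain across orientations: unit centerline response to an
        # aligned tube of the design diameter (2 sigma)
        gain = w[np.abs(across) <= sigma].sum()
        w /= gain if gain > 0 else np.sqrt((w ** 2).sum())
        kernels.append(G3Kernel(weights=w, orientation=theta, sigma=sigma))
    return kernels


def ridge_enhance(slice_: np.ndarray, bank: list[G3Kernel]) -> np.ndarray:
    """Per-pixel maximum over orientations of the rectified kernel correlation.

    Negative responses are clipped to zero (vessels are hyperintense), so a
    constant slice maps to exactly zero.
    """
    img = np.asarray(slice_, dtype=np.float64)
    if img.size and img.max() == img.min():
        return np.zeros_like(img)  # zero-sum kernels: no response to a constant
    img = img - img.mean()
    out = np.zeros_like(img)
    for k in bank:
        resp = ndimage.correlate(img, k.weights, mode="reflect")
        np.maximum(out, resp, out=out)
    return np.clip(out, 0.0, None)


def median_suppress(slice_: np.ndarray, radius: int = 1) -> np.ndarray:
    """Disc-footprint median filter removing isolated ridge-detection errors."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    coords = np.arange(-r, r + 1)
    ii, jj = np.meshgrid(coords, coords, indexing="ij")
    footprint = ii ** 2 + jj ** 2 <= r ** 2
    return ndimage.median_filter(
        np.asarray(slice_, dtype=np.float64), footprint=footprint, mode="reflect"
    )


def _ball_elements(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius))
    coords = np.arange(-r, r + 1, dtype=np.float64)
    ii, jj = np.meshgrid(coords, coords, indexing="ij")
    d2 = ii ** 2 + jj ** 2
    footprint = d2 <= radius ** 2
    heights = np.zeros_like(d2)
    heights[footprint] = np.sqrt(radius ** 2 - d2[footprint]) - radius
    return footprint, heights


def rollingball_subtract(slice_: np.ndarray, radius: float = 25.0) -> np.ndarray:
    """Rolling-ball background subtraction (Sternberg).

    The background is the grayscale opening of the image with a spherical
    structuring element of the given radius (the surface traced by a ball
    rolled under the intensity profile); it is subtracted and the result is
    non-negative.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    img = np.asarray(slice_, dtype=np.float64)
    footprint, heights = _ball_elements(radius)
    background = ndimage.grey_opening(
        img, footprint=footprint, structure=heights, mode="reflect"
    )
    return np.clip(img - background, 0.0, None)


def enhance_slice(
    slice_: np.ndarray,
    cfg: PipelineConfig | None = None,
    bank: list[G3Kernel] | None = None,
) -> np.ndarray:
    """Run all six steps on a single en-face slice (gaussian_2d smoothing)."""
    cfg = cfg or PipelineConfig()
    if bank is None:
        bank = build_g3_bank(cfg)
    out = subtract_offset(slice_, cfg.rms_offset)
    out = fft_bandpass(out, cfg.bandpass_large, cfg.bandpass_small, cfg.suppress_stripes)
    out = smooth(out, cfg)
    out = ridge_enhance(out, bank)
    out = median_suppress(out, cfg.median_radius)
    return rollingball_subtract(out, cfg.rollingball_radius)


def enhance_stack(
    s: EnFaceStack,
    cfg: PipelineConfig | None = None,
    return_steps: bool = False,
):
    """Apply the six-step enhancement to every slice of an en-face stack.

    In ``gaussian_2d`` mode each slice is independent; in ``median_3d`` mode
    the smoothing step couples adjacent slices. With ``return_steps`` the
    seven checkpoints (input + six steps) are returned as a dict of stacks
    keyed by :data:`STEP_NAMES`, for step-wise contrast analysis.

    The output stack is co-registered with the input: same extents, same
    [x, z, y] coordinates.
    """
    cfg = cfg or PipelineConfig()
    bank = build_g3_bank(cfg)
    data = s.data.astype(np.float64)
    steps: dict[str, np.ndarray] = {}

    def checkpoint(name: str, arr: np.ndarray) -> None:
        if return_steps:
            steps[name] = arr.copy()

    checkpoint("input", data)
    cur = np.clip(data - cfg.rms_offset, 0.0, None)
    checkpoint("offset_subtracted", cur)
    cur = _apply_per_slice(
        cur, lambda im: fft_bandpass(im, cfg.bandpass_large, cfg.bandpass_small,
                                     cfg.suppress_stripes)
    )
    checkpoint("bandpassed", cur)
    cur = smooth(cur, cfg)
    checkpoint("smoothed", cur)
    cur = _apply_per_slice(cur, lambda im: ridge_enhance(im, bank))
    checkpoint("ridge_enhanced", cur)
    cur = _apply_per_slice(cur, lambda im: median_suppress(im, cfg.median_radius))
    checkpoint("median_filtered", cur)
    cur = _apply_per_slice(cur, lambda im: rollingball_subtract(im, cfg.rollingball_radius))
    checkpoint("background_subtracted", cur)

    def wrap(arr: np.ndarray) -> EnFaceStack:
        return EnFaceStack(data=arr, dx=s.dx, dy=s.dy, dz=s.dz, provenance=s.provenance)

    if return_steps:
        return {name: wrap(arr) for name, arr in steps.items()}
    return wrap(cur)


def _apply_per_slice(stack: np.ndarray, fn) -> np.ndarray:
    out = np.empty_like(stack)
    for j in range(stack.shape[2]):
        out[:, :, j] = fn(stack[:, :, j])
    return out
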