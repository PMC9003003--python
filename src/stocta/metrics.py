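"""SNR/CNR evaluation, ground-truth mask construction and contrast reports.

SNR = Mean(signal) / Std(background): mean intensity on the vessel mask
divided by the standard deviation on its complement.

CNR = (mu_s - mu_n) / sqrt(0.5 * (sigma_s^2 + sigma_n^2)) between a vessel
signal region and a background tissue region.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local, threshold_otsu

from stocta.compositing import composite_frames
from stocta.enhance import STEP_NAMES, PipelineConfig, enhance_stack
from stocta.volume import EnFaceStack, OCTVolume4D, reslice_to_enface

__all__ = [
    "VesselMask",
    "ContrastReport",
    "snr",
    "cnr",
    "build_groundtruth_mask",
    "stepwise_cnr",
    "plexus_cnr_report",
]


@dataclass
class VesselMask:
    """Binary volume aligned with an :class:`EnFaceStack`."""

    data: np.ndarray
    source: str = "estimated"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.source not in ("phantom_truth", "estimated"):
            raise ValueError(f"unknown mask source {self.source!r}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ContrastReport:
    """Long-format table of contrast measurements.

    Rows are (region, method, step, metric, value); ``step`` indexes the
    pipeline checkpoints 1..7 (1 = composited input) or 0 when the metric
    was not computed at a pipeline step.
    """

    rows: list[tuple[str, str, int, str, float]] = field(default_factory=list)

    def add(self, region: str, method: str, step: int, metric: str, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError(f"non-finite metric value for {region}/{method}/{metric}")
        if metric.endswith(("SNR", "CNR")) and not 0 <= step <= 7:
            raise ValueError("step index must lie in [0, 7]")
        self.rows.append((region, method, int(step), metric, float(value)))

    def get(self, region: str, method: str, step: int, metric: str) -> float:
        for r, m, s, name, v in self.rows:
            if (r, m, s, name) == (region, method, step, metric):
                return v
        raise KeyError((region, method, step, metric))

    def to_csv(self) -> str:
        lines = ["region,method,step,metric,value"]
        for r, m, s, name, v in self.rows:
            lines.append(f"{r},{m},{s},{name},{v:.8g}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            [
                {"region": r, "method": m, "step": s, "metric": name, "value": v}
                for r, m, s, name, v in self.rows
            ],
            indent=1,
        )


def _as_array(image) -> np.ndarray:
    if isinstance(image, EnFaceStack):
        return image.data.astype(np.float64)
    return np.asarray(image, dtype=np.float64)


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, VesselMask):
        return mask.data
    return np.asarray(mask, dtype=bool)


def snr(image, mask) -> float:
    """Mean intensity on the mask over the intensity std on its complement."""
    data = _as_array(image)
    m = _as_bool(mask)
    if m.shape != data.shape:
        raise ValueError("mask shape mismatch")
    if not m.any():
        raise ValueError("vessel mask is empty")
    if m.all():
        raise ValueError("vessel mask covers the whole image; no background left")
    background_std = float(data[~m].std())
    if background_std == 0.0:
        raise ZeroDivisionError("background standard deviation is zero")
    return float(data[m].mean()) / background_std


def cnr(image, signal_mask, noise_mask) -> float:
    """(mu_s - mu_n) / sqrt(0.5 * (sigma_s^2 + sigma_n^2))."""
    data = _as_array(image)
    sm, nm = _as_bool(signal_mask), _as_bool(noise_mask)
    if sm.shape != data.shape or nm.shape != data.shape:
        raise ValueError("mask shape mismatch")
    if not sm.any() or not nm.any():
        raise ValueError("signal and noise masks must be nonempty")
    s_vals, n_vals = data[sm], data[nm]
    denom = np.sqrt(0.5 * (s_vals.std() ** 2 + n_vals.std() ** 2))
    if denom == 0.0:
        raise ZeroDivisionError("both regions have zero variance")
    return float((s_vals.mean() - n_vals.mean()) / denom)


def build_groundtruth_mask(
    stacks: list[EnFaceStack],
    lowpass_sigma: float = 2.0,
    local_window: int = 25,
    local_offset: float = 0.0,
) -> VesselMask:
    """Consensus vessel mask from the outputs of several algorithms.

    Each stack is min-max normalized, the stacks are averaged with equal
    weight, then: Gaussian low-pass to remove small elements, a global Otsu
    threshold zeroing everything below it, and a local adaptive (mean)
    threshold binarizing the result.
    """
    if len(stacks) < 1:
        raise ValueError("need at least one stack")
    shape = stacks[0].data.shape
    acc = np.zeros(shape, dtype=np.float64)
    for s in stacks:
        d = s.data.astype(np.float64)
        if d.shape != shape:
            raise ValueError("stacks must share extents")
        rng = d.max() - d.min()
        acc += (d - d.min()) / rng if rng > 0 else d
    avg = acc / len(stacks)
    if avg.max() == 0:
        warnings.warn("all-zero input stacks: returning empty mask", stacklevel=2)
        return VesselMask(np.zeros(shape, dtype=bool), source="estimated")
    smoothed = ndimage.gaussian_filter(avg, (lowpass_sigma, lowpass_sigma, 0), mode="reflect")
    try:
        global_thr = threshold_otsu(smoothed.ravel())
    except ValueError:  # single-valued image
        global_thr = smoothed.max()
    zeroed = np.where(smoothed >= global_thr, smoothed, 0.0)
    if local_window % 2 == 0:
        local_window += 1
    out = np.zeros(shape, dtype=bool)
    for j in range(shape[2]):
        plane = zeroed[:, :, j]
        if plane.max() == 0:
            continue
        local_thr = threshold_local(plane, block_size=local_window,
                                    method="mean", offset=local_offset)
        out[:, :, j] = plane > np.maximum(local_thr, 0.0)
    if not out.any():
        warnings.warn("ground-truth mask is empty", stacklevel=2)
    return VesselMask(out, source="estimated")


def stepwise_cnr(
    v: OCTVolume4D,
    cfg: PipelineConfig,
    signal_mask,
    noise_mask,
    methods: tuple[str, ...] = ("stdev", "mean", "single"),
    region: str = "all",
) -> ContrastReport:
    """CNR at each of the 7 pipeline checkpoints, per compositing method.

    Step 1 is the composited, resliced input; steps 2..7 follow the
    enhancement stages. A ``pct_change_CNR`` row records the percent change
    relative to step 1.
    """
    report = ContrastReport()
    for method in methods:
        stack = reslice_to_enface(composite_frames(v, method))
        steps = enhance_stack(stack, cfg, return_steps=True)
        base = None
        for idx, name in enumerate(STEP_NAMES, start=1):
            value = cnr(steps[name], signal_mask, noise_mask)
            report.add(region, method, idx, "CNR", value)
            if idx == 1:
                base = value
            if base not in (None, 0.0):
                report.add(region, method, idx, "pct_change_CNR",
                           100.0 * (value - base) / abs(base))
    return report


def plexus_cnr_report(
    stacks_by_method: dict[str, EnFaceStack],
    masks_by_plexus: dict[str, tuple[np.ndarray, np.ndarray]],
) -> ContrastReport:
    """CNR for each frame-compositing method within each plexus region.

    ``masks_by_plexus`` maps a region label to its (signal, noise) mask pair.
    """
    report = ContrastReport()
    for plexus, (sig, noise) in masks_by_plexus.items():
        for method, stack in stacks_by_method.items():
            report.add(plexus, method, 0, "CNR", cnr(stack, sig, noise))
    return report


def dice(a, b) -> float:
    """Dice overlap of two binary masks."""
    a, b = _as_bool(a), _as_bool(b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
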