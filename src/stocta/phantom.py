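"""Synthetic 4D OCT phantom with known vessel/fiber ground truth.

The phantom encodes the statistics the enhancement pipeline exploits:

* static tissue carries *frozen* fully developed speckle — identical across
  repeat frames, spatially correlated at a configurable length;
* flow voxels (inside tubular vessels) redraw their speckle independently
  per frame, producing the temporal "flicker" that STDEV compositing turns
  into contrast;
* static fiber bundles contaminate the superficial layer;
* vessels cast shadows on deeper voxels;
* sinusoidal bulk motion (breathing + heartbeat mapped through the scan
  rate) rigidly displaces each acquired frame in-plane;
* additive half-normal noise gives the non-tissue region a known RMS.

Intensity follows the fully developed speckle law: mean reflectivity times
a unit-mean exponential variate. A fixed seed yields bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from stocta.metrics import VesselMask
from stocta.baselines import ComplexVolume4D
from stocta.volume import OCTVolume4D

__all__ = [
    "LayerSpec",
    "VesselSpec",
    "FiberSpec",
    "MotionSpec",
    "PhantomSpec",
    "generate_phantom",
    "default_retina_spec",
    "plexus_masks",
]


@dataclass
class LayerSpec:
    """A tissue layer: depth range [y_start, y_stop) and mean reflectivity.

    ``flow`` marks diffusely perfused layers (choroid-like): their speckle
    decorrelates between frames like vessel flow, but they carry no vessel
    geometry and are not part of the vessel truth mask.
    """

    y_start: int
    y_stop: int
    mean_intensity: float
    label: str = ""
    flow: bool = False


@dataclass
class VesselSpec:
    """A tubular vessel along an in-plane polyline at a fixed depth.

    ``polyline`` is a sequence of (x, z) vertices; the tube has circular
    cross-section of the given radius centered at depth ``depth_y``.
    """

    polyline: list[tuple[float, float]]
    radius: float
    depth_y: float
    mean_intensity: float
    flow: bool = True

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("vessel radius must be >= 1 voxel")
        if len(self.polyline) < 2:
            raise ValueError("polyline needs at least two vertices")


@dataclass
class FiberSpec:
    """A static fiber bundle: a thin bright ridge in the superficial layer."""

    polyline: list[tuple[float, float]]
    width: float
    depth_y: float
    mean_intensity: float


@dataclass
class MotionSpec:
    """Bulk-motion model: sinusoidal breathing and heartbeat displacement.

    Each acquired frame (t, z) is rigidly shifted in-plane by
    ``A_b sin(2 pi f_b tau) + A_h sin(2 pi f_h tau)`` voxels along x (and a
    third of that along depth), where tau is the frame's acquisition time
    derived from the A-scan rate.
    """

    breathing_amplitude: float = 2.0
    breathing_hz: float = 1.0
    heart_hz: float = 2.7  # ~160 BPM
    heart_amplitude: float = 0.5
    scan_rate: float = 29400.0  # A-scans / s

    def __post_init__(self) -> None:
        if self.breathing_hz <= 0 or self.heart_hz <= 0 or self.scan_rate <= 0:
            raise ValueError("rates must be positive")


@dataclass
class PhantomSpec:
    """Full phantom description; ``seed`` fixes every random draw."""

    nx: int = 192
    ny: int = 96
    nt: int = 3
    nz: int = 192
    dx: float = 1.4
    dy: float = 1.9
    dz: float = 1.4
    layers: list[LayerSpec] = field(default_factory=list)
    vessels: list[VesselSpec] = field(default_factory=list)
    fibers: list[FiberSpec] = field(default_factory=list)
    background_rms: float = 20.0
    shadow_attenuation: float = 0.6
    shadow_flicker: float = 0.0
    motion: MotionSpec | None = None
    static_correlation: float = 1.2
    flow_decorrelation: bool = True
    flow_mix: float = 1.0
    flow_correlation: float = 0.0
    flow_washout: float = 1.0
    tissue_jitter: float = 0.0
    jitter_t_correlation: float = 0.0
    jitter_field_scale: float = 0.0
    jitter_field_amplitude: float = 0.8
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nt < 1:
            raise ValueError("t extent must be >= 1")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("extents must be >= 1")
        if not 0.0 <= self.shadow_attenuation <= 1.0:
            raise ValueError("shadow_attenuation must lie in [0, 1]")
        if not 0.0 < self.flow_mix <= 1.0:
            raise ValueError("flow_mix must lie in (0, 1]")
        if self.tissue_jitter < 0:
            raise ValueError("tissue_jitter must be >= 0")
        if self.flow_washout < 1.0:
            raise ValueError("flow_washout must be >= 1")
        for v in self.vessels:
            if not (0 <= v.depth_y < self.ny):
                raise ValueError(f"vessel depth {v.depth_y} outside volume")
            for x, z in v.polyline:
                if not (0 <= x < self.nx and 0 <= z < self.nz):
                    raise ValueError("vessel polyline vertex outside volume")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)


def _segment_distance(px: np.ndarray, pz: np.ndarray, p0, p1) -> np.ndarray:
    """Distance from grid points to the segment p0-p1 (in the x-z plane)."""
    x0, z0 = p0
    x1, z1 = p1
    vx, vz = x1 - x0, z1 - z0
    den = vx * vx + vz * vz
    if den == 0:
        return np.hypot(px - x0, pz - z0)
    tt = ((px - x0) * vx + (pz - z0) * vz) / den
    tt = np.clip(tt, 0.0, 1.0)
    return np.hypot(px - (x0 + tt * vx), pz - (z0 + tt * vz))


def _polyline_distance(nx: int, nz: int, polyline) -> np.ndarray:
    xx, zz = np.meshgrid(np.arange(nx, dtype=np.float64),
                         np.arange(nz, dtype=np.float64), indexing="ij")
    d = np.full((nx, nz), np.inf)
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        np.minimum(d, _segment_distance(xx, zz, p0, p1), out=d)
    return d


def _tube_mask(spec: PhantomSpec, polyline, radius: float, depth_y: float) -> np.ndarray:
    """Boolean [x, y, z] mask of a tube with circular cross-section."""
    d_xz = _polyline_distance(spec.nx, spec.nz, polyline)  # [x, z]
    y = np.arange(spec.ny, dtype=np.float64)
    dy2 = (y - depth_y) ** 2  # [y]
    # (x, y, z): d_xz^2 + dy^2 <= r^2
    return d_xz[:, None, :] ** 2 + dy2[None, :, None] <= radius ** 2


def _frozen_speckle(rng: np.random.Generator, shape, corr: float) -> np.ndarray:
    """Unit-mean exponential speckle, spatially correlated by smoothing."""
    f = rng.exponential(1.0, size=shape)
    if corr > 0:
        f = ndimage.gaussian_filter(f, corr, mode="reflect")
    return f / f.mean()


def generate_phantom(
    spec: PhantomSpec, return_complex: bool = False
) -> tuple[OCTVolume4D, VesselMask, VesselMask, "ComplexVolume4D | None"]:
    """Render a phantom volume plus its vessel and fiber truth masks.

    Returns ``(volume, vessel_mask, fiber_mask, complex_volume)``. Masks are
    in en-face alignment ``[x, z, y]`` (the geometry *before* bulk motion;
    registration is expected to undo the injected motion). The complex
    volume (if requested) carries the same speckle statistics as a complex
    circular-Gaussian field.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nt, nz = spec.nx, spec.ny, spec.nt, spec.nz

    # mean reflectivity map [x, y, z]
    mean_map = np.zeros((nx, ny, nz), dtype=np.float64)
    for layer in spec.layers:
        mean_map[:, layer.y_start:layer.y_stop, :] = layer.mean_intensity

    fiber_mask = np.zeros((nx, ny, nz), dtype=bool)
    for fb in spec.fibers:
        m = _tube_mask(spec, fb.polyline, fb.width / 2.0, fb.depth_y)
        fiber_mask |= m
        mean_map[m] = fb.mean_intensity

    # all vessels shape the reflectivity map and cast shadows, but only
    # perfused (flow) vessels constitute the angiographic ground truth
    vessel_mask = np.zeros((nx, ny, nz), dtype=bool)
    truth_mask = np.zeros((nx, ny, nz), dtype=bool)
    flow_mask = np.zeros((nx, ny, nz), dtype=bool)
    for layer in spec.layers:
        if layer.flow:
            flow_mask[:, layer.y_start:layer.y_stop, :] = True
    for vs in spec.vessels:
        m = _tube_mask(spec, vs.polyline, vs.radius, vs.depth_y)
        vessel_mask |= m
        if vs.flow:
            flow_mask |= m
            truth_mask |= m
        mean_map[m] = vs.mean_intensity

    # shadowing: voxels beneath any vessel are attenuated once
    below_vessel = np.zeros_like(vessel_mask)
    below_vessel[:, 1:, :] = np.cumsum(vessel_mask, axis=1)[:, :-1, :] > 0
    attenuation = np.where(below_vessel & ~vessel_mask, spec.shadow_attenuation, 1.0)
    mean_map *= attenuation

    static = mean_map * _frozen_speckle(rng, (nx, ny, nz), spec.static_correlation)

    data = np.empty((nx, ny, nt, nz), dtype=np.float64)
    data[:] = static[:, :, None, :]
    if spec.tissue_jitter > 0:
        # physiological micro-motion: small per-frame multiplicative jitter of
        # static tissue (residual decorrelation the paper's background carries)
        jitter = rng.normal(0.0, spec.tissue_jitter, size=(nx, ny, nt, nz))
        rho = spec.jitter_t_correlation
        if rho > 0:
            # micro-motion is slow relative to the frame rate: a share of the
            # jitter is common to all repeat frames (mean compositing keeps
            # it; stdev compositing cancels it)
            slow = rng.normal(0.0, spec.tissue_jitter, size=(nx, ny, 1, nz))
            jitter = rho * slow + math.sqrt(1.0 - rho ** 2) * jitter
        if spec.jitter_field_scale > 0:
            # decorrelation strength varies smoothly across the field of view
            env = rng.normal(size=(nx, nz))
            env = ndimage.gaussian_filter(env, spec.jitter_field_scale, mode="reflect")
            env /= max(env.std(), 1e-12)
            gain = np.clip(1.0 + spec.jitter_field_amplitude * env, 0.1, None)
            jitter *= gain[:, None, None, :]
        data *= np.clip(1.0 + jitter, 0.0, None)
    if spec.flow_decorrelation and flow_mask.any():
        idx = np.where(flow_mask)
        beta = spec.flow_mix
        frozen = static[flow_mask] / np.maximum(mean_map[flow_mask], 1e-12)
        for t in range(nt):
            # speckle grain: each frame's flow field redrawn, optionally
            # spatially correlated at the speckle grain size
            # flow washout: moving scatterers average k independent speckle
            # realizations within one exposure -> Gamma(k) intensity with
            # unit mean and contrast 1/sqrt(k); k = 1 is fully developed
            k = spec.flow_washout
            if k > 1.0:
                field = rng.gamma(k, 1.0 / k, size=(nx, ny, nz))
            else:
                field = rng.exponential(1.0, size=(nx, ny, nz))
            if spec.flow_correlation > 0:
                # speckle grain within a B-scan (x, y) at full contrast;
                # independent across z — each B-scan resamples the flow
                sm = ndimage.gaussian_filter(
                    field, (spec.flow_correlation, spec.flow_correlation, 0),
                    mode="reflect",
                )
                fluct = (sm - sm.mean()) / max(sm.std(), 1e-12)
                field = np.clip(1.0 + fluct, 0.0, None)
                field /= field.mean()
            mixed = (1.0 - beta) * frozen + beta * field[flow_mask]
            data[idx[0], idx[1], t, idx[2]] = mean_map[flow_mask] * mixed

    if spec.shadow_flicker > 0 and spec.flow_decorrelation and flow_mask.any():
        # light reaching voxels under a flowing vessel traverses moving blood:
        # the shadow attenuation itself decorrelates between frames (the
        # classic flickering shadow / projection artifact of speckle variance)
        below_flow = np.zeros_like(flow_mask)
        below_flow[:, 1:, :] = np.cumsum(flow_mask, axis=1)[:, :-1, :] > 0
        below_flow &= ~vessel_mask
        sidx = np.where(below_flow)
        for t in range(nt):
            wobble = np.clip(
                1.0 + spec.shadow_flicker * rng.normal(size=sidx[0].size),
                0.0, 2.0,
            )
            data[sidx[0], sidx[1], t, sidx[2]] *= wobble

    if return_complex:
        amp = np.sqrt(np.clip(data, 0.0, None))
        phase = rng.uniform(-np.pi, np.pi, size=(nx, ny, nz))
        cdata = amp * np.exp(1j * phase)[:, :, None, :]
        if spec.flow_decorrelation and flow_mask.any():
            idx = np.where(flow_mask)
            for t in range(nt):
                ph = rng.uniform(-np.pi, np.pi, size=idx[0].size)
                cdata[idx[0], idx[1], t, idx[2]] = (
                    amp[idx[0], idx[1], t, idx[2]] * np.exp(1j * ph)
                )
    else:
        cdata = None

    # bulk motion: rigid in-plane shift of each acquired frame
    if spec.motion is not None:
        mo = spec.motion
        frame_time = nx / mo.scan_rate
        for z in range(nz):
            for t in range(nt):
                tau = (z * nt + t) * frame_time
                sx = (mo.breathing_amplitude * math.sin(2 * math.pi * mo.breathing_hz * tau)
                      + mo.heart_amplitude * math.sin(2 * math.pi * mo.heart_hz * tau))
                sy = sx / 3.0
                if sx != 0.0 or sy != 0.0:
                    data[:, :, t, z] = ndimage.shift(
                        data[:, :, t, z], (sx, sy), order=1, mode="constant", cval=0.0
                    )
                    if cdata is not None:
                        cdata[:, :, t, z] = (
                            ndimage.shift(cdata[:, :, t, z].real, (sx, sy), order=1,
                                          mode="constant", cval=0.0)
                            + 1j * ndimage.shift(cdata[:, :, t, z].imag, (sx, sy),
                                                 order=1, mode="constant", cval=0.0)
                        )

    # additive noise: half-normal with RMS = background_rms
    if spec.background_rms > 0:
        noise = np.abs(rng.normal(0.0, spec.background_rms, size=data.shape))
        data += noise
        if cdata is not None:
            cnoise = rng.normal(0.0, spec.background_rms / math.sqrt(2.0),
                                size=(2,) + cdata.shape)
            cdata += cnoise[0] + 1j * cnoise[1]

    np.clip(data, 0.0, 2 ** spec.bit_depth - 1, out=data)

    volume = OCTVolume4D(data=data, dx=spec.dx, dy=spec.dy, dz=spec.dz,
                         bit_depth=spec.bit_depth, is_complex=False)
    # masks in en-face alignment [x, z, y]
    v_mask = VesselMask(truth_mask.transpose(0, 2, 1), source="phantom_truth")
    f_mask = VesselMask(fiber_mask.transpose(0, 2, 1), source="phantom_truth")
    cvol = None
    if cdata is not None:
        cvol = ComplexVolume4D(data=cdata, dx=spec.dx, dy=spec.dy, dz=spec.dz)
    return volume, v_mask, f_mask, cvol


def default_retina_spec(
    nx: int = 192, ny: int = 96, nz: int = 192, seed: int = 0,
    motion: bool = True, flow_decorrelation: bool = True,
    flow_mix: float = 1.0, flow_correlation: float = 0.0,
    flow_washout: float = 1.0, jitter_t_correlation: float = 0.0,
    tissue_jitter: float = 0.5, static_correlation: float = 1.2,
) -> PhantomSpec:
    """Desk-scale three-plexus retina phantom.

    Superficial plexus with fiber bundles and large vessels (up to 20-voxel
    diameter), an intermediate plexus including a 4-voxel-diameter vessel,
    and a fiber-free deep plexus with capillary-scale vessels (down to
    2-voxel diameter). Shadowing and bulk motion are on by default.
    """
    x1, z1 = nx - 1.0, nz - 1.0

    def frac(p, extent):
        return p * (extent - 1)

    layers = [
        LayerSpec(int(ny * 0.10), int(ny * 0.35), 70.0, label="superficial"),
        LayerSpec(int(ny * 0.35), int(ny * 0.62), 65.0, label="intermediate"),
        LayerSpec(int(ny * 0.62), int(ny * 0.88), 60.0, label="deep"),
        # bright, diffusely perfused choroid: fully decorrelating speckle
        # with no vessel geometry — contaminates raw temporal contrasts
        LayerSpec(int(ny * 0.88), int(ny * 0.97), 140.0, flow=True),
    ]
    y_sup = ny * 0.22
    y_int = ny * 0.48
    y_deep = ny * 0.76
    # vessel reflectivity sits close to tissue: the angiographic contrast
    # comes from temporal speckle decorrelation, not brightness
    vessels = [
        # superficial: large trunks, diameter 20 and 12
        VesselSpec([(frac(0.1, nx), 0.0), (frac(0.25, nx), z1)], 10.0, y_sup, 95.0),
        VesselSpec([(frac(0.6, nx), 0.0), (frac(0.5, nx), z1)], 6.0, y_sup, 92.0),
        # intermediate: medium vessels, one of diameter 4
        VesselSpec([(0.0, frac(0.3, nz)), (x1, frac(0.42, nz))], 4.0, y_int, 66.0),
        VesselSpec([(0.0, frac(0.7, nz)), (x1, frac(0.62, nz))], 2.0, y_int, 65.0),
        # non-perfused vessels: static tubes, invisible to flow contrast but
        # present as tissue structure (and sharpened by mean compositing)
        VesselSpec([(frac(0.15, nx), z1), (frac(0.3, nx), 0.0)], 3.0, y_int, 88.0,
                   flow=False),
        VesselSpec([(0.0, frac(0.86, nz)), (x1, frac(0.8, nz))], 2.5, y_int, 86.0,
                   flow=False),
        # deep: capillaries, diameters 4 and 2
        VesselSpec([(frac(0.35, nx), 0.0), (frac(0.42, nx), z1)], 2.0, y_deep, 61.0),
        VesselSpec([(0.0, frac(0.15, nz)), (x1, frac(0.2, nz))], 1.0, y_deep, 60.0),
        VesselSpec([(frac(0.8, nx), 0.0), (frac(0.75, nx), z1)], 1.5, y_deep, 61.0),
        VesselSpec([(frac(0.55, nx), z1), (frac(0.6, nx), 0.0)], 2.0, y_deep, 82.0,
                   flow=False),
    ]
    fibers = [
        FiberSpec([(0.0, frac(0.08, nz)), (x1, frac(0.26, nz))], 3.0, y_sup, 98.0),
        FiberSpec([(0.0, frac(0.5, nz)), (x1, frac(0.62, nz))], 3.0, y_sup, 94.0),
        FiberSpec([(0.0, frac(0.82, nz)), (x1, frac(0.9, nz))], 4.0, y_sup, 98.0),
        FiberSpec([(frac(0.85, nx), 0.0), (frac(0.95, nx), z1)], 3.0, y_sup, 96.0),
    ]
    mo = MotionSpec(scan_rate=40 * 3 * nx * 1.0) if motion else None
    return PhantomSpec(
        nx=nx, ny=ny, nt=3, nz=nz,
        layers=layers, vessels=vessels, fibers=fibers,
        motion=mo, flow_decorrelation=flow_decorrelation,
        flow_mix=flow_mix, flow_correlation=flow_correlation,
        flow_washout=flow_washout, jitter_t_correlation=jitter_t_correlation,
        tissue_jitter=tissue_jitter, static_correlation=static_correlation,
        shadow_flicker=0.5, seed=seed,
    )


def plexus_masks(
    spec: PhantomSpec,
    vessel_mask: VesselMask,
    dilate: int = 2,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-plexus (signal, noise) mask pairs in en-face alignment [x, z, y].

    Signal is the vessel voxels within the layer's depth range; noise is the
    rest of the layer, excluding a safety dilation ring around vessels
    (fibers stay in the noise region — they are background tissue).
    """
    vm = vessel_mask.data  # [x, z, y]
    if dilate > 0:
        structure = np.ones((2 * dilate + 1, 2 * dilate + 1, 2 * dilate + 1), dtype=bool)
        vm_dil = ndimage.binary_dilation(vm, structure=structure)
    else:
        vm_dil = vm
    out = {}
    for layer in spec.layers:
        if not layer.label:
            continue
        slab = np.zeros_like(vm)
        slab[:, :, layer.y_start:layer.y_stop] = True
        signal = vm & slab
        noise = slab & ~vm_dil
        if signal.any() and noise.any():
            out[layer.label] = (signal, noise)
    return out
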