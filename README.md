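# stocta — spatial-temporal speckle-variance OCT angiography

`stocta` turns high-density OCT intensity volumes into depth-resolved,
vessel-enhanced angiograms. It implements:

- a **4D volume model** with the index convention `[x, y, t, z]`
  (x: A-scan within a B-scan, y: depth, t: repeat frame, z: B-scan),
  multi-page TIFF I/O with a JSON sidecar, and lossless reslicing to the
  en-face (C-scan) order `[x, z, y]` or a virtual B-scan `[z, y, x]`;
- **rigid registration** of repeat frames and B-scans against bulk motion
  (Fourier phase correlation, sub-voxel refinement, optional rotation);
- **frame compositing** over t — arithmetic mean (structure-preserving) or
  sample standard deviation (flow-selective) — plus slab projections
  (max / mean / stdev, default 60 µm slabs) and color-coded depth maps;
- the **six-step 2.5D en-face enhancement** applied slice-by-slice:
  1. constant background-RMS offset subtraction (clamped at zero),
  2. FFT bandpass (default scales 40/3 voxels) with horizontal-stripe
     suppression,
  3. smoothing (2D Gaussian σ = 2, or a 3D median 5×5×3 for other systems),
  4. oriented ridge enhancement with a bank of 9 notched
     third-derivative-of-Gaussian kernels,
  5. median filtering,
  6. rolling-ball background subtraction;
- **baseline OCTA contrasts** for comparison: speckle variance, phase
  variance and complex differential variance (the latter two require
  complex-valued input);
- **contrast metrics**: SNR (mask mean / off-mask std), CNR
  `(µs − µn)/√(0.5(σs² + σn²))`, consensus ground-truth mask construction,
  per-plexus and per-step reports (CSV/JSON);
- a **synthetic phantom** with frozen static speckle, per-frame flow
  decorrelation inside tubular vessels, fiber bundles, vessel shadowing,
  sinusoidal bulk motion and calibrated background noise, with exact
  vessel/fiber truth masks.

Coordinates are 0-based; extents are half-open. "Horizontal" stripes are
bulk-motion bands: structures constant along x, varying along the B-scan
index z. All processing is floating point; quantization happens only on
export. The pipeline is fully deterministic.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (phantom-based
ordering and oracle-equivalence checks); it takes several minutes.

## CLI

```sh
st-octa phantom phantom.tif --seed 0                 # synthetic volume
st-octa register phantom.tif reg.tif --register both
st-octa enhance reg.tif octa.tif --composite stdev [--save-steps steps/]
st-octa project octa.tif proj --proj max --slab-um 60
st-octa project octa.tif depth --proj depth          # color-coded depth
st-octa baseline sv reg.tif sv.tif
st-octa metrics octa.tif --out metrics.json
st-octa run phantom.tif outdir/ --composite stdev    # all-in-one + manifest
```

Exit codes: 0 ok, 1 user error, 2 internal error. `run` and `enhance`
write a JSON manifest (inputs, config snapshot, outputs). The enhancement
config is a JSON file mirroring `PipelineConfig` field-for-field, e.g.

```json
{"rms_offset": 20, "bandpass_large": 40, "bandpass_small": 3,
 "gaussian_sigma": 2, "n_orientations": 9, "smoothing_mode": "gaussian_2d"}
```

## Python API

```python
import stocta

spec = stocta.default_retina_spec(seed=0)
volume, vessels, fibers, _ = stocta.generate_phantom(spec)
registered = stocta.register_volume(volume, mode="both")
stack = stocta.reslice_to_enface(stocta.composite_frames(registered, "stdev"))
octa = stocta.enhance_stack(stack, stocta.PipelineConfig())
print(stocta.snr(octa, vessels))
```

`enhance_stack(..., return_steps=True)` returns all seven checkpoints
(input + six steps) for step-wise contrast analysis.

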