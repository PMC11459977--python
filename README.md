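# pinspect

Pinhole-SPECT system-matrix modelling, iterative reconstruction, and
NEMA-style image-quality analysis in Python.

The package computes sparse per-view system matrices for single- and
multi-pinhole collimators by projecting the aperture through each hole onto
the detector (similar-triangles magnification, solid-angle sensitivity
`A·cosθ/(4πr²)`), with optional corrections:

- **PSF** — detector-space convolution with a unit-sum Gaussian built from
  the camera's intrinsic resolution (configurable truncation in standard
  deviations and subsampling factor);
- **DOI** — depth-of-interaction: the scintillation crystal is subdivided
  along the oblique photon path and the footprint re-accumulated at each
  depth with its interaction probability; with DOI off, half the crystal
  thickness is added to the detector radius;
- **attenuation** — `simple` (one factor per footprint along the
  voxel-to-hole line) or `full` (one factor per detector bin), via exact
  Siddon ray tracing;
- **masking** — default cylinder (object radius), attenuation map, or mask
  file; matrices can be kept in memory or recomputed per projection angle
  (bit-identical results, different memory/time trade-off).

On top of the matched forward/back projector it provides MLEM, OSEM,
OS-OSL-MRP (median root prior, one-step-late), and OS-SPS-QP (separable
paraboloidal surrogates with a quadratic prior and relaxed steps)
reconstruction; digital Tc-99m phantoms (image-quality hot-rod phantom,
mouse-sized triple line source, uniform cylinder) with Poisson-noisy
acquisition simulation; and figures of merit (per-rod CNR, CV, uniformity,
FWHM resolution via NEMA-style profile analysis).

Projection data and image volumes use a documented Interfile dialect
(`keyword := value` headers plus raw little-endian binary); the projector is
configured by three plain-text parameter files (reconstruction/matrix,
detector, collimator) in the same keyword syntax.

## CLI

```sh
# generate a phantom and a Poisson-noisy acquisition
pinspect simulate --phantom cylinder --counts 4000000 --seed 1 \
    --recon-par recon.par --detector-par detector.par \
    --collimator-par collimator.par --out-dir run/

# forward-project an image volume
pinspect forward --input run/activity.hv --recon-par recon.par \
    --detector-par detector.par --collimator-par collimator.par \
    --output run/forward.hs

# iterative reconstruction (snapshots every N subiterations)
pinspect reconstruct --input run/projections.hs --recon-par recon.par \
    --detector-par detector.par --collimator-par collimator.par \
    --output-prefix run/rec --save-every 7 --in-memory

# figures of merit over a snapshot series
pinspect analyze --kind uniformity --images run/rec_subiter0007.hv \
    --images run/rec_subiter0014.hv --output run/fom.csv
```

Every command writes a `manifest.json` (parameter files, seeds, matrix-config
fingerprint) sufficient to reproduce the run. See
`tests/test_cli.py::param_files` for complete sample parameter files.

## Layout

```
src/pinspect/
  io_interfile.py    Interfile-dialect I/O and keyword parameter files
  geometry.py        frames, circular orbits, Siddon ray tracing, DOI sampling
  system_matrix.py   sparse pinhole system matrices + forward/back projector
  recon.py           MLEM / OSEM / OS-OSL-MRP / OS-SPS-QP
  phantoms.py        digital phantoms and Poisson acquisition simulation
  analysis.py        CNR, CV, uniformity, FWHM figures of merit
  cli.py             the `pinspect` command-line interface
  _kernels.py        numba-compiled inner loops
```
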