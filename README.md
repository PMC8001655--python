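# dvctomo

Laboratory micro-CT post-processing for fatigue microcrack analysis in
cortical bone. The toolkit covers everything downstream of tomographic
reconstruction:

- **Projection preparation** (`dvctomo.projprep`) — flat-field/dark-field
  normalization with bad-pixel repair, interleaved sub-scan planning, and
  focal-spot drift estimation from repeated reference exposures with
  sub-pixel correction of every projection.
- **Two-step DVC** (`dvctomo.dvc_core`) — 3D median prefilter, integer
  displacement by Pearson-NCC hill climbing (plus an exhaustive oracle),
  sub-voxel refinement by a 3D Lucas–Kanade Gauss–Newton solver with a
  12-parameter local affine warp, two-step displacement-field filtering,
  and the virtual rigid-motion window-size calibration protocol (mean
  u_YZ, σ_YZ, MBE, RMSE per window size).
- **Registration & blending** (`dvctomo.register_blend`) — 125-point
  support-cube tracking near a crack tip, weighted rigid/affine
  least-squares fitting, trilinear resampling, and differential-tomography
  blending `Vb = Vr + m·Vl` with contrast-driven multiplier selection.
- **Strain mapping** (`dvctomo.strainmap`) — per-voxel affine from the 8
  constituting nodes, deformation gradients and Green–Lagrange tensors.
- **Crack metrology** (`dvctomo.crackmetrics`) — line-profile FWHM
  measurement, interior void segmentation with surface-crack exclusion,
  and mask-based width (inscribed-slab) / length (max Feret) metrics.
- **Synthetic phantoms** (`dvctomo.phantom`) — cylindrical bone-like
  volumes with Haversian-canal systems and speckle texture, planar crack
  insertion, prescribed deformations and drifting parallel-beam
  projection series, all with exported ground truth.
- **I/O** (`dvctomo.volio`) — multi-page grayscale TIFF or raw binary +
  text sidecar, with voxel size (µm) metadata preserved through round
  trips.

Array convention is `(z, y, x)` with voxel centers at integer indices;
physical position = `origin + index · voxel_size` (µm).

## CLI

A single entry point `dvct` wires the pipeline:

```sh
dvct phantom --shape 64,64,64 --canals 3 --seed 7 --out vol.tif
dvct drift-correct --projections proj.tif --subscans 10 --per-subscan 180 \
     --shift-deg 0.2 --out corrected.tif --out-csv drift.csv
dvct correlate --ref ref.tif --def loaded.tif --axis 0 --index 64 \
     --window 18 --offset 24 --out field.csv
dvct calibrate --volume vol.tif --step-shift 4,4,0 --n-steps 5 \
     --windows 6,8,10,12,14,16,18,20 --out calibration.csv
dvct register --ref ref.tif --def loaded.tif --tip 40,40,40 \
     --direction 0,1,0 --standoff 28 --out transform.json
dvct blend --ref ref.tif --def loaded.tif -m 20 --transform transform.json --out blended.tif
dvct strain --field field.csv --grid-shape 9,9 --out strain.csv
dvct measure --volume blended.tif --line 10,64,20:10,64,108 --out fwhm.json
```

Every command writes a `<out>.run.json` sidecar with its resolved
parameters; all stochastic behavior flows from explicit seeds.

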