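# affinerf

Closed-form canonical decomposition of 2-D affine image transformations and
the affine Gaussian derivative model of visual receptive fields, with an
engine that verifies affine covariance of filter responses, steers
directional derivatives, and relates viewing geometry (monocular slant,
binocular disparity gradients) to affine parameters.

## What it does

- **`affinerf.decomposition`** — factors a 2×2 map `A` as
  `R_{psi/2} R_{phi/2} diag(rho1, rho2) R_{phi/2} R_{-psi/2}` in closed form
  from four scalar descriptors of the matrix entries: `rho1 >= rho2 > 0`
  are the singular values, `phi` the total rotation, `psi/2` the symmetry
  axis of the non-isotropic part.  Derived quantities: uniform scale
  `sqrt(rho1 rho2)` and stretch ratio `rho1/rho2`.  Includes the inverse
  (`compose`) and the equivalent rotation–diagonal–rotation form.
- **`affinerf.geometry`** — affine maps induced by viewing geometry:
  `(1/Lambda) diag(1, cos nu)` for a monocularly viewed slanted patch, and
  the left-to-right binocular disparity-gradient map from vergence, gaze
  and depth gradient; dense deformation fields `(A - I) x` for
  visualization.
- **`affinerf.kernels`** — anisotropic Gaussian kernels parameterized by
  covariance matrix or by `(sigma1, sigma2, phi)`; closed-form first- and
  second-order directional-derivative receptive fields (simple-cell
  models); arbitrary-order, arbitrary-direction derivatives via Hermite
  expansion; space–time separable velocity-adapted kernels.
- **`affinerf.covariance`** — verifies that smoothing commutes with affine
  warps when `Sigma' = A Sigma A^T` (spatially and spatio-temporally),
  transforms gradients by `A^{-T}`, solves steering coefficients so that a
  directional derivative at any angle is a linear combination of `m + 1`
  fixed directions, matches responses across warped image pairs, and
  implements semigroup cascade smoothing (`Sigma2 = Sigma1 + Delta`).
- **`affinerf.stimuli`** — deterministic synthetic images and videos
  (gratings, band-limited noise as a continuous sum of random cosines,
  impulses), spline-based affine warping exact for 90° grid rotations, and
  figure-style kernel galleries.

## CLI

The `affinerf` command exposes the main operations; all emit JSON (or CSV)
and accept `--out`:

```sh
affinerf decompose --matrix '{"a11":1.5,"a12":0.5,"a21":0.5,"a22":1.5}'
affinerf compose --rho1 2 --rho2 1 --phi 0 --psi 1.5707963
affinerf mono-map --distance 1 --slant 1.0471976
affinerf bino-map --mu 0.7853982 --zx 0.3333333
affinerf deform-field --matrix '2 0
0 1' --plot field.png
affinerf kernel --sigma1 2 --sigma2 1 --m1 1 --out kernel.txt
affinerf stimulus --kind band_limited_noise --size 64 --out noise.txt
affinerf smooth --image noise.txt --c11 16 --c22 16 --out smoothed.txt
affinerf verify-cov --matrix '{"a11":0,"a12":-1,"a21":1,"a22":0}'
affinerf verify-st-cov --matrix '{"a11":1.2,"a12":0,"a21":0,"a22":1}'
affinerf steer --order 2 --theta 0.785 --basis '0,1.047,2.094'
affinerf cascade --image smoothed.txt --d11 4 --d22 4 --out coarser.txt
affinerf gallery --sweep derivative --out gallery.png
```

Verification commands exit nonzero when the measured residual exceeds
`--tolerance`.

## Conventions

- Array axis 0 is the `x1` (horizontal) coordinate, axis 1 is `x2`;
  grids are centred on the fixation point with pixel centres at integer
  multiples of the spacing.
- Angles: total rotation `phi` and symmetry parameter `psi` live in
  `(-pi, pi]`; kernel orientations (period pi) in `(-pi/2, pi/2]`.
- The mixed-order derivative normalization is `sigma1^m1 * sigma2^m2`
  (per-axis scale normalization).
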