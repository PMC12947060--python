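# Methods

This note records what the package models, the choices made where the
underlying methods leave freedom, and the known limitations. All problem
sizes quoted for tests and benchmarks are the package's own choices, selected
to keep everything runnable on a single desktop CPU core.

## 1. What is modeled

A cylindrical PET scanner is reduced to its index structure: `n_rings` rings
of `n_crystals_per_ring` crystals with fixed transaxial/axial pitches. The
full-scale profile (`SIGNA_LIKE`) is 45 rings x 448 crystals/ring with 4.0 mm
and 5.3 mm pitches. A *chessboard cancellation* removes crystals whose block
coordinates have odd parity: `kept(r, c) = ((r // block_rings + c //
block_crystals) % 2 == phase_bit)`. For geometries divisible by the block
sizes, exactly half the crystals are removed, and the standard/complementary
phases are exact complements. A line of response (LOR) survives iff both of
its endpoint crystals are kept, so the 1x1 chessboard retains

```
K(K-1) / (N(N-1)) = 10080*10079 / (20160*20159) = 24.998% ~ 25%
```

of all unordered crystal pairs. Full-scale pair statistics are computed by
ring-pair streaming or the closed form above; pairs are never materialised at
full scale.

## 2. Sinogram binning

Planes follow a Michelogram scheme in which the two oblique sinograms with
ring difference +-1 at each axial position are summed, and every other ring
pair up to the maximum ring difference is kept separately:

```
plane_count(R) = (2R - 1) + (R - 1)(R - 2)    # 45 rings -> 1981, 16 -> 241
```

Plane ordering is segment-major: group 0 interleaves direct planes and
summed rd=1 planes by axial position, followed by segments +-2, +-3, ...
This ordering is a package convention (vendor orderings are not public); it
is stored in the HDF5 metadata and shared by data and masks.

Transaxially, `n_angles = n_crystals_per_ring / 2` (standard interleaving)
and the default radial size is 357 at full scale, else `n/2 + 1` forced odd.
The radial index of a crystal pair is an integer derived from the canonical
crystal-index difference, with its sign fixed by which side of the view axis
the chord midpoint falls on. Consequences that the tests rely on:

- every in-FOV bin of a direct plane receives **exactly one** crystal pair,
  so chessboard cancellation makes its surviving fraction exactly 0 or 1
  (the zeroed diagonal-line class);
- every bin of a summed rd=1 plane receives the two mirror pairs, so its
  fraction lies in {0, 1/2} under the 1x1 chessboard — every pixel of these
  planes differs from the ground truth (the attenuated class);
- fractions are exact rationals from integer tallies; no epsilon thresholds.

Diametrically opposite crystal pairs (central radial bin) are a genuine edge
case: for cross-ring pairs both orientations map to the (r_min, r_max)
plane by a deterministic tie rule, so oblique planes can carry multiplicity
2 at the centre bin while the mirror plane carries 0 (fraction 1 by the
empty-bin convention — nothing to restore there).

The full-scale bin mask is computed per ring pair; tallies are memoised on
the kept-crystal rows of the two rings, which collapses the 2025 ring pairs
of a 1x1 chessboard to a handful of distinct tallies and keeps the exact
full-scale computation in seconds.

## 3. Synthetic data generator

Ground-truth data are voxel phantoms on the reduced geometry (16 rings x 64
crystals by default): an elliptical body with smooth lumpy background
(clipped Gaussian blobs), one high-uptake "bladder-like" ellipsoid at
`hot_contrast` (default 6x) times the background mean, and one cold (zero)
ellipsoid. Labels (outside/background/hot/cold) are kept alongside for ROI
metrics.

Expected sinograms come from a shared sparse parallel-beam projector
(bilinear sampling along rays, exact adjoint). Oblique planes project the
average of their two ring slices, weighted by the number of contributing
ring-pair directions (2 for summed rd=1 planes — double weight). The stack
is scaled so the mean direct-plane total equals `count_level` (default 2e4,
i.e. a few counts per affected bin — Poisson-limited, like low-dose data).

Counts are Poisson samples of the expectation. Detector cancellation is
applied by **binomial thinning per bin** with the surviving fraction. For
independent Poisson counts per LOR this is *exactly* equivalent in
distribution to removing the non-surviving LORs event by event; the test
suite verifies the equivalence against a per-LOR event simulation on a
4-ring toy geometry (chi-square, p > 0.01). Distorted data therefore have
precisely the missing-data structure of the crystal mask, with no further
physics (no attenuation, scatter, randoms, dead time — out of scope).

## 4. Restoration network

A residual U-Net restores each distorted plane:

- stem 3x3 convolution to `base_filters`; per encoder level an increasing
  number of residual blocks (conv-BN-ReLU-conv-BN + identity, then ReLU)
  followed by a stride-2 convolution that halves the grid and doubles the
  channels; one bottleneck residual block; per decoder level a 2x2
  transposed convolution, an **additive** skip merge with the matching
  encoder features, and one residual block; two final convolutions produce
  the single-channel output. Inputs are reflect-padded to a multiple of
  2^depth and cropped back.
- loss = (1 - SSIM) + MAE over the affected mask m; SSIM uses 11x11
  Gaussian windows (sigma 1.5) over valid window positions, and its analytic
  gradient is implemented alongside (verified against finite differences).
- Adam, initial learning rate 1e-3 with staircase decay 0.96 per epoch,
  batch size 64, early stopping on validation loss with patience 20, at most
  200 epochs (benchmark configurations use fewer).

Everything (layers, Adam, training loop) is NumPy: the environment provides
no deep-learning framework, and the network is the method under study, so it
is implemented in-repo with explicit backpropagation (channels-last layout;
convolutions evaluated as k^2 shifted matrix products, the fastest
pure-NumPy formulation at these sizes). Each plane is normalised to [0, 1]
by its own maximum; the training target is scaled by the *input's* factor so
the network can learn the count-level rescaling of attenuated rd=1 planes.
After denormalisation, unaffected pixels are copied bit-exactly from the
input (copy-through) and the output is clipped to be non-negative.

## 5. Interpolation baseline

Clough-Tocher piecewise-cubic interpolation fills affected pixels per plane.
For zeroed-line planes the references are the unaffected pixels; for summed
rd=1 planes every pixel is affected, so the attenuated (fraction > 0) pixels
act as references and only the zeros are predicted — which leaves those
planes at roughly half their true totals. This *unscaled* variant is the
primary baseline (matching the observation that interpolation underestimates
rd=1 plane counts); an optional global scale factor (reciprocal of the mean
surviving fraction) is exposed. Points outside the convex hull fall back to
nearest-neighbour values; degenerate reference sets (under three
non-collinear points) fall back to a constant mean fill.

## 6. Reconstruction

The vendor's fully-3D OSEM with physics corrections is out of scope and is
substituted by single-slice rebinning (each plane added to the axial slot at
its mean ring position; count-conserving) followed by 2D OSEM per slice:
multiplicative updates on the shared projector, subsets taken as every n-th
view (largest divisor of the angle count <= 28), default 2 iterations, and a
5 mm FWHM Gaussian postfilter applied last. With one subset this is MLEM and
conserves total projected counts to 1e-6 relative (tested).

## 7. Evaluation

- SSIM (valid Gaussian windows; the reference's max-min as default dynamic
  range) and MAE over the affected mask, per plane.
- Pearson correlation with fitted line on a random pixel sample without
  replacement; Fisher-Z comparison of two correlations,
  `z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`.
- Mann-Whitney U on per-slice metrics (exact for combined n <= 20 without
  ties, tie-corrected normal approximation otherwise).
- ROI metrics in image space: background variability BV = sigma/mu * 100 in
  the hot ROI and in a randomly placed compact background ROI; rBV as the
  restored/original ratio; contrast recovery CR as the restored-to-original
  contrast ratio in percent.

## 8. Benchmark sizing and honesty

The acceptance benchmark (16 rings x 64 crystals, 33 radial x 32 angular
bins, 241 planes per phantom, 7 phantoms with 6 for training, mirroring the
six-training-scan design at full scale) was sized to run in minutes while
keeping >= 500 training sinograms. The training-set size matters beyond
diversity: the learning rate decays by 0.96 per *epoch*, so with too few
sinograms per epoch the schedule freezes the network after a few hundred
gradient steps. Six training phantoms (1446 planes, 20 steps/epoch) keep the
schedule in its intended regime, and the smallest network configuration
(depth 2, 8 base filters) then clears the interpolation baseline with margin
(held-out median masked MAE ~4.25 vs 4.54). The held-out phantom is fixed
by the seeded rng sequence independently of the number of training phantoms
appended after it. Generator parameters (count level, contrast, geometry),
acceptance thresholds and seeds were fixed before any training measurements
and not adjusted afterwards.

Known limitations:

- no attenuation/scatter/randoms/normalisation physics; counts are ideal
  Poisson;
- the projector is parallel-beam on interleaved views (no arc correction,
  no depth of interaction);
- oblique-plane projection uses axial interpolation of ring slices rather
  than true 3D ray tracing (adequate at the small ring differences that
  dominate the summed scheme, increasingly approximate at large ring
  differences);
- reconstruction is 2D after SSRB, not fully-3D OSEM;
- clinical numeric endpoints (absolute MAE in counts, rBV/CR values) are not
  reproducible on synthetic desk-scale data and are treated as ordering
  properties between methods, not as numbers to match.
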