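# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic experiments do and do not show.

## Phantom model

A CTP study is simulated as a 2D brain-like layout whose voxel
time-attenuation curves follow the indicator-dilution model. The arterial
input function (AIF) is a gamma-variate,

    C_a(t) = A (t - t0)^alpha exp(-(t - t0)/beta)   for t > t0, else 0,

with defaults t0 = 5 s, alpha = 3, beta = 1.5 s and A chosen so the peak is
~300 HU — a typical bolus delay and first-pass width for a power-injected
contrast bolus. Tissue curves are the causal convolution of the AIF with a
flow-scaled residue function,

    C_t = (CBF/60) * dt * (C_a * R),    R(t) = exp(-t/MTT),

evaluated as a discrete rectangle-rule convolution on the frame grid. The
exponential residue is the simplest standard choice (a box residue is
available via `PhantomSpec.residue="box"` for deconvolution stress tests).
Geometry is an elliptical brain containing a white-matter core, a
gray-matter shell and a small ischemic lesion, with clinical-magnitude
kinetics:

| region | CBF (mL/100g/min) | MTT (s) | baseline (HU) |
|--------|------------------:|--------:|--------------:|
| gray   | 60 | 4.0  | 42 |
| white  | 25 | 4.8  | 34 |
| lesion | 10 | 10.0 | 38 |

so ground-truth CBV = CBF*MTT/60 is known per pixel. The seed jitters
ellipse centres/radii by a few percent, giving distinct anatomies for
training and held-out evaluation. Default geometry is 512 x 512 x 119
frames with dt = 45/119 s (a 45 s cine acquisition); tests and the
acceptance script use reduced spatial sizes (32-64 px) with the same
kinetics, which changes nothing but the pixel count.

The phantom omits beam hardening, motion, partial-volume effects and
multi-slice z-geometry; voxels within a region share one kinetic curve, so
spatial texture comes only from region boundaries. Passing tests therefore
demonstrate the machinery (degradation arithmetic, training dynamics,
deconvolution algebra) on idealized data, not clinical performance.

## Dose degradation

Tube-current noise follows sigma = K sqrt(1/I - 1/I0) with K = 103.09
mA^1/2 and I0 = 190 mAs. The noise field is "spectrum" (spatially
correlated) Gaussian noise, realized as white noise filtered by an
isotropic Gaussian kernel; the correlation width (default 1.5 px) is the
one free knob. Each frame's field is mean-centred and rescaled so its
empirical standard deviation equals sigma exactly — centring keeps the
noise free of DC offsets and makes the per-frame mean identically zero;
frames are independent (no temporal correlation is modelled). Noise is
added in HU to the full-dose volume before any down-sampling.

Temporal down-sampling keeps frames {0, s, 2s, ...} (anchored at index 0 so
the baseline frame survives) and multiplies dt by s; spatial down-sampling
keeps the same grid-wise lattice along X and Y. Up-interpolation back to
the original size is a cubic B-spline evaluated at coordinate j/s
(`scipy.ndimage.map_coordinates`, edge-replicating boundaries): it
reproduces constants exactly and passes through the kept samples.

## Patch representation

Images are cut on an edge-covering grid: stride multiples plus one final
start clamped to `axis_len - patch_size` whenever the tiling stops short.
This is the convention consistent with the published patch totals for the
clinical geometry (24 starts on a 512 axis, 576 patches per frame; 1,428
training frames -> 822,528 patches, 476 validation frames -> 274,176);
floor-only tiling would give 23^2 = 529 per frame and contradict those
totals. Intensities map affinely from the HU window [0, 255] to [0, 1]
(clipped for network input); metrics use the same 0-255 scale. With the
phantom's indicator-dilution scaling, peak tissue enhancement exceeds the
display window and clips — exactly as a 300 HU arterial bolus clips in a
0-255 display; metrics apply the identical window to both arms, so
comparisons remain fair. Reassembly averages overlapping pixels, which
inverts extraction exactly because overlapping contributions agree.

## Network

Convolution triples (f, n, c) follow (kernel, filters, input channels).
One KR-block at trunk width w and bottleneck r computes

    1x1 (w->r) -> 7x7 (r->w) -> 3x3 (w->w) -> sum of the 7x7 and 3x3 maps
        -> 1x1 (w->w) -> + block input,

with PReLU (per-channel slope, init 0.25) after every convolution. The
SRDN wraps: 7x7 (1->128), 7x7 (128->128), 1x1 shrink, four KR-blocks
(w = 128, r = 64), 1x1 expand, 3x3 (128->128), 3x3 (128->1), and a global
input shortcut. Design notes:

* The second 7x7 layer necessarily takes 128 input channels (the output of
  the first); the (7, 128, 1) triple can only describe the first layer.
* The final "deconvolutional" (3, 1, 1) layer is a stride-1 transposed
  convolution, which is mathematically a same-size convolution — patch
  sizes never change inside the network, so stride 1 is the only consistent
  reading. No activation follows it.
* Each KR-block carries its identity skip, so block outputs already flow
  residually into the next block; no second additive edge is inserted
  between adjacent blocks (a duplicate identity edge would double features
  and break the zero-weight identity property below).
* With every convolution weight zero and shortcuts enabled the whole
  network — and the three-branch restorer with its conjoint mean — is the
  identity map. This is the main structural invariant the tests pin down.
* The conjoint layer averages in volume space, after each branch's 2D
  outputs are restacked to 3D; branches are trained independently and
  merged only at inference.

Training is MSE + Adam (the restoration target is PSNR, whose optimum is
the conditional mean — MSE's minimizer), default lr 1e-4 and batch 64 at
full width. The desk preset (width 16, reduce 8, one KR-block, 32 x 32
patches, lr 1e-3, batch 16) keeps a full training run on one CPU core in
the low minutes; with it, 300 Adam steps on ~360 patch pairs gain ~5-7 dB
over the 40 mAs / S2 degraded input on a held-out phantom. All layers are
float32; forward/backward passes use im2col + GEMM; every random draw
(init, batch sampling, noise) flows from explicit seeds, so loss traces and
restored volumes are bit-reproducible.

## Metrics

PSNR uses Imax fixed to the dynamic range L = 255 rather than the
per-image maximum: a per-image Imax moves the yardstick between slices and
breaks cross-slice averaging. SSIM uses an 8 x 8 uniform moving window with
population local moments — matching the plain product-of-terms formula,
which states no Gaussian weighting; border windows are handled by
reflection. The paired t-test is one-tailed (H1: restored > degraded),
df = n - 1; zero-variance differences raise a degenerate-input error
rather than returning a meaningless statistic. Aggregate variances are
reported across slices (the only replication axis a single phantom has).

## Perfusion

CBV is the trapezoidal area ratio of baseline-subtracted tissue curves to
the AIF; CBF comes from standard (non-delay-corrected) TSVD: the causal
lower-triangular Toeplitz matrix built from the AIF times dt, singular
values below 0.1 of the largest zeroed, CBF = 60 * max of the recovered
residue. Hematocrit/density proportionality constants are 1 — the phantom
defines its own units and all comparisons are ground-truth-relative. The
baseline is the mean of the first 4 frames (the bolus arrives at 5 s, so
these are pre-contrast); both maps are invariant to constant HU offsets.

Numerical behaviour worth knowing: the rectangle-rule convolution in the
generator carries a quadrature bias of ~dt/(2 MTT) in the curve area, so
CBV recovery error grows with dt/MTT (+4.8% for gray matter at the default
dt = 0.378 s; +13% at dt = 1 s — use the default dt when CBV accuracy
matters). TSVD CBF shows the well-known truncation underestimation
(~6-11% at threshold 0.1 on noiseless data, shrinking as the threshold
drops); the error decreases monotonically as sv_threshold -> 0 on
noiseless data but the threshold is what stabilizes noisy deconvolution.

## Pipeline

`run_pipeline` executes three experiment families — super-resolution only
(full dose), denoising only (no down-sampling), and joint — over a dose
grid (default 20/40/60/80 mAs) and scale grid (S1/S2/S3). One model per
family is trained on patches pooled across the dose grid (mixed-current
training); every dose x scale cell is then restored and scored, with image
and perfusion reports per cell and a manifest recording the configuration
and every derived seed. XY branches see spatial degradation, XT/YT
branches temporal degradation; the joint test cells degrade all three axes.
Problem sizes default to desk scale (64 x 64 x 40); the architecture is
fully convolutional, so the same code runs the clinical 512 x 512 x 119
geometry unchanged when more compute is available.

## Known limitations

* Phantom realism: no acquisition physics beyond the noise model; piecewise
  -constant kinetics; single z-slice.
* The HU display window clips peak contrast enhancement (see above).
* Standard TSVD only — no delay/dispersion correction, no MTT/TTP/Tmax
  maps, no Tikhonov/Bayesian variants.
* Desk-scale training demonstrates learning dynamics, not the ceiling
  performance of the full-width architecture on clinical data.
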