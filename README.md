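# stirnet

Spatio-temporal restoration of low-dose, low-resolution CT perfusion (CTP),
exercised end-to-end on synthetic brain phantoms.

## The problem

CT perfusion images a contrast bolus passing through one brain slice: a cine
acquisition produces an `X x Y x T` volume (e.g. 512 x 512 x 119 frames over
~45 s at 190 mAs). The radiation dose is substantial, and the three obvious
ways to cut it each damage the data: lowering the tube current *I* raises
image noise as

    sigma = K * sqrt(1/I - 1/I0),

(with *I0* the reference current and *K* a scanner constant), lengthening the
frame interval removes temporal samples, and reducing the beam/receptor count
removes spatial samples. This package implements a learned restorer that
attacks all three degradations at once, together with everything needed to
study it without patient data: a kinetic phantom generator, the low-dose
simulator, the patch pipeline, image-quality metrics, and the clinical
endpoint — CBF/CBV perfusion maps by TSVD deconvolution.

## The method

The volume is sliced into three families of 2D cross-sections — `XY`
(spatial frames), `XT` and `YT` (one spatial axis against time) — so a 2D
convolutional network sees temporal structure as image structure. Each
family is restored by an **SRDN** (super-resolution denoising network): two
7x7 feature-extraction layers, a 1x1 shrinking layer, a chain of
**kernel-regulation blocks** (serial 1x1 -> 7x7 -> 3x3 convolutions whose
large- and small-kernel feature maps are blended by pixel-wise summation,
wrapped in an identity skip), a 1x1 expanding layer, and a two-layer
reconstruction head, plus a global input shortcut (the network learns a
residual). Training minimizes the MSE between restored and clean 41x41
patches (stride 21, edge-covering grid). At inference the three restored
volumes are blended by a **conjoint layer** — a voxel-wise mean.

Quality is scored per XY slice by PSNR (`20 log10(255/rmse)`) and SSIM
(stabilizers `c1 = 6.5025`, `c2 = 58.5225`, `c3 = 29.26125` at dynamic range
255), with paired one-tailed t-tests on the improvements. Perfusion maps
follow the indicator-dilution model: CBV as the area ratio of
baseline-subtracted tissue curves to the arterial input function (AIF), CBF
from truncated-SVD deconvolution of the AIF convolution matrix
(`CBF = 60 * max k`, `CBV = CBF * MTT / 60`).

The network layers (im2col convolutions, PReLU, Adam, backpropagation) are
implemented directly on numpy; everything is deterministic given its seed.

## Worked example

```python
import stirnet as sn

spec = sn.default_phantom_spec(48, 48, 119, seed=1)   # gray/white/lesion
vol, gt = sn.generate_phantom(spec)

dose = sn.DoseParams(I=40.0, seed=1)                  # 40 of 190 mAs
print(f"noise sigma at 40 mAs: {sn.noise_sigma(dose):.3f} HU")
low = sn.simulate_low_dose(vol, dose,
                           sn.SamplingSpec(scale=2, axis_set=frozenset("xy")))

aif = sn.make_aif(spec.aif, vol.times)
cbv = sn.compute_cbv(vol, aif)
cbf = sn.compute_cbf_tsvd(vol, aif)
for r in spec.regions:
    print(f"{r.name:6s}  true CBF {r.cbf:5.1f} -> est {cbf[r.mask].mean():5.1f}   "
          f"true CBV {r.cbv:4.2f} -> est {cbv[r.mask].mean():4.2f}")
```

prints

```
noise sigma at 40 mAs: 14.483 HU
gray    true CBF  60.0 -> est  53.3   true CBV 4.00 -> est 4.19
white   true CBF  25.0 -> est  22.5   true CBV 2.00 -> est 2.08
lesion  true CBF  10.0 -> est   9.4   true CBV 1.67 -> est 1.64
```

The 40 mAs current injects 14.5 HU of spatially correlated noise; on the
noiseless phantom the TSVD deconvolution recovers per-region CBF within the
usual truncation underestimation (here about 6-11%) and CBV within 5%.

The same loop is available from the shell:

```sh
stirnet phantom --out ph/ --seed 3
stirnet degrade --in ph/phantom.nii --ma 40 --scale 2 --axes xy --seed 1 --out low.nii
stirnet patchify --clean ph/phantom.nii --degraded low.nii --section xy --out pairs.npz
stirnet train --section xy --data pairs.npz --preset desk --out model/
stirnet restore --in low.nii --model model/ --out restored.nii
stirnet evaluate --gt ph/phantom.nii --lr low.nii --restored restored.nii --out report/
stirnet perfusion --in restored.nii --out maps/
stirnet run --out experiment/ --seed 0        # the full dose x scale grid
```

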