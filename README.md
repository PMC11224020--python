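# dcmorph

Morphometry for studying how migrating immune cells — dendritic cells in
particular — sense their own shape. When a dendritic cell squeezes through
tissue or is confined to a controlled height, its nucleus deforms: the
nuclear envelope unfolds, stretch sensors such as cPLA₂ accumulate in the
nucleus, and the cell upregulates the migration receptor CCR7. `dcmorph`
implements the image-derived statistics used to quantify each step of that
cascade from 2D masks and intensity images, plus seeded synthetic
generators that provide analytic ground truth for every measurement.

## What it computes

**Nuclear-envelope folding (EOP).** For a nucleus contour with perimeter
*P* and area *A*, let *R₀* = √(*A*/π) be the radius of the equal-area
circle. The excess of perimeter

&nbsp;&nbsp;&nbsp;&nbsp;EOP = (*P* − 2π*R₀*) / 2π*R₀*

is 0 for a circle (smooth, tense envelope) and grows toward 1 for a
heavily folded envelope. It is non-negative for every simple closed curve
(isoperimetric inequality) and invariant to translation, rotation and
scale.

**Contour smoothness (EFC ratio).** The contour is expanded into elliptic
Fourier descriptors (Kuhl–Giardina): harmonic *k* contributes an ellipse
with semi-axes *A_k* ≥ *B_k* (singular values of the 2×2 coefficient
block). With *N* = 25 harmonics,

&nbsp;&nbsp;&nbsp;&nbsp;EFC = (*A₁* + *B₁*) / Σ_{k=2..N} (*A_k* + *B_k*).

The larger the ratio, the more of the shape is captured by one smooth
ellipse; wrinkly contours score low. A numerically vanishing denominator
(e.g. a circle) is flagged degenerate and capped at 10⁶.

**Cell diameters over time.** Each timelapse frame's binary mask is
thinned to its skeleton; the exact Euclidean distance transform is sampled
along it and doubled to give local diameters. Per-frame min/mean/max are
averaged per cell, and residence fractions report the share of track time
spent at a minimum diameter in [2, 4) µm versus ≥ 4 µm (tracks ≥ 40 min).
Greedy nearest-centroid linking with a 20 µm/frame gate yields tracks and
median/mean speeds.

**Intensity rules.** Nucleus-to-cytosol ratio = mean over the nucleus mask
divided by mean over cell-minus-nucleus, measured in the plane where the
nucleus mask is largest; reporter means are gated against the image
background (median outside dilated cell masks).

**qPCR fold change.** Comparative-Ct: ΔCt = Ct_target − Ct_reference per
sample, ΔΔCt vs the control-condition mean, fold = 2^−ΔΔCt (control
geometric mean ≡ 1).

## Worked example

```sh
python examples/nuclear_folding.py
```

```
smooth        a_8=0.00  perimeter= 31.42 µm  EOP= 0.0000  EFC=degenerate (pure first ellipse)
mild folds    a_8=0.05  perimeter= 32.64 µm  EOP= 0.0382  EFC=   19.16
strong folds  a_8=0.10  perimeter= 35.97 µm  EOP= 0.1420  EFC=    9.38
```

Three synthetic nuclei of base radius 5 µm with radial folds of increasing
amplitude at angular frequency 8: the perimeter grows while the area stays
nearly fixed, so EOP rises from 0 to 0.14; the EFC ratio falls from
degenerate (a circle is a pure first ellipse) to 9.4 as the folds push
shape energy into higher harmonics. The other scripts in `examples/`
demonstrate diameters/residence/speed, intensity ratios, qPCR folds and a
full simulated two-condition study (`full_run.py`), each printing the
recovered values next to the generator's ground truth.

The same measurements are available from the shell:

```sh
dcmorph simulate nucleus --out fixtures/
dcmorph morphometry --masks fixtures/ --pixel-size 0.25 --out metrics.csv
dcmorph run --seed 1 --out study/
```

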