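# stromamech

Quantification toolkit for tumor-stroma mechanics. It implements the
measurement chains used to characterize how stromal cells (such as
pancreatic stellate cells, PSCs) remodel their extracellular matrix:

* **Fiber morphometrics** for SHG-like images of fibrillar collagen —
  alignment by FFT-ellipse eccentricity, fiber diameter by local
  (inscribed-disk) thickness, fiber length by skeleton branches, and ROI
  intensity density.
* **Micropillar traction forces** — subpixel spot tracking of
  pillar-array time-lapses, stage-drift correction from cell-free
  reference pillars, and force conversion through the linear spring law.
* **LFQ proteomics statistics** — low-abundance missing-value
  imputation, two-tailed unpaired t-tests with Benjamini–Hochberg FDR,
  ±50% regulation calls, plus RPKM normalization and an exact
  Mann–Whitney stability check for housekeeping gene sets.

Each measurement module is paired with a synthetic-data generator
(fiber fields with von Mises orientations, pillar movies with programmed
forces and drift, LFQ matrices with MNAR dropout) that provides exact
ground truth, so every estimator in the package is validated by
recovery, not by eye.

## The quantities at the core

**Alignment score.** Each image tile (default 100 µm) is mean-subtracted,
Hann-windowed and Fourier transformed; the centered power spectrum is
summarized by its power-weighted second-moment ellipse over the central
half-Nyquist disk. The score is the axis ratio

    e = minor / major  ∈ [0, 1]

A circular spectrum (e → 1) means no preferred fiber orientation;
parallel fibers concentrate spectral power orthogonal to their axis and
drive e → 0.

**Local thickness.** For a binarized fiber mask, thickness at pixel *p*
is the diameter of the largest disk that fits inside the foreground and
contains *p*:

    T(p) = 2 · max { r(c) : ‖p − c‖ ≤ r(c) }

with r(c) the inscribed-disk radius at c from the Euclidean distance
transform. The implementation (distance ridge + disk painting) equals
the brute-force definition exactly.

**Traction forces.** Pillar deflection d(t) = x(t) − x₀ (drift-corrected,
zero-force reference x₀) converts to force through the spring constant
k (nN/µm): F(t) = k·|d(t)|. Per pillar the peak force is max_t F(t); the
per-movie summary is the mean of peaks over the engaged pillars.

**Proteomics procedure.** Missing LFQ values of protein *p* are drawn
from Normal(m_p/100, (m_p/100)/100), where m_p is the protein's observed
non-zero minimum; groups are compared with equal-variance two-tailed
t-tests; q-values are BH step-up; a protein is called up (down) when
significant and its group mean ratio is ≥ 1.5 (≤ 1/1.5).

## Worked example

Simulate an isotropic collagen field and a strongly aligned one
(von Mises concentration κ = 8), then score both:

```bash
stromamech simulate-fibers --seed 1 --out iso

cat > fibers.yaml <<'YAML'
n_fibers: 200
orientation_kappa: 8.0
orientation_mean_rad: 0.7
YAML
stromamech simulate-fibers --config fibers.yaml --seed 1 --out aligned

stromamech score-alignment iso/fibers.tif     --tile-um 100 --out scores_iso
stromamech score-alignment aligned/fibers.tif --tile-um 100 --out scores_aligned
stromamech thickness iso/fibers.tif --out thick_iso
```

prints

```
mean alignment score 0.895 over 4 tiles
mean alignment score 0.414 over 4 tiles
mean fiber thickness 1.318 um
```

The isotropic field scores near 1 (circular spectrum, no preferred
orientation); the κ = 8 field scores far lower (aligned fibers). The
thickness mean of 1.32 µm matches the generator's fiber diameter
(2 × 0.6 µm radius) to within the half-pixel anti-aliasing rim.

Pillar force recovery end-to-end (simulate → track → correct drift →
forces), with 5/10/15 nN plateaus, stage drift and shot noise at
peak-SNR 10:

```bash
stromamech pillar-recovery --config pillars.yaml --seed 1 --out rec
# -> max relative peak-force error 2.935%
```

where `rec/recovery.csv` lists programmed versus recovered peak force
per pillar (e.g. 5.00 → 5.15 nN, 10.00 → 9.96 nN).

As a library, the same chains are plain functions:

```python
from stromamech import (FiberFieldParams, generate_fiber_image,
                        score_image_alignment)

img, truth = generate_fiber_image(FiberFieldParams(seed=1))
result = score_image_alignment(img, tile_um=100)
print(result.mean_score)        # 0.895
```

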