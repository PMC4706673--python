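# collagenkit

Quantitative analysis of collagen micro-organization in breast tissue, for
studies linking mammographic density (MD) to stromal remodelling. High MD is
a modifiable breast-cancer risk factor, yet the tissue-level drivers are
contested: is dense tissue simply more collagen, or differently *organised*
collagen? Answering that requires a chain of quantitative measurements —
histology compartment fractions, birefringent-collagen abundance and
alignment, fibril ultrastructure, micro-scale stiffness, and protein
abundance — each with its own pitfalls. `collagenkit` implements that chain
as a tested, reusable pipeline, together with seeded synthetic-data
generators so every stage can be validated against known ground truth
without patient material.

## What it computes

- **Histology segmentation** (`histoseg`): per-pixel classification of
  RGB sections into background / epithelial / stromal / adipose using
  hue-saturation-brightness rules (epithelium lowest brightness and hue,
  adipose highest, stroma intermediate; automatic 3-class Otsu brightness
  cuts), tissue fractions, stain-positive fractions (Masson collagen, PSR
  birefringence), and the peri-ductal band (stroma within 20 µm of ducts).
- **Fibre orientation** (`orientation`): Gaussian-windowed structure
  tensor J = [⟨f_x²⟩, ⟨f_x f_y⟩; ⟨f_x f_y⟩, ⟨f_y²⟩]; orientation
  θ per pixel and coherency (λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1], with an
  energy-gated ROI mean — the standard OrientationJ-style alignment
  statistic.
- **AFM topography** (`afm_topo`): plane-detrended, Hann-windowed 2-D
  power spectra of height maps; collagen D-band periodicity from the
  parabolic-interpolated radial-spectrum peak in the 40–100 nm band
  (≈66 nm for native fibrils); angular anisotropy of the annular power
  (discrete spots = aligned fibrils, diffuse ring = isotropic).
- **Force spectroscopy** (`forcespec`): extend-curve baseline correction,
  exhaustive piecewise contact-point detection, spherical Hertz fit
  F = (4/3)·E_r·√R·δ^{3/2} restricted to forces ≤ 70 % of peak,
  single-pass 2-SD quality control per modulus map, and Mann–Whitney /
  ANOVA group contrasts.
- **Proteomics** (`proteome`): normalisation, high/low group-mean fold
  changes, and the strict >2-fold differential screen.
- **Cohort statistics** (`study`): Pearson r² associations between density
  scores (VAS % area, Volpara % volume) and tissue metrics, low/high-MD
  group contrasts, and a deterministic JSON/CSV report; a `--simulate`
  mode runs the whole chain on generated data.
- **Synthetic data** (`synthetic`): seeded generators for three-compartment
  histology images, fibre images with calibrated alignment, D-banded
  fibril height maps, Hertzian force-curve grids and proteome tables —
  each returning a ground-truth record for parameter-recovery tests.

## Worked example

```python
import numpy as np
from collagenkit import (
    Cantilever, gen_force_grid, gen_heightmap, process_curve,
    build_modulus_map, radial_power_spectrum, dband_periodicity,
)

# D-band periodicity of an aligned, banded synthetic height map
hmap, truth = gen_heightmap(preset="tendon", seed=1)
result = dband_periodicity(radial_power_spectrum(hmap))
print(f"D-period {result.period:.1f} nm (planted {truth.params['period_nm']})")

# Hertzian modulus map with 2-SD quality control
cant = Cantilever(spring_constant=3.0, tip_radius=1.0)  # N/m, um
curves, truth = gen_force_grid(np.full((5, 5), 500.0), cant, seed=1)
fits = [process_curve(c, cant, coarse_step=3) for c in curves]
mmap = build_modulus_map(fits, region_size=25.0)
print(f"median modulus {mmap.median():.0f} kPa, "
      f"{mmap.excluded.sum()} of {mmap.grid.size} points excluded")
```

prints

```
D-period 65.4 nm (planted 66.0)
median modulus 472 kPa, 1 of 25 points excluded
```

The recovered period sits within the spectral-bin tolerance of the planted
66 nm D-band, and the fitted map centres near the planted 500 kPa modulus
(per-curve noise leaves a few-percent median error) with the usual small
QC exclusion.

A full simulated cohort analysis (22 patients, 6 low + 6 high MD selected
for mechanics) runs from the command line:

```sh
collagenkit study --simulate --seed 1 --out results/study
```

and writes `report.json` (associations with n, r², p; contrasts with U, p;
per-stage seeds) plus the cohort table.

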