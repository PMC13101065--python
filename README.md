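# qpmorph

Quantitative-phase-microscopy (QPM) morphometry of single cells: from raw
off-axis interferograms to per-cell height maps, binary masks, a
16-feature morphological panel, and the paired / trend statistics used to
characterize how cells — in the motivating application, type-1 astrocytes
subjected to a laser-induced shockwave — change shape over time.

QPM measures optical path length, OPL = n · t, per pixel. Under a uniform
average refractive index for the cytoplasm, the unwrapped phase φ maps to
physical height

    h = φ λ / (2π · p · Δn)

with λ the illumination wavelength (default 0.633 µm, red LED), Δn the
cell–medium index contrast (default 0.037 = 1.370 − 1.333), and p the
optical pass factor (2 for a reflective Linnik geometry). From h and a
single-cell mask the panel includes projected area, volume V = Σ h·px²,
dry mass m = V·Δn/α (α ≈ 0.19 µm³/pg, the specific refractive increment),
triangulated 3D surface area, height moments (variance, skewness,
non-excess kurtosis), circularity 4πA/P², eccentricity, perimeter,
perimeter/area, and the convex-hull complexity score
(hull − area)/hull — 0 for convex cells, higher for branched ones.

The package is organized as the pipeline runs:

| module | role |
|---|---|
| `qpmorph.phase` | Fourier fringe demodulation, Goldstein branch-cut unwrapping, phase→height |
| `qpmorph.segmentation` | crops, local-median threshold (50 px radius), open, keep-largest, background correction, auto-vs-manual percent error |
| `qpmorph.morphometry` | the 16-feature panel |
| `qpmorph.stats` | paired Wilcoxon signed-rank, Mann–Kendall tau-b trends, Rayleigh bubble energy |
| `qpmorph.synthetic` | star-shaped phantom cells, rendered interferograms, cohort simulation |
| `qpmorph.pipeline`, `qpmorph.cli` | config-driven end-to-end runs (`qpmorph` console command) |

Because no public raw-image archive exists for this kind of experiment,
the synthetic module generates phantom astrocytes (cosine-cap body plus
tapered radial branches) with exact ground truth, so the whole chain is
testable offline.

## Worked example

```python
import qpmorph as qp

# phantom cell -> interferogram -> reconstruction -> mask -> features
spec = qp.PhantomSpec(body_radius_um=12, n_branches=5, pixel_size_um=0.25, seed=7)
hm, truth_mask, truth = qp.generate_phantom_cell(spec)
ig = qp.render_interferogram(hm)                       # off-axis fringes
wp = qp.demodulate_fringes(ig)                         # wrapped phase
up = qp.unwrap_goldstein(wp)                           # continuous phase
rec = qp.phase_to_height(up, hm.wavelength_um, hm.delta_n,
                         hm.pass_factor, hm.pixel_size_um)
mask, particles = qp.segment_cell(rec.height_um, offset=0.05)
corrected = qp.background_correct(rec.height_um, particles)
feats = qp.extract_all(corrected, mask, qp.CalibrationParams(pixel_size_um=0.25))
```

prints, against the phantom's analytic ground truth:

```
            volume:     771.54   (truth     773.30)   # µm³
    projected_area:     653.81   (truth     632.64)   # µm²
      surface_area:     726.10   (truth     728.10)   # µm²
          dry_mass:     150.25   (truth     150.59)   # pg
       circularity:       0.16   (truth       0.13)
  complexity_score:       0.67   (truth       0.71)
```

i.e. the optical round trip (render → demodulate → unwrap → height →
segment → extract) recovers volume and surface area to well under 1% and
the dimensionless shape scores to a few hundredths.

Cohort-level statistics on the default simulated shock-response cohort
(204 cells, 9 timepoints):

```python
coh = qp.generate_cohort(n_cells=204, seed=42)
qp.summarize_pairwise(coh, -1.0, 10.0)       # 1 min before vs 10 min after
qp.trend_over_time(coh, "volume", timepoints=[10,30,50,70,90,110,120])
```

```
parameter      mean_diff      sem       p_value  significant
surface_area   -3819.11    152.76      3.9e-35       True     # µm²
volume           389.98     18.23      4.2e-34       True     # µm³
circularity        0.03      0.001     4.9e-34       True
volume trend: tau_b -1.0, p 0.0027
```

The signs tell the biology: immediately after the shock the cells retract
branches (surface area and perimeter drop), round up (circularity rises)
and swell (volume rises); over the following two hours the cohort-mean
volume declines monotonically back toward baseline (tau-b = −1) while
surface area recovers (tau-b = +1).

The same chain runs from the shell:

```sh
qpmorph simulate --out sim --n-cells 12 --timepoints "-1,10,60,120" --fringes
qpmorph run --config run.yaml
qpmorph verify --auto runA/masks --manual runB/masks --out report
```

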