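# retperf

Quantification of **macular tissue perfusion** — the blood flow supplying
the central retina divided by the volume of the tissue that flow feeds —
from two measurements a retinal clinic can make non-invasively:

1. **Blood flow** from fundus-camera velocimetry (Retinal Function
   Imager-style data): every arteriole and venule crossing a 2.5 mm
   circle centered on the fovea contributes a flow term. The vessel
   caliber *d* is read off the image as the **full width at half
   maximum (FWHM)** of the intensity profile perpendicular to the
   centerline at the crossing; with the signed velocity *v* (mm/s,
   negative for arterioles, positive for venules) the per-vessel flow is
   the plug-flow flux

   *Q* = |*v*| · π (*d*/2)² · 1000  [nl/s]

   Arteriolar and venular flows are summed separately and the macular
   flow is their average (inflow ≈ outflow). Velocities measured at the
   35° field of view (7.3 × 7.3 mm²) are converted to the 20° frame
   (4.3 × 4.3 mm²) by ×0.95 (arterioles) / ×0.92 (venules).

2. **Tissue volume** from OCT layer segmentation: seven boundary
   surfaces on a 6 × 6 mm raster (128 × 512 samples) delimit six
   intra-retinal layers (RNFL, GCIPL, INL, OPL, ONL, PR). The **inner
   retina** — RNFL+GCIPL+INL+OPL, the compartment containing the retinal
   vascular plexuses — is integrated over the same 2.5 mm foveal disc.

The perfusion metric is then

**tissue perfusion (nl/s/mm³) = blood flow (nl/s) / tissue volume (mm³)**

The package is aimed at readers and reviewers of retinal-hemodynamics
case–control studies (e.g. Alzheimer's disease vs cognitively normal
cohorts) who want every stage of such an analysis as tested, reusable
code. Because raw patient imaging is rarely shareable, `retperf` ships a
**synthetic scene generator**: vessel networks converging on the fovea,
rendered fundus images whose Gaussian vessel cross-sections have known
FWHM, OCT layer surfaces with a foveal pit, and two-arm cohorts drawn
from configurable group distributions — so the whole pipeline can be
validated against known ground truth.

## Worked example

```python
import retperf as rp

# one synthetic eye calibrated to carry 2.82 nl/s through a
# 1.0930 mm^3 inner retina (GCIPL 0.47 mm^3), rendered noiselessly
scene = rp.build_scene(2.82, 1.0930, 0.47, seed=7)

res = rp.measure_macular_flow(scene.image, scene.vessels)
vols = rp.layer_volume(scene.surfaces)
perf = rp.tissue_perfusion(res.macular_flow_nl_s, vols.inner_retina_mm3)
```

prints (via the obvious f-strings):

```
arteriolar total : 2.810 nl/s
venular total    : 2.816 nl/s
macular flow     : 2.813 nl/s
imbalance        : 0.0021
inner retina     : 1.0930 mm^3
GCIPL            : 0.4700 mm^3
tissue perfusion : 2.573 nl/s/mm^3
```

The image-based measurement recovers the injected 2.82 nl/s within
0.3%; the volume integration is exact by calibration; the perfusion is
flow/volume. A full two-arm study is one call:

```python
df = rp.simulate_cohort()          # 24 case + 19 control subjects
print(rp.comparison_markdown(rp.compare_groups(df)))
```

```
| Outcome | CAD (mean ± SD) | CN (mean ± SD) | Decrease | t | p |
|---|---|---|---|---|---|
| tissue perfusion (nl/s/mm^3) | 2.41 ± 1.02 (n=24) | 3.55 ± 0.41 (n=19) | 32% | -4.59 | 4.1e-05 |
| macular blood flow (nl/s) | 2.67 ± 1.10 (n=24) | 4.06 ± 0.42 (n=19) | 34% | -5.20 | 5.9e-06 |
| inner retina volume (mm^3) | 1.12 ± 0.08 (n=24) | 1.15 ± 0.10 (n=19) | 3% | -1.07 | 0.29 |
| GCIPL volume (mm^3) | 0.46 ± 0.04 (n=24) | 0.50 ± 0.04 (n=19) | 8% | -3.28 | 0.0021 |
```

i.e. one random realization of a study in which the case arm is
hypoperfused (~30% lower perfusion and flow, a few percent lower GCIPL
volume), with pooled-variance Student t-tests per outcome.

The `retperf` command exposes the same stages from a shell:
`retperf simulate | flow | volume | analyze | run` (see `--help`).

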