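# octenergy

Outer-retina **energy biomarkers** from optical coherence tomography
(OCT) B-scans, with a synthetic phantom generator so that every stage of
the analysis can be validated against exact ground truth.

Rod photoreceptors are among the most energy-demanding neurons in the
body, and two OCT-visible quantities track their metabolic state:

* **ELM–RPE thickness** — the distance from the external limiting
  membrane (ELM) to the basal retinal pigment epithelium (RPE) at
  Bruch's membrane. High rod energy demand (e.g. dark adaptation)
  acidifies the subretinal space and triggers water removal, so the
  ELM–RPE *contracts* by a few micrometers.
* **MCP/AR** — the minor-to-major aspect ratio of an ellipse
  moment-matched to the hyperreflective band immediately posterior to
  the ELM (the ellipsoid zone, dense with photoreceptor mitochondria)
  on the mean A-line reflectivity profile. Axial spreading of the band
  — associated with inefficient mitochondria — changes this shape
  descriptor.

`octenergy` implements the full measurement pipeline for these
biomarkers, for mouse retina studied cross-sectionally under light/dark
adaptation or genotype contrasts:

1. **phantom** — layered-retina B-scan simulator (reflectivity slabs for
   NFL/GCL, IPL, INL+OPL, ONL; Gaussian ELM/EZ/RPE bands; curvature,
   vessel shadows, multiplicative speckle, per-frame rigid jitter) with
   exact boundary ground truth, plus whole-cohort simulation with
   group-level effects on ELM–RPE, band elongation, contrast sensitivity
   and acuity.
2. **registration** — selection of the central frames of a volume
   (1-based inclusive, e.g. frames 450–549 of 1000), first-pass rigid
   registration (rotation grid + subpixel translation, scored by
   normalized cross-correlation), three iterations of non-rotational
   per-column/per-row refinement, then pixel-wise averaging with an NCC
   quality floor.
3. **segmentation** — classical per-column seed boundaries, dynamic
   programming shortest-path refinement within a band around each seed,
   subpixel (parabolic) localization of the ELM/EZ/RPE intensity peaks,
   and Bruch's membrane as the posterior half-maximum crossing of the
   RPE band.
4. **biomarkers** — analysis regions 350–624 µm from the optic nerve
   head on the inferior and superior sides; laminar thicknesses
   (ELM–RPE, IPL, INL+OPL, ONL); RPE flattening by integer column shifts
   (no stretching); mean reflectivity profiles; band delimitation by
   flanking minima with a chord baseline; moment-matched ellipse fit.
5. **stats** — per-mouse averaging, Welch mean differences with 95% CIs,
   and a gamma GLM with log link (fold changes) for contrast
   sensitivity.

## Worked example

Simulate a light/dark study (5 mice per condition, a 4 µm true dark
contraction of the ELM–RPE and a 20 % dark elongation of the EZ band)
and run the whole pipeline:

```yaml
# study.yaml
geometry: {rows: 320, cols: 480, lateral_px_um: 2.8}
registration: {rot_max_deg: 1.0}
simulate:
  groups:
    - {label: B6J, condition: light, n_mice: 5, elm_rpe_um: 50.0, ez_elongation: 1.0}
    - {label: B6J, condition: dark,  n_mice: 5, elm_rpe_um: 46.0, ez_elongation: 1.2}
  n_frames: 4
  speckle_sigma: 0.05
seed: 7
out_dir: study_out
```

```sh
octenergy run-all --config study.yaml
cat study_out/report.txt
```

```
elm_rpe_um [B6J/light vs B6J/dark]: mean 3.74 um, 95% CI 1.95-5.53 um (p = 0.0017, n = 5/5)
mcp_ar [B6J/light vs B6J/dark]: mean -0.01, 95% CI -0.01--0.01 (p = 1.9e-08, n = 5/5)
ipl_um [B6J/light vs B6J/dark]: mean -0.01 um, 95% CI -0.03-0.01 um (p = 0.35, n = 5/5)
...
```

Reading: relative to dark-adapted eyes the light condition measures a
**3.74 µm thicker ELM–RPE** (the simulated truth was 4 µm, recovered
within the between-mouse noise), a **lower MCP/AR in light** (the dark
group's elongated band raises its aspect ratio), and — as designed — no
light/dark difference in the inner laminar thicknesses. `study_out/`
also contains the tidy per-eye table (`biomarkers.csv`), the effect
table (`effects.csv`), the simulation truth (`truth.csv`) and a
`manifest.json` with the config hash and seed that make the run exactly
reproducible.

The CLI also exposes each stage separately (`octenergy register`,
`segment`, `measure`, `stats`) for real TIFF stacks with JSON metadata
sidecars; the same functionality is available as a library
(`octenergy.measure_eye`, `octenergy.run_pipeline`, ...).

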