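# octgland

Quantification of labial minor salivary gland (LSG) surface density from
volumetric optical coherence tomography (OCT) of the lower-lip mucosa.

LSGs are small mucus-secreting glands that are progressively destroyed in
cystic fibrosis; their surface density (glands/cm² of mucosa) is therefore a
candidate marker of CF-related alimentary-tract disease. In swept-source OCT
volumes the glands appear as hypointense foci against the bright muscular
layer, each connected to the surface by a narrow hypointense excretory duct.
This package implements the full quantification chain for such volumes and is
aimed at researchers building or validating OCT-based gland-counting
pipelines:

1. **simulate** — a synthetic SS-OCT phantom generator (layered mucosa,
   multiplicative speckle, depth attenuation, tilted/bulged surface,
   ellipsoidal glands with ducts) with exact ground truth, plus fixed
   two-cohort presets (18 + 18 subjects);
2. **reconstruct** — spectral-fringe synthesis and Fourier A-scan recovery,
   verifying the depth-frequency encoding principle;
3. **preprocess** — mucosal-surface segmentation and volume flattening so
   depth is measured below the tissue surface;
4. **glands** — en-face (C-scan) projection at 750 µm, detection of
   hypointense foci inside the 2.43 cm² useful imaging surface, excretory-duct
   matching, and the counting rule `accepted = has_duct OR on_border`;
5. **stats** — surface densities (count / 2.43 cm²), two-sided Mann–Whitney U
   comparison (exact for small samples, tie-corrected normal approximation
   otherwise), ICC(2,1) observer agreement, and the planning-stage sample-size
   formula `n = ⌈2 (z₁₋α/₂ + z_power)² σ²/δ²⌉`;
6. **pipeline / CLI** — a reproducible end-to-end run with manifests.

See `docs/methods.md` for the model, parameter defaults and their rationale.

## Worked example

Simulate the two built-in 18-subject cohorts at a reduced raster
(128×128×256 over the full 1.73×1.73 cm² field), run the pipeline, and
compare the groups:

```python
from octgland import PhantomConfig, RunConfig, ScanGeometry, run_cohort_pipeline

geometry = ScanGeometry(n_fast=128, n_slow=128, n_depth=256)
result = run_cohort_pipeline(RunConfig(phantom=PhantomConfig(geometry=geometry), seed=1))

for label, g in result.summary.groups.items():
    print(f"{label}: median {g.median:.2f} [IQR {g.q1:.2f}-{g.q3:.2f}] glands/cm^2")
print(f"Mann-Whitney U = {result.summary.u_statistic}, p = {result.summary.p_value:.2g}")
```

prints

```
CF-like: median 4.32 [IQR 3.40-6.07] glands/cm^2
HS-like: median 6.58 [IQR 5.76-8.13] glands/cm^2
Mann-Whitney U = 57.5, p = 0.00097
```

The lower-density cohort has a median LSG surface density of 4.32 glands/cm²
against 6.58 glands/cm² in the higher-density cohort, and the rank-sum test
rejects equality of the two distributions. Every detected count equals the
generator's ground truth (the phantoms' glands all carry ducts and lie inside
the useful surface, so the expected accepted count is simply the gland
count).

The same run is available from the shell:

```bash
octgland run --out runs/demo --seed 1 --n-lateral 128 --n-depth 256
octgland simulate --preset cf --out phantoms/ --seed 3 --n-lateral 128 --n-depth 256
octgland detect phantoms/CF-like-00.tif --out runs/demo
```

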