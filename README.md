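# tabfx

**Does the patient table matter for attenuation correction in myocardial-perfusion SPECT?**

`tabfx` is a fully synthetic, end-to-end testable re-creation of that
experiment, for medical-physics and nuclear-medicine researchers.  The CT
used for attenuation correction (AC) always contains the scanner's patient
table; emerging CT-less AC methods (e.g. deep-learning attenuation maps
estimated from emission data) cannot predict the table.  The package
quantifies how much the table actually contributes by reconstructing the
same projection data twice — with the table left in the attenuation map and
with it removed — and measuring the difference on quality-control phantoms
and on a simulated patient cohort.

## What it does

* **Synthetic studies** (`tabfx.synthetic`): a Jaszczak-type cylindrical
  phantom (216 mm ⌀, water-filled, uniform activity) and a torso proxy with
  a half-ellipsoid-shell left ventricle (optional regional perfusion
  defects), each resting in a parametric arc-shell carbon-fiber patient
  table, with voxelized ground-truth masks.
* **Table removal** (`tabfx.table_removal`): threshold the central CT slice
  at −700 HU, label connected regions, classify the most posterior region
  as the table, enlarge it by 3 dilations with a 9×9 kernel (subtracting
  body pixels so the dilation never eats the object), and remove the region
  from all slices.
* **Attenuation maps** (`tabfx.attenuation`): bilinear HU→μ conversion at
  140 keV (μ_water = 0.154 cm⁻¹, reduced bone slope) and world-frame
  trilinear resampling onto the reconstruction grid.
* **Acquisition** (`tabfx.acquisition`): attenuated parallel-beam
  projection over the clinical protocols — 64 views/360° (quality control)
  and 34 views/204° (MPI, −102°…+102° about the anterior axis) — with a
  129–150 keV photopeak and a 108–129 keV lower scatter window, optional
  Poisson noise, and energy-window scatter correction
  `S = (C_low / W_low) · W_peak / 2`.
* **Reconstruction** (`tabfx.reconstruction`): OSEM, 10 iterations × 3
  subsets (bit-reversal view interleaving), with attenuation inside a
  matched forward/backprojector pair

  `a_j ← a_j · [Σ_{i∈S} c_ij p_i / Σ_k c_ik a_k] / [Σ_{i∈S} c_ij]`.
* **Polar maps** (`tabfx.cardiac_polar`): short-axis reorientation, AHA
  17-segment bull's-eye with maximal-count radial sampling, and integer
  perfusion scores 0–4 from normalized segment uptake
  (≥70→0, 50–69→1, 30–49→2, 10–29→3, <10→4).
* **Comparison** (`tabfx.comparison`): percentage-difference volumes
  `100·(A−B)/A` masked at 5 % of max(A), and paired score statistics
  (pooled and per-segment paired t-tests, Shapiro–Wilk, Pearson r).

## Worked example

```python
from tabfx.pipeline import (
    ExperimentConfig, run_phantom_experiment,
    default_spect_grid, default_ct_grid,
)

cfg = ExperimentConfig(
    experiment="qc_phantom",
    spect_grid=default_spect_grid(2),   # 64^3 at 9.6 mm, full 614 mm FOV
    ct_grid=default_ct_grid(2),         # 256^2 x 48 at 2 x 2 x 5 mm
)
report = run_phantom_experiment(cfg)
print(f"max |% diff| = {report.diff.max_abs_pct:.1f}%")
print(f"mean per-angle count loss = {100 * report.count_reduction.mean():.1f}%")
```

prints

```
max |% diff| = 16.0%
mean per-angle count loss = 3.3%
```

Reading: omitting the default table from the attenuation map biases the
reconstruction by at most 16 % — and only in the voxels adjacent to the
table at the bottom of the phantom (`report.diff.argmax_index` sits in the
posterior third); the interior is essentially unaffected.  The table
removes on average 3.3 % of the photopeak counts per view over the 360°
orbit, inside the 2–12 % band reported for clinical pallets.  Running the
`cohort` experiment (19 simulated rest/stress studies) pools 19 × 17 = 323
paired segment scores; the two AC arms agree with r ≈ 0.99 and a
non-significant pooled paired t-test — the table does not change clinical
perfusion scoring.

The same pipelines are scriptable from the shell:

```bash
tabfx simulate out/ --downsample 4          # synthetic CT + activity
tabfx strip-table out/ct.nii.gz out/ct_stripped.nii.gz --mask out/mask.nii.gz
tabfx run --config my_experiment.yaml
```

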