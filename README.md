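# poroct

HR-microCT bone morphometry for small-animal studies: trabecular and
cortical macrostructure, plus segmentation of intracortical porosity into
**vascular canals** and **osteocyte lacunae** by connected-component
volume. The package also ships a synthetic phantom generator and a
scan-resolution simulator, so the whole chain — including the systematic
underestimation of vascular porosity at coarser voxel sizes — can be
exercised and verified on desk-scale data with analytic ground truth.

## Who it is for

Bone researchers analysing isotropic microCT stacks of rodent long bones
(CTAn-style workflows), and anyone who needs a tested, scriptable
implementation of the standard indices:

* **Trabecular**: BV/TV (%), Tb.Th, Tb.Sp (μm, maximal-sphere local
  thickness), Tb.N (per mm, as (BV/TV)/Tb.Th), thickness distribution.
* **Cortical**: Ct.Th (thickness of the automatically fitted cortical
  ROI), Ct.OD (per-slice plate-model 2A/P, with a diameter-consistent
  4A/P variant), Ct.TV.
* **Porosity classes** after despeckling below 280 μm³: lacunae
  (280 μm³ ≤ V < 4000 μm³) and canals (V ≥ 4000 μm³), each with porosity
  (Ca.V/Ct.TV, Lc.V/Ct.TV, %), density (N.Ca/Ct.TV, N.Lc/Ct.TV, #/mm³)
  and diameter (Ca.D, Lc.D, μm).
* **Statistics** for n = 7–8 groups: Shapiro–Wilk → F-test/Levene →
  pooled/Welch t or Kruskal–Wallis; Dixon outlier screen; paired t for
  matched 2 μm vs 1 μm acquisitions; HOMA-IR = (FBG × FPI)/405;
  percent-difference and fold-change effect descriptors.

## The core method

A grayscale stack is binarised (Otsu or a manual global threshold). For
the cortex, the largest bone component is closed with a 10 μm ball and
every enclosed void except the marrow cavity is filled slice by slice,
yielding a solid annular ROI that hugs the cortex; pores are then simply
ROI ∖ bone. Components smaller than the despeckling volume (280 μm³ —
35 voxels at 2 μm, 280 voxels at 1 μm) are discarded as noise, and the
remaining pores are split at 4000 μm³ into lacunar and vascular classes.
Local thickness everywhere follows the maximal-sphere definition
(largest inscribed sphere containing each voxel), computed from the
Euclidean distance transform by an opening ladder.

Phantoms are rendered with signed-distance anti-aliasing, so boundary
voxels carry partial-volume gray values; `simulate_scan` adds Gaussian
detector blur, integer block-average downsampling and noise. Running the
cortical pipeline on a thin-canal phantom acquired at 1 μm and at a
simulated 2 μm reproduces the resolution bias: the coarse scan misses and
fragments narrow canals, so canal density and vascular porosity come out
strictly lower.

## Worked example

```python
from poroct import (CorticalPhantomSpec, make_cortical_phantom,
                    run_cortical_pipeline, CorticalConfig)

spec = CorticalPhantomSpec(lacuna_count=200, rng_seed=7)   # 280 μm shaft, 1 μm voxels
vol, truth = make_cortical_phantom(spec)
res = run_cortical_pipeline(vol, CorticalConfig(ct_od_variant="cylinder_corrected"))

print(f"canals  : {res.canal.count}  (truth {truth.canal_count})")
print(f"lacunae : {res.lacunar.count} (truth {truth.lacuna_count})")
print(f"Ct.Th   : {res.cortical.ct_th_um:.1f} um (truth {truth.ct_th_um})")
print(f"Ct.OD   : {res.cortical.ct_od_um:.1f} um (truth {truth.ct_od_um})")
print(f"Ca.V/Ct.TV: {res.canal.porosity_pct:.2f}% "
      f"(truth {100 * truth.canal_volume_fraction:.2f}%)")
```

Output:

```
canals  : 10  (truth 10)
lacunae : 200 (truth 200)
Ct.Th   : 79.1 um (truth 80.0)
Ct.OD   : 280.3 um (truth 280.0)
Ca.V/Ct.TV: 3.76% (truth 3.77%)
```

Counts are recovered exactly because phantom structures are non-touching
and sized inside their volume classes; the metric errors (here ≤ 1.1%)
come from discretisation at the 1 μm render voxel.

The same machinery is scriptable from the shell:

```bash
poroct phantom cortical --spec spec.yaml --out phantom_dir/
poroct analyze-cortical --in stack.tif --voxel 1.0 --out report/
poroct resolution --seeds 5 --out resolution_report/
```

`analyze-cortical` writes `metrics.csv` (one row of the symbol-named
indices per specimen), a per-pore table, the despeckle sensitivity sweep
(lacunar metrics for lower bounds 150–550 μm³) and a `run_log.json` with
every parameter of the run.

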