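# ccparc

Connectivity-based parcellation of the midsagittal corpus callosum (CC)
section, with the accompanying group-comparison and normative morphometry.

Given a white-matter mask (or a ready-made CC section mask), a seven-label
cortical parcellation (volume or labeled mesh) and a whole-brain tractogram
(TCK/TRK, optionally with per-streamline weights), the pipeline:

1. intersects the mask with the midsagittal plane on an oversampled grid
   (default 2x, i.e. 1 mm -> 0.5 mm in-plane voxels);
2. selects streamlines crossing the section, keeps those connecting
   homologous (same-label, opposite-hemisphere) cortical parcels, and
   accumulates per-parcel fiber-density maps restricted to the section;
3. assigns one of seven anterior->posterior labels (frontopolar, anterior
   prefrontal, posterior prefrontal, precentral, postcentral, parietal,
   occipital) per section voxel by a regularized majority vote (self
   weight 1/2, each of the eight in-plane neighbours 1/12), filling
   zero-density voxels from their neighbourhood;
4. reports callosal parcel areas (CcPS, mm²), cortical parcel areas
   (CxPS/TCxS, cm²) and a QC summary.

The statistics layer fits the three group linear models (diagnosis, sex,
age, total cortical surface, optionally the parcel's cortical share),
reports one-tailed diagnosis p-values, eta-squared effect sizes and
Benjamini–Hochberg q-values, plus Welch t, Yates chi-squared and Fisher
exact descriptive tests. The normative layer fits controls only, derives
residues for all subjects, flags values below the control 10th percentile
and tests for excess flags per patient group.

A fully seeded synthetic module generates a strip-geometry phantom (with
known band ground truth, heterotopic/stray fibers and optional partial
agenesis) and simulated cohorts drawn from the same linear models, so the
entire pipeline is testable without any imaging data.

## CLI

```bash
# make a phantom dataset
ccparc simulate-phantom --seed 0 --out-dir scratch/phantom

# run the parcellation (plane given as 'x=<mm>' or a JSON {origin,normal})
ccparc parcellate \
    --wm-mask scratch/phantom/wm_mask.nii \
    --cortex-labels scratch/phantom/cortex_labels.nii \
    --tractogram scratch/phantom/tractogram.tck \
    --weights scratch/phantom/weights.txt \
    --plane x=16 --oversample 2 --endpoint-radius 3 \
    --out-dir scratch/out        # labelmap.nii, areas.csv, qc.json

# cortical areas from a labeled mesh (ASCII 'ccmesh' format)
ccparc cortical-areas --mesh scratch/phantom/cortex_mesh.txt --out cx.csv

# cohort statistics
ccparc simulate-cohort --seed 1 --out cohort.csv
ccparc group-stats --cohort cohort.csv --out-dir scratch/stats
ccparc normative  --cohort cohort.csv --percentile 10 --out-dir scratch/norm
```

Every command writes `run_config.json` with the resolved configuration
and its SHA-256 hash; identical inputs and seeds give byte-identical
outputs.

The cohort CSV schema is: `subject_id, group, sex, age_years, tcxs_cm2,
cxps_<parcel>_cm2` (x7), `ccps_<parcel>_mm2` (x7), `cc_total_mm2`, with
`group` in {control, FAS, NS-FASD} and `sex` as M/F or 1/0.

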