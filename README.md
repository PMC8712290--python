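# svca

Supervised-clustering pseudo-reference region extraction for dynamic TSPO
PET, as a tested Python library and CLI.

Quantifying TSPO PET without arterial sampling requires a pseudo-reference
region with minimal specific binding. This package implements the
supervised clustering approach: kinetic classes (low-binding grey matter,
white matter, blood, high-binding grey matter) are learned from a training
cohort of frame-normalized dynamic scans; at extraction time every
candidate voxel's normalized time-activity curve is decomposed against the
classes by non-negative least squares, and voxels whose low-binding
grey-matter weight fraction exceeds a threshold (default 0.9) form the
reference region, whose raw-space TAC is then averaged out.

The package also ships a fully analytic dynamic-PET phantom generator
(gamma-variate input + one-tissue-compartment classes, known per-voxel
mixing weights) so the entire pipeline is testable without any data
download, plus quality-control checks and a minimal Logan reference-region
DVR for end-to-end demonstration.

## Layout

| module | role |
| --- | --- |
| `svca.petio` | NIfTI / frame-timing I/O, geometric and temporal consistency |
| `svca.normalization` | frame-wise z-normalization within a brain mask |
| `svca.kinetic_classes` | tissue-mask preparation, blood-mask heuristic, class TAC extraction, cohort aggregation, leave-one-out builder |
| `svca.svca_core` | per-voxel NNLS decomposition, ratio thresholding, reference TAC extraction |
| `svca.qc_quant` | QC checks + Logan reference DVR |
| `svca.synthdata` | ground-truthed phantom scans and cohorts |
| `svca.cli` / `svca.config` | `svca` command-line entry point and validated configuration |

## CLI walk-through

```bash
# 1. simulate a 12-subject phantom cohort (NIfTI + timing CSV + manifest)
svca simulate --n-subjects 12 --noise-level 0.1 --seed 7 --out-dir phantom/

# 2. build the kinetic-class set from the cohort manifest
svca build-classes --cohort phantom/cohort_manifest.csv --out-dir classes/

# 3. extract a pseudo-reference region for one scan
svca extract-ref \
    --pet phantom/s01/pet.nii.gz --timing phantom/s01/timing.csv \
    --brain phantom/s01/brain.nii.gz --candidate phantom/s01/gm_prob.nii.gz \
    --classes classes/classes_ALL.json --threshold 0.9 \
    --out-dir out/

# 4. quality control on the run
svca qc --run-dir out/ --anat-tac out/ref_tac.csv --report qc.json
```

`extract-ref` writes the selected-voxel mask, the ratio map, per-class
weight maps, `ref_tac.csv` (raw activity units) and a JSON run manifest
with configuration, input hashes and QC verdicts. Genotype-stratified
class sets (HAB/MAB) are built with `--strata HAB,MAB` and routed strictly
at extraction time.

## Conventions worth knowing

- All times are seconds internally; frame timing comes from a two-column
  CSV (`frame_start,frame_end`) or BIDS-style JSON
  (`FrameTimesStart`/`FrameDuration`).
- Normalization uses the population SD and sets out-of-mask voxels to NaN.
- Masks must already be in PET space; nothing is ever resampled silently.
- The reference TAC is computed from the raw (un-normalized) dynamic PET.
- Selection uses a strict `>` threshold; ties in the blood-mask heuristic
  break by ascending linear voxel index, so every run is bit-reproducible.
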