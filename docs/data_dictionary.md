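# Data dictionary

Conventions: NIfTI volumes use an RAS+ diagonal affine from the voxel
spacing (mm); voxel indices are 0-based; masks use full-voxel
membership. All randomness is seeded; a run is reproducible from its
`config.yaml` alone.

## DWI stack directory (`dwi/`)

| file | content |
|---|---|
| `dwi_b<b>.nii` | one float volume per b value (signal, arbitrary units) |
| `bvalues.json` | manifest: `b_values` (s/mm²), `files` (b → filename), `spacing` (mm) |

## Scene ground truth (`scene_*/`)

| file | content |
|---|---|
| `labels.nii` | int16 label volume: 0 outside body, 1 liver background, ≥ 2 lesion ids |
| `lesions.csv` | per lesion: `lesion_id`, `class`, `center_{x,y,z}` (voxels), `radius_{x,y,z}` (voxels), `n_voxels`, `core_voxels`, `true_D` (mm²/s), `true_f` (fraction), `true_Dstar` (mm²/s), `true_S0` (signal units) |

## Parameter and index maps (`maps/`)

| file | content |
|---|---|
| `Dprime.nii`, `ADC.nii` | float maps in mm²/s (internal units; multiply by 10⁶ for the conventional scale) |
| `fprime.nii` | float map, unitless fraction (×10³ for the conventional scale) |
| `*_valid.nii` | uint8 validity mask (1 = estimate defined) |
| `I_D.nii`, `I_f.nii`, `I_ADC.nii`, `I_Df.nii` | uint8 index maps: 0 green, 100 red, 255 invalid |
| `overlays/*.png` | red/green blend over the windowed b-800 slice |

## Lesion records (`lesions.csv` from `ivim roi` / `ivim run`)

| column | units |
|---|---|
| `lesion_id` | integer |
| `class` | HCC, CCC, metastasis_CRC, metastasis_breast, haemangioma, FNH |
| `truth` | malignant / benign (implied by class) |
| `Dprime`, `ADC` | 10⁻⁶ mm²/s |
| `fprime` | 10⁻³ |
| `I_D`, `I_f`, `I_ADC`, `I_Df` | percent red in the analysed ROI, 0–100 |

## ROC results (`results.csv`)

One row per (contrast, marker): group sizes and means ± SD on the
display scales (1 decimal), group-difference p value and test used,
test direction (`>` = lower value is more positive, `<` = higher),
AUC with DeLong 95% CI, Youden-optimal cutoff (display scale, 1
decimal), and sensitivity/specificity/accuracy at the optimum (3
decimals).

## Cutoffs (`cutoffs.json`)

`D`, `f`, `ADC` in internal units (mm²/s, fraction), `provenance`
(`published defaults` or `derived`), and `percent_red` cutoffs for the
index-map classification rules.
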