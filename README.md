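# strokefuse

Resting-state fMRI biomarker screening and voxel-wise logistic fusion for
white-matter infarct segmentation, exercised end-to-end on a fully
synthetic, seeded stroke cohort.

Structural segmentation models for white-matter (WM) infarcts degrade badly
when moved to a new dataset, and part of the lost evidence is functional:
infarcted and perilesional WM shows altered BOLD dynamics.  `strokefuse`
implements a pipeline for finding and exploiting such rs-fMRI biomarkers:

1. **Feature extraction** — every voxel of the WM + lesion region of
   interest is probed with a 3×3×3 sliding window (minimum cluster size 2);
   each window yields 85 named time-series features: 77 automatic
   signal-processing metrics (moment/shape statistics, spectral peak
   amplitude and frequency, analytic-envelope statistics, autoregressive
   diagnostics with AIC order selection, de-trended variants) plus 8
   literature features (band amplitudes of fluctuation, band power ratios,
   Kendall W / tau local concordance).
2. **Screening** — features are ranked by lesion-to-WM contrast with a
   modified Fisher score, *Score = (Mean_L − Mean_WM)² / SD_WM²*, averaged
   over all training scans.
3. **Fusion** — the segmentation probability map *P* and the top-ranked
   feature maps *F_j* (z-scored per subject, zero-clipped against the
   expected contrast direction) enter a voxel-wise logistic model,
   ln(p/(1−p)) = β₀ + β₁P_z + Σ_j β_{j+1}F_{j,z}, fitted by a coarse
   full-grid search (3·4·6·6 = 432 coefficient combinations for two
   features) maximising mean training Dice of the p > 0.5 prediction.
4. **Evaluation** — three contenders (raw thresholded map, re-optimised
   map-only model, multivariate model) are compared by test-set Dice
   2TP/(2TP+FP+FN) under a subject-level 50/50 split and its swapped
   mirror, with paired t-tests on per-subject Dice.
5. **Outcome statistics** — per-subject biomarker levels are regressed
   against motor / neuropsychological recovery (FIM Walk, word
   comprehension, Posner cueing) in two Holm–Bonferroni-controlled test
   families, plus a paired test for the subacute-to-chronic biomarker
   decline.

Because the clinical data this kind of study uses are access-restricted,
the package ships a first-class synthetic cohort generator
(`strokefuse.cohort`) whose planted effects — a narrow-band oscillation
elevated inside the lesion, degraded probability maps, and a planted
word-comprehension association — define exactly what the pipeline should
recover.  See `docs/methods.md` for the models and all numerical
conventions.

## Worked example

```python
from strokefuse import CohortConfig, SyntheticCohort, generate_assessments
from strokefuse.pipeline import extract_cohort, evaluate_visit, biomarker_summary
from strokefuse.outcome import run_families

cfg = CohortConfig(seed=7)                  # 20 subjects, 7 runs/visit, 16^3 grid
cohort = SyntheticCohort(cfg)
data = extract_cohort(cohort, "subacute")   # sliding-window feature maps
res = evaluate_visit(data, split_seed=7)    # splits, screening, fusion, Dice

screen = res["info"][0]["screen"]
print("top biomarker:", screen.ranking_[0])
print(res["report"].round(3).to_string(index=False))

chronic = extract_cohort(cohort, "chronic")
summary = biomarker_summary({"subacute": data, "chronic": chronic},
                            "spectrum.peak_amplitude")
fam1, fam2 = run_families(summary, generate_assessments(cohort))
print("prognostic family flags:", fam1.flagged)
```

prints

```
top biomarker: spectrum.peak_amplitude
       model  mean_dice_original_split  mean_dice_swapped_split  mean_dice
    original                     0.268                    0.249      0.259
 reoptimized                     0.629                    0.580      0.605
multivariate                     0.869                    0.855      0.862
prognostic family flags: ['change_in_word_comprehension']
```

Reading the output: the planted narrow-band oscillation makes the spectral
peak amplitude the strongest of the 85 candidate biomarkers; thresholding
the degraded probability map at its default 0.5 recovers only Dice ≈ 0.26;
re-optimising the map-only model on the training half lifts the test Dice
to ≈ 0.60; adding the top two rs-fMRI feature maps lifts it to ≈ 0.86
(the remaining gap is the probability map's planted partial-miss and
false-positive corruption).  The prognostic family flags exactly the
planted association — higher subacute spectral peak amplitude predicts
word-comprehension improvement (here p = 0.0014, R² = 0.58) — while the
FIM Walk and Posner tests stay below the Holm thresholds
{0.017, 0.025, 0.05}.

The same workflow is available from the shell:

```bash
strokefuse simulate  --config cohort.yaml --out cohort/     # NIfTI + CSV + manifest
strokefuse screen    --config cohort.yaml --out ranking.csv
strokefuse run-all   --config cohort.yaml --out report/
strokefuse export-registry --out registry.json               # the 85 feature definitions
```

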