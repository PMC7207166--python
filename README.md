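# icdquant

High-content-screening quantification of **immunogenic cell death (ICD)
hallmarks** for cell biologists and screening groups working with automated
fluorescence microscopy.  ICD is a mode of cell death that exposes and
releases danger signals — calreticulin (CALR) translocation, HMGB1 nuclear
exodus, ATP secretion, eIF2α phosphorylation — and a strong functional
correlate of ICD induction is the inhibition of transcription and
translation.  `icdquant` implements the quantitative layer of such a screen
end to end:

- **Segmentation** — nuclear ROIs from the DNA stain (Gaussian smoothing,
  Otsu threshold, distance-transform watershed for touching nuclei) and
  secondary cytoplasmic annuli; per-cell area, mean intensities and the
  cytoplasmic coefficient of variation CV = σ/μ.
- **Hallmark statistics** — anchored inhibition percentages
  `100·(x̄_ctr − x̄)/(x̄_ctr − x̄_blank)` for EU (transcription) and AHA
  (translation) incorporation; top-hat dot area for CALR puncta with a
  per-timepoint control normalization and AUC summary; single-cell HMGB1
  release speed; positive-cell fractions from a control-separating
  threshold; the surface overlap coefficient SOC = |A∩B|/|A∪B| for
  fibrillarin/nucleolin colocalization and its ranking into % inhibition.
- **Dose response** — healthy/pyknotic/dead gating (PI, Hoechst, nuclear
  area) and a four-parameter log-logistic fit
  `y(x) = c + (d−c)/(1+(x/e)^b)` of the healthy fraction, inverted in
  closed form for the **IC60** (dose at which 40% of cells remain healthy):
  `IC60 = e·((d−c)/(0.4−c) − 1)^{1/b}`.
- **RUSH kinetics** — protein-synthesis inhibition
  `100·(1 − slope_cont/slope_avidin)` and reversibility
  `100·area(disc − cont)/area(avidin − biotin)` from retention-using-
  selective-hooks time courses.
- **Integration** — per-assay z-scores, Pearson correlations with explicit
  recorded exclusion lists, positive/negative hit gating against a
  reference compound, and two-sample Kolmogorov–Smirnov enrichment of
  annotated compound classes against the whole screened population.
- **Synthetic data** — every input (fields, tracks, RUSH curves, plates,
  compound tables) can be generated with planted ground truth, so the whole
  pipeline is testable as a recovery problem without any external data.

## Worked example

The end-to-end demo generates an anchored transcription-inhibition plate,
a dose-response plate, a RUSH time course, HMGB1 tracks and a compound
table, runs each stage and prints the recovered quantities:

```sh
$ icdquant demo --out results/demo --seed 1
config_hash: 98f8008f98df
inhibition_pct[CPD_A] (planted 30%): 29.99
inhibition_pct[CPD_B] (planted 70%): 70.0
ic60_uM (true 2.915): 2.92
rush_inhibition_pct (planted 80%): 80.06
rush_reversibility_pct: 48.09
hmgb1_mean_speed: -0.0371
n_positive_hits: 39
ks_p (planted shift 3 sd): 3.469370173165346e-28
```

Reading the output: the two treated wells carried planted transcription
inhibition of 30% and 70% and the segmentation→measurement→anchoring chain
recovers 29.99% and 70.0%; the simulated drug's true IC60 is 2.915 µM and
the 4PL fit returns 2.92 µM; the RUSH curves were built with 80% inhibition
and 60% reversibility (the measured 48.09% is 100·f·r = 0.8·0.6, the
area-ratio statistic on a partially inhibiting drug); the HMGB1 tracks lose
~3.7% of their normalized nuclear intensity per hour; and a 30-compound
class shifted by +3 sd in a ~2,000-compound table is detected by the KS
enrichment at p ≈ 3·10⁻²⁸.  `results/demo/` holds the per-stage CSVs, each
stamped with the config hash; rerunning with the same seed reproduces them
byte for byte.

Every stage is also exposed individually (`icdquant simulate`, `segment`,
`dose-response`, `rush`, `integrate`) and as plain library functions.

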