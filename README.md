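# prmpanel

Serum-proteomics biomarker discovery for intracranial aneurysm (IA):
rule-based design of parallel-reaction-monitoring (PRM) assays, peak-area
normalization and stable-isotope quantification, differential feature
statistics, and machine-learning selection of diagnostic protein panels —
driven by a synthetic-cohort generator with known ground truth.

## The problem

Ruptured intracranial aneurysms are catastrophic and current diagnosis is
imaging-based and late. A targeted-proteomics route to circulating
biomarkers quantifies a preselected set of proteotypic peptides in serum by
PRM, then asks which small combination of proteins separates patients from
controls (IA vs NC) and ruptured from unruptured patients (R vs UR). This
package implements that analysis chain as a tested library:

1. **Assay design** (`prmpanel.assay_design`). In-silico tryptic digestion
   (cleave after K/R, not before P); proteotypic-peptide filtering —
   unique to one protein, 7–25 residues, monoisotopic mass ≤ 6,000 Da,
   predicted detectability > 0.5, no Met/Cys; precursor charge chosen so
   m/z ∈ [350, 1250]; the top-3 library fragments excluding y1–y3/b1–b3;
   scheduled 3-min elution windows. Detectability/retention prediction is
   pluggable; a transparent hydropathy-based surrogate is bundled.
2. **Quantification** (`prmpanel.prm_quant`). Long-format peak-area tables
   (Skyline-export style) → log10 transform → two-step normalization
   (longitudinal per-sample correction anchored on spiked heavy standards
   and QC runs, then transverse per-feature batch-median correction), plus
   stable-isotope dilution: C_endogenous = C_SIS · area_endogenous / area_SIS.
3. **Feature statistics** (`prmpanel.diff_stats`). Fold change on
   linear-scale group means, Mann–Whitney U (exact for small samples),
   Benjamini–Hochberg adjustment, volcano classification, univariate ROC
   AUC, and OPLS-DA with VIP scores (orthogonal-signal-corrected PLS1;
   Σ VIP² = p).
4. **Candidate bank** (`prmpanel.biobank`). Merge tissue, serum and
   literature evidence by accession with provenance, restrict to
   serum-detectable candidates.
5. **Panel selection** (`prmpanel.panel_select`). Differential feature
   reservation (FC ≥ 1.2 two-sided, P < 0.05, VIP > 1), one peptide per
   protein by AUC, stratified 3:1 split, then recursive feature
   elimination with 10×10-fold cross-validated logistic regression; the
   subset size with the highest mean CV accuracy wins.
6. **Evaluation** (`prmpanel.evaluation`). Sensitivity, specificity,
   accuracy, PPV, NPV, Matthews correlation coefficient
   MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
   ROC/AUC with DeLong 95% confidence intervals, learning curves.

Because the original serum raw data are not shipped, the cohorts come from
`prmpanel.syndata`: an additive log10-scale generative model with group
effects, batch offsets, QC runs and spiked heavy-isotope reference
peptides, emulating a discovery cohort of n = 212 (100 NC, 57 UR, 55 R,
113 peptides from 100 proteins, 18 heavy references) and an external
cohort of n = 32 (20 NC, 6 UR, 6 R). See `docs/methods.md` for the model
and its limitations.

## Worked example

```sh
prmpanel run-all --seed 1 --out runs/ia
```

simulates both cohorts, normalizes them, screens the 113 features, selects
a panel for the IA-vs-NC contrast and prints:

```
            dataset        AUC (95% CI)      Sn     Sp     Ac    PPV     NPV   MCC
           training 0.977 (0.945-0.990)  91.67% 92.00% 91.82% 92.77%  90.79% 0.836
internal_validation 0.906 (0.773-0.964)  85.71% 88.00% 86.79% 88.89%  84.62% 0.736
external_validation 0.975 (0.872-0.996) 100.00% 80.00% 87.50% 75.00% 100.00% 0.775
panel: F022, F024, F026, F032, F033, F034, F036
```

Reading: of the 14 features passing the DFR filter, cross-validated
backward elimination kept seven; six of them are planted markers (the
generator plants six IA effects at F021–F026 and eight rupture effects at
F031–F038, which also separate the pooled IA group from controls).  The
panel classifies the held-out quarter of the discovery cohort with 86.79%
accuracy and the fresh external cohort with 87.50%. `--contrast R_vs_UR`
builds the rupture panel instead; `--strict` recomputes the feature filter
inside the training partition only (see methods note on leakage).

The same steps are available individually (`simulate`, `design-assays`,
`normalize`, `stats`, `bank`, `select-panel`, `evaluate`) and as library
calls (`prmpanel.pipeline.run_pipeline`).

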