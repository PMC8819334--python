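# Methods

This note documents the models, defaults and design choices behind
`prmpanel`, in the order the pipeline runs them.

## Synthetic cohorts (`syndata`)

Peak areas are generated on the log10 scale and exponentiated:

    x_ij = mu_j + beta_j * g(i) + b_batch(i) + s_i + eps_ij

* `mu_j ~ N(5.5, 0.8²)` — feature baselines, i.e. raw areas around
  10⁴–10⁷, the usual dynamic range of serum PRM peak areas.
* `beta_j = d * residual_sd` for features planted in a contrast's case
  group, 0 otherwise. Effects are additive in log10 — multiplicative on
  areas — matching the log-transformed analysis downstream. Unruptured
  (UR) samples carry the IA effects; ruptured (R) samples carry the IA
  plus the rupture effects, so the two contrasts are both expressible.
* `b_batch ~ N(0, batch_sd²)`, one offset per acquisition batch (default
  batch_sd = 0.2, 4 batches); `s_i ~ N(0, sample_drift_sd²)` is an
  optional per-sample loading/drift term, off by default.
* `eps ~ N(0, residual_sd²)` with residual_sd = 0.2 — a ~58% CV on linear
  scale before normalization, typical of unnormalized serum PRM.

QC runs are simulated pooled aliquots: their expectation per feature is
the size-weighted mean of the group means, with the batch offset and
noise of their batch (the composition of real pooled QC samples is a
protocol choice; it is configurable here). Heavy-channel (SIL) reference
areas share the instrument terms — batch offset, drift, noise — but never
the group effects, because standards are spiked after digestion; that is
exactly what makes them usable as normalization anchors. The default
design mirrors the targeted study the package emulates: 113 quantified
peptides mapping to 100 proteins, 18 heavy references, a discovery cohort
of 212 sera (100 NC / 57 UR / 55 R) and an external cohort of 32
(20 / 6 / 6). Default planted effects are six IA markers and eight
rupture markers at d = 1.5, the size-of-effect regime where a univariate
marker has AUC ≈ Φ(1.5/√2) ≈ 0.86 — strong but not trivial.

A `biology_seed` separates the biological layer (baselines) from the
sampling/instrument layer, so an external cohort can measure the *same*
peptides under fresh batches and noise. MCAR dropout is available
(`dropout_rate`); no other missingness mechanism, chromatographic peak
shape, or isobaric-labeling artifact is simulated. Consequences: passing
recovery tests here demonstrate correctness of the statistical chain
under an additive-shift batch model with roughly normal log-areas; they
do not establish robustness to informative missingness, interference, or
nonlinear saturation, which real data can show.

All randomness flows from one seed through named sub-streams
(proteome / baselines / batches / noise / dropout), so outputs are
bit-identical under a fixed configuration.

## Assay design (`assay_design`)

Digestion cleaves C-terminal to K or R unless proline follows; missed
cleavages default to 0 for proteotypic-peptide selection (the cleanest
proteotypic definition) and are configurable. Monoisotopic residue
masses, the proton mass (1.007276 Da) and water (18.010565 Da) are fixed
in `constants.py`. Filter order is fixed and audited per peptide:
uniqueness → length 7–25 → mass ≤ 6,000 Da → detectability > 0.5 →
forbidden residues (M, C, plus an optional motif list, empty by default —
only Met and Cys are categorical exclusions; other modification-prone
sites vary by protocol). At most two peptides per protein are kept,
ranked by predicted detectability; proteins with no eligible peptide are
reported as uncovered.

Precursor charge: m/z(z) = (M + z·1.007276)/z for z ∈ {1,2,3}; among
in-range charges (350–1,250) the priority is 2+ > 3+ > 1+. In practice
this choice is made by inspecting the spectrum signal; the fixed priority
is a deterministic surrogate justified by tryptic peptides predominantly
ionizing doubly charged. Transitions: fragments y1–y3/b1–b3 are excluded,
the remainder ranked by library intensity with ties broken toward the
higher ordinal and then the y series (longer fragments and y ions are
generally more specific); fewer than three eligible fragments rejects the
peptide. Scheduling windows are RT ± 1.5 min clipped to the gradient.

The bundled `heuristic_predictor` is explicitly non-learned: detectability
is a logistic function of GRAVY hydropathy and distance from a favourable
tryptic length, and the retention index is affine in GRAVY. It preserves
the shape of real predictor output (probabilities, hydrophobicity-ordered
retention) so the rule layer can be exercised and tested; its absolute
values carry no spectral information, and any trained predictor with the
same interface can be plugged in.

## Normalization (`prm_quant`)

Raw areas are log10-transformed (zeros become missing, not −∞; negative
areas are errors). Both correction steps are additive on the log scale —
multiplicative rescalings of raw areas, the standard model for
ionization-efficiency and loading drift — and median-based for robustness:

1. **Longitudinal (per sample, within batch):** subtract the difference
   between the sample's reference-peptide median and the median reference
   level over the batch's QC runs. References default to the heavy (SIL)
   standards; batches without QC runs fall back to the batch-wide
   reference median. The precise anchor set (SIL, iRT or pooled totals)
   is a protocol choice and is configurable.
2. **Transverse (per feature, between batches):** subtract the feature's
   per-batch median and re-anchor at its grand median. After this step
   every feature's per-batch medians agree to 1e-9 and its grand median
   is unchanged; the step is idempotent.

Missing values propagate (no imputation); features observed in fewer than
50% of study samples are flagged (threshold configurable). The SIL
quantity is C_endogenous = C_SIS · area_endogenous/area_SIS with the
light/heavy ratio reported as log2 L/H.

## Feature statistics (`diff_stats`)

Fold change is the ratio of linear-scale group means of normalized areas
(median aggregation available), applied two-sided in the downstream
filter — FC ≥ 1.2 or ≤ 1/1.2 — because down-regulated proteins are
legitimate markers. The Mann–Whitney test is exact (permutation null)
up to a pooled n of 12 without ties, otherwise the tie- and
continuity-corrected normal approximation; the switch point keeps the
exact branch enumerable by the test oracle. BH adjustment is the step-up
definition. Volcano presets: 1.5-fold with BH-adjusted P < 0.05
(serum-style) and 2-fold with raw P < 0.05 (tissue-style); both cutoffs
are configurable.

OPLS-DA is the single-response orthogonal-signal-correction form: after
autoscaling (unit variance — the standard scaling under which VIP scores
are interpreted against the >1 rule), `n_orthogonal` components
orthogonal to the class vector are deflated (default 1; with 0 the model
is plain PLS1), then one predictive component is extracted and
VIP_j = √(p·w_j²/Σw²), so Σ VIP² = p by construction. Constant columns
are removed with a warning and given VIP 0.

## Panel selection (`panel_select`)

DFR keeps features with two-sided FC beyond 1.2, Mann–Whitney P < 0.05
and VIP > 1. Proteins quantified by several peptides contribute their
best peptide by univariate AUC (ties: smaller P, then feature id). The
3:1 stratified split draws round(0.75·n) samples per class, seeded.

RFE-CV: features are standardized with training-set parameters only;
at each step the subset's accuracy is measured by stratified k-fold CV
(10 folds × 10 repeats by default; per-repeat shuffling derives from the
master seed), then the feature with the smallest absolute standardized
coefficient is eliminated (the ranking statistic for recursive
elimination; ties fall to the feature with the larger univariate P).
The final size maximizes mean CV accuracy with ties resolved toward the
smaller panel, and is refit on the full training set. Logistic fits are
near-maximum-likelihood with a small ridge (λ = 1e-4) to keep separable
problems finite; classification cuts predicted probability at 0.5. The
CV inner loop uses an in-package Newton-IRLS solver with the same
objective as the scikit-learn fit behind the public API (verified to
agree); this is purely a per-call-overhead optimization.

By default the feature screen (statistics + DFR) runs on the full
discovery cohort before the split, reproducing the common published
ordering; this leaks filter information into the internal validation set.
`strict_mode` recomputes the screen inside the training partition only,
and a regression test checks that strict mode is not systematically more
optimistic.

## Evaluation (`evaluation`)

Confusion-matrix proportions are computed in exact rational arithmetic;
metrics with empty denominators are reported as missing rather than 0,
except MCC which follows the 0-by-convention rule with an explicit flag.
ROC AUC is the trapezoidal area, identical to U/(n₁n₀) with ties counted
half. The AUC confidence interval uses DeLong's variance (midrank
formulation) with a logit-scale 95% interval clipped to [0,1] — the
default of common ROC software; a degenerate variance collapses the
interval. Because the interval method used for the original tables is
not recorded, CI endpoints are reported but not treated as reference
values. Learning curves refit on stratified subsamples against a fixed
validation set, so the fraction-1.0 point equals the full-data fit.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run the generator at the study
design sizes (212 + 32 samples, 113 features) for the end-to-end checks,
and at reduced sizes (40–100 features, 80–100 samples) for repeated-seed
recovery simulations — 50 seeds for the DFR filter, 25 for RFE-CV —
chosen so the whole suite completes in minutes on one CPU while keeping
Monte-Carlo bands meaningful. Identity-type invariants (batch-median
equalization, VIP normalization, AUC oracles) are asserted at 1e-9–1e-12;
Monte-Carlo quantities at their sampling error (e.g. type-I error
0.05 ± 0.02 over 1,000 null features).

## Known limitations

* The detectability/retention surrogate is heuristic; absolute assay
  lists are meaningful only relative to a real trained predictor.
* The generator's batch effect is a pure location shift on the log scale;
  scale (variance) batch effects and feature-specific drift are not
  modeled, so the normalization's behaviour under those regimes is
  untested.
* The exact composition of published panels cannot be recovered without
  the original raw cohort; panel membership is therefore never asserted,
  only recovery of planted synthetic markers.
* No pathway enrichment, network analysis, calibration or decision-curve
  analysis; plotting is intentionally out of scope.
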