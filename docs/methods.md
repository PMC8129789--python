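# Methods

This note documents the models implemented in `thermoprobe`, the
assumptions behind them, the defaults of the synthetic-data generators, and
the numerical choices made where the design was open.

## Three-treatment exometabolite classification

The cultivation design has three treatments: sterile starting medium stored
cold (`start`, n = 4), a sterile control incubated alongside the culture
(`incubated_control`, n = 5), and the inoculated culture
(`culture`, n = 5). Incubation at ~75 °C itself transforms medium
components, so abiotic (thermal) effects are read from the
start-vs-incubated-control contrast and biological effects from the
incubated-control-vs-culture contrast; a compound can legitimately carry one
label of each kind (e.g. thermally degraded *and* biologically consumed),
and the effects compose.

A compound/ionization-mode slice is labeled only when all three criteria
hold, with the inequalities applied strictly as printed:

1. Shapiro–Wilk p > 0.05 in at least two of the three treatment groups.
   Groups where the test is undefined (n < 3 or zero variance) count as
   non-normal rather than aborting the screen — this keeps the screen total
   over real data, where saturated or censored peaks produce ties.
2. Tukey–Kramer HSD adjusted p < 0.05 for at least one of the two contrasts
   of interest. The standard three-group studentized-range procedure with
   the Kramer correction for unequal n is used (the design is unbalanced,
   4/5/5); variance is pooled across all three groups. `scipy.stats.
   tukey_hsd` provides the computation; the test suite cross-checks it
   against `statsmodels` on random unbalanced datasets and against values
   frozen from an independent R session.
3. Mean peak height strictly above 10⁵ au in at least one treatment.

Attribution follows the sign of the mean difference. Reporting rules:
compounds significant in both ionization modes appear once, preferring
positive mode; compounds whose means are at or below 10⁵ au in *all*
treatments are dropped; compounds at or below the threshold in *some*
treatments are flagged `manual_inspection_flag` — peak-shape inspection on
chromatograms cannot be automated from peak heights, so the flag plus a
`manual_exclusions` config set surfaces the judgment instead of making it.
HMDB compound-class assignment is a join against a user-supplied lookup
table, not a computation.

Cell densities for filamentous growth are counted as total filament length
divided by a 4.0 µm average cell length, scaled by chamber volume and the
concentration factor of the counting preparation (the factor divides the
chamber density; it is the calibration constant of the concentration step).

## ¹³CO₂ calculus

- δ¹³C ↔ atom fraction: R = R_VPDB·(δ/1000 + 1), AF = R/(1+R), with
  R_VPDB = 0.0111802 (the community-standard VPDB ratio; the conversion
  constant is not negotiable elsewhere in the package). The pair of
  conversions is an exact algebraic inverse; the suite checks the round
  trip to 10⁻¹² (relative) across −1000‰ … +5000‰.
- Headspace moles: n = PV/RT with R = 0.082057 L·atm·mol⁻¹·K⁻¹; CO₂ moles
  scale by the mixing ratio (µmol CO₂ per mol gas). Temperature defaults to
  the 75 °C incubation (348.15 K). Headspace pressure after substrate and
  CO₂ additions is a config input, not a constant. Dilution of samples with
  CO₂-free air before the isotope analyzer affects amount, not the isotope
  ratio, and is therefore ignored for δ; concentrations come from a separate
  series.
- Excess ¹³C: n_CO₂ · (AF_sample − AF_baseline) · 10⁶ µmol. Two baselines
  matter and both are explicit inputs: the sterile labeled control is the
  abiotic baseline of the mass balance, and the natural-abundance-substrate
  culture is the biological baseline of the δ scale.
- Sampling correction: each 10-mL headspace withdrawal permanently removes
  well-mixed gas; cumulative production at time *t* adds back the CO₂ and
  excess ¹³C carried away by every prior sample, computed from the
  headspace state at each sampling instant. Removal is applied after the
  measurement at the same time point.
- Partition: excess_abiotic = sterile excess; excess_biotic = culture −
  sterile. The two-end-member mixing form is the minimal model consistent
  with one live and one sterile bottle. A negative biotic difference
  (possible under noise) floors to zero with a warning rather than an
  error; conservation (biotic + abiotic = total) holds exactly whenever the
  floor does not trigger.
- Rates are ordinary least-squares slopes of cumulative excess on time,
  reported with their standard error.

## Position-specific carbon-fate model

A steady-state label-accounting model, not a kinetic one: each labeled
carbon position maps to exactly one fate (released as CO₂ or retained)
under boolean pathway states. Glycolysis maps glucose C1/C6 → pyruvate C3,
C2/C5 → C2, C3/C4 → C1; pyruvate decarboxylation releases pyruvate C1; TCA
oxidation releases the acetyl carbons (pyruvate C2/C3, acetate C1/C2); the
oxidative PPP releases glucose C1 at 6-phosphogluconate dehydrogenase.
Acetate carbons are released when either `tca_oxidation` or
`acetate_oxidation` is on — the two flags describe entry routes to the same
oxidative fate, and this keeps the yield monotone in every flag. Re-entry
of PPP products into glycolysis is neglected, the same simplification used
when reading the flux ratio off the isotopomer signals.

Under the experimentally inferred state (glycolysis and pyruvate
decarboxylation on, TCA oxidation off — no ¹³CO₂ from 2,3-¹³C pyruvate),
U-¹³C glucose releases label at 2G + P atom-units (G = glycolytic flux,
P = oxPPP flux) while 1-¹³C glucose releases P, so the observed U:C1 signal
ratio inverts as G/P = (ratio − 1)/2; the forward signals are computed from
integer released-atom counts so the inversion is exact. A ratio of 25 gives
G/P = 12.

## MEROPS and KEGG summaries

- Hit filtering: E ≤ 10⁻¹⁰, one hit per query gene. Best-hit tie-breaking
  (bit score ↓, then E-value ↑, then family code lexicographically) is fixed
  for determinism. Filtering is idempotent.
- Family presence for cross-genome set algebra means count ≥ 1. The Venn
  partition is computed for any number of genomes as one disjoint cell per
  genome subset; cells sum to the union (property-tested against brute
  force).
- Percentile rank is the "top x%" convention: 100·|{r ≥ v}|/N.
- Percentages round half-up to two decimals, matching printed tables.
- KEGG module definitions support space (AND between ordered steps), comma
  (OR), parentheses, `+` (complex, all required), `-` (optional, ignored
  for completion) and `--` (a step with no KO assigned, counted as
  unsatisfied). A step that is wholly optional is excluded from the step
  count. MCR = satisfied steps / total steps; it is monotone under KO-set
  growth and is verified against an exhaustive truth-table oracle on every
  panel module (all ≤ 12 KOs, every subset enumerated). Q-values come from
  the upstream annotation pipeline and are consumed as inputs; feasibility
  is Q < 0.5, strictly, and unknown when Q is absent.

## Synthetic data: what it emulates and what it does not

Generators take explicit integer seeds (no global state) and are
byte-reproducible.

- **Peak tables.** Log-normal multiplicative replicate noise (MS peak
  heights are positive and right-skewed); `cv` sets the coefficient of
  variation, σ² = ln(1 + cv²), with a mean-one multiplier so treatment
  means are unbiased. Planted biological effects multiply the culture mean
  only; thermal effects multiply both incubated treatments. Replicate
  layout defaults to the 4/5/5 design. The standard benchmark plants 200
  effects (8×, the four classes in rotation) beside 200 nulls at baseline
  2×10⁵ au with cv 0.1. The replicate-level variance of real peak heights
  is not published; cv defaults are this package's choice of a realistic
  targeted-metabolomics precision, not measured values. The generator does
  not emulate retention-time drift, censored/saturated peaks, correlated
  compounds, or the large culture-replicate variability of a hard-to-grow
  organism — recovery rates on the benchmark therefore bound what clean
  data allow and say nothing about chromatographic failure modes (that is
  what the manual-inspection flag is for).
- **Headspace series.** Default conditions are Wheaton-bottle scale
  (0.5 L headspace, 1 atm, 348.15 K, baseline 1000 µmol mol⁻¹ CO₂ at
  δ = −10‰, sampled 10 time points over 180 h). Label release is modeled
  as addition of pure ¹³CO₂ scaled by 1/(1 − AF_baseline) so that the
  excess estimator recovers exactly rate × time — the generator is the
  algebraic inverse of the estimator, which is what makes the noiseless
  round trip exact and the noisy one a fair test of the sampling
  correction. Gaussian noise is applied to δ only. Culture series embed
  biotic + abiotic release, sterile series abiotic only. Real dynamics
  (growth-phase rate changes, dissolution into the medium, pressure drift)
  are not modeled.
- **Annotation tables / KO sets.** Families are planted at exact counts on
  random genes with a cytoplasm-heavy locality distribution; KO sets
  satisfy each module step independently with probability equal to the
  target completeness (shared KOs between modules can push realized MCR
  above target).

## Problem sizes and determinism

The default suite runs the benchmark at 400 compounds, the isotope round
trips at 10 time points, and the MCR oracle over every KO subset of twelve
panel definitions (≤ 2¹² subsets each); the whole suite completes in well
under a minute, and `scripts/acceptance.py` in ~20 s on one CPU. Hypothesis
property tests run derandomized. All seeds are explicit; the acceptance
script derives its sub-seeds from the single `--seed` argument.

## Known limitations

- The carbon-fate model is combinatorial bookkeeping; it cannot express
  partial pathway activity, isotope exchange, or CO₂ refixation, and the
  flux-ratio inversion inherits the no-PPP-re-entry simplification.
- The Tukey screen pools variance across all three groups; if the culture
  groups are strongly heteroscedastic the adjusted p-values are
  approximate. Whether the original screen pooled across two or three
  groups is not documented; the standard three-group procedure was chosen.
- The KEGG grammar subset covers ordinary metabolic modules; exotic
  definition constructs beyond space/comma/parentheses/`+`/`-`/`--` are not
  parsed.
- MAPLE-style Q-values are consumed, never computed.
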