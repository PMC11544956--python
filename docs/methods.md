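# Methods

## Problem and data model

The package screens fish for an illicit preservative treatment (a hydrogen
peroxide / sodium citrate dip sold to mask spoilage) from portable
near-infrared absorbance spectra taken on four sample matrices — eye, gill,
muscle, skin — in the 908–1676 nm range. The screening problem is a
two-class discrimination (control vs treated) under a paired design: on
each analysis day one control and one treated fish are measured, with
three replicate spectra per fish and matrix, and the treatment is applied
either 3 h (short term, vs a fresh control) or 24 h before measurement
(long term, vs an ice-stored control). The exploitable chemistry sits in a
few broad vibrational bands (the dominant water O–H first overtone near
1400 nm, a weak water band near 1000 nm, a lipid C–H second-overtone band
at 1150–1200 nm whose strength is matrix-dependent, and a C–H combination
shoulder near 1350 nm), while fish-to-fish biological variability is
larger than the treatment effect — which is why the paired structure, not
raw spectral distance, carries the signal.

## Workflow

For each (matrix, term, pretreatment) combination:

1. **Row-local pretreatment.** One of: standard normal variate (SNV) —
   per-spectrum centering and scaling (n−1 denominator) that removes
   additive offsets and multiplicative scatter; or a Savitzky–Golay first
   or second derivative with a 5-point window and quadratic fit. The three
   compete as alternatives; a config switch allows chaining SNV before a
   derivative instead. The derivative is computed in index units (the grid
   is uniform; a global 1/Δλ factor cannot change any classification) and
   truncates two wavelengths per edge (p → p−4), with a 5% relative
   tolerance on grid uniformity.
2. **Paired-day centering** (default on): subtract each day's mean
   spectrum, expressing every control/treated pair relative to its own
   average. The operation uses only within-day structure — never class
   identity — so it is applied identically to training and held-out days
   without leakage.
3. **PLS-DA.** PLS1 regression of the class code (control → 0, treated →
   1) on the column-autoscaled spectral block, NIPALS extraction with
   rank-1 deflation, prediction thresholded at 0.5 (ties → treated).
   Autoscaling means/sds are training-set parameters, refitted inside
   every cross-validation fold. VIP scores follow the canonical form
   VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
   SSY_a = q_a² t_aᵀt_a, so mean_j VIP_j² = 1.
4. **Leave-more-out cross-validation.** One cancellation group per
   analysis day: all six replicate rows of the day's two fish leave
   together (6 groups of 6 rows for the study design). Components are
   nested, so each fold is fitted once at A_max and truncated for smaller
   component counts.
5. **Backward elimination.** Per cycle: evaluate A = 1..A_max (default 5)
   by the day-grouped CV, keep the best A (ties → smaller A), rank
   wavelengths by the fold-averaged VIP at that A, remove the
   max(1, ⌊0.06·p⌋) lowest (equal VIPs break by ascending index), down to
   p_min = A_max+1. The winning cycle maximises CV accuracy, ties going to
   fewer wavelengths, then fewer components, then the earlier cycle. The
   loop is fully deterministic.
6. **Reporting.** One report row per model (selected wavelength count,
   components, calibration and CV accuracy and non-error rate), plus
   latent-variable scores, coefficients and the elimination trace for the
   best model per (matrix, term). Accuracy is the correct fraction × 100;
   NER is the mean of the two class sensitivities — they coincide on this
   balanced design unless errors concentrate in one class. The coefficient
   signs of the best short- and long-term models are compared on their
   shared wavelengths; opposite signs indicate the treatment moves a band
   in different directions against a fresh versus an ice-stored baseline.

## Synthetic study generator

Because the original spectra are distributed as a journal appendix rather
than a public accession, every stage is validated against a generator that
emulates the design: Gaussian absorbance bands with matrix-dependent
amplitudes (lipid band: muscle > eye ≈ gill > skin), per-fish band-
amplitude perturbations (sd 0.04 relative) *and* a per-fish per-wavelength
texture (sd 0.02 absorbance) shared by that fish's replicates, then
per-replicate multiplicative scatter (sd 0.05), additive offset (sd 0.02)
and white noise (sd 0.003). Treated fish receive term-specific band
deltas; the default deltas (|δ| ≤ 0.01) are deliberately smaller than the
fish-level variability and flip sign between terms on every affected band.
All draws come from one seeded stream, each multiplied by its sd
afterwards, so zeroing a variance component never shifts the other draws
(this is what makes the SNV-removes-scatter test exact).

The fish texture component deserves a note: without it, any single
informative wavelength separates the classes perfectly once days are
centered — only replicate noise remains — which no measured spectra would
show. The texture gives every wavelength a day-level noise floor, so
classification genuinely has to pool evidence across wavelengths.

Presets: `null` (no deltas — type-I calibration), `weak` (deltas scaled to
the fish-effect sd), `strong` (ten narrow σ = 2 nm spikes centred on grid
points with alternating signs, amplitude 0.10, flipped between terms).
The spike form makes "the informative wavelengths" a well-defined
10-element set; the amplitude was calibrated once so the full pipeline
classifies perfectly while each spike alone remains unreliable, and then
frozen. What the generator does *not* model: inter-matrix correlation
(each matrix is simulated independently, as each is analysed separately),
wavelength-dependent noise, instrument drift, and real band shapes —
passing tests demonstrate the statistical machinery, not instrument-level
realism.

## Statistical behaviour worth knowing

- **Day-block dispersion.** After paired-day centering, a held-out day's
  six rows succeed or fail nearly as a block (the day's fish contrast
  either aligns with the model or not), so a null 36-row CV accuracy is
  close to Binomial(6, ½)·6/36 — per-study values from 0 to 100% are
  normal. Calibration checks therefore band the *mean* over many simulated
  studies (observed null mean ≈ 54% over 20 studies), not single draws.
- **Selection bias of the shared CV.** The elimination loop ranks
  wavelengths by fold-averaged VIP and then *selects the trace cycle by
  the same CV it reports*. Each held-out day influenced the VIP ranking
  through the other five folds, so the selected-cycle CV accuracy is
  optimistic: on pure-null data it typically reaches 100%. This mirrors
  the classic non-nested feature-selection pitfall; the reported CV
  accuracy of a BE-selected model should be read as a model-selection
  score, not an unbiased error estimate. An honest error estimate would
  need an outer CV around the whole elimination loop, which is outside the
  reproduced workflow.
- **A corollary for recovery claims.** Because ties at maximal CV accuracy
  resolve toward fewer wavelengths, the selected subset is driven to
  p_min = 6; recovery of the 10-spike truth is therefore assessed on the
  elimination *order* (the 10 longest-surviving wavelengths, see
  `BEResult.longest_surviving`), which is the meaningful measure of
  whether VIP ranking found the signal.
- **Accuracy granularity.** All CV accuracies on the 36-row design are
  multiples of 100/36 (97.22, 94.44, 91.67, …), which is also the
  granularity of the published numbers.

## Numerical choices and degenerate inputs

n−1 standard deviations throughout (SNV, autoscaling); constant rows or
columns raise errors naming the offending row/wavelength (detection
threshold 1e−12 relative, since a "constant" column's computed sd is
~1e−15 after centering). NIPALS stops with an error if the X–y covariance
or the X rank is exhausted before the requested component count. The
single-group CV scheme degenerates, by construction, to calibration
metrics. Model serialization is plain JSON and round-trips float64
exactly. Problem sizes follow the study design everywhere (36 rows, 125
wavelengths, 6 folds); the calibration analyses use 20 simulated studies
per preset.

## Known limitations

Two-class PLS1 only (no multi-class, no probabilistic thresholds); no MSC
or detrending pretreatments; day assignments must be supplied (the sample
code does not encode them); reproduction of the published per-matrix
accuracy table requires the original spectra, for which no public
accession exists — with a spectra CSV and a fish→day map, the same
pipeline runs unchanged on the real data.
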