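# Methods

`ugiqc` models the data-analytical backbone of a large covalent acrylamide
library campaign: virtual enumeration of Ugi four-component reaction
(U-4CR) products, microtiter-plate bookkeeping, adduct-based mass-spectral
detection on two platforms, cross-platform agreement and stability
statistics, and descriptor-based modelling of precipitation outcomes. A
synthetic-data generator with a ground-truth ledger stands in for raw
instrument files, so every stage is testable end to end.

## Product enumeration

The ammonia/acrylic-acid variant of the U-4CR condenses an aldehyde
(R-CHO), an isocyanide (R'-NC), ammonia and acrylic acid into an
N-acryloyl amino-acid amide,

    CH2=CH-C(=O)-NH-CH(R)-C(=O)-NH-R'

with loss of one water. Assembly is performed as explicit molecular-graph
surgery in RDKit: the aldehyde carbonyl oxygen is removed, an acryloyl-NH
is grafted onto the former carbonyl carbon (the new alpha carbon), and the
isocyanide carbon is converted to the second amide carbonyl. Composition
therefore satisfies the additivity identity

    m(product) = m(aldehyde) + m(isocyanide) + m(NH3) + m(acrylic acid) - m(H2O),

which is asserted (to 1e-4 Da) inside the assembly routine itself. The
alpha carbon is a stereocenter created racemically; it is emitted without
stereo annotation. Building-block validation is strict: exactly one
aldehyde group (sp2 CH=O, two H for formaldehyde) or exactly one
isocyanide group; bifunctional blocks are rejected rather than multiply
enumerated. Distinct reagent pairs that produce the same canonical
structure are kept as separate reaction records with a duplicate flag,
because campaign counts are per reaction, not per unique structure.

Monoisotopic masses are computed from a single pinned table of
most-abundant-isotope exact masses, so every mass in the package is
bit-stable; the test suite cross-checks the table against RDKit's periodic
table as an independent per-atom summation oracle. Tolerance is 1e-4 Da
throughout.

## Descriptors

Five descriptors drive outcome modelling: SLogP and SMR (Crippen atomic
contributions), TopoPSA (Ertl topological polar surface area, Å²), MW
(average molecular weight, Da) and nHBDon (N-H/O-H donor count). All
modelling is done on min-max (0-1) normalized columns; a constant column
normalizes to zeros by convention. Note that for the core scaffold nHBDon
is exactly 2 (the two secondary amides); with the built-in building-block
vocabularies it is constant across the library and therefore carries no
signal in the importance model.

## Plates

96- and 384-well plates with letter+number addressing. Four 96-well plates
stamp into one 384-well plate by the standard interleaved-quadrant
convention: source plate k in {1..4}, well (r, c), lands at
(2r-1+(k-1)//2, 2c-1+(k-1)%2). The mapping is bijective on occupied wells
and has an exact inverse. Heatmap export writes plate-shaped CSV grids
with NaN for empty wells.

## Detection

Compounds are sought as their singly charged adducts [M+H]+ (+1.007276),
[M+Na]+ (+22.989218) and [M-H]- (-1.007276); the shifts fold the electron
mass into the ion-mass constants and are pinned in one table. A compound
is assessable only if all three adduct m/z values fall inside the
acquisition window (default 50-650 Da); non-assessable compounds are
excluded from every denominator.

Matching selects the peak with smallest |ppm error| within the tolerance
(default 10 ppm, TOF-like; an absolute Da tolerance is available for
quadrupole-like platforms), breaking exact ties by higher intensity, then
lower m/z. A matched peak is called detected when its intensity reaches
`snr_min` (default 3) times the noise floor, estimated as the median
intensity of the spectrum's non-matched peaks. Peaks matched by any adduct
of the compound under consideration count as signal, not background —
otherwise a compound's strong [M+Na]+ would raise the floor against its
own weaker [M+H]+ and the noiseless limit would not have full recall. A
spectrum with no non-matched peaks uses a floor of 1 intensity unit.

Compound-level aggregation defaults to the any-adduct rule (detected in at
least one ionized form across both modes); an all-adducts rule is also
provided. The any-adduct default is the one under which a library-level
"detectable" fraction is meaningful for compounds that ionize in only one
mode.

## Agreement statistics

With one platform fixed as reference (UPLC-MS by default) the package
computes confusion matrices at compound level and at adduct level (one
cell per compound × adduct), with accuracy, sensitivity and specificity.
Library stability over storage is summarized two ways: conservative
(detected by both platforms) and permissive (detected by either). Percent
renderings round half-up to whole percents; raw fractions are always
carried alongside. Per-compound AUC values ([M+H]+ in positive mode,
[M-H]- in negative) are correlated between platforms with Pearson's r
after stripping compounds absent from every adduct on both platforms;
fewer than three remaining pairs or zero variance raise errors rather
than returning a number.

## Outcome labelling and importance model

Reactions are labelled green (precipitated, NMR purity strictly > 80%),
red (precipitated, purity <= 80% — the computable surrogate for an
inconsistent NMR spectrum) or black (no precipitate). The retained library
is the green count. Per-class descriptor distributions are summarized on
the normalized scale (min, quartiles, median, max, and Gaussian KDE
samples on an even grid) in tidy CSV form.

Feature importance uses a seeded random forest inside stratified
cross-validation (default 5 folds, 200 trees): permutation importance
(balanced-accuracy drop, 10 repeats) is measured on each held-out fold,
averaged, clipped at zero and normalized to sum 1; model quality is the
cross-validated balanced accuracy. Ties in the ranking break
alphabetically. Two caveats are inherent to permutation importance and
documented behaviour here: correlated features dilute each other's
importance (SLogP correlates ~0.8-0.9 with SMR and MW on these products),
and a perfectly duplicated column splits its importance with its copy.

## Synthetic campaigns

The generator emulates the study's data-generating process at its scale
and rates; all defaults live in `SimulationConfig`:

- **Building blocks** — seeded sampling without replacement from built-in,
  hand-curated vocabularies (56 aldehydes, 56 isocyanides), stock molarity
  2.5 or 5.0 M at random. Default 52 aldehydes × 49 isocyanides = 2548
  reactions, the closest cross-product to the campaign scale of ~2551
  reactions (that count is not a product of two small integers, so a
  rectangular design cannot match it exactly).
- **Precipitation** — Bernoulli with P = logistic(b0 + beta·z) on the
  normalized descriptors; default coefficients favour precipitation for
  lipophilic, low-TopoPSA products (slogp +2.5, topopsa -1.5, smr +1.0,
  mw +0.5, nhbdon -0.5). The intercept is calibrated by bisection so the
  expected precipitation rate equals 1612/2551 ≈ 63.2%.
- **Purity** — a two-component Beta mixture scaled to 0-100%: a
  high-purity component Beta(40, 4) and a low-purity component Beta(8, 4).
  The mixture weight is solved in closed form so the expected fraction of
  precipitates above 80% equals 1235/1612 ≈ 76.6%, giving a retained
  library of ~1235 in expectation.
- **Two-year survival** — one Bernoulli flag per retained compound
  (default p = 0.88), shared by both platforms; no degradation kinetics
  are modelled.
- **Adduct response** — conditional on survival, each platform/adduct pair
  responds with a Bernoulli probability. The real per-adduct response
  rates are unpublished; the defaults (AEMS 0.85/0.50/0.55, UPLC-MS
  0.70/0.30/0.45 for [M+H]+/[M+Na]+/[M-H]-) are plausibility choices that
  make AEMS the more sensitive platform.
- **Spectra** — responding adducts appear at m/z perturbed by a Normal ppm
  error (sigma 3 ppm) with lognormal intensity (mu 5, sigma 1, arbitrary
  units); a fraction rho = 0.6 of the log-intensity variance is a
  per-compound latent ionization factor shared across platforms and
  adducts, so cross-platform AUC correlations are positive as in real
  libraries. Background noise is Poisson-many uniform-m/z peaks of low
  lognormal intensity, with the positive-mode rate (30/spectrum) strictly
  above the negative-mode rate (10/spectrum), mimicking the elevated TIC
  of positive-ion background.
- **Measurement plan** — retained compounds fill 96-well plates row-major
  and are stamped into 384-well plates; the first platform measures all
  retained compounds, the second a seeded representative subset of 384.

Everything derives from one integer seed via spawned child generators per
stage, so a campaign is byte-identical under a fixed seed, and the ledger
records every true flag. Two consistency properties are tested: with zero
mass error and zero background, detection at snr_min = 1 recovers the
ledger's response flags exactly; and empirical rates converge to their
configured probabilities within binomial 3-sigma bands.

What the generator does not emulate: chromatography and retention time,
isotope patterns, adduct cross-talk, in-source fragmentation, plate-edge
effects, and any correlation between descriptors and degradation. Passing
tests therefore validate the analysis machinery, not instrument physics.

## Problem sizes and determinism choices

The default campaign (2548 reactions, ~1235 retained, 384-compound
cross-platform subset) runs the whole pipeline in well under a minute. The
test suite exercises statistical properties at n = 1000 products with 20
seeded repetitions for importance recovery, and uses a reduced campaign
(16 × 12 building blocks) for the byte-determinism check; the acceptance
script runs the full default scale. All stochastic tests fix their seeds;
3-sigma binomial bands are used wherever a rate is compared to its target.

## Known limitations

- The built-in vocabularies avoid extra H-bond donors, so nHBDon is
  constant across generated libraries; the importance model correctly
  reports it as uninformative, but campaigns with donor-bearing R groups
  are outside what the defaults emulate.
- A single survival probability cannot reproduce simultaneously a
  full-library detectability of 88% and a subset either-platform rate of
  94%; the generator treats survival as the latent state and leaves
  platform marginals to the response probabilities.
- The per-adduct noise estimator is a median over non-matched peaks; in
  very sparse spectra (fewer than ~5 background peaks) it is coarse, and
  the unit floor dominates.
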