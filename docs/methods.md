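# Methods

## Scope and model

`feedenergy` implements the summative approach to feed energy: total
digestible nutrients at maintenance intake are the sum of truly
digestible crude protein, fatty acids (×2.25 for their higher energy
density), non-fiber carbohydrate and NDF, minus a constant 7 percentage
units of metabolic fecal loss. The protein, fat and NFC terms are common
to all variants; the digestible-NDF term is supplied by one of five
sub-models — two chemistry-only surface-law forms (the classical 0.75 /
exponent-0.667 form and a tropical re-fit with scale 0.6232 and exponent
1.2258) and three assay-driven forms that scale NDF by a measured 48-h
NDF degradability (in vitro with coefficient 1.0 or 0.75, or in situ
with coefficient 1.0).

Assumptions worth stating explicitly:

- The surface law treats lignin as an indigestible core shielding fiber
  in proportion to (L/(NDF−NDICP))^(2/3); the printed coefficient 0.667
  is used verbatim rather than the exact 2/3 so results match published
  tables cell-for-cell.
- `dFA = EE − 1` is clamped at zero. Feeds with ether extract below 1 %
  of DM would otherwise contribute negative digestible fat; the clamp is
  the conventional reading and is required to reproduce the bundled
  reference predictions for low-fat grasses (EE = 0.8).
- The processing adjustment factor FAP multiplies the NFC term and is
  1.0 throughout the bundled data; it is kept as a per-feed field.
- At exactly TDN_1x = 60 the intake-discount rule applies the
  no-discount branch, preserving TDN_3x ≤ TDN_1x. The rule is
  discontinuous (the discount is 1.0 unit just above 60); it is applied
  as printed, not smoothed.
- ME_3x = 0.036·TDN_3x exactly. The published ME column this mirrors is
  internally inconsistent with that constant in several cells (±0.1
  after rounding); the equation, not the column, is authoritative here.

## Parameters and units

All composition fields are % of DM (DM itself % as-fed); degradabilities
are %; TDN in percentage units; ME in Mcal/kg DM. The constants — 2.25
fat energy multiplier, 0.98 NFC digestion coefficient, 1.2 / 0.4 bound-
protein penalties, 7 endogenous loss, 0.75/0.667 and 0.6232/1.2258
surface-law pairs, the 60 % discount threshold, 0.18/10.3 discount
coefficients and 0.036 Mcal per TDN point — are model constants, not
tunables, and are defined once next to the function that uses them.

## Data layer

Validation distinguishes hard invariants (negative fractions, NDICP ≥
NDF, lignin ≥ NDF−NDICP, NFC inconsistent with the by-difference
identity beyond 0.15 points) from soft anomalies that occur in real
published data and only warn (ADF > NDF, ADICP > NDICP). Ash and NFC
are interconvertible through NFC = 100 − [CP + (NDF−NDICP) + EE + Ash];
whichever is absent on read is derived from the other, so models always
see both. The bundled twelve-feed table carries ash back-derived from
the published NFC, and three transcription corrections documented in its
`note` columns: two restored decimal points and a one-row rotation of
the four middle in situ rows, adopted because the published calibration
line (Y = 0.8313X + 15.475, R² = 0.94), the in situ TDN column and the
ISDMD–IVTDMD correlation (R² = 0.92) are all reproduced exactly under
the rotated assignment and none under the printed one.

## Regression engine

Model precision is the OLS of predicted TDN on observed 48-h in vitro
true DM digestibility, one point per feed (n = 12 in the bundled data;
replicate-level fits are out of scope because replicates are not part of
the data model). The fit is computed from centered sums — slope =
Sxy/Sxx, intercept = ȳ − b·x̄, R² = Sxy²/(Sxx·Syy) — so the numerical
contract is explicit; standard errors use the usual residual-variance
formulas and are NaN at n = 2. Constant x raises an error (undefined
slope). R² is clipped to [0, 1] against floating-point overshoot. The
test suite checks the engine against an independent normal-equation
solve and against statsmodels to 1e−9, plus the classical identities
(R² = r², slope(y|x)·slope(x|y) = R², affine equivariance).

## Synthetic data generator

The generator emulates the bundled table's variability: default ranges
CP 4.3–17.7, EE 0.8–3.5, ash 3.5–15, NDF 25.9–77.9 (% of DM),
NDICP/NDF 0.04–0.15, L/(NDF−NDICP) 0.08–0.26, ADICP/NDICP 0.2–0.7,
forage fraction 8/12 — the ranges observed across the twelve feeds.
Rows are valid by construction: NDF is drawn after CP, EE and ash and
capped so NFC (computed by difference) is non-negative; ratio
parameterisation guarantees NDICP < NDF and lignin < NDF−NDICP. A
configuration whose NDF minimum exceeds the feasible cap is rejected as
infeasible rather than silently clipped.

Degradability is linked to chemistry through the surface law: the
"true" 48-h NDF degradability is the value making the assay-driven dNDF
equal the chemistry-driven one. Modes: `surface_law_exact` (assays
report the truth exactly — the regime where the in vitro and surface-law
models must coincide to 1e−9, used as an end-to-end oracle),
`surface_law_noisy` (independent truncated-Gaussian noise, default sd 3
percentage points, comparable to the assay standard errors in the
bundled data; clipped to [0, 100], not resampled, keeping generation
O(n)), and `independent` (uniform draws, severing the link). Observed
IVTDMD is generated as a true-digestibility proxy — the sum
dCP + 2.25·dFA + dNFC + dNDF without the endogenous-loss subtraction,
clipped to [0, 100], plus the mode's noise. This proxy is a modelling
convenience for exercising the evaluation pipeline; it is not an assay
model, and passing tests on synthetic data therefore demonstrate
pipeline correctness, not biological realism. Real assays add
correlated replicate structure, time-course kinetics and feed-specific
biases (e.g. cutin-bound fiber) that the generator deliberately does not
simulate.

Randomness: a single integer seed; every field draws from its own
sub-stream keyed by a CRC-32 of the field name in a fixed documented
order, so adding fields later cannot shift existing draws and identical
configurations give bit-identical tables.

Under assay noise of sd 3 at n = 200 the in vitro model's precision R²
concentrates near 0.87 (40-seed Monte-Carlo band 0.81–0.94, mean ± 4 sd);
the regression test asserts membership in that pre-computed band rather
than a point value, since noise necessarily attenuates R² below its
noise-free value of 1.

## Numerical choices and degenerate inputs

Full floating precision everywhere; rounding to one decimal happens only
in rendered reports (full-precision `*_full.csv` companions are always
written). Digestible CP is undefined at CP = 0 and raises; the linear
concentrate form is clamped at zero for extreme ADICP/CP. Surface-law
dNDF is exactly 0.75·(NDF−NDICP) at L = 0 and 0 at L = NDF−NDICP;
lignin beyond that range is an error (negative digestible mass). An
empty input table yields empty outputs without error in I/O paths but is
rejected when constructing the analysis model, and a method whose
required degradability field is missing raises an error naming both the
method and the field.

## Problem sizes

The bundled analysis is twelve feeds × five models and runs in well
under a second. Property tests use up to 1000 generated feeds for the
equivalence oracle and 200 for the noisy-precision band; these sizes
give comfortable statistical resolution while keeping the whole suite
fast.

## Known limitations

- The discount rule's discontinuity at 60 means feeds near the threshold
  can rank differently at maintenance and production intakes.
- Precision is judged against in vitro true DM digestibility as the
  observed benchmark, itself a proxy for in vivo digestibility; a high
  R² means agreement with the assay, not validated in vivo accuracy.
- Feed-class assignment (forage vs concentrate) switches the dCP form
  discontinuously; borderline feeds (e.g. whole-plant byproducts) can
  shift TDN by a few tenths depending on classification.
- No net-energy systems, no intake levels other than 1× and 3×, and no
  replicate-level mean-separation statistics are implemented.
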