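# Methods

## Scope and model

`wbequant` covers the computational half of a multi-drug wastewater
surveillance workflow. The measurement chain is:

1. every sample is spiked with isotopically labelled internal standards
   (IS) before extraction, so per-sample effects — injection volume, matrix
   ionization suppression or enhancement, extraction losses shared by
   analyte and label — cancel in the **response ratio**
   `y = area_native / area_IS`;
2. over a calibrant series with nominal extract concentrations `x` (ng/mL),
   the ratio is modelled as a straight line `y = a·x + b` per compound;
3. inverse prediction maps a field sample's ratio to an extract
   concentration, the gravimetric concentration factor maps extract ng/mL
   to wastewater ng/L, and the per-capita chain maps ng/L to mg/day per
   1000 inhabitants.

## Calibration

* **Design.** 22 levels spaced geometrically from 0.001 to 200 ng/mL
  (`calibrate.default_levels`). Geometric spacing is the natural choice for
  a five-decade range; only the endpoints and the count are fixed
  constraints, the spacing is this package's choice.
* **Weighting.** Default `1/x`; `none` and `1/x²` selectable. Over five
  decades an unweighted fit is dominated by the top level, inflating
  low-end relative error. `1/x` is the common compromise in regulated
  bioanalysis; `1/x²` is variance-optimal under purely multiplicative
  noise and is available where low-end accuracy matters most.
* **Acceptance.** `R² ≥ 0.995` (strict default) with `0.99` selectable;
  R² is computed on the weighted fit. Rejected curves refuse inverse
  prediction; the pipeline reports affected compounds as not quantifiable
  rather than silently passing them through.
* **Uncertainty propagation.** `calibrate.slope_relative_se` gives the
  analytic (sandwich) relative SE of the weighted slope under
  multiplicative response noise. The noise-predicted measurement CV used in
  parameter-recovery tests is `hypot(cv_ratio, slope_se)`: the response
  noise of the sample itself plus the shared calibration uncertainty. For
  the default design at 5 % per-area noise this is ≈ 8.0 %.

## LOD/LOQ decision rules

Per-run limits use chromatographic S/N thresholds of 3:1 (LOD) and 10:1
(LOQ) on quantifier peak height over baseline noise SD. Manual practice
determines these visually; this package replaces eyeballing with a
**monotone-suffix scan**: the reported level is the lowest level from which
every higher level also clears the threshold, so a noisy dip above a
spurious low crossing invalidates it. This is a deliberate, documented
departure from manual determination — deterministic and auditable.

Across runs, the mean of the first five *determined* values per compound
freezes into a reference; each later run reports
`max(run value, reference)`. Both branches of that rule are conservative: a
run claiming better sensitivity than the reference is reported at the
reference, a worse run at its own (higher) value. Non-detect runs do not
count toward the five. State persists in a human-readable JSON file.

Censoring uses half-open intervals: `conc < LOD → below_lod`,
`LOD ≤ conc < LOQ → between_lod_loq`, `conc ≥ LOQ → quantified`; negative
inverse predictions are below_lod and 0-censored in ng/L. The boundary
convention is this package's choice; nothing downstream depends on the tie
side.

## Quantitation, units and QC

The concentration factor is `extract_volume_mL / (mass_g / density / 1000)`
— a 100 g aliquot at density 1.0 reconstituted to 0.5 mL concentrates 5×
in (ng/mL → ng/L) units. The interim evaporation endpoint (~0.125 mL) is
not a separate factor because dilution to the final 0.5 mL supersedes it.
LOD/LOQ are propagated to ng/L with the same factor, keeping censoring
scale-consistent.

QC gates: spiked-QC accuracy `100·mean/nominal` within **[80, 120] %**
(inclusive, mirroring "within ±20 %") and replicate RSD **< 20 %**
(strict, mirroring "below 20 %"); blanks must be below LOD. A failed gate
flags every measurement in the batch (`qc_pass=False`) but deletes
nothing — rejection policy belongs to the study, not the library.

Below-LOD values contribute to summaries via a substitution policy:
`half_lod` (default), `zero`, `lod_over_sqrt2`, or `exclude`.
Between-LOD/LOQ values contribute their measured value and keep their
flag. LOD/2 is the field's default convention; it biases means upward when
censoring is heavy, which is why the flag travels with every record.

## SPE recovery

Extraction efficiency is the ratio of means, `100·mean(before)/mean(after)`
over triplicate spike-before / spike-after extractions, per compound per
sorbent. Values above 100 % indicate matrix enhancement and are never
clipped. The printed RSD is attributed, by default, to the before-spike
(whole-method) replicates, with replicate-wise ratio RSD as an option — a
single published RSD per compound cannot disambiguate the two, so the
attribution is documented rather than guessed silently. Ratio-of-means
estimators carry a small positive bias of order `CV²/n` (≈ 0.3 % at CV 10 %,
n = 3), visible in the Monte-Carlo helper `recovery_estimates`.

## Back-calculation

Excretion rate: `E = C · F · 10⁻⁶ / (P/1000)` in mg/day per 1000
inhabitants (C in ng/L, F in L/day, P persons). Consumption:
`E / f_excretion`, further multiplied by `MW_parent / MW_metabolite` when
the measured biomarker is a metabolite. Units are the field convention.
Flow joins per sample date when a dated site record exists, else the site
constant. When both parent and metabolite are measured, both estimates are
reported; the metabolite-derived one is the preferred consumption figure
(less sensitive to direct disposal).

Excretion fractions in the default panel are literature-typical values and
the dominant uncertainty of any consumption estimate; they are data, not
code, and should be replaced with study-specific values. Compounds without
a fraction yield excretion rates only.

## Synthetic data generator

`simulate.SimConfig` defaults define the emulated campaign: 22 calibrant
levels (0.001–200 ng/mL), 5 % multiplicative area noise, triplicate spiked
QCs at 10 ng/mL, 100 g aliquots to 0.5 mL extracts, 17 sites × 35 weekly
samples, and recovery triplicates at CV 10 % with true efficiencies of
0.85/1.00 (amphetamine) and 0.78/1.12 (methamphetamine) on MCX/HLB.

* Area noise is mean-1 lognormal (areas are positive; MS area noise is
  multiplicative). Native and IS areas draw **independent** noise factors,
  so the response ratio carries CV ≈ √2·5 % ≈ 7.07 %.
* Matrix suppression is one uniform(0.6, 1.2) factor per extracted sample
  applied to native and IS alike — the situation isotope dilution cancels
  exactly; `differential_suppression` adds native-only noise to break the
  cancellation for stress tests.
* Field truth is lognormal per site-week around per-compound medians
  (typical influent magnitudes for the well-characterized biomarkers,
  50 ng/L otherwise; geometric CV 0.5).
* S/N studies use additive Gaussian baseline noise on height
  (`height = slope·level + N(0, σ)`), the regime where detection limits
  live.

What the generator does **not** emulate: chromatographic peak shape,
retention drift, carryover, analyte degradation during transport/storage,
correlated inter-compound matrix effects, population dynamics (tourism,
commuting). Passing parameter-recovery tests therefore demonstrates the
pipeline's correctness under its own statistical assumptions, not the
field accuracy of any real campaign.

Test and validation studies run deliberately reduced designs (e.g. 4
biomarkers × 5 sites × 6 weeks, 10–200 seeds) — large enough for stable
statistics, small enough to iterate on; the full 52 × 17 × 35 default
remains available.

## The packaged panel

The default panel is assembled from published multi-drug recovery and
application tables plus literature pharmacokinetics. Where a primary source
for an entry was not available, the entry is a flagged placeholder (one
native, two standards) chosen to preserve the documented 52/22 shape and
class composition; ambiguous class assignments (caffeine as stimulant,
phencyclidine under "other"/hallucinogens, zolpidem under "other") follow
the same composition. Transition (SRM) m/z metadata is optional and carried
only for documentation. The panel is normative data for this artifact:
replace it wholesale for your own instrument method.

## Numerical choices and degenerate inputs

* WLS is closed-form (numpy); an independent statsmodels WLS cross-checks
  it in the tests.
* A flat calibration series yields `accepted=False` (not an exception) when
  the algebra is defined; fewer than 3 distinct levels or zero level
  variance raise errors.
* Readers validate types and invariants row-by-row and report row numbers;
  writers fix column order and use 17-significant-digit floats so identical
  inputs give byte-identical files and `read(write(x)) == x` exactly.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give identical batches.
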