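# Methods

## Model and assumptions

The package estimates the daily flux of fermentation products released by the
large-intestinal microbiota and absorbed by the host. The central assumption
is steady state: the gut community neither grows nor shrinks on the timescale
of days, so bacterial biomass lost in feces is replaced by growth, and the
substrates fueling that growth set the accompanying fermentation-product
release. Two consequences are exploited as independent estimators:

1. **Via feces.** The daily bacterial biomass excreted, `M_fec,bac`, equals
   daily biomass production. Multiplying by the community's per-biomass total
   excretion `ε_tot` gives `FP_tot = ε_tot · M_fec,bac`.
2. **Via carbohydrates.** The microbiota-available carbohydrates `M_carb`
   (in hexose equivalents) limit biomass production through the community's
   hexose demand `1/Y_carb`, giving `FP_tot = ε_tot · Y_carb · M_carb`.

On a world where `M_fec,bac = Y_carb · M_carb` the routes agree identically;
on real (or realistically generated) inputs their few-percent agreement is
the framework's internal cross-validation. A third, coarser consistency check
derives the release from the ATP turnover needed to build the daily biomass.

Static composition, no explicit cross-feeding kinetics (net acetate rates
implicitly absorb acetate cross-feeding), and no within-day dynamics are
modelled; these are deliberate scope limits, not oversights.

## Rate extraction

During steady exponential growth, metabolite concentrations are linear in
culture density, so rates are regression slopes rather than differences:

- growth rate `μ`: OLS slope of ln(OD600) vs. time (SE of the slope as its
  uncertainty); replicates with `μ ≤ 0` or `r² < 0.9` are excluded as
  non-growing (threshold configurable);
- per-biomass rates: OLS slope of concentration vs. OD600 (mM per OD unit)
  divided by the OD→dry-weight conversion `od_to_dw`.

`od_to_dw` is **not** a universal constant; it defaults to 0.5 g dry biomass
per litre per OD600 unit (a typical value for dense-celled gut anaerobes) and
is recorded with every profile. Calibrate it per spectrophotometer/strain
when absolute rates matter; all downstream fluxes scale linearly with it,
and it cancels in slope-ratio quantities.

Samples are restricted to OD600 in [0.04, 0.5] (absorbance linear in
biomass; configurable). Acetate is a *net* rate because the standard growth
medium carries 10 mM background acetate: net uptake (negative rate) is legal
for acetate and clipped-at-zero-with-warning for all other products. Slope
fitting is insensitive to a constant background, which is why no background
subtraction is attempted. Replicates are combined as unweighted means with
across-replicate SDs (never SEs).

The carbon balance per strain — carbon in consumed sugar vs. carbon in
excreted products — should be near 1 for fermentative growth; ratios above
1.1 are flagged as likely consumption of other medium components. pH
sensitivity is a linear trend of each rate across pH conditions, reported as
the relative change from pH 6 to 7.

## Community weighting

Tables are aggregated to the **genus** level by default: coverage by
characterized strains is already high there, while strain-level metabolic
differences are not yet averaged away (rank is a config knob). Biomass not
represented by any characterized strain is dropped and the remaining weights
renormalized — equivalent to assigning unrepresented taxa the represented-set
average behaviour. The alternative `coverage_discount` mode multiplies all
fluxes by the covered fraction instead and serves as a sensitivity bound;
both are provided because the right treatment of unrepresented biomass is
genuinely open. Multiple strains mapping to one genus are averaged
unweighted first. Per-sample abundance sums in [0.97, 1.0001] are accepted
and renormalized; anything else is an input error.

The reference community profile uses the measured healthy-gut constants
`ε_tot = 29 mmol/g` and demand `13 mmol hexose/g` with a representative
molar product mix (acetate 0.40, butyrate 0.17, propionate 0.13, formate
0.12, lactate 0.10, succinate 0.08); profiles derived from abundance tables
are used wherever variation across compositions is the question.

## Diet → MACs

`mac_g = starch_passage·starch + fiber_digestibility·fiber +
sugar_passage·sugar`, with scenarios low (0.10, 0.30), medium (0.13, 0.50)
and high (0.15, 0.75) spanning observed ranges of starch passage and
microbial fiber digestion; simple sugars are assumed fully absorbed in the
small intestine (`sugar_passage = 0`, configurable for malabsorption).
Gram↔hexose conversion defaults to 180 g/mol (free glucose), with a 162 g/mol
anhydroglucose option for polymer bookkeeping; the choice is logged because
published mass/molar pairings imply slightly different conventions (the
reference pairing of 36 g with 198 mmol implies ≈182 g/mol). Where a printed
molar value (198 mmol/day) is itself the input, it is used directly rather
than re-derived through the conversion.

The protein/mucin contribution is computed as an explicit **upper bound**:
all protein reaching the colon (ileal passage fraction 0.1 of dietary
protein, plus 5 g/day mucin) is assumed fully fermented at 2 mmol products
per g, none assimilated. With reference inputs this ceiling is well under
20% of the total release; the true contribution is smaller still.

The ATP-route defaults are chosen self-consistently with the measured
community constants: ~13 mmol hexose per g biomass at ~4 ATP per hexose
gives 52 mmol ATP per g biomass, and ~29 products per 52 ATP gives 1.8 ATP
per product.

## Fecal model

Dry-mass fraction models (coefficients configurable, refittable from any
paired wet/dry table):

- constant: `α_dw = 0.25` (reference-style narrow output; 120 g/day wet →
  30 g/day dry → 16 g/day bacterial at `α_bac = 16/30`);
- linear: `α_dw = 1 − (0.69 + 4.63·10⁻⁴·M_wet)`;
- non-linear: `α_dw = 1 − (0.49 + 0.03·√M_wet − 7·10⁻⁴·M_wet)`, flattening
  at high output and acting as an upper-bound model for dry mass.

The published coefficient strings for the latter two are typographically
ambiguous in their units; the defaults above were resolved to reproduce a
dry fraction falling from ≈0.28 at 100 g/day to ≈0.19 at 400 g/day, and a
refit routine is provided so users with source data never need the defaults.
Evaluated fractions are clamped to [0.05, 0.6] (empirical fits must not be
extrapolated into unphysical territory). `α_bac` is constant across fecal
mass for lack of data on its variation — at very high outputs this makes
the fecal route an overestimate. Transit time is `τ = k/M_wet` with
`k = 7200 g·h` (≈60 h at 120 g/day).

## Carbon flow, uncertainty, variation

The carbon ledger takes MAC carbon as `0.40 · mac_g` (carbohydrate carbon
fraction equal to glucose), product carbon from molar fluxes and per-product
carbon counts (acetate 2, propionate 3, butyrate 4, lactate 3, formate 1,
succinate 4), biomass carbon at 0.39 g C per g dry biomass, and a 2% fecal
loss of released products; produced = absorbed + lost holds exactly by
construction. On communities with near-unity strain carbon balances, >90% of
MAC carbon ends up in fermentation products.

Uncertainty uses first-order Gaussian propagation: for product/quotient
chains the relative variances of independent terms add. This is accurate to
a few percent for relative SDs up to ~15% (validated against a seeded
Monte-Carlo oracle in the tests). Cohort and composition variation are
summarized by coefficients of variation (SD/mean, ddof = 1) and percentiles
with linear interpolation between order statistics (the convention matters
for medians and is therefore fixed and documented).

Per-product absorbed fluxes are floored at zero when summing totals:
absorbed flux cannot be negative even when a community's net acetate rate is.

## Energy

Default combustion enthalpies (kJ/mmol): acetate 0.875, propionate 1.527,
butyrate 2.184, lactate 1.368, formate 0.255, succinate 1.491 — standard
thermochemical values, overridable by a user CSV. Human context: 10 MJ/day
expenditure, 70 kg reference body mass (an assumption, not a measurement),
2.14 m² colonic epithelial area. Mouse context: 38 kJ/day expenditure, 25 g
body mass, with an 8.1 kJ/day energy-extraction gap between conventionally
colonized and germ-free animals; the harvest-energy route (mouse fecal
output 1.6 g/day wet at dry fraction 0.30 and bacterial fraction 0.55)
reproduces that gap to within ~15%, supporting the interpretation that the
gap *is* the fermentation-product energy.

## Synthetic data: what it emulates, and what it does not

Generators draw from independent RNG streams keyed by (seed, generator
name), so outputs are bit-for-bit reproducible and insensitive to the
addition of new generators. Default seed: 20250730.

- **Growth experiments**: exponential OD between 0.05 and 0.45 with
  concentrations exactly linear in OD plus additive Gaussian noise. No lag,
  saturation, or pH drift — so recovery tests validate the estimator, not
  robustness to model violations.
- **Strain archetypes**: five family templates (succinate/propionate-
  producing Bacteroidaceae, butyrate-producing Lachnospiraceae and
  Ruminococcaceae, 3:2 lactate:acetate Bifidobacteriaceae, mixed-acid
  Enterobacteriaceae). Each strain draws hexose demand uniformly within
  ±30% of 13 mmol/g and a carbon-conversion fraction in [0.91, 1.01]; total
  excretion follows from carbon conservation, so carbon balances are inside
  [0.90, 1.05] *by construction* and the abundance-weighted community lands
  near 29 mmol/g and 13 mmol/g. These targets are asserted by calibration
  tests, not hard-coded into outputs.
- **Abundance samples**: Dirichlet draws (precision 50) over 60 genera with
  an uneven base measure concentrating ~84% of biomass in the archetype
  genera — emulating the uneven composition of healthy-adult gut
  metagenomes, not any particular cohort's covariance structure.
- **Diet cohorts**: right-skewed lognormal intakes with medians below the
  reference (US-style), a 12-month sinusoidal carbohydrate cycle peaking
  well above the reference (forager-style), and the fixed British-style
  reference record (fiber 24, starch 185, sugar 100, protein 85 g/day;
  medium-scenario MACs ≈ 36 g/day).
- **Fecal cohorts**: narrow lognormal around 120 g/day wet (1970s-UK-like)
  vs. a heavy-tailed lognormal whose maxima reach several times the British
  mean (global-like).

Passing tests on these fixtures show the estimators, ledgers, and summaries
are implemented correctly and behave sensibly on realistically shaped
inputs. They do **not** show that real cohort medians or percentile
envelopes are reproduced: published cohort-scale numbers (e.g. a US-cohort
median near 286 mmol/day, seasonal peaks near 1,000 mmol/day, fecal-route
maxima near 1,500 mmol/day, coverage fractions of 59.6%/83.7%) require the
real metagenome/diet/fecal microdata, which are out of scope; the test suite
replaces them with ordering and band assertions on the synthetic fixtures.

## Numerical choices and problem sizes

All regressions are ordinary least squares via `scipy.stats.linregress` or
normal-equation least squares (`numpy.linalg.lstsq`) — verified against
directly computed normal equations. Abundance tables are renormalized to
column sums of exactly 1. Degenerate inputs fail loudly (zero uptake for a
carbon balance, identical OD values, fewer than 3 points, < 3 pH levels,
zero-valued terms with non-zero SD in relative propagation). Reported point
estimates carry full precision internally; rounding to 2 significant figures
happens only in CLI table display.

Default problem sizes — 219 abundance samples, 200-record cohorts,
1e5 Monte-Carlo draws, 20 archetype strains — keep the whole suite under a
few seconds while leaving estimator variances far below the assertion
tolerances.

## Known limitations

- Static community composition; no prediction of compositional responses to
  diet.
- Cross-feeding only implicit (net acetate); lactate conversion is not
  modelled, so per-product (not total) fluxes are least reliable where
  lactate utilizers are abundant.
- Constant bacterial fraction of fecal dry weight; fecal-route estimates at
  very high outputs are upper bounds.
- The OD→dry-weight conversion is a documented default, not a measured
  constant; absolute per-biomass rates inherit its uncertainty.
- Minor fermentation end products (H₂, CO₂, H₂S, branched-chain acids) are
  outside the six-product accounting.
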