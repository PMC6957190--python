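# Methods

This note documents the statistical model behind `allofrac`: what is being
estimated, how the synthetic-data generator was parameterised, and which
design decisions and limitations a user should know about.

## 1. The measurement model

A plasma sample from a transplant recipient contains a two-genome mixture:
a fraction `1 − df` of cell-free DNA (cfDNA) from the recipient and a
fraction `df` from the donor organ. The assay quantifies both alleles of
each of 94 biallelic SNPs (plus 2 non-polymorphic controls used as
quantification calibrators).

**Informative targets.** At a target where the recipient is homozygous,
all minor-allele signal must come from the donor (or from assay
background). The donor contributes that signal with both chromosomes when
homozygous for the opposite allele, and with one chromosome when
heterozygous, so the per-target estimate is

```
df_target = multiplier × minor-allele fraction,   multiplier ∈ {1, 2}
```

For unrelated pairs under Hardy-Weinberg equilibrium with minor-allele
frequency `q` (and `p = 1 − q`), the probability that a target is
informative is `p²(1−p²) + q²(1−q²)`, maximised at `q = 0.5` where it is
exactly 0.375. Per-target estimates above 0.5 are excluded as genotyping
inconsistencies (a correctly assigned biallelic minor species cannot exceed
half the molecule population).

**Method 1 (donor genotype known).** DF is the median of the per-target
estimates over informative, calibrator-passed targets. The median is used
because individual targets occasionally misbehave (cross-reactivity,
background); it is exactly `df` on noise-free data, which the test suite
asserts to 1e-12 across 0.1–10% DF.

**Method 2 (donor genotype unknown).** Donor genotypes are inferred by a
staged Monte Carlo:

1. *Stage 1* draws candidate donor genotype vectors from Hardy-Weinberg
   priors at the panel allele frequencies, restricted to
   recipient-homozygous targets. Each candidate implies a DF (median of its
   per-target estimates) and is scored by a Gaussian likelihood of the
   observed log minor fractions. The scored candidates give a
   likelihood-weighted working DF.
2. Per-target donor-genotype posteriors are formed analytically at the
   working DF (prior × per-target likelihood), rather than from the raw
   candidate counts — this Rao-Blackwellisation removes most of the
   stage-1 sampling noise.
3. *Stage 2* draws donor vectors from those posteriors; each draw yields a
   candidate DF, and the reported DF is a linear calibration applied to the
   median of the candidate-DF distribution.

The likelihood is a three-component mixture per target, over donor
minor-allele copy number g ∈ {0, 1, 2} with means `log(g·df/2 + ε)`:

- For g ∈ {1, 2}, the scale σ is *pooled* across targets — the median of
  the per-target replicate SDs of log minor fractions, scaled to the SE of
  the replicate mean and floored at 0.05. Per-target scale estimates from
  duplicate wells are far too noisy to use individually.
- For g = 0 (no donor signal), the observation is assay background. Its
  level ε = 5e-4 is set to roughly half the blank limit of the DF assay
  (0.110%), and its dispersion is `sqrt(σ² + 0.8²)` because the background
  level itself varies widely between targets and runs. Without a wide,
  correctly-centred background component, background-only targets at low
  DF are misread as weak donor signal, producing a DF-dependent bias that
  no linear calibration can remove.

**Calibration.** The shipped `McConfig.calibration = (0.9986, 0.000123)`
maps the Method-2 midpoint onto the Method-1 computation. It was fitted by
`scripts/calibrate_method2.py`: a 120-sample synthetic cohort spanning the
linear range (seed 424242), Passing-Bablok regression of Method 1 on
uncalibrated Method 2 over the training half, verified on the held-out
half and on an independent 200-sample cohort where the calibrated methods
are statistically equivalent (slope CI containing 1, intercept CI
containing 0). The residual intercept (+0.012% DF) reflects a real
asymmetry: Method 1 inherits the additive assay background in full, while
Method 2's posterior assigns part of it to the g = 0 component.

## 2. The synthetic-data generator

`simulate_qgt_sample` produces per-target, per-replicate allele quantities
from a mass-balance model: total cfDNA mass is split across targets, mixed
as `(1 − df)` recipient + `df` donor according to the two genotypes, then
degraded by three noise components:

| parameter | default | role |
|---|---|---|
| `noise_cv` | 0.10 | independent lognormal noise per replicate and allele |
| `minor_gain_log_sd` | 0.06 | per-run lognormal gain shared by all minor-species measurements |
| `crosstalk_median` / `crosstalk_log_sd` | 4e-4 / 0.8 | mass-conserving allele cross-talk (background), lognormal across targets |
| `run_effect_log_sd` | 0.72 | run-level coherence of the background level (reagent lot / instrument effects) |

The decomposition matters. Reference precision data for assays of this
kind span days, operators and reagent lots, so much of the observed
replicate %CV is *between-run* variation. Between-run variation spreads
the DF estimate between runs but does not blur the twofold
(heterozygous-vs-homozygous-donor) separation of per-target signals within
a run; putting all of the noise into independent per-target scatter makes
donor-genotype inference irreducibly ambiguous and Method-1/Method-2
equivalence impossible, which contradicts the observed behaviour of such
assays. The calibration targets were the reference %CVs of DF
determination across the dynamic range: with the defaults, 46-replicate
Method-1 %CVs measure 23.8% / 8.1% / 6.2% at 0.2% / 1% / 10% true DF
(23.5% / 7.7% / 5.8% in an independent seed stream), bracketing the
reference values ≈23% (low) and ≈7% (high), and blank samples produce a
median DF of 0.05% with a 95th percentile near the 0.110% blank limit.

With `noise_cv = 0` and `crosstalk_median = 0` the generator is exact:
per-target mass conservation holds bitwise, and minor fractions equal
their theoretical values. Cross-talk reassigns mass between the two
alleles of a target but never creates or destroys it.

**What the generator does *not* emulate:** amplification curves and Cp
calling (the instrument's job), allele dropout, copy-number variants,
primer competition, pipetting-volume drift, or sequence-specific
amplification bias. Contamination is modelled purely as recipient-genotype
genomic DNA mass (6.6 pg per diploid leukocyte).

## 3. Quality control

Every DF result carries the full gate table (observed value, threshold,
pass/fail per gate; nothing is silently dropped):

- ≥ 75 of 96 calibrator-passed targets; ≥ 70 quantifiable targets;
- ≥ 27 informative targets (below this, median sampling error dominates);
- RNase P log-value within [8, 10] (sample input adequacy);
- robust CV of per-target estimates ≤ 100%
  (`100 · 1.4826 · MAD / median`);
- skew ≤ 1.01, where skew = `max(mean/median, median/mean)` of the nonzero
  per-target estimates — a relatedness-sensitive asymmetry metric, since a
  related donor violates the Hardy-Weinberg assumptions and distorts one
  tail of the estimate distribution;
- Alu ratio ≤ 0.45 when fragmentation data are present.

**Known conservatism of the skew gate.** Under the calibrated noise model
the per-target estimates are approximately lognormal with σ ≈ 0.3, for
which the expected mean/median ratio is `exp(σ²/2) ≈ 1.05` before sampling
noise. The default threshold of 1.01 therefore fails a substantial share
of ordinary, unrelated-donor samples (it is a strict distribution-shape
test, not a calibrated false-positive rate). The threshold is deliberately
configurable (`skew_max`); users simulating with the default noise model
should expect skew-gate failures on clean samples and widen the gate, or
treat it as a relatedness *flag* rather than a hard validity gate.

## 4. Fragmentation and contamination

Plasma cfDNA from apoptosis is short (~167 bp); DNA from lysed leukocytes
is long. Short (115 bp) and long (247 bp) Alu amplicons measure both: the
short amplicon amplifies everything, the long one mostly lysis-derived
DNA. The ratio `alu247/alu115` sits near 0.2–0.4 in clean plasma and rises
toward 1 with contamination; the default failure threshold is 0.45.

Contamination by recipient genomic DNA dilutes the donor signal:
`df_obs = df_true · T / (T + C)` for cfDNA mass `T` and contamination mass
`C`. The donor mass is conserved exactly (`df_obs·(T+C) = df_true·T`), and
both the observed DF and the Alu ratio are strictly monotone in the lysed
cell count — the mechanism by which unflagged leukocyte lysis can turn a
true-positive DF into a false negative. Note that both reported quantities
are *ratios* and therefore rational, not linear, functions of the
contamination mass; the underlying measured concentrations (`alu115 = T +
C`, `alu247 = ρT + C`) are exactly linear in it.

## 5. Validation statistics

The `valstats` module implements the standard detection-capability and
method-comparison machinery, each verified against worked examples or
independent oracles in the test suite:

- **LoB**: nonparametric rank rule, position `round_half_up(0.5 + B·(1−α))`
  of the sorted blanks (757 blanks at α = 0.05 → rank 720).
- **LoD**: `LoB + cp·SD_low` with the small-sample multiplier
  `cp = 1.645/(1 − 1/(4(L−J)))`; per-reagent-lot inputs take the greatest
  per-lot LoD.
- **LoQ**: precision-profile crossing of a target %CV (power-law fit on
  log-log axes), floored at the LoD; or, for flat profiles, the lowest
  level with confirmed %CV below the limit; or the total-error bound
  `bias + 2·SD`.
- **Linearity**: first- to third-order OLS fits with the highest-order
  coefficient's significance deciding each order.
- **Passing-Bablok**: shifted median of pairwise slopes (offset by the
  count of slopes < −1, making the estimator invariant to swapping
  methods), rank-based confidence intervals, equivalence = slope CI ∋ 1
  and intercept CI ∋ 0. Chosen over OLS because both methods carry
  measurement error.
- **ROC**: mid-rank Mann-Whitney AUC (tie-corrected), Youden-index cutoff
  over midpoints between distinct scores with ties broken toward the
  higher cutoff (preserving the negative predictive value).
- **Reference intervals**: nonparametric rank interpolation with
  per-subject averaging.

Clinical constants shipped as defaults: decision cutoff 0.32% DF
(classification is `increased_probability` at or above it), LoB 0.110%,
LoD 0.165%, LoQ 0.125%, linear range 0.165–10%.

## 6. Numerical and interface choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; cohort simulation derives per-sample seeds (< 2³¹) from a master
  seed, so any sample can be regenerated in isolation. Estimators are
  bit-deterministic for a fixed seed.
- Percentages appear only at the user interface (config, CLI, reports);
  every internal computation uses fractions, and conversion happens in
  exactly two helper functions.
- JSON reports are sorted-key and fixed-indent — byte-identical for
  identical inputs. Text reports print DF with 3 significant figures.
- Config files are validated with pydantic (`extra="forbid"`): unknown
  keys and type errors are rejected with the offending key named.

## 7. Limitations

- The simulator's noise parameters are calibrated to reference %CV levels,
  not fitted to raw instrument data; absolute precision figures from the
  simulator are indicative, not metrologically traceable.
- Method 2's calibration is valid for the shipped noise model and panel;
  refit it (`scripts/calibrate_method2.py`) after changing either.
- The skew QC gate's default threshold is conservative under the
  calibrated noise model (see §3).
- Relatedness simulation uses a single-parameter allele-sharing model; it
  does not reproduce specific pedigrees.
- Panel allele frequencies are synthetic (folded MAF 0.28–0.50 by design);
  population-specific informativity predictions require real frequencies
  via `load_panel`.
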