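# allofrac

Donor-fraction quantification of transplant-recipient cell-free DNA.

After a solid-organ transplant, a small fraction of the DNA fragments
circulating in the recipient's plasma originates from the graft. That
**donor fraction (DF)** rises when graft cells die, so it serves as a
noninvasive rejection marker. `allofrac` models and analyses an
allele-specific qPCR assay that measures DF over a panel of 94 biallelic
SNPs plus 2 control targets:

- **panel** — SNP panel model, target informativity (a target is
  informative when the recipient is homozygous and the donor carries the
  opposite allele; at minor-allele frequency 0.5 the probability of this is
  exactly 37.5% for unrelated pairs under Hardy-Weinberg equilibrium).
- **simulator** — synthetic genotype pairs (with optional relatedness),
  allele-quantification runs with a calibrated three-component noise model,
  leukocyte-lysis contamination, fragmentation signals, standard curves and
  whole cohorts with ground truth.
- **quantify** — qPCR standard curves and amplification efficiency, total
  cell-free DNA (TCF) summaries, the Alu-ratio fragmentation QC and the DF
  dilution model for genomic-DNA contamination.
- **donor_fraction** — the two DF estimators: **Method 1** (donor genotype
  known; median of per-target estimates) and **Method 2** (donor genotype
  unknown; staged Monte Carlo genotype inference), plus run QC gates and
  the clinical risk classification at the 0.32% cutoff.
- **valstats** — analytical-validation statistics: limits of
  blank/detection/quantitation, precision profiles, polynomial linearity,
  Passing-Bablok method comparison, ROC/Youden cutoff selection, and
  nonparametric reference intervals.
- **cli** — a `click` command-line interface and validated YAML/JSON run
  configuration tying everything into reproducible workflows.

## Worked example

Simulate a cohort sample with a true DF of 0.8% and run the full clinical
workflow (fragmentation QC → TCF → DF → classification):

```sh
allofrac simulate --seed 46 --n-samples 1 --df-percent 0.8 --out demo
allofrac report --method with-donor \
  --sample demo/samples.csv \
  --recipient demo/recipient_genotypes.csv \
  --donor demo/donor_genotypes.csv \
  --sample-id sim0000 --rnasep-log 9.1 \
  --alu115 10 --alu247 3 \
  --tcf-replicate 9.8 --tcf-replicate 10.4 \
  --format text
```

prints

```
Sample: sim0000
Software version: 0.1.0  (seed 0)

TCF: 10.10 ng/mL (n=2)
Fragmentation: Alu ratio 0.300 [pass]
Donor fraction (with_donor): 0.891%
Classification: increased_probability

QC gates:
  calibrators            observed=94 threshold=>= 75 [PASS]
  rnasep_range           observed=9.1 threshold=[8.0, 10.0] [PASS]
  quantifiable_targets   observed=94 threshold=>= 70 [PASS]
  informative_targets    observed=33 threshold=>= 27 [PASS]
  rcv                    observed=9.596042009698907 threshold=<= 100.0% [PASS]
  skew                   observed=1.000866451747882 threshold=<= 1.01 [PASS]
  fragmentation          observed=0.3 threshold=ratio <= 0.45 [PASS]
```

The same workflow is available from Python:

```python
import allofrac as af

panel = af.default_panel()
rec, don = af.simulate_genotype_pair(panel, relatedness=0.0, seed=5)
sample = af.simulate_qgt_sample(af.SimConfig(seed=1, df_true=0.008),
                                panel, rec, don)

# Method 1: donor genotype known
r1 = af.estimate_df_method1(sample, rec, don, panel)

# Method 2: donor genotype inferred by staged Monte Carlo
r2 = af.estimate_df_method2(sample, rec, panel,
                            mc=af.McConfig(n_stage1=3000, n_stage2=6000, seed=1))
print(r1.df_percent, r2.df_percent, r1.classification)
```

Other subcommands: `allofrac df` (DF only, JSON or text), `allofrac fragqc`,
`allofrac tcf`, `allofrac validate {lob,lod,loq,linearity,precision}`,
`allofrac compare pb`, `allofrac roc`. Every command accepts `--config`
with a validated YAML/JSON file; unknown keys are rejected. All DF values
in files, options and reports are percentages; internal computation uses
fractions.

## Layout

```
src/allofrac/      package (panel, simulator, quantify, donor_fraction,
                   valstats, cli; data/default_panel.tsv)
tests/             pytest suite incl. tests/test_acceptance.py
scripts/           acceptance.py, calibrate_method2.py
docs/methods.md    methods note: model, parameters, limitations
```
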