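"""Synthetic data with known ground truth for every stage of the workflow.

The generator emulates the measurement chain of an allele-specific qPCR
donor-fraction assay:

* Hardy-Weinberg genotype pairs at the panel minor-allele frequencies, with
  an optional allele-copying relatedness knob (a donor allele is copied
  identical-by-descent from the recipient with the given probability);
* two-genome cfDNA mixtures at a specified true donor fraction, with
  recipient-only genomic-DNA contamination from lysed leukocytes that both
  dilutes the observed DF and raises the long-fragment Alu ratio;
* allele-specific quantities per target and replicate, with three
  measurement-noise components: independent per-replicate lognormal noise,
  a shared per-run quantification gain on the minor species (coherent
  between-run bias, as captured by multi-day/operator/lot precision
  studies), and a small mass-conserving allele cross-talk with run-level
  variation that reproduces the nonzero blank response of the real assay;
* qPCR standard curves with Gaussian Cp noise;
* whole cohorts with truth records and the odd/even split-by-ascending-DF
  utility used in method-comparison designs.

All randomness flows from one explicit seed; every simulated artifact
records the seed in its truth metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .panel import GenotypeCall, SnpPanel
from .quantify import FragmentationResult, flag_fragmentation
from .donor_fraction import QgtSample

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_genotype_pair",
    "simulate_qgt_sample",
    "simulate_fragmentation",
    "simulate_cohort",
    "simulate_standard_curve",
    "odd_even_split",
    "contamination_mass",
]

#: Diploid human genomic DNA mass per lysed leukocyte, picograms.
GDNA_PG_PER_CELL = 6.6


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated quantitative-genotyping sample."""

    seed: int = 0
    df_true: float = 0.01
    tcf_ng_per_ml: float = 10.0
    plasma_ml: float = 4.0
    noise_cv: float = 0.10
    n_replicates: int = 2
    lysed_cells_per_ml: float = 0.0
    gdna_pg_per_cell: float = GDNA_PG_PER_CELL
    apoptotic_long_ratio: float = 0.3
    relatedness: float = 0.0
    crosstalk_median: float = 4e-4
    crosstalk_log_sd: float = 0.8
    run_effect_log_sd: float = 0.72
    minor_gain_log_sd: float = 0.06
    calibrator_pass_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.df_true <= 1.0:
            raise ValueError("df_true must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for name in ("tcf_ng_per_ml", "plasma_ml", "lysed_cells_per_ml",
                     "gdna_pg_per_cell", "crosstalk_median"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.relatedness <= 1.0:
            raise ValueError("relatedness must be in [0, 1]")
        if not 0.0 <= self.apoptotic_long_ratio <= 1.0:
            raise ValueError("apoptotic_long_ratio must be in [0, 1]")
        if self.minor_gain_log_sd < 0 or self.run_effect_log_sd < 0:
            raise ValueError("log-sd noise parameters must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth accompanying one simulated sample."""

    sample_id: str
    df_true: float
    tcf_true: float
    contamination_mass: float  # ng/mL
    recipient: list[GenotypeCall]
    donor: list[GenotypeCall]
    seed: int

    def __post_init__(self) -> None:
        if len(self.recipient) != len(self.donor):
            raise ValueError("recipient/donor genotype vectors differ in length")


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def contamination_mass(lysed_cells_per_ml: float,
                       gdna_pg_per_cell: float = GDNA_PG_PER_CELL) -> float:
    """Recipient gDNA mass (ng/mL plasma) released by lysed leukocytes."""
    return lysed_cells_per_ml * gdna_pg_per_cell / 1000.0


def simulate_genotype_pair(
    panel: SnpPanel,
    relatedness: float = 0.0,
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[list[GenotypeCall], list[GenotypeCall]]:
    """Draw a recipient/donor genotype pair over the panel's non-control targets.

    Recipient alleles are iid Bernoulli(maf); each donor allele is copied
    from a uniformly chosen recipient allele with probability
    ``relatedness``, else drawn from the population. ``relatedness = 0``
    reproduces unrelated Hardy-Weinberg pairs. The panel convention is that
    the ALT allele carries the folded minor-allele frequency.
    """
    if not 0.0 <= relatedness <= 1.0:
        raise ValueError("relatedness must be in [0, 1]")
    rng = _rng(seed)
    q = panel.mafs
    n = len(q)
    rec_alleles = rng.random((n, 2)) < q[:, None]  # True = ALT
    copy = rng.random((n, 2)) < relatedness
    which = rng.integers(0, 2, size=(n, 2))
    pop = rng.random((n, 2)) < q[:, None]
    don_alleles = np.where(copy, np.take_along_axis(rec_alleles, which, axis=1), pop)
    recipient = [GenotypeCall.from_alt_copies(int(c)) for c in rec_alleles.sum(axis=1)]
    donor = [GenotypeCall.from_alt_copies(int(c)) for c in don_alleles.sum(axis=1)]
    return recipient, donor


def simulate_fragmentation(
    apoptotic_mass: float, long_ratio: float, contamination_mass: float
) -> tuple[float, float]:
    """Alu amplicon concentrations implied by the fragment-length mix.

    The short amplicon responds to apoptotic and longer fragments alike
    (``alu115 = apoptotic + contamination``); the long amplicon only to
    fragments of >= 247 bp (``alu247 = long_ratio * apoptotic +
    contamination``). Units are the input mass-concentration units.
    """
    if apoptotic_mass < 0 or contamination_mass < 0:
        raise ValueError("masses must be non-negative")
    if not 0.0 <= long_ratio <= 1.0:
        raise ValueError("long_ratio must be in [0, 1]")
    alu115 = apoptotic_mass + contamination_mass
    alu247 = long_ratio * apoptotic_mass + contamination_mass
    return float(alu115), float(alu247)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_qgt_sample(
    cfg: SimConfig,
    panel: SnpPanel,
    recipient: Sequence[GenotypeCall],
    donor: Sequence[GenotypeCall],
    sample_id: str = "sim",
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> QgtSample:
    """Simulate one quantitative-genotyping run of a two-genome mixture.

    Contamination by lysed recipient leukocytes adds recipient-only mass
    ``C = lysed_cells_per_ml * gdna_pg_per_cell / 1000`` (ng/mL) to the true
    cfDNA mass ``T``, so the effective donor fraction of the measured pool
    is ``df_true * T / (T + C)``. Measured per-allele quantities are the
    true quantities after allele cross-talk, times lognormal noise,
    independently per replicate.
    """
    targets = panel.informative_targets
    if len(recipient) != len(targets) or len(donor) != len(targets):
        raise ValueError("genotype vectors must match the panel's non-control targets")
    rng = _rng(cfg.seed if seed is None else seed)

    rec_alt = np.array([g.alt_copies for g in recipient], dtype=float)
    don_alt = np.array([g.alt_copies for g in donor], dtype=float)
    if np.any(np.isnan(rec_alt)):
        raise ValueError("recipient NO_CALL genotypes not supported in simulation")
    if cfg.df_true > 0 and np.all(np.isnan(don_alt)):
        raise ValueError("df_true > 0 requires donor genotypes")

    T = cfg.tcf_ng_per_ml
    C = contamination_mass(cfg.lysed_cells_per_ml, cfg.gdna_pg_per_cell)
    if T + C <= 0:
        raise ValueError("total DNA mass is zero")
    df_eff = cfg.df_true * T / (T + C)

    n = len(targets)
    mass_per_target = (T + C) * cfg.plasma_ml / n  # ng per target
    alt_share = (1.0 - df_eff) * rec_alt / 2.0 + df_eff * np.nan_to_num(don_alt) / 2.0
    true_alt = mass_per_target * alt_share
    true_ref = mass_per_target - true_alt

    # Mass-conserving allele cross-talk: per-target leak fraction of each
    # allele's signal misassigned to the other allele.
    if cfg.crosstalk_median > 0:
        # run-level factor: background level varies coherently between runs
        # (reagent lot / instrument effects), on top of per-target variation
        run_factor = float(np.exp(cfg.run_effect_log_sd * rng.standard_normal()))
        leak = (cfg.crosstalk_median * run_factor
                * np.exp(cfg.crosstalk_log_sd * rng.standard_normal(n)))
        leak = np.clip(leak, 0.0, 0.05)
    else:
        leak = np.zeros(n)
    meas_alt = true_alt * (1 - leak) + true_ref * leak
    meas_ref = true_ref * (1 - leak) + true_alt * leak

    # Shared per-run quantification gain on the minor species: trace-level
    # allele quantification is biased coherently across targets within a run
    # (mastermix lot / instrument), which spreads DF between runs at every DF
    # level without blurring the per-target genotype separation within a run.
    # Like the lognormal noise, this is measurement bias, not mass, and is
    # disabled together with it at noise_cv = 0.
    if cfg.noise_cv > 0 and cfg.minor_gain_log_sd > 0:
        gain = float(np.exp(cfg.minor_gain_log_sd * rng.standard_normal()))
        minor_is_alt = meas_alt < meas_ref
        meas_alt = np.where(minor_is_alt, meas_alt * gain, meas_alt)
        meas_ref = np.where(minor_is_alt, meas_ref, meas_ref * gain)

    rows = []
    noise = _lognormal_factors(rng, cfg.noise_cv, (cfg.n_replicates, n, 2))
    cal_pass = (rng.random(n) < cfg.calibrator_pass_rate)
    for rep in range(cfg.n_replicates):
        rows.append(pd.DataFrame({
            "target_id": [t.target_id for t in targets],
            "replicate": rep + 1,
            "ref_quantity": meas_ref * noise[rep, :, 0],
            "alt_quantity": meas_alt * noise[rep, :, 1],
            "calibrator_pass": cal_pass,
        }))
    records = pd.concat(rows, ignore_index=True)

    alu115, alu247 = simulate_fragmentation(T, cfg.apoptotic_long_ratio, C)
    alu_noise = _lognormal_factors(rng, cfg.noise_cv / 3.0, 2)
    frag = flag_fragmentation(alu247 * alu_noise[1], alu115 * alu_noise[0])

    rnasep_log = 9.0 + 0.4 * np.log10((T + C) / 10.0)
    if cfg.noise_cv > 0:
        rnasep_log += 0.1 * rng.standard_normal()

    return QgtSample(sample_id=sample_id, records=records,
                     rnasep_log_value=float(rnasep_log), fragmentation=frag)


def simulate_cohort(
    n_samples: int,
    df_values: Union[Sequence[float], tuple[str, float, float]],
    cfg: SimConfig,
    panel: SnpPanel,
    seed: Union[int, np.random.Generator] = 0,
) -> tuple[list[QgtSample], list[TruthRecord]]:
    """Simulate a cohort with ground truth.

    ``df_values`` is either an explicit sequence of true DFs (length
    ``n_samples``) or ``("log_uniform", lo, hi)`` for DFs drawn log-uniformly
    in [lo, hi]. Each sample gets an independent genotype pair at the
    configured relatedness.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(seed)
    if isinstance(df_values, tuple) and df_values and df_values[0] == "log_uniform":
        _, lo, hi = df_values
        dfs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    else:
        dfs = np.asarray(list(df_values), dtype=float)
        if dfs.size != n_samples:
            raise ValueError("df_values length must equal n_samples")

    samples, truths = [], []
    for i, df in enumerate(dfs):
        sid = f"sim{i:04d}"
        sample_seed = int(rng.integers(0, 2**31 - 1))
        pair_rng = np.random.default_rng(sample_seed)
        rec, don = simulate_genotype_pair(panel, cfg.relatedness, pair_rng)
        scfg = replace(cfg, df_true=float(df))
        samples.append(simulate_qgt_sample(scfg, panel, rec, don,
                                           sample_id=sid, seed=pair_rng))
        truths.append(TruthRecord(
            sample_id=sid, df_true=float(df), tcf_true=cfg.tcf_ng_per_ml,
            contamination_mass=contamination_mass(cfg.lysed_cells_per_ml,
                                                  cfg.gdna_pg_per_cell),
            recipient=rec, donor=don, seed=sample_seed,
        ))
    return samples, truths


def odd_even_split(truths: Sequence[TruthRecord]) -> tuple[list[int], list[int]]:
    """Split indices into two subsets alternating by ascending true DF rank.

    Arranging samples linearly by ascending DF and alternating membership
    gives two subsets with matched DF distributions, as used to separate
    algorithm-tuning data from revalidation data.
    """
    order = np.argsort([t.df_true for t in truths], kind="stable")
    odd = [int(i) for i in order[0::2]]
    even = [int(i) for i in order[1::2]]
    return odd, even


def simulate_standard_curve(
    efficiency: float,
    intercept: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: Union[int, np.random.Generator] = 0,
) -> pd.DataFrame:
    """Simulate qPCR standard-curve points (conc, Cp).

    Cp = intercept + slope * log10(conc) with slope = -1/log10(1 +
    efficiency), plus Gaussian Cp noise of SD ``noise_sd``.
    """
    if not 0.0 < efficiency <= 1.5:
        raise ValueError("efficiency must be in (0, 1.5]")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = _rng(seed)
    slope = -1.0 / np.log10(1.0 + efficiency)
    cp = intercept + slope * np.log10(conc)
    if noise_sd > 0:
        cp = cp + rng.normal(0.0, noise_sd, size=conc.size)
    return pd.DataFrame({"conc": conc, "cp": cp})
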