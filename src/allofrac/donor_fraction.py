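"""Donor-fraction estimation from allele-specific quantifications.

The donor fraction (DF) is the proportion of plasma cell-free DNA that
originates from the transplanted organ. At every panel SNP where the
recipient is homozygous, any signal on the allele the recipient lacks must
come from the donor (or from assay background). The per-target DF estimate
is ``multiplier x minor-allele fraction`` — multiplier 2 when the donor is
heterozygous (only half its genome carries the minor allele), 1 when the
donor is homozygous for it — and the reported DF is the median of those
estimates across informative targets.

Two estimators are provided:

* **Method 1** (donor genotype known): informative targets and multipliers
  are fixed by the two genotype vectors; DF is the median of the per-target
  estimates over calibrator-passed targets.
* **Method 2** (donor genotype unknown): donor genotypes are inferred by a
  staged Monte Carlo. Stage 1 draws candidate donor genotype vectors from
  Hardy-Weinberg priors at the panel allele frequencies, scores each against
  the observed minor fractions, and converts the scored candidates into
  per-target donor-genotype posteriors. Stage 2 draws donor vectors from
  those posteriors; each draw yields a candidate DF (median of its
  per-target estimates) and the final call is a linear calibration applied
  to the median of the candidate-DF distribution.

Both estimators carry the run QC gates (informative-target count, robust
CV, skew, RNase P window, calibrator and quantifiable counts) and the risk
classification at the clinical cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .panel import GenotypeCall, SnpPanel, is_informative
from .quantify import FragmentationResult

__all__ = [
    "QgtSample",
    "DfResult",
    "McConfig",
    "QcThresholds",
    "RiskCall",
    "per_target_minor_fraction",
    "estimate_df_method1",
    "estimate_df_method2",
    "compute_rcv",
    "compute_skew",
    "apply_qc",
    "classify_risk",
    "read_genotypes_csv",
    "read_genotypes_vcf",
    "read_sample_csv",
]

GenotypeVector = Mapping[str, GenotypeCall]

#: Per-target DF estimates above this ceiling are excluded as genotyping
#: inconsistencies: a correctly assigned biallelic minor species cannot
#: exceed half the molecule population.
ESTIMATE_CEILING = 0.5


@dataclass
class QgtSample:
    """One quantitative-genotyping run of a plasma sample.

    ``records`` has one row per target x replicate with columns
    ``target_id, replicate, ref_quantity, alt_quantity, calibrator_pass``.
    """

    sample_id: str
    records: pd.DataFrame
    rnasep_log_value: Optional[float] = None
    fragmentation: Optional[FragmentationResult] = None

    REQUIRED_COLUMNS = ("target_id", "replicate", "ref_quantity", "alt_quantity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"sample {self.sample_id}: records missing columns {missing}")
        if "calibrator_pass" not in self.records.columns:
            self.records = self.records.assign(calibrator_pass=True)
        q = self.records[["ref_quantity", "alt_quantity"]].to_numpy(dtype=float)
        if np.any(q < 0):
            raise ValueError(f"sample {self.sample_id}: negative allele quantities")

    def averaged(self) -> pd.DataFrame:
        """Replicate-averaged quantities per target (arithmetic mean).

        A target's calibrator passes only if it passed in every replicate.
        """
        return (
            self.records.groupby("target_id", sort=False)
            .agg(
                ref_quantity=("ref_quantity", "mean"),
                alt_quantity=("alt_quantity", "mean"),
                calibrator_pass=("calibrator_pass", "all"),
                n_replicates=("replicate", "size"),
            )
        )


@dataclass(frozen=True)
class QcThresholds:
    """Run-validity gates applied to every DF result."""

    informative_min: int = 27
    quantifiable_min: int = 70
    calibrator_min: int = 75
    rcv_max: float = 100.0  # percent
    skew_max: float = 1.01
    rnasep_log_min: float = 8.0
    rnasep_log_max: float = 10.0
    frag_ratio_max: float = 0.45


@dataclass(frozen=True)
class McConfig:
    """Staged Monte Carlo settings for the no-donor-genotype estimator."""

    n_stage1: int = 10_000
    n_stage2: int = 25_000
    seed: int = 0
    # (slope, intercept) of the final linear adjustment, fitted against the
    # known-donor-genotype computation on synthetic cohorts spanning the
    # linear range (see scripts/calibrate_method2.py)
    calibration: tuple[float, float] = (0.998604266989226, 0.00012265788220196315)
    sigma_floor: float = 0.05  # floor on the pooled log-scale scatter
    # assay minor-allele background characterisation (from blank studies:
    # per-target background fraction ~ half the DF limit of blank, with a
    # wide lognormal spread between targets and runs)
    background_floor: float = 5e-4
    background_log_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n_stage1 < 1 or self.n_stage2 < 1:
            raise ValueError("Monte Carlo stage sizes must be positive")


@dataclass(frozen=True)
class RiskCall:
    classification: str  # "low_probability" | "increased_probability"
    below_loq: bool


@dataclass
class DfResult:
    """Estimated donor fraction with QC metrics and classification."""

    sample_id: str
    method: str  # "with_donor" | "no_donor"
    df: Optional[float]  # fraction; None when no estimate possible
    n_informative: int = 0
    n_quantifiable: int = 0
    n_calibrator_pass: int = 0
    rcv: Optional[float] = None  # percent
    skew: Optional[float] = None
    qc_pass: bool = False
    qc_reasons: list[str] = field(default_factory=list)
    qc_details: dict[str, dict] = field(default_factory=dict)
    per_target_estimates: Optional[np.ndarray] = None
    candidate_percentiles: Optional[dict[str, float]] = None
    classification: Optional[str] = None
    below_loq: Optional[bool] = None
    below_lob: bool = False

    @property
    def df_percent(self) -> Optional[float]:
        return None if self.df is None else 100.0 * self.df


def per_target_minor_fraction(
    ref_quantity: float, alt_quantity: float, recipient: GenotypeCall
) -> Optional[float]:
    """Minor-species proportion at one target, replicate-averaged.

    The minor allele is the one the recipient lacks; a heterozygous
    recipient masks any donor signal (returns None), as does a zero total
    quantity.
    """
    total = ref_quantity + alt_quantity
    if total <= 0:
        return None
    if recipient is GenotypeCall.HOM_REF:
        return float(alt_quantity / total)
    if recipient is GenotypeCall.HOM_VAR:
        return float(ref_quantity / total)
    return None  # HET or NO_CALL recipient: uninformative


def compute_rcv(per_target_estimates: Sequence[float]) -> float:
    """Robust coefficient of variation, percent: 100 * 1.4826 * MAD / median."""
    est = np.asarray(per_target_estimates, dtype=float)
    if est.size < 2:
        raise ValueError("rCV requires >= 2 per-target estimates")
    med = float(np.median(est))
    if med <= 0:
        raise ValueError("rCV undefined: median of estimates is not positive")
    mad = float(np.median(np.abs(est - med)))
    return 100.0 * 1.4826 * mad / med


def compute_skew(per_target_estimates: Sequence[float]) -> float:
    """Relatedness-sensitive asymmetry of the per-target estimates.

    A related donor violates the Hardy-Weinberg genotype assumptions the
    assay relies on, which distorts one tail of the apparent per-target DF
    estimates and pulls the mean away from the median. The metric is the
    symmetric mean/median ratio ``max(mean/median, median/mean)`` over
    nonzero estimates, so distortion in either direction raises it above
    its symmetric-distribution value of 1.
    """
    est = np.asarray(per_target_estimates, dtype=float)
    est = est[est > 0]
    if est.size < 2:
        raise ValueError("skew requires >= 2 nonzero per-target estimates")
    med = float(np.median(est))
    mean = float(np.mean(est))
    if med <= 0:
        raise ValueError("skew undefined: median of estimates is not positive")
    ratio = mean / med
    return max(ratio, 1.0 / ratio)


def classify_risk(
    df: float, cutoff: float = 0.0032, loq: float = 0.00125
) -> RiskCall:
    """Classify rejection probability at the clinical DF cutoff.

    Negativity is defined strictly below the cutoff (default 0.32%), so a
    DF exactly at the cutoff classifies as increased probability. Estimates
    below the limit of quantitation carry a ``below_loq`` annotation.
    """
    if df < 0:
        raise ValueError("df must be non-negative")
    classification = "increased_probability" if df >= cutoff else "low_probability"
    return RiskCall(classification=classification, below_loq=df < loq)


def _as_genotype_map(
    genotypes: Union[GenotypeVector, Sequence[GenotypeCall], np.ndarray],
    panel: SnpPanel,
) -> dict[str, GenotypeCall]:
    """Accept a target_id->call mapping or a vector aligned to the panel."""
    if isinstance(genotypes, Mapping):
        return dict(genotypes)
    targets = panel.informative_targets
    if len(genotypes) != len(targets):
        raise ValueError(
            f"genotype vector length {len(genotypes)} != panel size {len(targets)}"
        )
    return {t.target_id: g for t, g in zip(targets, genotypes)}


def apply_qc(
    sample: QgtSample, result: DfResult, qc: QcThresholds = QcThresholds()
) -> DfResult:
    """Evaluate every run-validity gate independently and annotate the result.

    Each gate records its observed value and threshold; ``qc_pass`` is the
    conjunction and ``qc_reasons`` lists every failed gate, so no failure is
    silently dropped.
    """
    gates: dict[str, dict] = {}

    def gate(name: str, observed, ok: bool, threshold) -> None:
        gates[name] = {"observed": observed, "threshold": threshold, "pass": bool(ok)}

    gate("calibrators", result.n_calibrator_pass,
         result.n_calibrator_pass >= qc.calibrator_min, f">= {qc.calibrator_min}")
    rp = sample.rnasep_log_value
    gate("rnasep_range", rp,
         rp is not None and qc.rnasep_log_min <= rp <= qc.rnasep_log_max,
         f"[{qc.rnasep_log_min}, {qc.rnasep_log_max}]")
    gate("quantifiable_targets", result.n_quantifiable,
         result.n_quantifiable >= qc.quantifiable_min, f">= {qc.quantifiable_min}")
    gate("informative_targets", result.n_informative,
         result.n_informative >= qc.informative_min, f">= {qc.informative_min}")
    gate("rcv", result.rcv,
         result.rcv is not None and result.rcv <= qc.rcv_max, f"<= {qc.rcv_max}%")
    gate("skew", result.skew,
         result.skew is not None and result.skew <= qc.skew_max, f"<= {qc.skew_max}")
    if sample.fragmentation is not None:
        gate("fragmentation", sample.fragmentation.alu_ratio,
             sample.fragmentation.flag == "pass", f"ratio <= {qc.frag_ratio_max}")

    result.qc_details = gates
    result.qc_reasons = [name for name, g in gates.items() if not g["pass"]]
    result.qc_pass = not result.qc_reasons
    return result


def _counts(avg: pd.DataFrame) -> tuple[int, int]:
    """(calibrator-passed, calibrator-passed with nonzero total) target counts."""
    n_cal = int(avg["calibrator_pass"].sum())
    total = avg["ref_quantity"] + avg["alt_quantity"]
    n_quant = int((avg["calibrator_pass"] & (total > 0)).sum())
    return n_cal, n_quant


def _finalize(
    sample: QgtSample,
    result: DfResult,
    qc: QcThresholds,
    cutoff: float,
    loq: float,
) -> DfResult:
    result = apply_qc(sample, result, qc)
    if result.df is not None:
        risk = classify_risk(result.df, cutoff=cutoff, loq=loq)
        result.classification = risk.classification
        result.below_loq = risk.below_loq
    return result


def estimate_df_method1(
    sample: QgtSample,
    recipient: Union[GenotypeVector, Sequence[GenotypeCall]],
    donor: Union[GenotypeVector, Sequence[GenotypeCall]],
    panel: SnpPanel,
    qc: QcThresholds = QcThresholds(),
    cutoff: float = 0.0032,
    loq: float = 0.00125,
) -> DfResult:
    """DF with donor genotype known: median of per-target estimates.

    Per informative target (recipient homozygous, donor carrying the
    opposite allele), estimate = multiplier x minor fraction; the DF is the
    median over calibrator-passed targets, with estimates above
    ``ESTIMATE_CEILING`` excluded as genotype inconsistencies.
    """
    rec = _as_genotype_map(recipient, panel)
    don = _as_genotype_map(donor, panel)
    avg = sample.averaged()
    n_cal, n_quant = _counts(avg)

    estimates = []
    for t in panel.informative_targets:
        if t.target_id not in avg.index:
            continue
        row = avg.loc[t.target_id]
        if not row["calibrator_pass"]:
            continue
        info = is_informative(rec.get(t.target_id, GenotypeCall.NO_CALL),
                              don.get(t.target_id, GenotypeCall.NO_CALL))
        if not info.informative:
            continue
        f = per_target_minor_fraction(row["ref_quantity"], row["alt_quantity"],
                                      rec[t.target_id])
        if f is None:
            continue
        est = info.multiplier * f
        if est <= ESTIMATE_CEILING:
            estimates.append(est)

    est = np.asarray(estimates, dtype=float)
    result = DfResult(
        sample_id=sample.sample_id, method="with_donor",
        df=float(np.median(est)) if est.size else None,
        n_informative=int(est.size), n_quantifiable=n_quant,
        n_calibrator_pass=n_cal, per_target_estimates=est,
    )
    if est.size >= 2 and np.median(est) > 0:
        result.rcv = compute_rcv(est)
        if np.count_nonzero(est) >= 2:
            result.skew = compute_skew(est)
    return _finalize(sample, result, qc, cutoff, loq)


def estimate_df_method2(
    sample: QgtSample,
    recipient: Union[GenotypeVector, Sequence[GenotypeCall]],
    panel: SnpPanel,
    mc: McConfig = McConfig(),
    qc: QcThresholds = QcThresholds(),
    cutoff: float = 0.0032,
    loq: float = 0.00125,
) -> DfResult:
    """DF without donor genotype, by staged Monte Carlo genotype inference.

    Stage 1 draws ``n_stage1`` candidate donor genotype vectors from
    Hardy-Weinberg priors restricted to recipient-homozygous targets and
    scores each by a Gaussian likelihood of the observed log minor fractions
    given the candidate's implied DF (median of its per-target estimates).
    The scored candidates yield a likelihood-weighted working DF, from which
    per-target donor-genotype posteriors are formed (Rao-Blackwellised:
    prior x per-target likelihood at the working DF). Stage 2 draws
    ``n_stage2`` donor vectors from those posteriors; each draw's candidate
    DF is the median of its per-target estimates, and the final call applies
    the linear calibration to the median of the candidate-DF distribution.
    Deterministic for a fixed ``mc.seed``.
    """
    rec = _as_genotype_map(recipient, panel)
    avg = sample.averaged()
    n_cal, n_quant = _counts(avg)
    rng = np.random.default_rng(mc.seed)

    # Recipient-homozygous, calibrator-passed, quantifiable targets.
    tids, fracs, sigmas, q_minor = [], [], [], []
    rep_frac = _replicate_fractions(sample, rec)
    for t in panel.informative_targets:
        call = rec.get(t.target_id, GenotypeCall.NO_CALL)
        if call not in (GenotypeCall.HOM_REF, GenotypeCall.HOM_VAR):
            continue
        if t.target_id not in avg.index:
            continue
        row = avg.loc[t.target_id]
        if not row["calibrator_pass"]:
            continue
        f = per_target_minor_fraction(row["ref_quantity"], row["alt_quantity"], call)
        if f is None:
            continue
        tids.append(t.target_id)
        fracs.append(f)
        # population frequency of the allele the recipient lacks (ALT carries
        # the panel's folded MAF by convention)
        q_minor.append(t.maf if call is GenotypeCall.HOM_REF else 1.0 - t.maf)

    if len(tids) < 2:
        raise ValueError(
            f"sample {sample.sample_id}: only {len(tids)} recipient-homozygous "
            "quantifiable targets; donor-genotype inference impossible"
        )

    f = np.asarray(fracs)
    sig = np.full(len(tids), _pooled_log_scatter(rep_frac, tids, mc))
    qv = np.asarray(q_minor)
    eps = mc.background_floor

    base = DfResult(sample_id=sample.sample_id, method="no_donor", df=None,
                    n_quantifiable=n_quant, n_calibrator_pass=n_cal)
    if np.all(f == 0):
        # single-genome sample with no background signal at all
        base.df = 0.0
        base.below_lob = True
        base.n_informative = 0
        base.per_target_estimates = np.array([])
        return _finalize(sample, base, qc, cutoff, loq)

    z = np.log(f + eps)
    # the no-donor-signal component is much more dispersed than replicate
    # scatter because the background level itself varies between targets/runs
    sig0 = np.sqrt(sig**2 + mc.background_log_sd**2)
    prior = np.stack([(1 - qv) ** 2, 2 * qv * (1 - qv), qv**2], axis=1)  # (T, 3)

    # --- Stage 1: score prior-drawn candidate donor vectors -----------------
    G1 = rng.binomial(2, qv, size=(mc.n_stage1, len(tids)))
    df_cand1, ll1 = _score_candidates(G1, f, z, sig, sig0, eps)
    ok = np.isfinite(ll1)
    if not np.any(ok):
        raise ValueError(f"sample {sample.sample_id}: no scorable stage-1 candidates")
    w = _softmax(ll1[ok])
    df_work = _weighted_median(df_cand1[ok], w)

    # Per-target posterior over donor minor-allele copies at the working DF.
    mu_g = np.log(np.outer(np.array([0.0, 0.5, 1.0]), np.full(len(tids), df_work)) + eps)  # (3, T)
    sig_g = np.stack([sig0, sig, sig])  # (3, T)
    loglik_tg = -((z[None, :] - mu_g) ** 2) / (2 * sig_g**2) - np.log(sig_g)
    post = prior.T * np.exp(loglik_tg - loglik_tg.max(axis=0, keepdims=True))
    post = (post / post.sum(axis=0, keepdims=True)).T  # (T, 3)

    # --- Stage 2: explore the posterior ------------------------------------
    cum = np.cumsum(post, axis=1)
    u = rng.random(size=(mc.n_stage2, len(tids)))
    G2 = (u[..., None] > cum[None, :, :]).sum(axis=2)
    df_cand2, _ = _score_candidates(G2, f, z, sig, sig0, eps, score=False)
    df_cand2 = df_cand2[np.isfinite(df_cand2)]
    if df_cand2.size == 0:
        base.df = 0.0
        base.below_lob = True
        base.per_target_estimates = np.array([])
        return _finalize(sample, base, qc, cutoff, loq)

    slope_c, intercept_c = mc.calibration
    df_final = slope_c * float(np.median(df_cand2)) + intercept_c
    pct = {f"p{p}": float(np.percentile(df_cand2, p)) for p in (5, 25, 50, 75, 95)}

    # Per-target estimates under the maximum-posterior donor genotypes,
    # for the rCV/skew QC metrics.
    g_map = np.argmax(post, axis=1)
    mult = np.where(g_map == 1, 2.0, np.where(g_map == 2, 1.0, np.nan))
    est = mult * f
    est = est[np.isfinite(est) & (est <= ESTIMATE_CEILING)]

    base.df = max(df_final, 0.0)
    base.n_informative = int(est.size)
    base.per_target_estimates = est
    base.candidate_percentiles = pct
    if est.size >= 2 and np.median(est) > 0:
        base.rcv = compute_rcv(est)
        if np.count_nonzero(est) >= 2:
            base.skew = compute_skew(est)
    return _finalize(sample, base, qc, cutoff, loq)


def _replicate_fractions(
    sample: QgtSample, rec: Mapping[str, GenotypeCall]
) -> dict[str, np.ndarray]:
    """Per-replicate minor fractions per target, for scatter estimation."""
    out: dict[str, list[float]] = {}
    for row in sample.records.itertuples(index=False):
        call = rec.get(row.target_id)
        if call not in (GenotypeCall.HOM_REF, GenotypeCall.HOM_VAR):
            continue
        fr = per_target_minor_fraction(row.ref_quantity, row.alt_quantity, call)
        if fr is not None:
            out.setdefault(row.target_id, []).append(fr)
    return {k: np.asarray(v) for k, v in out.items()}


def _pooled_log_scatter(
    rep_frac: Mapping[str, np.ndarray], tids: Sequence[str], mc: McConfig
) -> float:
    """Pooled log-scale scatter of the replicate-averaged minor fractions.

    Per-target scatter estimates from duplicate wells are far too noisy to
    use individually, so the likelihood uses one pooled scale: the median
    across targets of the per-target replicate SD of log minor fractions,
    scaled to the standard error of the replicate mean, floored at
    ``sigma_floor``.
    """
    sems = []
    for tid in tids:
        reps = rep_frac.get(tid)
        if reps is None or reps.size < 2:
            continue
        s = float(np.std(np.log(reps + mc.background_floor), ddof=1))
        sems.append(s / math.sqrt(reps.size))
    pooled = float(np.median(sems)) if sems else 0.0
    return max(pooled, mc.sigma_floor)


def _score_candidates(
    G: np.ndarray,
    f: np.ndarray,
    z: np.ndarray,
    sig: np.ndarray,
    sig0: np.ndarray,
    eps: float,
    score: bool = True,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Candidate DFs (median of per-target estimates) and log-likelihoods.

    ``G`` holds donor minor-allele copy counts, one row per candidate
    vector. Rows without any informative target get DF = nan. ``sig0`` is
    the (wider) scatter of the no-donor-signal component.
    """
    mult = np.where(G == 1, 2.0, np.where(G == 2, 1.0, np.nan))
    est = mult * f[None, :]
    with np.errstate(all="ignore"):
        df_cand = np.nanmedian(np.where(est <= ESTIMATE_CEILING, est, np.nan), axis=1)
    if not score:
        return df_cand, None
    mu = np.log(G * np.where(np.isfinite(df_cand), df_cand, 0.0)[:, None] / 2.0 + eps)
    sg = np.where(G == 0, sig0[None, :], sig[None, :])
    ll = -np.sum((z[None, :] - mu) ** 2 / (2 * sg**2) + np.log(sg), axis=1)
    ll = np.where(np.isfinite(df_cand), ll, -np.inf)
    return df_cand, ll


def _softmax(ll: np.ndarray) -> np.ndarray:
    w = np.exp(ll - ll.max())
    return w / w.sum()


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


# --------------------------------------------------------------------------
# File readers (external interfaces)
# --------------------------------------------------------------------------

def read_genotypes_csv(path: str | Path, sample_id: Optional[str] = None) -> dict[str, GenotypeCall]:
    """Read genotype calls from `sample_id, target_id, genotype` CSV."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "target_id", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if sample_id is not None:
        df = df[df["sample_id"] == sample_id]
        if df.empty:
            raise ValueError(f"{path}: no rows for sample {sample_id!r}")
    elif df["sample_id"].nunique() > 1:
        raise ValueError(f"{path}: multiple samples present; pass sample_id")
    out = {}
    for row in df.itertuples(index=False):
        try:
            out[row.target_id] = GenotypeCall[row.genotype]
        except KeyError as exc:
            raise ValueError(f"{path}: invalid genotype {row.genotype!r} "
                             f"for target {row.target_id}") from exc
    return out


def read_genotypes_vcf(path: str | Path, panel: SnpPanel) -> dict[str, GenotypeCall]:
    """Read GT calls from a single-sample VCF, matching panel targets by ID.

    Only biallelic records whose ID matches a panel target are used; GT is
    the only field consulted.
    """
    from cyvcf2 import VCF

    by_id = {t.target_id: t for t in panel.targets}
    out: dict[str, GenotypeCall] = {}
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected a single-sample VCF, got {len(vcf.samples)}")
    for rec in vcf:
        if rec.ID not in by_id or len(rec.ALT) != 1:
            continue
        gt = rec.genotypes[0][:2]
        if -1 in gt:
            out[rec.ID] = GenotypeCall.NO_CALL
        else:
            out[rec.ID] = GenotypeCall.from_alt_copies(int(gt[0]) + int(gt[1]))
    return out


def read_sample_csv(
    path: str | Path,
    sample_id: Optional[str] = None,
    rnasep_log_value: Optional[float] = None,
    fragmentation: Optional[FragmentationResult] = None,
) -> QgtSample:
    """Read per-target allele quantifications from long-format CSV.

    Expected columns: ``sample_id, target_id, allele, replicate, quantity``
    (allele in {ref, alt}) or the wide form with ``ref_quantity`` /
    ``alt_quantity`` columns.
    """
    df = pd.read_csv(path)
    if "allele" in df.columns:  # long form
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        elif df["sample_id"].nunique() > 1:
            raise ValueError(f"{path}: multiple samples present; pass sample_id")
        if df.empty:
            raise ValueError(f"{path}: no measurement rows")
        sid = str(df["sample_id"].iloc[0])
        wide = df.pivot_table(index=["target_id", "replicate"], columns="allele",
                              values="quantity", aggfunc="sum").reset_index()
        wide = wide.rename(columns={"ref": "ref_quantity", "alt": "alt_quantity"})
        if "calibrator_pass" in df.columns:
            cp = df.groupby(["target_id", "replicate"])["calibrator_pass"].all().reset_index()
            wide = wide.merge(cp, on=["target_id", "replicate"])
        records = wide
    else:
        if sample_id is not None and "sample_id" in df.columns:
            df = df[df["sample_id"] == sample_id]
        sid = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else (sample_id or "sample")
        records = df
    return QgtSample(sample_id=sid, records=records,
                     rnasep_log_value=rnasep_log_value, fragmentation=fragmentation)
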