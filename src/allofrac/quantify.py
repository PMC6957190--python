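"""qPCR quantification and DNA-fragmentation quality control.

Covers three supporting measurements of the donor-fraction workflow:

* standard-curve fitting of crossing point (Cp) against log10 concentration,
  with amplification efficiency derived from the slope;
* total cell-free DNA (TCF) concentration summaries from replicate
  quantifications;
* the Alu-repeat fragmentation ratio. Short-amplicon (ALU115) qPCR amplifies
  essentially all cfDNA fragments; the long amplicon (ALU247) only fragments
  of at least 247 bp, i.e. DNA that did not arise from apoptosis. Their
  ratio rises when leukocytes lyse after blood draw and spill long genomic
  DNA into the plasma, which simultaneously dilutes the donor fraction —
  the ``df_dilution`` mass-balance model quantifies that dilution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StandardCurve",
    "FragmentationResult",
    "TcfMeasurement",
    "fit_standard_curve",
    "quantify_from_curve",
    "alu_ratio",
    "flag_fragmentation",
    "df_dilution",
    "summarize_tcf",
    "DEFAULT_FRAG_RATIO_MAX",
]

#: Default fragmentation rejection threshold: just above the 0.2-0.4 band
#: observed for properly handled plasma. No consensus clinical cutoff exists,
#: so this is configurable everywhere it is used.
DEFAULT_FRAG_RATIO_MAX = 0.45


@dataclass(frozen=True)
class StandardCurve:
    """Fitted qPCR standard curve: Cp = intercept + slope * log10(conc)."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")


@dataclass(frozen=True)
class FragmentationResult:
    """Alu-ratio fragmentation QC outcome."""

    alu115_conc: float
    alu247_conc: float
    alu_ratio: float
    flag: str  # "pass" | "fail"
    reason: str = ""


@dataclass(frozen=True)
class TcfMeasurement:
    """Replicate-summarised total cfDNA concentration (ng per mL plasma)."""

    concentration: float
    method: str = "rnasep"
    n: int = 0
    sd: Optional[float] = None
    cv_percent: Optional[float] = None


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of mean Cp on log10(concentration).

    Amplification efficiency follows from the slope as
    ``10**(-1/slope) - 1`` (1.0 = perfect doubling each cycle, slope
    -3.32193).
    """
    conc = np.array([p[0] for p in points], dtype=float)
    cp = np.array([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("standard-curve concentrations must be positive")
    if len(np.unique(conc)) < 3:
        raise ValueError("standard curve requires >= 3 distinct concentrations")
    x = np.log10(conc)
    slope, intercept = np.polyfit(x, cp, 1)
    if slope >= 0:
        raise ValueError(f"fitted slope {slope:.4f} is non-negative; check input orientation")
    resid = cp - (intercept + slope * x)
    ss_tot = float(np.sum((cp - cp.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept),
                         efficiency=float(efficiency), r_squared=r2)


def quantify_from_curve(cp: float, curve: StandardCurve) -> float:
    """Invert the standard curve: concentration = 10**((cp - intercept)/slope)."""
    return float(10.0 ** ((cp - curve.intercept) / curve.slope))


def alu_ratio(alu247: float, alu115: float) -> float:
    """Long/short Alu amplicon concentration ratio, clipped to [0, 1].

    Theoretical bounds: 0 when all template is shorter than 247 bp (fully
    apoptotic), 1 when template DNA is not fragmented at all. Tiny numerical
    excess above 1 is clipped; a genuinely larger excess is an input error.
    """
    if alu115 < 0 or alu247 < 0:
        raise ValueError("Alu concentrations must be non-negative")
    if alu115 == 0:
        raise ValueError("ALU115 concentration is zero; ratio undefined")
    ratio = alu247 / alu115
    if ratio > 1.0 + 1e-9:
        raise ValueError(f"Alu ratio {ratio:.4f} exceeds 1; inconsistent quantifications")
    return float(min(max(ratio, 0.0), 1.0))


def flag_fragmentation(
    alu247: float, alu115: float, threshold: float = DEFAULT_FRAG_RATIO_MAX
) -> FragmentationResult:
    """Evaluate fragmentation QC: fail when the Alu ratio exceeds ``threshold``.

    A failing ratio signals leukocyte lysis / genomic-DNA contamination that
    dilutes the donor fraction and risks a false-negative rejection call.
    The comparison is strict (ratio exactly at threshold passes).
    """
    ratio = alu_ratio(alu247, alu115)
    if ratio > threshold:
        return FragmentationResult(
            alu115_conc=alu115, alu247_conc=alu247, alu_ratio=ratio, flag="fail",
            reason=f"alu_ratio {ratio:.3f} > {threshold:.3f}: possible leukocyte lysis/contamination",
        )
    return FragmentationResult(alu115_conc=alu115, alu247_conc=alu247,
                               alu_ratio=ratio, flag="pass")


def df_dilution(df_true: float, tcf_mass: float, contamination_mass: float) -> float:
    """Observed donor fraction after recipient-only gDNA contamination.

    Donor mass is conserved while recipient mass grows, so
    ``df_obs = df_true * T / (T + C)`` for true cfDNA mass ``T`` and
    contaminating recipient genomic DNA mass ``C`` (same units).
    """
    if tcf_mass < 0 or contamination_mass < 0:
        raise ValueError("masses must be non-negative")
    total = tcf_mass + contamination_mass
    if total == 0:
        raise ValueError("tcf_mass + contamination_mass is zero")
    return float(df_true * tcf_mass / total)


def summarize_tcf(
    replicate_concentrations: Sequence[float],
    plasma_ml: float = 1.0,
    elution_factor: float = 1.0,
    method: str = "rnasep",
) -> TcfMeasurement:
    """Summarise replicate TCF quantifications to ng per mL plasma.

    Inputs are taken to be per-mL-plasma already unless conversion factors
    are supplied: ``elution_factor`` converts extract concentration to total
    extract mass per sample and the result is normalised by the plasma input
    volume (clinically 4 mL). A single replicate yields no SD/CV.
    """
    reps = np.asarray(replicate_concentrations, dtype=float)
    if reps.size < 1:
        raise ValueError("at least one replicate required")
    if np.any(reps < 0):
        raise ValueError("negative concentration in replicates")
    if plasma_ml <= 0:
        raise ValueError("plasma volume must be positive")
    scale = elution_factor / plasma_ml
    mean = float(reps.mean()) * scale
    if reps.size == 1:
        return TcfMeasurement(concentration=mean, method=method, n=1)
    sd = float(reps.std(ddof=1)) * scale
    cv = 100.0 * sd / mean if mean > 0 else math.inf
    return TcfMeasurement(concentration=mean, method=method, n=int(reps.size),
                          sd=sd, cv_percent=float(cv))
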