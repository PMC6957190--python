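"""Biallelic SNP panel model and target informativity.

A donor-fraction assay genotypes a fixed panel of biallelic SNPs in the
recipient's plasma cell-free DNA. A target is *informative* for a given
recipient-donor pair when the recipient is homozygous and the donor carries
at least one copy of the allele the recipient lacks: only then does donor
cfDNA produce a minor-allele signal that can be quantified. Under
Hardy-Weinberg equilibrium the probability of that configuration for an
unrelated pair is ``p^2 (1 - p^2) + q^2 (1 - q^2)`` with allele frequencies
``p = 1 - maf`` and ``q = maf``, which peaks at 0.375 for maf = 0.5.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCall",
    "SnpTarget",
    "SnpPanel",
    "InformativityCall",
    "informativity_probability",
    "is_informative",
    "expected_panel_informativity",
    "load_panel",
    "default_panel",
]

_NUCLEOTIDES = frozenset("ACGT")


class GenotypeCall(enum.Enum):
    """Diploid genotype call at a biallelic site."""

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_VAR = "HOM_VAR"
    NO_CALL = "NO_CALL"

    @property
    def alt_copies(self) -> Optional[int]:
        """Number of ALT alleles carried, or None for NO_CALL."""
        return {"HOM_REF": 0, "HET": 1, "HOM_VAR": 2, "NO_CALL": None}[self.value]

    @classmethod
    def from_alt_copies(cls, n: int) -> "GenotypeCall":
        return (cls.HOM_REF, cls.HET, cls.HOM_VAR)[n]


@dataclass(frozen=True)
class SnpTarget:
    """One biallelic SNP of the panel.

    ``maf`` is the panel-level minor-allele frequency folded to [0, 0.5];
    ref/alt orientation is carried separately so the minor allele may be
    either. ``population_mafs`` optionally stores per-population MAFs for
    reporting.
    """

    target_id: str
    ref_allele: str
    alt_allele: str
    maf: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    is_control: bool = False
    population_mafs: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in _NUCLEOTIDES or self.alt_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"{self.target_id}: alleles must be single nucleotides, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.target_id}: ref and alt alleles are identical")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.target_id}: maf {self.maf} outside [0, 0.5]")
        if self.population_mafs is not None:
            for pop, m in self.population_mafs.items():
                if not 0.0 <= m <= 0.5:
                    raise ValueError(
                        f"{self.target_id}: population {pop} MAF {m} outside [0, 0.5]"
                    )


@dataclass
class SnpPanel:
    """Ordered SNP marker set; controls are excluded from DF estimation."""

    targets: list[SnpTarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.target_id for t in self.targets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate target ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.targets)

    def __iter__(self):
        return iter(self.targets)

    @property
    def control_ids(self) -> list[str]:
        return [t.target_id for t in self.targets if t.is_control]

    @property
    def informative_targets(self) -> list[SnpTarget]:
        """Non-control targets usable for donor-fraction estimation."""
        return [t for t in self.targets if not t.is_control]

    @property
    def mafs(self) -> np.ndarray:
        """MAF vector over non-control targets, in panel order."""
        return np.array([t.maf for t in self.informative_targets], dtype=float)


@dataclass(frozen=True)
class InformativityCall:
    """Outcome of classifying one recipient/donor genotype pair."""

    informative: bool
    minor_allele: Optional[str] = None  # "REF" or "ALT"
    multiplier: Optional[int] = None  # 2 if donor HET, 1 if donor hom-minor
    reason: Optional[str] = None


def informativity_probability(maf: float) -> float:
    """P(target informative) for an unrelated pair under Hardy-Weinberg.

    Sums the genotype-pair configurations in which the recipient is
    homozygous and the donor carries >= 1 copy of the opposite allele:
    ``p^2 (1 - p^2) + q^2 (1 - q^2)``. Frequencies in (0.5, 1] are folded
    to ``1 - maf`` with a warning.
    """
    if not 0.0 <= maf <= 1.0:
        raise ValueError(f"maf {maf} outside [0, 1]")
    if maf > 0.5:
        warnings.warn(
            f"maf {maf} > 0.5; folding to minor-allele frequency {1 - maf}",
            stacklevel=2,
        )
        maf = 1.0 - maf
    p = 1.0 - maf
    q = maf
    return p * p * (1.0 - p * p) + q * q * (1.0 - q * q)


def is_informative(recipient: GenotypeCall, donor: GenotypeCall) -> InformativityCall:
    """Classify a recipient/donor genotype pair at one target.

    Informative iff the recipient is homozygous and the donor carries at
    least one copy of the allele the recipient lacks. The multiplier converts
    the observed minor-allele fraction into a per-target donor-fraction
    estimate: a heterozygous donor contributes the minor allele with only
    half its genome share (multiplier 2); a donor homozygous for the minor
    allele contributes it fully (multiplier 1).
    """
    if recipient is GenotypeCall.NO_CALL or donor is GenotypeCall.NO_CALL:
        return InformativityCall(False, reason="no_call")
    if recipient is GenotypeCall.HET:
        return InformativityCall(False, reason="recipient_heterozygous")
    minor = "ALT" if recipient is GenotypeCall.HOM_REF else "REF"
    donor_minor_copies = (
        donor.alt_copies if minor == "ALT" else 2 - donor.alt_copies
    )
    if donor_minor_copies == 0:
        return InformativityCall(False, reason="donor_matches_recipient")
    return InformativityCall(True, minor_allele=minor, multiplier=2 if donor_minor_copies == 1 else 1)


def expected_panel_informativity(panel: SnpPanel) -> float:
    """Mean Hardy-Weinberg informativity probability over non-control targets."""
    targets = panel.informative_targets
    if not targets:
        raise ValueError("panel has no non-control targets")
    return float(np.mean([informativity_probability(t.maf) for t in targets]))


_REQUIRED_COLUMNS = ("target_id", "ref", "alt", "maf")


def load_panel(path: str | Path, format: str = "tsv") -> SnpPanel:
    """Read a panel definition from a TSV with header row.

    Expected columns: ``target_id, chrom, pos, ref, alt, maf`` plus optional
    ``is_control`` (0/1) and any number of ``maf_<population>`` columns.
    Rows violating target invariants are reported with their line numbers.
    """
    if format != "tsv":
        raise ValueError(f"unsupported panel format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"target_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty panel file") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: panel file contains no targets")

    pop_cols = [c for c in df.columns if c.startswith("maf_")]
    targets: list[SnpTarget] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            maf = float(row["maf"])
        except (TypeError, ValueError):
            errors.append(f"line {line_no}: unparsable maf {row['maf']!r}")
            continue
        pops = {c[4:]: float(row[c]) for c in pop_cols if pd.notna(row[c])} or None
        try:
            targets.append(
                SnpTarget(
                    target_id=str(row["target_id"]),
                    ref_allele=str(row["ref"]),
                    alt_allele=str(row["alt"]),
                    maf=maf,
                    chrom=str(row["chrom"]) if "chrom" in df.columns else None,
                    pos=int(row["pos"]) if "pos" in df.columns else None,
                    is_control=bool(int(row["is_control"])) if "is_control" in df.columns else False,
                    population_mafs=pops,
                )
            )
        except ValueError as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise ValueError(f"{path}: invalid panel rows:\n" + "\n".join(errors))
    try:
        return SnpPanel(targets)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def default_panel() -> SnpPanel:
    """The bundled 94-target + 2-control clinical panel fixture."""
    from importlib.resources import files

    return load_panel(str(files("allofrac") / "data" / "default_panel.tsv"))
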