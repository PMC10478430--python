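"""Domain types for paired primary/metastasis tumour cohorts.

The pipeline compares three layers of data for each patient: somatic
mutations (mutant allele frequencies, MAF), miRNA qPCR measurements
(Ct cycles against the RNU6B reference gene), and RPPA protein
intensities normalised to total protein.  Tumour cellularity (TC, the
percentage of tumour cells in the sampled tissue) accompanies every
pair because it dilutes both allele frequencies and expression signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

ROLES = ("primary", "metastasis")
TISSUE_ROLES = ("normal", "primary", "metastasis")


@dataclass(frozen=True)
class MutationCall:
    """One somatic variant observation in one tumour of a pair.

    ``present=False`` encodes an explicit wild-type observation at a locus
    that is mutant in the partner tumour.  ``maf`` is the mutant allele
    fraction in [0, 1]; it is ``None`` for presence-only data such as the
    published mutation table.  Functional predictions (SIFT/PolyPhen/FATHMM)
    and any other extra columns ride along in ``annotations``.
    """

    case_id: str
    role: str
    gene: str
    hgvs_c: str
    present: bool
    maf: float | None = None
    codon: str | None = None
    exon: str | None = None
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.maf is not None:
            if not (0.0 <= self.maf <= 1.0):
                raise ValidationError(
                    f"maf must lie in [0, 1], got {self.maf} "
                    f"({self.case_id}/{self.gene} {self.hgvs_c})"
                )
            if not self.present and self.maf > 0:
                raise ValidationError(
                    f"absent call cannot carry maf > 0 ({self.case_id}/{self.gene})"
                )

    @property
    def locus(self) -> tuple[str, str]:
        """Locus identity key: (gene, HGVS.c)."""
        return (self.gene, self.hgvs_c)


@dataclass(frozen=True)
class TumourPairRecord:
    """Tumour cellularity (percent) for both members of a matched pair."""

    case_id: str
    tc_primary: float
    tc_metastasis: float

    def __post_init__(self) -> None:
        for name, tc in (("tc_primary", self.tc_primary),
                         ("tc_metastasis", self.tc_metastasis)):
            if not (0.0 < tc <= 100.0):
                raise ValidationError(
                    f"{name} must lie in (0, 100], got {tc} (case {self.case_id})"
                )

    def tc(self, role: str) -> float:
        return self.tc_primary if role == "primary" else self.tc_metastasis


@dataclass(frozen=True)
class CtRecord:
    """Raw qPCR observation for one miRNA in one tissue sample.

    ``sample_id`` identifies the case for tumour tissue; normal tissue uses
    its own identifier (a pooled-normal baseline in the reference study).
    """

    sample_id: str
    role: str
    mirna_id: str
    ct_replicates: tuple[float, ...]
    ct_reference: float

    def __post_init__(self) -> None:
        if self.role not in TISSUE_ROLES:
            raise ValidationError(f"role must be one of {TISSUE_ROLES}, got {self.role!r}")
        if len(self.ct_replicates) < 1:
            raise ValidationError(f"need >= 1 Ct replicate ({self.sample_id}/{self.mirna_id})")
        if any(ct <= 0 for ct in self.ct_replicates) or self.ct_reference <= 0:
            raise ValidationError(f"Ct values must be positive ({self.sample_id}/{self.mirna_id})")

    @property
    def ct_mean(self) -> float:
        return float(np.mean(self.ct_replicates))

    @property
    def ct_sd(self) -> float:
        """Replicate standard deviation (0 for a single replicate)."""
        if len(self.ct_replicates) < 2:
            return 0.0
        return float(np.std(self.ct_replicates, ddof=1))


@dataclass(frozen=True)
class RppaMeasurement:
    """One RPPA spot: raw marker intensity plus the total-protein signal
    used for loading normalisation."""

    sample_id: str
    role: str
    marker: str
    raw_signal: float
    total_protein_signal: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.raw_signal < 0:
            raise ValidationError(f"raw_signal must be >= 0 ({self.sample_id}/{self.marker})")
        if self.total_protein_signal <= 0:
            raise ValidationError(
                f"total_protein_signal must be > 0 ({self.sample_id}/{self.marker})"
            )


@dataclass
class Thresholds:
    """Every cut-off used by the three analysis layers.

    Defaults are the published conventions: heterogeneity-score bands at
    0.95/1.05, a 0.5 heterogeneity-score change for intra-status calls,
    2-fold / 0.5-fold expression categories, a 2-fold PM-RE alteration
    cut-off, and 50% majority rules at the pathway, pair and population
    levels.
    """

    hs_atc_low: float = 0.95
    hs_atc_high: float = 1.05
    delta_hs: float = 0.5
    rr_high: float = 2.0
    rr_low: float = 0.5
    pm_re_cutoff: float = 2.0
    pathway_fraction: float = 0.5
    pair_fraction: float = 0.5
    population_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("hs_atc_low", "hs_atc_high", "delta_hs", "rr_high",
                     "rr_low", "pm_re_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        for name in ("pathway_fraction", "pair_fraction", "population_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")


# Alternative expression-category preset derived from the pooled-normal
# calibration (0.5/1.5-fold) instead of the default 0.5/2.0 convention.
POOLED_NORMAL_PRESET = {"rr_high": 1.5, "rr_low": 0.5}


@dataclass
class AnalysisConfig:
    """Run-wide configuration: thresholds plus statistical conventions.

    ``null_policy`` selects the null proportion of the one-proportion
    z-test ("complement" reproduces the published convention p0 = 1 - p);
    ``rounding`` optionally rounds both proportions to three decimals
    before the z formula (spreadsheet-compatible mode).
    """

    thresholds: Thresholds = field(default_factory=Thresholds)
    null_policy: str = "complement"
    rounding: str = "none"
    tc_correction_sign: int = 1   # +1: corrected RR = measured RR * (100/TC)
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.null_policy != "complement" and not isinstance(self.null_policy, float):
            raise ValidationError("null_policy must be 'complement' or a fixed p0 float")
        if self.rounding not in ("none", "three_decimals"):
            raise ValidationError("rounding must be 'none' or 'three_decimals'")
        if self.tc_correction_sign not in (1, -1):
            raise ValidationError("tc_correction_sign must be +1 or -1")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "AnalysisConfig":
        raw = dict(raw)
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_dict(self) -> dict:
        return asdict(self)


def pairs_by_case(pairs: Sequence[TumourPairRecord]) -> dict[str, TumourPairRecord]:
    """Index pair records by case id, rejecting conflicting duplicates."""
    out: dict[str, TumourPairRecord] = {}
    for p in pairs:
        if p.case_id in out and out[p.case_id] != p:
            raise ValidationError(f"conflicting cellularity records for case {p.case_id}")
        out[p.case_id] = p
    return out
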