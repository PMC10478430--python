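"""Somatic-mutation heterogeneity scoring and paired concordance.

The heterogeneity score (HS) of a mutation is

    HS = MAF * 2 / (TC / 100)

where MAF is the mutant allele fraction and TC the tumour cellularity in
percent.  HS is about 1 when every tumour cell carries one mutant copy:
values well below indicate a subclonal mutation (present in a
Subpopulation of Tumour Cells, STC), values around 1 a clonal mutation
(All Tumour Cells, ATC), and values above 1 a copy-number-variation
background (CNV).  HS = 0 is wild type (WT).  Comparing the HS category
of each locus between a primary tumour and its matched metastasis yields
inter-status changes (category flips) and intra-status changes (same
category, HS shifted by at least 0.5 - the shift expected if the whole
tumour-cell population gains or loses one allele copy).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .cohort import MutationCall, TumourPairRecord, Thresholds, pairs_by_case
from .errors import DomainError, ValidationError
from .stats import PearsonResult, PropTestResult, one_proportion_z, pearson_r

WT, STC, ATC, CNV = "WT", "STC", "ATC", "CNV"

#: Trunk drivers arise early and are clonal in essentially all tumour
#: cells; TP53 is used as the branching-driver fallback reference.
TRUNK_DRIVER_GENES = ("APC", "KRAS", "NRAS", "BRAF")
BRANCH_DRIVER_GENES = ("TP53",)


@dataclass(frozen=True)
class HeterogeneityAssessment:
    case_id: str
    role: str
    gene: str
    hgvs_c: str
    hs: float
    status: str

    @property
    def locus(self) -> tuple[str, str]:
        return (self.gene, self.hgvs_c)


@dataclass(frozen=True)
class LocusComparison:
    case_id: str
    gene: str
    hgvs_c: str
    status_primary: str
    status_metastasis: str
    delta_hs: float
    change_class: str  # none | inter_status | intra_status


@dataclass(frozen=True)
class MafrRecord:
    case_id: str
    role: str
    gene: str
    hgvs_c: str
    mafr: float
    reference_gene: str
    reference_hgvs_c: str


@dataclass(frozen=True)
class DiscordanceSummary:
    n_inter: int
    n_intra: int
    n_none: int
    discordant: int
    denominator: int
    test: PropTestResult | None


def heterogeneity_score(maf: float, tc: float) -> float:
    """HS = MAF * 2 / (TC/100); 0 for a wild-type (MAF = 0) locus.

    Values above 2 are legal (amplified mutant allele) and are flagged
    downstream rather than capped.
    """
    if not (0.0 <= maf <= 1.0):
        raise ValidationError(f"maf must lie in [0, 1], got {maf}")
    if tc <= 0 or tc > 100:
        raise DomainError(f"tumour cellularity must lie in (0, 100], got {tc}")
    if maf == 0:
        return 0.0
    return maf * 2.0 / (tc / 100.0)


def classify_background(hs: float, thresholds: Thresholds | None = None) -> str:
    """Map an HS value onto WT / STC / ATC / CNV.

    WT is exactly 0; STC is (0, 0.95); ATC is the closed band [0.95, 1.05];
    CNV is (1.05, inf).  The three positive bands partition (0, inf).
    """
    thr = thresholds or Thresholds()
    if hs < 0:
        raise DomainError(f"hs must be >= 0, got {hs}")
    if hs == 0:
        return WT
    if hs < thr.hs_atc_low:
        return STC
    if hs <= thr.hs_atc_high:
        return ATC
    return CNV


def assess_cohort(calls: Sequence[MutationCall],
                  pairs: Sequence[TumourPairRecord],
                  thresholds: Thresholds | None = None) -> list[HeterogeneityAssessment]:
    """Score every MAF-bearing call against its sample's cellularity."""
    tc = pairs_by_case(pairs)
    out = []
    for c in calls:
        if c.maf is None:
            raise ValidationError(
                f"call {c.case_id}/{c.gene} {c.hgvs_c} has no MAF; "
                "presence-only data cannot be heterogeneity-scored"
            )
        if c.case_id not in tc:
            raise ValidationError(f"no cellularity record for case {c.case_id}")
        hs = heterogeneity_score(c.maf, tc[c.case_id].tc(c.role))
        out.append(HeterogeneityAssessment(
            case_id=c.case_id, role=c.role, gene=c.gene, hgvs_c=c.hgvs_c,
            hs=hs, status=classify_background(hs, thresholds),
        ))
    return out


def compare_pair_locus(a: HeterogeneityAssessment, b: HeterogeneityAssessment,
                       change_threshold: float = 0.5) -> LocusComparison:
    """Classify the primary-to-metastasis change at one locus.

    A category flip is an inter-status change; the same category with an
    HS shift of at least ``change_threshold`` is an intra-status change;
    anything else is no change.
    """
    if (a.case_id, a.locus) != (b.case_id, b.locus):
        raise ValidationError(
            f"mismatched comparison: {a.case_id}/{a.locus} vs {b.case_id}/{b.locus}"
        )
    if a.role != "primary" or b.role != "metastasis":
        raise ValidationError("compare_pair_locus expects (primary, metastasis) order")
    delta = abs(a.hs - b.hs)
    if a.status != b.status:
        change = "inter_status"
    elif delta >= change_threshold:
        change = "intra_status"
    else:
        change = "none"
    return LocusComparison(
        case_id=a.case_id, gene=a.gene, hgvs_c=a.hgvs_c,
        status_primary=a.status, status_metastasis=b.status,
        delta_hs=delta, change_class=change,
    )


def compare_cohort(assessments: Sequence[HeterogeneityAssessment],
                   change_threshold: float = 0.5) -> list[LocusComparison]:
    """Pair up assessments by (case, locus) and classify every locus."""
    by_key: dict[tuple, dict[str, HeterogeneityAssessment]] = {}
    for a in assessments:
        by_key.setdefault((a.case_id, a.locus), {})[a.role] = a
    out = []
    for (case_id, locus), roles in by_key.items():
        if set(roles) != {"primary", "metastasis"}:
            raise ValidationError(
                f"locus {locus} of case {case_id} observed for only one role"
            )
        out.append(compare_pair_locus(roles["primary"], roles["metastasis"],
                                      change_threshold))
    return out


def discordance_summary(comparisons: Sequence[LocusComparison],
                        denominator_policy: str = "primary_loci",
                        null_policy: str | float = "complement",
                        rounding: str = "none") -> DiscordanceSummary:
    """Count inter/intra/no-change loci and test the discordant fraction.

    ``denominator_policy="primary_loci"`` restricts to loci mutant in the
    primary tumour (the published convention: n mutant alleles detected in
    primaries); ``"union_loci"`` keeps every compared locus.  The test is
    the complement-null one-proportion z-test; at the degenerate boundaries
    (0 or all loci discordant) z is reported as -/+inf with p = 0.
    """
    if len(comparisons) == 0:
        raise DomainError("no locus comparisons supplied")
    if denominator_policy == "primary_loci":
        subset = [c for c in comparisons if c.status_primary != WT]
    elif denominator_policy == "union_loci":
        subset = list(comparisons)
    else:
        raise ValidationError(f"unknown denominator policy {denominator_policy!r}")
    if not subset:
        raise DomainError("denominator is empty under the chosen policy")
    counts = Counter(c.change_class for c in subset)
    n_inter = counts.get("inter_status", 0)
    n_intra = counts.get("intra_status", 0)
    n_none = counts.get("none", 0)
    discordant = n_inter + n_intra
    n = len(subset)
    if discordant == 0 or discordant == n:
        sign = -1.0 if discordant == 0 else 1.0
        test = PropTestResult(k=discordant, n=n, p_hat=discordant / n,
                              p0=1.0 - discordant / n,
                              z=sign * float("inf"), p_value=0.0)
    else:
        test = one_proportion_z(discordant, n, null_policy, rounding)
    return DiscordanceSummary(n_inter=n_inter, n_intra=n_intra, n_none=n_none,
                              discordant=discordant, denominator=n, test=test)


def mutation_concordance(calls: Sequence[MutationCall]) -> dict:
    """Presence/absence concordance over all loci of all pairs.

    A locus is *identical* when both members of the pair agree (present in
    both, or absent in both); private loci are present in exactly one role.
    Each locus must be observed for both roles (wild type encoded
    explicitly), as in the packaged mutation table.
    """
    by_key: dict[tuple, dict[str, bool]] = {}
    for c in calls:
        by_key.setdefault((c.case_id, c.locus), {})[c.role] = c.present
    identical = private_primary = private_metastasis = 0
    n_primary = n_metastasis = 0
    for key, roles in by_key.items():
        if set(roles) != {"primary", "metastasis"}:
            raise ValidationError(f"locus {key} observed for only one role")
        p, m = roles["primary"], roles["metastasis"]
        n_primary += p
        n_metastasis += m
        if p == m:
            identical += 1
        elif p:
            private_primary += 1
        else:
            private_metastasis += 1
    return {
        "total_loci": len(by_key),
        "identical_loci": identical,
        "private_primary": private_primary,
        "private_metastasis": private_metastasis,
        "mutations_primary": n_primary,
        "mutations_metastasis": n_metastasis,
    }


def gene_frequencies(calls: Sequence[MutationCall],
                     case_ids: Iterable[str] | None = None) -> "pd.DataFrame":
    """Per-gene case fraction and mutation count over the combined groups.

    A case counts for a gene when either member of its pair carries at
    least one mutation in that gene.  ``case_ids`` fixes the denominator
    (needed when mutation-free cases carry no calls); it defaults to the
    cases present in ``calls``.  Fractions are rounded to whole percent.
    """
    import pandas as pd

    if case_ids is None:
        case_ids = {c.case_id for c in calls}
    case_ids = list(dict.fromkeys(case_ids))
    if not case_ids:
        raise DomainError("no cases supplied")
    rows = []
    present = [c for c in calls if c.present]
    for gene in sorted({c.gene for c in present}):
        gene_calls = [c for c in present if c.gene == gene]
        cases = {c.case_id for c in gene_calls}
        loci = {(c.case_id, c.hgvs_c) for c in gene_calls}
        rows.append({
            "gene": gene,
            "n_cases": len(cases),
            "case_percent": round(100.0 * len(cases) / len(case_ids)),
            "n_mutations": len(loci),
        })
    return (pd.DataFrame(rows, columns=["gene", "n_cases", "case_percent", "n_mutations"])
            .sort_values(["n_cases", "gene"], ascending=[False, True])
            .reset_index(drop=True))


def mafr_table(calls: Sequence[MutationCall],
               trunk_genes: Sequence[str] = TRUNK_DRIVER_GENES,
               branch_genes: Sequence[str] = BRANCH_DRIVER_GENES) -> list[MafrRecord]:
    """Mutant-allele-frequency ratios relative to a per-sample driver.

    Within each sample the reference is the highest-MAF mutation in a
    trunk-driver gene, falling back to a branching driver when no trunk
    driver is mutant.  MAFR = MAF_locus / MAF_driver cancels cellularity,
    which affects both numerator and denominator equally.  Samples without
    any driver are skipped with a warning.
    """
    by_sample: dict[tuple[str, str], list[MutationCall]] = {}
    for c in calls:
        if c.present and c.maf:
            by_sample.setdefault((c.case_id, c.role), []).append(c)
    out = []
    for (case_id, role), sample_calls in by_sample.items():
        driver = None
        for genes in (trunk_genes, branch_genes):
            candidates = [c for c in sample_calls if c.gene in genes]
            if candidates:
                driver = max(candidates, key=lambda c: c.maf)
                break
        if driver is None:
            warnings.warn(f"sample {case_id}/{role} has no driver mutation; skipped",
                          stacklevel=2)
            continue
        for c in sample_calls:
            out.append(MafrRecord(
                case_id=case_id, role=role, gene=c.gene, hgvs_c=c.hgvs_c,
                mafr=c.maf / driver.maf,
                reference_gene=driver.gene, reference_hgvs_c=driver.hgvs_c,
            ))
    return out


def correlate_pairs(values_primary: Sequence[float],
                    values_metastasis: Sequence[float]) -> PearsonResult:
    """Pearson correlation of paired per-locus values (HS or MAFR)."""
    return pearson_r(values_primary, values_metastasis)
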