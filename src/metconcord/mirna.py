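"""ddCt miRNA quantification with tumour-cellularity normalisation.

Relative quantification proceeds in the classic two steps against the
RNU6B small-RNA reference gene:

    dCt  = Ct(target) - Ct(RNU6B)
    ddCt = dCt(tumour) - dCt(normal tissue)

Because only a fraction TC of the sampled tissue consists of tumour
cells, the measured tumour signal is diluted by stroma.  The ddCt is
therefore corrected to 100% cellularity by subtracting log2(100/TC),
i.e. the corrected relative ratio RR = 2^-ddCt is multiplied by 100/TC.
RR categorises expression as high (>= 2), low (<= 0.5) or normal.

Pair-level discordance is measured by the primary-to-metastasis
relative-expression ratio (PM-RE = RR_primary / RR_metastasis): a pair
is *altered* for a miRNA when PM-RE shows at least a two-fold change in
either direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CtRecord, Thresholds, TumourPairRecord, pairs_by_case
from .errors import DomainError, ValidationError
from .stats import (AdjustedPValues, KappaResult, PropTestResult, bh_adjust,
                    cohens_kappa, one_proportion_z)

CATEGORIES = ("high", "normal", "low")
REPLICATE_SD_WARN = 0.5  # cycles; the assay QC bound for replicate scatter


@dataclass(frozen=True)
class ExpressionQuant:
    sample_id: str
    role: str
    mirna_id: str
    delta_ct: float
    delta_delta_ct: float
    delta_delta_ct_tc: float
    rr: float
    category: str


@dataclass(frozen=True)
class PmReCall:
    case_id: str
    mirna_id: str
    pm_re: float
    altered: bool


@dataclass(frozen=True)
class OverallDiscordance:
    fractions: "pd.Series"       # per-miRNA altered fraction
    n_majority: int              # miRNAs with fraction >= 0.5
    n_mirnas: int
    discordant: bool


def delta_delta_ct(ct_target_tumour: float, ct_ref_tumour: float,
                   ct_target_normal: float, ct_ref_normal: float) -> float:
    """ddCt = (Ct_target - Ct_ref)_tumour - (Ct_target - Ct_ref)_normal."""
    for v in (ct_target_tumour, ct_ref_tumour, ct_target_normal, ct_ref_normal):
        if v is None or not math.isfinite(v):
            raise ValidationError("all four Ct values are required")
    return (ct_target_tumour - ct_ref_tumour) - (ct_target_normal - ct_ref_normal)


def tc_normalise_ddct(ddct: float, tc: float, sign: int = 1) -> float:
    """Correct a ddCt to 100% tumour cellularity.

    With the default ``sign=+1`` the corrected relative ratio is the
    measured one multiplied by 100/TC (stromal dilution attenuates tumour
    signal; dividing by the tumour fraction restores it):

        ddCt_tc = ddCt - log2(100 / TC)

    ``sign=-1`` applies the opposite convention.
    """
    if tc <= 0 or tc > 100:
        raise DomainError(f"tumour cellularity must lie in (0, 100], got {tc}")
    return ddct - sign * math.log2(100.0 / tc)


def relative_ratio(ddct_tc: float) -> float:
    """RR = 2^-ddCt (fold change relative to normal tissue)."""
    return 2.0 ** (-ddct_tc)


def categorise_rr(rr: float, high_cutoff: float = 2.0, low_cutoff: float = 0.5) -> str:
    """high if RR >= high_cutoff, low if RR <= low_cutoff, else normal."""
    if rr <= 0:
        raise DomainError(f"relative ratio must be positive, got {rr}")
    if rr >= high_cutoff:
        return "high"
    if rr <= low_cutoff:
        return "low"
    return "normal"


def quantify_cohort(records: Sequence[CtRecord],
                    pairs: Sequence[TumourPairRecord],
                    thresholds: Thresholds | None = None,
                    tc_correction_sign: int = 1) -> list[ExpressionQuant]:
    """Run the full ddCt chain for every tumour sample in a Ct table.

    ``records`` must contain, per miRNA, exactly one ``normal``-role
    baseline record (the pooled-normal tissue) and any number of tumour
    records whose ``sample_id`` is the case id.  Replicates are averaged;
    a replicate SD above 0.5 cycles triggers a warning.
    """
    thr = thresholds or Thresholds()
    tc = pairs_by_case(pairs)
    normal_dct: dict[str, float] = {}
    for r in records:
        if r.role == "normal":
            if r.mirna_id in normal_dct:
                raise ValidationError(f"duplicate normal baseline for {r.mirna_id}")
            normal_dct[r.mirna_id] = r.ct_mean - r.ct_reference
    out = []
    for r in records:
        if r.role == "normal":
            continue
        if r.ct_sd > REPLICATE_SD_WARN:
            warnings.warn(
                f"replicate Ct SD {r.ct_sd:.2f} > {REPLICATE_SD_WARN} cycles "
                f"for {r.sample_id}/{r.mirna_id}", stacklevel=2)
        if r.mirna_id not in normal_dct:
            raise ValidationError(f"no normal-tissue baseline for {r.mirna_id}")
        if r.sample_id not in tc:
            raise ValidationError(f"no cellularity record for case {r.sample_id}")
        dct = r.ct_mean - r.ct_reference
        ddct = dct - normal_dct[r.mirna_id]
        ddct_tc = tc_normalise_ddct(ddct, tc[r.sample_id].tc(r.role),
                                    tc_correction_sign)
        rr = relative_ratio(ddct_tc)
        out.append(ExpressionQuant(
            sample_id=r.sample_id, role=r.role, mirna_id=r.mirna_id,
            delta_ct=dct, delta_delta_ct=ddct, delta_delta_ct_tc=ddct_tc,
            rr=rr, category=categorise_rr(rr, thr.rr_high, thr.rr_low),
        ))
    return out


def quants_to_rr_table(quants: Sequence[ExpressionQuant], role: str) -> pd.DataFrame:
    """Pivot quantifications into a case x miRNA RR matrix for one role."""
    rows = [q for q in quants if q.role == role]
    return pd.DataFrame(
        {"case_id": [q.sample_id for q in rows],
         "mirna_id": [q.mirna_id for q in rows],
         "rr": [q.rr for q in rows]}
    ).pivot(index="case_id", columns="mirna_id", values="rr")


def category_table(quants: Sequence[ExpressionQuant]) -> pd.DataFrame:
    """Pivot categories into a pair x (miRNA, role) frame (table2 layout)."""
    df = pd.DataFrame(
        {"pair_id": [q.sample_id for q in quants],
         "role": [q.role for q in quants],
         "mirna_id": [q.mirna_id for q in quants],
         "category": [q.category for q in quants]}
    )
    wide = df.pivot(index="pair_id", columns=["mirna_id", "role"], values="category")
    return wide.sort_index(axis=1)


def concordance_by_mirna(categories: pd.DataFrame) -> dict[str, KappaResult]:
    """Cohen's kappa of primary vs metastasis categories, per miRNA.

    ``categories`` has a MultiIndex column per (miRNA, role) with values
    in {high, normal, low} (the table2 fixture layout).  Each miRNA's
    3x3 contingency table is tested; tables where one tumour role uses a
    single category come back ``defined=False``.
    """
    out = {}
    for mirna in categories.columns.get_level_values(0).unique():
        sub = categories[mirna]
        table = np.zeros((3, 3), dtype=int)
        for p, m in zip(sub["primary"], sub["metastasis"]):
            p, m = str(p).lower(), str(m).lower()
            if p not in CATEGORIES or m not in CATEGORIES:
                raise ValidationError(f"unknown category label {p!r}/{m!r} for {mirna}")
            table[CATEGORIES.index(p), CATEGORIES.index(m)] += 1
        out[mirna] = cohens_kappa(table)
    return out


def pm_re_from_ratios(ratios: pd.DataFrame, cutoff: float = 2.0) -> list[PmReCall]:
    """Alteration calls from a precomputed pair x miRNA PM-RE matrix.

    A pair is altered for a miRNA when PM-RE >= cutoff or <= 1/cutoff
    (boundaries inclusive).
    """
    if cutoff <= 1:
        raise DomainError(f"cutoff must exceed 1, got {cutoff}")
    calls = []
    for pair_id, row in ratios.iterrows():
        for mirna, value in row.items():
            value = float(value)
            if value <= 0 or not math.isfinite(value):
                raise DomainError(f"PM-RE must be positive and finite, got {value}")
            calls.append(PmReCall(
                case_id=str(pair_id), mirna_id=str(mirna), pm_re=value,
                altered=value >= cutoff or value <= 1.0 / cutoff,
            ))
    return calls


def pm_re_calls(rr_primary: pd.DataFrame, rr_metastasis: pd.DataFrame,
                cutoff: float = 2.0) -> list[PmReCall]:
    """PM-RE = RR_primary / RR_metastasis on matched case x miRNA tables."""
    if (rr_primary <= 0).any().any() or (rr_metastasis <= 0).any().any():
        raise DomainError("relative ratios must be positive")
    common = rr_primary.index.intersection(rr_metastasis.index)
    ratios = rr_primary.loc[common] / rr_metastasis.loc[common]
    return pm_re_from_ratios(ratios, cutoff)


def altered_counts(calls: Sequence[PmReCall]) -> pd.Series:
    """Per-miRNA altered-pair counts, in first-appearance column order."""
    order = list(dict.fromkeys(c.mirna_id for c in calls))
    counts = {m: 0 for m in order}
    for c in calls:
        counts[c.mirna_id] += c.altered
    return pd.Series(counts, name="altered")


def pm_re_tests(counts: Mapping[str, int] | pd.Series, n: int,
                null_policy: str | float = "complement",
                rounding: str = "none") -> pd.DataFrame:
    """Complement-null z-test per miRNA plus BH adjustment across the family."""
    counts = pd.Series(counts)
    if (counts > n).any():
        raise ValidationError("altered count exceeds the number of pairs")
    results: list[PropTestResult] = [
        one_proportion_z(int(k), n, null_policy, rounding) for k in counts
    ]
    adj: AdjustedPValues = bh_adjust([r.p_value for r in results])
    return pd.DataFrame({
        "mirna_id": counts.index,
        "altered": counts.values,
        "n": n,
        "z": [r.z for r in results],
        "p_value": [r.p_value for r in results],
        "p_adjusted": adj.adjusted,
    })


def overall_discordance(calls: Sequence[PmReCall]) -> OverallDiscordance:
    """The 50%-of-pairs-in-50%-of-miRNAs discordance rule.

    Overall expression is discordant between the tumour groups when at
    least half of the miRNAs show an altered PM-RE in at least half of
    the pairs (both bounds inclusive).
    """
    if not calls:
        raise DomainError("no PM-RE calls supplied")
    df = pd.DataFrame({"mirna": [c.mirna_id for c in calls],
                       "altered": [c.altered for c in calls]})
    fractions = df.groupby("mirna", sort=False)["altered"].mean()
    n_majority = int((fractions >= 0.5).sum())
    return OverallDiscordance(
        fractions=fractions, n_majority=n_majority, n_mirnas=len(fractions),
        discordant=n_majority >= 0.5 * len(fractions),
    )
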