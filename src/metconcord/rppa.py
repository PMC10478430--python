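"""RPPA pathway-alteration cascade for paired tumours.

Marker intensities are first normalised to the total-protein signal of
the same spot (loading control).  The metastatic value is then corrected
for the cellularity difference between the two members of a pair,

    E_m_tc = E_m + (dTC / 100) * E_m,   dTC = TC_primary - TC_metastasis,

so that a less-cellular metastasis sample is scaled up.  A marker is
*altered* in a pair when |E_primary - E_m_tc| strictly exceeds the
marker's standard deviation over the whole tumour population (primary
and TC-adjusted metastatic values combined).  Direction is reported
relative to the metastasis: ``up`` means the metastasis is higher.

Alterations cascade hierarchically with inclusive 50% majority rules:
isoforms and modified forms collapse onto their parent biomarker; a
pathway is altered in a pair when at least half its collapsed markers
are; a pair's profile is altered when at least half its pathways are;
and the two tumour populations differ when at least half the pairs have
altered profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import RppaMeasurement, TumourPairRecord, pairs_by_case
from .errors import DomainError, ValidationError
from .stats import KappaResult, cohens_kappa

DIRECTIONS = ("up", "none", "down")

#: Modified/isoform markers collapse onto their parent biomarker.
DEFAULT_ISOFORM_MAP: dict[str, str] = {
    "P85": "PI3K",
    "P110": "PI3K",
    "PTEN": "PTEN",
    "phosphoPTEN": "PTEN",
    "pAKT-ser": "AKT",
    "pAKT-thr": "AKT",
}

#: The six biological pathway groups, over collapsed marker names.
DEFAULT_PATHWAY_MAP: dict[str, tuple[str, ...]] = {
    "CAM-EMT": ("CD34", "CD31", "D2-40", "BEREP4", "AE1-3", "E-cadherin"),
    "RAS-RAF-MEK": ("RAS", "RASA1", "pCRAF"),
    "PI3K-AKT-PTEN": ("PI3K", "PTEN", "AKT", "mtor", "pGSK"),
    "TGFB-SMAD4": ("TGFB", "SMAD4"),
    "apoptosis": ("BCL2",),
    "transcriptional-misregulation": ("WT1", "KLF4"),
}

#: The validation comparisons: isoforms/modified forms and functionally
#: related markers expected to share alteration status.
DEFAULT_VALIDATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("CD34", "CD31"),
    ("P85", "P110"),
    ("PTEN", "phosphoPTEN"),
    ("RAS", "RASA1"),
    ("pAKT-ser", "pAKT-thr"),
    ("mtor", "pAKT-ser"),
    ("mtor", "pAKT-thr"),
    ("TGFB", "SMAD4"),
)

#: The membrane-receptor marker is named inconsistently in the source
#: material; both spellings resolve to one stored marker.
MARKER_ALIASES = {"TGFBRII": "TGFB"}

ALL_MARKERS: tuple[str, ...] = (
    "CD34", "CD31", "D2-40", "BEREP4", "AE1-3", "E-cadherin",
    "RAS", "RASA1", "pCRAF",
    "P85", "P110", "PTEN", "phosphoPTEN", "pAKT-ser", "pAKT-thr", "mtor", "pGSK",
    "TGFB", "SMAD4", "BCL2", "WT1", "KLF4",
)


@dataclass(frozen=True)
class AlterationCall:
    case_id: str
    marker: str
    e_primary: float
    e_metastasis_tc: float
    sd: float
    direction: str  # up | none | down

    @property
    def differential(self) -> float:
        return self.e_primary - self.e_metastasis_tc

    @property
    def altered(self) -> bool:
        return self.direction != "none"


@dataclass(frozen=True)
class PathwayCall:
    case_id: str
    pathway: str
    altered_fraction: float
    altered: bool


@dataclass(frozen=True)
class PopulationSummary:
    pair_altered: "pd.Series"     # per-case profile-altered flag
    pair_fractions: "pd.Series"   # per-case fraction of altered pathways
    population_fraction: float
    population_different: bool


def relative_expression(raw: float, total_protein: float) -> float:
    """Loading-normalised expression: raw signal / total-protein signal."""
    if total_protein <= 0:
        raise DomainError(f"total protein signal must be positive, got {total_protein}")
    if raw < 0:
        raise ValidationError(f"raw signal must be >= 0, got {raw}")
    return raw / total_protein


def tc_normalise_met(e_m: float, tc_primary: float, tc_metastasis: float) -> float:
    """Scale a metastatic expression to the primary's cellularity.

    E_m_tc = E_m * (1 + dTC/100) with dTC = TC_primary - TC_metastasis;
    the identity when the two cellularities are equal.
    """
    for tc in (tc_primary, tc_metastasis):
        if not (0 < tc <= 100):
            raise DomainError(f"tumour cellularity must lie in (0, 100], got {tc}")
    return e_m * (1.0 + (tc_primary - tc_metastasis) / 100.0)


def marker_sd(expressions: Sequence[float]) -> float:
    """Sample SD (n-1 denominator) over the whole tumour population."""
    values = np.asarray(expressions, dtype=float)
    if values.size < 2:
        raise DomainError("need >= 2 expression values for a dispersion estimate")
    return float(np.std(values, ddof=1))


def alteration_call(case_id: str, marker: str, e_p: float, e_m_tc: float,
                    sd: float) -> AlterationCall:
    """Call a marker altered when |E_p - E_m_tc| strictly exceeds the SD.

    Ties at exactly one SD are not altered ("greater than" is strict).
    Direction is relative to the metastasis: up = metastasis higher.
    """
    diff = e_p - e_m_tc
    if abs(diff) > sd:
        direction = "up" if diff < 0 else "down"
    else:
        direction = "none"
    return AlterationCall(case_id=case_id, marker=marker, e_primary=e_p,
                          e_metastasis_tc=e_m_tc, sd=sd, direction=direction)


def alteration_calls(measurements: Sequence[RppaMeasurement],
                     pairs: Sequence[TumourPairRecord]) -> list[AlterationCall]:
    """Run the normalise / TC-adjust / SD-threshold chain on a cohort.

    The per-marker SD is computed *after* TC adjustment of the metastatic
    values, over both roles combined.
    """
    tc = pairs_by_case(pairs)
    expr: dict[tuple[str, str], dict[str, float]] = {}
    for m in measurements:
        marker = MARKER_ALIASES.get(m.marker, m.marker)
        if m.sample_id not in tc:
            raise ValidationError(f"no cellularity record for case {m.sample_id}")
        e = relative_expression(m.raw_signal, m.total_protein_signal)
        entry = expr.setdefault((m.sample_id, marker), {})
        if m.role in entry:
            raise ValidationError(
                f"duplicate measurement for {m.sample_id}/{marker}/{m.role}")
        if m.role == "metastasis":
            pair = tc[m.sample_id]
            e = tc_normalise_met(e, pair.tc_primary, pair.tc_metastasis)
        entry[m.role] = e
    markers = sorted({marker for (_, marker) in expr})
    sds = {}
    for marker in markers:
        values = [v for (cid, mk), roles in expr.items() if mk == marker
                  for v in roles.values()]
        sds[marker] = marker_sd(values)
    calls = []
    for (case_id, marker), roles in sorted(expr.items()):
        if set(roles) != {"primary", "metastasis"}:
            raise ValidationError(
                f"marker {marker} of case {case_id} measured for only one role")
        calls.append(alteration_call(case_id, marker, roles["primary"],
                                     roles["metastasis"], sds[marker]))
    return calls


def validate_isoform_concordance(
    calls: Sequence[AlterationCall],
    pair_list: Sequence[tuple[str, str]] = DEFAULT_VALIDATION_PAIRS,
) -> dict[tuple[str, str], KappaResult]:
    """Kappa agreement of alteration status between related marker pairs.

    For each (marker, isoform) pair, the up/none/down calls across all
    tumour pairs form a 3x3 contingency table.  Marker pairs missing from
    the data are skipped with a warning.
    """
    by_marker: dict[str, dict[str, str]] = {}
    for c in calls:
        by_marker.setdefault(c.marker, {})[c.case_id] = c.direction
    out = {}
    for m1, m2 in pair_list:
        if m1 not in by_marker or m2 not in by_marker:
            warnings.warn(f"validation pair ({m1}, {m2}) missing from data; skipped",
                          stacklevel=2)
            continue
        cases = sorted(set(by_marker[m1]) & set(by_marker[m2]))
        table = np.zeros((3, 3), dtype=int)
        for case in cases:
            table[DIRECTIONS.index(by_marker[m1][case]),
                  DIRECTIONS.index(by_marker[m2][case])] += 1
        out[(m1, m2)] = cohens_kappa(table)
    return out


def collapse_isoforms(
    calls: Sequence[AlterationCall],
    isoform_map: Mapping[str, str] = DEFAULT_ISOFORM_MAP,
) -> pd.DataFrame:
    """Collapse isoform/modified-form calls onto parent biomarkers.

    The parent is altered when any member form is altered (so repeated
    alterations count once).  Returns a case x parent-marker boolean frame.
    """
    rows = [{"case_id": c.case_id,
             "marker": isoform_map.get(c.marker, c.marker),
             "altered": c.altered} for c in calls]
    df = pd.DataFrame(rows)
    if df.empty:
        raise DomainError("no alteration calls supplied")
    return (df.groupby(["case_id", "marker"])["altered"].any()
              .unstack("marker"))


def pathway_calls(
    collapsed: pd.DataFrame,
    pathway_map: Mapping[str, Sequence[str]] = DEFAULT_PATHWAY_MAP,
    pathway_fraction: float = 0.5,
) -> list[PathwayCall]:
    """Apply the >= 50%-of-markers rule per pathway and case."""
    out = []
    for pathway, members in pathway_map.items():
        members = list(members)
        if not members:
            raise ValidationError(f"pathway {pathway!r} has no member markers")
        missing = [m for m in members if m not in collapsed.columns]
        if missing:
            warnings.warn(f"pathway {pathway}: markers {missing} missing from data",
                          stacklevel=2)
        present = [m for m in members if m in collapsed.columns]
        if not present:
            continue
        for case_id, row in collapsed[present].iterrows():
            frac = float(row.sum()) / len(members)
            out.append(PathwayCall(case_id=str(case_id), pathway=pathway,
                                   altered_fraction=frac,
                                   altered=frac >= pathway_fraction))
    return out


def pair_and_population_summary(
    calls: Sequence[PathwayCall],
    pair_fraction: float = 0.5,
    population_fraction: float = 0.5,
) -> PopulationSummary:
    """Pair-level profile flags and the population-level verdict.

    A pair's profile is altered when >= half its pathways are altered;
    the populations differ when >= half the pairs have altered profiles
    (both inclusive).
    """
    if not calls:
        raise DomainError("no pathway calls supplied")
    df = pd.DataFrame({"case_id": [c.case_id for c in calls],
                       "altered": [c.altered for c in calls]})
    fractions = df.groupby("case_id", sort=True)["altered"].mean()
    pair_altered = fractions >= pair_fraction
    pop_fraction = float(pair_altered.mean())
    return PopulationSummary(
        pair_altered=pair_altered, pair_fractions=fractions,
        population_fraction=pop_fraction,
        population_different=pop_fraction >= population_fraction,
    )
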