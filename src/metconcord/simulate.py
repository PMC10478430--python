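"""Seeded synthetic paired-tumour cohorts with designed effect structure.

Each generator inverts the corresponding analysis model so that, at zero
noise, the pipeline recovers the design exactly:

* mutations: a target heterogeneity status fixes a target HS inside its
  band; the emitted MAF = HS * (TC/100) / 2 inverts the HS formula, and
  discordant loci redraw the metastasis status;
* Ct values: the target miRNA Ct is the reference Ct plus a baseline
  dCt minus the measured log2 fold, where the measured fold is the true
  fold *diluted* by tumour cellularity (the inverse of the pipeline's
  100/TC correction);
* RPPA: log-normal relative expressions; markers of a designated-altered
  pathway are shifted by a multiple of the dispersion scale, and the
  emitted metastatic value is the TC-adjustment inverse of the truth.

One RNG stream per generator, derived from the master seed by a fixed
stream id, so enabling one data type never shifts another's draws.
Identical (design, seed) yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import CtRecord, MutationCall, RppaMeasurement, TumourPairRecord
from .errors import DesignError
from . import io as mio
from .rppa import ALL_MARKERS, DEFAULT_ISOFORM_MAP, DEFAULT_PATHWAY_MAP

_STREAM_MUTATION, _STREAM_CT, _STREAM_RPPA = 1, 2, 3

#: HS bands used for target sampling: (low, high) per status.  The
#: analysis bands are open-ended; sampling needs finite, interior bands.
STATUS_BANDS = {
    "WT": (0.0, 0.0),
    "STC": (0.3, 0.9),
    "ATC": (0.95, 1.05),
    "CNV": (1.1, 1.7),
}

MAF_TRUNCATION = (0.01, 0.99)  # avoids degenerate HS for present mutations


@dataclass(frozen=True)
class MutationLocusDesign:
    gene: str
    status: str                  # WT | STC | ATC | CNV target in the primary
    discordance_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in STATUS_BANDS:
            raise DesignError(f"unknown status {self.status!r}")
        if not (0.0 <= self.discordance_prob <= 1.0):
            raise DesignError("discordance_prob must lie in [0, 1]")


@dataclass(frozen=True)
class MirnaDesign:
    mirna_id: str
    log2_effect: float = 0.0     # true primary-vs-metastasis log2 fold
    noise_sd: float = 0.0        # per-replicate Ct noise, cycles
    altered_prob: float = 1.0    # fraction of pairs carrying the effect

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be >= 0")
        if not (0.0 <= self.altered_prob <= 1.0):
            raise DesignError("altered_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationDesign:
    """Study-condition defaults mirror the reference cohort: about twenty
    pairs, cellularities between 40 and 90 percent, a 0.7 locus
    discordance rate, two-fold-plus miRNA shifts in 70% of pairs with
    0.2-cycle replicate noise, and pathway alteration probability 0.65."""

    n_pairs: int = 21
    tc_range: tuple[float, float] = (40.0, 90.0)
    mutation: tuple[MutationLocusDesign, ...] = (
        MutationLocusDesign("APC", "CNV", 0.7),
        MutationLocusDesign("KRAS", "STC", 0.7),
        MutationLocusDesign("TP53", "CNV", 0.7),
    )
    mirna: tuple[MirnaDesign, ...] = tuple(
        MirnaDesign(m, log2_effect=e, noise_sd=0.2, altered_prob=0.7)
        for m, e in (("miRNA20a", 2.0), ("miRNA21", -2.0), ("miRNA29a", 2.0),
                     ("miRNA31", -2.0), ("miRNA92", 2.0), ("miRNA224", -2.0))
    )
    rppa_pathway_probs: dict = field(
        default_factory=lambda: {p: 0.65 for p in DEFAULT_PATHWAY_MAP})
    rppa_noise_sd: float = 0.25   # log-scale marker variation
    rppa_shift_mult: float = 3.0  # alteration shift in dispersion units
    rppa_pair_noise_sd: float = 0.02
    hs_bands: dict = field(default_factory=lambda: dict(STATUS_BANDS))

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise DesignError("n_pairs must be >= 1")
        lo, hi = self.tc_range
        if not (0 < lo <= hi <= 100):
            raise DesignError(f"tc_range must satisfy 0 < low <= high <= 100, got {self.tc_range}")
        if self.rppa_noise_sd < 0 or self.rppa_pair_noise_sd < 0:
            raise DesignError("noise SDs must be >= 0")
        targeted = {d.status for d in self.mutation}
        for status, (_, band_hi) in self.hs_bands.items():
            if status in targeted and band_hi * hi / 200.0 > MAF_TRUNCATION[1]:
                raise DesignError(
                    f"infeasible design: status {status} at TC {hi}% would need "
                    f"MAF > {MAF_TRUNCATION[1]}")


def _rng(stream: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(seed)])


def _draw_tc(rng: np.random.Generator, design: SimulationDesign) -> float:
    lo, hi = design.tc_range
    return float(np.round(rng.uniform(lo, hi), 1)) if hi > lo else float(lo)


def _draw_hs(rng: np.random.Generator, status: str, jitter: bool = True,
             bands=None) -> float:
    lo, hi = (bands or STATUS_BANDS)[status]
    if status == "WT":
        return 0.0
    if not jitter or lo == hi:
        return (lo + hi) / 2.0
    return float(rng.uniform(lo, hi))


def generate_pairs(design: SimulationDesign, seed: int,
                   prefix: str = "S") -> list[TumourPairRecord]:
    rng = _rng(_STREAM_MUTATION, seed)
    return [TumourPairRecord(f"{prefix}{i + 1}",
                             _draw_tc(rng, design), _draw_tc(rng, design))
            for i in range(design.n_pairs)]


def generate_mutation_cohort(
    design: SimulationDesign, seed: int, outdir=None, hs_jitter: bool = True,
    pairs: list[TumourPairRecord] | None = None,
) -> tuple[list[MutationCall], list[TumourPairRecord], dict]:
    """Paired mutation calls realising the designed background statuses.

    Returns (calls, pairs, truth); ``truth`` records the designed and
    realised per-locus discordance.  With ``outdir`` set, writes
    ``mutations.tsv`` and ``pairs.tsv``.  Pass ``pairs`` to share one set
    of cellularities across data types.
    """
    rng = _rng(_STREAM_MUTATION, seed)
    if pairs is None:
        pairs = [TumourPairRecord(f"S{i + 1}", _draw_tc(rng, design),
                                  _draw_tc(rng, design))
                 for i in range(design.n_pairs)]
    calls: list[MutationCall] = []
    n_discordant = n_loci = 0
    for pair in pairs:
        for j, locus in enumerate(design.mutation):
            hgvs = f"c.sim{j + 1}"
            hs_p = _draw_hs(rng, locus.status, hs_jitter, design.hs_bands)
            discordant = bool(rng.random() < locus.discordance_prob)
            if discordant:
                others = [s for s in design.hs_bands if s != locus.status]
                status_m = others[int(rng.integers(len(others)))]
                hs_m = _draw_hs(rng, status_m, hs_jitter, design.hs_bands)
            else:
                # stay within the band, well below the 0.5 change threshold
                lo, hi = design.hs_bands[locus.status]
                wobble = rng.uniform(-0.1, 0.1) if (hs_jitter and hs_p > 0) else 0.0
                hs_m = float(np.clip(hs_p + wobble, lo, hi))
            if locus.status != "WT":
                n_loci += 1
                n_discordant += discordant
            for role, hs in (("primary", hs_p), ("metastasis", hs_m)):
                maf = hs * (pair.tc(role) / 100.0) / 2.0
                if maf > 0:
                    maf = float(np.clip(maf, *MAF_TRUNCATION))
                calls.append(MutationCall(
                    case_id=pair.case_id, role=role, gene=locus.gene,
                    hgvs_c=hgvs, present=maf > 0, maf=maf,
                ))
    truth = {
        "designed_discordance": {d.gene: d.discordance_prob for d in design.mutation},
        "realised_discordant_fraction": (n_discordant / n_loci) if n_loci else 0.0,
        "n_primary_loci": n_loci,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_mutation_table(calls, pairs, outdir / "mutations.tsv")
        mio.write_pair_table(pairs, outdir / "pairs.tsv")
    return calls, pairs, truth


def generate_ct_cohort(
    design: SimulationDesign, seed: int, outdir=None, n_replicates: int = 3,
    pairs: list[TumourPairRecord] | None = None,
) -> tuple[list[CtRecord], list[TumourPairRecord], dict]:
    """Ct table (pooled-normal baseline plus tumour rows) with designed
    primary-vs-metastasis log2 effects.

    The emitted tumour Ct embeds the cellularity dilution, so the
    pipeline's 100/TC correction recovers the designed fold exactly at
    zero noise.
    """
    rng = _rng(_STREAM_CT, seed)
    if pairs is None:
        pairs = [TumourPairRecord(f"S{i + 1}", _draw_tc(rng, design),
                                  _draw_tc(rng, design))
                 for i in range(design.n_pairs)]
    ct_ref = 18.0
    records: list[CtRecord] = []
    truth_altered: dict[str, int] = {}
    baseline_dct = {m.mirna_id: float(np.round(rng.uniform(1.0, 4.0), 3))
                    for m in design.mirna}
    for m in design.mirna:
        records.append(CtRecord(
            sample_id="pooled_normal", role="normal", mirna_id=m.mirna_id,
            ct_replicates=(ct_ref + baseline_dct[m.mirna_id],) * n_replicates,
            ct_reference=ct_ref,
        ))
    for pair in pairs:
        for m in design.mirna:
            altered = bool(rng.random() < m.altered_prob)
            truth_altered[m.mirna_id] = truth_altered.get(m.mirna_id, 0) + altered
            # metastasis true log2 fold vs normal is 0; the primary carries
            # the designed effect in altered pairs
            for role, fold in (("primary", m.log2_effect if altered else 0.0),
                               ("metastasis", 0.0)):
                tc = pair.tc(role)
                measured_fold = fold + np.log2(tc / 100.0)
                base_ct = ct_ref + baseline_dct[m.mirna_id] - measured_fold
                reps = tuple(
                    float(base_ct + (rng.normal(0.0, m.noise_sd) if m.noise_sd else 0.0))
                    for _ in range(n_replicates))
                records.append(CtRecord(
                    sample_id=pair.case_id, role=role, mirna_id=m.mirna_id,
                    ct_replicates=reps, ct_reference=ct_ref,
                ))
    truth = {
        "designed_effects": {m.mirna_id: m.log2_effect for m in design.mirna},
        "designed_altered_prob": {m.mirna_id: m.altered_prob for m in design.mirna},
        "realised_altered_fraction": {
            k: v / design.n_pairs for k, v in truth_altered.items()},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_ct_table(records, outdir / "ct.csv")
        mio.write_pair_table(pairs, outdir / "pairs.tsv")
    return records, pairs, truth


def generate_rppa_cohort(
    design: SimulationDesign, seed: int, outdir=None,
    markers: Sequence[str] = ALL_MARKERS,
    pairs: list[TumourPairRecord] | None = None,
) -> tuple[list[RppaMeasurement], list[TumourPairRecord], dict]:
    """Log-normal RPPA intensities with per-pathway designed alterations.

    When a pathway is designated altered in a pair, every form of every
    collapsed member biomarker is shifted by ``rppa_shift_mult`` times the
    dispersion scale with a shared per-parent direction, so the pathway's
    collapsed altered fraction is 1 and isoforms agree in status.
    """
    rng = _rng(_STREAM_RPPA, seed)
    if pairs is None:
        pairs = [TumourPairRecord(f"S{i + 1}", _draw_tc(rng, design),
                                  _draw_tc(rng, design))
                 for i in range(design.n_pairs)]
    parent_forms: dict[str, list[str]] = {}
    for form in markers:
        parent = DEFAULT_ISOFORM_MAP.get(form, form)
        parent_forms.setdefault(parent, []).append(form)
    sd_scale = design.rppa_noise_sd if design.rppa_noise_sd > 0 else 0.1
    measurements: list[RppaMeasurement] = []
    truth_pathway: dict[str, list[bool]] = {p: [] for p in design.rppa_pathway_probs}
    n_pairs_altered = 0
    for pair in pairs:
        shifted: dict[str, float] = {}  # form -> shift direction
        pathway_flags = {}
        for pathway, pi in design.rppa_pathway_probs.items():
            altered = bool(rng.random() < pi)
            pathway_flags[pathway] = altered
            truth_pathway[pathway].append(altered)
            if altered:
                for parent in DEFAULT_PATHWAY_MAP[pathway]:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    for form in parent_forms.get(parent, ()):
                        shifted[form] = sign
        n_pairs_altered += (
            sum(pathway_flags.values()) >= 0.5 * len(pathway_flags))
        dtc_factor = 1.0 + (pair.tc_primary - pair.tc_metastasis) / 100.0
        for marker in markers:
            e_m_true = float(np.exp(
                rng.normal(0.0, design.rppa_noise_sd))) if design.rppa_noise_sd \
                else 1.0
            noise = (float(np.exp(rng.normal(0.0, design.rppa_pair_noise_sd)))
                     if design.rppa_pair_noise_sd else 1.0)
            e_p = e_m_true * noise
            if marker in shifted:
                e_p = e_m_true + shifted[marker] * design.rppa_shift_mult * sd_scale
                if e_p <= 0:
                    e_p = e_m_true + design.rppa_shift_mult * sd_scale
            # emit the pre-adjustment metastatic value so the pipeline's
            # TC correction recovers e_m_true
            e_m_emitted = e_m_true / dtc_factor
            for role, e in (("primary", e_p), ("metastasis", e_m_emitted)):
                total = float(np.round(np.exp(rng.normal(np.log(50.0), 0.1)), 6))
                measurements.append(RppaMeasurement(
                    sample_id=pair.case_id, role=role, marker=marker,
                    raw_signal=float(e * total), total_protein_signal=total,
                ))
    truth = {
        "designed_pathway_probs": dict(design.rppa_pathway_probs),
        "realised_pathway_fractions": {
            p: float(np.mean(v)) for p, v in truth_pathway.items()},
        "realised_pair_altered_fraction": n_pairs_altered / design.n_pairs,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_rppa_table(measurements, outdir / "rppa.csv")
        mio.write_pair_table(pairs, outdir / "pairs.tsv")
    return measurements, pairs, truth
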