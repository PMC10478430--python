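"""Parameter recovery: each generator inverted through its pipeline stage.

For every data layer a synthetic cohort is generated at a designed rate
and pushed through the corresponding analysis; the recovered rate is
compared with the design value via the exact (Clopper-Pearson) 95%
binomial interval.  Sizes: 500 mutation loci (100 pairs x 5 loci),
100 pairs x 1 miRNA, and 200 RPPA pairs.

Writes results/recovery/.
"""

from scipy.stats import binom, binomtest

from metconcord import heterogeneity as het
from metconcord import io as mio
from metconcord import mirna as mi
from metconcord import rppa as rp
from metconcord.simulate import (MirnaDesign, MutationLocusDesign,
                                 SimulationDesign, generate_ct_cohort,
                                 generate_mutation_cohort,
                                 generate_rppa_cohort)

SEED = 11


def _check(label: str, k: int, n: int, design_value: float) -> dict:
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    ok = ci.low <= design_value <= ci.high
    print(f"  {label:28s} designed {design_value:.3f}  recovered {k}/{n} "
          f"= {k / n:.3f}  CI ({ci.low:.3f}, {ci.high:.3f})  "
          + ("OK" if ok else "OUTSIDE CI"))
    return {"designed": design_value, "k": k, "n": n,
            "ci_low": ci.low, "ci_high": ci.high, "within_ci": ok}


def main() -> None:
    report = {}
    print("mutation discordance (0.7 designed, 500 loci):")
    design = SimulationDesign(
        n_pairs=100,
        mutation=tuple(MutationLocusDesign(g, s, 0.7) for g, s in
                       (("APC", "CNV"), ("KRAS", "STC"), ("TP53", "CNV"),
                        ("NRAS", "ATC"), ("SMAD4", "STC"))))
    calls, pairs, _ = generate_mutation_cohort(design, SEED)
    summary = het.discordance_summary(
        het.compare_cohort(het.assess_cohort(calls, pairs)))
    report["mutation_discordance"] = _check(
        "locus discordant fraction", summary.discordant, summary.denominator, 0.7)

    print("\nmiRNA altered PM-RE (0.8 designed, 100 pairs):")
    design = SimulationDesign(
        n_pairs=100,
        mirna=(MirnaDesign("m1", log2_effect=2.0, noise_sd=0.1,
                           altered_prob=0.8),))
    records, pairs, _ = generate_ct_cohort(design, SEED)
    quants = mi.quantify_cohort(records, pairs)
    pm = mi.pm_re_calls(mi.quants_to_rr_table(quants, "primary"),
                        mi.quants_to_rr_table(quants, "metastasis"))
    report["mirna_altered"] = _check(
        "pair altered fraction", sum(c.altered for c in pm), len(pm), 0.8)

    print("\nRPPA altered pairs (per-pathway 0.5 designed, 200 pairs):")
    design = SimulationDesign(
        n_pairs=200,
        rppa_pathway_probs={p: 0.5 for p in rp.DEFAULT_PATHWAY_MAP})
    measurements, pairs, _ = generate_rppa_cohort(design, SEED)
    psummary = rp.pair_and_population_summary(rp.pathway_calls(
        rp.collapse_isoforms(rp.alteration_calls(measurements, pairs))))
    # a pair is altered when >= 3 of its 6 independently-drawn pathways are
    implied = float(1 - binom.cdf(2, 6, 0.5))
    report["rppa_pair_altered"] = _check(
        "profile-altered fraction", int(psummary.pair_altered.sum()),
        len(psummary.pair_altered), implied)

    report["seed"] = SEED
    mio.write_reports(report, "results/recovery")
    print("\nwrote results/recovery/")


if __name__ == "__main__":
    main()
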