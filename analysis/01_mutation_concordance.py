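"""Mutation-level concordance of the 22 primary/metastasis pairs.

Runs the packaged mutation table through presence/absence concordance and
per-gene frequency summaries, then applies the complement-null proportion
test to the discordant heterogeneity-status counts (41 of 58 mutant
alleles; the abstract's alternative count of 40 is tested alongside).
Per-locus heterogeneity scores require the supplementary allele
frequencies, which are not printed, so HS scoring itself is exercised on
synthetic cohorts in ``04_parameter_recovery.py``.

Writes results/mutations/.
"""

from metconcord import heterogeneity as het
from metconcord import io as mio
from metconcord.stats import one_proportion_z


def main() -> None:
    calls, case_ids = mio.table1_mutation_calls()
    conc = het.mutation_concordance(calls)
    freqs = het.gene_frequencies(calls, case_ids)

    print(f"{conc['total_loci']} mutation loci across {len(case_ids)} pairs")
    print(f"  identical in both tumours : {conc['identical_loci']}/{conc['total_loci']}"
          f" ({100 * conc['identical_loci'] / conc['total_loci']:.0f}%)")
    print(f"  private to the primary    : {conc['private_primary']}")
    print(f"  private to the metastasis : {conc['private_metastasis']}")
    print(f"  mutations detected        : {conc['mutations_primary']} primary,"
          f" {conc['mutations_metastasis']} metastatic")
    print("\nper-gene case frequencies (either tumour of the pair):")
    print(freqs.to_string(index=False))

    tests = {}
    for label, (k, n) in {"results_41_of_58": (41, 58),
                          "abstract_40_of_58": (40, 58)}.items():
        res = one_proportion_z(k, n, "complement", "three_decimals")
        tests[label] = res.to_dict()
        print(f"\nheterogeneity-status discordance {k}/{n}: "
              f"z = {res.z:.3f}, difference = {res.difference:.3f}, "
              f"p = {res.p_value:.2e}")

    mio.write_reports({"gene_frequencies": freqs,
                       "concordance": conc,
                       "discordance_tests": tests},
                      "results/mutations")
    print("\nwrote results/mutations/")


if __name__ == "__main__":
    main()
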