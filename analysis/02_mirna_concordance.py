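"""miRNA expression concordance between primary tumours and metastases.

Two complementary views over the 21 pairs x 6 miRNAs:

1. category agreement - Cohen's kappa per miRNA on the packaged
   high/normal/low category table;
2. pair-level alteration - PM-RE ratios from the packaged
   relative-expression table, a two-fold alteration cut-off, the
   complement-null proportion test per miRNA with BH adjustment, and the
   overall 50%-of-pairs-in-50%-of-miRNAs discordance rule.

Writes results/mirna/.
"""

from metconcord import io as mio
from metconcord import mirna as mi


def main() -> None:
    table2 = mio.load_fixture("table2")
    kappas = mi.concordance_by_mirna(table2)
    print("category concordance (Cohen's kappa):")
    for mirna, k in kappas.items():
        if k.defined:
            print(f"  {mirna:9s} kappa = {k.kappa:6.3f}  SE = {k.se:.3f}  "
                  f"95% CI = ({k.ci95[0]:.3f}, {k.ci95[1]:.3f})")
        else:
            print(f"  {mirna:9s} undefined (one tumour group used a single "
                  f"category; po = pe = {k.po:.3f})")

    table3 = mio.load_fixture("table3")
    calls = mi.pm_re_from_ratios(table3, cutoff=2.0)
    counts = mi.altered_counts(calls)
    tests = mi.pm_re_tests(counts, len(table3))
    overall = mi.overall_discordance(calls)

    print("\naltered PM-RE (>= 2-fold change in either direction):")
    for row in tests.itertuples(index=False):
        print(f"  {row.mirna_id:9s} {row.altered:2d}/{row.n} pairs  "
              f"z = {row.z:6.3f}  p = {row.p_value:.4g}  "
              f"adjusted p = {row.p_adjusted:.4g}")
    print(f"\naltered fractions span "
          f"{100 * overall.fractions.min():.2f}-{100 * overall.fractions.max():.2f}% "
          f"of pairs across the {overall.n_mirnas} miRNAs")
    verdict = "DISCORDANT" if overall.discordant else "concordant"
    print(f"overall miRNA expression between the tumour groups: {verdict} "
          f"({overall.n_majority}/{overall.n_mirnas} miRNAs altered in >= half the pairs)")

    mio.write_reports({
        "pm_re_tests": tests,
        "kappa": {m: k.to_dict() for m, k in kappas.items()},
        "altered_fractions": overall.fractions.to_dict(),
        "overall_discordant": bool(overall.discordant),
    }, "results/mirna")
    print("\nwrote results/mirna/")


if __name__ == "__main__":
    main()
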