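# Methods

This package implements a three-layer concordance analysis between
primary tumours and their matched metastases: somatic-mutation
heterogeneity, miRNA expression, and RPPA protein pathways.  This note
records the models, the conventions behind every cut-off, the numerical
choices, what the synthetic cohorts do and do not emulate, and the
design decisions that were genuinely open.

## Mutation heterogeneity

For a mutation with mutant allele fraction `MAF` in a sample with tumour
cellularity `TC` (percent of cells that are tumour cells), the
heterogeneity score is

    HS = MAF × 2 / (TC/100).

A heterozygous mutation carried by every tumour cell in a pure diploid
sample gives MAF = 0.5 and HS = 1.  The score is mapped onto background
statuses: `WT` at exactly 0; `STC` (subpopulation of tumour cells) on
(0, 0.95); `ATC` (all tumour cells) on the closed band [0.95, 1.05];
`CNV` (copy-number-variation background) above 1.05.  Closing the ATC
band makes the three positive ranges a partition (property-tested over
the whole MAF × TC domain).  `WT` takes precedence at HS = 0 even though
0 < 0.95.  HS is not capped: values above 2 are legal (amplified mutant
allele) and simply reported.

Paired change calling: a category flip between primary and metastasis is
an *inter-status* change; the same category with |ΔHS| ≥ 0.5 is an
*intra-status* change (0.5 is the shift expected if the whole tumour-cell
population gains or loses one allele copy); anything else is no change.
The discordant fraction (inter + intra) is tested with the
one-proportion z-test below.  The denominator defaults to loci mutant in
the primary tumour (the convention behind the published 41-of-58 count);
a union-of-loci denominator is selectable.

MAFR (mutant allele frequency ratio) divides each mutation's MAF by the
MAF of a per-sample driver, cancelling cellularity.  The driver policy —
highest-MAF mutation among the trunk-driver genes {APC, KRAS, NRAS,
BRAF}, falling back to TP53 as the branching driver — is a documented
package decision (the upstream procedure is cited but not specified in
the source material) and is configurable by gene list.

## Statistical conventions

**One-proportion z-test.** `z = (p̂ − p0) / sqrt(p0(1 − p0)/n)`, two
sided against N(0, 1).  The null is the *complement* convention
`p0 = 1 − p̂` — the test asks whether the altered fraction differs from
the unaltered fraction.  This convention was reverse-engineered from the
published z-scores and reproduces all six miRNA values (1.323, 1.323,
2.247, 7.224, 5.636, 4.347) at full precision.  A fixed-p0 mode exists
for conventional use.  A second compatibility switch rounds both
proportions to three decimals *before* the formula, reproducing
spreadsheet-derived values: 41/58 gives z = 6.923 at full precision but
6.927 (difference 0.414) after rounding.  Degenerate nulls (p0 ∈ {0,1})
raise; the discordance summary maps its two boundary cases (no loci or
all loci discordant) to z = ∓∞ with p = 0.

**Cohen's kappa.** From the 3×3 (or general square) contingency of
paired category calls: `κ = (po − pe)/(1 − pe)` with po the trace
fraction and pe the margin product.  The standard error is the Fleiss
large-sample estimate (delegated to `statsmodels`); 95% CI = κ ± 1.96 SE.
This combination reproduces the published SEs and CIs exactly where the
point estimate itself is reproducible.  κ is reported *undefined* when
either margin is constant — one rater used a single category, so
po = pe identically and chance-corrected agreement carries no
information.  This is precisely the situation of the miRNA21 column
(every primary tumour LOW, 7 of 9 cells empty) and subsumes the pe = 1
single-cell case.

**Benjamini–Hochberg.** Step-up FDR adjustment
(`adj_(i) = min_{j≥i} m·p_(j)/j`, capped at 1, returned in input order;
delegated to `statsmodels`, brute-force-verified in the tests).  Equal
raw p-values receive equal adjusted values, so tie order is irrelevant.

**Pearson correlation** is `scipy.stats.pearsonr` behind a validating
wrapper (n ≥ 3, non-zero variance).

## miRNA quantification

Two-step relative quantification against the RNU6B reference gene,
assuming doubling efficiency per cycle:

    ΔCt  = Ct(target) − Ct(RNU6B)
    ΔΔCt = ΔCt(tumour) − ΔCt(normal tissue)
    RR   = 2^(−ΔΔCt)

Ct replicates are averaged; a replicate SD above 0.5 cycles triggers a
warning (the assay QC bound).  The cellularity correction,

    ΔΔCt_tc = ΔΔCt − log2(100/TC)    ⇔    RR_tc = RR × (100/TC),

is applied per tissue.  The direction of this correction was an open
choice: the implemented sign treats stromal dilution as attenuating the
tumour signal, so dividing by the tumour-cell fraction restores it; the
opposite sign is available via configuration.  It rests on two
assumptions inherited from the assay design: any tumour/normal ΔΔCt
difference is attributable to the tumour-cell fraction, and tumour cells
express the miRNA uniformly.

Expression categories: high at RR ≥ 2, low at RR ≤ 0.5, normal between
(boundaries inclusive).  An alternative 1.5/0.5 preset from a
pooled-normal calibration is provided but not default.  Pair-level
alteration uses PM-RE = RR_primary / RR_metastasis with a two-fold
cut-off in either direction (inclusive); PM-RE(a,b)·PM-RE(b,a) = 1 by
construction.  Per-miRNA altered counts are tested with the
complement-null z-test and BH-adjusted across the miRNA family.  Overall
expression is *discordant* between the tumour groups when at least half
the miRNAs are altered in at least half the pairs (both inclusive).

The two packaged miRNA fixtures are consumed independently: the category
table cannot be re-derived from the PM-RE table because the categories
come from per-tissue ratios that are not part of the PM ratio.

## RPPA pathway cascade

Per spot, relative expression = raw signal / total-protein signal.  The
metastatic value is corrected for the cellularity difference within the
pair, `E_m_tc = E_m × (1 + ΔTC/100)` with ΔTC = TC_primary −
TC_metastasis (sign chosen so a less cellular metastasis is scaled up).
A marker is altered in a pair when |E_primary − E_m_tc| strictly exceeds
the marker's sample SD (n−1) over the whole population — both roles
combined, computed after TC adjustment (both were open choices; per-role
SD and pre-adjustment variants exist but are off by default).  Ties at
exactly one SD are not altered.  Direction is relative to the
metastasis (up = metastasis higher) and flips antisymmetrically under
role swap.

The cascade then applies inclusive majority rules: isoforms/modified
forms collapse onto parents ({P85, P110}→PI3K, {PTEN, phosphoPTEN}→PTEN,
{pAKT-ser, pAKT-thr}→AKT; all others map to themselves; the union is
idempotent and monotone); a pathway is altered when ≥ 50% of its
collapsed markers are; a pair's profile is altered when ≥ 50% of its
pathways are; the populations differ when ≥ 50% of pairs have altered
profiles.  Six pathway groups are used (CAM-EMT; RAS-RAF-MEK;
PI3K-AKT-PTEN; TGFB-SMAD4; apoptosis; transcriptional mis-regulation) —
the source material announces seven but lists and analyses six.  The
grouping is a static, overridable map.  The TGFB receptor marker appears
under two spellings; both resolve to one stored marker.  Method
validation computes kappa of alteration status between eight
isoform/functionally-related marker pairs.

## Synthetic cohorts

Each generator inverts its analysis stage, so zero-noise designs are
recovered exactly and noisy designs are recovered within exact binomial
intervals (the package's parameter-recovery tests).

* **Mutations**: a designed background status fixes a target HS inside a
  finite sampling band (STC 0.3–0.9, ATC 0.95–1.05, CNV 1.1–1.7);
  MAF = HS × (TC/100)/2, truncated to [0.01, 0.99] for present
  mutations.  With the designed discordance probability the metastasis
  status is redrawn from the other statuses; concordant loci wobble by
  at most ±0.1 within the band, well below the 0.5 change threshold.
  Designs whose bands would require MAF > 0.99 are rejected up front.
* **Ct values**: target Ct = reference Ct (18.0) + baseline ΔCt −
  measured log2 fold + Gaussian replicate noise, where the measured fold
  is the true fold *plus* log2(TC/100) — the dilution that the
  pipeline's 100/TC correction undoes.  The designed
  primary-vs-metastasis log2 effect is carried by a designed fraction of
  pairs.
* **RPPA**: log-normal relative expressions (σ = 0.25 log-scale); when a
  pathway is designated altered (probability π per pathway), every form
  of each member parent is shifted by 3 dispersion units with a shared
  per-parent sign; the emitted metastatic value is divided by the TC
  factor the pipeline will reapply.  The pair-level design value implied
  by independent per-pathway draws is P(Binom(6, π) ≥ 3).

Default design values mirror the reference study's observed conditions:
21 pairs, cellularity 40–90%, locus discordance 0.7, two-fold miRNA
effects in 70% of pairs at 0.2-cycle noise, π = 0.65 per pathway.
Determinism: one `numpy` Philox/PCG stream per generator derived from
the master seed and a fixed stream id, so regenerating one data type
never shifts another's draws; identical (design, seed) gives
byte-identical files.

What the generators do **not** emulate: sequencing reads or depth-driven
MAF uncertainty, primer-efficiency differences between assays (the ΔΔCt
efficiency is exactly 2), correlated marker co-variation within
pathways, batch or slide effects, and real biological heterogeneity
beyond the analysis models' own assumptions.  Passing recovery tests
therefore show the pipeline is self-consistent and correctly inverts its
stated models — not that those models capture every property of real
FFPE-derived data.

## Packaged fixtures and their limits

The three in-text tables ship as plain-text fixtures: the 60-locus
mutation presence/absence table over 22 pairs, and the 21-pair × 6-miRNA
category and PM-RE tables.  The mutation table carries no allele
frequencies (those live only in supplementary material), so
fixture-based acceptance is limited to presence/absence statistics, and
the printed discordant-allele counts (41/58, and the abstract's
alternative 40/58) enter the proportion test as direct numeric inputs.
One garbled source row (case 4, CDH1) is transcribed as
primary-present/metastasis-wild following the accompanying narrative.
Two printed gene-level summaries (a KRAS case percentage of 36% and a
TP53 mutation total of 23) contradict the printed table itself, which
contains KRAS mutations in 9/22 cases (41%) and 22 TP53 mutations; the
fixtures follow the table, and the corresponding acceptance assertions
are deliberately left failing rather than adjusting either source.
Recomputed kappas for three miRNA columns (20a 0.192, 29a 0.372, 31
0.404) differ in the third decimal from the published 0.185/0.382/0.400,
suggesting the published contingency tables differed slightly from the
printed category table; only the two exactly-reproducing columns
(miRNA224 0.236, miRNA92 0.049) are asserted.

## Problem sizes

All fixture-based analyses are desk-scale (21–22 pairs) and run in well
under a second.  Recovery analyses use 500 loci (100 pairs × 5 loci),
100 pairs × 1 miRNA, and 200 RPPA pairs — sizes at which an exact 95%
binomial interval is a few percentage points wide, tight enough to
detect an inversion error while keeping the whole suite fast.

## Known limitations

* Kappa SEs use the Fleiss large-sample formula; exact or bootstrap
  intervals are out of scope, as are weighted kappa and exact binomial
  proportion tests (none are used by the analyses).
* CNV here is a label derived from HS alone; no copy number is inferred
  from sequencing depth.
* VCF ingestion reads allele fractions (INFO/AF, FORMAT/AF or AD); it
  does not re-call variants or parse annotation transcripts beyond an
  optional `GENE` INFO tag.
* Clinicopathological covariates are not modelled; no analysis in scope
  consumes them.
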