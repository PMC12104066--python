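# Methods

## Scope and data model

`ecscreen` implements the *downstream* half of an expanded carrier
screening (ECS) study: it starts from classified variant calls (one row per
observed allele per participant, already assigned an ACMG class) and a gene
panel, and ends with cohort epidemiology. Read alignment, variant calling,
ACMG classification, and the disambiguation of highly homologous regions
(*SMN1/SMN2*, *CYP21A2/CYP21A1P*, *HBA1/HBA2*) are upstream concerns: calls
arrive already resolved.

Four record types carry the analysis: `PanelEntry` (gene, AR/XLR
inheritance, condition, one of twelve disease categories, and a registry of
low-penetrance alleles), `Participant` (sex, age, ethnicity, screening
indication subgroup, couple id), `VariantCall` (gene, allele, SNV / indel /
exon-level CNV / structural CNV allele, het / hom / hemi zygosity, ACMG
class), and the validated `Cohort` container. Files are UTF-8
tab-separated tables with `.` for missing optional fields; alpha-globin
structural haplotypes printed with superscripts (αα/--^SEA^) are normalised
to an ASCII vocabulary (`--SEA`, `--THAI`, `-a3.7`, `-a4.2`, `HKaa`)
storing only the non-reference allele. A minimal VCF ingestion path exists
(gene and class from `GENE`/`ACMG` INFO keys) but TSV is primary.

## Variant prioritization

The filter chain is an ordered, configurable rule list. Two rules are
built in — panel membership, then ACMG class ∈ {P, LP} — with a hook for
additional rules; each dropped call carries exactly one machine-readable
reason (the first failing rule). We deliberately did not invent further
filters (allele-frequency or consequence-based): calls arrive classified,
so class and panel membership are the only defensible criteria.

Low-penetrance alleles — common alleles with a reduced probability of
causing disease, shipped in the default registry as *GJB2* c.109G>A,
*UGT1A1* c.1091C>T and *HFE* c.187C>G — are **flagged, not dropped**.
Downstream statistics take an include/exclude switch so both unadjusted
and adjusted rates can be reported from one filtered set.

## Carrier statistics

* A *carrier* is a participant with ≥ 1 retained call. Carrier rate and
  mean burden per sample (MBP = retained calls / subset size) are defined
  over any subset predicate; an empty subset raises rather than silently
  returning 0/0.
* Per-gene summaries report both a zygosity-weighted **allele count**
  (het/hemi = 1, hom = 2) and a per-person **carrier count**; panel
  literature prints both views side by side, and they answer different
  questions (allele frequency vs. screening yield).
* Carrier-frequency denominators follow inheritance: the whole cohort for
  autosomal genes, females only for XLR genes, since hemizygous males are
  affected rather than carriers. Hemizygous male calls are validated
  (XLR genes, males only) and surfaced as informational records.
* "1 in N" is `round_half_away_from_zero(denominator / carriers)`, null at
  zero carriers.
* Cumulative carrier rate over a gene set: `CCR = 1 − Π_g (1 − cf_g)`,
  assuming independence across genes; bounded by `[max cf, Σ cf]`,
  order-invariant, and monotone in every frequency (property-tested).
* Hardy-Weinberg incidence projection: with carrier frequency cf and the
  rare-allele approximation q = cf/2, AR birth incidence is q² and XLR
  male birth incidence is q. Because cf as measured includes homozygotes,
  an exact-HWE alternative q = 1 − √(1 − cf) is available behind a flag;
  for the frequencies seen in carrier screening (cf ≤ 0.2) the two differ
  by at most a few percent relative.

## At-risk couples

A couple is at risk through either of two mechanisms: both partners carry
a retained P/LP variant in the **same AR gene** (offspring risk 1/4), or
the **female** carries a P/LP variant in an **XLR gene** (risk recorded as
1/2; whether that figure is per pregnancy or per male pregnancy is a
reporting convention we document rather than resolve). Matching is by gene
symbol, not allele — trans/cis phasing is outside a screening report's
scope. Design choices, switchable where sensible:

* Low-penetrance alleles do not qualify a couple by default (they are not
  reportable for reproductive risk).
* Homozygous female XLR carriers are the same mechanism with a
  `female_homozygous` flag, not a separate class.
* A hemizygous male partner signals an affected partner, not a carrier
  couple; it is reported separately and never as an ARC.

The analytic expectation under gene- and partner-independence,
`P(ARC) = 1 − Π_AR (1 − cf_g²) · Π_XLR (1 − cf_g)`, serves as the oracle
against which simulated cohorts are checked.

## Contingency statistics

Pearson's χ² is computed from the O/E formula with expected counts from
the product of marginals; the p-value kernel is the regularized upper
incomplete gamma Q(df/2, x/2). The Yates continuity correction
(|O−E| → max(|O−E|−0.5, 0), 2×2 only) is always computed alongside the
uncorrected statistic: published screening tables sometimes mix the two
conventions (statistics matching the uncorrected formula next to p-values
matching the corrected one), so reports emit both with a footnote instead
of guessing intent. Group means are compared with Welch's unequal-variance
two-sided t-test (no variance-homogeneity assumption is defensible for
screening subgroups). Implementations are cross-checked in the test suite
against scipy's independent routines and, for the t-test, an exact
permutation oracle.

## Synthetic cohorts

The generator draws, per autosomal gene, independent Bernoulli carrier
status at the gene's carrier frequency for every participant; carried
alleles come from the gene's allele mix; homozygosity given carriage uses
the HWE-consistent conditional q²/(1−(1−q)²) with q = 1 − √(1 − cf) unless
overridden. XLR genes are sampled in females only (male hemizygotes
optional, default off). Couples are paired randomly within subgroup. One
root seed feeds per-gene substreams keyed by a stable hash, so adding a
gene never perturbs another gene's draws; identical seed and configuration
give byte-identical output files.

What the generator deliberately does **not** model: linkage and gene-gene
correlation, consanguinity and assortative mating, ethnicity-stratified
frequencies, VUS calls, sequencing error, and within-gene compound
heterozygosity in one person (each carrier draws one call per gene).
Passing tests therefore demonstrate the correctness of the *analysis* under
the independence model the estimators themselves assume — not robustness
to the correlation structure of real populations.

The study-replica configuration measures per-gene carrier frequencies and
allele mixes from the reference cohort (below); the frequencies sum to
≈ 1.16 expected variants per sample, giving a simulated carrier rate of
≈ 69% at the published cohort size.

## The reference cohort

The deterministic reference cohort reconstructs a published 220-couple
(440-participant) regional pilot cohort from its aggregate tables alone:
subgroup sizes (79 genetic-screening couples; 20 infertility, 94
spontaneous-abortion, 27 late-abnormality couples), per sex × subgroup
carrier and variant counts (304 carriers, 511 retained P/LP calls), the
per-gene allele totals of the high-frequency genes (88 *GJB2* alleles of
which 78 are c.109G>A; 8 female *G6PD* calls including one homozygote),
the full CNV genotype table (43 CNV calls; alpha-globin mix 14 ×
`--SEA` / 7 × `-a3.7` / 2 × `-a4.2`), and the 14 at-risk couples
(6 AR-shared-gene: *ARSA*, *SMN1*, *SLC26A4*, *GALC*, *PAH*,
*HBA1/HBA2*; 8 *G6PD*; split 5 GS / 9 MAR). Individual-level assignment of
the remaining low-frequency calls is not published; a deterministic greedy
procedure distributes them so that every published marginal is met while
no unintended at-risk couple arises (partners never share a gene outside
the six designated couples) and no female outside the designated eight
carries an X-linked variant. The panel is a synthetic stand-in: genes
named in the published tables carry their real conditions and categories,
the remainder are real recessive-disease genes or clearly marked
placeholder symbols.

Two published quantities resist exact reconstruction and are documented
rather than forced. The carrier burden histogram percentages
(51.64 / 34.54 / 9.54 / 4.28 over 304 carriers) imply 506 calls, which
contradicts the published total of 511; the reconstruction keeps the
totals exact and the 2- and 3-variant classes at the printed proportions,
leaving the 1- and 4-variant classes within 0.4 percentage points.
Similarly, a handful of printed per-condition "1 in N" integers cannot be
derived from the printed allele counts (e.g. an adjusted rate of 1/444 in
a 440-person cohort); per-gene summaries are always recomputed from the
cohort's own counts.

## Numerical and testing choices

* Percentages print to 2 decimals; "1 in N" rounds half away from zero.
* χ² agreement with the scipy oracle is asserted to 1e-10 on random small
  tables; published statistics to ±0.005 and p-values to ±0.002.
* Simulation-based checks use fixed seed sets and standard-error bands at
  the 99% level: parameter recovery over 100 seeds at 250 couples
  (≥ 99% of (seed, gene) trials within 3 binomial σ), ARC convergence over
  25 cohorts of 2,000 couples against the analytic expectation. These
  problem sizes keep the default suite under ten seconds while leaving the
  Monte-Carlo bands well-powered.
* Degenerate inputs fail loudly: empty rate denominators, zero table
  marginals, frequencies outside [0, 1], non-paired participants in couple
  analyses (skipped with a logged warning).

## Known limitations

* ARC detection is gene-level; two variants in *cis* in one partner would
  still count, and allele-level phasing is out of scope.
* The incidence projection assumes random mating and a closed population;
  it is a screening-programme planning number, not a clinical risk.
* The reference cohort is a *statistical* replica: analyses that depend on
  individual-level co-occurrence beyond the published marginals (e.g.
  which exact participant carries which filler variant) are arbitrary
  within the published constraints.
* Residual risk after a negative screen (Bayesian update on test
  sensitivity) is not computed.
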