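# Methods

`teimmune` re-implements, as a tested pipeline, a population-genetics
screen for candidate adaptive transposable element (TE) insertions near
immune genes in *Drosophila melanogaster*, together with the downstream
functional analyses: allele-specific expression (ASE) from
pyrosequencing allele counts, infection-survival comparison, qPCR
relative expression and ChIP-qPCR enrichment. A synthetic-data module
generates every input with the statistical structure the analyses
assume, so the whole pipeline can be validated without wet-lab data.

## Screening model

The screen starts from a reference TE annotation (5416 insertions at
reference scale) and removes, sequentially: INE-1 elements (an ancient
family fixed in the species, uninformative for adaptation),
repeat-flanked / nested / segmental-duplication insertions (their
presence/absence cannot be called reliably from short reads), and
insertions whose midpoint lies in a zero-recombination interval of
either of two recombination-map dialects. Sequential exclusion is
deliberate: each step's count refers to insertions surviving the
previous steps, so catalog size minus the three step counts equals the
retained count. The either-map rule for zero recombination is the
default; a both-maps rule is available (`zero_recomb_rule="both"`)
because published map dialects disagree at region edges.

Population frequency is estimated per (TE, population) as
`present / (present + absent)` over called strains; all-missing cells
are reported as undefined, never as zero. A TE is *fixed* when its
frequency is exactly 1 in every population with a defined frequency (no
tolerance — the estimator is a ratio of integer counts). Candidates are
the non-fixed TEs with frequency >= 0.10 (inclusive threshold) in at
least one population. Candidate sets are monotone in the threshold by
construction. De novo (non-reference) insertions pass a separate
pre-filter: present in >= 15 strains of a 177-strain panel and
PCR-verified, then the same frequency threshold on count/177.

Gene assignment is strand-aware on 1-based inclusive coordinates: every
gene with < 1000 bp between spans (gap 0 on overlap) is associated;
with none in the window, the nearest gene (all of them on an exact
distance tie) is used. Overlapping TEs are classified exon / UTR /
intron from transcript CDS structure; non-overlapping ones 5'/3' from
the gene strand. Candidates are intersected with input immune-evidence
flags; the literature curation behind those flags is input data, not
computed here.

## ASE model

For a cross heterozygous for a TE, reads are assigned to alleles at a
diagnostic SNP that must be synonymous in, and inside the CDS of, every
alternative transcript, and heterozygous between the crossed strains.
SNPs in panel-wide perfect association with TE presence are avoided
when possible, and nonsynonymous-coding or conserved-flank variants in
perfect association are reported as confounders ("perfect association"
operationalises the linked-variant check: allele vector equal to the TE
presence vector or its complement across all called strains).

The statistic is the gDNA-normalised ratio
`(cdna_te/cdna_ref) / (gdna_te/gdna_ref)`: the gDNA of a heterozygote
carries both alleles 1:1, so its measured ratio estimates the
PCR-amplification bias, which cancels. Replicate log2 ratios are tested
against 0 with a one-sample two-tailed t (df = n-1), and corrected with
Benjamini-Hochberg at 5% FDR within each condition (the two conditions
are summarised separately; `fdr_family="all"` widens the family). Zero
allele counts are a hard error by default with an optional Haldane
+0.5 on all four counts; zero replicate variance yields p in {0, 1}
with a degenerate flag rather than NaN. ASE prevalence against
literature values uses a two-sided Fisher exact test with the reference
counts as explicit parameters.

**Limitation.** When the gDNA assay is measured once per cross (the
experimental design — pooled heterozygous females), the three replicate
ratios share its sampling error, which the t-test ignores; at
pyrosequencing depths of ~1e4 this inflates the type-I rate severalfold
above nominal. The calibration simulations therefore use independent
gDNA noise per replicate (iid ratios), for which the small-sample t is
essentially exact; per-replicate gDNA can also be supplied in real data
(`gdna_per_replicate`).

## Survival model

Kaplan-Meier curves use the product-limit estimator (censoring
supported even though fly assays are usually monitored to completion);
two-group comparison is the standard observed-minus-expected log-rank
with a 1-df chi-square, treating flies as independent. Vial structure
is carried through and an optional whole-vial permutation p-value is
available as a clustering robustness check. The effect size is the odds
ratio of death from the 2x2 dead/alive table at t*, the first observed
time at which the *susceptible* group (lower KM survival at the last
common time, overridable) reaches the stated cumulative mortality (0.50
default; per-comparison overrides such as 0.30 or 0.96 accepted).
Interpolation between monitoring times is deliberately not done. The CI
is the Woolf interval `exp(ln OR +/- 1.96*sqrt(sum 1/cell))` with a
Haldane +0.5 on any zero cell, flagged. Flies censored strictly before
t* are excluded from the table.

## qPCR and ChIP model

Relative expression is `2^-(Ct_target - Ct_reference)` against a
housekeeping reference; all inference runs on log2 relative quantities
(variance stabilising for multiplicative qPCR error). Contrasts use the
Welch t by default (pooled variance optional); the genotype x treatment
analysis is a 2x2 ANOVA with interaction fitted as a linear model with
sum-to-zero contrasts — on balanced designs the sum-of-squares
decomposition is unambiguous. Primer efficiency is accepted as QC
metadata only, not corrected for. The percentage of total gene
expression contributed by TE-initiated transcripts is
`100 * te / total`; because the two are separate assays, overshoot up
to 20% (configurable) is capped at 100% with a flag.

ChIP enrichment normalises each IP against its own input:
`2^-(ct_IP - (ct_input + log2(input_fraction)))`; with
`input_fraction=1` (default, the aliquot fraction being unreported)
this is plain dCT, with the true fraction it is the percent-of-input
form. QC requires the enriched control locus (18S-like) to exceed the
depleted one (Rpl32-like); a failure warns prominently but does not
abort. Strain contrasts are Welch t on log2 enrichment per flank and
flip sign exactly under strain-order swap.

## Synthetic cohort

One global seed; each generator draws from a deterministically derived
substream, so a fixed `SimConfig` reproduces the cohort bit for bit.
True parameters are always emitted as sidecar tables (true frequencies,
true cis effects, true hazard ratios), giving every stage a recovery
oracle.

* **Catalog / maps.** Each TE belongs to exactly one cascade category
  (INE-1 / repeat-flanked / zero-recombination / clean), multinomial at
  the reference-annotation fractions 2234/5416, 1561/5416, 813/5416, or
  exact with `category_counts`. Zero-category TEs are placed inside the
  proximal rate-0 block (default 20% of each arm, pericentromere-like);
  both map dialects share the block boundary with different tile sizes
  and nonzero rates.
* **Genotypes.** A mixture component per TE — rare (U(0.005, 0.095) per
  population), high (U(0.10, 0.60)), or fixed — with masses 0.58 /
  0.135 / 0.285 taken from the observed proportions of the annotated
  set (231/808 fixed, 109/808 high); Bernoulli strains, missing calls
  at 5%. Realized candidate counts on synthetic cohorts exceed the
  nominal high mass because estimation noise at panel sizes of tens of
  strains, maximised over four populations, promotes borderline rare
  TEs past the threshold — a property real panels share.
* **Pyrosequencing.** Exchangeable-read binomials: gDNA TE-allele count
  ~ Binomial(depth, b/(b+1)), cDNA ~ Binomial(depth,
  b·2^beta/(b·2^beta+1)), with bias b shared between the assays of a
  cross and the cis effect beta acting on cDNA only. The binomial model
  is the simplest one consistent with a multiplicative per-assay bias
  (no published read-count model exists for these assays). Depth
  defaults to 2000 reads — a realistic pyrosequencing order of
  magnitude; it is a config knob, not an inferred value.
* **Survival.** Weibull death times, S(t) = exp(-r (t/scale)^shape)
  with r the product of genotype and (if infected) treatment hazard
  ratios (defaults 2 and 8; scale 60 h, shape 2), ceiled to the
  monitoring grid (interval monitoring), censored past the last check.
  Ten flies per vial, 8 vials per arm by default.
* **Ct.** Ct = baseline - log2(quantity) + N(0, sd), baseline 22,
  sd 0.2; the housekeeping reference has fixed quantity 1; ChIP designs
  emit paired IP/input Cts plus enriched/depleted control loci.

What the generator does **not** emulate: read-level sequencing error,
pyrogram signal processing, overdispersion between biological
replicates beyond binomial/Gaussian noise, vial-level frailty in
survival, or linkage between TEs. Passing tests therefore show the
statistics are implemented correctly and calibrated under the assumed
noise models — not that those models capture all structure in real fly
data.

## Problem sizes and checks

The test suite exercises the cascade at the full 5416-TE annotation
scale and runs calibration simulations at 2000 ASE assays (depth 1e4),
200 replicates per cis-effect level (depth 1e5), and 1000 equal-hazard
survival simulations; `scripts/acceptance.py` recomputes the same
quantities at those sizes from a user-supplied seed. Oracles are kept
independent of the implementation: brute-force set subtraction for the
cascade, an enumeration over SNPs for diagnostic-SNP selection, the
step-up definition for BH, hand product-limit / O-E-V / Woolf formulas
for survival, and a hand sum-of-squares decomposition for the 2x2
ANOVA. The study's published per-TE frequency table and replicate
allele-ratio table are not redistributed here; the tests that would
recompute the printed candidate and significant-gene counts from them
run whenever those tables are placed under `tests/data/`.
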