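# Methods

## The analysis model

The pipeline asks, per variant, whether a focal population's allele and
genotype frequencies are compatible with those of a pooled reference formed
from every other population/region.  The data model is deliberately simple:
each label contributes a diploid genotype triplet (hom-REF, het, hom-ALT) per
variant; allele counts are always derived from genotypes (REF = 2·homref +
het, ALT = 2·homalt + het).  The VCF side publishes allele-level fields, and
the genotype distribution is reconstructed exactly from (AN, AC, nhomalt):
`homalt = nhomalt`, `het = AC − 2·nhomalt`, `homref = AN/2 − het − homalt`.
This reconstruction is this package's choice: allele-level catalogues do not
publish genotype triplets directly, but the three fields determine them
uniquely for diploid autosomal sites.

Differences among the non-focal populations are deliberately ignored: the
pooled "others" row treats the reference labels as one population.  The test
is therefore sensitive to focal-vs-rest departures, not to structure within
the reference pool.

## Integration rules

- **Merge**: inner join on the exact (chrom, pos, ref, alt) key, 1-based
  GRCh37, autosomes only, biallelic SNVs only (multi-allelic lines and
  indels are skipped at read time and counted).  Duplicate keys within one
  catalogue are errors; labels must be unique across catalogues.
- **Missingness**: a label absent for a variant (missing INFO keys, or a `.`
  cell) is excluded from both the frequency filter and the others-pool for
  that variant — it is treated as "no data", not as zero counts.  Variants
  with an absent focal cell are dropped right after the merge, since no
  focal-vs-rest comparison exists for them; this also keeps every annotated
  variant testable.
- **Common-variant filter**: keep a variant when its ALT frequency strictly
  exceeds the threshold (default 0.01) in at least one non-absent label.
  The `all` mode (every label above threshold) is available as a config
  switch, but `any` is the default: several SNPs in the published result
  table have ALT frequencies at or near zero in most labels and would be
  removed by the `all` rule, contradicting the published set of 18 tested
  SNPs.  ALT frequency (not folded minor-allele frequency) is filtered,
  matching the semantics of the AN/AC fields.
- **Filter order**: the frequency filter runs before the clinical
  intersection, matching the published variant-count funnel.
- **Clinical intersection**: inner join on the variant key; duplicate
  annotations produce duplicate result rows; significance strings are kept
  verbatim.  A SNP is *clinically significant* when its label is in a
  configurable set, default {"risk factor", "drug response"}.

## Statistics

**Expected counts.** `E_j = (focal total) · others_j / (others total)`,
for the allele pair and genotype triple alike.  The expected row sums to the
focal total by construction (tested to 1e-9).  An all-absent reference pool
raises "no reference population" from `expected_counts`; the aggregation
layer converts that degenerate case to NaN expecteds, and the exact tests
return p = 1 on the degenerate margin, so the pipeline never crashes on it.

**Exact tests.** Both tests condition on the table margins.  The 2×2 test
enumerates the hypergeometric support directly; the 2×K test (K = 3 for
genotypes) enumerates the K−1 free cells of the smaller-total row, bounded
by the column margins — at focal totals of a few hundred this is at most a
few tens of thousands of candidate tables.  Point probabilities use
log-gamma arithmetic, so reference pools of 10^5–10^6 alleles lose no
precision.  The two-sided p-value follows the probability-mass convention:
the sum of point probabilities not exceeding the observed one, with a
relative tie tolerance of 1e-7 (the convention used by mainstream
implementations); when every table qualifies the p-value is exactly 1.  The
2×K path reduces exactly to the 2×2 path at K = 2.

One property worth stating precisely: for fixed margins the p-value is
monotone in the observed table's point probability (it is by construction).
It is *not* in general monotone in the distance between the focal counts and
the others-proportion — with small margins the hypergeometric mode can sit
away from the row-proportion point, so moving the focal counts "toward
expectation" can lower the p-value.  The tests assert the point-probability
monotonicity, which is the statement that actually holds.

**Multiple testing.** Benjamini–Hochberg step-up at q = 0.05, applied
separately to the allele-test family and the genotype-test family (each
family's m is the number of tested SNPs).  Ties share a fate.  SNPs with
degenerate tables (p ≡ 1) remain in the family, matching the published count
of 18 tested SNPs.

**Residuals.** Haberman's adjusted standardized residuals on the full 2×K
observed table with independence expecteds derived from its margins,
computed only for BH-significant SNPs.  On a 2×2 table each squared residual
equals the Pearson chi-square statistic — the identity the tests use as an
oracle.  Cells with zero expected value (or a margin equal to the grand
total) have no defined residual and are reported as NaN.  The report exposes
the focal row; the published figures correspond to its signs.

## Synthetic cohorts

`simulate_cohort` emulates the integrated data: per variant a baseline ALT
frequency is drawn from Beta(0.2, 2) — a rare-heavy, exome-like spectrum —
and every label draws its genotype triplet multinomially from Hardy–Weinberg
proportions ((1−p)², 2p(1−p), p²) at its frequency.  Only the focal label
can deviate, through planted per-variant frequency deltas (clipped to [0, 1]
with a warning).  Defaults are the study conditions used throughout the
tests: 8 VCF populations plus 7 table regions, focal "Arabian_Peninsula"
with 171 individuals (the focal exome cohort's scale), 5 000 individuals per
reference label (a scaled-down stand-in for the real catalogues' much larger
cohorts; large enough that the pooled reference dominates the focal cohort's
sampling noise), 2 % per-cell missingness (the published table shows modest
per-variant call-rate loss), and an annotation overlay of 3.6 % (18 of 500
variants), with significance labels drawn in the proportions of the 18-SNP
reference annotation table.  Planted variants are always annotated, so
power is measured on variants that reach the test stage.  When
`rare_fraction` forces variants rare, their frequencies are drawn from
U(0.0001, 0.005) — comfortably below the 0.01 filter threshold, so
finite-cohort sampling noise cannot push a label across it.

What the generator does **not** model: linkage disequilibrium between
variants, demographic site-frequency-spectrum realism, inbreeding
(a consanguinity coefficient would make the focal hom/het balance a richer
stress test; the generator is HWE-only by design), or sequencing error.
Passing tests therefore demonstrate correctness of the integration and the
statistics under idealized random-mating sampling, not robustness to those
real-data features.

`table2_fixture` is the package's regression anchor: the focal column holds
the published observed genotype counts of the 18 reference SNPs, and the
reference pool is constructed at 250× the published expected proportions, so
the pipeline's recomputed expected cells land on the printed values.  Two
construction details matter.  First, the pool is split into a hom-REF pool
and an ALT-carrier pool; the carrier pool's ALT frequency is ≥ 0.5 whenever
any ALT allele exists, so all 18 SNPs pass the common-variant filter — as
they did in the published funnel — while the pooled proportions are
unchanged.  Second, the two SNPs with zero ALT alleles everywhere get a
2-individual hom-ALT spike in the carrier pool (shifting expected cells by
< 0.02, far below print rounding); without it no filter could retain them.
Because the true reference-cohort sizes behind the published expecteds are
unrecoverable, fixture p-values are close approximations of the published
ones (the borderline SNPs shift), so the BH marks are asserted on the
published p-values directly, and the fixture is held to the funnel
(18 tested) and the clinical intersection (exactly rs13266634 and rs5219).

## Numerical and interface choices

- All stored p-values keep full precision; only the report TSV rounds to
  three decimals ("0.000" means p < 0.0005).  Expected counts are shown at
  one decimal.
- The JSON report is deterministic (sorted keys) — identical inputs and
  config produce byte-identical files; NaN serializes as null.
- Problem sizes in the test suite and acceptance script (100 null cohorts
  and 20 planted-recovery cohorts of 500 variants each; exhaustive 2×2
  oracle comparison up to margins of 30; 200 random 2×3 oracle tables)
  were chosen so the full suite completes in about a minute while still
  exercising the large-margin code paths.
- Seeds fully determine every simulation; the acceptance script derives
  independent sub-seed streams from its single `--seed` argument.

## Known limitations

- Only autosomal biallelic SNVs; no X/Y/MT, no indels, no multi-allelic
  decomposition, no liftover between genome builds.
- The exact tests are conservative (discrete), so the null-calibration
  false-rejection rate typically sits below the nominal q.
- Clinical significance matching is exact string membership; real ClinVar
  exports with compound labels ("Benign/Likely benign") need the
  `clinical_labels` set adjusted.
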