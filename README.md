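# popdiff

Find disease-associated variants whose allele or genotype frequencies deviate
in one focal population, by integrating two population exome catalogues with a
clinical-annotation table.

The package is aimed at population-genetics analyses of the following shape:
one catalogue (gnomAD-style VCF) publishes per-population allele-level counts
`AN_pop` (called alleles), `AC_pop` (ALT alleles) and `nhomalt_pop`
(ALT-homozygous individuals); a second catalogue (GME-Variome-style TSV)
publishes per-region genotype counts; a ClinVar-style export supplies clinical
significance for disease-relevant SNPs.  The motivating use case is type 2
diabetes in the Arabian Peninsula: eight gnomAD exome populations plus seven
Greater-Middle-East regions give fifteen labels, with the Arabian Peninsula as
the focal region and the fourteen others pooled as the reference.

## Method

For each biallelic SNV present in both catalogues (exact match on chromosome,
1-based GRCh37 position, REF and ALT), common variants (ALT allele frequency
> 0.01 in at least one population/region) are intersected with the clinical
annotations.  For each remaining SNP the focal counts are compared with the
pooled counts of all other populations/regions:

- Expected focal counts under equal frequencies:
  `E_j = (focal total) · others_j / (others total)`, applied to the
  (REF, ALT) allele pair and to the (REF/REF, REF/ALT, ALT/ALT) genotype
  triple.
- Exact conditional tests: Fisher's exact test on the 2×2 allele table and
  its Freeman–Halton extension on the 2×3 genotype table, both computed by
  full enumeration with log-gamma arithmetic (two-sided, probability-mass
  convention), so pooled totals of 10^5–10^6 alleles are handled exactly.
- Benjamini–Hochberg FDR control at q = 0.05, applied to the allele-test and
  genotype-test families separately.
- For significant SNPs, Haberman's adjusted standardized residuals
  `r_ij = (O_ij − E_ij) / sqrt(E_ij (1 − row_i/N)(1 − col_j/N))`
  localize which allele/genotype drives the deviation.

A synthetic-cohort generator (Hardy–Weinberg genotypes at Beta-distributed
ALT frequencies, planted focal deviations, per-cell missingness, sparse
annotation overlay) stands in for the real downloads, and a fixed 18-SNP
reference cohort reproduces the published T2D analysis end to end.

## Worked example

```bash
popdiff fixture -o fixture/            # write the 18-SNP reference cohort
popdiff run --vcf fixture/fixture.vcf --gme fixture/fixture_gme.tsv \
    --clinvar fixture/fixture_clinvar.tsv -o report/
```

The `run` command prints the stage funnel:

```
n_vcf	18
n_table	18
n_merged	18
n_common	18
n_annotated	18
n_tested	18
n_sig_allele	9
n_sig_genotype	9
n_clinical	2
```

18 SNPs survive the three-way intersection and are tested; exactly two —
*SLC30A8* rs13266634 ("risk factor") and *KCNJ11* rs5219 ("drug response") —
are both clinically and statistically significant.  `report/report.tsv`
mirrors the published result table (observed and expected allele/genotype
counts, display-rounded p-values, `*`/`#`/`§` significance marks), e.g. for
rs13266634:

```
rsid        marks  obs_ref obs_alt exp_ref exp_alt p_allele ...
rs13266634  *#§    298     44      244.0   98.0    0.000
```

meaning the focal region carries 298 REF (risk) alleles where 244 were
expected — a risk-allele excess — at an allele-test p-value below 0.0005
(full precision in `report.json`).  The adjusted residuals in `report.json`
show the direction: positive for REF/hom-REF, negative for the heterozygote.

The same interface runs on synthetic cohorts:

```bash
popdiff simulate --seed 7 -o sim/ --planted 12:0.30
popdiff run --vcf sim/cohort.vcf --gme sim/cohort_gme.tsv \
    --clinvar sim/cohort_clinvar.tsv -o sim_report/
popdiff spectrum --vcf sim/cohort.vcf --gme sim/cohort_gme.tsv -o spectrum.tsv
```

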