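# paraconv

Population-genetic analysis of a recently duplicated gene family whose
paralogs exchange sequence by interlocus gene conversion.

The motivating system is a plant immune "guardee" protease that exists as
two young paralogous loci (A and B) in a wild tomato population, with a
third, rare copy excluded from analysis.  The coding regions of the two
copies are nearly indistinguishable, two deeply diverged intron-linked
haplotype classes ("sequence types") segregate at *both* loci at
intermediate frequency — the classic footprint of balancing selection —
and allele-specific phenotypes (sensitivity to a fungal protease
inhibitor, strength of the hypersensitive response) map onto single amino
acid replacements.  Analysing such data requires machinery that standard
single-locus toolkits do not provide, and that is what this package
implements:

* **`paraconv.coalsim`** — an event-driven structured coalescent for two
  paralogous loci with a duplication event at time `t_dup` (4N
  generations), stepwise population expansion (factor `f` at time
  `t_exp`), and interlocus gene conversion at population rate
  `C = 4Nc` per site with geometric tract lengths (mean `lambda_tract`).
  Per site, conversion acts exactly like two-island migration at rate
  `C`, giving a closed-form oracle: for a pair of lineages,
  `E[T_same] = 2` and `E[T_diff] = 2 + 1/C` (2N units).
* **`paraconv.sumstats`** — π, Watterson's θ_W, Tajima's D, Fu & Li's D
  (outgroup-polarized), Hudson's F_ST = 1 − H_w/H_b, sliding windows,
  and the classification of homologous columns into shared, private and
  fixed polymorphisms between the paralogs (the conversion-rate signal).
* **`paraconv.abc_inference`** — rejection ABC with Beaumont-style
  local-linear regression adjustment, acceptance-ratio Bayes factors for
  conversion vs no conversion, and demographic calibration (θ, `f`,
  `t_exp`) from a panel of single-copy reference loci.
* **`paraconv.neutrality`** — demography- and conversion-aware null
  distributions of Tajima's D with add-one empirical p-values.
* **`paraconv.association`** — the single-marker GLM scan (OLS of a
  binary phenotype on 0/1 genotypes, F-test, MAF > 0.25 filter,
  Bonferroni correction).
* **`paraconv.seq_model` / `paraconv.synthetic_data`** — FASTA alignment
  IO, pseudogene flagging (premature stops / frameshifts), intron-based
  sequence typing, and a generator producing synthetic allele panels
  with the full observed structure (14 + 9 alleles, intron dimorphism,
  pseudogenes, phenotype classes driven by designated causal SNPs).

The numbered scripts under `analysis/` chain these modules into the full
study: generate the panel, summarise it, estimate the conversion rate by
ABC, fit the demography, test neutrality, and scan for genotype–
phenotype associations.  Each writes its tables under `results/`.

## Worked example

```bash
python analysis/01_generate_data.py --seed 1
python analysis/02_summary_statistics.py
python analysis/06_association_scan.py
```

prints (abridged):

```
wrote 14+9 alleles (L=1000), 2 pseudogenes, causal sites {'avr2': 240, 'hr': 857}
      unit    n  pi_site  theta_W  tajimas_D
   locus_A   13 0.020179 0.018690   0.358468
   locus_B    8 0.023607 0.020055   0.953746
F_ST between sequence types: 0.262
cross-locus classes: shared=24 private_A=34 private_B=28 fixed=0

contrast avr2 (planted causal site: 240):
 position  r2  p_raw  p_bonferroni
      240 1.0    0.0           0.0
```

Reading this: after excluding the two pseudogene alleles, both loci are
highly diverse, the recovered sequence types are strongly differentiated
(F_ST ≈ 0.26), the paralogs share many polymorphisms while fixing none —
the signature of frequent interlocus conversion — and the planted causal
SNP is the unique Bonferroni-significant association with R² = 1.
`analysis/03_gene_conversion_abc.py` then estimates `C` by ABC (20,000
simulations, best 200 retained, regression-adjusted) and computes the
Bayes factor for conversion against no conversion.

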