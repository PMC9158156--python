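# famead

Family-based genetic analysis of early-onset Alzheimer's disease (EOAD).

Many families with clustered early-onset Alzheimer's disease carry no
detectable mutation in the classical genes (*APP*, *PSEN1*, *PSEN2*).
This package implements, as a tested pipeline with a synthetic-cohort
generator, the combined monogenic + polygenic work-up of such a cohort:

1. **Pedigree reconstruction from genotypes** — pairwise kinship
   coefficients from common SNPs (allele frequency > 5%) with the robust
   moment estimator
   `phi = (N_het,het − 2·N_opp,hom) / (N_het_i + N_het_j)`,
   relationship degrees from the standard powers-of-two bands
   (0.354 / 0.177 / 0.0884 / 0.0442), and families as connected
   components of pairs related at 2nd degree or closer with ≥ 2 affected
   members.
2. **Rare-variant segregation filtering** — per-family variant views
   filtered by quality-by-depth ≥ 5; coding (missense / nonsense /
   frameshift) or splice-region (≤ 2 bp) consequence; gnomAD allele
   frequency < 0.1%; heterozygous in all affected and homozygous
   reference in all unaffected members.
3. **Classification and gene prioritization** — dementia-panel
   screening; pathogenic / VUS / likely-benign labels (likely benign =
   tolerated by ≥ 2 of SIFT, PolyPhen2, MutationTaster and/or CADD < 10;
   pathogenic = database-reported, or truncating in a high-penetrance
   PTV gene such as *SORL1* or *GRN*); novel candidates from identical
   variants in ≥ 2 families, one gene in ≥ 3 families, or 2 families
   with CADD > 15 plus a literature link, with a blacklist for
   artifact-prone regions.
4. **Ordinal burden testing** — proportional-odds (cumulative-logit)
   regression with outcome ordering EOAD > LOAD > control,
   `P(Y ≤ k | x) = logistic(α_k − x'β)`, fitted by Newton-Raphson with
   analytic gradient and Hessian; dominant carrier coding, cumulative
   CADD strata (15/20/25/30), carrier minima (10 per gene, 5 per
   variant), 10 ancestry PCs, Wald tests with a likelihood-ratio
   fallback under separation, and Benjamini-Hochberg FDR.
5. **Risk profiling** — a weighted polygenic risk score (PRS) over a
   35-variant panel gated on imputation quality (R² ≥ 0.3), centered on
   a population-control mean so that 0 is the population average and
   `OR = exp(score)`; APOE risk from per-allele effects (+1.20 per ε4,
   −0.47 per ε2) on the same centered scale (ε3/ε3 → −0.36,
   ε4/ε4 → 2.04); family scores as means over affected members.
6. **Family statistics and actionability** — Welch t-tests for PRS
   subgroups, Mann-Whitney U (with continuity) for APOE risk, Spearman
   correlation between the two, and a rule-based split into
   *monogenic* / *risk factors identified* / *unresolved* families.

The statistical core (kinship estimator, proportional-odds likelihood,
scoring rules) is implemented here; standard steps ride on pysam
(VCF v4.2), scipy/statsmodels (classical tests, FDR), scikit-learn
(estimator API), networkx and pandas.

## Worked example

The packaged fixture `table1_families.tsv` carries the published
per-family summary values for the 36-family cohort (family size, mean
onset age, pathogenic variant / VUS gene, family-averaged APOE risk and
PRS on the population-centered scale):

```python
from famead import load_table1, summarize_cohort, apoe_risk, beta_to_or

table = load_table1()
rep = summarize_cohort(table)
print(f"PRS mean {rep['prs']['overall_mean']:.2f} (SD {rep['prs']['overall_sd']:.2f})")
ap = rep["prs"]["app_psen1_vs_rest"]
print(f"APP/PSEN1 vs rest PRS: {ap['mean_in']:.2f} vs {ap['mean_out']:.2f} (p={ap['p']:.3f})")
aa = rep["apoe"]["pv_vs_rest"]
print(f"PV vs rest APOE: {aa['mean_in']:.2f} vs {aa['mean_out']:.2f} (p={aa['p']:.3f})")
co = rep["apoe_prs_correlation"]["all_families"]
print(f"Spearman APOE~PRS: rho={co['rho']:.2f} (p={co['p']:.3f})")
print("categories:", rep["categories"])
print(f"APOE e3/e3 {apoe_risk('33'):.2f}, e4/e4 {apoe_risk('44'):.2f}, "
      f"OR(0.61) = {beta_to_or(0.61):.2f}")
```

prints

```
PRS mean 0.05 (SD 0.28)
APP/PSEN1 vs rest PRS: -0.22 vs 0.10 (p=0.006)
PV vs rest APOE: 0.29 vs 1.15 (p=0.010)
Spearman APOE~PRS: rho=0.48 (p=0.003)
categories: {'monogenic': 8, 'risk_factors': 19, 'unresolved': 9}
APOE e3/e3 -0.36, e4/e4 2.04, OR(0.61) = 1.84
```

That is: family polygenic risk is on average barely above the
population mean; families with an *APP*/*PSEN1* mutation carry *less*
polygenic and APOE risk than unexplained families (the mutation
suffices on its own); 8 families are explained monogenically, 19 carry
at least one identifiable risk factor (VUS, APOE-ε4 homozygosity, or
elevated PRS), and 9 remain genetically unresolved.

A full synthetic run — simulate a cohort, reconstruct families from
genotypes, filter, classify, score, and categorize:

```python
from famead import SimulationConfig, run_pipeline

report = run_pipeline(SimulationConfig(n_families=12, seed=5), run_burden=True)
print(report["stages"], report["categories"])
```

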