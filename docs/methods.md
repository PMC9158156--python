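# Methods

This note documents the models and procedures implemented in `famead`,
the parameters that matter, the design choices that were genuinely
open, and what the synthetic-data tests do and do not establish.

## Kinship and family reconstruction

Pairwise kinship is estimated from biallelic genotype calls (0/1/2,
missing allowed) with the robust within-family moment estimator

    phi_hat = (N_het,het − 2 · N_opp,hom) / (N_het_i + N_het_j),

counting over sites non-missing in both samples after excluding sites
with pooled-sample minor allele frequency ≤ 5% (the `maf_filter`
parameter; the pooled-cohort frequency is the default because the
source cohorts were pooled before relatedness estimation, but an
external frequency field can be substituted). The ratio of expectations
equals the true kinship coefficient for any outbred relationship —
0.5 (duplicate/MZ), 0.25 (1st degree), 0.125 (2nd), 0.0625 (3rd),
0 (unrelated) — independent of the allele-frequency spectrum, which is
why unlinked common SNPs suffice and linkage disequilibrium can be
ignored at genome-wide site counts.

Degrees are assigned with the standard half-open powers-of-two bands
(2^−3/2, 2^−5/2, 2^−7/2, 2^−9/2) = (0.354, 0.177, 0.0884, 0.0442); a
boundary value belongs to the closer-relationship side, NaN (no
heterozygous sites) maps to "unknown". Families are connected
components of the graph joining pairs at ≤ `max_degree` (default 2nd
degree, configurable to 3rd: the cohort definition states "at least
second-degree"), keeping components with ≥ 2 affected members; family
ids are assigned deterministically from sorted member ids. Missing
genotypes are handled by pairwise-complete deletion, matching the
per-pair count definitions. Pairs with fewer than 100 usable sites are
flagged rather than dropped.

## Segregation filter

Four conjunctive stages in fixed order: (1) quality-by-depth ≥ 5
(inclusive); (2) consequence in {missense, nonsense, frameshift} or a
splice-region call within 2 bp of an exon–intron junction; (3) gnomAD
total allele frequency < 0.1% (strict; the non-Finnish European field
is available behind `use_nfe`); (4) heterozygous in every affected —
MCI counts as affected — and homozygous reference in every unaffected
member. Missing QD or allele frequency passes its stage (novel variants
are legitimately absent from gnomAD; several published hits have
frequency 0), missing consequence fails stage 2 (coding status cannot
be confirmed), and a missing genotype fails segregation (the pattern
cannot be confirmed). Because stages are conjunctive, the survivor set
is order-independent; only the per-stage audit counts depend on order.
Multi-allelic records are decomposed to biallelic on VCF read, with
genotypes re-coded per alternate allele. Autosomes only; hemizygous
chromosome-X handling is out of scope.

## Classification and prioritization

Two explicit rules operationalize the clinical classification, with the
pathogenic rule evaluated first: *pathogenic* if database-reported
pathogenic (an input flag — live database queries are deliberately not
performed, for reproducibility and licensing) or a truncating variant
in a configurable high-penetrance-PTV gene set (default {SORL1, GRN},
encoding the judgment that truncating SORL1/GRN alleles are reportable
even when novel); *likely benign* if ≥ 2 of the three predictor calls
are "tolerated" and/or CADD < 10; otherwise *VUS* (with "insufficient
evidence" recorded when no predictor call and no CADD exist).

Novel-gene prioritization runs on non-panel survivors of families
without a confirmed monogenic cause: (a) identical variants
(chrom:pos:ref:alt after decomposition) in ≥ 2 families; (b) one gene
hit in ≥ 3 distinct families (each needing only ≥ 1 qualifying variant
— the stricter "three distinct alleles" reading was rejected as it is
not what a sharing screen computes); (c) one gene in exactly 2 families
with CADD > 15 in both and a curated literature link (a per-gene
boolean input). A blacklist of regions/variant ids stands in for manual
IGV review: candidates whose every supporting variant matches are
flagged and excluded.

## Proportional-odds burden test

Outcomes are ordered control (0) < LOAD (1) < EOAD (2); the
cumulative-logit model P(Y ≤ k | x) = logistic(α_k − x'β) makes a
positive β an enrichment toward early onset. The log-likelihood is
maximized by Newton–Raphson with analytic gradient and Hessian,
starting from empirical cumulative logits and β = 0, with step-halving
on any likelihood decrease; convergence at max-norm gradient < 1e−8 or
100 iterations. Standard errors come from the inverse observed
information; the burden coefficient is tested by Wald (cheap at scale
and standard in burden testing; the choice was open) with a
likelihood-ratio fallback when separation is detected (|β| > 30 or
non-convergence). Zero-variance covariates are unidentifiable jointly
with the cutpoints and are reported as β = 0, p = 1. The implementation
is validated against `statsmodels` `OrderedModel` (independent oracle)
and collapses exactly to binary logistic regression with two outcome
levels.

Gene-level scans use a dominant carrier indicator (≥ 1 qualifying
allele), cumulative CADD strata — stratum 20 means all variants with
CADD ≥ 20, matching how "CADD > 15/25" results are reported — a
minimum of 10 carriers (5 at variant level), 10 ancestry PCs computed
once per cohort (not per stratum; the alternative was open and the
single-cohort PCA is the simpler, standard choice), and
Benjamini–Hochberg FDR across the emitted result list.

## Risk scores

PRS = Σ dosage_k · weight_k over the non-APOE panel variants, after
dropping variants with imputation R² below 0.3 (0.6 for array-genotyped
panels); dosages may be hard calls or fractional. Scores are centered
by subtracting the mean raw score of a population control set (default
size 980), so 0 is the population mean and exp(score) an odds ratio.
The packaged 35-variant weight table is a **synthetic stand-in** (the
study's weight list is not publicly printed): realistic meta-GWAS
magnitudes, median imputation R² 0.73. Consequently the published
per-family PRS values are validated through the packaged family table,
not recomputed from genotypes. The agreement between two dosage sources
is exposed as a diagnostic (`prs_source_correlation`), not a gate.

APOE risk uses +1.20 per ε4 allele and −0.47 per ε2 allele minus a
population-mean offset of 0.36. The signs follow the risk-allele
orientation (the meta-GWAS prints the rs429358 effect as −1.20 for the
non-risk allele); the offset is not printed anywhere but is forced by
the published anchor ε3/ε3 = −0.36 and is configurable or recomputable
from a control set. The scale is anchored so ε3/ε4 = 0.84, ε4/ε4 =
2.04, ε2/ε3 = −0.83. Family risk (APOE and PRS) is the arithmetic mean
over affected members only — a deliberate simplification of shared
polygenic burden inherited from the study design.

## Family statistics and categories

PRS subgroups are compared with Welch's unequal-variance t-test (the
published analysis says only "unpaired t-test"; Welch is robust to the
6-vs-30 group sizes, and the pooled variant is available by flag — for
this reason, and because the published per-family inputs are rounded to
2 decimals, printed p-values are not contract-tested except where they
reproduce). APOE risk uses the Mann–Whitney U normal approximation with
tie and continuity corrections; the APOE–PRS association uses Spearman
with average ranks.

Categories: *monogenic* iff the PV flag is set; *risk factors* if any
of VUS, APOE (≥ 1 affected ε4/ε4 carrier — the definition that matches
the 18 flagged families), or PRS ≥ 0.45 fires; else *unresolved*. The
0.45 threshold is the midpoint-ish value of the interval (0.42, 0.47]
that exactly reproduces the published PRS flags; it is configurable.
Report rounding is half-away-from-zero at 2 decimals.

One reproducibility caveat found while validating against the published
table: the text reports the APOE–PRS Spearman correlation as 0.48
(p = 0.003) "in the remaining 28 families" after excluding the eight
pathogenic-variant families, but recomputing from the printed
per-family values gives rho = 0.41 (p = 0.028) for that subset and
rho = 0.48 (p = 0.003) — both digits matching print — over all 36
families. The published statistic was therefore evidently computed over
the full table; `correlate_apoe_prs` supports both, the full-table
variant carries the published value, and the 28-family variant is
regression-tested at its recomputed value. Relatedly, the printed
"PV vs rest" PRS mean 0.03 recomputes as −0.03 (a dropped sign in the
published subgroup table), and exp(2.04) is 7.69, not the printed 7.34;
neither value is used as a contract.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis
assumes, at study-condition defaults: 36 families with 2–4 affected
members (siblings, or — with probability 0.3 in families of ≥ 3 — a
nephew through an unobserved sibling, giving second-degree affected
pairs), at most one unaffected elderly member (an observed founder;
default 0, as only 4/36 study families had one); 10,000 unlinked common
SNPs (MAF uniform on 0.05–0.5, founders in Hardy–Weinberg, Mendelian
gene dropping, 0% missingness by default); a planted fully-segregating
rare coding variant per planned family (default plan: 8 pathogenic-
panel families, 8 VUS-panel families) plus 76 background rare variants
per family, each violating exactly one tagged filter stage; APOE
genotypes drawn from an ε4-heavy mix matching the cohort (or fixed per
family by plan); PRS dosages binomial at panel allele frequencies for
the cohort and a 980-sample control set; and a replication cohort of
833 EOAD / 521 LOAD / 6,949 controls with per-gene Bernoulli carrier
indicators (frequency 0.05 across 37 genes), 10 standard-normal PCs,
and outcome labels drawn from the true cumulative-logit model given
the carrier status of designated causal genes (β = 0 yields an exact
permutation null with exact class sizes).

Deliberately not emulated: linkage disequilibrium (the kinship moment
estimator needs only independent sites), sequence-level annotation
(CADD, predictor calls and gnomAD frequencies are generated input
fields, as they were consumed from an annotation pipeline), capture-kit
and per-site quality-score structure, X-chromosome inheritance,
within-family correlation of polygenic dosages, and imputation itself
(R² is input metadata). Passing tests therefore demonstrate
correctness of the estimators and rules under the stated generative
assumptions — Mendelian transmission, independent common sites,
annotation-driven filtering — not robustness to LD, batch effects, or
call-quality artifacts in real exomes.

Determinism: every stochastic step flows from `SimulationConfig.seed`;
identical configs produce byte-identical output files. VCF I/O uses
pysam; because htslib stores INFO floats in single precision, the
generator emits annotation floats at fixed decimal precision (QD 2,
CADD 1, frequencies 6) and the reader re-rounds, making write→read
round-trips exact.

## Problem sizes used in the validation suite

Kinship recovery uses 20 replicate pedigrees at 50,000 SNPs (class-mean
tolerance 0.02 ≈ 3σ of the replicate means); clustering recovery uses
10 planted families plus 20 unrelated singletons at 10,000 SNPs; the
null calibration of the ordinal test uses 1,000 independent genes at
n = 2,000 with 10 PCs (type-I tolerance 0.02 at α = 0.05, ~3σ binomial
bands); effect recovery averages 10 replicates at n = 5,000. These
sizes keep the whole suite under a minute while leaving Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

- The PRS weight panel and gene panel are synthetic stand-ins; analyses
  depending on the true weights (absolute PRS values from genotypes)
  are validated against the published family table instead.
- Family averaging treats the polygenic burden as exchangeable among
  affected members and ignores kinship-induced correlation.
- The proportional-odds model assumes a common β across outcome
  cutpoints; no proportionality test is provided.
- The categorizer is a transparent rule set, not a calibrated clinical
  decision tool; thresholds are configurable and should be re-derived
  for other cohorts.
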