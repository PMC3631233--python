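# pedlink

Family-based linkage analysis toolkit: pedigree/marker-map I/O and QC,
exact parametric and nonparametric linkage statistics, clinical
stratification with a conditional permutation test, gene-drop power
simulation, candidate-variant segregation triage, and a synthetic cohort
generator so the whole pipeline is testable end to end without any external
data.

## What is inside

| Module | Purpose |
| --- | --- |
| `pedlink.pedigree` | `Pedigree` / `MarkerMap` / `DiseaseModel` data model, PED & MAP readers/writers, validation (loops rejected), trimming, founder allele-frequency estimation, Haldane/Kosambi map functions |
| `pedlink.qc` | Mendelian-error scan (P-P-C and P-C), exact HWE test, the ordered SNP filter cascade (call rate, cross-batch presence, Mendel family fraction, MAF, HWE, duplicate bp, missing cM, duplicate cM at 2 dp) with per-family genotype masking, inbreeding-F outliers, evenly-spaced multipoint marker selection |
| `pedlink.linkage` | Elston–Stewart two-locus peeling (`peeling`), two-point LOD curves + Smith-admixture HLOD + 1-LOD-down support intervals (`twopoint`), Lander–Green inheritance-vector HMM (`descent`), S_all NPL scores and Kong–Cox linear/exponential LODs (`npl`), r²-threshold LD clustering with EM haplotype frequencies (`ldcluster`), multipoint error detection/masking (`errors`), and scan orchestration with reusable per-family score tables (`scan`) |
| `pedlink.stratperm` | Condition-based family stratification, per-stratum scans, and the random half-split conditional permutation test (chromosome-wide and genome-wide empirical p, add-one corrected) |
| `pedlink.powersim` | Exact no-rejection sampling of disease genotypes given phenotypes, linked-marker gene drop, Monte-Carlo power with exact binomial CI |
| `pedlink.variants` | Three-criterion variant triage and per-family sharing / reduced-penetrance classification |
| `pedlink.simulate` | Synthetic multiplex cohorts (ascertained for ≥2 affected sampled members), linked/unlinked strata, planted QC defects, truth ledger |
| `pedlink.cli` / `pedlink.pipeline` | `pedlink` command-line interface and the end-to-end pipeline with a JSON manifest |

## CLI

```bash
pedlink simulate --seed 1 --out sim/ --families 16          # PED/MAP/flags/truth
pedlink qc       --ped sim/cohort.ped --map sim/cohort.map \
                 --batches sim/batches.tsv --out qc/
pedlink linkage  --ped qc/filtered.ped --map qc/filtered.map --out scan/
pedlink stratify --ped ... --map ... --flags sim/clinical_flags.tsv --out strat/
pedlink permute  --ped ... --map ... --flags ... --reps 500 --seed 1 --out perm.tsv
pedlink power    --ped ... --map ... --theta 0.01 --marker-maf 0.30 --reps 1000
pedlink variants --variants variants.tsv --carriers carriers.tsv --out triage.tsv
pedlink run-all  --seed 1 --out run/                        # full pipeline + manifest
```

All randomness is seeded; rerunning any command with the same seed
reproduces byte-identical outputs.

## Notes on scope

Biallelic autosomal SNPs; loop-free pedigrees (loops are rejected with a
clear error); X-chromosome analysis, VCF ingestion and intensity-level QC
are out of scope.  Two-point likelihoods are exact for any loop-free family
size via variable elimination; multipoint analyses enumerate inheritance
vectors and skip (with a warning) families whose meiosis count exceeds the
configurable bit cap.
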