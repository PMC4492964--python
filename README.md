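# msatpop

A microsatellite population-genetics toolkit for partially clonal,
two-type coral-style datasets:

- **Genotype tables** — diploid allele-size matrices with mito-type
  labels; readers/writers for GenAlEx-style CSV, STRUCTURE, and Genepop
  dialects (0 = missing; STRUCTURE recodes alleles through a persisted
  dictionary); locus-QC actions (drop locus / zero a call).
- **SSR discovery** — perfect tandem-repeat detection (3/4-base motifs)
  in FASTA, with candidate selection at 3-mer ≥ 10 and 4-mer ≥ 8 units.
- **Clonality** — multilocus-lineage (MLL) assignment under the
  ≤ 1-mismatch clone rule (single-linkage closure), the N_MLL/N
  clonality index, and single-locus-variant QC flagging.
- **Diversity statistics** — per-locus N_A, H_E (1 − Σp²), H_O,
  F_IS = (H_E − H_O)/H_E, chi-square HWE tests, permutation G-tests for
  linkage disequilibrium, Benjamini–Hochberg FDR flags, cross-type
  shared-allele counts.
- **Differentiation** — multi-locus F_ST between groups (Nei–Chesser
  corrected by default) with a label-permutation significance test.
- **Bayesian clustering** — a from-scratch admixture-model Gibbs sampler
  (cluster allele frequencies, per-individual memberships Q, shared
  alpha updated by Metropolis), Ln P(D) model choice, Evanno ΔK, and
  CLUMPP-style label-aligned merging of replicate runs.
- **DAPC** — discriminant analysis of principal components on
  allele-dosage profiles, with the floor(n/3) PC-retention rule.
- **Synthetic data** — Balding–Nichols two-population generator with
  clonal ramets, stepwise somatic mutations, scoring errors, and missing
  calls, plus planted-repeat FASTA fixtures; every stochastic module is
  testable against its planted truth.

## CLI

All functionality is exposed through one entry point:

```sh
msatpop simulate --config sim.yaml --out genotypes.csv --truth truth.json
msatpop discover-ssr --fasta contigs.fa --out ssr.tsv
msatpop mll --in genotypes.csv --dialect genalex --type mt-L --out mll.tsv
msatpop stats --in genotypes.csv --type mt-L --mll mll.tsv --out stats.tsv
msatpop ld --in genotypes.csv --type mt-L --n-perm 1000 --seed 1 --out ld.tsv
msatpop fst --in genotypes.csv --n-perm 999 --seed 1 --out fst.json
msatpop cluster --in genotypes.str --dialect structure --k-min 1 --k-max 6 \
    --iters 10 --burn-in 100000 --reps 1000000 --seed 1 --out runs/
msatpop evanno --runs runs/ --out evanno.tsv
msatpop dapc --in genotypes.csv --mll mll.tsv --pcs auto --out dapc.tsv
msatpop run --config pipeline.yaml --out results/
msatpop report --dir results/
```

`msatpop run` executes the whole analysis (MLL → diversity/HWE → LD+FDR
→ F_ST → clustering K range with replicate runs → ΔK → merged Q → DAPC),
writes per-stage TSV/JSON artifacts plus `report.json`/`report.txt`, and
derives one deterministic seed per stage from the master seed, so reruns
reproduce every numeric artifact byte-for-byte.

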