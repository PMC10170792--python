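# seqblup

Genomic prediction toolkit for sequence-level marker data: marker-panel
construction and QC, genomic relationship matrices (GRM), REML variance
components and heritability, GBLUP/MultiBLUP breeding-value prediction with
cross-validated accuracy and bias, genotype-imputation accuracy metrics,
population-structure diagnostics, and a synthetic-data generator that makes
the whole pipeline testable without any external download.

## Modules

| module            | purpose |
|-------------------|---------|
| `seqblup.simdata` | structured genotype/phenotype simulation (Balding–Nichols subpopulations, block LD, additive traits with fixed effects), genotype corruption, sample hold-out |
| `seqblup.panels`  | `GenotypeMatrix`/`VariantPanel`, call-rate/MAF QC, random thinning (bernoulli/exact), sliding-window LD pruning, panel intersection |
| `seqblup.pheno`   | corrected phenotypes (OLS or animal-model GLS fixed-effect removal), trait summaries |
| `seqblup.grm`     | GRM construction (shared-denominator `vanraden1`, per-marker `vanraden2`), combination, GCTA binary/text I/O |
| `seqblup.varcomp` | AI-REML with EM fallback (1–2 genomic components), restricted log-likelihood, heritability-by-panel profiles |
| `seqblup.predict` | GBLUP (Henderson MME + closed-form check), MultiBLUP, accuracy/bias, k-fold × repeated cross-validation, percent-increase reporting |
| `seqblup.imputeval` | concordance rate and dosage r² per variant, MAF-binned (0.01) and genome-wide summaries, summary plot |
| `seqblup.structure` | PCA from the GRM, IBS similarity, LD-decay curve, Euclidean phenotype distance |
| `seqblup.pipeline` / `seqblup.cli` | YAML-configured end-to-end runs and per-stage subcommands |

## CLI

```bash
seqblup simulate --n 300 --n-snp 5000 --n-indel 1000 --seed 1 --out-prefix sim
seqblup qc       --genotypes sim.dosage.tsv --out qc.tsv
seqblup panel    --genotypes qc.tsv --thin-count 1000 --out panel1k.txt
seqblup grm      --genotypes qc.tsv --panel-file panel1k.txt --out-prefix g1k
seqblup reml     --grm-prefix g1k --phenotypes sim.pheno.tsv --trait trait --out h2.tsv
seqblup cv       --grm-prefix g1k --phenotypes sim.pheno.tsv --trait trait --out cv.tsv
seqblup impacc   --truth sim.vcf --imputed imputed.vcf --out-prefix acc
seqblup structure --genotypes qc.tsv --out-prefix struct
seqblup run      --config config.yaml --seed 1
```

Every subcommand honours `--seed`; identical seeds give identical outputs.

A minimal `config.yaml` for `seqblup run`:

```yaml
out_dir: results
simulate:
  n_individuals: 300
  n_snp: 5000
  n_indel: 1000
  trait: {h2_snp: 0.3, n_causal_snp: 100}
panel_sizes: [1000]
models: [gblup]
adjust_method: fixed_only
cv_k: 5
cv_reps: 5
seed: 1
```

## File formats

- **Dosage dialect**: TSV; header `sample_id` + variant ids
  (`chrom:pos:ref:alt`), one row per sample, values 0/1/2 or `NA`.
- **VCF**: uncompressed, biallelic, hard GT calls; INFO tag `VT=SNP|INDEL`.
- **PLINK bed/bim/fam**: read-only, SNP-major layout.
- **GRM binary triplet** (`.grm.bin`, `.grm.N.bin`, `.grm.id`): lower
  triangle with diagonal, row-major, little-endian float32; the `.N.bin`
  file repeats the marker count per element; `.grm.id` is
  family-id / sample-id per line. A plain-text lower-triangle writer
  (`id1  id2  n_markers  value`) is also provided.
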