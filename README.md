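# fikat — functionally informed kernel-based rare-variant association tests

`fikat` tests whether rare variants in a gene are jointly associated with a
quantitative trait, using variant effect predictions to decide *which*
variants enter the test and *how* they are combined. It is aimed at exome
association studies where per-variant power is negligible and the signal has
to be aggregated per gene, and at methodologists who want a fully simulatable
implementation of the two-stage score/restricted-likelihood-ratio testing
procedure.

## The model

For a quantitative trait **y** on *n* individuals with covariates **X**,

```
y ~ N(Xα, σ²_e I + σ²_g K),     K = φ(G) φ(G)ᵀ,
```

where **G** holds the mean-centered minor-allele dosages of a gene's
qualifying variants and φ maps them into intermediate variables. The null
hypothesis is σ²_g = 0 (one-sided). The choice of φ encodes the biology:

| design | φ(G) | used for |
|---|---|---|
| max-weight collapsing (gbvc) | per-individual max variant weight | pLOF, missense, splice |
| weighted linear kernel | G_c · diag(√w) | splice |
| locally collapsing kernel | G_c · diag(√w) · C (variants at one amino-acid position share a column) | missense |
| directional RBP kernel | G_c · diag(√w) · L with LLᵀ = S = Q∘R | RBP-binding |

Weights w are the mean SIFT/PolyPhen deleteriousness probability
((1−SIFT)+PolyPhen)/2 for missense variants, the maximum SpliceAI delta score
for splice variants, the largest absolute per-RBP binding change |p_alt −
p_ref| for RBP variants, and 1 for pLOF. For the RBP kernel, Q is the cosine
similarity of the signed effect vectors and R a Gaussian positional
similarity r_ij = exp(−γ(x_i−x_j)²) with γ = −ln(0.5)/50² (similarity 0.5 at
50 bp).

Testing is two-stage (the sLRT): variance-component score tests run
genome-wide, with p-values for the weighted chi-square null via Ruben's
series (absolute accuracy 1e-7) and a saddlepoint tail. Genes whose score p
falls below t = 0.1 also get a restricted likelihood-ratio test; its
nonstandard boundary null is sampled exactly (100 draws per gene), pooled
within (phenotype × category × test-type) groups, and summarised by the
parametric mixture π·χ²₀ + (1−π)·a·χ²_d fitted by log-survival regression on
the top decile. Category-only and category+pLOF designs are merged per gene
with the Cauchy combination test; Bonferroni controls the FWER over all
emitted tests.

## Worked example

Simulate a small study and run the pipeline end to end:

```bash
fikat simulate --out demo --n-samples 300 --n-genes 20 --seed 3
fikat qc-report --bed demo.bed --out demo.qc.tsv
fikat run --bed demo.bed --pheno demo.pheno.tsv --covar demo.covar.tsv \
          --annot demo.annot.tsv --genes demo.genes.tsv \
          --out demo.results.tsv --seed 1
```

prints

```
wrote demo.bed/.bim/.fam and TSV tables
74/200 variants pass QC
wrote 0 tests to demo.results.tsv (cutoff nan, 0 significant)
```

The QC report keeps 74 of 200 variants: the default MAF cutoff (0.1%) is a
biobank-scale threshold, and at n = 300 every variant with even one carrier
exceeds it — the passing variants are the monomorphic ones, so no gene is
testable. This is the expected behaviour of study-scale thresholds on a
desk-scale sample; at desk scale, relax the cutoff in a YAML config
(`maf_max: 0.02`) and pass it with `--config`:

```bash
printf 'maf_max: 0.02\n' > demo.yaml
fikat run --bed demo.bed --pheno demo.pheno.tsv --covar demo.covar.tsv \
          --annot demo.annot.tsv --genes demo.genes.tsv \
          --config demo.yaml --out demo.results.tsv --seed 1
```

```
wrote 34 tests to demo.results.tsv (cutoff 1.4706e-03, 0 significant)
```

Each row of `demo.results.tsv` is one (phenotype, gene, category, test-type)
test: the score statistic and p-value, the RLRT statistic and pooled-null
p-value when the gene triggered the second stage, the Cauchy-combined and
final p-values, a Bonferroni significance flag (cutoff = 0.05 / number of
tests), and the genomic inflation factor λ_GC of the group's genome-wide
score tests. Zero significant genes on a null simulation is the correct
outcome.

Library use mirrors the CLI: `fikat.simulate` generates studies in memory,
`fikat.kernels` builds φ(G), `fikat.assoc` provides the tests, and
`fikat.pipeline.run_study` orchestrates them (see `docs/methods.md`).

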