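# nbcall

Multi-sample, error-model-based variant calling for low variant allele
fractions. For every candidate alteration (SNV, insertion or deletion at a
position), nbcall estimates the systematic sequencing error rate across a
cohort of samples by robust negative-binomial regression (zero intercept,
linear link, variance `mu + sigma*mu^2`), then calls a sample's variant as
a statistical outlier from that error model: an upper-tail p-value,
Benjamini–Hochberg q-values across the cohort, and a Phred-scaled quality
(`QVAL = -10*log10(q)`). Strand-bias, proximity and low-confidence-change
filters annotate calls; tumour–normal pairs receive a somatic/germline
status backed by a binomial power check; technical duplicates can be
intersected to suppress library artefacts. A count-level simulator
generates cohorts with the same statistical structure for benchmarking.

Because true mutations are identified as outliers, the approach targets
variants that are rare in the cohort: variants shared by more than ~20% of
samples get absorbed into the error model and are no longer detected
(`extra_robust` mode mitigates this for moderately common variants).

## Layout

| module | contents |
| --- | --- |
| `nbcall.pileup` | samtools-mpileup text parser (BQ/MQ filtering, indels, strand split) and the flat per-sample counts table |
| `nbcall.model` | robust NB error-model fit, classical ML baseline, NB upper-tail probabilities |
| `nbcall.calling` | p/q/QVAL computation, RVSB, post-calling filters, replicate intersection, tumour–normal status, detectability rule |
| `nbcall.vcfio` | multi-sample VCF v4.2 writer (error model in INFO, per-sample stats in FORMAT) and pysam-based reader for re-scoring |
| `nbcall.simulate` | synthetic cohorts (NB errors, log-uniform-VAF spikes, duplicates), sensitivity/FPR benchmarks, error-rate landscape |
| `nbcall.cli` | `nbcall` command-line tool |

## CLI

```sh
# simulate a cohort: counts table(s) + truth TSV
nbcall simulate --seed 7 --n-samples 100 --n-sites 20 --depth 5000 \
    --error-rate 1e-3 --n-spikes 10 --duplicates -o cohort

# call variants (counts table, mpileup or VCF input) -> multi-sample VCF
nbcall call cohort.counts.tsv -o calls.vcf --min-qval 50
nbcall call sample.mpileup --format mpileup --samples s1,s2,s3 -o calls.vcf
nbcall call cohort.counts.tsv --tn-pairs pairs.tsv -o calls.vcf   # somatic status
nbcall call cohort.counts.tsv --replicates cohort.rep2.counts.tsv -o calls.vcf

# sensitivity benchmark against the simulator's truth
nbcall benchmark --counts cohort.counts.tsv --counts-rep2 cohort.rep2.counts.tsv \
    --truth cohort.truth.tsv -o sensitivity.tsv

# error-rate landscape (decade x base-change table)
nbcall landscape --counts cohort.counts.tsv -o landscape.tsv
```

Exit codes: 0 success, 1 usage error, 2 data error. Germline calling:
`--germline` (threshold 30, extra-robust fit).

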