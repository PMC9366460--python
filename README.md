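# heliopipe

Data-preparation and simulation machinery for multispecies-coalescent
(MSC/MSci) analyses of unphased diploid genome data, built around the
workflow used to study species divergence and introgression in the
*Heliconius erato–sara* clade.

Full-likelihood coalescent inference (bpp-style) wants thousands of short,
well-spaced, strictly filtered multilocus alignments in which heterozygous
sites are kept as IUPAC ambiguity codes rather than collapsed or phased by
guesswork. `heliopipe` provides the pieces that turn raw genotype calls
into such data — and a generative simulator to verify every piece against
known truth:

- **`error_model`** — the analytic genotype-calling error model. Under a
  binomial read model with per-read base-calling error ε, the genotype
  likelihoods at a site with k alternative reads out of n are
  `L(00|k) = C(n,k)(1−ε)^(n−k) ε^k`, `L(01|k) = C(n,k)(1/2)^n`,
  `L(11|k) = C(n,k)(1−ε)^k ε^(n−k)`; the calling error is the binomial
  expectation of the miscall indicator. The error is famously
  *non-monotone* in both n and ε; the module tabulates it exactly and
  recommends minimum-depth filters (`DP ≥ 20` keeps error `< 0.05%` at
  ε = 0.001). It also estimates ε empirically from AD counts at deep
  homozygous sites.
- **`variant_qc`** — the genotype filter cascade
  (`QUAL ≥ 20`, `GQ ≥ 20`, `max(meanDP/2, 20) ≤ DP ≤ 2·meanDP`, 5-bp indel
  masking, haploid-Z depth floor 10), recoding failures as missing.
- **`locus_builder`** — extraction of noncoding loci (≥ 100 bp, ≤ 2 kb,
  ≥ 2 kb apart) and uncapped one-per-region coding loci; repeat masking,
  missing-data rules, unphased IUPAC alignments, 100/200-locus blocks
  (trailing blocks < 40 loci dropped), bpp-style phylip + Imap output.
- **`phase_tools`** — exhaustive heterozygote phase enumeration
  (`2^(h−1)` unordered resolutions for h het sites), seeded random phasing
  and haploid consensus for robustness experiments.
- **`synthetic_data`** — a coalescent simulator on species networks with
  introgression: lineages coalesce at rate 2/θ per pair in mutational
  time and cross horizontal edges with probability γ at timed events;
  JC69 sequences, diploid individuals, and a binomial read channel emit
  reference FASTA + GFF3 + BED + VCF + truth files. The default network is
  the six-species *erato–sara* history with its four introgression events.
- **`summaries`** — closed-form triplet topology probabilities under ILS
  (`P(discordant) = (2/3)e^(−2Δτ/θ)`), topology tallies, τ→years
  conversion, and through-origin regression.

## Worked example

```python
import numpy as np
import heliopipe as hp
from heliopipe.error_model import GenotypeClass, genotype_error_rate

# the depth-filter justification: calling error at epsilon = 0.001, DP = 20
hom = genotype_error_rate(GenotypeClass.HOM_REF, 20, 0.001)
het = genotype_error_rate(GenotypeClass.HET, 20, 0.001)
print(f"hom {hom:.2e}  het {het:.2e}")      # hom 1.13e-06  het 4.02e-04

# the anomaly: lowering the base error raises the calling error at n = 7
print(genotype_error_rate(GenotypeClass.HOM_REF, 7, 0.010))  # 0.002031...
print(genotype_error_rate(GenotypeClass.HOM_REF, 7, 0.005))  # 0.034479...

# end-to-end: simulate a genome on the default introgression network,
# filter the calls, extract loci, group blocks
net = hp.synthetic_data.default_network()
cfg = hp.synthetic_data.SimConfig(n_loci=60, locus_length=(120, 250))
result = hp.pipeline.run_pipeline(net, cfg, "demo_out", seed=7)
print(result.recovery, len(result.blocks))   # 1.0 1

# root divergence in calendar years at mu = 2.9e-9 /site/gen, 4 gen/yr
print(hp.summaries.mutation_scaled_to_years(0.027, hp.summaries.HELICONIUS_SCALE))
# 2327586.2  (~2.3 Myr)
```

The first block prints the error rates that motivate the `DP ≥ 20` filter:
at the empirically estimated ε ≈ 0.001, even the worse heterozygote class
stays at 4×10⁻⁴ (< 0.05%). The pipeline run reports that every planted
locus was recovered through filtering and extraction and grouped into one
100-locus-capped block.

A thin CLI mirrors the library: `heliopipe errormodel | filtergt | extract
| phase | simulate | summarize | run` (see `heliopipe --help`).

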