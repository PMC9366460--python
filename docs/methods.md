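# Methods

This note records the models implemented in `heliopipe`, the defaults they
ship with, and the design choices made where more than one reasonable
convention exists.

## Genotype-calling error under a binomial read model

A biallelic site in one diploid sample is covered by `n` reads of which `k`
support the alternative allele. With a per-read base-calling error `eps`
(assumed identical across reads and independent of the true base), the
three genotype likelihoods are binomial:

    L(00 | k) = C(n,k) (1-eps)^(n-k) eps^k
    L(01 | k) = C(n,k) (1/2)^n
    L(11 | k) = C(n,k) (1-eps)^k eps^(n-k)

The call is the argmax; the genotype-calling error for a true genotype is
the expectation of the miscall indicator over `k ~ Binomial(n, p)` with
`p = eps` for a true homozygote and `p = 1/2` for a true heterozygote.
Because the call is a threshold rule on a discrete variable, the error is
non-monotone in both `n` and `eps`: at `eps = 0.01` the homozygote error
*rises* from 0.0199 at `n = 2` to 0.0585 at `n = 6` before collapsing at
`n = 7`, and at `n = 7` *halving* `eps` from 0.01 to 0.005 raises the error
from 0.0020 to 0.0345. `recommend_min_depth` therefore checks the whole
depth suffix `[n*, n_max]`, not just `n*`, and signals explicitly when no
floor attains the target.

Numerical choices: binomial pmfs use exact integer coefficients with
log-space powers (stable for subnormal `eps`, and within 1e-12 of exact
rational arithmetic for `n <= 100`, asserted in the tests). The HOM_ALT
likelihood is computed as the reflected pmf `pmf(n-k, n, eps)` so the
homozygote symmetry is exact in floating point. Exact likelihood ties are
broken by the fixed preference HET > HOM_REF > HOM_ALT; no reported
quantity sits on a tie (for `eps < 0.5` the `k = n/2` tie always resolves
to HET anyway). In haploid mode (single-copy chromosomes, e.g. the Z in
female Lepidoptera) there are two genotype classes and ties at `k = n/2`
resolve to REF, which makes the ALT error marginally larger at even depths;
this asymmetry is unavoidable whichever side the tie prefers.

The empirical base-error estimator follows the deep-homozygote procedure:
only homozygous calls with `DP >= 50` outside repeat-masked intervals are
used, erroneous reads are `DP` minus the AD entry of the called allele, and
the estimate is summed errors over summed depth, separately for GT=00 and
GT=11. Multi-allelic records are excluded (the estimator is biallelic);
allele 0 is the VCF REF.

## Genotype filter cascade

Retained genotypes must satisfy, in this order (used for the failure
tally): site `QUAL >= 20`; `GQ >= 20`; per-sample depth window
`max(mean_dp/2, 20) <= DP <= 2*mean_dp` (floor 10 for haploid samples);
not within 5 bp of an indel. Failures are recoded as missing rather than
removed. Conventions the VCF does not pin down:

- `mean_dp` is fixed per sample from a single pass over QUAL-passing called
  genotypes, before any depth filtering, so the window does not depend on
  its own outcome.
- The 5 bp indel window is measured from the indel's VCF anchor (POS);
  deletions additionally mask 5 bp beyond their REF span — the conservative
  reading.
- FORMAT/DP is preferred; INFO/DP is the fallback when a sample lacks it.

The cascade is idempotent and monotone in each threshold (property-tested),
and on synthetic data the discordance of retained genotypes with the
simulated truth is bounded by the analytic error at the minimum retained
depth (tested at 3 binomial standard errors).

## Locus extraction

Coding regions are merged exons; noncoding regions are their complement
(introns plus intergenic). The noncoding scan moves left to right and
initiates a locus at the first position at least 2,000 bp beyond the end of
the previous locus with at least 100 bp left in the region, extending to
the region end or 2,000 bp. The 2 kb spacing approximates free
recombination between loci while each short locus is treated as
recombination-free. Coding loci get one uncapped locus per merged region
under the same gates. Two unstated endpoint conventions were fixed here:
the 2 kb gap is measured end-to-start (inter-locus gap), and it applies
across region boundaries and to coding loci as well.

Alignment cleaning order is fixed: (1) drop repeat-overlapping columns;
(2) reject the locus if more than 50% of remaining cells (sites x
individuals) are missing; (3) drop every column containing any missing
cell; (4) reject if fewer than 10 columns remain. Heterozygotes are IUPAC
ambiguity codes throughout; sequences are never phased here.
Parsimony-informativeness on diploid data is counted by letting each IUPAC
code contribute both alleles: a column is informative when at least two
alleles are each carried by at least two individuals (a documented
heuristic; conventions vary for ambiguity data).

Blocks chunk loci in genomic order per chromosome region into groups of 100
(or 200); a trailing group of fewer than 40 loci is dropped. Internal
coordinates are 0-based half-open; VCF and GFF3 are converted on read, BED
is native. The multilocus phylip writer labels sequences `id^individual`
so the caret token resolves through the Imap file.

## Phase utilities

A sequence with `h` heterozygous sites has `max(1, 2^(h-1))` distinct
unordered phase resolutions (the first het site is fixed to a canonical
orientation to avoid double counting); the count law is asserted against
brute-force enumeration up to `h = 12`. Random phasing draws uniformly over
resolutions and the haploid consensus picks one base per het site —
both mimic the chimaeric haplotypes of assembly-based pipelines and are
reproducible by seed. Likelihood-weighted averaging over resolutions inside
tree likelihoods is deliberately not reimplemented here; it belongs to the
downstream MSC inference engine.

## The species-network simulator

The network is a rooted species tree with node ages `tau` and branch
population parameters `theta = 4*N*mu`, both in expected substitutions per
site, plus timed introgression events. `gamma` is stored as the probability
that a recipient lineage takes the horizontal (donor) edge backward in
time; configs written for inference tools that parameterize the same edge
as `phi` (with introgression probability `1 - phi`) should be converted
explicitly — the two conventions differ only by complementation, a known
source of sign errors. Bidirectional events are two paired events at equal
time, applied to a snapshot of the pre-event state so one lineage cannot
cross twice in the same instant.

Simulation is the standard backward-in-time algorithm: between breakpoints
(node ages, event times) each branch with `k` lineages coalesces at total
rate `k(k-1)/theta` (pair rate `2/theta` in mutational time); competing
exponentials pick the branch. The simulator is checked against the
closed-form within-population pairwise time (mean `theta/2`, exponential),
the rooted-triplet discordance probability `(2/3) exp(-2*delta_tau/theta)`
on a six-point grid, the configured `gamma` via horizontal-edge usage
counts, and an independent coalescent engine (msprime) by a two-sample
Kolmogorov–Smirnov test on pairwise coalescent ages.

Sequences evolve under JC69 only (branch length is already the expected
substitutions per site; richer substitution models belong to the inference
stage, not the test harness). Diploid individuals are two independent
haplotype draws from their species — random mating, as the MSC assumes.

The shipped default network reproduces the six-species *Heliconius
erato–sara* introgression history: backbone
`((((Era,Him),Sia),Tel),(Dem,Sar))` with `tau` = 0.005 (Era–Him), 0.015
(+Sia), 0.021 (+Tel), 0.012 (Dem–Sar), 0.027 (root); events Tel→Sia with
`gamma = 0.80` just below the Sia split (the hybrid-speciation signal), an
ancient Tel↔(Dem,Sar)-ancestor exchange at 0.018 with `gamma` 0.35/0.10, a
sister-species Era↔Him exchange at 0.002 with 0.15/0.05, and weak Sar→Dem
flow (0.005). The published estimates for this system are printed as
per-chromosome ranges; the defaults take one consistent value inside each
range, with `theta = 0.01` for every population (the typical order of the
published estimates). All defaults are overridable.

## The read channel and synthetic datasets

Per site and individual the depth is Poisson (default mean 30, matching
high-coverage resequencing; a fixed-depth mode exists for calibration
runs); each read samples one of the two alleles evenly and is miscalled as
the site's companion allele with probability `eps` (default 0.001, the
order of the empirical base-error estimate for such data). The companion of
a heterozygote is its other allele; for homozygotes it is the reference
allele, or a per-site random alternative when the individual matches the
reference — the same two-allele folding the analytic model uses, so the
channel's discordance is exactly the analytic error rate (verified at
10^6 sites within 3 binomial standard errors). Calls use the ML rule at the
channel's own `eps`; GQ is the phred-scaled likelihood ratio of the best to
the second-best genotype, capped at 99; zero depth yields a missing call.
Site QUAL is emitted as a constant high value: modelling site-quality
miscalibration is out of scope, and the QUAL filter is unit-tested
directly.

`generate_dataset` lays loci on one synthetic chromosome separated by
2,100 bp spacers and writes the annotation so extraction re-derives exactly
the planted loci (spacers annotated as exons for noncoding datasets, loci
as exons for coding ones). It emits reference FASTA, GFF3, BED repeats,
a multi-sample VCF with GT/DP/GQ/AD, per-locus true gene trees (newick) and
true diploid alignments. Output is byte-identical under a fixed seed.

What the generator does *not* emulate: mapping and alignment artifacts,
indel calling, site-quality miscalibration, depth autocorrelation along the
genome, intralocus recombination, and continuous (IM-style) gene flow.
Passing tests therefore validate the pipeline's rule logic and the
coalescent/likelihood mathematics, not robustness to alignment error in
real data.

## Problem sizes

Statistical checks run at desk scale: 10^4 replicates for coalescent
moments and topology grids, 10^6 sites for read-channel calibration, and
500 planted loci (about 110 kb of genotyped sites across six diploid
individuals) for the end-to-end recovery run, with 60-locus versions in the
unit suite. These sizes put 3-standard-error bands well inside the effect
sizes being verified.

## Known limitations

- The simulator assumes one panmictic population per branch; inversion
  polymorphism or other ancestral structure is not modelled.
- The informative-site count on IUPAC data is a heuristic; do not compare
  its absolute values against tools that count haploid columns.
- The haploid (Z) path shares the filter plumbing but the synthetic
  generator only emits autosomal (diploid) data.
- `proportional_regression` reports `r^2 = 1 - RSS / sum(y^2)`;
  through-origin `r^2` conventions differ across packages.
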