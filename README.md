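# carrotdom

Population-genetic and expression analysis of carrot domestication from
pooled root-transcriptome sequencing — an error-model SNP caller for
pooled samples, diversity and differentiation statistics with bootstrap
CIs, joint site-frequency-spectrum machinery, a
bottleneck–growth–migration demographic model fitted by composite
likelihood, and a unique-expression contrast — exercised end to end on
synthetic data generated in-repo.

**Who it is for.** Researchers studying crop domestication (or any
two-population divergence) from pooled sequencing of a handful of
libraries, who need genotypes from k-individual pools with a defensible
error model, standard diversity summaries, and a fitted demographic
history without hand-rolling the SFS plumbing.

## The statistics at the core

*Pooled calling.* With nucleotide counts ranked n₁ ≥ n₂ ≥ n₃ ≥ n₄ and
n = Σnᵢ per sample and position, the per-nucleotide error rate is
ε = (n₃ + n₄)/(2n); the largest plausible error count is
n_E = qbinom(0.99, n, ε); and a pool of k diploids contains a
heterozygote iff the corrected minor count exceeds the 1% quantile at the
minimum pool allele ratio, (n₂ − n_E) > qbinom(0.01, n, 1/(2k)).
Positions need reads in every sample, ≤ 1 missing genotype, ≥ 2 distinct
genotypes and ≤ 2 alleles to be SNP sites.

*Diversity and structure.* He = 1 − Σp², % polymorphic loci, θ_π, θ_w
(per site or per kb), Tajima's D, and Hudson's Fst as a ratio of
averages, all with percentile CIs from 1000 bootstrap resamples of SNP
positions.

*Demography.* Wild carrot constant at N_W; the cultivated lineage splits
T_B + T generations ago, bottlenecks at ν_B·N_W for T_B generations, then
grows exponentially to ν_C·N_W with gene flow m_WC (into wild) and m_CW
(into cultivated).  Three migration variants (none / symmetric /
asymmetric) are fitted to the folded joint SFS projected to 10×10 by
maximizing a multinomial composite likelihood with θ profiled out; CIs
come from refitting spectra resampled over SNPs.  Expected spectra come
from either a coalescent Monte-Carlo engine (msprime branch lengths) or
a deterministic moment-ODE engine — same contract, cross-checked against
each other.

*Expression.* Per-sample normalized coverage is contrasted as
d = (m_C − m_W)/((m_C + m_W)/2) ∈ [−2, 2]; contigs covered in ≥ 5 of 6
cultivated (or ≥ 4 of 5 wild) libraries and absent from the entire other
group are unique-expression calls.

## Worked example

```bash
python analysis/01_simulate_and_call.py --seed 42 --n-positions 1500
python analysis/02_diversity.py --seed 42 --boot 200
python analysis/04_expression.py --seed 42 --n-contigs 2000 --boot 300
```

prints (numbers are produced by the runs above):

```
1500 positions simulated -> 1494 callable -> 375 SNP sites retained

cultivated: He=0.196 P=0.627 D=+1.085
      wild: He=0.224 P=0.892 D=+0.104
Fst(cultivated, wild) = 0.131 (95% CI 0.114 - 0.150)
cultivated/wild He ratio = 0.88

mean expression difference d = -0.067 (95% CI -0.107 - -0.029) over 2000 contigs
unique expression: 174 cultivated-only, 47 wild-only (planted: 174/47; recovered exactly: True)
```

Reading it: of 1500 simulated transcriptome positions, 375 pass the
error-model caller and SNP-site filters.  Under the fitted domestication
history the cultivated group keeps ~88% of wild heterozygosity but shows
the bottleneck's signature (strongly positive Tajima's D) and clear
differentiation from wild carrot.  The expression contrast recovers every
planted on/off contig and a small overall down-regulation in cultivated
roots.  `analysis/03_demography.py` fits the three migration variants to
a simulated ~600-SNP joint spectrum and bootstraps CIs for the
asymmetric-model parameters.

A `carrotdom` command-line interface wraps the same library
(`carrotdom call-snps|stats|sfs|fit-demography|expression|simulate|run`);
`carrotdom run --config analysis.yaml` executes the whole pipeline with a
reproducibility manifest.

## Layout

```
src/carrotdom/    library: caller, popgen, sfs, sfs_ode, demography,
                  expression, simulate, io_formats, pipeline, cli
analysis/         numbered narrative drivers writing results/
tests/            pytest suite incl. end-to-end acceptance checks
scripts/          acceptance.py
docs/methods.md   model details, conventions, limitations
```
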