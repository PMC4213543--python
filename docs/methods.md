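# Methods

This package re-implements, as a tested pipeline on synthetic data, the
statistical core of a domestication study of carrot root transcriptomes:
SNP discovery from pooled RNA-seq libraries with an explicit sequencing
error model, diversity and differentiation statistics with bootstrap
confidence intervals, joint site-frequency-spectrum (SFS) machinery, a
bottleneck–growth–migration demographic model fitted by composite
likelihood, and an expression contrast that flags genes switched on or
off by domestication.

## Pooled-sample genotype calling

Each library pools k diploid individuals (k = 3 for most samples, k = 2
for one), so any true allele has pool frequency ≥ 1/(2k).  At a position,
with nucleotide counts ranked n1 ≥ n2 ≥ n3 ≥ n4 and n = Σnᵢ:

* error rate ε = (n3 + n4) / (2n): the top two nucleotides are treated as
  potential alleles, everything else as sequencing error; division by two
  gives a per-specific-nucleotide rate.  Note that at a truly homozygous
  position the largest of the three error piles is counted as "n2", so ε
  is a slight underestimate there; at heterozygous positions it is
  unbiased.  The pipeline's mean ε over all samples and positions floors
  the local estimate (a locally clean position still allows for the
  experiment-wide error rate).
* n_E = qbinom(0.99, n, ε_used): the largest error count plausible at the
  99% level.  Only nucleotides with counts above n_E are valid alleles;
  zero or more than two valid alleles, ε ≥ 0.05, more than one 'N' base,
  or n < 2k make the call missing.
* heterozygote rule: the pool contains a heterozygote iff the corrected
  minor count n2 − n_E exceeds qbinom(0.01, n, 1/(2k)) — simultaneously
  "too common for error" and "no rarer than a single heterozygous
  individual would make it".  Both one-sided 1% rules bound the
  false-het and false-allele rates by construction; the calibration test
  measures them at ≤ 2% over depths 10–500 and ε ∈ [0, 0.02].

SNP sites are positions with reads in every retained sample, at most one
missing genotype, at least two distinct genotypes, and at most two
alleles.  Strict inequalities are used throughout ("larger than n_E",
"higher than the expected minimum"), and ties in count ranking are broken
by the fixed order A<C<G<T; three-way ties are discarded by the
two-allele rule anyway.

## Diversity statistics

He = 1 − Σp² averaged over loci; P = fraction of loci with ≥ 2 observed
alleles; θπ = Σ 2p(1−p)·n/(n−1); θw = Σ 1/a_{n_site} (equal to S/a_n for
complete data); all computed from observed allele copies (heterozygote =
one copy of each allele, missing = nothing), optionally per site or per
kb given a surveyed length L — L is a required user input because the
appropriate denominator (callable sites vs full reference) is a study
choice.  Tajima's D uses the 1989 variance constants; with missing data
the constants use the modal per-site sample size and sites with fewer
than four observed copies are skipped — the statistic is only exactly
defined for complete data, and the test suite checks exact agreement with
an enumeration oracle there.  Fst defaults to Hudson's estimator as a
ratio of averages (robust to unequal and small sample sizes), with
Weir & Cockerham (1984) available behind a flag.  All confidence
intervals are percentile intervals from 1000 bootstrap resamples of SNP
positions (seeded).

## SFS machinery

Spectra are arrays indexed by derived (unfolded) or minor (folded) allele
copies, with fixed corners always masked.  Polarization uses an outgroup:
a locus with at least four non-missing outgroup genotype calls takes the
most frequent outgroup allele as ancestral; ties and under-called loci
stay unpolarized and are folded.  Projection to a smaller sample size is
the exact hypergeometric average over subsamples, applied per axis; loci
with missing calls are projected per locus straight onto the target grid.
Folding sums complementary entries, keeps the 50/50 diagonal once, and
masks the major half; projection of a folded spectrum goes through its
canonical unfolding, which provably commutes with folding.

## Demographic model

Wild carrot keeps a constant size N_W.  The cultivated lineage splits
T_B + T generations ago, sits at size ν_B·N_W for T_B generations, then
grows exponentially to ν_C·N_W over the last T generations, during which
gene flow occurs (m_WC into wild, m_CW into cultivated; three variants:
none, symmetric, asymmetric).  Parameters are expressed relative to N_W
(sizes ν = N/N_W with N counted in gene copies, times in N_W generations,
migration in 1/N_W per generation); `as_units("2NW")` converts to the
2N-based convention used by diffusion tools, since published values of
this kind often leave the factor of two implicit.

Two interchangeable engines compute the expected joint SFS:

* **coalescent** (default for `expected_sfs`): msprime branch-length
  frequency spectra averaged over replicates and scaled by 1/(2N_W), so a
  constant-size marginal tends to 1/i.  Unbiased; Monte-Carlo noise
  ~ 1/√reps.
* **ode** (default for fitting): the moment equations of the
  Wright–Fisher diffusion integrated directly in the spectrum entries.
  Neutral drift closes exactly at the sample size (tridiagonal generator
  with stationary solution 1/i); migration couples to spectra one sample
  larger in the source population and is closed by a quadratic jackknife
  (exact for locally quadratic frequency densities).  The ancestral
  equilibrium spectrum is split hypergeometrically at the divergence
  time; the bottleneck phase is propagated exactly in the product
  eigenbasis of the two commuting drift generators; the growth phase uses
  Crank–Nicolson steps (max_step 0.15 time units; halving the step
  changes entries by < 0.5%).  Against the coalescent engine the folded
  10×10 spectra agree to a median ~3–4% per entry, within Monte-Carlo
  error plus closure error.

The fitting objective is the multinomial composite log-likelihood with
the overall mutation rate θ profiled out analytically (a Poisson mode is
also provided).  The optimizer is Nelder–Mead on log-parameters with
multiple random log-uniform starts; the deterministic ODE objective is
what makes this search reliable — with the Monte-Carlo engine the
likelihood noise at affordable replicate counts is the same size as the
signal distinguishing the weakly identified parameters.  The coalescent
engine remains the independent cross-check: a contract test verifies the
two engines agree entrywise.

Model comparison chains the variants: the no-migration optimum seeds the
symmetric fit (with m = 0 evaluated exactly as a candidate), and both
seed the asymmetric fit, so the nesting inequality
ll(none) ≤ ll(sym) ≤ ll(asym) holds on every dataset by construction.
2Δll is compared to χ² (df 1 or 2) with the explicit caveat that
composite-likelihood ratio tests are approximations.

Parameter CIs are percentile intervals over bootstrap refits of data
resampled over SNP positions (for an observed spectrum this is a
multinomial resample of its entries).  Each bootstrap refit uses one
random start plus a wide-simplex start at the point estimate: the
likelihood surface at ~600 folded SNPs is a broad ridge along which very
different (ν_B, T_B, T, ν_C) combinations fit almost equally well, and
narrow warm-started refits would understate that uncertainty.

## Synthetic data

Generators are pure functions of config + seed.  Pileups: per position a
population allele frequency (uniform on [0.05, 0.95] for the polymorphic
fraction), 2k pool copies binomial, depth negative-binomial (mean 30,
matching the study's per-library coverage; dispersion 0.3, typical
RNA-seq overdispersion), reads multinomial with per-specific-nucleotide
error (default 0.005).  Genotype matrices come from msprime (JC69
mutations, many short independent 5-kb replicates so retained SNPs are
nearly unlinked) under either the domestication model or a two-deme
island model calibrated so Hudson's equilibrium Fst = 1/(1 + 8Nm) hits a
target; outgroup individuals carry the ancestral allele.  Observed
spectra are entrywise Poisson draws around θ× the expected SFS.
Expression tables: log-normal baselines × per-contig group effects ×
per-sample depth factors with negative-binomial noise; planted
unique-expression contigs (defaults 174 cultivated-only and 47 wild-only,
the counts reported for the real transcriptome) are zeroed in the other
group with presence enforced in their own.

What the generators do **not** emulate: linkage between SNP sites within
a transcript, ascertainment bias of a validated SNP panel, reference/
mapping bias of pooled alignment, and library-specific error-rate
heterogeneity.  Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated model, not robustness to
those real-data complications.

## Expression contrast

Coverage is normalized per sample by its mean over all contigs (spacer
bases are excluded from any denominator by construction, as they receive
no alignments).  The difference statistic d = (m_C − m_W)/((m_C + m_W)/2)
uses the mean of the two group means in the denominator: with unequal
group sizes (6 vs 5) this is the only convention that keeps d in [−2, 2]
and exactly antisymmetric under group exchange; the literal grand mean
over all samples is available via `denominator="grand-mean"`.  "Present"
means coverage > 0; unique-expression calls require presence in ≥ 5 of 6
cultivated (resp. ≥ 4 of 5 wild) samples and zero coverage in the entire
other group, with the thresholds scaling as ceilings of the same
fractions for other group sizes.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at the scale the
analyses are designed for: caller calibration on 10⁴ positions, oracle
equivalence on 10³ positions × 10 pools, a 622-SNP diversity panel,
spectra projected to 10×10 and folded with ~600 SNPs, and the recovery
experiment at 20 replicates with 24 bootstrap refits each.  With a
modest number of refits the sample 2.5%/97.5% quantiles cannot be
resolved beyond the extreme order statistics, so the demographic CIs use
the conservative order-statistic convention (lower/higher) rather than
interpolation; more refits sharpen the tails at proportional cost.  Composite-likelihood model floors
(1e-12 of total mass) prevent infinite penalties from empty model
entries.  All randomness flows from explicit seeds; reruns are
bit-for-bit reproducible.

## Known limitations

* The migration closure makes the ODE engine approximate (few percent per
  entry); fits of migration-heavy histories inherit that bias, which is
  small against the sampling noise of a ~600-SNP spectrum.
* At this data size the demographic parameters are only weakly
  identified: the composite-likelihood surface is nearly flat along
  trade-offs between bottleneck depth, duration, and growth time, so
  point estimates scatter widely and honest CIs are wide.  This mirrors
  the wide intervals reported for this class of analyses.
* Composite-likelihood p-values ignore linkage between sites and should
  be read as heuristics.
* Tajima's D under missing data uses a fixed-n convention (modal per-site
  sample size); alternatives differ at the few-percent level.
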