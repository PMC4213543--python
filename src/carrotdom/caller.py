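"""Error-model genotype calling for pooled RNA-seq samples.

Each sequenced sample is a pool of k diploid individuals (k=3 for most
carrot samples, k=2 for WPT), so a real minor allele is present at a
frequency of at least 1/(2k) in the pool.  Calling proceeds per sample and
position from the ranked nucleotide counts n1 >= n2 >= n3 >= n4:

1. the two non-allele nucleotides estimate the per-nucleotide sequencing
   error rate, eps = (n3 + n4) / (2 n);
2. the largest plausible error count n_E is the 0.99 binomial quantile of
   (n, eps_used), where eps_used is floored at the global mean eps over
   all samples and positions so that locally error-free positions are not
   over-trusted;
3. nucleotides with counts above n_E are valid alleles; anything other
   than one or two valid alleles makes the call missing;
4. the pool contains a heterozygous individual when the error-corrected
   minor count n2 - n_E exceeds the 0.01 binomial quantile of
   (n, 1/(2k)) - i.e. a minor allele too common to be explained by error
   yet compatible with a single heterozygote in the pool.

Missing ('N') is also assigned when eps >= 0.05, or when fewer than 2k
reads cover the position.  SNP sites are then selected across samples:
reads present in every retained sample, at most one missing genotype, at
least two distinct genotypes, and at most two alleles.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix


class CallState(enum.Enum):
    HOMOZYGOUS = "hom"
    HETEROZYGOUS = "het"
    MISSING = "missing"


@dataclass(frozen=True)
class PoolSpec:
    """Pooling design of one sample: k diploid individuals per pool."""

    k: int

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("individuals_per_pool must be >= 1")

    @property
    def min_reads(self) -> int:
        """Minimum read depth to genotype: one read per chromosome, 2k."""
        return 2 * self.k

    @property
    def min_allele_ratio(self) -> float:
        """Lowest true frequency of an allele in the pool, 1/(2k)."""
        return 1.0 / (2 * self.k)


@dataclass
class ErrorModel:
    """Binomial sequencing-error model shared across the calling rules.

    epsilon_global_mean is the mean per-nucleotide error rate over all
    samples and positions; it floors the local estimate when computing
    n_E.  Positions where the local rate itself reaches
    ``local_epsilon_cutoff`` (0.05) are not trusted at all.
    ``denominator`` selects whether the raw error estimate divides the
    minor-nucleotide total by 2n (per-specific-nucleotide rate, default)
    or by n.
    """

    epsilon_global_mean: float = 0.0
    quantile_valid: float = 0.99
    quantile_het: float = 0.01
    local_epsilon_cutoff: float = 0.05
    denominator: str = "2n"  # "2n" | "n"

    def __post_init__(self):
        if not 0 <= self.epsilon_global_mean <= 1:
            raise ValueError("epsilon_global_mean must be in [0, 1]")
        for q in (self.quantile_valid, self.quantile_het):
            if not 0 < q < 1:
                raise ValueError("quantiles must be in (0, 1)")
        if self.denominator not in ("2n", "n"):
            raise ValueError("denominator must be '2n' or 'n'")


@dataclass
class GenotypeCall:
    """Outcome of calling one sample at one position."""

    state: CallState
    alleles: tuple[int, ...]  # codes; () when missing
    n: int = 0
    n1: int = 0
    n2: int = 0
    n_E: int = 0

    @property
    def codes(self) -> tuple[int, int]:
        if self.state is CallState.MISSING:
            return (MISSING, MISSING)
        if self.state is CallState.HOMOZYGOUS:
            return (self.alleles[0], self.alleles[0])
        return tuple(sorted(self.alleles))  # type: ignore[return-value]


def _ranked(counts: np.ndarray) -> np.ndarray:
    """Nucleotide codes sorted by descending count, ties by A<C<G<T."""
    return np.lexsort((np.arange(4), -np.asarray(counts)))


def estimate_error_rate(counts, denominator: str = "2n") -> float:
    """Per-nucleotide error rate from the two non-allele counts.

    eps = (n3 + n4) / (2 n): the most- and second-most-observed
    nucleotides are treated as real alleles, everything else as error;
    dividing by 2 (two error nucleotides observed out of the possible
    substitution targets) converts to a rate per specific nucleotide.
    """
    counts = np.asarray(counts)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("position has no reads: error rate undefined")
    order = _ranked(counts)
    n3n4 = int(counts[order[2]] + counts[order[3]])
    denom = 2 * n if denominator == "2n" else n
    return n3n4 / denom


def binomial_quantile(p: float, n: int, rate: float) -> int:
    """Smallest integer q with Binomial(n, rate) CDF(q) >= p."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if rate <= 0:
        return 0
    return int(stats.binom.ppf(p, n, rate))


def max_errors(n: int, epsilon_local: float, model: ErrorModel) -> int:
    """Largest plausible error count n_E at the 0.99 level.

    The local error estimate is floored at the global mean so a locally
    clean position (eps=0) still allows for the experiment-wide error
    rate.
    """
    eps_used = max(epsilon_local, model.epsilon_global_mean)
    return binomial_quantile(model.quantile_valid, n, eps_used)


def heterozygote_test(n: int, n2: int, n_E: int, pool: PoolSpec,
                      quantile_het: float = 0.01) -> bool:
    """Does the corrected minor count support a heterozygote in the pool?

    True iff (n2 - n_E) exceeds the `quantile_het` binomial quantile of
    (n, 1/(2k)): the minor allele is both too common for error and at
    least as common as expected for a single heterozygous individual.
    """
    threshold = binomial_quantile(quantile_het, n, pool.min_allele_ratio)
    return (n2 - n_E) > threshold


def call_genotype(counts, pool: PoolSpec, model: ErrorModel,
                  count_n_bases: int = 0) -> GenotypeCall:
    """Call one sample at one position from its A/C/G/T counts.

    Missing when: >1 'N' base observed (such positions are normally
    removed before calling, see `call_pileup`), local eps >= 0.05, depth
    below 2k, or the number of valid alleles is 0 or >2.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if count_n_bases > 1 or n == 0:
        return GenotypeCall(CallState.MISSING, (), n=n)
    eps_local = estimate_error_rate(counts, model.denominator)
    order = _ranked(counts)
    n1, n2 = int(counts[order[0]]), int(counts[order[1]])
    if eps_local >= model.local_epsilon_cutoff:
        return GenotypeCall(CallState.MISSING, (), n=n, n1=n1, n2=n2)
    if n < pool.min_reads:
        return GenotypeCall(CallState.MISSING, (), n=n, n1=n1, n2=n2)
    n_E = max_errors(n, eps_local, model)
    valid = [int(a) for a in order if counts[a] > n_E]
    if len(valid) == 0 or len(valid) > 2:
        return GenotypeCall(CallState.MISSING, (), n=n, n1=n1, n2=n2, n_E=n_E)
    if heterozygote_test(n, n2, n_E, pool, model.quantile_het):
        top2 = (int(order[0]), int(order[1]))
        return GenotypeCall(CallState.HETEROZYGOUS, top2, n=n, n1=n1, n2=n2, n_E=n_E)
    return GenotypeCall(CallState.HOMOZYGOUS, (int(order[0]),), n=n, n1=n1, n2=n2, n_E=n_E)


# ----------------------------------------------------------------------
# whole-pileup calling
# ----------------------------------------------------------------------

def global_mean_epsilon(pileup: pd.DataFrame, denominator: str = "2n") -> float:
    """Mean local error rate over all (position, sample) pairs with reads."""
    counts = pileup[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
    n = counts.sum(axis=1)
    keep = n > 0
    top2 = np.sort(counts[keep], axis=1)[:, :2].sum(axis=1)  # n3+n4
    denom = (2 * n[keep]) if denominator == "2n" else n[keep]
    if keep.sum() == 0:
        return 0.0
    return float(np.mean(top2 / denom))


def call_pileup(
    pileup: pd.DataFrame,
    pools: dict[str, int],
    model: ErrorModel | None = None,
    exclude: tuple[str, ...] = (),
    groups: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Call every sample at every eligible position of a pileup.

    Positions must have reads in all retained samples (samples listed in
    `exclude`, e.g. the very-low-coverage WNL-M library, are dropped
    first), and positions where any sample shows more than one 'N' base
    are removed outright.  When `model` is None the global mean error
    rate is estimated from the eligible positions themselves.
    """
    df = pileup[~pileup["sample_id"].isin(exclude)]
    samples = sorted(set(df["sample_id"]))
    for s in samples:
        if s not in pools:
            raise KeyError(f"no pool size for sample {s!r}")
    wide = df.set_index(["contig_id", "pos", "sample_id"]).unstack("sample_id")
    # positions with reads present in all samples and no >1-N sample
    depth = wide[["A", "C", "G", "T"]].T.groupby(level="sample_id").sum().T
    n_bases = wide["N"]
    eligible = (depth.notna() & (depth > 0)).all(axis=1) & (
        n_bases.fillna(0) <= 1
    ).all(axis=1)
    wide = wide[eligible]
    if model is None:
        sub = df.set_index(["contig_id", "pos"]).loc[wide.index].reset_index()
        model = ErrorModel(epsilon_global_mean=global_mean_epsilon(sub))
    loci = list(wide.index)
    codes = np.full((len(loci), len(samples), 2), MISSING, dtype=np.int8)
    for j, s in enumerate(samples):
        pool = PoolSpec(pools[s])
        acgt = wide.loc[:, [(b, s) for b in "ACGT"]].to_numpy(dtype=np.int64)
        nn = wide.loc[:, ("N", s)].to_numpy(dtype=np.int64)
        for i in range(len(loci)):
            call = call_genotype(acgt[i], pool, model, count_n_bases=int(nn[i]))
            codes[i, j] = call.codes
    return GenotypeMatrix(codes, loci, samples, groups=groups)


def select_snp_sites(gm: GenotypeMatrix, max_missing: int = 1) -> GenotypeMatrix:
    """SNP-site filter across samples.

    Retains positions with at most `max_missing` missing genotypes, at
    least two distinct non-missing genotypes, and at most two alleles.
    """
    keep = np.zeros(gm.n_loci, dtype=bool)
    for i in range(gm.n_loci):
        calls = gm.codes[i]
        present = calls[calls[:, 0] != MISSING]
        n_missing = gm.n_samples - len(present)
        if n_missing > max_missing or len(present) == 0:
            continue
        distinct_genotypes = {tuple(c) for c in present}
        alleles = set(present.ravel().tolist())
        keep[i] = len(distinct_genotypes) >= 2 and len(alleles) <= 2
    return gm.subset_loci(keep)
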