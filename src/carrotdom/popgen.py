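"""Diversity and differentiation statistics with bootstrap CIs.

Estimators used for the domestication contrast: mean expected
heterozygosity He, proportion of polymorphic loci P, nucleotide diversity
theta_pi, Watterson's theta_w (per site, or per kb given the surveyed
length L), Tajima's D, and Fst between groups (Hudson ratio-of-averages by
default, Weir & Cockerham 1984 as an alternative).  Confidence intervals
come from resampling SNP positions (1000 bootstrap samples by default).

Allele frequencies use observed allele copies only: a heterozygote
contributes one copy of each allele, missing calls contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .genotypes import GenotypeMatrix


def _freqs(counts: np.ndarray):
    """Per-locus (major-or-first allele frequency, observed copies)."""
    n = counts.sum(axis=1)
    return counts, n


def expected_heterozygosity(gm: GenotypeMatrix, group=None) -> float:
    """Mean per-locus expected heterozygosity, He = 1 - sum(p_a^2).

    Loci with no observed alleles in the group are excluded from the
    mean.
    """
    counts, n = _freqs(gm.allele_counts(group))
    keep = n > 0
    if not keep.any():
        raise ValueError("no locus has observed alleles in this group")
    p = counts[keep] / n[keep, None]
    he = 1.0 - (p**2).sum(axis=1)
    return float(he.mean())


def proportion_polymorphic(gm: GenotypeMatrix, group=None) -> float:
    """Fraction of loci with more than one observed allele in the group."""
    counts, n = _freqs(gm.allele_counts(group))
    keep = n > 0
    n_alleles = (counts[keep] > 0).sum(axis=1)
    return float((n_alleles >= 2).mean())


def _pairwise_het_per_site(counts: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2p(1-p) n/(n-1), multi-allele safe."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / n[:, None]
        h = (1.0 - (p**2).sum(axis=1)) * n / (n - 1)
    return h


def theta_pi(gm: GenotypeMatrix, group=None, L: float | None = None,
             per_kb: bool = False) -> float:
    """Nucleotide diversity: mean pairwise differences over L sites.

    With L=None the sum over SNP sites is returned undivided ("total"
    diversity of the SNP panel); with L it is per site, or per kb when
    `per_kb`.
    """
    counts, n = _freqs(gm.allele_counts(group))
    keep = n >= 2
    total = float(_pairwise_het_per_site(counts[keep], n[keep]).sum())
    return _scale(total, L, per_kb)


def theta_w(gm: GenotypeMatrix, group=None, L: float | None = None,
            per_kb: bool = False) -> float:
    """Watterson's theta: segregating sites over the harmonic number a_n.

    Per-site sample sizes may differ when calls are missing, so each
    segregating site contributes 1/a_{n_site}; with complete data this is
    exactly S / a_n.
    """
    counts, n = _freqs(gm.allele_counts(group))
    seg = ((counts > 0).sum(axis=1) >= 2) & (n >= 2)
    a_n = np.array([_harmonic(int(m) - 1) for m in n[seg]])
    total = float((1.0 / a_n).sum()) if seg.any() else 0.0
    return _scale(total, L, per_kb)


def _scale(total: float, L, per_kb: bool) -> float:
    if L is None:
        return total
    if L <= 0:
        raise ValueError("surveyed length L must be positive")
    return total / L * (1000.0 if per_kb else 1.0)


def _harmonic(k: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, k + 1)))


def tajimas_d(gm: GenotypeMatrix, group=None, min_alleles: int = 4) -> float:
    """Tajima's (1989) D over the group's segregating sites.

    Sites with fewer than `min_alleles` observed copies are skipped.  The
    variance constants use the modal per-site sample size; with complete
    data this is the textbook statistic.  Returns NaN when no site
    segregates.
    """
    counts, n = _freqs(gm.allele_counts(group))
    usable = n >= min_alleles
    counts, n = counts[usable], n[usable]
    seg = (counts > 0).sum(axis=1) >= 2
    S = int(seg.sum())
    if S == 0:
        import warnings

        warnings.warn("Tajima's D undefined with no segregating sites")
        return float("nan")
    pi_total = float(_pairwise_het_per_site(counts[seg], n[seg]).sum())
    sizes, freq = np.unique(n[seg], return_counts=True)
    n_mode = int(sizes[np.argmax(freq)])
    a1 = _harmonic(n_mode - 1)
    a2 = _harmonic(n_mode - 1, 2)
    b1 = (n_mode + 1) / (3 * (n_mode - 1))
    b2 = 2 * (n_mode**2 + n_mode + 3) / (9 * n_mode * (n_mode - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n_mode + 2) / (a1 * n_mode) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    w_total = S / a1
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0 if pi_total == w_total else float("nan")
    return float((pi_total - w_total) / np.sqrt(var))


# ----------------------------------------------------------------------
# Fst
# ----------------------------------------------------------------------

@dataclass
class FstEstimate:
    fst: float
    ci: tuple[float, float] | None = None


def _hudson_components(gm: GenotypeMatrix, groupA, groupB):
    cA, nA = _freqs(gm.allele_counts(groupA))
    cB, nB = _freqs(gm.allele_counts(groupB))
    # biallelic: frequency of the overall-first observed allele
    both = cA + cB
    first = np.argmax(both > 0, axis=1)
    idx = np.arange(gm.n_loci)
    pA = np.where(nA > 0, cA[idx, first] / np.maximum(nA, 1), np.nan)
    pB = np.where(nB > 0, cB[idx, first] / np.maximum(nB, 1), np.nan)
    ok = (nA >= 2) & (nB >= 2)
    num = (pA - pB) ** 2 - pA * (1 - pA) / np.maximum(nA - 1, 1) - pB * (
        1 - pB
    ) / np.maximum(nB - 1, 1)
    den = pA * (1 - pB) + pB * (1 - pA)
    ok &= den > 0  # loci monomorphic in both groups carry no signal
    return num[ok], den[ok]


def _wc_components(gm: GenotypeMatrix, groupA, groupB):
    """Weir & Cockerham (1984) a, b, c variance components per locus."""
    comps = []
    for i in range(gm.n_loci):
        stats_pp = []
        for grp in (groupA, groupB):
            idx = gm.sample_indices(grp)
            calls = gm.codes[i, idx]
            called = calls[calls[:, 0] >= 0]
            if len(called) == 0:
                break
            alleles = np.unique(np.concatenate([gm.codes[i][gm.codes[i] >= 0]]))
            if len(alleles) > 2 or len(alleles) == 0:
                break
            ref = alleles[0]
            p = (called == ref).sum() / (2 * len(called))
            h = (called[:, 0] != called[:, 1]).mean()
            stats_pp.append((len(called), p, h))
        if len(stats_pp) < 2:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats_pp
        if n1 < 2 or n2 < 2:
            continue
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        if pbar in (0.0, 1.0) and s2 == 0:
            continue
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        comps.append((a, a + b + c))
    arr = np.array(comps) if comps else np.zeros((0, 2))
    return arr[:, 0], arr[:, 1]


def fst(gm: GenotypeMatrix, groupA, groupB, estimator: str = "hudson") -> FstEstimate:
    """Genetic differentiation between two groups (ratio of averages).

    Numerator and denominator are averaged over loci separately, which is
    the robust way to combine loci with unequal information.  Loci
    monomorphic in both groups are excluded.
    """
    if estimator == "hudson":
        num, den = _hudson_components(gm, groupA, groupB)
    elif estimator == "weir-cockerham":
        num, den = _wc_components(gm, groupA, groupB)
    else:
        raise ValueError(f"unknown Fst estimator {estimator!r}")
    if len(den) == 0 or den.sum() == 0:
        raise ValueError("no informative loci for Fst")
    return FstEstimate(fst=float(num.sum() / den.sum()))


# ----------------------------------------------------------------------
# bootstrap over SNP positions
# ----------------------------------------------------------------------

def bootstrap_ci(
    statistic: Callable[[GenotypeMatrix], float],
    gm: GenotypeMatrix,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile CI from resampling loci with replacement, seeded."""
    if gm.n_loci < 2:
        raise ValueError("bootstrap needs at least two loci")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, gm.n_loci, size=gm.n_loci)
        vals[b] = statistic(gm.subset_loci(idx))
    lo, hi = np.nanpercentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass
class DiversityEstimates:
    """One group's row of the diversity table, with 95% CIs."""

    group: str
    He: float
    P: float
    theta_pi: float
    theta_w: float
    tajimas_D: float
    ci: dict[str, tuple[float, float]]


def diversity_table(
    gm: GenotypeMatrix,
    groups: list[str],
    L: float | None = None,
    per_kb: bool = False,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[DiversityEstimates]:
    """He, P, theta_pi, theta_w and Tajima's D per group with bootstrap CIs."""
    out = []
    for g_i, g in enumerate(groups):
        stats_fns = {
            "He": lambda m, g=g: expected_heterozygosity(m, g),
            "P": lambda m, g=g: proportion_polymorphic(m, g),
            "theta_pi": lambda m, g=g: theta_pi(m, g, L, per_kb),
            "theta_w": lambda m, g=g: theta_w(m, g, L, per_kb),
            "tajimas_D": lambda m, g=g: tajimas_d(m, g),
        }
        point = {k: f(gm) for k, f in stats_fns.items()}
        cis = {
            k: bootstrap_ci(f, gm, n_boot=n_boot, seed=None if seed is None else seed + 1000 * g_i + j)
            for j, (k, f) in enumerate(stats_fns.items())
        }
        out.append(DiversityEstimates(group=g, ci=cis, **point))
    return out
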