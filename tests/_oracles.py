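"""Independent brute-force oracles used by the test suite.

Everything here is written as a direct, slow transliteration of the
method descriptions - explicit loops, enumeration, exact CDF summation -
and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

NUCS = "ACGT"


# ----------------------------------------------------------------------
# binomial quantile by exact CDF summation
# ----------------------------------------------------------------------

def brute_binomial_quantile(p: float, n: int, rate: float) -> int:
    if rate <= 0:
        return 0
    cdf = 0.0
    for q in range(n + 1):
        cdf += math.comb(n, q) * rate**q * (1 - rate) ** (n - q)
        if cdf >= p:
            return q
    return n


# ----------------------------------------------------------------------
# prose transliteration of the pooled caller
# ----------------------------------------------------------------------

def prose_call(counts, n_bases, k, eps_global, denominator="2n"):
    """Returns ('missing',), ('hom', a) or ('het', a, b) with codes sorted.

    Follows the calling prose rule by rule: rank nucleotides, estimate
    the error rate from the third- and fourth-ranked counts, floor at the
    global mean, binomial 0.99 quantile for the maximum error count,
    valid-allele count, then the corrected-minor-count heterozygote test
    against the 0.01 quantile at ratio 1/(2k).
    """
    counts = list(counts)
    n = sum(counts)
    if n_bases > 1 or n == 0:
        return ("missing",)
    order = sorted(range(4), key=lambda a: (-counts[a], a))
    n1, n2, n3, n4 = (counts[a] for a in order)
    eps = (n3 + n4) / (2 * n if denominator == "2n" else n)
    if eps >= 0.05:
        return ("missing",)
    if n < 2 * k:
        return ("missing",)
    eps_used = max(eps, eps_global)
    n_E = brute_binomial_quantile(0.99, n, eps_used)
    valid = [a for a in order if counts[a] > n_E]
    if len(valid) == 0 or len(valid) > 2:
        return ("missing",)
    threshold = brute_binomial_quantile(0.01, n, 1 / (2 * k))
    if (n2 - n_E) > threshold:
        return ("het",) + tuple(sorted(order[:2]))
    return ("hom", order[0])


def prose_site_filter(site_calls, max_missing=1):
    """Keep a site: <=1 missing, >=2 distinct non-missing genotypes,
    <=2 alleles across samples."""
    present = [c for c in site_calls if c[0] != "missing"]
    if len(site_calls) - len(present) > max_missing or not present:
        return False
    genotypes = set(present)
    alleles = set()
    for c in present:
        alleles.update(c[1:])
    return len(genotypes) >= 2 and len(alleles) <= 2


# ----------------------------------------------------------------------
# diversity statistics by explicit counting
# ----------------------------------------------------------------------

def _site_alleles(calls):
    """Observed allele copies at one site: list of codes, two per call."""
    out = []
    for c in calls:
        if c[0] == "het":
            out.extend([c[1], c[2]])
        elif c[0] == "hom":
            out.extend([c[1], c[1]])
    return out


def naive_he(sites):
    """sites: list of per-site call lists."""
    vals = []
    for calls in sites:
        alleles = _site_alleles(calls)
        if not alleles:
            continue
        n = len(alleles)
        h = 1.0
        for a in set(alleles):
            h -= (alleles.count(a) / n) ** 2
        vals.append(h)
    return sum(vals) / len(vals)


def naive_prop_polymorphic(sites):
    flags = []
    for calls in sites:
        alleles = _site_alleles(calls)
        if not alleles:
            continue
        flags.append(len(set(alleles)) >= 2)
    return sum(flags) / len(flags)


def naive_pi_total(sites):
    """Mean pairwise differences, summed over sites, by pair enumeration."""
    total = 0.0
    for calls in sites:
        alleles = _site_alleles(calls)
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(
            1 for i, j in itertools.combinations(range(n), 2)
            if alleles[i] != alleles[j]
        )
        total += diffs / math.comb(n, 2)
    return total


def naive_w_total(sites):
    total = 0.0
    for calls in sites:
        alleles = _site_alleles(calls)
        n = len(alleles)
        if n < 2 or len(set(alleles)) < 2:
            continue
        total += 1.0 / sum(1 / i for i in range(1, n))
    return total


def naive_tajimas_d(sites, min_alleles=4):
    """Tajima 1989 with the published constants, complete data assumed."""
    used = [c for c in sites if len(_site_alleles(c)) >= min_alleles]
    seg = [c for c in used if len(set(_site_alleles(c))) >= 2]
    S = len(seg)
    if S == 0:
        return float("nan")
    n = len(_site_alleles(seg[0]))
    pi = naive_pi_total(seg)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def naive_hudson_fst(sites_a, sites_b):
    """Hudson ratio of averages from two aligned per-site call lists."""
    nums, dens = [], []
    for ca, cb in zip(sites_a, sites_b):
        aa, ab = _site_alleles(ca), _site_alleles(cb)
        na, nb = len(aa), len(ab)
        if na < 2 or nb < 2:
            continue
        alleles = sorted(set(aa) | set(ab))
        ref = alleles[0]
        p1 = aa.count(ref) / na
        p2 = ab.count(ref) / nb
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den == 0:
            continue
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (na - 1)
            - p2 * (1 - p2) / (nb - 1)
        )
        nums.append(num)
        dens.append(den)
    return sum(nums) / sum(dens)


# ----------------------------------------------------------------------
# SFS helpers
# ----------------------------------------------------------------------

def hypergeom_weight(m, j, n, i):
    """P(i of n subsampled copies are derived | j of m are derived)."""
    if i > j or (n - i) > (m - j):
        return 0.0
    return math.comb(j, i) * math.comb(m - j, n - i) / math.comb(m, n)


def naive_fold_1d(counts):
    n = len(counts) - 1
    out = [0.0] * len(counts)
    for x, c in enumerate(counts):
        comp = n - x
        if x < comp:
            out[x] += c + counts[comp]
        elif x == comp:
            out[x] += c
    return out


def genotype_calls_from_matrix(gm, group=None):
    """Convert a GenotypeMatrix group into oracle-style per-site calls."""
    idx = gm.sample_indices(group)
    sites = []
    for i in range(gm.n_loci):
        calls = []
        for j in idx:
            a, b = int(gm.codes[i, j, 0]), int(gm.codes[i, j, 1])
            if a < 0:
                calls.append(("missing",))
            elif a == b:
                calls.append(("hom", a))
            else:
                calls.append(("het", a, b))
        sites.append(calls)
    return sites
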