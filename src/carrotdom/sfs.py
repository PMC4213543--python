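"""Site-frequency-spectrum construction, polarization, projection, folding.

A 1D or 2D SFS holds SNP counts indexed by derived (unfolded) or minor
(folded) allele copy number; the 2D case is the joint spectrum of two
populations.  The fixed corners ([0], [n]; [0,0], [n1,n2]) carry no
polymorphism information and are always masked; folding additionally
masks the major-allele half.  Masked entries are excluded from
likelihoods but still store any mass moved into them, so projection and
folding conserve total mass over the full array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@lru_cache(maxsize=64)
def _default_mask_cached(shape, folded: bool) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(0 for _ in shape)] = True
    mask[tuple(d - 1 for d in shape)] = True
    if folded:
        tote = _total_index(shape)
        mask |= tote > (sum(d - 1 for d in shape)) / 2
    return mask


def _default_mask(shape, folded: bool) -> np.ndarray:
    return _default_mask_cached(tuple(shape), folded).copy()


@lru_cache(maxsize=64)
def _total_index(shape) -> np.ndarray:
    """Array whose entry is the summed index along all axes."""
    grids = np.indices(shape)
    return grids.sum(axis=0)


@dataclass
class SiteFrequencySpectrum:
    """SNP counts by allele copy number, with mask and folding state."""

    counts: np.ndarray
    mask: np.ndarray | None = None
    folded: bool = False
    pop_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")
        if self.mask is None:
            self.mask = _default_mask(self.counts.shape, self.folded)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape must match counts shape")

    @property
    def ndim(self) -> int:
        return self.counts.ndim

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(d - 1 for d in self.counts.shape)

    def total(self) -> float:
        """Mass over unmasked entries (number of usable SNPs)."""
        return float(self.counts[~self.mask].sum())

    def grand_total(self) -> float:
        """Mass over every entry, masked corners included."""
        return float(self.counts.sum())

    def unmasked(self) -> np.ndarray:
        return self.counts[~self.mask]

    def copy(self) -> "SiteFrequencySpectrum":
        return SiteFrequencySpectrum(
            self.counts.copy(), self.mask.copy(), self.folded, self.pop_labels
        )

    def __eq__(self, other):
        if not isinstance(other, SiteFrequencySpectrum):
            return NotImplemented
        return (
            self.folded == other.folded
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.counts, other.counts, rtol=1e-12, atol=0)
        )


# ----------------------------------------------------------------------
# polarization
# ----------------------------------------------------------------------

def polarize(gm: GenotypeMatrix, outgroup: GenotypeMatrix,
             min_outgroup_calls: int = 4) -> GenotypeMatrix:
    """Set per-locus ancestral alleles from outgroup genotypes.

    A locus is polarized when the outgroup has at least
    `min_outgroup_calls` non-missing genotype calls; the outgroup allele
    at highest frequency is then considered ancestral.  Frequency ties
    and under-called loci stay unpolarized (to be folded downstream).
    """
    if outgroup.loci != gm.loci:
        raise ValueError("outgroup calls must be aligned to the same loci")
    ancestral = np.full(gm.n_loci, MISSING, dtype=np.int8)
    counts = outgroup.allele_counts()
    n_calls = outgroup.n_samples - outgroup.missing_per_locus()
    for i in range(gm.n_loci):
        if n_calls[i] < min_outgroup_calls:
            continue
        c = counts[i]
        top = c.max()
        if top == 0 or (c == top).sum() > 1:
            continue
        ancestral[i] = int(np.argmax(c))
    out = gm.subset_loci(np.arange(gm.n_loci))
    out.ancestral = ancestral
    return out


# ----------------------------------------------------------------------
# construction
# ----------------------------------------------------------------------

def _projection_weights(m: int, j: int, n: int) -> np.ndarray:
    """Hypergeometric weights of entry j (of m copies) onto 0..n copies."""
    i = np.arange(n + 1)
    return stats.hypergeom.pmf(i, m, j, n)


def build_sfs(
    gm: GenotypeMatrix,
    groups: tuple[str, str] | tuple[str],
    polarized: bool = True,
    target_sizes: tuple[int, ...] | None = None,
) -> SiteFrequencySpectrum:
    """Tally the (joint) SFS from a genotype matrix.

    Diploid genotypes contribute two allele copies.  Loci where every
    call is complete add one count at their derived-copy coordinates;
    loci with missing calls are redistributed to `target_sizes` with
    hypergeometric projection weights so the spectrum stays on one
    sample-size grid.  With ``polarized=False`` the orientation is
    arbitrary and the result is folded to the minor-allele convention;
    polarized loci lacking an ancestral allele are skipped.
    """
    idx = [gm.sample_indices(g) for g in groups]
    full_sizes = tuple(2 * len(ix) for ix in idx)
    if target_sizes is None:
        target_sizes = full_sizes
    if any(t > f for t, f in zip(target_sizes, full_sizes)):
        raise ValueError("target sizes cannot exceed sampled copies")
    shape = tuple(t + 1 for t in target_sizes)
    counts = np.zeros(shape)
    all_counts = [gm.allele_counts(g) for g in groups]
    n_skipped = 0
    for i in range(gm.n_loci):
        per_group = [c[i] for c in all_counts]
        observed = np.flatnonzero(sum(per_group))
        if len(observed) > 2:
            raise ValueError(f"locus {gm.loci[i]} has >2 alleles")
        if any(c.sum() == 0 for c in per_group):
            n_skipped += 1
            continue
        if polarized:
            anc = gm.ancestral[i]
            if anc == MISSING or (anc not in observed and len(observed) > 1):
                n_skipped += 1
                continue
            derived_candidates = [a for a in observed if a != anc]
            derived = derived_candidates[0] if derived_candidates else None
        else:
            derived = observed[-1] if len(observed) > 1 else None
        weights = []
        for c, t in zip(per_group, target_sizes):
            m = int(c.sum())
            d = int(c[derived]) if derived is not None else 0
            if m == t:
                w = np.zeros(t + 1)
                w[d] = 1.0
            elif m > t:
                w = _projection_weights(m, d, t)
            else:  # fewer observed copies than the target: cannot project up
                weights = None
                break
            weights.append(w)
        if weights is None:
            n_skipped += 1
            continue
        if len(weights) == 1:
            counts += weights[0]
        else:
            counts += np.outer(weights[0], weights[1])
    if n_skipped:
        logger.info("build_sfs: skipped %d loci (unpolarized or no calls)", n_skipped)
    out = SiteFrequencySpectrum(counts, folded=False, pop_labels=tuple(groups))
    return fold(out) if not polarized else out


# ----------------------------------------------------------------------
# projection and folding
# ----------------------------------------------------------------------

def project(sfs: SiteFrequencySpectrum, target_sizes) -> SiteFrequencySpectrum:
    """Project to smaller sample sizes by hypergeometric re-averaging.

    Equivalent to averaging the spectrum over all possible subsamples of
    the requested size, applied independently along each axis.  Total
    mass (masked corners included) is conserved; projecting to the
    current size is the identity.  Folded input is projected via its
    canonical unfolding and re-folded, which commutes with folding.
    """
    target_sizes = tuple(int(t) for t in np.atleast_1d(target_sizes))
    if len(target_sizes) != sfs.ndim:
        raise ValueError("need one target size per axis")
    cur = sfs.sample_sizes
    if any(t > c for t, c in zip(target_sizes, cur)):
        raise ValueError(f"cannot project {cur} up to {target_sizes}")
    was_folded = sfs.folded
    counts = np.where(sfs.mask & (sfs.counts == 0), 0.0, sfs.counts)
    for axis, (m, n) in enumerate(zip(cur, target_sizes)):
        if m == n:
            continue
        w = np.array([_projection_weights(m, j, n) for j in range(m + 1)])
        counts = np.moveaxis(
            np.tensordot(np.moveaxis(counts, axis, 0), w, axes=([0], [0])),
            -1,
            axis,
        )
    out = SiteFrequencySpectrum(counts, folded=False, pop_labels=sfs.pop_labels)
    return fold(out) if was_folded else out


def fold(sfs: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Fold to the minor-allele convention; idempotent.

    Entry x and its complement (n - x jointly over all axes) are summed
    into the minor-frequency half; entries at exactly half frequency are
    kept once; the major half is zeroed and masked.
    """
    counts = np.where(sfs.mask & (sfs.counts == 0), 0.0, sfs.counts)
    rev = counts[tuple(slice(None, None, -1) for _ in range(counts.ndim))]
    folded = counts + rev
    tote = _total_index(counts.shape)
    half = sum(d - 1 for d in counts.shape) / 2
    folded[tote == half] *= 0.5
    folded[tote > half] = 0.0
    mask = _default_mask(counts.shape, folded=True)
    return SiteFrequencySpectrum(folded, mask=mask, folded=True,
                                 pop_labels=sfs.pop_labels)
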