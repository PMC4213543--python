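"""Shared genotype-matrix container.

Biallelic SNP calls for pooled or individual samples.  Each call is an
unordered pair of nucleotide codes (A=0, C=1, G=2, T=3); homozygotes carry
the same code twice and missing calls are ``(-1, -1)``.  Samples carry
group labels (``cultivated`` / ``wild`` / ``outgroup`` in the domestication
analysis, but any labels work).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

NUCLEOTIDES = "ACGT"
NUC_TO_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}
MISSING = -1


class GenotypeMatrix:
    """Calls for ``n_loci`` sites by ``n_samples`` samples.

    Parameters
    ----------
    codes:
        int8 array of shape ``(n_loci, n_samples, 2)``; allele codes 0-3,
        missing = -1.  Each pair is stored sorted so het A/G == het G/A.
    loci:
        sequence of ``(contig_id, position)`` tuples (1-based positions).
    samples:
        sample identifiers, one per column.
    groups:
        optional mapping sample -> group label.
    ancestral:
        optional int8 array of per-locus ancestral allele codes
        (-1 = unpolarized).
    """

    def __init__(
        self,
        codes: np.ndarray,
        loci: Sequence[tuple[str, int]],
        samples: Sequence[str],
        groups: Mapping[str, str] | None = None,
        ancestral: np.ndarray | None = None,
    ):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 3 or codes.shape[2] != 2:
            raise ValueError("codes must have shape (n_loci, n_samples, 2)")
        if codes.shape[0] != len(loci):
            raise ValueError("codes/loci length mismatch")
        if codes.shape[1] != len(samples):
            raise ValueError("codes/samples length mismatch")
        # normalize: missing pairs are (-1,-1); pairs sorted
        codes = np.sort(codes, axis=2)
        half_missing = (codes[:, :, 0] == MISSING) & (codes[:, :, 1] != MISSING)
        if np.any(half_missing):
            raise ValueError("half-missing calls are not representable")
        self.codes = codes
        self.loci = list(loci)
        self.samples = list(samples)
        self.groups = dict(groups) if groups is not None else {}
        if ancestral is None:
            ancestral = np.full(codes.shape[0], MISSING, dtype=np.int8)
        self.ancestral = np.asarray(ancestral, dtype=np.int8)
        if self.ancestral.shape != (codes.shape[0],):
            raise ValueError("ancestral must be one code per locus")

    # ------------------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def sample_indices(self, group: str | Iterable[str] | None = None) -> np.ndarray:
        """Column indices of the samples in `group` (all samples if None).

        `group` may also be an explicit iterable of sample names.
        """
        if group is None:
            return np.arange(self.n_samples)
        if isinstance(group, str):
            names = [s for s in self.samples if self.groups.get(s) == group]
            if not names:
                raise KeyError(f"no samples in group {group!r}")
        else:
            names = list(group)
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[s] for s in names], dtype=int)

    # ------------------------------------------------------------------
    def allele_counts(self, group=None) -> np.ndarray:
        """Per-locus counts of observed allele copies, shape (n_loci, 4).

        Heterozygotes contribute one copy of each allele, homozygotes two
        of the same; missing calls contribute nothing.
        """
        idx = self.sample_indices(group)
        sub = self.codes[:, idx, :].reshape(self.n_loci, -1)
        counts = np.zeros((self.n_loci, 4), dtype=np.int64)
        for a in range(4):
            counts[:, a] = (sub == a).sum(axis=1)
        return counts

    def missing_per_locus(self, group=None) -> np.ndarray:
        idx = self.sample_indices(group)
        return (self.codes[:, idx, 0] == MISSING).sum(axis=1)

    def distinct_alleles(self, group=None) -> list[np.ndarray]:
        """Sorted array of allele codes observed at each locus."""
        counts = self.allele_counts(group)
        return [np.flatnonzero(c) for c in counts]

    # ------------------------------------------------------------------
    def subset_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.codes[idx],
            [self.loci[i] for i in idx],
            self.samples,
            self.groups,
            self.ancestral[idx],
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            self.codes[:, idx, :],
            self.loci,
            [self.samples[i] for i in idx],
            {s: g for s, g in self.groups.items() if s in set(names)},
            self.ancestral,
        )

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.codes, other.codes)
            and self.loci == other.loci
            and self.samples == other.samples
            and self.groups == other.groups
            and np.array_equal(self.ancestral, other.ancestral)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_loci} loci x {self.n_samples} samples, "
            f"groups={sorted(set(self.groups.values()))})"
        )
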