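"""File formats and reference-contig handling.

The pipeline exchanges four small text formats:

* nucleotide-count pileups (TSV: contig_id, pos, sample_id, A, C, G, T, N),
* genotype matrices (minimal VCF 4.2 with GT fields only),
* site frequency spectra (dimensions / flat counts / mask dialect, so files
  interchange with diffusion-based SFS tools),
* per-contig coverage tables (TSV, contigs x samples).

It also implements the reference construction step: contigs assembled de
novo are kept when mean coverage >= 40 or length >= 500 bases, and the
selected contigs are concatenated with a 30-letter NNNNNNNNNNCCCCCCCCCCNNNNNNNNNN
spacer designed not to disturb read alignment at contig ends.
"""

from __future__ import annotations


from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, NUC_TO_CODE, NUCLEOTIDES, GenotypeMatrix

SPACER = "N" * 10 + "C" * 10 + "N" * 10

PILEUP_COLUMNS = ["contig_id", "pos", "sample_id", "A", "C", "G", "T", "N"]


@dataclass
class ContigRecord:
    """A de novo assembled contig with its mapping summary."""

    contig_id: str
    length: int
    mean_coverage: float
    sequence: str | None = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"contig {self.contig_id}: length must be >= 1")
        if self.mean_coverage < 0:
            raise ValueError(f"contig {self.contig_id}: coverage must be >= 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"contig {self.contig_id}: sequence/length mismatch")


def select_reference_contigs(
    contigs: Sequence[ContigRecord],
    min_coverage: float = 40.0,
    min_length: int = 500,
) -> list[ContigRecord]:
    """Keep contigs with mean coverage >= 40 OR length >= 500 bases.

    The coverage threshold targets contigs covered well enough (3-4 reads
    per sample) to genotype every pooled sample; the length threshold keeps
    long contigs regardless.  Order is preserved; an empty input gives an
    empty output.
    """
    return [
        c
        for c in contigs
        if c.mean_coverage >= min_coverage or c.length >= min_length
    ]


class ReferenceMap:
    """Coordinate map between contig-local and concatenated positions.

    All positions are 1-based.  Spacer bases belong to no contig:
    ``to_local`` returns None for them, and they are excluded from any
    coverage denominator (they receive no alignments by design).
    """

    def __init__(self, contigs: Sequence[ContigRecord]):
        ids = [c.contig_id for c in contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig_id: concatenated mapping would be ambiguous")
        self.contigs = list(contigs)
        self._offsets = {}
        self._starts = []  # concatenated start (0-based) of each contig
        off = 0
        for i, c in enumerate(contigs):
            self._offsets[c.contig_id] = off
            self._starts.append(off)
            off += c.length
            if i < len(contigs) - 1:
                off += len(SPACER)
        self.total_length = off

    def to_concatenated(self, contig_id: str, pos: int) -> int:
        c = next(c for c in self.contigs if c.contig_id == contig_id)
        if not 1 <= pos <= c.length:
            raise ValueError(f"position {pos} outside contig {contig_id}")
        return self._offsets[contig_id] + pos

    def to_local(self, pos: int) -> tuple[str, int] | None:
        """Map a concatenated position back; None if it falls in a spacer."""
        if not 1 <= pos <= self.total_length:
            raise ValueError(f"position {pos} outside reference")
        i = bisect_right(self._starts, pos - 1) - 1
        c = self.contigs[i]
        local = pos - self._starts[i]
        if local > c.length:
            return None
        return c.contig_id, local


def concatenate_reference(contigs: Sequence[ContigRecord]) -> tuple[str, ReferenceMap]:
    """Concatenate contig sequences with the 10N+10C+10N spacer."""
    if not all(c.sequence is not None for c in contigs):
        raise ValueError("all contigs must carry sequences")
    ref_map = ReferenceMap(contigs)
    sequence = SPACER.join(c.sequence for c in contigs)
    return sequence, ref_map


# ----------------------------------------------------------------------
# pileup TSV
# ----------------------------------------------------------------------

def write_pileup_tsv(pileup: pd.DataFrame, path) -> None:
    df = pileup[PILEUP_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> pd.DataFrame:
    """Read a nucleotide-count pileup; one row per (contig, pos, sample)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "sample_id": str})
    except Exception as exc:  # add file context
        raise ValueError(f"{path}: malformed pileup TSV ({exc})") from exc
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pileup TSV missing columns {sorted(missing)}")
    counts = df[["A", "C", "G", "T", "N"]].to_numpy()
    if (counts < 0).any():
        bad = int(np.argwhere((counts < 0).any(axis=1))[0][0])
        raise ValueError(f"{path}: line {bad + 2}: negative count")
    return df[PILEUP_COLUMNS]


# ----------------------------------------------------------------------
# minimal VCF 4.2
# ----------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write biallelic calls as a minimal VCF 4.2 with GT fields only.

    REF is the lower allele code (or the ancestral allele when set), ALT
    the other observed allele; monomorphic loci get ALT='.'.  Missing
    calls are './.'.  Group labels are not part of VCF; keep them in a
    side table.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=carrotdom",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples),
    ]
    counts = gm.allele_counts()
    for i, (contig, pos) in enumerate(gm.loci):
        observed = np.flatnonzero(counts[i])
        if len(observed) > 2:
            raise ValueError(f"locus {contig}:{pos} has >2 alleles; not representable")
        anc = gm.ancestral[i]
        if anc != MISSING and anc in observed:
            ref = int(anc)
            alts = [a for a in observed if a != ref]
        elif len(observed) > 0:
            ref = int(observed[0])
            alts = [int(a) for a in observed[1:]]
        else:
            ref, alts = 0, []
        alt_str = NUCLEOTIDES[alts[0]] if alts else "."
        code_to_idx = {ref: 0}
        if alts:
            code_to_idx[alts[0]] = 1
        gts = []
        for s in range(gm.n_samples):
            a, b = gm.codes[i, s]
            if a == MISSING:
                gts.append("./.")
            else:
                gts.append(f"{code_to_idx[int(a)]}/{code_to_idx[int(b)]}")
        info = f"AA={NUCLEOTIDES[anc]}" if anc != MISSING else "."
        lines.append(
            f"{contig}\t{pos}\t.\t{NUCLEOTIDES[ref]}\t{alt_str}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, groups=None) -> GenotypeMatrix:
    """Parse a VCF into a GenotypeMatrix (cyvcf2 backend)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci, rows, anc = [], [], []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        codes = []
        for g in var.genotypes:
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                codes.append((MISSING, MISSING))
            else:
                codes.append((NUC_TO_CODE[alleles[a]], NUC_TO_CODE[alleles[b]]))
        loci.append((var.CHROM, var.POS))
        rows.append(codes)
        aa = dict(var.INFO).get("AA")
        anc.append(NUC_TO_CODE.get(aa, MISSING) if aa else MISSING)
    codes = np.array(rows, dtype=np.int8).reshape(len(loci), len(samples), 2)
    return GenotypeMatrix(codes, loci, samples, groups=groups,
                          ancestral=np.array(anc, dtype=np.int8))


def read_genotype_matrix(path, groups=None) -> GenotypeMatrix:
    """Read calls from VCF (``.vcf``) or a simple genotype TSV.

    The TSV dialect has columns contig_id, pos, then one column per sample
    holding two nucleotide letters ('AG', 'CC') or 'NN' for missing.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return read_vcf(path, groups=groups)
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_cols = [c for c in df.columns if c not in ("contig_id", "pos")]
    loci = list(zip(df["contig_id"], df["pos"].astype(int)))
    codes = np.full((len(df), len(sample_cols), 2), MISSING, dtype=np.int8)
    for j, col in enumerate(sample_cols):
        for i, val in enumerate(df[col]):
            if val != "NN":
                codes[i, j] = sorted(NUC_TO_CODE[ch] for ch in val)
    return GenotypeMatrix(codes, loci, sample_cols, groups=groups)


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    rows = {}
    rows["contig_id"] = [c for c, _ in gm.loci]
    rows["pos"] = [p for _, p in gm.loci]
    for j, s in enumerate(gm.samples):
        col = []
        for i in range(gm.n_loci):
            a, b = gm.codes[i, j]
            col.append("NN" if a == MISSING else NUCLEOTIDES[a] + NUCLEOTIDES[b])
        rows[s] = col
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# SFS text dialect
# ----------------------------------------------------------------------

def write_sfs(sfs, path) -> None:
    """Write an SFS: dims+folding line, flat counts, flat 0/1 mask."""
    shape = " ".join(str(d) for d in sfs.counts.shape)
    fold = "folded" if sfs.folded else "unfolded"
    body = " ".join(repr(float(x)) for x in sfs.counts.ravel())
    mask = " ".join("1" if m else "0" for m in sfs.mask.ravel())
    Path(path).write_text(f"{shape} {fold}\n{body}\n{mask}\n")


def read_sfs(path):
    from .sfs import SiteFrequencySpectrum

    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: SFS file needs 3 lines (dims, counts, mask)")
    head = lines[0].split()
    if head[-1] not in ("folded", "unfolded"):
        raise ValueError(f"{path}: line 1: expected 'folded' or 'unfolded' flag")
    folded = head[-1] == "folded"
    shape = tuple(int(x) for x in head[:-1])
    counts = np.array([float(x) for x in lines[1].split()])
    mask = np.array([bool(int(x)) for x in lines[2].split()])
    n_expected = int(np.prod(shape))
    if counts.size != n_expected or mask.size != n_expected:
        raise ValueError(
            f"{path}: {counts.size} counts / {mask.size} mask entries for shape {shape}"
        )
    return SiteFrequencySpectrum(
        counts.reshape(shape), mask=mask.reshape(shape), folded=folded
    )


# ----------------------------------------------------------------------
# coverage tables and group labels
# ----------------------------------------------------------------------

def read_coverage_tsv(path) -> pd.DataFrame:
    """Contigs x samples coverage table, contig_id as index."""
    df = pd.read_csv(path, sep="\t", index_col="contig_id")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative coverage")
    return df


def write_coverage_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="contig_id")


def read_groups_tsv(path) -> dict[str, str]:
    """Two-column TSV sample_id<TAB>group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))


def write_groups_tsv(groups: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)
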