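"""Coverage normalization and the expression-difference contrast.

Read coverage per contig is first normalized within each sample by that
sample's mean coverage over all contigs (so total sequencing effort
cancels), then contrasted between groups with

    d = (m_C - m_W) / ((m_C + m_W) / 2)

where m_C and m_W are the group means of normalized coverage.  The
statistic is bounded in [-2, 2], antisymmetric under swapping the groups,
and hits the boundaries when one group has no coverage at all
("unique expression").  Contigs expressed in (nearly) all samples of one
group and in no sample of the other are called unique-expression contigs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionTable:
    """Raw or normalized coverage, contigs x samples, with group labels."""

    coverage: pd.DataFrame  # index = contig_id, columns = sample_id
    groups: dict[str, str]  # sample_id -> group label

    def __post_init__(self):
        if (self.coverage.to_numpy() < 0).any():
            raise ValueError("coverage must be non-negative")
        unknown = set(self.coverage.columns) - set(self.groups)
        if unknown:
            raise ValueError(f"samples without group labels: {sorted(unknown)}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.coverage.columns if self.groups[s] == group]

    def sample_means(self) -> pd.Series:
        return self.coverage.mean(axis=0)


def normalize_coverage(table: ExpressionTable) -> ExpressionTable:
    """Divide each sample's column by its mean coverage over all contigs.

    After normalization every sample's mean is exactly 1, so samples with
    different sequencing depths become comparable.
    """
    means = table.sample_means()
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"samples with zero total coverage: {bad}")
    return ExpressionTable(table.coverage / means, table.groups)


def expression_difference(
    normalized: ExpressionTable,
    group_cultivated: str = "cultivated",
    group_wild: str = "wild",
    denominator: str = "group-mean",
) -> pd.Series:
    """Per-contig expression difference d between the two groups.

    The default denominator is the mean of the two group means, which
    keeps d in [-2, 2] and symmetric under group exchange regardless of
    unequal group sizes; ``denominator="grand-mean"`` uses the plain mean
    over all samples of both groups instead.  Contigs with no coverage in
    either group are excluded.
    """
    cult = normalized.samples_in(group_cultivated)
    wild = normalized.samples_in(group_wild)
    if not cult or not wild:
        raise ValueError("both groups need at least one sample")
    m_c = normalized.coverage[cult].mean(axis=1)
    m_w = normalized.coverage[wild].mean(axis=1)
    if denominator == "group-mean":
        denom = (m_c + m_w) / 2
    elif denominator == "grand-mean":
        denom = normalized.coverage[cult + wild].mean(axis=1)
    else:
        raise ValueError("denominator must be 'group-mean' or 'grand-mean'")
    keep = denom > 0
    return ((m_c - m_w) / denom)[keep].rename("d")


def mean_difference_ci(
    d: pd.Series | np.ndarray, n_boot: int = 1000, seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Mean d with a percentile bootstrap CI over contigs, seeded."""
    vals = np.asarray(d, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two contigs")
    rng = np.random.default_rng(seed)
    means = np.array(
        [vals[rng.integers(0, len(vals), size=len(vals))].mean() for _ in range(n_boot)]
    )
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(vals.mean()), float(lo), float(hi)


def call_unique_expression(
    raw: ExpressionTable,
    group_cultivated: str = "cultivated",
    group_wild: str = "wild",
    min_cultivated: int | None = None,
    min_wild: int | None = None,
    presence_threshold: float = 0.0,
) -> tuple[list[str], list[str]]:
    """Contigs expressed only in one group.

    Cultivated-unique: coverage above `presence_threshold` in at least
    `min_cultivated` cultivated samples AND zero coverage in every wild
    sample; wild-unique symmetrically.  The defaults scale the original
    presence rules (5 of 6 cultivated varieties, 4 of 5 wild populations)
    to the actual group sizes as ceilings of the same fractions.
    """
    cult = raw.samples_in(group_cultivated)
    wild = raw.samples_in(group_wild)
    if min_cultivated is None:
        min_cultivated = math.ceil(5 / 6 * len(cult))
    if min_wild is None:
        min_wild = math.ceil(4 / 5 * len(wild))
    present = raw.coverage > presence_threshold
    n_cult = present[cult].sum(axis=1)
    n_wild = present[wild].sum(axis=1)
    absent_wild = (raw.coverage[wild] == 0).all(axis=1)
    absent_cult = (raw.coverage[cult] == 0).all(axis=1)
    unique_c = list(raw.coverage.index[(n_cult >= min_cultivated) & absent_wild])
    unique_w = list(raw.coverage.index[(n_wild >= min_wild) & absent_cult])
    return unique_c, unique_w


def histogram(d: pd.Series | np.ndarray, bin_width: float = 0.1) -> pd.DataFrame:
    """Bin d values over [-2, 2]; counts sum to the number of contigs."""
    vals = np.asarray(d, dtype=float)
    n_bins = int(round(4.0 / bin_width))
    edges = np.linspace(-2.0, 2.0, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    # np.histogram is right-open except the last bin, so values at 2.0 land
    # in the final bin and the total is conserved
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
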