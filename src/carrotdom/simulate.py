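"""Synthetic-data generators for every pipeline stage.

Each generator is a pure function of its config (including the seed) and
produces data satisfying the downstream stage's preconditions: pooled
nucleotide-count pileups with sequencing error, two-population genotype
matrices from coalescent simulations, Poisson-sampled joint spectra under
the domestication model, and per-contig coverage tables with planted
unique-expression contigs.  Distributional choices (negative-binomial
depth with dispersion 0.3, log-normal baselines) mimic RNA-seq
overdispersion and are all config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .demography import DomesticationParams, build_demography, expected_sfs
from .expression import ExpressionTable
from .genotypes import NUC_TO_CODE, GenotypeMatrix
from .io_formats import PILEUP_COLUMNS
from .sfs import SiteFrequencySpectrum


def _neg_binomial(rng, mean, dispersion, size):
    """NB draws with var = mean + dispersion * mean^2 (RNA-seq style)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ----------------------------------------------------------------------
# pooled pileups
# ----------------------------------------------------------------------

@dataclass
class PileupSimConfig:
    """Conditions for simulating pooled per-position nucleotide counts."""

    n_positions: int = 1000
    pools: dict[str, int] = field(
        default_factory=lambda: {f"S{i}": 3 for i in range(1, 11)}
    )
    frac_polymorphic: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.95)
    depth_mean: float = 30.0
    depth_dispersion: float = 0.3
    eps_true: float = 0.005  # per-specific-nucleotide error rate
    n_rate: float = 0.0005  # per-read chance of an 'N' base call
    seed: int = 0


def _apply_errors(counts: np.ndarray, eps: float, rng) -> np.ndarray:
    """Substitute each read to each other nucleotide with rate eps."""
    if eps <= 0:
        return counts
    out = counts.copy()
    for b in range(4):
        errs = rng.binomial(counts[:, b], min(3 * eps, 1.0))
        out[:, b] -= errs
        targets = [t for t in range(4) if t != b]
        spread = rng.multinomial(errs, [1 / 3] * 3)
        for k, t in enumerate(targets):
            out[:, t] += spread[:, k]
    return out


def simulate_pooled_pileup(config: PileupSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a pileup and the per-(position, sample) truth table.

    For each position: a population alternative-allele frequency is drawn
    (or zero for monomorphic positions), each pool draws 2k allele
    copies, read depth is negative-binomial, reads are drawn from the
    pooled allele proportions, and sequencing errors substitute each read
    to each other nucleotide with rate `eps_true`.
    """
    rng = np.random.default_rng(config.seed)
    n_pos = config.n_positions
    poly = rng.random(n_pos) < config.frac_polymorphic
    p_alt = np.where(poly, rng.uniform(*config.maf_range, size=n_pos), 0.0)
    ref = rng.integers(0, 4, size=n_pos)
    shift = rng.integers(1, 4, size=n_pos)
    alt = (ref + shift) % 4  # distinct from ref
    pileup_rows, truth_rows = [], []
    for sample, k in config.pools.items():
        copies = rng.binomial(2 * k, p_alt)  # alt copies among 2k
        depth = _neg_binomial(rng, config.depth_mean, config.depth_dispersion,
                              (n_pos,))
        n_bases = rng.binomial(depth, config.n_rate)
        depth_acgt = depth - n_bases
        alt_reads = rng.binomial(depth_acgt, copies / (2 * k))
        counts = np.zeros((n_pos, 4), dtype=np.int64)
        np.add.at(counts, (np.arange(n_pos), ref), depth_acgt - alt_reads)
        np.add.at(counts, (np.arange(n_pos), alt), alt_reads)
        counts = _apply_errors(counts, config.eps_true, rng)
        for i in range(n_pos):
            pileup_rows.append(
                ("sim", i + 1, sample, *counts[i].tolist(), int(n_bases[i]))
            )
            truth_rows.append(
                ("sim", i + 1, sample, int(ref[i]), int(alt[i]),
                 int(copies[i]), 2 * k)
            )
    pileup = pd.DataFrame(pileup_rows, columns=PILEUP_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["contig_id", "pos", "sample_id", "ref_code", "alt_code",
                 "alt_copies", "total_copies"],
    )
    return pileup, truth


# ----------------------------------------------------------------------
# genotype matrices from the coalescent
# ----------------------------------------------------------------------

def _island_demography(fst_target: float, N: float = 10_000.0) -> msprime.Demography:
    """Two diploid demes of size N with symmetric migration tuned so the
    equilibrium Hudson Fst is `fst_target`.

    With 2N gene copies per deme, E[T_within] = 4N and
    E[T_between] = 4N + 1/(2m), so Fst = 1 / (1 + 8 N m) - the classic
    1 / (1 + 4 Nm) in terms of the haploid deme size.
    """
    if not 0 < fst_target < 1:
        raise ValueError("fst_target must be in (0, 1)")
    m = (1.0 / fst_target - 1.0) / (8.0 * N)
    d = msprime.Demography()
    d.add_population(name="A", initial_size=N)
    d.add_population(name="B", initial_size=N)
    d.set_migration_rate(source="A", dest="B", rate=m)
    d.set_migration_rate(source="B", dest="A", rate=m)
    return d


def simulate_genotype_matrix(
    n_per_group: tuple[int, int] = (10, 10),
    n_snps: int = 500,
    seed: int = 0,
    params: DomesticationParams | None = None,
    fst_target: float | None = None,
    group_names: tuple[str, str] = ("wild", "cultivated"),
    n_outgroup: int = 0,
    mu: float = 1e-8,
) -> GenotypeMatrix:
    """Two-population diploid genotype matrix sampled from the coalescent.

    Exactly one of `params` (the domestication model) or `fst_target`
    (a symmetric island model) selects the demography.  Optional outgroup
    individuals carry the ancestral allele, homozygous at every locus.
    Biallelic segregating sites are accumulated over as much simulated
    sequence as needed to reach `n_snps`.
    """
    if (params is None) == (fst_target is None):
        raise ValueError("give exactly one of params or fst_target")
    if params is not None:
        demog = build_demography(params, N_W=10_000.0)
        pops = {"W": n_per_group[0], "C": n_per_group[1]}
    else:
        demog = _island_demography(fst_target)
        pops = {"A": n_per_group[0], "B": n_per_group[1]}
    rng = np.random.default_rng(seed)
    codes_rows, anc = [], []
    # many short independent replicates keep linkage between retained SNPs
    # weak, so estimator checks see close to n_snps independent loci
    L = 5_000
    attempts = 0
    while len(codes_rows) < n_snps:
        attempts += 1
        if attempts > 3000:
            raise RuntimeError("failed to accumulate enough SNPs; raise mu or L")
        ts = msprime.sim_ancestry(
            samples=pops, ploidy=2, demography=demog,
            recombination_rate=1e-8, sequence_length=L,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        ts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.JC69(),
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        for var in ts.variants():
            if len(var.alleles) != 2 or var.genotypes.max() > 1:
                continue
            a0, a1 = (NUC_TO_CODE[a] for a in var.alleles[:2])
            g = np.where(var.genotypes == 0, a0, a1).astype(np.int8)
            codes_rows.append(g.reshape(-1, 2))
            anc.append(a0)  # JC69 ancestral state is the reference allele
    idx = rng.choice(len(codes_rows), size=n_snps, replace=False)
    idx.sort()
    codes = np.stack([codes_rows[i] for i in idx])
    ancestral = np.array([anc[i] for i in idx], dtype=np.int8)
    n_ind = codes.shape[1]
    samples = []
    groups = {}
    for g_i, (gname, count) in enumerate(zip(group_names, n_per_group)):
        for j in range(count):
            name = f"{gname[:4]}{j + 1}"
            samples.append(name)
            groups[name] = gname
    assert len(samples) == n_ind
    loci = [("sim", i + 1) for i in range(n_snps)]
    if n_outgroup > 0:
        out_codes = np.repeat(
            ancestral[:, None, None], n_outgroup * 2, axis=1
        ).reshape(n_snps, n_outgroup, 2)
        codes = np.concatenate([codes, out_codes.astype(np.int8)], axis=1)
        for j in range(n_outgroup):
            name = f"outg{j + 1}"
            samples.append(name)
            groups[name] = "outgroup"
    return GenotypeMatrix(codes, loci, samples, groups=groups, ancestral=ancestral)


# ----------------------------------------------------------------------
# observed spectra under the demographic model
# ----------------------------------------------------------------------

def simulate_sfs(
    params: DomesticationParams,
    theta: float,
    sample_sizes: tuple[int, int] = (10, 10),
    seed: int = 0,
    folded: bool = False,
    engine_reps: int = 1000,
    engine: str = "coalescent",
) -> SiteFrequencySpectrum:
    """Poisson-sampled observed SFS around theta times the expected SFS.

    Unmasked entries are drawn independently Poisson(theta * expected);
    masked entries are zeroed; the mask is preserved.  The expected total
    SNP count is theta times the unmasked model mass.
    """
    rng = np.random.default_rng(seed)
    model = expected_sfs(
        params, sample_sizes, reps=engine_reps,
        seed=int(rng.integers(1, 2**31 - 1)), folded=folded, engine=engine,
    )
    out = model.copy()
    out.counts = np.where(out.mask, 0.0, rng.poisson(theta * model.counts))
    return out


# ----------------------------------------------------------------------
# expression tables
# ----------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Conditions for simulating per-contig coverage with group effects."""

    n_contigs: int = 2000
    n_cultivated: int = 6
    n_wild: int = 5
    baseline_log_mean: float = 3.0  # log-normal baseline coverage
    baseline_log_sd: float = 1.0
    group_logfc_sd: float = 0.0  # per-contig cultivated/wild log-fold effect
    group_logfc_mean: float = 0.0
    depth_factor_log_sd: float = 0.5  # per-sample sequencing-effort spread
    dispersion: float = 0.3
    n_unique_cultivated: int = 174
    n_unique_wild: int = 47
    seed: int = 0

    def __post_init__(self):
        if self.n_unique_cultivated + self.n_unique_wild > self.n_contigs:
            raise ValueError("unique contigs exceed n_contigs")


def simulate_expression_table(
    config: ExpressionSimConfig,
) -> tuple[ExpressionTable, pd.Series]:
    """Coverage table plus per-contig truth labels.

    Coverage is baseline x group effect x per-sample depth factor with
    negative-binomial noise.  The first `n_unique_cultivated` contigs are
    zeroed in every wild sample (and vice versa for the next
    `n_unique_wild`), with presence enforced in their own group so the
    planted unique-expression pattern survives the noise.
    """
    rng = np.random.default_rng(config.seed)
    nc, nw = config.n_cultivated, config.n_wild
    contigs = [f"contig{i + 1}" for i in range(config.n_contigs)]
    samples = [f"C{i + 1}" for i in range(nc)] + [f"W{i + 1}" for i in range(nw)]
    groups = {s: ("cultivated" if s.startswith("C") else "wild") for s in samples}
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                         size=config.n_contigs)
    logfc = rng.normal(config.group_logfc_mean, config.group_logfc_sd,
                       size=config.n_contigs)
    depth = rng.lognormal(0.0, config.depth_factor_log_sd, size=len(samples))
    mean = np.empty((config.n_contigs, len(samples)))
    for j, s in enumerate(samples):
        eff = np.exp(logfc) if groups[s] == "cultivated" else 1.0
        mean[:, j] = base * eff * depth[j]
    cov = _neg_binomial(rng, mean, config.dispersion, mean.shape).astype(float)
    labels = np.array(["shared"] * config.n_contigs, dtype=object)
    cu = slice(0, config.n_unique_cultivated)
    wu = slice(config.n_unique_cultivated,
               config.n_unique_cultivated + config.n_unique_wild)
    labels[cu], labels[wu] = "cultivated_only", "wild_only"
    cult_cols = np.arange(nc)
    wild_cols = np.arange(nc, nc + nw)
    cov[cu][:, wild_cols] = 0.0
    cov[wu][:, cult_cols] = 0.0
    # presence in the own group must survive the noise
    own = cov[cu][:, cult_cols]
    cov[cu, : nc] = np.maximum(own, 1.0)
    own_w = cov[wu][:, wild_cols]
    cov[wu, nc:] = np.maximum(own_w, 1.0)
    table = ExpressionTable(
        pd.DataFrame(cov, index=contigs, columns=samples), groups
    )
    truth = pd.Series(labels, index=contigs, name="truth")
    return table, truth
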