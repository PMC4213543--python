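"""Domestication-bottleneck demographic model and composite-likelihood fit.

The model: a wild population of constant size N_W; at time T_B + T before
present the cultivated lineage splits off and passes through a bottleneck
of size N_B lasting T_B generations; its size then grows exponentially to
N_C over the last T generations, during which gene flow occurs in both
directions (m_WC cultivated->wild, m_CW wild->cultivated, forwards in
time).  All parameters are scaled by N_W: sizes nu = N/N_W, times in
units of N_W generations, migration in units of 1/N_W per generation
(`DomesticationParams.as_units("2NW")` converts to the diffusion-tool
convention of 2*N_W generations and 2*N_W*m).

Three migration variants are fitted to an observed joint SFS: none
(m_WC = m_CW = 0), symmetric (m_WC = m_CW), and asymmetric.  The expected
spectrum is computed by a coalescent Monte-Carlo engine (msprime): branch
lengths subtending each joint frequency class, averaged over replicates,
are proportional to the expected SFS under an infinite-sites mutation
model, with the overall mutation rate theta profiled out of the
multinomial composite likelihood analytically.  Within one fit the engine
uses common random numbers (a fixed seed), making the objective a
deterministic function of the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import msprime
from scipy import optimize, stats
from scipy.special import gammaln

from .sfs import SiteFrequencySpectrum, fold as fold_sfs

VARIANTS = ("no_migration", "symmetric", "asymmetric")

_PARAM_NAMES = {
    "no_migration": ("nu_B", "nu_C", "T_B", "T"),
    "symmetric": ("nu_B", "nu_C", "T_B", "T", "m"),
    "asymmetric": ("nu_B", "nu_C", "T_B", "T", "m_WC", "m_CW"),
}

# log-uniform ranges for random optimizer starts, and hard box bounds
_START_RANGES = {
    "nu_B": (1e-3, 0.5),
    "nu_C": (0.01, 2.0),
    "T_B": (3e-3, 0.3),
    "T": (0.1, 3.0),
    "m": (0.05, 20.0),
    "m_WC": (0.05, 20.0),
    "m_CW": (0.05, 20.0),
}
_HARD_BOUNDS = {
    "nu_B": (1e-4, 5.0),
    "nu_C": (1e-3, 20.0),
    "T_B": (1e-4, 2.0),
    "T": (1e-3, 8.0),
    "m": (1e-4, 60.0),
    "m_WC": (1e-4, 60.0),
    "m_CW": (1e-4, 60.0),
}


@dataclass(frozen=True)
class DomesticationParams:
    """Scaled parameters of the bottleneck-growth-migration model.

    nu_B, nu_C: bottleneck and present cultivated sizes relative to N_W;
    T_B, T: bottleneck and growth durations in N_W generations;
    m_WC, m_CW: migration rates (x N_W); variant names the migration
    structure.
    """

    nu_B: float
    nu_C: float
    T_B: float
    T: float
    m_WC: float = 0.0
    m_CW: float = 0.0
    variant: str = "asymmetric"

    def __post_init__(self):
        for name in ("nu_B", "nu_C", "T_B", "T"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.m_WC < 0 or self.m_CW < 0:
            raise ValueError("migration rates must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "no_migration" and (self.m_WC or self.m_CW):
            raise ValueError("no_migration variant requires m_WC = m_CW = 0")
        if self.variant == "symmetric" and not math.isclose(self.m_WC, self.m_CW):
            raise ValueError("symmetric variant requires m_WC = m_CW")

    def as_units(self, units: str = "NW") -> dict[str, float]:
        """Parameter dict in 'NW' or '2NW' (diffusion-style) units."""
        d = {
            "nu_B": self.nu_B,
            "nu_C": self.nu_C,
            "T_B": self.T_B,
            "T": self.T,
            "m_WC": self.m_WC,
            "m_CW": self.m_CW,
        }
        if units == "NW":
            return d
        if units == "2NW":
            return {
                "nu_B": self.nu_B,
                "nu_C": self.nu_C,
                "T_B": self.T_B / 2,
                "T": self.T / 2,
                "m_WC": 2 * self.m_WC,
                "m_CW": 2 * self.m_CW,
            }
        raise ValueError("units must be 'NW' or '2NW'")

    @classmethod
    def from_vector(cls, variant: str, values) -> "DomesticationParams":
        names = _PARAM_NAMES[variant]
        if len(values) != len(names):
            raise ValueError(f"{variant} expects {len(names)} parameters")
        kv = dict(zip(names, values))
        if variant == "no_migration":
            return cls(variant=variant, m_WC=0.0, m_CW=0.0, **kv)
        if variant == "symmetric":
            m = kv.pop("m")
            return cls(variant=variant, m_WC=m, m_CW=m, **kv)
        return cls(variant=variant, **kv)

    def to_vector(self) -> np.ndarray:
        names = _PARAM_NAMES[self.variant]
        vals = []
        for n in names:
            vals.append(self.m_WC if n == "m" else getattr(self, n))
        return np.array(vals)


# ----------------------------------------------------------------------
# expected SFS engine
# ----------------------------------------------------------------------

_N_W = 1000.0  # internal absolute scale; results are invariant to it


def build_demography(params: DomesticationParams, N_W: float = _N_W,
                     migration_during_bottleneck: bool = False) -> msprime.Demography:
    """msprime demography for the model (populations 'W', 'C', 'ANC')."""
    T_gen = max(params.T * N_W, 1e-6)
    TB_gen = max(params.T_B * N_W, 1e-6)
    N_C = params.nu_C * N_W
    N_B = params.nu_B * N_W
    g = math.log(N_C / N_B) / T_gen
    d = msprime.Demography()
    d.add_population(name="W", initial_size=N_W)
    d.add_population(name="C", initial_size=N_C, growth_rate=g)
    d.add_population(name="ANC", initial_size=N_W)
    # backwards-time source/dest: lineages in C jump to W at the rate of
    # forward migration W->C (m_CW), and vice versa
    if params.m_CW > 0:
        d.set_migration_rate(source="C", dest="W", rate=params.m_CW / N_W)
    if params.m_WC > 0:
        d.set_migration_rate(source="W", dest="C", rate=params.m_WC / N_W)
    if not migration_during_bottleneck:
        d.add_migration_rate_change(time=T_gen, rate=0)
    d.add_population_parameters_change(
        time=T_gen, population="C", initial_size=N_B, growth_rate=0
    )
    d.add_population_split(time=T_gen + TB_gen, derived=["W", "C"], ancestral="ANC")
    d.sort_events()
    return d


def expected_sfs(
    params: DomesticationParams,
    sample_sizes: tuple[int, int] = (10, 10),
    reps: int = 400,
    seed: int = 1,
    folded: bool = False,
    N_W: float = _N_W,
    migration_during_bottleneck: bool = False,
    engine: str = "coalescent",
) -> SiteFrequencySpectrum:
    """Expected (real-valued) joint SFS of (wild, cultivated) samples.

    Two engines behind one contract.  ``engine="coalescent"`` (default)
    averages branch-length frequency spectra over `reps` independent
    msprime replicates, scaled by 1/(2 N_W) so a panmictic constant-size
    marginal tends to the neutral 1/i spectrum; it is unbiased, fully
    deterministic given `seed`, but carries Monte-Carlo noise.
    ``engine="ode"`` integrates the moment equations of the diffusion
    (see `sfs_ode`): deterministic and smooth in the parameters, which
    the likelihood optimizer needs, at the price of a small closure
    approximation in the migration terms.
    """
    if engine == "ode":
        from .sfs_ode import expected_sfs_ode

        out = expected_sfs_ode(
            params, sample_sizes,
            migration_during_bottleneck=migration_during_bottleneck,
        )
        return fold_sfs(out) if folded else out
    if engine != "coalescent":
        raise ValueError(f"unknown engine {engine!r}")
    demog = build_demography(params, N_W, migration_during_bottleneck)
    n_w, n_c = sample_sizes
    acc = None
    for ts in msprime.sim_ancestry(
        samples={"W": n_w, "C": n_c},
        ploidy=1,
        demography=demog,
        num_replicates=reps,
        random_seed=seed,
    ):
        sets = [ts.samples(population=0), ts.samples(population=1)]
        afs = ts.allele_frequency_spectrum(
            sets, mode="branch", polarised=True, span_normalise=True
        )
        acc = afs if acc is None else acc + afs
    counts = acc / reps / (2 * N_W)
    out = SiteFrequencySpectrum(counts, folded=False, pop_labels=("wild", "cultivated"))
    return fold_sfs(out) if folded else out


# ----------------------------------------------------------------------
# composite likelihood
# ----------------------------------------------------------------------

def composite_loglik(observed: SiteFrequencySpectrum,
                     model: SiteFrequencySpectrum,
                     mode: str = "multinomial") -> float:
    """Composite log-likelihood of an observed SFS under a model SFS.

    Multinomial mode profiles theta out analytically (model scaled to the
    observed total); Poisson mode evaluates independent Poisson entries
    at the optimal theta_hat = sum(obs)/sum(model).  Masked entries are
    ignored.  Model entries are floored at 1e-12 of the model total so a
    Monte-Carlo zero cannot produce an infinite penalty.
    """
    if observed.counts.shape != model.counts.shape:
        raise ValueError("observed and model SFS shapes differ")
    if observed.folded != model.folded:
        raise ValueError("observed and model folding states differ")
    use = ~(observed.mask | model.mask)
    obs = observed.counts[use]
    mod = model.counts[use]
    mod_total = mod.sum()
    if mod_total <= 0:
        raise ValueError("model SFS has no mass on unmasked entries")
    mod = np.maximum(mod, 1e-12 * mod_total)
    if mode == "multinomial":
        return float((obs * np.log(mod / mod.sum())).sum())
    if mode == "poisson":
        theta = obs.sum() / mod_total
        lam = theta * mod
        return float((obs * np.log(lam) - lam - gammaln(obs + 1)).sum())
    raise ValueError("mode must be 'multinomial' or 'poisson'")


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

@dataclass
class FitResult:
    params: DomesticationParams
    loglik: float
    theta_hat: float
    n_starts: int
    converged: bool
    ci: dict[str, tuple[float, float]] | None = None


def _make_objective(observed, variant, sample_sizes, reps, engine_seed, mode,
                    engine="ode"):
    names = _PARAM_NAMES[variant]
    lo = np.log([_HARD_BOUNDS[n][0] for n in names])
    hi = np.log([_HARD_BOUNDS[n][1] for n in names])

    def loglik_at(params: DomesticationParams) -> float:
        model = expected_sfs(
            params, sample_sizes, reps=reps, seed=engine_seed,
            folded=observed.folded, engine=engine,
        )
        return composite_loglik(observed, model, mode=mode)

    def objective(x: np.ndarray) -> float:
        xc = np.clip(x, lo, hi)
        penalty = 1e4 * float(np.abs(x - xc).sum())
        params = DomesticationParams.from_vector(variant, np.exp(xc))
        return -loglik_at(params) + penalty

    return objective, loglik_at, names


def fit(
    observed: SiteFrequencySpectrum,
    variant: str = "asymmetric",
    n_starts: int = 20,
    seed: int = 0,
    sample_sizes: tuple[int, int] | None = None,
    reps: int = 200,
    maxfev: int = 200,
    mode: str = "multinomial",
    extra_starts: tuple[DomesticationParams, ...] = (),
    refine_reps: int = 0,
    refine_maxfev: int = 60,
    engine: str = "ode",
    simplex_scale: float | None = None,
) -> FitResult:
    """Maximize the composite likelihood over log-parameters.

    Derivative-free simplex search from `n_starts` log-uniform random
    starts (the composite-likelihood surface is rugged), plus any
    `extra_starts` evaluated both directly and as simplex starts when
    representable.  With `refine_reps` > 0 the best candidate is polished
    by a second simplex run at that (higher) engine replicate count,
    reducing Monte-Carlo roughness around the optimum.  Deterministic
    given `seed`; the engine seed is fixed across all evaluations (common
    random numbers), so likelihoods of different variants fitted with the
    same seed/reps are directly comparable.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if sample_sizes is None:
        sample_sizes = observed.sample_sizes
    rng = np.random.default_rng(seed)
    engine_seed = int(rng.integers(1, 2**31 - 1))
    objective, loglik_at, names = _make_objective(
        observed, variant, sample_sizes, reps, engine_seed, mode, engine
    )
    best_ll, best_params, any_converged = -np.inf, None, False
    # direct evaluation of explicit candidates (allows exact m = 0)
    for cand in extra_starts:
        cand_v = cand if cand.variant == variant else replace(cand, variant=variant)
        ll = loglik_at(cand_v)
        if ll > best_ll:
            best_ll, best_params = ll, cand_v
    starts = []
    for _ in range(n_starts):
        starts.append(
            [
                math.exp(rng.uniform(math.log(_START_RANGES[n][0]),
                                     math.log(_START_RANGES[n][1])))
                for n in names
            ]
        )
    for cand in extra_starts:
        vec = DomesticationParams(
            nu_B=cand.nu_B, nu_C=cand.nu_C, T_B=cand.T_B, T=cand.T,
            m_WC=max(cand.m_WC, _HARD_BOUNDS.get("m_WC", (1e-4,))[0]),
            m_CW=max(cand.m_CW, _HARD_BOUNDS.get("m_CW", (1e-4,))[0]),
            variant=variant,
        ).to_vector()
        starts.append(list(vec))
    for x0 in starts:
        options = {"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-3}
        if simplex_scale is not None:
            # wide initial simplex in log space: explores flat likelihood
            # ridges that the default 5% perturbation never leaves
            base = np.log(x0)
            simplex = [base]
            for d in range(len(base)):
                v = base.copy()
                v[d] += simplex_scale
                simplex.append(v)
            options["initial_simplex"] = np.array(simplex)
        res = optimize.minimize(
            objective,
            np.log(x0),
            method="Nelder-Mead",
            options=options,
        )
        any_converged = any_converged or bool(res.success)
        params = DomesticationParams.from_vector(variant, np.exp(res.x))
        ll = -res.fun if np.isfinite(res.fun) else -np.inf
        if ll > best_ll:
            best_ll, best_params = ll, params
    if best_params is None or not np.isfinite(best_ll):
        raise RuntimeError("no optimizer start converged to a finite likelihood")
    final_reps = reps
    if engine == "coalescent" and refine_reps and refine_reps > reps:
        final_reps = refine_reps
        objective, loglik_at, _ = _make_objective(
            observed, variant, sample_sizes, refine_reps, engine_seed, mode, engine
        )
        res = optimize.minimize(
            objective,
            np.log(np.maximum(best_params.to_vector(), 1e-4)),
            method="Nelder-Mead",
            options={"maxfev": refine_maxfev, "xatol": 1e-3, "fatol": 1e-3},
        )
        polished = DomesticationParams.from_vector(variant, np.exp(res.x))
        if np.isfinite(res.fun) and -res.fun > loglik_at(best_params):
            best_params, best_ll = polished, -res.fun
        else:
            best_ll = loglik_at(best_params)
    model = expected_sfs(best_params, sample_sizes, reps=final_reps,
                         seed=engine_seed, folded=observed.folded, engine=engine)
    theta_hat = observed.total() / model.total()
    return FitResult(
        params=best_params,
        loglik=best_ll,
        theta_hat=float(theta_hat),
        n_starts=len(starts),
        converged=any_converged,
    )


# ----------------------------------------------------------------------
# model comparison and bootstrap CIs
# ----------------------------------------------------------------------

def compare_models(
    observed: SiteFrequencySpectrum,
    seed: int = 0,
    n_starts: int = 8,
    reps: int = 200,
    maxfev: int = 200,
    mode: str = "multinomial",
    engine: str = "ode",
) -> dict:
    """Fit all three migration variants and report likelihood ratios.

    Each richer variant's candidate set includes the poorer variant's
    optimum (with the missing migration rates at exactly zero), and all
    fits share one engine seed, so the nesting inequality
    ll(none) <= ll(symmetric) <= ll(asymmetric) holds by construction.
    Chi-squared p-values treat 2*delta-loglik as a likelihood-ratio
    statistic; with a composite likelihood they are approximations.
    """
    fits: dict[str, FitResult] = {}
    fits["no_migration"] = fit(
        observed, "no_migration", n_starts=n_starts, seed=seed, reps=reps,
        maxfev=maxfev, mode=mode, engine=engine,
    )
    p0 = fits["no_migration"].params
    fits["symmetric"] = fit(
        observed, "symmetric", n_starts=n_starts, seed=seed, reps=reps,
        maxfev=maxfev, mode=mode, engine=engine,
        extra_starts=(replace(p0, variant="symmetric"),),
    )
    p1 = fits["symmetric"].params
    fits["asymmetric"] = fit(
        observed, "asymmetric", n_starts=n_starts, seed=seed, reps=reps,
        maxfev=maxfev, mode=mode, engine=engine,
        extra_starts=(
            replace(p1, variant="asymmetric"),
            replace(p0, variant="asymmetric"),
        ),
    )
    ll = {v: fits[v].loglik for v in VARIANTS}
    lrt = {
        "asym_vs_sym": _lrt(ll["asymmetric"], ll["symmetric"], df=1),
        "asym_vs_none": _lrt(ll["asymmetric"], ll["no_migration"], df=2),
        "sym_vs_none": _lrt(ll["symmetric"], ll["no_migration"], df=1),
    }
    return {"fits": fits, "lrt": lrt,
            "note": "composite-likelihood approximation; p-values are indicative"}


def _lrt(ll1: float, ll0: float, df: int) -> dict:
    stat = max(2 * (ll1 - ll0), 0.0)
    return {"stat": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}


def resample_sfs(observed: SiteFrequencySpectrum, rng) -> SiteFrequencySpectrum:
    """Bootstrap-resample SNPs of an observed SFS (multinomial over entries)."""
    out = observed.copy()
    use = ~observed.mask
    counts = observed.counts[use]
    total = int(round(counts.sum()))
    if total == 0:
        return out
    probs = counts / counts.sum()
    out.counts[use] = rng.multinomial(total, probs)
    return out


def bootstrap_params(
    data,
    variant: str = "asymmetric",
    n_boot: int = 100,
    seed: int = 0,
    point: FitResult | None = None,
    groups: tuple[str, str] | None = None,
    target_sizes: tuple[int, int] | None = None,
    polarized: bool = False,
    fit_kwargs: dict | None = None,
) -> dict[str, tuple[float, float]]:
    """Percentile CIs from refitting datasets resampled over SNP positions.

    `data` is either an observed SiteFrequencySpectrum (SNPs resampled
    multinomially over spectrum entries, which is what resampling SNP
    positions induces on the spectrum) or a GenotypeMatrix (loci
    resampled, spectrum rebuilt).  Bootstrap refits warm-start from the
    point estimate when provided.
    """
    from .genotypes import GenotypeMatrix
    from .sfs import build_sfs, project as project_sfs

    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_starts", 1)
    rng = np.random.default_rng(seed)
    names = _PARAM_NAMES[variant]
    draws: dict[str, list[float]] = {n: [] for n in names}

    def observed_from(gm_boot):
        s = build_sfs(gm_boot, groups, polarized=polarized)
        if target_sizes is not None:
            s = project_sfs(s, target_sizes)
        return s

    for b in range(n_boot):
        if isinstance(data, GenotypeMatrix):
            idx = rng.integers(0, data.n_loci, size=data.n_loci)
            obs_b = observed_from(data.subset_loci(idx))
        else:
            obs_b = resample_sfs(data, rng)
        extra = (replace(point.params, variant=variant),) if point else ()
        res = fit(
            obs_b, variant, seed=int(rng.integers(1, 2**31 - 1)),
            extra_starts=extra, **fit_kwargs,
        )
        vec = res.params.to_vector()
        for n, v in zip(names, vec):
            draws[n].append(float(v))
    # with a modest number of refits the sample 2.5% quantile cannot be
    # resolved below the extreme order statistics; the conservative
    # order-statistic convention avoids anti-conservative interpolation
    return {
        n: (
            float(np.percentile(draws[n], 2.5, method="lower")),
            float(np.percentile(draws[n], 97.5, method="higher")),
        )
        for n in names
    }
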