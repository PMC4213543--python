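"""Deterministic expected-SFS engine: moment equations for the joint SFS.

Propagates the expected joint site frequency spectrum of the
bottleneck-growth-migration model as a system of ordinary differential
equations in the spectrum entries themselves, the moment-closure
formulation of the Wright-Fisher diffusion.  For neutral drift the
moment hierarchy closes exactly at the sample size; the migration terms
couple to spectra one sample larger in the source population and are
closed with a quadratic jackknife (entries of the (n+1)-sample spectrum
interpolated from the n-sample spectrum, exact for frequency densities
that are polynomials of degree <= 2).

Scaling conventions match the coalescent Monte-Carlo engine in
`demography`: population sizes are relative to the wild size N_W, input
times are in N_W generations, migration rates in units of 1/N_W per
generation, and the equilibrium single-population spectrum is 1/i.  One
unit of internal ODE time equals N_W/2 generations, so an input duration
T contributes 2T time units.

The integrator is Crank-Nicolson on the (n1+1)(n2+1)-dimensional linear
system Phi' = A(t) Phi + u, with the exponential growth of the
cultivated population discretized at the step midpoints.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import linalg

from .sfs import SiteFrequencySpectrum


# ----------------------------------------------------------------------
# building blocks (cached per sample size)
# ----------------------------------------------------------------------

@lru_cache(maxsize=None)
def _drift_matrix(n: int) -> np.ndarray:
    """Neutral drift generator for a sample of n copies (per 1/nu).

    Row i of the returned D satisfies
    dPhi_i/dtau = (1/(4 nu)) * sum_j D[i, j] Phi_j with
    D[i, i-1] = (i-1)(n-i+1), D[i, i] = -2 i (n-i),
    D[i, i+1] = (i+1)(n-i-1); the stationary interior solution is 1/i.
    """
    D = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        if i - 1 >= 0:
            D[i, i - 1] = (i - 1) * (n - i + 1)
        D[i, i] = -2.0 * i * (n - i)
        if i + 1 <= n:
            D[i, i + 1] = (i + 1) * (n - i - 1)
    return D / 4.0


@lru_cache(maxsize=None)
def _project_down_matrix(n: int) -> np.ndarray:
    """Exact hypergeometric projection from sample size n to n - 1."""
    from scipy import stats

    P = np.zeros((n, n + 1))
    for j in range(n + 1):
        P[:, j] = stats.hypergeom.pmf(np.arange(n), n, j, n - 1)
    return P


def _beta_moment(n: int, k: int, p: int) -> float:
    """integral of C(n,k) x^(k+p) (1-x)^(n-k) dx over [0, 1]."""
    return math.comb(n, k) * math.exp(
        math.lgamma(k + p + 1) + math.lgamma(n - k + 1) - math.lgamma(n + p + 2)
    )


@lru_cache(maxsize=None)
def _jackknife_up_matrix(n: int) -> np.ndarray:
    """Approximate upsampling from sample size n to n + 1.

    Each entry l of the (n+1)-sample spectrum is a weighted sum of three
    neighbouring entries of the n-sample spectrum; the weights are the
    unique choice reproducing the moments of x^p for p = 0, 1, 2, i.e.
    exact whenever the underlying frequency density is quadratic.
    """
    J = np.zeros((n + 2, n + 1))
    for l in range(n + 2):
        centre = l * n / (n + 1)
        k0 = int(np.clip(round(centre) - 1, 0, n - 2))
        ks = [k0, k0 + 1, k0 + 2]
        A = np.array([[_beta_moment(n, k, p) for k in ks] for p in range(3)])
        b = np.array([_beta_moment(n + 1, l, p) for p in range(3)])
        J[l, ks] = np.linalg.solve(A, b)
    return J


@lru_cache(maxsize=None)
def _migration_operator(n1: int, n2: int) -> np.ndarray:
    """Generator of migration into population 1 from population 2, per
    unit scaled rate.

    Derived from the diffusion advection term -d/dx1 [(x2 - x1) phi]:
    the x1 part is closed at (n1, n2); the x2 part couples to the
    (n1 - 1, n2 + 1) spectrum, reached by exact downward projection on
    axis 1 and jackknife upsampling on axis 2.
    """
    shape = (n1 + 1, n2 + 1)
    size = shape[0] * shape[1]
    op = np.zeros((size, size))

    def idx(i, j):
        return i * (n2 + 1) + j

    # closed part: + (i+1) Phi(i+1, j) - i Phi(i, j)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            op[idx(i, j), idx(i, j)] -= i
            if i + 1 <= n1:
                op[idx(i, j), idx(i + 1, j)] += i + 1

    # cross part: n1/(n2+1) * (j+1) * [aux(i-1, j+1) - aux(i, j+1)]
    # with aux = (P1 x J2) Phi of shape (n1, n2+2)
    P1 = _project_down_matrix(n1)  # (n1, n1+1)
    J2 = _jackknife_up_matrix(n2)  # (n2+2, n2+1)
    # aux as linear map: aux[a, b] = sum_{i,j} P1[a,i] J2[b,j] Phi[i,j]
    for i_to in range(n1 + 1):
        for j_to in range(n2 + 1):
            b = j_to + 1  # aux column
            coef = n1 * (j_to + 1) / (n2 + 1)
            for i_src in range(n1 + 1):
                for j_src in range(n2 + 1):
                    w = J2[b, j_src]
                    if w == 0.0:
                        continue
                    acc = 0.0
                    if i_to - 1 >= 0:
                        acc += P1[i_to - 1, i_src]
                    acc -= P1[i_to, i_src] if i_to <= n1 - 1 else 0.0
                    if acc != 0.0:
                        op[idx(i_to, j_to), idx(i_src, j_src)] += coef * acc * w
    return op


@lru_cache(maxsize=None)
def _static_operators(n1: int, n2: int):
    """Kronecker-assembled drift generators and migration operators."""
    I1 = np.eye(n1 + 1)
    I2 = np.eye(n2 + 1)
    D1 = np.kron(_drift_matrix(n1), I2)  # pop 1 drift (x 1/nu1)
    D2 = np.kron(I1, _drift_matrix(n2))  # pop 2 drift (x 1/nu2)
    M12 = _migration_operator(n1, n2)  # into pop 1 from pop 2
    # into pop 2 from pop 1: same operator with axes swapped
    M21 = _swap_axes_operator(_migration_operator(n2, n1), n1, n2)
    # mutation influx: singletons in either population, theta = 1
    u = np.zeros((n1 + 1) * (n2 + 1))
    u[1 * (n2 + 1) + 0] = n1 / 4.0
    u[0 * (n2 + 1) + 1] = n2 / 4.0
    return D1, D2, M12, M21, u


def _swap_axes_operator(op_swapped: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Rewrite an operator built on (n2+1, n1+1)-shaped spectra so it acts
    on (n1+1, n2+1)-shaped spectra with the two axes exchanged."""
    size = (n1 + 1) * (n2 + 1)
    perm = np.zeros(size, dtype=int)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            perm[i * (n2 + 1) + j] = j * (n1 + 1) + i
    out = np.empty((size, size))
    out[:, :] = op_swapped[np.ix_(perm, perm)]
    return out


# ----------------------------------------------------------------------
# integration
# ----------------------------------------------------------------------

@lru_cache(maxsize=None)
def _equilibrium_split(n1: int, n2: int) -> np.ndarray:
    """Ancestral equilibrium (1/i for n1+n2 copies) split hypergeometrically."""
    from scipy import stats

    n_tot = n1 + n2
    phi = np.zeros((n1 + 1, n2 + 1))
    for k in range(1, n_tot):
        w = stats.hypergeom.pmf(np.arange(n1 + 1), n_tot, k, n1)
        for a in range(n1 + 1):
            b = k - a
            if 0 <= b <= n2 and w[a] > 0:
                phi[a, b] += w[a] / k
    return phi.ravel()


@lru_cache(maxsize=8)
def _identity(n: int) -> np.ndarray:
    return np.eye(n)


_GETRF, _GETRS = linalg.get_lapack_funcs(
    ("getrf", "getrs"), (np.empty((2, 2), dtype=np.float64),)
)


def _crank_nicolson(phi, A, u, h, steps):
    # dgetrf/dgetrs called directly: the scipy wrappers' validity checks
    # cost more than the 121x121 factorization itself
    getrf, getrs = _GETRF, _GETRS
    eye = _identity(len(phi))
    lhs = eye - (h / 2) * A
    rhs_mat = eye + (h / 2) * A
    lu, piv, info = getrf(lhs, overwrite_a=True)
    if info != 0:
        raise np.linalg.LinAlgError("Crank-Nicolson system is singular")
    hu = h * u
    for _ in range(steps):
        phi, info = getrs(lu, piv, rhs_mat @ phi + hu, overwrite_b=True)
    return phi


def _expm_phase(phi, A, u, tau):
    """Exact propagation of phi' = A phi + u over tau (augmented expm).

    Used for constant-coefficient phases, which can be arbitrarily stiff
    (drift rate ~ 1/nu_B) without costing accuracy.
    """
    n = len(phi)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = tau * A
    aug[:n, n] = tau * u
    out = linalg.expm(aug) @ np.append(phi, 1.0)
    return out[:n]


@lru_cache(maxsize=None)
def _drift_eig(n: int):
    """Eigendecomposition of the single-population drift generator."""
    lam, V = np.linalg.eig(_drift_matrix(n))
    return lam.real, V.real, np.linalg.inv(V).real


def _drift_only_phase(phi, u, n1, n2, nu1, nu2, tau):
    """Exact drift propagation without migration.

    The two populations' drift generators commute (they act on different
    Kronecker axes), so phi' = (D1/nu1 + D2/nu2) phi + u diagonalizes in
    the product eigenbasis: each mode c evolves as
    c(tau) = e^(lam tau) c0 + (e^(lam tau) - 1)/lam * psi.
    Exact for any stiffness, at the cost of two small matrix products.
    """
    lam1, V1, W1 = _drift_eig(n1)
    lam2, V2, W2 = _drift_eig(n2)
    shape = (n1 + 1, n2 + 1)
    c0 = W1 @ phi.reshape(shape) @ W2.T
    psi = W1 @ u.reshape(shape) @ W2.T
    lam = lam1[:, None] / nu1 + lam2[None, :] / nu2
    growth = np.exp(lam * tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        integral = np.where(np.abs(lam) > 1e-12, (growth - 1.0) / lam, tau)
    c = growth * c0 + integral * psi
    return (V1 @ c @ V2.T).ravel()


def expected_sfs_ode(
    params,
    sample_sizes: tuple[int, int] = (10, 10),
    max_step: float = 0.15,
    migration_during_bottleneck: bool = False,
) -> SiteFrequencySpectrum:
    """Expected joint (wild, cultivated) SFS by moment-ODE integration.

    Matches the coalescent engine's contract and scale (equilibrium
    marginals 1/i); fully deterministic and smooth in the parameters,
    which is what the composite-likelihood optimizer needs.
    """
    n1, n2 = sample_sizes
    D1, D2, M12, M21, u = _static_operators(n1, n2)
    # forward migration m_CW (wild -> cultivated, pop 2 receives) scales the
    # operator of pop 2; m_WC scales pop 1's. One input unit = 1/2 ODE unit.
    mig = (params.m_WC / 2.0) * M12 + (params.m_CW / 2.0) * M21
    phi = _equilibrium_split(n1, n2).copy()

    # bottleneck phase: cultivated at nu_B (constant generator, solved exactly)
    tau_b = 2.0 * params.T_B
    if migration_during_bottleneck:
        phi = _expm_phase(phi, D1 + D2 / params.nu_B + mig, u, tau_b)
    else:
        phi = _drift_only_phase(phi, u, n1, n2, 1.0, params.nu_B, tau_b)

    # growth phase: exponential nu_B -> nu_C with migration active
    tau_g = 2.0 * params.T
    g = math.log(params.nu_C / params.nu_B) / tau_g
    steps = max(8, int(np.ceil(tau_g / max_step)))
    h = tau_g / steps
    for s in range(steps):
        t_mid = (s + 0.5) * h
        nu2 = params.nu_B * math.exp(g * t_mid)
        A = D1 + D2 / nu2 + mig
        phi = _crank_nicolson(phi, A, u, h, 1)
    counts = np.maximum(phi.reshape(n1 + 1, n2 + 1), 0.0)
    return SiteFrequencySpectrum(counts, folded=False,
                                 pop_labels=("wild", "cultivated"))
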