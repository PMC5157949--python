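"""Lognormal within-mutation-type mutation-rate mixture.

Even among sites sharing a mutation type (say, non-CpG C>T), per-site rates
``M`` vary.  That heterogeneity is modelled here as

    log10 M  ~  Normal(log10 mu - sigma^2 ln(10) / 2,  sigma^2),

a lognormal whose location term is chosen so that ``E[M] = mu`` — the
mean-preserving parameterization.  ``sigma`` is quoted in log10-rate units;
the working default is ``SIGMA_DEFAULT = 0.57``, with the Hodgkinson et al.
chimp/human co-occurrence estimates (0.83 non-CpG, 0.8 CpG transitions)
shipped as named constants.

Combining the mixture with finite-sites grid quantities gives the expected
rare fraction at mean rate ``mu`` by total expectation and Bayes' rule:

    E[Y|S=1; mu] = Int E[Y|M,S=1] P(S=1|M) g(M; mu) dM
                   / Int P(S=1|M') g(M'; mu) dM'.

Polymorphic sites are size-biased towards high-rate sites because
``P(S=1|M)`` increases with ``M``; the mixture therefore depresses the rare
fraction below the fixed-rate prediction at the same mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .finite_sites import RateGrid

__all__ = [
    "LognormalRateMixture",
    "SIGMA_DEFAULT",
    "SIGMA_HODGKINSON_NONCPG",
    "SIGMA_HODGKINSON_CPG",
    "density_g",
    "tail_prob",
    "conditional_density_f",
    "mixture_rare_fraction",
    "mixture_rare_fraction_se",
    "sample_rates",
    "sample_rates_conditional",
    "fit_sigma",
]

LN10 = np.log(10.0)

SIGMA_DEFAULT = 0.57
SIGMA_HODGKINSON_NONCPG = 0.83
SIGMA_HODGKINSON_CPG = 0.8


@dataclass(frozen=True)
class LognormalRateMixture:
    """Mean-preserving lognormal distribution of per-site rates.

    mu: mean rate, per bp per generation per haploid (``E[M] = mu``).
    sigma: spread of log10 M (log10-rate units); 0 degenerates to a point
        mass at ``mu``.
    """

    mu: float
    sigma: float = SIGMA_DEFAULT

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def log10_location(self) -> float:
        return np.log10(self.mu) - self.sigma**2 * LN10 / 2.0

    @property
    def median(self) -> float:
        return 10.0 ** self.log10_location

    def support(self, trunc_sigmas: float = 4.0):
        """Truncated integration range [mu*10^-k*sigma, mu*10^k*sigma]."""
        half = trunc_sigmas * self.sigma
        return self.mu * 10.0 ** (-half), self.mu * 10.0 ** half


def density_g(M, mixture: LognormalRateMixture):
    """Lognormal density g(M; mu) of per-site rates (per unit of M)."""
    if mixture.sigma == 0:
        raise ValueError("sigma=0 is a point mass at mu; densities are undefined")
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("rates must be positive")
    z = (np.log10(M) - mixture.log10_location) / mixture.sigma
    return norm.pdf(z) / (M * LN10 * mixture.sigma)


def tail_prob(k: float, sigma: float = SIGMA_DEFAULT) -> float:
    """P(M > k * mu): probability a site's rate exceeds k times the type mean.

    Independent of ``mu`` by the lognormal scaling property.  With the
    default sigma = 0.57, about 3% of sites exceed 5x the type mean.
    """
    if k <= 0:
        raise ValueError("fold-threshold k must be positive")
    if sigma == 0:
        return 0.0 if k > 1 else 1.0
    return float(norm.sf((np.log10(k) + sigma**2 * LN10 / 2.0) / sigma))


def _log_grid(mixture, grid: RateGrid, n_points: int, trunc_sigmas: float,
              clip_to_grid: bool = False):
    lo, hi = mixture.support(trunc_sigmas)
    if not clip_to_grid and (lo < grid.rates[0] * (1 - 1e-9)
                             or hi > grid.rates[-1] * (1 + 1e-9)):
        raise ValueError(
            f"integration range [{lo:.3g}, {hi:.3g}] exceeds the rate grid "
            f"[{grid.rates[0]:.3g}, {grid.rates[-1]:.3g}]; extend the grid or "
            "reduce mu/sigma/trunc_sigmas"
        )
    lo = max(lo, grid.rates[0])
    hi = min(hi, grid.rates[-1])
    if lo >= hi:
        raise ValueError("mixture support does not overlap the rate grid")
    return np.linspace(np.log10(lo), np.log10(hi), n_points)


def _edge_atoms(mixture, grid: RateGrid):
    """Probability mass of g falling outside the grid's rate range.

    In clip mode the out-of-range mass is assigned the edge values of the
    grid (the same convention as clipped interpolation).
    """
    z_lo = (np.log10(grid.rates[0]) - mixture.log10_location) / mixture.sigma
    z_hi = (np.log10(grid.rates[-1]) - mixture.log10_location) / mixture.sigma
    return float(norm.cdf(z_lo)), float(norm.sf(z_hi))


def _interp_grid(x_log10, grid: RateGrid, field: str):
    """Linear interpolation of a grid column against log10(rate)."""
    return np.interp(x_log10, np.log10(grid.rates), getattr(grid, field))


def conditional_density_f(M, mixture: LognormalRateMixture, grid: RateGrid,
                          *, n_points: int = 1025, trunc_sigmas: float = 4.0):
    """Rate density among biallelic sites, f(M | S=1; mu), by Bayes' rule.

    ``P(S=1|M)`` is interpolated log-linearly on the grid; the normalizing
    constant is a trapezoid quadrature in log10 M over the truncated support.
    """
    x = _log_grid(mixture, grid, n_points, trunc_sigmas)
    Mx = 10.0 ** x
    integrand = _interp_grid(x, grid, "p_biallelic") * density_g(Mx, mixture) * Mx * LN10
    Z = np.trapezoid(integrand, x)
    M = np.asarray(M, dtype=float)
    p_at = np.interp(np.log10(M), np.log10(grid.rates), grid.p_biallelic)
    return p_at * density_g(M, mixture) / Z


def _quadrature_parts(mixture, grid, n_points, trunc_sigmas, clip_to_grid=False):
    x = _log_grid(mixture, grid, n_points, trunc_sigmas, clip_to_grid)
    Mx = 10.0 ** x
    w = density_g(Mx, mixture) * Mx * LN10  # g in log10 units
    p = _interp_grid(x, grid, "p_biallelic")
    e = _interp_grid(x, grid, "e_rare")
    return x, w, p, e


def mixture_rare_fraction(mixture: LognormalRateMixture, grid: RateGrid,
                          *, n_points: int = 1025, trunc_sigmas: float = 4.0,
                          clip_to_grid: bool = False) -> float:
    """Expected rare fraction E[Y|S=1; mu] under the lognormal rate mixture.

    Trapezoid quadrature in log10 M of ``E[Y|M,S=1] f(M|S=1; mu)`` with both
    grid factors interpolated log-linearly.  ``sigma=0`` reduces to the grid
    value at ``mu``.  By default a support extending beyond the grid raises;
    ``clip_to_grid=True`` instead assigns the out-of-range tail mass the
    grid's edge values (appropriate when the edges are already in the
    flat/limiting regime).
    """
    if mixture.sigma == 0:
        if not grid.rates[0] <= mixture.mu <= grid.rates[-1]:
            raise ValueError(f"mu={mixture.mu:g} outside grid coverage "
                             f"[{grid.rates[0]:g}, {grid.rates[-1]:g}]")
        return float(np.interp(np.log10(mixture.mu), np.log10(grid.rates), grid.e_rare))
    x, w, p, e = _quadrature_parts(mixture, grid, n_points, trunc_sigmas, clip_to_grid)
    num = np.trapezoid(e * p * w, x)
    den = np.trapezoid(p * w, x)
    if clip_to_grid:
        m_lo, m_hi = _edge_atoms(mixture, grid)
        num += (m_lo * grid.p_biallelic[0] * grid.e_rare[0]
                + m_hi * grid.p_biallelic[-1] * grid.e_rare[-1])
        den += m_lo * grid.p_biallelic[0] + m_hi * grid.p_biallelic[-1]
    return float(num / den)


def sample_rates_conditional(mixture: LognormalRateMixture, grid: RateGrid,
                             size: int, rng: np.random.Generator,
                             *, n_points: int = 4097) -> np.ndarray:
    """Draw per-site rates from f(M | S=1; mu) — the rate law of *polymorphic*
    sites, size-biased towards high rates by P(S=1|M).

    Sampling is by discrete inverse-CDF on a fine log10 grid clipped to the
    rate grid, with the out-of-range g-mass kept as atoms at the edges (the
    clip convention of :func:`mixture_rare_fraction`); within-bin positions
    are jittered uniformly.
    """
    if mixture.sigma == 0:
        return np.full(size, mixture.mu)
    x = _log_grid(mixture, grid, n_points, trunc_sigmas=8.0, clip_to_grid=True)
    Mx = 10.0 ** x
    w = density_g(Mx, mixture) * Mx * LN10 * _interp_grid(x, grid, "p_biallelic")
    dx = x[1] - x[0]
    weights = np.concatenate([
        w[:-1] * dx,
        [_edge_atoms(mixture, grid)[0] * grid.p_biallelic[0],
         _edge_atoms(mixture, grid)[1] * grid.p_biallelic[-1]],
    ])
    weights /= weights.sum()
    idx = rng.choice(len(weights), size=size, p=weights)
    out = np.empty(size)
    interior = idx < n_points - 1
    out[interior] = 10.0 ** (x[idx[interior]] + rng.random(int(interior.sum())) * dx)
    out[idx == n_points - 1] = grid.rates[0]
    out[idx == n_points] = grid.rates[-1]
    return out


def mixture_rare_fraction_se(mixture: LognormalRateMixture, grid: RateGrid,
                             *, n_points: int = 1025, trunc_sigmas: float = 4.0) -> float:
    """Propagated Monte-Carlo SE of :func:`mixture_rare_fraction`.

    The quadrature is linear in the interpolated ``e_rare`` and (to first
    order) in ``p_biallelic``; their per-grid-point simulation SEs are pushed
    through the interpolation hat weights.
    """
    if mixture.sigma == 0:
        return float(np.interp(np.log10(mixture.mu), np.log10(grid.rates), grid.se_e))
    x, w, p, e = _quadrature_parts(mixture, grid, n_points, trunc_sigmas)
    xg = np.log10(grid.rates)
    # hat-function interpolation weights A[q, i]
    A = np.zeros((len(x), len(xg)))
    idx = np.clip(np.searchsorted(xg, x) - 1, 0, len(xg) - 2)
    frac = np.clip((x - xg[idx]) / (xg[idx + 1] - xg[idx]), 0.0, 1.0)
    A[np.arange(len(x)), idx] = 1 - frac
    A[np.arange(len(x)), idx + 1] += frac
    # trapezoid weights
    c = np.gradient(x)
    den = np.sum(c * p * w)
    E = np.sum(c * e * p * w) / den
    dE_de = (c * p * w) @ A / den
    dE_dp = (c * w * (e - E)) @ A / den
    var = np.nansum((dE_de * grid.se_e) ** 2) + np.nansum((dE_dp * grid.se_p) ** 2)
    return float(np.sqrt(var))


def sample_rates(mixture: LognormalRateMixture, size: int,
                 rng: np.random.Generator):
    """Draw per-site rates M ~ g(M; mu, sigma)."""
    if mixture.sigma == 0:
        return np.full(size, mixture.mu)
    return 10.0 ** rng.normal(mixture.log10_location, mixture.sigma, size=size)


def fit_sigma(mu_values, observed_rare_fractions, grid: RateGrid,
              sigma_grid=None, **quad_kwargs) -> float:
    """Least-squares 1-D grid search for sigma over a rare-fraction curve.

    An extension beyond the fixed-sigma analysis: given observed rare
    fractions at several mean rates, returns the sigma whose mixture
    predictions minimize the summed squared error.
    """
    if sigma_grid is None:
        sigma_grid = np.linspace(0.0, 1.0, 101)
    obs = np.asarray(observed_rare_fractions, dtype=float)
    best, best_err = None, np.inf
    for s in sigma_grid:
        try:
            pred = np.array([
                mixture_rare_fraction(LognormalRateMixture(mu, s), grid, **quad_kwargs)
                for mu in mu_values
            ])
        except ValueError:
            continue  # sigma pushes the support outside the grid
        err = float(np.sum((pred - obs) ** 2))
        if err < best_err:
            best, best_err = float(s), err
    if best is None:
        raise ValueError("no sigma in the search grid kept the integration "
                         "range inside the rate grid")
    return best
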