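"""Two-category phylogenetic model of mutation-rate ascertainment.

Why are substituted-species sites enriched for hypermutable positions, and
why does the enrichment depend on which species carries the substitution?
The model here combines three ingredients:

* a per-site rate multiplier ``M ~ g(M)`` (the lognormal mixture of
  :mod:`ratesfs.rate_mixture`, with mean 1);
* Poisson substitution on the substituted species' branch — probability
  ``1 - exp(-rate * branch_exposure)`` with ``M`` scaling the rate; and
* two mutation categories: ``U`` ("uniform clock"), whose yearly rate is the
  same on every lineage (CpG transitions behave this way — their mutational
  mechanism is replication-independent), and ``G`` (generation-scaled),
  whose per-generation rate translates to a yearly rate inversely
  proportional to the lineage's generation time.

Conditioning a site on being polymorphic in humans AND substituted in
species ``s`` size-biases ``M`` upwards (both events are rate-driven), and
re-weights the two categories: lineages with long generation times
accumulate fewer generation-scaled substitutions per year, so their
substituted sites are relatively enriched for uniform-clock (CpG-like)
mutations.  Within the primates, generation time broadly shortens with
divergence from human, which predicts a CpG enrichment gradient across
substituted species — the mechanism behind the cSFS skew trend.

All densities are evaluated by trapezoid quadrature on a log10 grid of the
multiplier.  In the pure uniform-clock limit the posterior rate distribution
is exactly identical across substituted species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .rate_mixture import LN10, LognormalRateMixture, density_g

__all__ = [
    "LineageBranch",
    "MutationCategoryMix",
    "default_lineages",
    "branch_substitution_prob",
    "rate_distribution_at_substituted_sites",
    "uniform_clock_enrichment",
]


@dataclass(frozen=True)
class LineageBranch:
    """One primate lineage relative to human.

    branch_years: time since the split from the human lineage (years),
        i.e. the species-side branch length.
    generation_years: the species' generation time in years.
    human_branch_years: the matching human-side branch length (defaults to
        the same span).
    """

    species: str
    branch_years: float
    generation_years: float
    human_branch_years: float | None = None

    def __post_init__(self):
        if self.branch_years <= 0 or self.generation_years <= 0:
            raise ValueError("branch lengths and generation times must be positive")
        if self.human_branch_years is None:
            object.__setattr__(self, "human_branch_years", self.branch_years)


@dataclass(frozen=True)
class MutationCategoryMix:
    """Mixture of uniform-clock (U) and generation-scaled (G) mutations.

    frac_uniform: fraction of sites in category U; the rest are G.
    rate_uniform: yearly substitution rate of a U site with multiplier 1
        (the same on every lineage — the "uniform clock").
    rate_generational: per-generation rate of a G site with multiplier 1
        (converted to a yearly rate on a lineage by dividing by that
        lineage's generation time).
    multiplier: per-site rate multiplier distribution (mean 1 by default).
    reference_generation_years: generation time of the focal (human)
        lineage, used to express U rates per generation when comparing the
        two categories on the polymorphism side.
    """

    frac_uniform: float
    rate_uniform: float
    rate_generational: float
    multiplier: LognormalRateMixture = field(
        default_factory=lambda: LognormalRateMixture(1.0, 0.57))
    reference_generation_years: float = 29.0

    def __post_init__(self):
        if not (0 <= self.frac_uniform <= 1):
            raise ValueError("frac_uniform must lie in [0, 1]")
        if self.rate_uniform < 0 or self.rate_generational < 0:
            raise ValueError("rates must be >= 0")

    def reference_rate_per_generation(self, category: str) -> float:
        """Mean per-generation rate of a category on the focal lineage."""
        if category == "U":
            return self.rate_uniform * self.reference_generation_years
        if category == "G":
            return self.rate_generational
        raise ValueError("category must be 'U' or 'G'")


def default_lineages() -> dict:
    """Editable default branch lengths and generation times (from the
    packaged YAML; the values are literature-typical choices, see the file's
    comments for sources)."""
    with resources.files("ratesfs.data").joinpath("primate_lineages.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return {
        # YAML 1.1 reads exponent literals like 6.5e6 as strings; coerce
        name: LineageBranch(species=name,
                            **{k: float(v) for k, v in params.items()})
        for name, params in doc["lineages"].items()
    }


def branch_substitution_prob(M: float, branch: LineageBranch,
                             category: str, mix: MutationCategoryMix):
    """P(substitution on the branch) for a site with multiplier ``M``.

    Category U: ``1 - exp(-r_U * M * t_years)`` — invariant to generation
    time.  Category G: ``1 - exp(-r_G * M * t_years / g_years)`` — the
    per-generation rate is spread over ``t/g`` generations.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("rate multiplier must be >= 0")
    if category == "U":
        lam = mix.rate_uniform * M * branch.branch_years
    elif category == "G":
        lam = (mix.rate_generational * M * branch.branch_years
               / branch.generation_years)
    else:
        raise ValueError("category must be 'U' or 'G'")
    return -np.expm1(-lam)


def _human_poly_prob(rate_per_gen, rate_grid=None):
    """P(polymorphic in the human sample | per-generation rate), up to scale.

    Defaults to the linear-in-rate approximation (valid when per-site
    diversity is small); a finite-sites RateGrid gives the exact saturating
    curve (grid rates are per bp per generation, the same units).
    """
    r = np.asarray(rate_per_gen, dtype=float)
    if rate_grid is None:
        return r
    x = np.log10(np.clip(r, rate_grid.rates[0], rate_grid.rates[-1]))
    return np.interp(x, np.log10(rate_grid.rates), rate_grid.p_biallelic)


def _quad_grid(mix: MutationCategoryMix, n_points: int, trunc_sigmas: float):
    lo, hi = mix.multiplier.support(trunc_sigmas)
    x = np.linspace(np.log10(lo), np.log10(hi), n_points)
    M = 10.0 ** x
    gM = density_g(M, mix.multiplier) * M * LN10  # density in log10 units
    return x, M, gM


def rate_distribution_at_substituted_sites(
    branch: LineageBranch,
    mix: MutationCategoryMix,
    *,
    rate_grid=None,
    n_points: int = 2001,
    trunc_sigmas: float = 4.0,
):
    """Posterior density of the per-generation mutation rate at
    substituted-``s`` sites.

    Within each category the joint weight of a multiplier ``M`` is
    ``P(polymorphic in human | rate) * P(substituted in s | M) * g(M)``;
    the site's human-side per-generation rate is ``M`` times the category's
    reference rate, so the two categories contribute two shifted copies of
    the multiplier posterior on the rate axis.  Conditioning on polymorphism
    and substitution size-biases the result towards high rates; species
    whose generation time suppresses the G category shift further towards
    the (faster, CpG-like) U rates.

    Returns ``(rate_grid_values, density)`` with the density per unit of
    log10 rate, normalized to integrate to 1.
    """
    x, M, gM = _quad_grid(mix, n_points, trunc_sigmas)
    pieces = []
    for cat, frac in (("U", mix.frac_uniform), ("G", 1 - mix.frac_uniform)):
        ref = mix.reference_rate_per_generation(cat)
        w = (frac * _human_poly_prob(M * ref, rate_grid)
             * branch_substitution_prob(M, branch, cat, mix) * gM)
        pieces.append((np.log10(ref), w))
    # common log10-rate axis covering both shifted copies
    lo = min(s for s, _ in pieces) + x[0]
    hi = max(s for s, _ in pieces) + x[-1]
    xr = np.linspace(lo, hi, n_points)
    dens = np.zeros_like(xr)
    for shift, w in pieces:
        dens += np.interp(xr, x + shift, w, left=0.0, right=0.0)
    Z = np.trapezoid(dens, xr)
    if not np.isfinite(Z) or Z <= 0:
        raise ValueError("posterior is not normalizable with these parameters")
    return 10.0 ** xr, dens / Z


def uniform_clock_enrichment(
    branch: LineageBranch,
    mix: MutationCategoryMix,
    *,
    rate_grid=None,
    n_points: int = 2001,
    trunc_sigmas: float = 4.0,
) -> float:
    """Expected fraction of substituted-``s`` sites in the uniform-clock class.

    Bayes re-weighting of the prior category fractions by each category's
    marginal probability of producing a human polymorphism plus an ``s``
    substitution.  Strictly increasing in the species' generation time (the
    G category is penalized on slow-generation lineages); equal generation
    times across species give identical enrichment.
    """
    x, M, gM = _quad_grid(mix, n_points, trunc_sigmas)
    wU = mix.frac_uniform * np.trapezoid(
        _human_poly_prob(M * mix.reference_rate_per_generation("U"), rate_grid)
        * branch_substitution_prob(M, branch, "U", mix) * gM, x)
    wG = (1 - mix.frac_uniform) * np.trapezoid(
        _human_poly_prob(M * mix.reference_rate_per_generation("G"), rate_grid)
        * branch_substitution_prob(M, branch, "G", mix) * gM, x)
    if wU + wG == 0:
        raise ValueError("both categories have zero substitution probability")
    return float(wU / (wU + wG))
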