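"""Finite-sites Jukes–Cantor mutation on coalescent genealogies.

Under the infinite-sites model every mutation creates a new segregating site
and the SFS is independent of the mutation rate.  At high per-site rates that
assumption breaks: recurrent and back mutations at the same site push large
samples towards common variants.  This module quantifies the effect by
dropping Jukes–Cantor (uniform 4x4) mutations on Kingman genealogies and
tabulating, across a grid of per-site rates ``M``:

* ``P(S=1 | M)`` — the probability a simulated site is biallelic, and
* ``E[Y | S=1, M]`` — the fraction of biallelic sites that are rare
  (minor-allele count <= 2 by default),

the two ingredients of the within-mutation-type rate-mixture integral in
:mod:`ratesfs.rate_mixture`.

Sites are simulated in non-recombining blocks (default 1 kb) that share a
genealogy, so all Monte-Carlo standard errors are computed by treating each
genealogy as a cluster.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import DemographicModel

__all__ = [
    "SiteClassCounts",
    "RateGrid",
    "default_rate_grid",
    "simulate_genealogies",
    "mutate_jc",
    "pair_biallelic_prob_jc",
    "estimate_grid",
]

# the standard mutation-rate grid: 40 log-spaced points, per bp per
# generation per haploid
GRID_MIN_RATE = 1e-9
GRID_MAX_RATE = 5.3e-5
GRID_NUM_RATES = 40


def default_rate_grid(num: int = GRID_NUM_RATES,
                      lo: float = GRID_MIN_RATE,
                      hi: float = GRID_MAX_RATE) -> np.ndarray:
    return np.geomspace(lo, hi, num)


@dataclass
class SiteClassCounts:
    """Per-site allelic classification of one mutated genealogy block."""

    n_sites: int
    n_monomorphic: int
    n_biallelic: int
    n_triallelic: int
    n_quadallelic: int
    minor_counts: np.ndarray   # per biallelic site
    derived_counts: np.ndarray  # per biallelic site (non-root allele copies)

    def __post_init__(self):
        total = (self.n_monomorphic + self.n_biallelic
                 + self.n_triallelic + self.n_quadallelic)
        if total != self.n_sites:
            raise ValueError("site class counts do not sum to n_sites")


def simulate_genealogies(model: DemographicModel, n: int, num_trees: int,
                         seed: int | None = None, *, sequence_length: int = 1000):
    """Yield independent single-tree TreeSequences of ``n`` chromosomes.

    Trees are Kingman genealogies with branch lengths in generations; each
    carries ``sequence_length`` non-recombining sites for mutation dropping.
    """
    import msprime

    if n < 2:
        raise ValueError("n must be >= 2")
    yield from msprime.sim_ancestry(
        samples={"pop": n}, ploidy=1, demography=model.to_msprime(),
        sequence_length=sequence_length, num_replicates=num_trees,
        random_seed=None if seed is None else seed,
    )


def mutate_jc(ts, M: float, seed: int | None = None) -> SiteClassCounts:
    """Drop Jukes–Cantor mutations at rate ``M`` per site per generation.

    The root base of every site is drawn uniformly (the JC stationary
    distribution); mutation events are Poisson along branches and replace the
    current base with one of the other three uniformly, so multiple and back
    mutations arise naturally.  Leaf bases determine whether each site is
    monomorphic, biallelic, tri- or quadallelic.

    For biallelic sites the derived allele is the non-root allele; if
    recurrent mutation removes the root allele from the sample entirely, the
    site is polarized by the minor allele (a rare event, part of the
    mispolarization phenomenon being modelled).
    """
    import msprime

    if M < 0:
        raise ValueError("mutation rate must be >= 0")
    n = ts.num_samples
    L = int(ts.sequence_length)
    mts = msprime.sim_mutations(
        ts, rate=M, model=msprime.JC69(), discrete_genome=True,
        random_seed=None if seed is None else seed,
    )
    n_mono = L
    n_bi = n_tri = n_quad = 0
    minor = []
    derived = []
    for var in mts.variants():
        counts = np.bincount(var.genotypes, minlength=len(var.alleles))
        observed = counts > 0
        k = int(observed.sum())
        if k <= 1:
            continue  # mutations reverted; still monomorphic
        n_mono -= 1
        if k == 2:
            n_bi += 1
            c = counts[observed]
            minor.append(int(c.min()))
            # allele index 0 is the ancestral (root) state in tskit variants
            if counts[0] > 0:
                derived.append(int(n - counts[0]))
            else:
                derived.append(int(c.min()))
        elif k == 3:
            n_tri += 1
        else:
            n_quad += 1
    return SiteClassCounts(
        n_sites=L, n_monomorphic=n_mono, n_biallelic=n_bi,
        n_triallelic=n_tri, n_quadallelic=n_quad,
        minor_counts=np.array(minor, dtype=int),
        derived_counts=np.array(derived, dtype=int),
    )


def pair_biallelic_prob_jc(N: float, M: float) -> float:
    """Closed-form P(two sampled chromosomes differ) under JC + constant size.

    Independent oracle for the simulator at ``n=2``: integrating the JC
    mismatch probability ``(3/4)(1 - exp(-(8/3) M t))`` over the exponential
    pairwise coalescence time (mean ``2N`` generations) gives
    ``(3/4) * theta' / (1 + theta')`` with ``theta' = (16/3) N M``.
    """
    theta = (16.0 / 3.0) * N * M
    return 0.75 * theta / (1.0 + theta)


@dataclass
class RateGrid:
    """Simulated finite-sites quantities across a mutation-rate grid."""

    rates: np.ndarray        # strictly increasing, per bp per gen per haploid
    p_biallelic: np.ndarray  # P(S=1 | M)
    e_rare: np.ndarray       # E[Y | S=1, M]
    se_p: np.ndarray
    se_e: np.ndarray
    n_sites: np.ndarray      # sites simulated per rate
    n_biallelic: np.ndarray
    sample_size: int
    model_name: str = ""
    rare_max_count: int = 2
    seed: int | None = None
    flags: list | None = None

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(np.diff(self.rates) <= 0):
            raise ValueError("rates must be strictly increasing")
        for name in ("p_biallelic", "e_rare"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
            setattr(self, name, v)

    def to_tsv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame({
            "rate": self.rates, "p_biallelic": self.p_biallelic,
            "e_rare": self.e_rare, "se_p": self.se_p, "se_e": self.se_e,
            "n_sites": self.n_sites, "n_biallelic": self.n_biallelic,
        })
        df.to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {"sample_size": self.sample_size, "model_name": self.model_name,
                    "rare_max_count": self.rare_max_count, "seed": self.seed,
                    "flags": self.flags or []}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_tsv(cls, path) -> "RateGrid":
        df = pd.read_csv(path, sep="\t")
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"sample_size": 0}
        return cls(
            rates=df["rate"].to_numpy(), p_biallelic=df["p_biallelic"].to_numpy(),
            e_rare=df["e_rare"].to_numpy(), se_p=df["se_p"].to_numpy(),
            se_e=df["se_e"].to_numpy(), n_sites=df["n_sites"].to_numpy(),
            n_biallelic=df["n_biallelic"].to_numpy(),
            sample_size=meta.get("sample_size", 0),
            model_name=meta.get("model_name", ""),
            rare_max_count=meta.get("rare_max_count", 2),
            seed=meta.get("seed"), flags=meta.get("flags"),
        )


def _cluster_ratio(num_t: np.ndarray, den_t: np.ndarray):
    """Ratio estimate with a cluster (per-genealogy) standard error."""
    den = den_t.sum()
    if den == 0:
        return np.nan, np.nan
    r = num_t.sum() / den
    T = len(num_t)
    if T < 2:
        return r, np.nan
    resid = num_t - r * den_t
    se = np.sqrt(T / (T - 1) * np.sum(resid ** 2)) / den
    return float(r), float(se)


def estimate_grid(
    model: DemographicModel,
    n: int,
    rates=None,
    *,
    min_biallelic: int = 10_000,
    sites_per_tree: int = 1000,
    rare_max_count: int = 2,
    seed: int | None = None,
    pilot_trees: int = 16,
    max_sites_per_tree: int = 200_000,
    max_trees_per_rate: int = 20_000,
) -> RateGrid:
    """Estimate ``P(S=1|M)`` and ``E[Y|S=1,M]`` across a rate grid.

    For each rate, genealogies carrying ``sites_per_tree`` non-recombining
    sites are simulated until at least ``min_biallelic`` biallelic sites have
    accumulated.  A pilot batch sizes the remaining work; at low rates the
    block length is enlarged (sites within a block are conditionally
    independent given the genealogy, so this only trades variance between the
    within- and between-tree levels, which the cluster standard errors
    account for).  Rates whose biallelic yield collapses (recurrent mutation
    saturating sites) are flagged rather than silently dropped.
    """
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = default_rate_grid()
    rates = np.asarray(rates, dtype=float)
    if np.any(np.diff(rates) <= 0):
        raise ValueError("rates must be sorted strictly increasing")

    p_list, e_list, sp_list, se_list = [], [], [], []
    ns_list, nb_list, flags = [], [], []
    for M in rates:
        per_tree = []  # (sites, biallelic, rare)
        L = sites_per_tree

        def run_batch(num_trees, L):
            sim_seed = int(rng.integers(1, 2**31 - 1))
            mut_seed = int(rng.integers(1, 2**31 - 1))
            for k, ts in enumerate(simulate_genealogies(
                    model, n, num_trees, seed=sim_seed, sequence_length=L)):
                sc = mutate_jc(ts, M, seed=mut_seed + k)
                rare = int((sc.minor_counts <= rare_max_count).sum())
                per_tree.append((sc.n_sites, sc.n_biallelic, rare))

        run_batch(pilot_trees, L)
        got = sum(b for _, b, _ in per_tree)
        while got < min_biallelic:
            yield_per_tree = max(got / len(per_tree), 1e-9)
            need_trees = int(np.ceil((min_biallelic - got) / yield_per_tree))
            if need_trees > 4 * pilot_trees and L < max_sites_per_tree:
                # cheaper to lengthen blocks than to multiply genealogies
                scale = min(need_trees / (4 * pilot_trees), max_sites_per_tree / L)
                L = int(min(max_sites_per_tree, np.ceil(L * max(scale, 2))))
                # floor the yield estimate so a biallelic-free pilot still
                # schedules a finite follow-up batch
                yield_per_site = max(got, 1) / sum(s for s, _, _ in per_tree)
                need_trees = int(np.ceil((min_biallelic - got) / (yield_per_site * L)))
            if len(per_tree) + need_trees > max_trees_per_rate:
                warnings.warn(f"rate {M:g}: biallelic yield too low; stopping early")
                flags.append({"rate": float(M), "issue": "insufficient_biallelic"})
                break
            run_batch(min(need_trees, max_trees_per_rate - len(per_tree)), L)
            got = sum(b for _, b, _ in per_tree)

        arr = np.array(per_tree, dtype=float)
        p, sp = _cluster_ratio(arr[:, 1], arr[:, 0])
        e, se = _cluster_ratio(arr[:, 2], arr[:, 1])
        p_list.append(p); sp_list.append(sp)
        e_list.append(e); se_list.append(se)
        ns_list.append(int(arr[:, 0].sum())); nb_list.append(int(arr[:, 1].sum()))

    return RateGrid(
        rates=rates, p_biallelic=np.array(p_list), e_rare=np.array(e_list),
        se_p=np.array(sp_list), se_e=np.array(se_list),
        n_sites=np.array(ns_list), n_biallelic=np.array(nb_list),
        sample_size=n, model_name=model.name, rare_max_count=rare_max_count,
        seed=seed, flags=flags,
    )
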