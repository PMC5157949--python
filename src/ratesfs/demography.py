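"""Piecewise demographic models and coalescent expectations under them.

Models are lists of epochs ordered from the present backwards.  Sizes are
*diploid* effective sizes (a pair of lineages coalesces at rate ``1/(2N)``
per generation) and time is measured in generations before present; epoch
boundaries are half-open ``[start, end)``.

Growth rates are quoted per generation.  The default reading of a rate ``r``
is compound-per-generation, ``N(t) = N0 * (1+r)**-t`` going backwards, with
an exact-exponential alternative ``N(t) = N0 * exp(-r t)`` available via
``growth_convention="exact"``.

Three computations are provided on top of the models:

* the expected infinite-sites SFS of a sample (analytic via the death-chain
  spectral representation in arbitrary precision, or by averaging branch-mode
  allele-frequency spectra over simulated genealogies);
* the probability that a sample's genealogy retains >= 2 lineages at an
  ancient time, e.g. the human-chimpanzee split;
* an upper bound on the probability that a polymorphic site is ancestrally
  shared with another species, via branch-length-weighted genealogies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "Epoch",
    "DemographicModel",
    "preset_model",
    "expected_sfs_infinite",
    "prob_two_or_more_lineages",
    "ancestral_polymorphism_bound",
    "expected_shared_sites",
]

ANALYTIC_MAX_N = 512  # beyond this the arbitrary-precision path gets too costly


@dataclass(frozen=True)
class Epoch:
    """One demographic epoch, described at its recent (younger) end.

    duration: length in generations; ``None`` marks the terminal (oldest,
        unbounded) epoch.
    size_at_recent_end: diploid effective size at the younger boundary.
    growth_rate: per-generation exponential growth rate looking forward in
        time (0 = constant size within the epoch).
    """

    duration: float | None
    size_at_recent_end: float
    growth_rate: float = 0.0

    def __post_init__(self):
        if self.size_at_recent_end <= 0:
            raise ValueError("population sizes must be positive")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("epoch durations must be positive")


@dataclass(frozen=True)
class DemographicModel:
    """Ordered epochs from the present backwards; exactly one terminal epoch."""

    epochs: tuple
    name: str = ""
    growth_convention: str = "compound"  # or "exact"

    def __post_init__(self):
        eps = tuple(self.epochs)
        if not eps:
            raise ValueError("a model needs at least one epoch")
        if any(e.duration is None for e in eps[:-1]) or eps[-1].duration is not None:
            raise ValueError("exactly the last epoch must be unbounded (duration=None)")
        if self.growth_convention not in ("compound", "exact"):
            raise ValueError("growth_convention must be 'compound' or 'exact'")
        if eps[-1].growth_rate != 0:
            raise ValueError("the terminal epoch must have zero growth")
        object.__setattr__(self, "epochs", eps)

    # -- size trajectory ------------------------------------------------------

    def _alpha(self, rate: float) -> float:
        """Backwards exponential decay rate corresponding to a quoted rate."""
        return math.log1p(rate) if self.growth_convention == "compound" else rate

    def epoch_starts(self) -> np.ndarray:
        starts = [0.0]
        for e in self.epochs[:-1]:
            starts.append(starts[-1] + e.duration)
        return np.array(starts)

    def size_at(self, t: float) -> float:
        """Diploid size at time ``t`` generations before present."""
        if t < 0:
            raise ValueError("time must be nonnegative")
        starts = self.epoch_starts()
        k = int(np.searchsorted(starts, t, side="right") - 1)
        e = self.epochs[k]
        return e.size_at_recent_end * math.exp(-self._alpha(e.growth_rate) * (t - starts[k]))

    @property
    def terminal_size(self) -> float:
        """Pre-out-of-Africa (oldest-epoch) diploid size."""
        return self.epochs[-1].size_at_recent_end

    # -- conversions ----------------------------------------------------------

    def to_msprime(self):
        """An msprime Demography for *ploidy-1* samples.

        msprime's pair-coalescence rate with ploidy-1 samples is ``1/N``; our
        sizes are diploid with rate ``1/(2N)``, so sizes are doubled here.
        Always simulate with ``ploidy=1`` and ``samples={"pop": n}`` where
        ``n`` is the number of chromosomes.
        """
        import msprime

        d = msprime.Demography()
        starts = self.epoch_starts()
        e0 = self.epochs[0]
        d.add_population(name="pop", initial_size=2 * e0.size_at_recent_end,
                         growth_rate=self._alpha(e0.growth_rate))
        for t0, e in zip(starts[1:], self.epochs[1:]):
            d.add_population_parameters_change(
                time=t0, initial_size=2 * e.size_at_recent_end,
                growth_rate=self._alpha(e.growth_rate), population="pop")
        return d

    def discretized(self, steps_per_epoch: int = 64) -> "DemographicModel":
        """Piecewise-constant approximation (growth epochs sliced geometrically).

        Used by the analytic SFS path, where constant epochs admit closed-form
        coalescent-intensity integrals.
        """
        out = []
        starts = self.epoch_starts()
        for t0, e in zip(starts, self.epochs):
            if e.growth_rate == 0 or e.duration is None:
                out.append(Epoch(e.duration, e.size_at_recent_end, 0.0))
                continue
            edges = np.linspace(0, e.duration, steps_per_epoch + 1)
            a = self._alpha(e.growth_rate)
            for lo, hi in zip(edges[:-1], edges[1:]):
                mid = 0.5 * (lo + hi)
                out.append(Epoch(hi - lo, e.size_at_recent_end * math.exp(-a * mid), 0.0))
        return DemographicModel(tuple(out), name=self.name + "+discretized",
                                growth_convention=self.growth_convention)

    def coalescent_intensity_segments(self):
        """(Lambda_at_start, 2N, duration) per constant epoch; requires no growth."""
        if any(e.growth_rate != 0 for e in self.epochs):
            raise ValueError("call .discretized() first: growth epochs present")
        segs = []
        lam = 0.0
        for e in self.epochs:
            twoN = 2.0 * e.size_at_recent_end
            segs.append((lam, twoN, e.duration))
            if e.duration is not None:
                lam += e.duration / twoN
        return segs

    # -- YAML serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "name": self.name,
            "growth_convention": self.growth_convention,
            "epochs": [
                {"duration_generations": e.duration, "diploid_size": e.size_at_recent_end,
                 "growth_rate": e.growth_rate}
                for e in self.epochs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DemographicModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        eps = tuple(
            Epoch(d["duration_generations"], d["diploid_size"], d.get("growth_rate", 0.0))
            for d in doc["epochs"]
        )
        return cls(eps, name=doc.get("name", ""),
                   growth_convention=doc.get("growth_convention", "compound"))


# --- presets -----------------------------------------------------------------

def preset_model(name: str, **overrides) -> DemographicModel:
    """Shipped demographic models.

    ``constant``
        Flat diploid size (default 10,000).
    ``modified_nelson_recent``
        The re-fit recent-growth epoch for non-Finnish Europeans — current
        diploid size 4,009,877 growing at 5.38% per generation since 119.47
        generations ago — placed on top of a constant pre-out-of-Africa size
        of 10,000 diploids.  The intermediate epochs of the original Nelson
        et al. parameterization are not part of this preset; supply them via
        ``modified_nelson(older_epochs=...)`` if you have them.
    ``tennessen_european``
        The Tennessen et al. (2012) European single-population model
        (two-phase recent growth, two bottlenecks, African expansion,
        ancestral size 7,310), transcribed from that publication.
    """
    if name == "constant":
        N = overrides.pop("size", 10_000)
        return DemographicModel((Epoch(None, N),), name="constant")
    if name == "modified_nelson_recent":
        anc = overrides.pop("ancestral_size", 10_000)
        return DemographicModel(
            (Epoch(119.47, 4_009_877, 0.0538), Epoch(None, anc)),
            name="modified_nelson_recent",
        )
    if name == "tennessen_european":
        return DemographicModel(
            (
                Epoch(204.6, 512_000, 0.0195),
                Epoch(715.4, 9_279, 0.00307),
                Epoch(1120.0, 1_861, 0.0),
                Epoch(3880.0, 14_474, 0.0),
                Epoch(None, 7_310, 0.0),
            ),
            name="tennessen_european",
        )
    raise KeyError(f"unknown preset {name!r}; available: constant, "
                   "modified_nelson_recent, tennessen_european")


def modified_nelson(older_epochs, name="modified_nelson") -> DemographicModel:
    """Modified-Nelson model with user-supplied pre-growth epochs.

    The recent epoch uses the re-fit growth parameters; ``older_epochs`` must
    be the Nelson et al. epochs from 119.47 generations backwards (a sequence
    of :class:`Epoch`, last one unbounded).
    """
    return DemographicModel((Epoch(119.47, 4_009_877, 0.0538), *older_epochs), name=name)


# --- expected infinite-sites SFS --------------------------------------------

def _tavare_level_times(segs, n: int, dps: int):
    """E[T_k], k=2..n, via the death-chain spectral decomposition (mpmath).

    ``segs`` are constant-epoch coalescent-intensity segments.  The ancestral
    lineage-count process, time-changed by the cumulative coalescent
    intensity, is the standard pure-death chain; its transition function is an
    alternating sum with catastrophic float cancellation, hence arbitrary
    precision.
    """
    from mpmath import binomial, exp, mp, mpf

    with mp.workdps(dps):
        e = [mpf(0)] * (n + 1)  # e[j] = integral of exp(-C(j,2) * Lambda(t)) dt
        for j in range(2, n + 1):
            c = mpf(j * (j - 1)) / 2
            tot = mpf(0)
            for lam0, twoN, dur in segs:
                pre = exp(-c * mpf(lam0)) * mpf(twoN) / c
                if dur is None:
                    tot += pre
                else:
                    tot += pre * (1 - exp(-c * mpf(dur) / mpf(twoN)))
            e[j] = tot

        ET = np.zeros(n + 1, dtype=object)
        for k in range(2, n + 1):
            s = mpf(0)
            rising_k = mpf(1)  # k^(j-1) rising, updated incrementally
            falling_n = mpf(1)  # n_(j) falling
            rising_n = mpf(1)  # n^(j) rising
            fact_jk = mpf(1)
            # initialize products at j = k
            for i in range(k - 1):
                rising_k *= (k + i)
            for i in range(k):
                falling_n *= (n - i)
                rising_n *= (n + i)
            fact_k = mpf(math.factorial(k))
            for j in range(k, n + 1):
                if j > k:
                    rising_k *= (k + j - 2)
                    falling_n *= (n - j + 1)
                    rising_n *= (n + j - 1)
                    fact_jk *= (j - k)
                coeff = (2 * j - 1) * rising_k * falling_n / (fact_k * fact_jk * rising_n)
                if (j - k) % 2:
                    coeff = -coeff
                s += coeff * e[j]
            ET[k] = s

        # E[xi_b] ~ sum_k p(b | k) * k * E[T_k]
        xi = np.zeros(n - 1)
        for b in range(1, n):
            s = mpf(0)
            for k in range(2, n - b + 2):
                p = binomial(n - b - 1, k - 2) / binomial(n - 1, k - 1)
                s += p * k * ET[k]
            xi[b - 1] = float(s)
    return xi


def expected_sfs_infinite(
    model: DemographicModel,
    n: int,
    method: str = "auto",
    *,
    reps: int = 200,
    seed: int | None = None,
    steps_per_epoch: int = 64,
):
    """Expected infinite-sites SFS (proportions) for ``n`` chromosomes.

    ``method="analytic"`` uses the exact death-chain representation (constant
    epochs exactly; growth epochs are discretized piecewise-constant with
    ``steps_per_epoch`` slices).  It is limited to moderate ``n`` — the
    alternating sums require arbitrary-precision arithmetic whose cost grows
    quadratically — and raises beyond ``ANALYTIC_MAX_N`` instead of returning
    unstable numbers.  ``method="simulation"`` averages branch-mode
    allele-frequency spectra over ``reps`` independent genealogies (unbiased
    for any ``n``).  ``"auto"`` picks analytic when feasible.
    """
    from .spectra import SpectrumUnfolded

    if n < 2:
        raise ValueError("n must be >= 2")
    if method == "auto":
        method = "analytic" if n <= ANALYTIC_MAX_N else "simulation"
    if method == "analytic":
        if n > ANALYTIC_MAX_N:
            raise ValueError(
                f"analytic SFS limited to n <= {ANALYTIC_MAX_N} "
                "(arbitrary-precision cost); use method='simulation'"
            )
        if len(model.epochs) == 1:
            # constant size: the classical 1/i law, exact
            xi = 1.0 / np.arange(1, n)
        else:
            segs = model.discretized(steps_per_epoch).coalescent_intensity_segments()
            dps = max(30, int(0.8 * n) + 15)
            xi = _tavare_level_times(segs, n, dps)
            if np.any(xi < 0) or not np.all(np.isfinite(xi)):
                raise ArithmeticError(
                    "analytic SFS numerically unstable at this n/precision"
                )
        return SpectrumUnfolded(n, xi / xi.sum())
    if method == "simulation":
        import msprime

        tot = np.zeros(n + 1)
        for ts in msprime.sim_ancestry(
            samples={"pop": n}, ploidy=1, demography=model.to_msprime(),
            num_replicates=reps, random_seed=None if seed is None else seed,
        ):
            tot += ts.allele_frequency_spectrum(
                mode="branch", polarised=True, span_normalise=False)
        xi = tot[1:n]
        return SpectrumUnfolded(n, xi / xi.sum())
    raise ValueError("method must be 'auto', 'analytic' or 'simulation'")


# --- lineage survival & ancestral polymorphism -------------------------------

def prob_two_or_more_lineages(
    model: DemographicModel,
    n: int,
    t: float,
    *,
    method: str = "auto",
    reps: int = 2000,
    seed: int | None = None,
) -> float:
    """P(TMRCA of an n-sample > t), i.e. >= 2 sample lineages survive to ``t``.

    Analytic closed form for ``n=2`` under a constant model; otherwise
    estimated from simulated coalescent genealogies.  Monotone non-increasing
    in ``t`` and equal to 1 at ``t=0``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 1.0
    constant = len(model.epochs) == 1
    if method == "auto":
        method = "analytic" if (constant and n == 2) else "simulation"
    if method == "analytic":
        if not (constant and n == 2):
            raise ValueError("analytic form implemented for constant-size n=2 only")
        return math.exp(-t / (2 * model.terminal_size))
    import msprime

    hits = 0
    for ts in msprime.sim_ancestry(
        samples={"pop": n}, ploidy=1, demography=model.to_msprime(),
        num_replicates=reps, random_seed=None if seed is None else seed,
    ):
        if ts.max_root_time > t:
            hits += 1
    return hits / reps


def ancestral_polymorphism_bound(
    model: DemographicModel,
    n: int,
    t_split: float,
    *,
    worst_case: bool = False,
    reps: int = 2000,
    seed: int | None = None,
) -> float:
    """Upper bound on P(a sampled polymorphism is ancestrally shared).

    A neutral polymorphism observed today can predate the split from another
    species only if >= 2 lineages ancestral to the sample survive back to
    ``t_split``.  Conditioning on the site being polymorphic favours
    genealogies with more mutational opportunity, so each simulated genealogy
    is weighted by its total branch length and the weighted fraction with
    >= 2 surviving lineages is returned.

    ``worst_case=True`` removes all coalescence between the present and the
    start of the terminal (pre-out-of-Africa) epoch: all ``n`` lineages enter
    the constant ancient epoch intact, which can only inflate the bound.
    """
    import msprime

    if t_split == 0:
        return 1.0
    if model.epochs[-1].growth_rate != 0:
        raise ValueError("terminal epoch must be constant")
    t_ooa = float(model.epoch_starts()[-1])
    if worst_case:
        if t_split < t_ooa:
            raise ValueError(
                f"worst_case requires t_split ({t_split}) at or beyond the "
                f"terminal epoch start ({t_ooa})")
        sim_model = DemographicModel((Epoch(None, model.terminal_size),),
                                     name=model.name + "+no_recent_coalescence")
    else:
        sim_model = model
    num = 0.0
    den = 0.0
    for ts in msprime.sim_ancestry(
        samples={"pop": n}, ploidy=1, demography=sim_model.to_msprime(),
        num_replicates=reps, random_seed=None if seed is None else seed,
    ):
        tree = ts.first()
        length = tree.total_branch_length
        t_query = t_split
        if worst_case:
            # genealogy is frozen over [0, t_ooa): n stems of length t_ooa
            length += n * t_ooa
            t_query = t_split - t_ooa
        surviving = sum(
            1 for u in tree.nodes()
            if tree.parent(u) != -1
            and tree.time(u) <= t_query < tree.time(tree.parent(u))
        )
        if worst_case and t_query == 0:
            surviving = n
        num += length * (1.0 if surviving >= 2 else 0.0)
        den += length
    return num / den


def expected_shared_sites(p: float, n_sites: int) -> int:
    """Expected count of ancestrally shared sites, rounded to nearest integer."""
    if not (0 <= p <= 1):
        raise ValueError("p must be a probability")
    return int(round(p * n_sites))
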