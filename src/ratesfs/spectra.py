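"""Site frequency spectra and their summary statistics.

The site frequency spectrum (SFS) records, for a sample of ``n`` chromosomes,
how many segregating sites have each possible allele count.  Two flavours are
used throughout this package:

* :class:`SpectrumUnfolded` — classes indexed by *derived* allele count
  ``1..n-1`` (requires polarized data, e.g. via an outgroup).
* :class:`SpectrumFolded` — classes indexed by *minor* allele count
  ``1..floor(n/2)``; no polarization needed.

Counts may be real-valued so that expected spectra (e.g. from hypergeometric
projection or analytic demographic predictions) share the same containers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "SpectrumUnfolded",
    "SpectrumFolded",
    "TwoPopSiteCounts",
    "fold",
    "fraction_rare",
    "fraction_maf_le",
    "project",
    "projected_rare_fraction",
    "projection_masses",
    "sharing_by_count",
    "stratified_rare_fraction",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
]

RARE_MAX_COUNT_DEFAULT = 2  # singletons + doubletons


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("spectrum counts must be a 1-D vector")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("spectrum counts must be finite and nonnegative")
    return arr


@dataclass(frozen=True)
class SpectrumUnfolded:
    """Unfolded SFS: ``counts[i-1]`` = number of sites with derived count ``i``."""

    sample_size: int
    counts: np.ndarray

    def __post_init__(self):
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2 chromosomes")
        arr = _as_counts(self.counts)
        if len(arr) != self.sample_size - 1:
            raise ValueError(
                f"expected {self.sample_size - 1} classes for n={self.sample_size}, "
                f"got {len(arr)}"
            )
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def minor_counts(self) -> np.ndarray:
        """Minor allele count of each class (min(i, n-i))."""
        i = np.arange(1, self.sample_size)
        return np.minimum(i, self.sample_size - i)


@dataclass(frozen=True)
class SpectrumFolded:
    """Folded SFS: ``counts[i-1]`` = number of sites with minor count ``i``."""

    sample_size: int
    counts: np.ndarray

    def __post_init__(self):
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2 chromosomes")
        arr = _as_counts(self.counts)
        if len(arr) != self.sample_size // 2:
            raise ValueError(
                f"expected {self.sample_size // 2} folded classes for "
                f"n={self.sample_size}, got {len(arr)}"
            )
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def minor_counts(self) -> np.ndarray:
        return np.arange(1, self.sample_size // 2 + 1)


@dataclass(frozen=True)
class TwoPopSiteCounts:
    """Per-site minor-allele counts split between two subpopulations.

    ``count_a[i] + count_b[i]`` is the combined minor-allele count of site
    ``i``; totals give the number of chromosomes sampled per subpopulation.
    """

    count_a: np.ndarray
    count_b: np.ndarray
    total_a: int
    total_b: int

    def __post_init__(self):
        a = np.asarray(self.count_a, dtype=int)
        b = np.asarray(self.count_b, dtype=int)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("count_a and count_b must be 1-D arrays of equal length")
        if np.any(a < 0) or np.any(a > self.total_a):
            raise ValueError("count_a outside [0, total_a]")
        if np.any(b < 0) or np.any(b > self.total_b):
            raise ValueError("count_b outside [0, total_b]")
        if np.any((a + b) == 0):
            raise ValueError("every site must carry at least one minor-allele copy")
        object.__setattr__(self, "count_a", a)
        object.__setattr__(self, "count_b", b)

    @property
    def combined(self) -> np.ndarray:
        return self.count_a + self.count_b


def fold(spectrum: SpectrumUnfolded) -> SpectrumFolded:
    """Fold an unfolded spectrum onto minor-allele counts.

    Class ``i`` of the output is class ``i`` plus class ``n-i`` of the input
    for ``i < n/2``; for even ``n`` the central class ``n/2`` is copied once.
    The total number of sites is conserved exactly.
    """
    n = spectrum.sample_size
    half = n // 2
    out = np.zeros(half)
    for i in range(1, half + 1):
        out[i - 1] = spectrum.counts[i - 1]
        if i != n - i:
            out[i - 1] += spectrum.counts[n - i - 1]
    return SpectrumFolded(n, out)


def _minor_count_mask(spectrum, max_minor: float) -> np.ndarray:
    return spectrum.minor_counts <= max_minor


def fraction_rare(spectrum, rare_max_count: int = RARE_MAX_COUNT_DEFAULT) -> float:
    """Fraction of segregating sites whose minor-allele count is small.

    ``rare_max_count=2`` counts singletons and doubletons, the working
    definition of "rare" used throughout this package.  Works on folded and
    unfolded spectra alike (for unfolded input the minor count of class ``i``
    is ``min(i, n-i)``).
    """
    total = spectrum.total
    if total <= 0:
        raise ValueError("cannot compute a rare fraction of an empty spectrum")
    mask = _minor_count_mask(spectrum, rare_max_count)
    return float(spectrum.counts[mask].sum() / total)


def fraction_maf_le(spectrum, maf_threshold: float = 0.01) -> float:
    """Fraction of segregating sites with minor allele frequency <= threshold."""
    if not (0 < maf_threshold <= 0.5):
        raise ValueError("maf_threshold must lie in (0, 0.5]")
    total = spectrum.total
    if total <= 0:
        raise ValueError("cannot compute a MAF fraction of an empty spectrum")
    mask = _minor_count_mask(spectrum, maf_threshold * spectrum.sample_size)
    return float(spectrum.counts[mask].sum() / total)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """P[j, i] = hypergeometric prob of j derived in m draws given i of n."""
    i = np.arange(1, n)  # derived counts in the full sample
    j = np.arange(0, m + 1)[:, None]
    return hypergeom.pmf(j, n, i[None, :], m)


def project(spectrum: SpectrumUnfolded, m: int) -> SpectrumUnfolded:
    """Expected SFS of a subsample of ``m`` chromosomes (hypergeometric).

    Classes ``j=0`` (variant lost) and ``j=m`` (fixed in the subsample) are
    dropped: the returned spectrum covers expected *segregating* sites only,
    so its total is generally smaller than the input total.  Rare fractions
    computed from it are automatically conditioned on segregating — the raw
    and segregating-renormalized forms give identical fractions.  ``m == n``
    returns the input spectrum unchanged.
    """
    n = spectrum.sample_size
    if not (2 <= m <= n):
        raise ValueError(f"subsample size m={m} must satisfy 2 <= m <= n={n}")
    if m == n:
        return SpectrumUnfolded(n, spectrum.counts.copy())
    P = _projection_matrix(n, m)
    expected = P @ spectrum.counts
    return SpectrumUnfolded(m, expected[1:m])


def projection_masses(spectrum: SpectrumUnfolded, m: int) -> dict:
    """Expected mass lost (j=0) and fixed (j=m) when projecting to ``m``."""
    n = spectrum.sample_size
    if not (2 <= m <= n):
        raise ValueError(f"subsample size m={m} must satisfy 2 <= m <= n={n}")
    P = _projection_matrix(n, m)
    expected = P @ spectrum.counts
    return {
        "segregating": float(expected[1:m].sum()),
        "lost": float(expected[0]),
        "fixed": float(expected[m]),
    }


def projected_rare_fraction(spectrum: SpectrumUnfolded, m: int,
                            rare_max_count: int = RARE_MAX_COUNT_DEFAULT) -> float:
    """Rare fraction after projection to ``m``, without the full matrix.

    Equivalent to ``fraction_rare(project(spectrum, m))`` but evaluates the
    hypergeometric pmf only at the lost/fixed classes and the rare classes at
    both spectrum ends — O(n) per subsample size, usable at large ``n``.
    """
    n = spectrum.sample_size
    if not (2 <= m <= n):
        raise ValueError(f"subsample size m={m} must satisfy 2 <= m <= n={n}")
    i = np.arange(1, n)
    c = spectrum.counts
    lost = hypergeom.pmf(0, n, i, m) + hypergeom.pmf(m, n, i, m)
    segregating = float(np.sum(c * (1.0 - lost)))
    if segregating <= 0:
        raise ValueError("no segregating mass after projection")
    rare_js = [j for j in range(1, rare_max_count + 1) if j < m]
    rare_js += [m - j for j in range(1, rare_max_count + 1) if 0 < m - j < m]
    rare = sum(float(np.sum(c * hypergeom.pmf(j, n, i, m))) for j in set(rare_js))
    return rare / segregating


def sharing_by_count(sites: TwoPopSiteCounts, bins=None) -> pd.DataFrame:
    """Cross-population sharing of polymorphisms, binned by combined count.

    For each (log-spaced by default) bin of the combined minor-allele count,
    returns the fraction of sites observed polymorphic in *both*
    subpopulations.  Empty bins are reported with ``sharing = NaN`` rather
    than zero.
    """
    combined = sites.combined
    if bins is None:
        hi = combined.max()
        bins = np.unique(np.round(np.geomspace(1, max(hi, 2), 12)).astype(int))
        bins = np.append(bins, hi + 1)
    bins = np.asarray(bins)
    shared = (sites.count_a > 0) & (sites.count_b > 0)
    idx = np.digitize(combined, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        sel = idx == b
        nsites = int(sel.sum())
        rows.append(
            {
                "bin_lo": bins[b],
                "bin_hi": bins[b + 1],
                "n_sites": nsites,
                "sharing": float(shared[sel].mean()) if nsites else np.nan,
            }
        )
    return pd.DataFrame(rows)


def stratified_rare_fraction(
    sites: pd.DataFrame,
    covariate: str,
    *,
    n_bins: int = 8,
    categorical: bool | None = None,
    rare_max_count: int = RARE_MAX_COUNT_DEFAULT,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rare fraction per covariate stratum, with percentile-bootstrap 95% CIs.

    ``sites`` needs a ``minor_count`` column and the covariate column.
    Continuous covariates are standardized by their mean over all input sites
    and then binned on a log scale (mirroring how recombination-rate and
    chromatin analyses are standardized to a genomewide mean); categorical
    covariates (or ``categorical=True``) are grouped as-is.  Strata with fewer
    than 2 sites get an undefined CI, flagged via ``ci_defined``.
    """
    rng = np.random.default_rng(seed)
    rare = (sites["minor_count"].to_numpy() <= rare_max_count).astype(float)
    cov = sites[covariate]
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(cov)
    if categorical:
        labels = cov.astype(str).to_numpy()
        strata = pd.unique(labels)
    else:
        x = cov.to_numpy(dtype=float)
        if np.any(x <= 0):
            raise ValueError("continuous covariates must be positive for log binning")
        x = x / x.mean()  # standardize to the mean over all input sites
        edges = np.geomspace(x.min(), x.max() * (1 + 1e-12), n_bins + 1)
        bin_idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
        labels = np.array([f"[{edges[b]:.3g},{edges[b + 1]:.3g})" for b in bin_idx])
        strata = np.array([f"[{edges[b]:.3g},{edges[b + 1]:.3g})" for b in range(n_bins)])
    rows = []
    for s in strata:
        sel = labels == s
        k = int(sel.sum())
        if k == 0:
            rows.append({"stratum": s, "n_sites": 0, "rare_fraction": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "ci_defined": False})
            continue
        vals = rare[sel]
        est = float(vals.mean())
        if k < 2:
            rows.append({"stratum": s, "n_sites": k, "rare_fraction": est,
                         "ci_lo": np.nan, "ci_hi": np.nan, "ci_defined": False})
            continue
        boots = rng.integers(0, k, size=(n_bootstrap, k))
        bmeans = vals[boots].mean(axis=1)
        lo, hi = np.percentile(bmeans, [2.5, 97.5])
        rows.append({"stratum": s, "n_sites": k, "rare_fraction": est,
                     "ci_lo": float(lo), "ci_hi": float(hi), "ci_defined": True})
    return pd.DataFrame(rows)


# --- serialization -----------------------------------------------------------

def write_spectrum_tsv(spectrum, path_or_buf) -> None:
    """Write a spectrum as 2-column TSV with a metadata header line."""
    folded = isinstance(spectrum, SpectrumFolded)
    header = f"# sample_size={spectrum.sample_size}\tfolded={int(folded)}\n"
    body = pd.DataFrame(
        {"allele_count": spectrum.minor_counts if folded else np.arange(1, spectrum.sample_size),
         "n_sites": spectrum.counts}
    ).to_csv(sep="\t", index=False)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header + body)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(header + body)


def read_spectrum_tsv(path_or_buf):
    """Read a spectrum written by :func:`write_spectrum_tsv`."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    first, rest = text.split("\n", 1)
    if not first.startswith("#"):
        raise ValueError("missing spectrum metadata header line")
    meta = dict(tok.split("=") for tok in first.lstrip("# ").split("\t"))
    n = int(meta["sample_size"])
    folded = bool(int(meta["folded"]))
    df = pd.read_csv(io.StringIO(rest), sep="\t")
    cls = SpectrumFolded if folded else SpectrumUnfolded
    counts = np.zeros(n // 2 if folded else n - 1)
    counts[df["allele_count"].to_numpy() - 1] = df["n_sites"].to_numpy()
    return cls(n, counts)
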