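"""The phylogenetically-conditioned SFS (cSFS) and mutation-type annotation.

A human SNP, together with the orthologous reference alleles of nonhuman
primates, falls into one of a small set of divergence categories:

* ``human_private`` — every observed primate ortholog carries the human
  major allele;
* ``substituted_<species>`` — exactly one primate carries the human *minor*
  allele while all the others (baboon included) carry the major allele,
  evidence that the same mutation occurred and fixed independently on that
  primate's lineage;
* ``other`` — anything else (several minor-carriers, third alleles, ...).

Baboon participates only in the ascertainment: there is no
substituted-baboon category.  The cSFS is the human SFS restricted to one
such category; comparing cSFS across substituted species of increasing
divergence is the core descriptive analysis this package reproduces, and
mutation-type composition (especially the CpG-transition fraction) is its
principal explanatory covariate.

Site tables are pandas DataFrames in a documented TSV dialect (see
``SITE_TABLE_COLUMNS``); ``'.'`` marks a missing primate allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .spectra import SpectrumFolded, fraction_rare

__all__ = [
    "SPECIES",
    "ASCERTAINMENT_SPECIES",
    "MONO_TYPES",
    "CPG_TYPE",
    "classify_categories",
    "closest_minor_carrier",
    "assign_mutation_types",
    "build_csfs",
    "cpg_fraction_by_category",
    "strand_partition",
    "rate_vs_rare_regression",
    "read_site_table",
    "write_site_table",
    "read_vcf_sites",
]

# ordered by relatedness to human, closest first
SPECIES = ("chimpanzee", "gorilla", "orangutan", "gibbon", "macaque")
ASCERTAINMENT_SPECIES = SPECIES + ("baboon",)

MONO_TYPES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")
CPG_TYPE = "CpG>TpG"

SITE_TABLE_COLUMNS = [
    "chrom", "pos", "major", "minor", "minor_count", "total",
    "flank_up", "flank_down", "strand", "func_class",
    *ASCERTAINMENT_SPECIES,
    "recomb_rate", "chromatin",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SiteRecord:
    """One human SNP with its primate orthologs and annotations."""

    chrom: str
    pos: int
    major: str
    minor: str
    minor_count: int
    total: int
    flank_up: str = ""
    flank_down: str = ""
    strand: str = "."
    func_class: str = "intronic"
    primate_alleles: dict | None = None  # species -> base or None
    recomb_rate: float = np.nan
    chromatin: str = "."

    def __post_init__(self):
        for allele in (self.major, self.minor):
            if allele not in "ACGT" or len(allele) != 1:
                raise ValueError(f"invalid allele {allele!r}")
        if self.major == self.minor:
            raise ValueError("major and minor alleles must differ")
        if not (0 < self.minor_count <= self.total / 2):
            raise ValueError("minor count must satisfy 0 < count <= total/2")
        if len(self.flank_up) > 30 or len(self.flank_down) > 30:
            raise ValueError("flanks are limited to 30 bases")


def _primate_frame(df: pd.DataFrame) -> pd.DataFrame:
    sub = df.loc[:, list(ASCERTAINMENT_SPECIES)].astype("string")
    return sub.where(~sub.isin([".", "N", ""]) & sub.notna())


def classify_categories(df: pd.DataFrame, strict: bool = True) -> pd.Series:
    """Divergence category of every site in the table.

    ``human_private`` requires every *observed* primate allele to equal the
    human major; ``substituted_<s>`` requires species ``s`` to carry the
    human minor and, in ``strict`` mode (the default, matching the
    baboon-based ascertainment), *all six* primates to be nonmissing with the
    other five carrying the major.  ``strict=False`` ignores missing species
    when testing the substituted pattern — a lenient, non-faithful mode.
    Sites with no primate data at all raise.
    """
    prim = _primate_frame(df)
    n_obs = prim.notna().sum(axis=1)
    if (n_obs == 0).any():
        bad = df.index[n_obs == 0][:5].tolist()
        raise ValueError(f"sites with all primate alleles missing, e.g. rows {bad}")
    major = df["major"].astype(str)
    minor = df["minor"].astype(str)
    eq_major = prim.eq(major, axis=0)
    eq_minor = prim.eq(minor, axis=0)
    all_obs_major = (eq_major | prim.isna()).all(axis=1)
    out = pd.Series("other", index=df.index, dtype=object)
    out[all_obs_major] = "human_private"
    n_minor = eq_minor.sum(axis=1)
    for s in SPECIES:
        others = [sp for sp in ASCERTAINMENT_SPECIES if sp != s]
        cond = eq_minor[s].fillna(False) & (n_minor == 1)
        if strict:
            cond &= eq_major[others].all(axis=1).fillna(False) & prim.notna().all(axis=1)
        else:
            cond &= (eq_major[others] | prim[others].isna()).all(axis=1)
        out[cond] = f"substituted_{s}"
    return out


def closest_minor_carrier(df: pd.DataFrame) -> pd.Series:
    """Nearest primate (chimp < gorilla < ... < macaque) carrying the minor.

    The alternative conditioning mode: unlike the substituted-species
    pattern it does not require the other primates to match the major.
    Returns ``None`` where no primate carries the human minor allele.
    """
    prim = _primate_frame(df)
    minor = df["minor"].astype(str)
    out = pd.Series([None] * len(df), index=df.index, dtype=object)
    for s in reversed(SPECIES):  # nearest species assigned last wins
        hit = prim[s].eq(minor).fillna(False)
        out[hit] = s
    return out


def _collapse(major, minor, up, down):
    """Canonical strand representation: central major allele in {A, C}."""
    if major in "AC":
        return major, minor, up, down
    return (major.translate(_COMP), minor.translate(_COMP),
            _revcomp(down), _revcomp(up))


def _one_type(major, minor, up, down, level):
    if level == "mono":
        maj, mnr, *_ = _collapse(major, minor, up, down)
        return f"{maj}>{mnr}"
    if level == "cpg_ti":
        nxt = down[:1]
        prv = up[-1:]
        if (major == "C" and minor == "T") or (major == "G" and minor == "A"):
            ctx = nxt if major == "C" else prv
            if ctx in ("", "N"):
                return None  # context undeterminable
            if (major == "C" and nxt == "G") or (major == "G" and prv == "C"):
                return CPG_TYPE
        maj, mnr, *_ = _collapse(major, minor, up, down)
        return f"{maj}>{mnr}"
    if level == "trimer":
        maj, mnr, u, d = _collapse(major, minor, up, down)
        prv, nxt = u[-1:], d[:1]
        if prv in ("", "N") or nxt in ("", "N"):
            return None
        return f"{prv}{maj}{nxt}>{prv}{mnr}{nxt}"
    raise ValueError("level must be 'mono', 'cpg_ti' or 'trimer'")


def assign_mutation_types(df: pd.DataFrame, level: str = "cpg_ti") -> pd.Series:
    """Strand-collapsed mutation type of the major->minor change per site.

    Levels: ``mono`` (6 types, e.g. ``A>C`` covers A->C and T->G),
    ``cpg_ti`` (mono plus a ``CpG>TpG`` override for C->T transitions in CpG
    context, judged from the human reference flank), ``trimer`` (3-mer
    context types).  Sites whose needed flank base is ambiguous get ``None``.
    """
    return pd.Series(
        [
            _one_type(maj, mnr, up if isinstance(up, str) else "",
                      dn if isinstance(dn, str) else "", level)
            for maj, mnr, up, dn in zip(df["major"], df["minor"],
                                        df["flank_up"], df["flank_down"])
        ],
        index=df.index, dtype=object,
    )


def _category_order():
    return ["human_private"] + [f"substituted_{s}" for s in SPECIES] + ["other"]


def build_csfs(
    df: pd.DataFrame,
    conditioning: str = "substituted",
    *,
    functional_classes=None,
    rare_max_count: int = 2,
    min_chromosomes: int | None = None,
    strict: bool = True,
):
    """Per-category folded spectra, rare fractions and CDF tables.

    ``conditioning="substituted"`` uses the exactly-one-substituted-species
    categories; ``"closest"`` uses the nearest minor-carrying primate.  The
    optional ``min_chromosomes`` reproduces the sample-size filter used on
    real exome data (100,000 chromosomes).  All sites must share one total
    chromosome count so that counts live in a single spectrum.

    Returns ``(spectra, summary)``: a dict ``(category, func_class) ->
    SpectrumFolded`` and a tidy summary DataFrame with binomial-CI rare
    fractions and the cumulative distribution over minor-count classes.
    Empty categories appear with zero sites rather than being dropped.
    """
    work = df
    if min_chromosomes is not None:
        work = work[work["total"] >= min_chromosomes]
    totals = work["total"].unique()
    if len(totals) != 1:
        raise ValueError(
            "sites have differing total chromosome counts "
            f"({sorted(totals)[:4]}...); project or subsample to a common n first")
    n = int(totals[0])
    if conditioning == "substituted":
        cats = classify_categories(work, strict=strict)
        order = _category_order()
    elif conditioning == "closest":
        carrier = closest_minor_carrier(work)
        cats = carrier.map(lambda s: f"closest_{s}" if s else "human_private")
        order = ["human_private"] + [f"closest_{s}" for s in SPECIES]
    else:
        raise ValueError("conditioning must be 'substituted' or 'closest'")
    if functional_classes is None:
        functional_classes = sorted(work["func_class"].unique())
    half = n // 2
    spectra = {}
    rows = []
    for cat in order:
        for fc in functional_classes:
            sel = work[(cats == cat) & (work["func_class"] == fc)]
            counts = np.bincount(sel["minor_count"], minlength=half + 1)[1:half + 1]
            spec = SpectrumFolded(n, counts.astype(float))
            spectra[(cat, fc)] = spec
            k = int(counts.sum())
            n_rare = int(counts[:rare_max_count].sum())
            if k > 0:
                rf = n_rare / k
                lo, hi = proportion_confint(n_rare, k, method="wilson")
                cdf = np.cumsum(counts) / k
            else:
                rf, lo, hi, cdf = np.nan, np.nan, np.nan, np.full(half, np.nan)
            rows.append({"category": cat, "func_class": fc, "n_sites": k,
                         "rare_fraction": rf, "ci_lo": lo, "ci_hi": hi,
                         "cdf": cdf})
    return spectra, pd.DataFrame(rows)


def cpg_fraction_by_category(df: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Proportion of CpG->TpG sites per divergence category, with 95% CI.

    The CpG-transition fraction rises for substituted species closer to
    human; because CpG transitions are depleted of rare variants, it is a
    strong predictor of cSFS skew.
    """
    cats = classify_categories(df, strict=strict)
    types = assign_mutation_types(df, level="cpg_ti")
    rows = []
    for cat in _category_order():
        sel = types[cats == cat].dropna()
        k = len(sel)
        ncpg = int((sel == CPG_TYPE).sum())
        if k:
            frac = ncpg / k
            lo, hi = proportion_confint(ncpg, k, method="wilson")
        else:
            frac = lo = hi = np.nan
        rows.append({"category": cat, "n_sites": k, "cpg_fraction": frac,
                     "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def strand_partition(df: pd.DataFrame):
    """Re-express mutation types relative to the coding strand.

    Transcription-coupled repair makes some types (A->G, A->T) more mutable
    on the template strand; detecting the SFS signature requires keeping the
    two orientations apart instead of strand-collapsing.  The change is
    mapped onto the coding strand of the host gene, then labelled by its
    canonical form plus whether that form sits on the coding or template
    strand.  CpG-transition sites and strandless records are excluded; the
    number excluded is reported.

    Returns ``(annotated_frame, excluded_counts)`` where the frame carries
    ``strand_type`` ("A>G" etc.) and ``strand_class`` ("coding"/"template").
    """
    types = assign_mutation_types(df, level="cpg_ti")
    stranded = df["strand"].isin(["+", "-"])
    keep = stranded & (types != CPG_TYPE) & types.notna()
    excluded = {"strandless": int((~stranded).sum()),
                "cpg_or_ambiguous": int((stranded & ~keep).sum())}
    sub = df[keep].copy()
    maj = sub["major"].astype(str)
    mnr = sub["minor"].astype(str)
    minus = sub["strand"] == "-"
    cmaj = maj.where(~minus, maj.str.translate(_COMP))
    cmnr = mnr.where(~minus, mnr.str.translate(_COMP))
    canonical = cmaj.isin(list("AC"))
    t_maj = cmaj.where(canonical, cmaj.str.translate(_COMP))
    t_mnr = cmnr.where(canonical, cmnr.str.translate(_COMP))
    sub["strand_type"] = t_maj + ">" + t_mnr
    sub["strand_class"] = np.where(canonical, "coding", "template")
    return sub, excluded


def rate_vs_rare_regression(rare_fractions, mean_rates, weights=None):
    """Weighted least squares of per-type rare fraction on mean mutation rate.

    Weights default to equal (then this is OLS); pass per-type site counts to
    reproduce the count-weighted regression.  Returns (slope, se, p_value).
    """
    import statsmodels.api as sm

    y = np.asarray(rare_fractions, dtype=float)
    x = np.asarray(mean_rates, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 mutation types")
    if x.max() == x.min():
        raise ValueError("mean rates are all equal; slope undefined")
    X = sm.add_constant(x)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    res = sm.WLS(y, X, weights=w).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


# --- I/O ---------------------------------------------------------------------

def write_site_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in SITE_TABLE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep=".")


def read_site_table(path, min_chromosomes: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in SITE_TABLE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"site table lacks required columns {missing}")
    df["pos"] = df["pos"].astype(int)
    df["minor_count"] = df["minor_count"].astype(int)
    df["total"] = df["total"].astype(int)
    if min_chromosomes is not None:
        df = df[df["total"] >= min_chromosomes].reset_index(drop=True)
    return df


def read_vcf_sites(vcf_path, sidecar_path) -> pd.DataFrame:
    """Build a site table from a VCF (AC/AN) plus an annotation sidecar TSV.

    The VCF supplies alleles and allele counts (biallelic records only); the
    sidecar, keyed on (chrom, pos), supplies flanks, strand, functional
    class, primate alleles and covariates.  Coordinates are 1-based.
    """
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(vcf_path)):
        if len(v.ALT) != 1:
            continue  # multi-allelic: excluded upstream
        an = v.INFO.get("AN")
        ac = v.INFO.get("AC")
        if an is None or ac is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} lacks AC/AN")
        ac = int(ac if np.isscalar(ac) else ac[0])
        an = int(an)
        ref, alt = v.REF, v.ALT[0]
        if ac <= an - ac:
            major, minor, mc = ref, alt, ac
        else:
            major, minor, mc = alt, ref, an - ac
        rows.append({"chrom": v.CHROM, "pos": v.POS, "major": major,
                     "minor": minor, "minor_count": mc, "total": an})
    base = pd.DataFrame(rows)
    side = pd.read_csv(sidecar_path, sep="\t", dtype={"chrom": str},
                       keep_default_na=False, na_values=[""])
    return base.merge(side, on=["chrom", "pos"], how="inner")
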