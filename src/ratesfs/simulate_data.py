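"""Synthetic exome-like site tables with full ground truth.

Real large-cohort site tables (tens of thousands of exomes joined with
primate reference alleles) cannot be bundled, so every analysis stage in
this package is exercised against tables drawn from a generative model that
mirrors their statistical structure:

category  ->  mutation type  ->  per-site rate M ~ g(M; mu_type, sigma)
          ->  rare/common and minor-allele count  ->  primate alleles,
          flanks, strand, functional class and covariates,

with every latent variable recorded in a manifest.  Defaults are desk-scale
(50,000 sites, 2,000 chromosomes); the category proportions follow the
human-private-dominated composition of large exome data with a substituted
species gradient from chimpanzee (fewest) to gibbon (most), and the
per-category CpG-transition fractions decline with divergence from human —
the composition signal the cSFS analyses are designed to detect.  Setting
``rate_grid`` makes the rare/common draw finite-sites aware (rare
probability falls with M); otherwise the infinite-sites expected spectrum
of the configured demography is used for all sites.

Sites are independent: linkage disequilibrium is deliberately not emulated,
matching the site-wise nature of every analysis here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csfs import CPG_TYPE, MONO_TYPES, SPECIES
from .demography import DemographicModel, preset_model, expected_sfs_infinite
from .rate_mixture import (
    LognormalRateMixture,
    sample_rates,
    sample_rates_conditional,
)
from .spectra import TwoPopSiteCounts, fold

__all__ = ["GeneratorConfig", "generate_sites", "split_two_populations", "write_vcf"]

_COMP = str.maketrans("ACGT", "TGCA")
_BASES = np.array(list("ACGT"))

# canonical (pyrimidine/A-centred) representation of each mono type
_TYPE_ALLELES = {t: (t[0], t[2]) for t in MONO_TYPES}
_TYPE_ALLELES[CPG_TYPE] = ("C", "T")


def _default_category_proportions():
    return {
        "human_private": 0.90,
        "substituted_chimpanzee": 0.012,
        "substituted_gorilla": 0.016,
        "substituted_orangutan": 0.020,
        "substituted_gibbon": 0.028,
        "substituted_macaque": 0.024,
    }


def _default_cpg_fractions():
    return {
        "human_private": 0.08,
        "substituted_chimpanzee": 0.30,
        "substituted_gorilla": 0.25,
        "substituted_orangutan": 0.20,
        "substituted_gibbon": 0.15,
        "substituted_macaque": 0.10,
    }


def _default_mono_mix():
    return {"C>T": 0.38, "A>G": 0.26, "C>A": 0.10, "C>G": 0.09,
            "A>C": 0.08, "A>T": 0.09}


def _default_mean_rates():
    # per bp per generation per haploid; de-novo-study-motivated orderings:
    # CpG transitions an order of magnitude above other types, transitions
    # above transversions
    return {CPG_TYPE: 1.2e-7, "C>T": 9e-9, "A>G": 8e-9, "C>A": 3e-9,
            "C>G": 3.5e-9, "A>C": 2.5e-9, "A>T": 2.5e-9}


@dataclass
class GeneratorConfig:
    """Tunable knobs of the synthetic site-table generator (seed mandatory)."""

    seed: int
    n_sites: int = 50_000
    n_chromosomes: int = 2_000
    category_proportions: dict = field(default_factory=_default_category_proportions)
    cpg_fraction: dict = field(default_factory=_default_cpg_fractions)
    mono_mix: dict = field(default_factory=_default_mono_mix)
    mean_rates: dict = field(default_factory=_default_mean_rates)
    sigma: float = 0.57
    model: DemographicModel | None = None  # default: modified_nelson_recent
    func_class_mix: dict = field(default_factory=lambda: {
        "intronic": 0.5, "synonymous": 0.2, "nonsynonymous": 0.3})
    strand_mix: dict = field(default_factory=lambda: {"+": 0.45, "-": 0.45, ".": 0.10})
    flank_length: int = 5
    # optional injected effects, all zero/off by default
    ns_species_rare_shift: dict = field(default_factory=dict)  # category -> log-odds
    syn_species_rare_shift: dict = field(default_factory=dict)
    template_rare_shift: dict = field(default_factory=dict)    # mono type -> prob delta
    chromatin_states: tuple = ("Tss", "Enh", "Tx", "Het", "Quies")
    sfs_sim_reps: int = 200

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("category_proportions", "cpg_fraction", "mono_mix",
                     "func_class_mix", "strand_mix"):
            d = getattr(self, name)
            tot = sum(d.values())
            if name != "cpg_fraction" and not np.isclose(tot, 1.0, atol=1e-6):
                raise ValueError(f"{name} proportions must sum to 1 (got {tot})")
        if self.model is None:
            self.model = preset_model("modified_nelson_recent")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _count_class_tables(config, rng):
    """Folded expected spectrum of the configured demography, split into
    rare (minor count <= 2) and common conditional class distributions."""
    n = config.n_chromosomes
    method = "analytic" if n <= 512 else "simulation"
    sfs = expected_sfs_infinite(
        config.model, n, method=method,
        reps=config.sfs_sim_reps, seed=int(rng.integers(1, 2**31 - 1)))
    folded = fold(sfs).counts
    rare_p = folded[:2] / folded[:2].sum()
    common_p = folded[2:] / folded[2:].sum()
    inf_rare_fraction = float(folded[:2].sum() / folded.sum())
    return rare_p, common_p, inf_rare_fraction


def generate_sites(config: GeneratorConfig, rate_grid=None):
    """Generate a site table plus its ground-truth manifest.

    Returns ``(table, manifest)``: the table follows the documented TSV
    dialect (classifiable by :mod:`ratesfs.csfs` with 100% agreement by
    construction); the manifest records category, mutation type, site rate,
    rare probability and strand orientation per site.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_sites
    n = config.n_chromosomes
    L = config.flank_length

    cats = np.array(list(config.category_proportions))
    cat_idx = rng.choice(len(cats), size=n_sites,
                         p=np.array(list(config.category_proportions.values())))
    category = cats[cat_idx]

    # mutation type: CpG transition with the category's fraction, otherwise
    # a mono type from the shared composition
    mtype = np.empty(n_sites, dtype=object)
    cpg_p = np.array([config.cpg_fraction[c] for c in cats])[cat_idx]
    is_cpg = rng.random(n_sites) < cpg_p
    mtype[is_cpg] = CPG_TYPE
    mono_names = np.array(list(config.mono_mix))
    mono_draw = rng.choice(len(mono_names), size=n_sites,
                           p=np.array(list(config.mono_mix.values())))
    mtype[~is_cpg] = mono_names[mono_draw[~is_cpg]]

    # per-site rates: every generated row is a polymorphic site, so with a
    # rate grid the rates follow the polymorphism-conditioned f(M|S=1; mu)
    # rather than the unconditional g — polymorphic sites are rate-enriched
    M = np.empty(n_sites)
    for t, mu in config.mean_rates.items():
        sel = mtype == t
        if sel.any():
            mix_t = LognormalRateMixture(mu, config.sigma)
            if rate_grid is None:
                M[sel] = sample_rates(mix_t, int(sel.sum()), rng)
            else:
                M[sel] = sample_rates_conditional(mix_t, rate_grid,
                                                  int(sel.sum()), rng)

    # rare probability per site
    rare_p_classes, common_p_classes, inf_rare = _count_class_tables(config, rng)
    if rate_grid is not None:
        p_rare = np.interp(np.log10(M), np.log10(rate_grid.rates),
                           rate_grid.e_rare)
    else:
        p_rare = np.full(n_sites, inf_rare)

    # functional class, strand, orientation
    func = rng.choice(np.array(list(config.func_class_mix)), size=n_sites,
                      p=np.array(list(config.func_class_mix.values())))
    strand = rng.choice(np.array(list(config.strand_mix)), size=n_sites,
                        p=np.array(list(config.strand_mix.values())))
    flipped = rng.random(n_sites) < 0.5  # purine-representation orientation

    # injected per-category selection-like effects (log-odds shifts)
    for shifts, fclass in ((config.ns_species_rare_shift, "nonsynonymous"),
                           (config.syn_species_rare_shift, "synonymous")):
        if shifts:
            shift = np.array([shifts.get(c, 0.0) for c in category])
            hit = func == fclass
            p_rare = np.where(hit, _sigmoid(_logit(np.clip(p_rare, 1e-9, 1 - 1e-9))
                                            + shift), p_rare)

    # injected template-strand rare-fraction gap for selected types:
    # the canonical-form change sits on the template strand when the
    # reference (collapsed) representation and the gene strand disagree
    strand_class = np.where(strand == ".", ".",
                            np.where((strand == "-") ^ flipped, "template", "coding"))
    if config.template_rare_shift:
        delta = np.array([config.template_rare_shift.get(t, 0.0) for t in mtype])
        p_rare = np.clip(p_rare + np.where(strand_class == "template", delta, 0.0),
                         1e-6, 1 - 1e-6)

    rare = rng.random(n_sites) < p_rare
    minor_count = np.empty(n_sites, dtype=int)
    n_rare = int(rare.sum())
    minor_count[rare] = rng.choice([1, 2], size=n_rare, p=rare_p_classes)
    minor_count[~rare] = rng.choice(np.arange(3, n // 2 + 1),
                                    size=n_sites - n_rare, p=common_p_classes)

    # sequence context in canonical orientation, then optional flip
    up = rng.choice(_BASES, size=(n_sites, L))
    down = rng.choice(_BASES, size=(n_sites, L))
    # constraints on the base adjacent to the focal site
    is_ct = mtype == "C>T"
    down[is_cpg, 0] = "G"
    clash = is_ct & (down[:, 0] == "G")
    down[clash, 0] = rng.choice(np.array(list("ACT")), size=int(clash.sum()))

    major = np.array([_TYPE_ALLELES[t][0] for t in mtype])
    minor = np.array([_TYPE_ALLELES[t][1] for t in mtype])

    up_s = np.empty(n_sites, dtype=object)
    down_s = np.empty(n_sites, dtype=object)
    for i in range(n_sites):
        u = "".join(up[i])
        d = "".join(down[i])
        if flipped[i]:
            major[i] = major[i].translate(_COMP)
            minor[i] = minor[i].translate(_COMP)
            u, d = d.translate(_COMP)[::-1], u.translate(_COMP)[::-1]
        up_s[i] = u
        down_s[i] = d

    table = pd.DataFrame({
        "chrom": "chrS", "pos": np.arange(1, n_sites + 1) * 100,
        "major": major, "minor": minor, "minor_count": minor_count,
        "total": n, "flank_up": up_s, "flank_down": down_s,
        "strand": strand, "func_class": func,
    })
    for sp in SPECIES:
        table[sp] = np.where(category == f"substituted_{sp}", minor, major)
    table["baboon"] = major
    table["recomb_rate"] = rng.lognormal(mean=0.0, sigma=0.8, size=n_sites)
    table["chromatin"] = rng.choice(np.array(config.chromatin_states), size=n_sites)

    manifest = pd.DataFrame({
        "category": category, "mutation_type": mtype, "site_rate": M,
        "p_rare": p_rare, "rare": rare, "flipped_orientation": flipped,
        "strand_class": strand_class, "func_class": func,
        "minor_count": minor_count,
    })
    return table, manifest


def split_two_populations(table: pd.DataFrame, proportion: float,
                          seed: int, *, recurrent_flags=None) -> TwoPopSiteCounts:
    """Allocate each site's minor copies between two subpopulations.

    Default allocation is hypergeometric: the ``total`` chromosomes are split
    into two panels of sizes ``proportion`` / ``1-proportion`` and the minor
    copies sampled without replacement — what subsampling one panmictic pool
    would produce.  Sites flagged in ``recurrent_flags`` instead model two
    independent mutational origins: one copy is planted on each side before
    the rest are allocated, the sharing signature recurrent mutation leaves
    at hypermutable sites.
    """
    if not (0 < proportion < 1):
        raise ValueError("proportion must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    counts = table["minor_count"].to_numpy(dtype=int)
    totals = table["total"].to_numpy(dtype=int)
    if np.any(counts < 1):
        raise ValueError("all sites must carry at least one minor copy")
    n_a = np.round(proportion * totals).astype(int)
    if recurrent_flags is None:
        recurrent_flags = np.zeros(len(counts), dtype=bool)
    recurrent_flags = np.asarray(recurrent_flags, dtype=bool) & (counts >= 2)
    base = np.where(recurrent_flags, 1, 0)
    avail = counts - 2 * base
    a = base + rng.hypergeometric(np.maximum(n_a - base, 0),
                                  np.maximum(totals - n_a - base, 0), avail)
    b = counts - a
    return TwoPopSiteCounts(count_a=a, count_b=b,
                            total_a=int(n_a[0]), total_b=int(totals[0] - n_a[0]))


def write_vcf(table: pd.DataFrame, path) -> None:
    """Emit the human polymorphism side of a site table as a plain-text VCF.

    AC/AN carry the minor-allele count and total; REF is the major allele.
    Annotations and primate alleles travel in the TSV sidecar instead.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.major}\t{row.minor}\t.\t.\t"
                     f"AC={row.minor_count};AN={row.total}\n")
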