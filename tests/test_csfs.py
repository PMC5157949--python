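"""Divergence-category classification, mutation typing and cSFS summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import pearsonr

import ratesfs as r
from ratesfs.csfs import (
    ASCERTAINMENT_SPECIES,
    CPG_TYPE,
    SPECIES,
    assign_mutation_types,
    build_csfs,
    classify_categories,
    closest_minor_carrier,
    cpg_fraction_by_category,
    rate_vs_rare_regression,
    read_site_table,
    read_vcf_sites,
    strand_partition,
    write_site_table,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _record(major="A", minor="G", primates=None, **kw):
    row = {
        "chrom": "1", "pos": kw.pop("pos", 100), "major": major, "minor": minor,
        "minor_count": kw.pop("minor_count", 1), "total": kw.pop("total", 1000),
        "flank_up": kw.pop("flank_up", "TTTTT"),
        "flank_down": kw.pop("flank_down", "TTTTT"),
        "strand": kw.pop("strand", "+"), "func_class": kw.pop("func_class", "intronic"),
        "recomb_rate": 1.0, "chromatin": "Tx",
    }
    primates = primates or {}
    for sp in ASCERTAINMENT_SPECIES:
        row[sp] = primates.get(sp, major)
    row.update(kw)
    return row


def _frame(rows):
    return pd.DataFrame(rows)


class TestClassification:
    def test_hand_fixture_all_categories(self):
        rows = [
            _record(pos=1),  # all primates major -> human_private
            _record(pos=2, primates={"orangutan": "G"}),
            _record(pos=3, primates={"chimpanzee": "G"}),
            _record(pos=4, primates={"gibbon": "G"}),
            _record(pos=5, primates={"chimpanzee": "G", "gorilla": "G"}),  # two carriers
            _record(pos=6, primates={"macaque": "C"}),  # third allele
            _record(pos=7, primates={"baboon": "G"}),  # baboon never substituted
        ]
        cats = classify_categories(_frame(rows))
        assert cats.tolist() == [
            "human_private", "substituted_orangutan", "substituted_chimpanzee",
            "substituted_gibbon", "other", "other", "other",
        ]

    def test_strict_vs_lenient_on_missing(self):
        df = _frame([_record(primates={"orangutan": "G", "baboon": "."})])
        assert classify_categories(df, strict=True).iloc[0] == "other"
        assert classify_categories(df, strict=False).iloc[0] == "substituted_orangutan"
        # missing species still leave human_private assignable
        df2 = _frame([_record(primates={"baboon": "."})])
        assert classify_categories(df2, strict=True).iloc[0] == "human_private"

    def test_all_missing_raises(self):
        df = _frame([_record(primates={sp: "." for sp in ASCERTAINMENT_SPECIES})])
        with pytest.raises(ValueError):
            classify_categories(df)

    def test_closest_minor_carrier(self):
        df = _frame([
            _record(primates={"gorilla": "G", "macaque": "G"}),
            _record(),
            _record(primates={"chimpanzee": "G", "gorilla": "G"}),
        ])
        got = closest_minor_carrier(df)
        assert got.tolist() == ["gorilla", None, "chimpanzee"]

    def test_closest_agrees_on_substituted_sites(self, synth_table):
        table, manifest = synth_table
        cats = classify_categories(table)
        closest = closest_minor_carrier(table)
        sub = cats.str.startswith("substituted_")
        assert (closest[sub] == cats[sub].str.replace("substituted_", "")).all()

    @given(st.lists(
        st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT"),
                  st.lists(st.sampled_from(["A", "C", "G", "T", "."]),
                           min_size=6, max_size=6)),
        min_size=1, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_partition_property(self, raw):
        rows = []
        for maj, mnr, prim in raw:
            if maj == mnr or all(p == "." for p in prim):
                continue
            rows.append(_record(maj, mnr,
                                primates=dict(zip(ASCERTAINMENT_SPECIES, prim))))
        if not rows:
            return
        cats = classify_categories(_frame(rows))
        valid = {"human_private", "other"} | {f"substituted_{s}" for s in SPECIES}
        assert set(cats) <= valid  # every record in exactly one category


class TestMutationTypes:
    @pytest.mark.parametrize(
        "major,minor,up,down,level,expected",
        [
            ("C", "T", "AAAAA", "GAAAA", "cpg_ti", CPG_TYPE),
            ("G", "A", "AAAAC", "AAAAA", "cpg_ti", CPG_TYPE),
            ("C", "T", "AAAAA", "AAAAA", "cpg_ti", "C>T"),
            ("A", "C", "AAAAA", "AAAAA", "mono", "A>C"),
            ("T", "G", "AAAAA", "AAAAA", "mono", "A>C"),  # strand collapse
            ("C", "T", "AAAAA", "GAAAA", "mono", "C>T"),  # mono ignores context
            ("A", "G", "AACCA", "TGGAA", "trimer", "AAT>AGT"),
        ],
    )
    def test_examples(self, major, minor, up, down, level, expected):
        df = _frame([_record(major, minor, flank_up=up, flank_down=down)])
        assert assign_mutation_types(df, level).iloc[0] == expected

    def test_ambiguous_flank_flagged(self):
        df = _frame([_record("C", "T", flank_down="NAAAA")])
        assert assign_mutation_types(df, "cpg_ti").iloc[0] is None
        assert assign_mutation_types(df, "trimer").iloc[0] is None

    @given(st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT"),
                     st.text(alphabet="ACGT", min_size=3, max_size=6),
                     st.text(alphabet="ACGT", min_size=3, max_size=6)))
    @settings(max_examples=80, deadline=None)
    def test_strand_involution(self, tup):
        maj, mnr, up, down = tup
        if maj == mnr:
            return
        df = _frame([_record(maj, mnr, flank_up=up, flank_down=down)])
        flipped = _frame([_record(
            maj.translate(_COMP), mnr.translate(_COMP),
            flank_up=down.translate(_COMP)[::-1],
            flank_down=up.translate(_COMP)[::-1])])
        for level in ("mono", "cpg_ti", "trimer"):
            assert (assign_mutation_types(df, level).iloc[0]
                    == assign_mutation_types(flipped, level).iloc[0])


class TestBuildCsfs:
    def test_hand_fixture_counts(self):
        rows = (
            [_record(pos=i, minor_count=1, func_class="synonymous") for i in range(4)]
            + [_record(pos=10 + i, minor_count=5, func_class="synonymous",
                       primates={"gibbon": "G"}) for i in range(3)]
            + [_record(pos=20, minor_count=2, func_class="nonsynonymous")]
        )
        spectra, summary = build_csfs(_frame(rows))
        s = summary.set_index(["category", "func_class"])
        assert s.loc[("human_private", "synonymous"), "n_sites"] == 4
        assert s.loc[("human_private", "synonymous"), "rare_fraction"] == 1.0
        assert s.loc[("substituted_gibbon", "synonymous"), "n_sites"] == 3
        assert s.loc[("substituted_gibbon", "synonymous"), "rare_fraction"] == 0.0
        # empty categories present with zero counts, not dropped
        assert s.loc[("substituted_chimpanzee", "synonymous"), "n_sites"] == 0

    def test_conservation_across_categories(self, synth_table):
        table, _ = synth_table
        spectra, _ = build_csfs(table)
        total = sum(spec.total for spec in spectra.values())
        assert total == len(table)

    def test_mixed_totals_rejected(self):
        rows = [_record(pos=1, total=1000), _record(pos=2, total=2000)]
        with pytest.raises(ValueError):
            build_csfs(_frame(rows))

    def test_min_chromosome_filter(self):
        rows = [_record(pos=1, total=200_000), _record(pos=2, total=2000)]
        _, summary = build_csfs(_frame(rows), min_chromosomes=100_000)
        assert summary["n_sites"].sum() == 1

    def test_generator_ground_truth_recovered(self, synth_table):
        # per-category rare fractions must cover the generator's single truth
        table, manifest = synth_table
        _, summary = build_csfs(table)
        truth = manifest.groupby("category")["p_rare"].mean()
        agg = (summary.groupby("category")
               .apply(lambda g: (g["rare_fraction"] * g["n_sites"]).sum()
                      / max(g["n_sites"].sum(), 1), include_groups=False))
        for cat in truth.index:
            n = summary.groupby("category")["n_sites"].sum()[cat]
            se = np.sqrt(0.25 / n)
            assert abs(agg[cat] - truth[cat]) < 4 * se


class TestCpGComposition:
    def test_gradient_recovered(self, synth_table):
        table, _ = synth_table
        out = cpg_fraction_by_category(table).set_index("category")
        cfg_fracs = {
            "human_private": 0.08, "substituted_chimpanzee": 0.30,
            "substituted_gorilla": 0.25, "substituted_orangutan": 0.20,
            "substituted_gibbon": 0.15, "substituted_macaque": 0.10,
        }
        for cat, want in cfg_fracs.items():
            assert out.loc[cat, "ci_lo"] - 0.01 <= want <= out.loc[cat, "ci_hi"] + 0.01

    def test_no_cpg_category(self):
        rows = [_record("A", "G", pos=i) for i in range(5)]
        out = cpg_fraction_by_category(_frame(rows)).set_index("category")
        assert out.loc["human_private", "cpg_fraction"] == 0.0

    def test_rare_fraction_anticorrelated_with_cpg(self, synth_table_grid):
        # CpG transitions are high-rate, hence depleted of rare variants; a
        # category's rare fraction falls with its CpG enrichment
        (table, _), _ = synth_table_grid
        _, summary = build_csfs(table)
        cpg = cpg_fraction_by_category(table).set_index("category")
        agg = (summary.groupby("category")
               .apply(lambda g: (g["rare_fraction"] * g["n_sites"]).sum()
                      / max(g["n_sites"].sum(), 1), include_groups=False))
        cats = [c for c in agg.index if cpg.loc[c, "n_sites"] > 0]
        rho = pearsonr(agg[cats], cpg.loc[cats, "cpg_fraction"]).statistic
        assert rho < -0.8


class TestStrandPartition:
    def test_plus_strand_reference_is_coding(self):
        df = _frame([_record("A", "G", strand="+")])
        part, _ = strand_partition(df)
        assert part["strand_type"].iloc[0] == "A>G"
        assert part["strand_class"].iloc[0] == "coding"

    def test_minus_strand_flips_to_template(self):
        df = _frame([_record("A", "G", strand="-")])
        part, _ = strand_partition(df)
        # coding-strand change is T>C, i.e. A>G on the template strand
        assert part["strand_type"].iloc[0] == "A>G"
        assert part["strand_class"].iloc[0] == "template"

    def test_cpg_and_strandless_excluded(self):
        rows = [
            _record("C", "T", flank_down="GAAAA"),
            _record("A", "G", strand="."),
            _record("A", "G"),
        ]
        part, excluded = strand_partition(_frame(rows))
        assert len(part) == 1
        assert excluded == {"strandless": 1, "cpg_or_ambiguous": 1}

    def test_generator_agrees_and_gap_recovered(self):
        # inject a template-strand rare-fraction deficit for A>G and recover
        # it within a 3-sigma binomial band
        cfg = r.GeneratorConfig(
            seed=808, n_sites=60_000,
            mono_mix={"A>G": 0.8, "C>A": 0.1, "A>C": 0.1},
            cpg_fraction={k: 0.0 for k in [
                "human_private", "substituted_chimpanzee", "substituted_gorilla",
                "substituted_orangutan", "substituted_gibbon", "substituted_macaque"]},
            strand_mix={"+": 0.5, "-": 0.5, ".": 0.0},
            template_rare_shift={"A>G": -0.03},
        )
        table, manifest = r.generate_sites(cfg)
        part, _ = strand_partition(table)
        assert (part["strand_class"].to_numpy()
                == manifest.loc[part.index, "strand_class"].to_numpy()).all()
        part["rare"] = part["minor_count"] <= 2
        g = part[part["strand_type"] == "A>G"].groupby("strand_class")["rare"]
        gap = g.mean()["coding"] - g.mean()["template"]
        se = np.sqrt(sum(0.25 / g.size()[k] for k in ("coding", "template")))
        assert abs(gap - 0.03) < 3 * se
        assert gap > 0


class TestRateVsRareRegression:
    def test_exact_on_linear_inputs(self):
        rates = np.array([1e-9, 2e-9, 3e-9, 4e-9])
        rare = 0.7 - 1e7 * rates
        slope, se, p = rate_vs_rare_regression(rare, rates)
        assert slope == pytest.approx(-1e7)
        assert p < 1e-6

    def test_weights_default_to_ols(self):
        rng = np.random.default_rng(6)
        rates = np.geomspace(1e-9, 1e-7, 6)
        rare = 0.6 - 5e5 * rates + rng.normal(0, 0.01, 6)
        a = rate_vs_rare_regression(rare, rates)
        b = rate_vs_rare_regression(rare, rates, weights=np.ones(6))
        assert a == pytest.approx(b)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(ValueError):
            rate_vs_rare_regression([0.5, 0.6, 0.7], [1e-8, 1e-8, 1e-8])

    def test_negative_slope_on_generated_types(self, synth_table_grid):
        (table, manifest), cfg = synth_table_grid
        types = assign_mutation_types(table, "cpg_ti")
        rare = table["minor_count"] <= 2
        per_type = pd.DataFrame({"type": types, "rare": rare}).groupby("type")["rare"]
        means = per_type.mean()
        counts = per_type.size()
        rates = pd.Series(cfg.mean_rates)
        keep = means.index.intersection(rates.index)
        slope, se, p = rate_vs_rare_regression(
            means[keep], rates[keep], weights=counts[keep])
        assert slope < 0


class TestIO:
    def test_site_table_round_trip(self, tmp_path, synth_table):
        table, _ = synth_table
        path = tmp_path / "sites.tsv"
        write_site_table(table.head(500), path)
        back = read_site_table(path)
        pd.testing.assert_frame_equal(
            back, table.head(500).reset_index(drop=True), check_dtype=False)

    def test_read_requires_core_columns(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"chrom": ["1"], "pos": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_site_table(path)

    def test_vcf_adapter(self, tmp_path, synth_table):
        table, _ = synth_table
        head = table.head(200)
        vcf = tmp_path / "sites.vcf"
        sidecar = tmp_path / "sidecar.tsv"
        r.simulate_data.write_vcf(head, vcf)
        write_site_table(head.drop(columns=["major", "minor", "minor_count", "total"]),
                         sidecar)
        back = read_vcf_sites(vcf, sidecar)
        assert len(back) == 200
        assert (back["minor_count"].to_numpy() == head["minor_count"].to_numpy()).all()
        assert (back["major"].to_numpy() == head["major"].to_numpy()).all()
        cats_a = classify_categories(back)
        cats_b = classify_categories(head)
        assert (cats_a.to_numpy() == cats_b.to_numpy()).all()
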