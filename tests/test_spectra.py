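"""Spectrum containers, folding, rare fractions, projection and sharing."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ratesfs.spectra import (
    SpectrumFolded,
    SpectrumUnfolded,
    TwoPopSiteCounts,
    fold,
    fraction_maf_le,
    fraction_rare,
    project,
    projected_rare_fraction,
    projection_masses,
    read_spectrum_tsv,
    sharing_by_count,
    stratified_rare_fraction,
    write_spectrum_tsv,
)

spectra_strategy = st.integers(2, 12).flatmap(
    lambda n: st.lists(st.integers(0, 50), min_size=n - 1, max_size=n - 1)
    .map(lambda c: SpectrumUnfolded(n, np.array(c, dtype=float)))
)


class TestFold:
    @pytest.mark.parametrize(
        "n,counts,expected",
        [(6, [4, 3, 2, 1, 0], [4, 4, 2]), (4, [5, 2, 1], [6, 2])],
    )
    def test_fold_arithmetic(self, n, counts, expected):
        assert fold(SpectrumUnfolded(n, counts)).counts.tolist() == expected

    @given(spectra_strategy)
    @settings(max_examples=50, deadline=None)
    def test_fold_conserves_total(self, spec):
        assert fold(spec).total == pytest.approx(spec.total)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpectrumUnfolded(4, [1, 2])  # wrong length
        with pytest.raises(ValueError):
            SpectrumUnfolded(4, [1, -2, 1])  # negative
        with pytest.raises(ValueError):
            SpectrumFolded(1, [])


class TestRareFractions:
    def test_folded_examples(self):
        assert fraction_rare(SpectrumFolded(8, [12, 8, 5, 5])) == pytest.approx(20 / 30)
        assert fraction_rare(SpectrumFolded(6, [0, 0, 7])) == 0.0

    def test_unfolded_uses_minor_counts(self):
        # derived classes {1, 2, 4, 5} of n=6 have minor count <= 2
        spec = SpectrumUnfolded(6, [4, 3, 2, 1, 0])
        assert fraction_rare(spec) == pytest.approx(0.8)

    def test_empty_spectrum_raises(self):
        with pytest.raises(ValueError):
            fraction_rare(SpectrumFolded(6, [0, 0, 0]))

    def test_scale_invariance(self):
        spec = SpectrumFolded(8, [12, 8, 5, 5])
        scaled = SpectrumFolded(8, 7.5 * np.array([12, 8, 5, 5.0]))
        assert fraction_rare(spec) == pytest.approx(fraction_rare(scaled))

    def test_maf_threshold_semantics(self):
        spec = SpectrumFolded(200, np.arange(1, 101, dtype=float))
        # MAF <= 1% of 200 chromosomes = minor count <= 2
        assert fraction_maf_le(spec, 0.01) == pytest.approx(fraction_rare(spec, 2))
        assert fraction_maf_le(spec, 0.5) == 1.0
        for bad in (0.0, -0.1, 0.6):
            with pytest.raises(ValueError):
                fraction_maf_le(spec, bad)


def _enumerate_projection(n, i, m):
    """Expected subsample spectrum for one site by exhaustive enumeration
    over all chromosome subsets — the brute-force projection oracle."""
    pool = [1] * i + [0] * (n - i)
    out = np.zeros(m + 1)
    subsets = list(itertools.combinations(range(n), m))
    for sub in subsets:
        out[sum(pool[k] for k in sub)] += 1
    return out / len(subsets)


class TestProjection:
    def test_identity_at_m_equals_n(self):
        spec = SpectrumUnfolded(6, [4, 3, 2, 1, 0])
        np.testing.assert_allclose(project(spec, 6).counts, spec.counts)

    def test_single_site_halving(self):
        # one site at derived count 2 of n=4, projected to m=2:
        # enumeration over the 6 pairs gives 2/3 singleton, 1/6 lost, 1/6 fixed
        spec = SpectrumUnfolded(4, [0, 1, 0])
        proj = project(spec, 2)
        assert proj.counts[0] == pytest.approx(2 / 3)
        masses = projection_masses(spec, 2)
        assert masses["lost"] == pytest.approx(1 / 6)
        assert masses["fixed"] == pytest.approx(1 / 6)
        assert masses["segregating"] == pytest.approx(2 / 3)

    def test_matches_exhaustive_enumeration_all_small_spectra(self):
        # projection is linear in the spectrum, so checking every basis
        # spectrum (single site at each derived count) for all n <= 8 and
        # every m covers all small spectra exactly
        for n in range(2, 9):
            for i in range(1, n):
                basis = np.zeros(n - 1)
                basis[i - 1] = 1.0
                spec = SpectrumUnfolded(n, basis)
                for m in range(2, n + 1):
                    expected = _enumerate_projection(n, i, m)[1:m]
                    np.testing.assert_allclose(
                        project(spec, m).counts, expected, atol=1e-12)

    def test_composition(self):
        rng = np.random.default_rng(1)
        spec = SpectrumUnfolded(12, rng.integers(0, 30, 11).astype(float))
        via = project(project(spec, 9), 5)
        direct = project(spec, 5)
        np.testing.assert_allclose(via.counts, direct.counts, atol=1e-10)

    def test_bounds_checked(self):
        spec = SpectrumUnfolded(6, [4, 3, 2, 1, 0])
        for m in (1, 7):
            with pytest.raises(ValueError):
                project(spec, m)

    def test_monte_carlo_subsampling_agrees(self):
        rng = np.random.default_rng(2)
        n, m, reps = 30, 10, 10_000
        counts = rng.integers(0, 20, n - 1).astype(float)
        spec = SpectrumUnfolded(n, counts)
        expected = fraction_rare(project(spec, m))
        # Monte-Carlo: hypergeometric subsample per site draw
        i = np.repeat(np.arange(1, n), counts.astype(int))
        rare = np.zeros(reps)
        seg = np.zeros(reps)
        for k in range(reps // 100):
            draws = rng.hypergeometric(i, n - i, m, size=(100, len(i)))
            keep = (draws > 0) & (draws < m)
            minor = np.minimum(draws, m - draws)
            rare[k * 100:(k + 1) * 100] = ((minor <= 2) & keep).sum(axis=1)
            seg[k * 100:(k + 1) * 100] = keep.sum(axis=1)
        est = rare.sum() / seg.sum()
        se = np.std(rare / seg) / np.sqrt(reps)
        assert abs(est - expected) < 3 * se + 1e-9

    def test_fast_rare_fraction_matches_full_projection(self):
        rng = np.random.default_rng(3)
        spec = SpectrumUnfolded(40, rng.integers(0, 25, 39).astype(float))
        for m in (5, 17, 40):
            assert projected_rare_fraction(spec, m) == pytest.approx(
                fraction_rare(project(spec, m)), abs=1e-12)


class TestSharing:
    def test_degenerate_cases(self):
        all_a = TwoPopSiteCounts(np.array([3, 5]), np.array([0, 0]), 10, 10)
        assert sharing_by_count(all_a, bins=[1, 100])["sharing"].iloc[0] == 0.0
        split = TwoPopSiteCounts(np.ones(5, int), np.ones(5, int), 10, 10)
        assert sharing_by_count(split, bins=[1, 100])["sharing"].iloc[0] == 1.0

    def test_empty_bin_reported_missing(self):
        sites = TwoPopSiteCounts(np.array([1]), np.array([0]), 10, 10)
        out = sharing_by_count(sites, bins=[1, 2, 4, 100])
        assert np.isnan(out["sharing"].iloc[1])
        assert out["n_sites"].iloc[1] == 0

    def test_binomial_split_closed_form(self):
        # c copies split Binomial(c, p): sharing -> 1 - p^c - (1-p)^c
        rng = np.random.default_rng(4)
        p, c, nsites = 0.3, 5, 40_000
        a = rng.binomial(c, p, nsites)
        keep = (a > 0) | (c - a > 0)  # always true; counts always positive
        sites = TwoPopSiteCounts(a[keep], (c - a)[keep], 1000, 1000)
        got = sharing_by_count(sites, bins=[c, c + 1])["sharing"].iloc[0]
        want = 1 - p**c - (1 - p) ** c
        se = np.sqrt(want * (1 - want) / nsites)
        assert abs(got - want) < 3 * se


class TestStratifiedRareFraction:
    def test_all_singletons_single_stratum(self):
        df = pd.DataFrame({"minor_count": [1] * 20, "state": ["x"] * 20})
        out = stratified_rare_fraction(df, "state", seed=0)
        assert out["rare_fraction"].iloc[0] == 1.0
        assert out["ci_lo"].iloc[0] == 1.0 and out["ci_hi"].iloc[0] == 1.0

    def test_two_strata_recover_truth(self):
        rng = np.random.default_rng(5)
        n = 10_000
        df = pd.DataFrame({
            "minor_count": np.concatenate([
                np.where(rng.random(n) < 0.4, 1, 5),
                np.where(rng.random(n) < 0.7, 1, 5),
            ]),
            "grp": ["a"] * n + ["b"] * n,
        })
        out = stratified_rare_fraction(df, "grp", seed=6).set_index("stratum")
        for grp, truth in (("a", 0.4), ("b", 0.7)):
            assert out.loc[grp, "ci_lo"] <= truth <= out.loc[grp, "ci_hi"]

    def test_bootstrap_reproducible(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"minor_count": rng.integers(1, 8, 500),
                           "rate": rng.lognormal(0, 1, 500)})
        a = stratified_rare_fraction(df, "rate", seed=11)
        b = stratified_rare_fraction(df, "rate", seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_stratum_flagged(self):
        df = pd.DataFrame({"minor_count": [1, 4], "grp": ["a", "b"]})
        out = stratified_rare_fraction(df, "grp", seed=1).set_index("stratum")
        assert not out["ci_defined"].any()


def test_tsv_round_trip():
    for spec in (SpectrumUnfolded(6, [4, 3, 2, 1, 0]), SpectrumFolded(7, [9, 2, 0])):
        buf = io.StringIO()
        write_spectrum_tsv(spec, buf)
        buf.seek(0)
        back = read_spectrum_tsv(buf)
        assert type(back) is type(spec)
        assert back.sample_size == spec.sample_size
        np.testing.assert_allclose(back.counts, spec.counts)
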