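import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hlagdiv.diversity import (
    TajimaCoefficients,
    empirical_null,
    feature_summary,
    hwe_exact,
    hwe_screen,
    nucleotide_diversity,
    per_site_pi,
    segregating_sites,
    sliding_windows,
    tajimas_d,
)
from hlagdiv.genemodel import GenomicInterval

from conftest import make_cohort, snp


class TestSegregatingSites:
    def test_monomorphic_zero(self):
        assert segregating_sites(np.zeros((6, 10))) == 0

    def test_counts_variable_columns(self):
        H = np.zeros((4, 10), dtype=int)
        H[0, [1, 5, 7]] = 1
        assert segregating_sites(H) == 3

    def test_triallelic_column_counts_once(self):
        H = np.array([[0], [1], [2], [0]])
        assert segregating_sites(H) == 1


class TestPi:
    def test_two_copies_one_difference(self):
        H = np.array([[0], [1]])
        assert nucleotide_diversity(H, 100)[1] == pytest.approx(0.01)

    def test_site_contribution_two_two_split(self):
        H = np.array([[0], [0], [1], [1]])
        assert per_site_pi(H)[0] == pytest.approx(4 / 6)

    def test_identical_rows_zero(self):
        assert nucleotide_diversity(np.ones((5, 8)), 8)[0] == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        arrays(np.int8, (6, 9), elements=st.integers(0, 2)),
    )
    def test_frequency_formula_equals_exhaustive_pairwise(self, H):
        n = H.shape[0]
        pairs = list(itertools.combinations(range(n), 2))
        mean_hamming = sum(np.sum(H[i] != H[j]) for i, j in pairs) / len(pairs)
        assert nucleotide_diversity(H, 1)[0] == pytest.approx(mean_hamming, abs=1e-9)


class TestTajima:
    def test_coefficients_n4(self):
        c = TajimaCoefficients.for_n(4)
        assert c.a1 == pytest.approx(1 + 1 / 2 + 1 / 3)
        assert c.a2 == pytest.approx(1 + 1 / 4 + 1 / 9)

    def test_zero_when_pi_equals_watterson(self):
        c = TajimaCoefficients.for_n(10)
        assert tajimas_d(10, 5, 5 / c.a1) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_oracle_value(self):
        # independent formula-literal evaluation of the 1989 coefficients
        assert tajimas_d(10, 5, 2.0) == pytest.approx(0.5276433822908873, abs=1e-12)

    def test_undefined_at_zero_sites(self):
        with pytest.raises(ValueError):
            tajimas_d(10, 0, 0.0)


class TestSlidingWindows:
    def _cohort(self, positions, rows=8):
        variants = [snp(p) for p in positions]
        H = np.zeros((rows, len(positions)), dtype=int)
        H[0, :] = 1
        return make_cohort(variants, H, samples=[f"S{i}" for i in range(rows // 2)])

    def test_window_count_exact_span(self):
        c = self._cohort([120])
        w = sliding_windows(c, GenomicInterval("chr6S", 100, 600), 500, 1)
        assert len(w) == 1

    def test_window_count_and_centers(self):
        c = self._cohort([120])
        w = sliding_windows(c, GenomicInterval("chr6S", 100, 602), 500, 1)
        assert len(w) == 3
        assert np.allclose(np.diff(w["center"]), 1.0)

    def test_too_short_interval_rejected(self):
        c = self._cohort([120])
        with pytest.raises(ValueError):
            sliding_windows(c, GenomicInterval("chr6S", 100, 200), 500)

    def test_counts_match_bruteforce_per_window(self):
        rng = np.random.default_rng(2)
        pos = sorted(rng.choice(np.arange(0, 800), 30, replace=False))
        variants = [snp(int(p)) for p in pos]
        H = rng.integers(0, 2, (10, 30))
        c = make_cohort(variants, H, samples=[f"S{i}" for i in range(5)])
        w = sliding_windows(c, GenomicInterval("chr6S", 0, 800), 500, 37)
        for _, row in w.iterrows():
            sel = [j for j, p in enumerate(pos) if row["start"] <= p < row["start"] + 500]
            sub = H[:, sel]
            assert row["S"] == segregating_sites(sub)
            assert row["pi_total"] == pytest.approx(
                nucleotide_diversity(sub, 500)[0] if sel else 0.0
            )


class TestEmpiricalNull:
    def _background(self, seed=0, n_sites=300, L=50_000):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(L, n_sites, replace=False))
        H = (rng.random((40, n_sites)) < 0.2).astype(int)
        return make_cohort(
            [snp(int(p)) for p in pos], H, samples=[f"S{i}" for i in range(20)]
        )

    def test_seed_reproducible_bitwise(self):
        bg = self._background()
        iv = GenomicInterval("chr6S", 0, 50_000)
        a = empirical_null(bg, iv, 500, 500, 7)
        b = empirical_null(bg, iv, 500, 500, 7)
        assert np.array_equal(a["pi_per_site"].values, b["pi_per_site"].values)
        assert a["tajima_d"].q99 == b["tajima_d"].q99

    def test_quantiles_monotone(self):
        bg = self._background()
        nulls = empirical_null(bg, GenomicInterval("chr6S", 0, 50_000), 800, 500, 1)
        for nd in nulls.values():
            assert nd.q99 <= nd.q999

    def test_zero_variant_background_degenerate(self):
        H = np.zeros((8, 1), dtype=int)
        H[0, 0] = 1
        bg = make_cohort([snp(200_000)], H, samples=[f"S{i}" for i in range(4)])
        nulls = empirical_null(bg, GenomicInterval("chr6S", 0, 10_000), 200, 500, 3)
        assert nulls["pi_per_site"].mean == 0.0
        assert math.isnan(nulls["tajima_d"].mean)  # flagged: no S>0 windows


def test_feature_summary_matches_direct_recomputation(bundle):
    fs = feature_summary(bundle.cohort, bundle.model)
    m = bundle.model
    for _, row in fs.iterrows():
        iv = m.features[row["feature"]]
        idx = bundle.cohort.sites_in(iv)
        sub = bundle.cohort.H[:, idx]
        assert row["S"] == segregating_sites(sub)
        if row["S"] == 0:
            assert math.isnan(row["tajima_d"])
    union_S = fs[fs["feature"].str.startswith(("exon", "intron"))]["S"].sum()
    gene_iv = GenomicInterval(m.contig, m.exons[0].start, m.exons[-1].end)
    assert union_S == segregating_sites(bundle.cohort.H[:, bundle.cohort.sites_in(gene_iv)])


class TestHweExact:
    def test_modal_configuration_near_one(self):
        assert hwe_exact(25, 50, 25) > 0.5

    def test_two_diploids_enumeration(self):
        assert hwe_exact(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_is_one(self):
        assert hwe_exact(50, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 2, 3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6))
    def test_matches_full_enumeration_oracle(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        N = aa + ab + bb  # 2N <= 36, enumeration exact
        nb = 2 * bb + ab
        n_minor = min(nb, 2 * N - nb)
        if n_minor == 0:
            assert hwe_exact(aa, ab, bb) == 1.0
            return

        def prob(het):
            hom_min = (n_minor - het) // 2
            hom_maj = N - het - hom_min
            return (
                math.factorial(N)
                / (math.factorial(hom_min) * math.factorial(het) * math.factorial(hom_maj))
                * 2**het
                * math.factorial(n_minor)
                * math.factorial(2 * N - n_minor)
                / math.factorial(2 * N)
            )

        hets = range(n_minor % 2, n_minor + 1, 2)
        probs = {h: prob(h) for h in hets}
        expected = sum(p for p in probs.values() if p <= probs[ab] * (1 + 1e-9))
        assert hwe_exact(aa, ab, bb) == pytest.approx(expected, rel=1e-9)


def test_hwe_screen_on_generated_cohort(bundle):
    scr = hwe_screen(bundle.cohort, min_individuals=10)
    assert set(scr["population"]) == set(bundle.cohort.manifest.table["population"])
    assert ((scr["p_value"] >= 0) & (scr["p_value"] <= 1)).all()
    # random-mating generator: deviations after Bonferroni should be rare
    assert scr["deviates"].mean() < 0.05
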