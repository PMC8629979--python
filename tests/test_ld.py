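import itertools

import numpy as np
import pandas as pd
import pytest

from hlagdiv.genemodel import GenomicInterval
from hlagdiv.ld import (
    complete_ld_groups,
    greedy_tag_selection,
    ld_site_filter,
    multiblock_ld,
    pairwise_ld,
)

from conftest import make_cohort, snp


def cohort_from_haplotypes(hapcols):
    """hapcols: (rows, sites) 0/1 matrix; row count must be even."""
    H = np.asarray(hapcols, dtype=int)
    variants = [snp(10 * (j + 1)) for j in range(H.shape[1])]
    return make_cohort(variants, H, samples=[f"S{i}" for i in range(H.shape[0] // 2)])


def brute_force_ld(x, y):
    """2x2 contingency oracle for one site pair."""
    n = len(x)
    pa, pb = x.mean(), y.mean()
    pab = np.mean(x & y)
    D = pab - pa * pb
    if D > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif D < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return D, 0.0, 0.0
    return D, D / dmax, D * D / (pa * (1 - pa) * pb * (1 - pb))


class TestPairwiseLd:
    def test_perfect_ld(self):
        c = cohort_from_haplotypes([[1, 1], [1, 1], [0, 0], [0, 0]])
        row = pairwise_ld(c, np.array([0, 1])).iloc[0]
        assert row["Dprime"] == pytest.approx(1.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_equilibrium(self):
        c = cohort_from_haplotypes([[1, 1], [1, 0], [0, 1], [0, 0]])
        row = pairwise_ld(c, np.array([0, 1])).iloc[0]
        assert row["D"] == pytest.approx(0.0)
        assert row["r2"] == pytest.approx(0.0)

    def test_hand_counted_table(self):
        # AB x4, Ab x1, aB x1, ab x4 -> D=0.15, D'=0.6, r2=0.36
        rows = [[1, 1]] * 4 + [[1, 0]] + [[0, 1]] + [[0, 0]] * 4
        c = cohort_from_haplotypes(rows)
        row = pairwise_ld(c, np.array([0, 1])).iloc[0]
        assert row["D"] == pytest.approx(0.15)
        assert row["Dprime"] == pytest.approx(0.6)
        assert row["r2"] == pytest.approx(0.36)

    def test_monomorphic_site_rejected(self):
        c = cohort_from_haplotypes([[1, 0], [1, 0], [1, 0], [1, 0]])
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_ld(c, np.array([0, 1]))

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            H = rng.integers(0, 2, (20, 6))
            # keep polymorphic columns only
            keep = [j for j in range(6) if 0 < H[:, j].mean() < 1]
            if len(keep) < 2:
                continue
            c = cohort_from_haplotypes(H[:, keep])
            pairs = pairwise_ld(c, np.arange(len(keep)))
            for _, row in pairs.iterrows():
                a, b = int(row["i"]), int(row["j"])
                D, dp, r2 = brute_force_ld(H[:, keep][:, a], H[:, keep][:, b])
                assert row["D"] == pytest.approx(D, abs=1e-12)
                assert row["Dprime"] == pytest.approx(dp, abs=1e-12)
                assert row["r2"] == pytest.approx(r2, abs=1e-12)

    def test_invariant_under_allele_label_swap(self):
        rng = np.random.default_rng(4)
        H = rng.integers(0, 2, (30, 2))
        if not (0 < H[:, 0].mean() < 1 and 0 < H[:, 1].mean() < 1):
            pytest.skip("degenerate draw")
        c1 = cohort_from_haplotypes(H)
        swapped = H.copy()
        swapped[:, 0] = 1 - swapped[:, 0]
        c2 = cohort_from_haplotypes(swapped)
        r1 = pairwise_ld(c1, np.array([0, 1])).iloc[0]
        r2_ = pairwise_ld(c2, np.array([0, 1])).iloc[0]
        assert r1["r2"] == pytest.approx(r2_["r2"], abs=1e-12)
        assert abs(r1["Dprime"]) == pytest.approx(abs(r2_["Dprime"]), abs=1e-12)


class TestSiteFilter:
    def test_maf_boundary_strictly_exclusive(self):
        # 100 copies: MAF exactly 0.01 must be excluded; the second site is
        # drawn in HWE proportions so it survives the screen
        rng = np.random.default_rng(0)
        H = np.zeros((100, 2), dtype=int)
        H[0, 0] = 1  # maf exactly 0.01
        H[:, 1] = (rng.random(100) < 0.3).astype(int)
        c = make_cohort([snp(10), snp(20)], H, samples=[f"S{i}" for i in range(50)])
        sites, prov = ld_site_filter(c, maf_min=0.01)
        assert sites.tolist() == [1]
        assert prov.loc[0, "excluded_by"] == "maf"

    def test_triallelic_excluded(self):
        from hlagdiv.cohort import VariantRecord

        v = VariantRecord("chr6S", 10, ".", "C", ("T", "G"))
        H = np.array([[1], [2], [0], [0]] * 5)
        c = make_cohort([v], H, samples=[f"S{i}" for i in range(10)])
        sites, prov = ld_site_filter(c)
        assert len(sites) == 0
        assert prov.loc[0, "excluded_by"] == "not-biallelic-snp"

    def test_surviving_set_matches_direct_computation(self, bundle):
        sites, prov = ld_site_filter(bundle.cohort, maf_min=0.01)
        n = bundle.cohort.n_copies
        for j, v in enumerate(bundle.cohort.variants):
            expected_bi = len(v.alts) == 1 and v.type == "SNP"
            maf = min(
                (bundle.cohort.H[:, j] != 0).mean(), (bundle.cohort.H[:, j] == 0).mean()
            )
            if not expected_bi:
                assert j not in sites
            elif maf <= 0.01:
                assert j not in sites


class TestGroupsAndTags:
    def test_mutual_complete_ld_single_group(self):
        c = cohort_from_haplotypes(np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]]))
        pairs = pairwise_ld(c, np.arange(3))
        assert complete_ld_groups(pairs, np.arange(3)) == [[0, 1, 2]]

    def test_no_edges_all_singletons(self):
        c = cohort_from_haplotypes(np.array([[1, 1], [1, 0], [0, 1], [0, 0]] * 3))
        pairs = pairwise_ld(c, np.arange(2))
        assert complete_ld_groups(pairs, np.arange(2)) == [[0], [1]]

    def test_planted_duplicate_columns_grouped(self, bundle):
        """Founder-private regulatory variants are carbon copies of one
        another, hence r^2 = 1 and a single complete-LD group."""
        truth = bundle.truth
        label_to_pos = {v.label: v.pos for v in truth.planted}
        pos_to_site = {v.pos: j for j, v in enumerate(bundle.cohort.variants)}
        f2_sites = [pos_to_site[label_to_pos[l]] for l in ("reg1", "reg2", "reg3")]
        sites, _ = ld_site_filter(bundle.cohort, maf_min=0.01)
        assert set(f2_sites) <= set(sites.tolist())
        pairs = pairwise_ld(bundle.cohort, sites)
        groups = complete_ld_groups(pairs, sites)
        containing = [g for g in groups if f2_sites[0] in g]
        assert len(containing) == 1
        assert set(f2_sites) <= set(containing[0])

    def test_single_tag_when_all_pairs_perfect(self):
        c = cohort_from_haplotypes(np.array([[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]]))
        pairs = pairwise_ld(c, np.arange(3))
        tags = greedy_tag_selection(pairs, np.arange(3), r2_threshold=0.95)
        assert len(tags.tags) == 1
        assert tags.verify(pairs)
        assert tags.uncovered == []

    def test_every_site_own_tag_without_ld(self):
        c = cohort_from_haplotypes(np.array([[1, 1], [1, 0], [0, 1], [0, 0]] * 3))
        pairs = pairwise_ld(c, np.arange(2))
        tags = greedy_tag_selection(pairs, np.arange(2), r2_threshold=0.95)
        assert sorted(tags.tags) == [0, 1]

    def test_planted_block_structure_yields_k_tags(self):
        # three founder blocks: sites within a block identical
        rng = np.random.default_rng(0)
        assign = rng.integers(0, 3, 40)
        blocks = [np.array([1, 0, 0]), np.array([0, 1, 0]), np.array([0, 0, 1])]
        H = np.stack([np.concatenate([blocks[a], blocks[a]]) for a in assign])
        # 6 sites: sites 0-2 and 3-5 duplicate the same 3-class labels
        c = cohort_from_haplotypes(H)
        pairs = pairwise_ld(c, np.arange(6))
        tags = greedy_tag_selection(pairs, np.arange(6), r2_threshold=0.95)
        groups = complete_ld_groups(pairs, np.arange(6))
        assert len(tags.tags) == len([g for g in groups])  # one tag per r2=1 class
        assert tags.verify(pairs)


class TestMultiblock:
    def test_masked_site_never_appears(self, bundle):
        iv = bundle.model.interval
        mid = (iv.start + iv.end) // 2
        blocks = [
            GenomicInterval(iv.contig, iv.start, mid),
            GenomicInterval(iv.contig, mid + 10, iv.end),
        ]
        masked_pos = {v.pos for v in bundle.cohort.variants[:5]}
        pairs, sites = multiblock_ld(bundle.cohort, blocks, masked_pos)
        assert not (set(sites["pos"]) & masked_pos)

    def test_overlapping_blocks_rejected(self, bundle):
        iv = bundle.model.interval
        blocks = [
            GenomicInterval(iv.contig, iv.start, iv.start + 100),
            GenomicInterval(iv.contig, iv.start + 50, iv.end),
        ]
        with pytest.raises(ValueError, match="disjoint"):
            multiblock_ld(bundle.cohort, blocks)

    def test_cross_block_perfect_ld_preserved(self):
        # same founder assignment on both sides of a gap -> inter-block r2=1
        H = np.array([[1, 1], [1, 1], [0, 0], [0, 0]] * 5)
        variants = [snp(100), snp(5000)]
        c = make_cohort(variants, H, samples=[f"S{i}" for i in range(10)])
        blocks = [GenomicInterval("chr6S", 0, 1000), GenomicInterval("chr6S", 4000, 6000)]
        pairs, sites = multiblock_ld(c, blocks)
        inter = pairs[(pairs["block_i"] == 0) & (pairs["block_j"] == 1)]
        assert len(inter) == 1
        assert inter.iloc[0]["r2"] == pytest.approx(1.0)
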