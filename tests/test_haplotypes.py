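from collections import Counter

import numpy as np
import pytest

from hlagdiv.cohort import AlleleCatalog, VariantRecord
from hlagdiv.genemodel import GenomicInterval
from hlagdiv.haplotypes import (
    associate_allele_utr,
    extract_haplotypes,
    frequency_table,
    name_haplotypes,
    variant_inventory,
)

from conftest import make_cohort, make_manifest, snp

REF = "ACGTACGTACGTACGTACGT"  # offset 0, 20 bp
FEAT = GenomicInterval("chr6S", 4, 16)


class TestExtraction:
    def test_no_variants_gives_reference_substring(self):
        cohort = make_cohort([snp(2, ref="G", alt="A")], np.zeros((4, 1)))
        seqs = extract_haplotypes(cohort, REF, FEAT)
        assert seqs == [REF[4:16]] * 4

    def test_snp_substituted_only_on_carrier_copy(self):
        cohort = make_cohort([snp(6, ref="G", alt="T")], [[0], [0], [0], [1]])
        seqs = extract_haplotypes(cohort, REF, FEAT)
        assert seqs[0] == REF[4:16]
        assert seqs[3] == REF[4:6] + "T" + REF[7:16]

    def test_deletion_shortens_sequence(self):
        # anchored 15-bp ref span deleting 14 bases would exceed the toy
        # feature; use a 4-bp deletion: ref ACGTA -> A at pos 5
        v = VariantRecord("chr6S", 5, ".", REF[5:10], (REF[5],))
        cohort = make_cohort([v], [[0], [1], [0], [0]])
        seqs = extract_haplotypes(cohort, REF, FEAT)
        assert len(seqs[1]) == len(seqs[0]) - 4

    def test_ref_mismatch_rejected(self):
        cohort = make_cohort([snp(6, ref="A", alt="T")], [[0], [1], [0], [0]])
        with pytest.raises(ValueError, match="mismatch"):
            extract_haplotypes(cohort, REF, FEAT)

    def test_overlapping_spans_on_one_copy_rejected(self):
        v1 = VariantRecord("chr6S", 5, ".", REF[5:10], (REF[5],))
        v2 = snp(7, ref="T", alt="A")
        cohort = make_cohort([v1, v2], [[1, 1], [0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="overlap"):
            extract_haplotypes(cohort, REF, FEAT)


class TestNaming:
    def test_catalog_match_takes_catalog_name(self):
        cat = AlleleCatalog("cds", {"G*01:01:01:01": "AAAA"})
        names, inv = name_haplotypes(["AAAA", "AAAA"], cat, "NOV-")
        assert names == ["G*01:01:01:01"] * 2

    def test_novel_numbering_by_descending_count(self):
        seqs = ["CCCC"] * 51 + ["GGGG"] * 3
        names, inv = name_haplotypes(seqs, AlleleCatalog("cds", {}), "NOV-")
        assert names[0] == "NOV-1" and names[-1] == "NOV-2"
        assert inv[0].global_count == 51

    def test_tie_broken_by_lexicographic_sequence(self):
        names, _ = name_haplotypes(["TTTT", "AAAA"], AlleleCatalog("cds", {}), "NOV-")
        assert names == ["NOV-2", "NOV-1"]

    def test_naming_invariant_under_copy_permutation(self):
        rng = np.random.default_rng(3)
        seqs = [("AAAA", "CCCC", "GGGG")[i] for i in rng.integers(0, 3, 40)]
        names, _ = name_haplotypes(seqs, None, "N-")
        perm = rng.permutation(40)
        names_p, _ = name_haplotypes([seqs[i] for i in perm], None, "N-")
        assert [names[i] for i in perm] == names_p


class TestFrequencyTable:
    def test_single_haplotype_has_frequency_one(self):
        samples = [f"S{i}" for i in range(10)]
        m = make_manifest(samples)
        ft = frequency_table(["X"] * 20, m, samples, "full", "population")
        assert ft["frequency"].tolist() == [1.0]
        assert ft["two_n"].tolist() == [20]

    def test_frequencies_sum_to_one_per_group(self):
        samples = [f"S{i}" for i in range(10)]
        m = make_manifest(samples)
        names = ["A"] * 14 + ["B"] * 6
        ft = frequency_table(names, m, samples, "full", "population")
        assert ft["frequency"].sum() == pytest.approx(1.0, abs=1e-9)
        assert sorted(ft["frequency"]) == [0.3, 0.7]

    def test_global_equals_count_weighted_merge_of_populations(self, bundle):
        from hlagdiv.haplotypes import extract_haplotypes, name_haplotypes

        seqs = extract_haplotypes(
            bundle.cohort, bundle.reference, bundle.model.interval, bundle.ref_offset
        )
        names, _ = name_haplotypes(seqs, bundle.catalogs["full"], "NOV-")
        man, samples = bundle.cohort.manifest, bundle.cohort.samples
        glob = frequency_table(names, man, samples, "full", "global")
        pop = frequency_table(names, man, samples, "full", "population")
        merged = pop.groupby("name")["count"].sum()
        for _, row in glob.iterrows():
            assert merged[row["name"]] == row["count"]
        assert glob["count"].sum() == bundle.cohort.n_copies

    def test_min_n_companion_filter(self):
        samples = [f"S{i}" for i in range(12)]
        m = make_manifest(samples, population=["BIG"] * 10 + ["TINY"] * 2)
        ft = frequency_table(["X"] * 24, m, samples, "full", "population")
        flags = dict(zip(ft["group"], ft["group_passes_min_n"]))
        assert flags == {"BIG": True, "TINY": False}


class TestAlleleUtrAssociation:
    def test_exclusive_partner_has_internal_frequency_one(self):
        rows = associate_allele_utr(["A"] * 6, ["U1"] * 6, 2)
        assert rows["internal_frequency"].tolist() == [1.0]

    def test_internal_frequency_denominator_includes_filtered_pairs(self):
        # allele A: 5x U1, 1x U2 (singleton dropped from rows, kept in denom)
        cds = ["A"] * 6
        utr = ["U1"] * 5 + ["U2"]
        rows = associate_allele_utr(cds, utr, 2)
        assert rows["utr"].tolist() == ["U1"]
        assert rows["internal_frequency"].iloc[0] == pytest.approx(5 / 6)

    def test_matches_direct_count_oracle(self, bundle):
        from hlagdiv.proteins import splice_cds

        cds = splice_cds(bundle.cohort, bundle.reference, bundle.model, bundle.ref_offset)
        utr = extract_haplotypes(
            bundle.cohort, bundle.reference, bundle.model.features["utr3"], bundle.ref_offset
        )
        cn, _ = name_haplotypes(cds, bundle.catalogs["cds"], "NG-")
        un, _ = name_haplotypes(utr, bundle.catalogs["utr3"], "NU-")
        rows = associate_allele_utr(cn, un, 2)
        pair_oracle = Counter(zip(cn, un))
        allele_oracle = Counter(cn)
        total = len(cn)
        for _, r in rows.iterrows():
            c = pair_oracle[(r["allele"], r["utr"])]
            assert c == r["pair_count"] >= 2
            assert r["global_frequency"] == pytest.approx(c / total)
            assert r["internal_frequency"] == pytest.approx(c / allele_oracle[r["allele"]])

    def test_internal_frequencies_sum_to_one_before_filter(self):
        rng = np.random.default_rng(0)
        cds = [f"A{i}" for i in rng.integers(0, 4, 100)]
        utr = [f"U{i}" for i in rng.integers(0, 3, 100)]
        rows = associate_allele_utr(cds, utr, min_pair_count=1)
        sums = rows.groupby("allele")["internal_frequency"].sum()
        assert np.allclose(sums, 1.0)

    def test_mismatched_copy_sets_rejected(self):
        with pytest.raises(ValueError):
            associate_allele_utr(["A"], ["U", "U"])


class TestVariantInventory:
    def test_empty_feature(self):
        cohort = make_cohort([snp(100)], [[1], [0], [0], [0]])
        total, poly, _ = variant_inventory(cohort, GenomicInterval("chr6S", 0, 50))
        assert (total, poly) == (0, 0)

    def test_threshold_strictly_above_one_percent(self):
        # frequencies 0.5, 0.009..., 0.02 across 250 copies
        rows = 250
        H = np.zeros((rows, 3), dtype=int)
        H[:125, 0] = 1
        H[:2, 1] = 1  # 0.008
        H[:5, 2] = 1  # 0.02
        variants = [snp(10), snp(20), snp(30)]
        cohort = make_cohort(variants, H, samples=[f"S{i}" for i in range(rows // 2)])
        total, poly, table = variant_inventory(cohort)
        assert total == 3
        assert poly == 2

    def test_matches_generator_truth(self, bundle):
        truth = bundle.truth
        total, _, table = variant_inventory(bundle.cohort)
        assert total == len(truth.planted) + len(truth.novel_variants)
        freqs = dict(zip(table["pos"], table["alt_frequency"]))
        counts = Counter()
        for row, f in enumerate(truth.founder_per_copy):
            for k in truth.founder_variants[truth.founder_names[f]]:
                counts[truth.planted[k].pos] += 1
        n = bundle.cohort.n_copies
        for pos, c in counts.items():
            assert freqs[pos] == pytest.approx(c / n)
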