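"""Pairwise FST among populations — SNP-based (Hudson) and haplotype-based
(G_ST form on coding-allele spectra) — with classical MDS projections of
each matrix.  Haplotype-level differentiation is typically crisper than
SNP-level, since whole-haplotype frequencies integrate many sites."""

import numpy as np

from _shared import fixture_bundle, outdir

from hlagdiv.haplotypes import extract_haplotypes, frequency_table, name_haplotypes
from hlagdiv.popstruct import classical_mds, haplotype_fst_pairwise, snp_fst_pairwise
from hlagdiv.proteins import splice_cds

b = fixture_bundle()
out = outdir("structure")

fst_snp = snp_fst_pairwise(b.cohort, min_n=10)
fst_snp.to_frame().to_csv(out / "fst_snp.tsv", sep="\t")

cds_names, _ = name_haplotypes(
    splice_cds(b.cohort, b.reference, b.model, b.ref_offset),
    b.catalogs["cds"], "NOVEL-G",
)
ft = frequency_table(cds_names, b.cohort.manifest, b.cohort.samples, "cds", "population")
fst_hap = haplotype_fst_pairwise(ft, min_n=10)
fst_hap.to_frame().to_csv(out / "fst_haplotype.tsv", sep="\t")

for tag, fst in (("SNP", fst_snp), ("haplotype", fst_hap)):
    emb = classical_mds(fst, k=2)
    emb.to_frame().to_csv(out / f"mds_{tag.lower()}.tsv", sep="\t", index=False)
    iu = np.triu_indices(len(fst.populations), 1)
    print(f"{tag}-based FST ({fst.estimator}): mean {fst.matrix[iu].mean():.4f}, "
          f"max {fst.matrix[iu].max():.4f}; MDS goodness-of-fit {emb.goodness_of_fit:.2f}")
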