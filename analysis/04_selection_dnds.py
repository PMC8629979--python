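"""Nei-Gojobori codon-based Z-tests of selection on the distinct coding
sequences, per exon and pooled.  The expected picture mirrors conserved
class-I-like coding regions: no single exon significant on its own, with
purifying-selection evidence strengthening as exons are pooled."""

from _shared import SEED, fixture_bundle, outdir

from hlagdiv.haplotypes import name_haplotypes
from hlagdiv.pipeline import dnds_table
from hlagdiv.proteins import splice_cds

b = fixture_bundle()
out = outdir("selection")

cds = splice_cds(b.cohort, b.reference, b.model, b.ref_offset)
_, inventory = name_haplotypes(cds, b.catalogs["cds"], "NOVEL-G")
seqs = {h.name: h.sequence for h in inventory}
table = dnds_table(seqs, b.model, reps=1000, seed=SEED)
table.to_csv(out / "dnds.tsv", sep="\t", index=False)
cols = ["region", "n_sequences", "n_codons", "z_neutral", "p_neutral", "p_purifying"]
print(table[cols].to_string(index=False))
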