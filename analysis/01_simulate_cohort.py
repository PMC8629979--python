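"""Generate the study's synthetic cohort: a ~7.7 kb HLA-G-like locus carried
by eight founder haplotypes (including nonsynonymous, synonymous, frameshift
and 14-bp 3'UTR-indel variants), sampled into six populations of 30
individuals with Dirichlet-divergent founder frequencies and rare novel
singleton mutations.  Writes phased VCF + reference + manifest + catalogs +
truth to results/fixture."""

from _shared import FIXTURE, SEED, fixture_bundle

bundle = fixture_bundle()
c = bundle.cohort
print(f"wrote fixture bundle to {FIXTURE} (seed {SEED})")
print(f"  {c.n_samples} samples / {c.n_copies} haplotype copies, "
      f"{len(c.variants)} variants over {len(bundle.model.interval)} bp")
print(f"  founders: {', '.join(bundle.truth.founder_names)}")
print(f"  planted effect variants: "
      f"{sorted({v.effect for v in bundle.truth.planted})}")
print(f"  novel singleton mutations: {len(bundle.truth.novel_variants)}")
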