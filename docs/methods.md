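# Methods

## Coordinate frame and gene model

All internal arithmetic is 0-based half-open genomic; the HLA-style
ATG-relative frame (+1 = A of the first translated ATG, −1 immediately
upstream, no position 0) is used only at I/O and reporting boundaries, with a
round-trip identity guaranteed over the analysis interval. A gene model
declares contig, strand, the ATG anchor and exon intervals; introns, the
promoter (default 4328 bp, abutting exon 1) and the 3'UTR (the last exon —
the post-stop sequence of upstream exons is treated as invariant) are
derived, never stored. Minus-strand support is limited to
reverse-complementing at sequence-extraction time; all bundled fixtures are
plus-strand.

## Haplotype reconstruction and naming

Each haplotype copy's sequence over a feature is the reference with that
copy's alleles substituted right-to-left (so indels cannot invalidate
coordinates of earlier edits). VCF ref alleles are checked against the
reference FASTA; overlapping ref spans within one copy are an error; a
deletion crossing a feature boundary is clipped at the boundary
(conservative). Indel spellings are trim-normalized at load so the 14-bp
3'UTR indel and similar variants have one canonical anchored representation;
genuine left-alignment against the reference is assumed of the input, per
VCF convention.

Naming is exact, case-insensitive string identity against a catalog —
haplotype resolutions here are *defined* by literal sequence identity over
fixed intervals, so no alignment is wanted. Novel sequences are numbered by
decreasing global count with lexicographic sequence order breaking ties,
which makes naming deterministic and invariant to sample order.

Frequencies are computed over 2N haplotype copies. The allele↔3'UTR table
reports, per observed (coding allele, 3'UTR) pair, the global frequency
(pair count / total copies) and the internal frequency (pair count / allele
count). Internal denominators are taken over **all** partners before the
min-pair-count filter (default 2) removes rows, so retained internal
frequencies need not sum to 1 — the same convention that makes published
versions of such tables slightly non-self-consistent under rounding.

## Protein translation

The CDS is spliced exon-by-exon from the ATG through the coding exons, so
exon boundaries survive indels. Translation uses the standard code, stops at
the first stop codon (never emitted), and flags: frameshift (CDS length ≢ 0
mod 3), premature stop (before the canonical length), and
no-stop-within-CDS. The last flag stands in for intron read-through of
frameshift null alleles: the biologically reported stop may lie in retained
intron, which we record as an event rather than simulate. The signal peptide
is fixed at 24 residues (configurable); mature numbering starts after it.
The residue report tracks the dimer Cys (mature 42), KIR2DL4 contacts
(76/79), ILT-2/ILT-4 contacts (195/197) and the CD8-binding DQTQDVE motif
(223–229), each classified intact / altered / absent-due-to-truncation, plus
all polymorphic residues versus a designated reference allotype.

## Diversity statistics

S counts columns with ≥2 distinct alleles (indels and multi-allelic sites
count once). π is the frequency-form mean pairwise difference,
Σ_sites (n/(n−1))(1−Σpₐ²), proven in tests equal to exhaustive pairwise
Hamming counting. Tajima's D uses the standard coefficients; with S = 0 the
variance term vanishes, so D is signalled as undefined (NaN in tracks, error
in the scalar API) rather than 0. Windows (default 500 bp, step 1) attach
the statistic to the midpoint; the per-window computation uses prefix sums
over site positions, so dense step-1 scans are O(sites + windows).

Empirical nulls draw window starts uniformly **with replacement** over a
background interval; S=0 windows contribute π=0/S=0 but are excluded from
the D null. Quantiles are nearest-rank order statistics, stated so
thresholds are bit-reproducible under a fixed seed.

The HWE screen applies the exact conditional test (sum of probabilities of
heterozygote configurations no more probable than observed, given allele
counts) per bi-allelic SNP per population with ≥10 individuals. A
"deviation" is p below 0.05 after Bonferroni across that population's tested
SNPs; the correction choice is recorded in the output since reported
deviation counts depend on it.

## dN/dS

Nei–Gojobori-style counting: potential synonymous sites per codon are the
expected synonymous fraction of the nine single-base neighbours (stop
targets count as nonsynonymous, so S+N = 3 per codon); observed differences
are averaged over all orderings of the changes, with pathways through stop
codons excluded and fully-stop-blocked codon pairs skipped and counted.
Proportions are pooled over all sequence pairs and Jukes–Cantor corrected
(error at p ≥ 3/4). The variance of d_N − d_S comes from bootstrap over
codon columns (default 1000 replicates, seeded); Z is referred to a standard
normal — two-tailed for neutrality, one-tailed for the directional
alternatives with p ≡ 1 when the directional statistic is non-positive.
Bootstrap-over-codons was chosen over the analytical variance because it is
assumption-light and its convention is recorded in the result metadata.
Input sets are the distinct exon-defined sequences, one copy each
(frequency-unweighted); frameshifted, length-shifted or internally-stopped
sequences are excluded from the alignment and counted.

## LD and tag SNPs

Two-locus haplotype frequencies are counted directly — the cohort is phased,
which is also why D′ = 1 is exact whenever a haplotype class is absent. Site
eligibility: bi-allelic SNPs with MAF strictly > 1% (the configurable
alternative 0.1% is supported) passing pooled-sample exact HWE with
Bonferroni. Complete-LD groups are connected components of the r² ≥ 1−1e-12
graph (ε absorbs floating-point noise). Tag selection is a greedy set cover
(pick the site covering most uncovered sites at r² > 0.95; ties to the lower
genomic position), re-verified independently after selection. The
multi-block variant drops masked positions (e.g. sites coinciding with known
structural variants) and computes inter-block pairs across disjoint
segments.

## Population structure

SNP-level FST is the Hudson ratio-of-averages estimator on allele-copy
frequencies with the finite-sample correction, combining sites as
Σ numerators / Σ denominators and skipping sites monomorphic across the
pair; it is well defined on phased copies and stable at small n, which is
why it is the single implemented estimator (the estimator tag travels with
the matrix so conventions stay explicit). Haplotype-level FST treats each
distinct haplotype name as one allele of a super-locus, with unbiased
within-population gene diversities and a Nei–Chesser-style small-sample
correction on the total diversity; without the H_T correction the estimate
for identical spectra is strictly negative at O(1/n), with it the identity
case sits at ~0 (still ≤ 0). Negative estimates are clipped to [0,1] only
when the matrix is used as MDS distances; raw values are retained.

Classical (Torgerson) MDS double-centers the squared distances and keeps the
top-k positive-eigenvalue axes; negative eigenvalues are dropped with a
warning, fewer-than-k positive eigenvalues return fewer axes flagged, and
each axis's sign is fixed by making its largest-magnitude loading positive
so embeddings are deterministic.

## Synthetic data

Two generators, all randomness flowing from one seed through named
generators (no global state):

**Neutral coalescent** — exponential epoch durations with rate k(k−1)/2,
Poisson(θ/2 × tree length) mutations placed uniformly on branches,
infinite-sites positions uniform in [0, L). Used to calibrate the
estimators: E[S] = a₁θ, E[π] = θ. An independent simulator (msprime) serves
as a distributional cross-check in the tests. Note a real property of
Tajima's D exposed by this calibration: its expectation under neutrality at
n=50, θ=10 is ≈ −0.09, not 0 (numerator and variance estimate are
correlated), with a per-replicate SD near 0.9 — so a 2000-replicate mean has
a Monte-Carlo SE of ≈0.02 and band checks of ±0.1 around zero sit within
noise of their boundary.

**Structured locus** — a haplotype-pool model rather than a demographic
simulation, because the modelled locus is characterized by a small set of
conserved, high-LD full-length haplotypes that can be planted exactly and
checked exactly. The default emulates the study conditions: a 7720-bp
region (4328 bp promoter, 8 exons/7 introns with a 1017-bp CDS over exons
1–6, 100 bp downstream, last transcribed base at +3292); eight founder
haplotypes at base frequencies 0.24…0.05 (few frequent haplotypes plus a
rarer tail); planted effect variants — a Thr→Ser exchange at mature residue
31 (A>T in exon 2), a Thr→Met exchange at mature residue 258 (C>T in exon
4), a synonymous third-position exon-2 change, a 1-bp exon-3 frameshift
(null-allele analogue), a 14-bp 3'UTR deletion and a 3'UTR SNP, and 16
founder-private promoter/intron SNPs that create exact r²=1 groups; per
population (default six of 30 individuals) founder frequencies drawn from
Dirichlet(α·base), α defaulting to 15 for the modest differentiation typical
of this locus, smaller α meaning more divergence; and Poisson(0.15) novel
singleton SNPs per sampled copy at never-before-used positions (infinite
sites), so novelty detection is unambiguous. Catalogs ship only the first
six founders, so novel-name assignment is exercised on every run.

What the generator does **not** emulate: recombination (the region behaves
as a single segregation block), selection acting within the sample,
mutation-rate heterogeneity, and the locus's elevated absolute nucleotide
diversity relative to its chromosomal background (founders differ at a
handful of sites, so window-π sits at background levels). Passing tests
therefore demonstrate correctness of the estimators and bookkeeping on data
with the right *structure* (few founders, strong LD, rare novels, Dirichlet
divergence), not the real locus's absolute parameter values.

## Problem sizes and seeds

Defaults used by the test suite and the acceptance script: coalescent
calibration at n=50, θ=10, 2000 replicates; dN/dS type-I calibration over
500 neutral sequence sets (12 sequences × 60 codons, Poisson(6) mutations
each, 500 bootstrap replicates); the structured locus at 180 samples / 77–85
variants. Stochastic tests fix seed 0 (the package-wide convention) or the
fixture seed 1; every consumer of randomness takes an explicit
`numpy.random.Generator` or integer seed.

## Known limitations

- Exact-match naming cannot assign partial (exon-subset) identity; a novel
  sequence one base off a catalog entry is simply novel.
- The HWE screen and LD filter use the pooled or per-population exact test
  with Bonferroni; other correction conventions change the reported
  deviation counts.
- NG86 with JC correction underestimates divergence under strong
  transition/transversion bias; no ML (codeml-style) estimation is provided.
- Frameshift translation stops at the spliced CDS end; genomic read-through
  into introns is flagged, not reconstructed.
- FST is estimated without significance testing (no permutation), and MDS is
  classical only.
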