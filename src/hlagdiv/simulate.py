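"""Synthetic datasets with the statistical structure the analyses assume.

Two generators:

* :func:`simulate_coalescent` — a standard neutral (Hudson) coalescent with
  infinite-sites mutation, used to calibrate the diversity estimators
  (E[S] = a1 * theta, E[pi] = theta, E[D] ~ 0).

* :func:`simulate_structured_locus` — a haplotype-pool model of an HLA-G-like
  locus: a ~7.7 kb region (4.3 kb promoter, 8 exons, 7 introns, 100 bp
  downstream) carried by a small set of founder haplotypes at high frequency,
  Dirichlet-divergent founder frequencies across populations, and rare novel
  singleton mutations sprinkled on sampled copies.  Founders plant the
  locus's signature variant classes: a nonsynonymous SNP with a known
  amino-acid exchange, a second nonsynonymous exchange, a synonymous SNP, a
  1-bp coding frameshift (null-allele analogue) and a 14-bp 3'UTR indel.
  Because founders differ at fixed variant sets, founder-private variant
  pairs are in perfect LD by construction — the property that makes the real
  locus taggable by few SNPs.

All randomness flows from a single seed through named generators.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    AlleleCatalog,
    PhasedCohort,
    SampleManifest,
    VariantRecord,
    write_catalog,
    write_fasta,
    write_phased_vcf,
)
from .genemodel import GeneModel, GenomicInterval, write_gene_model
from .proteins import MOTIFS

# ----------------------------------------------------------------------
# neutral coalescent
# ----------------------------------------------------------------------


def simulate_coalescent(
    n: int,
    theta: float,
    L: int = 1,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard neutral coalescent for ``n`` haplotypes with scaled mutation
    rate ``theta`` (= 4*Ne*mu per locus).

    Coalescence times are exponential with rate k(k-1)/2 while k lineages
    remain (time in units of 2Ne generations); mutations are Poisson with
    mean theta/2 per unit branch length, dropped uniformly on branches and
    mapped to distinct uniform positions in [0, L) (infinite sites).

    Returns (H, positions): H is an (n, S) 0/1 matrix with columns in
    position order.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = np.random.default_rng(rng)
    # epochs: with k lineages, duration t_k; record the lineage leaf-sets
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    epochs: list[tuple[float, list[frozenset[int]]]] = []
    while len(lineages) > 1:
        k = len(lineages)
        t = rng.exponential(2.0 / (k * (k - 1)))
        epochs.append((t, list(lineages)))
        i, j = rng.choice(k, size=2, replace=False)
        merged = lineages[i] | lineages[j]
        lineages = [x for h, x in enumerate(lineages) if h not in (i, j)]
        lineages.append(merged)
    total_len = sum(t * len(lin) for t, lin in epochs)
    n_mut = rng.poisson(theta / 2.0 * total_len) if total_len > 0 else 0
    if n_mut == 0:
        return np.zeros((n, 0), dtype=np.int8), np.empty(0)
    # choose a branch per mutation, weight = epoch duration per lineage
    weights = np.array([t for t, lin in epochs for _ in lin])
    branches = [leafset for t, lin in epochs for leafset in lin]
    picks = rng.choice(len(branches), size=n_mut, p=weights / weights.sum())
    positions = rng.random(n_mut) * L
    order = np.argsort(positions)
    H = np.zeros((n, n_mut), dtype=np.int8)
    for col, b in enumerate(picks[order]):
        H[list(branches[b]), col] = 1
    return H, positions[order]


def coalescent_calibration(
    n: int = 50,
    theta: float = 10.0,
    reps: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Monte-Carlo calibration of the diversity estimators on the neutral
    coalescent: returns the replicate means of S, pi and Tajima's D together
    with their neutral expectations (E[S] = a1*theta, E[pi] = theta).
    Replicates with S = 0, where D is undefined, are excluded from the D mean.
    """
    from .diversity import TajimaCoefficients, nucleotide_diversity, tajimas_d

    rng = np.random.default_rng(seed)
    S_vals, pi_vals, d_vals = [], [], []
    for _ in range(reps):
        H, _ = simulate_coalescent(n, theta, 1, rng)
        S = H.shape[1]
        S_vals.append(S)
        pi = nucleotide_diversity(H, 1)[0] if S else 0.0
        pi_vals.append(pi)
        if S:
            d_vals.append(tajimas_d(n, S, pi))
    a1 = TajimaCoefficients.for_n(n).a1
    return {
        "mean_S": float(np.mean(S_vals)),
        "expected_S": a1 * theta,
        "mean_pi": float(np.mean(pi_vals)),
        "expected_pi": theta,
        "mean_tajima_d": float(np.mean(d_vals)),
        "reps": reps,
    }


# ----------------------------------------------------------------------
# codon-sequence regimes for the dN/dS tests
# ----------------------------------------------------------------------


def _random_stopfree_cds(n_codons: int, rng: np.random.Generator) -> str:
    from Bio.Data.CodonTable import standard_dna_table

    codons = sorted(standard_dna_table.forward_table)
    picks = rng.integers(0, len(codons), n_codons)
    return "".join(codons[i] for i in picks)


def simulate_codon_set(
    n_seqs: int,
    n_codons: int,
    mut_per_seq: float,
    regime: str = "neutral",
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Sequence sets for calibrating the codon Z-tests.

    regime 'neutral': each sequence receives Poisson(mut_per_seq) single-base
    changes at uniform positions to uniform alternative bases (redrawn if the
    change creates an internal stop), so synonymous and nonsynonymous changes
    occur in proportion to their available sites.  regime 'synonymous_only':
    only changes preserving the amino acid are accepted — a purifying caricature
    with d_N = 0.
    """
    from .dnds import _aa

    if regime not in {"neutral", "synonymous_only"}:
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(rng)
    ancestor = _random_stopfree_cds(n_codons, rng)
    out = []
    for _ in range(n_seqs):
        seq = list(ancestor)
        for _ in range(rng.poisson(mut_per_seq)):
            for _attempt in range(200):
                p = int(rng.integers(0, 3 * n_codons))
                b = "ACGT"[int(rng.integers(0, 4))]
                if b == seq[p]:
                    continue
                c0 = 3 * (p // 3)
                codon = "".join(seq[c0 : c0 + 3])
                mut = codon[: p - c0] + b + codon[p - c0 + 1 :]
                if _aa(mut) == "*":
                    continue
                if regime == "synonymous_only" and _aa(mut) != _aa(codon):
                    continue
                seq[p] = b
                break
        out.append("".join(seq))
    return out


# ----------------------------------------------------------------------
# structured haplotype-pool locus
# ----------------------------------------------------------------------

_CODON_CHOICES: dict[str, list[str]] = {}


def _codons_for(aa: str) -> list[str]:
    if not _CODON_CHOICES:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, a in standard_dna_table.forward_table.items():
            _CODON_CHOICES.setdefault(a, []).append(codon)
        for a in _CODON_CHOICES:
            _CODON_CHOICES[a].sort()
    return _CODON_CHOICES[aa]


def make_default_gene_model(contig: str = "chr6S", origin: int = 10_000) -> GeneModel:
    """Eight-exon model of the synthetic locus: 1017 bp CDS over exons 1-6
    (stop codon at the end of exon 6), exon 8 = 3'UTR, 4328 bp promoter,
    100 bp downstream; last transcribed base at ATG-relative +3292."""
    atg = origin + 4328
    exon_lens = [72, 270, 276, 276, 99, 24, 30, 350]
    intron_lens = [130, 250, 600, 120, 400, 150, 245]
    exons = []
    pos = atg
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(contig, pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return GeneModel(contig, "+", atg, exons, 4328, 100, n_coding_exons=6)


N_CODONS = 339  # 338 residues + stop
SIGNAL_PEPTIDE_LEN = 24
CODING_SNP_MATURE_RESIDUE = 31  # Thr -> Ser via A>T at the codon's first base
EXON4_SNP_MATURE_RESIDUE = 258  # Thr -> Met via C>T at the codon's second base


def _build_reference(model: GeneModel, rng: np.random.Generator) -> str:
    """Reference sequence of the analysis interval, with a CDS whose mature
    protein carries every canonical functional motif plus the two codons the
    planted nonsynonymous SNPs act on."""
    aa_pool = "ARNDQEGHILKFPSWYV"  # no C/M/T: reserved for planted positions
    mature = [aa_pool[i] for i in rng.integers(0, len(aa_pool), 314)]
    for motif in MOTIFS.values():
        for p, aa in motif.items():
            mature[p - 1] = aa
    mature[CODING_SNP_MATURE_RESIDUE - 1] = "T"
    mature[EXON4_SNP_MATURE_RESIDUE - 1] = "T"
    signal = "M" + "".join(
        aa_pool[i] for i in rng.integers(0, len(aa_pool), SIGNAL_PEPTIDE_LEN - 1)
    )
    protein = signal + "".join(mature)
    codons = []
    for aa in protein:
        opts = _codons_for(aa)
        codons.append(opts[int(rng.integers(0, len(opts)))])
    codons[0] = "ATG"
    codons[SIGNAL_PEPTIDE_LEN + CODING_SNP_MATURE_RESIDUE - 1] = "ACC"  # Thr
    codons[SIGNAL_PEPTIDE_LEN + EXON4_SNP_MATURE_RESIDUE - 1] = "ACG"  # Thr
    cds = "".join(codons) + "TAA"
    assert len(cds) == 3 * N_CODONS

    iv = model.interval
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, len(iv))))
    # lay the CDS into the coding exons
    off = 0
    for ex in model.coding_exons:
        start = ex.start - iv.start
        if ex.contains(model.atg_genomic):
            start = model.atg_genomic - iv.start
        ln = ex.end - (start + iv.start)
        seq[start : start + ln] = cds[off : off + ln]
        off += ln
    return "".join(seq)


@dataclass
class PlantedVariant:
    pos: int  # 0-based genomic, anchored for indels
    ref: str
    alt: str
    effect: str  # synonymous / nonsynonymous / frameshift / utr_indel / regulatory
    label: str = ""


@dataclass
class SyntheticTruth:
    seed: int
    founder_names: list[str]
    founder_variants: dict[str, list[int]]  # founder -> indices into planted
    planted: list[PlantedVariant]
    base_freqs: list[float]
    pop_freqs: dict[str, list[float]]
    alpha: float
    mu_novel: float
    founder_per_copy: list[int]
    novel_variants: list[PlantedVariant] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "founder_names": self.founder_names,
            "founder_variants": self.founder_variants,
            "planted": [vars(v) for v in self.planted],
            "base_freqs": self.base_freqs,
            "pop_freqs": self.pop_freqs,
            "alpha": self.alpha,
            "mu_novel": self.mu_novel,
            "founder_per_copy": self.founder_per_copy,
            "novel_variants": [vars(v) for v in self.novel_variants],
        }
        return json.dumps(d, indent=1)


@dataclass
class FixtureBundle:
    cohort: PhasedCohort
    reference: str
    ref_offset: int
    model: GeneModel
    catalogs: dict[str, AlleleCatalog]
    founder_seqs: dict[str, str]
    truth: SyntheticTruth


def _cds_offset_to_genomic(model: GeneModel, off: int) -> int:
    """Map an offset into the spliced CDS to its genomic position."""
    pos = model.atg_genomic
    for k, ex in enumerate(model.coding_exons):
        start = model.atg_genomic if k == 0 else ex.start
        ln = ex.end - start
        if off < ln:
            return start + off
        off -= ln
    raise ValueError("offset beyond CDS")


def _plant_variants(model: GeneModel, reference: str) -> list[PlantedVariant]:
    """The fixed effect-bearing variants of the synthetic locus."""
    iv = model.interval

    def base(pos: int) -> str:
        return reference[pos - iv.start]

    out = []
    # nonsynonymous, alpha-1-domain analogue: ACC -> TCC (Thr -> Ser)
    p = _cds_offset_to_genomic(model, 3 * (SIGNAL_PEPTIDE_LEN + CODING_SNP_MATURE_RESIDUE - 1))
    out.append(PlantedVariant(p, base(p), "T", "nonsynonymous", "Thr31Ser"))
    # nonsynonymous, alpha-3/TM analogue: ACG -> ATG (Thr -> Met)
    p = _cds_offset_to_genomic(model, 3 * (SIGNAL_PEPTIDE_LEN + EXON4_SNP_MATURE_RESIDUE - 1) + 1)
    out.append(PlantedVariant(p, base(p), "T", "nonsynonymous", "Thr258Met"))
    # synonymous third-position change in exon 2 (codon 40, CDS offset 119)
    cod = 39  # 0-based codon index, inside exon 2
    cstart = 3 * cod
    codon = "".join(base(_cds_offset_to_genomic(model, cstart + k)) for k in range(3))
    from .dnds import _aa

    alt = next(
        b for b in "ACGT" if b != codon[2] and _aa(codon[:2] + b) == _aa(codon)
    )
    p = _cds_offset_to_genomic(model, cstart + 2)
    out.append(PlantedVariant(p, base(p), alt, "synonymous", "syn-exon2"))
    # 1-bp frameshift deletion in exon 3 (anchored spelling)
    ex3 = model.features["exon3"]
    p = ex3.start + 29
    out.append(
        PlantedVariant(p, reference[p - iv.start : p - iv.start + 2], base(p), "frameshift", "del1-exon3")
    )
    # 14-bp deletion in the 3'UTR (last exon)
    utr = model.features["utr3"]
    p = utr.start + 79
    out.append(
        PlantedVariant(
            p, reference[p - iv.start : p - iv.start + 15], base(p), "utr_indel", "del14-utr3"
        )
    )
    # a single-base UTR SNP (distinct 3'UTR without the indel)
    p = utr.start + 160
    alt = "A" if base(p) != "A" else "G"
    out.append(PlantedVariant(p, base(p), alt, "utr_snp", "snp-utr3"))
    # regulatory (promoter / intron) founder-private SNPs
    prom = model.features["promoter"]
    reg_positions = (
        [prom.start + o for o in (400, 1200, 2000, 2600, 3200, 3800, 120, 800)]
        + [model.features["intron2"].start + o for o in (40, 120, 200)]
        + [model.features["intron3"].start + o for o in (100, 300, 500)]
        + [model.features["intron5"].start + o for o in (50, 250)]
    )
    for k, p in enumerate(reg_positions):
        alt = "A" if base(p) != "A" else "C"
        out.append(PlantedVariant(p, base(p), alt, "regulatory", f"reg{k + 1}"))
    return out


# founder -> planted-variant labels.  Founder 1 is the reference haplotype.
FOUNDER_PLAN: dict[str, list[str]] = {
    "F1": [],
    "F2": ["syn-exon2", "reg1", "reg2", "reg3"],
    "F3": ["Thr31Ser", "reg9", "reg10"],
    "F4": ["Thr258Met", "reg4", "reg5"],
    "F5": ["del1-exon3", "del14-utr3", "reg12"],
    "F6": ["del14-utr3", "reg6", "reg7", "reg14"],
    "F7": ["snp-utr3", "reg15", "reg16"],
    "F8": ["syn-exon2", "del14-utr3", "reg8"],
}
DEFAULT_BASE_FREQS = [0.24, 0.18, 0.14, 0.12, 0.10, 0.09, 0.08, 0.05]
CATALOGED_FOUNDERS = ["F1", "F2", "F3", "F4", "F5", "F6"]  # F7/F8 stay novel


def simulate_structured_locus(
    model: GeneModel | None = None,
    base_freqs: list[float] | None = None,
    alpha: float = 15.0,
    pops: dict[str, int] | None = None,
    mu_novel: float = 0.15,
    seed: int = 0,
) -> FixtureBundle:
    """Sample a phased cohort from the founder haplotype pool.

    Per population, founder frequencies are Dirichlet(alpha * base_freqs) —
    smaller ``alpha`` means stronger between-population divergence.  Each
    sampled copy is a founder plus Poisson(mu_novel) fresh singleton SNPs at
    previously unused positions (infinite sites), so every novel sequence is
    unambiguously detectable.
    """
    rng = np.random.default_rng(seed)
    ref_rng = np.random.default_rng(rng.integers(0, 2**31))
    if model is None:
        model = make_default_gene_model()
    reference = _build_reference(model, ref_rng)
    iv = model.interval
    planted = _plant_variants(model, reference)
    by_label = {v.label: k for k, v in enumerate(planted)}
    founder_names = list(FOUNDER_PLAN)
    founder_variants = {
        f: sorted(by_label[lab] for lab in labs) for f, labs in FOUNDER_PLAN.items()
    }
    if base_freqs is None:
        base_freqs = list(DEFAULT_BASE_FREQS)
    if len(base_freqs) != len(founder_names):
        raise ValueError("base_freqs must match the founder count")
    if abs(sum(base_freqs) - 1.0) > 1e-9:
        raise ValueError("base_freqs must sum to 1")
    if pops is None:
        pops = {f"POP{i + 1}": 30 for i in range(6)}

    pop_freqs = {
        p: rng.dirichlet(alpha * np.asarray(base_freqs)).tolist() for p in pops
    }

    # positions unavailable for novel mutations: planted sites + indel spans
    used = set()
    for v in planted:
        used.update(range(v.pos, v.pos + len(v.ref)))

    samples, pop_col = [], []
    founder_per_copy: list[int] = []
    novel_per_copy: list[list[PlantedVariant]] = []
    novels: list[PlantedVariant] = []
    for pname, size in pops.items():
        freqs = np.asarray(pop_freqs[pname])
        for i in range(size):
            samples.append(f"{pname}_S{i + 1:03d}")
            pop_col.append(pname)
            for _ in range(2):
                f = int(rng.choice(len(founder_names), p=freqs))
                founder_per_copy.append(f)
                muts = []
                for _ in range(rng.poisson(mu_novel)):
                    while True:
                        p = iv.start + int(rng.integers(0, len(iv)))
                        if p not in used:
                            break
                    used.add(p)
                    refb = reference[p - iv.start]
                    alt = "ACGT"[int(rng.integers(0, 4))]
                    while alt == refb:
                        alt = "ACGT"[int(rng.integers(0, 4))]
                    nv = PlantedVariant(p, refb, alt, "novel", f"novel@{p}")
                    muts.append(nv)
                    novels.append(nv)
                novel_per_copy.append(muts)

    # assemble the VCF-style variant set
    all_planted = planted + novels
    order = np.argsort([v.pos for v in all_planted], kind="stable")
    variants = [
        VariantRecord(iv.contig, all_planted[k].pos, ".", all_planted[k].ref, (all_planted[k].alt,))
        for k in order
    ]
    col_of = {id(all_planted[k]): c for c, k in enumerate(order)}
    H = np.zeros((2 * len(samples), len(variants)), dtype=np.int16)
    for row, f in enumerate(founder_per_copy):
        for k in founder_variants[founder_names[f]]:
            H[row, col_of[id(planted[k])]] = 1
        for nv in novel_per_copy[row]:
            H[row, col_of[id(nv)]] = 1

    regions = {p: f"REGION{(i // 2) + 1}" for i, p in enumerate(pops)}
    manifest = SampleManifest(
        pd.DataFrame(
            {
                "sample": samples,
                "population": pop_col,
                "country": [p.replace("POP", "COUNTRY") for p in pop_col],
                "region": [regions[p] for p in pop_col],
            }
        )
    )
    cohort = PhasedCohort(variants, samples, H, manifest)

    founder_seqs = _founder_sequences(
        model, reference, planted, founder_variants, founder_names
    )
    catalogs = _build_catalogs(model, reference, planted, founder_variants)
    truth = SyntheticTruth(
        seed,
        founder_names,
        founder_variants,
        planted,
        list(base_freqs),
        pop_freqs,
        alpha,
        mu_novel,
        founder_per_copy,
        novels,
    )
    return FixtureBundle(cohort, reference, iv.start, model, catalogs, founder_seqs, truth)


def _apply(seq: str, offset: int, variants: list[PlantedVariant]) -> str:
    for v in sorted(variants, key=lambda x: -x.pos):
        o = v.pos - offset
        seq = seq[:o] + v.alt + seq[o + len(v.ref) :]
    return seq


def _founder_sequences(model, reference, planted, founder_variants, founder_names):
    iv = model.interval
    return {
        f: _apply(reference, iv.start, [planted[k] for k in founder_variants[f]])
        for f in founder_names
    }


def _founder_feature_seq(model, reference, planted, ks, feature) -> str:
    iv = model.interval
    sub = reference[feature.start - iv.start : feature.end - iv.start]
    vs = [planted[k] for k in ks if feature.start <= planted[k].pos < feature.end]
    return _apply(sub, feature.start, vs)


def _founder_cds(model, reference, planted, ks) -> str:
    parts = []
    for i, ex in enumerate(model.coding_exons):
        start = model.atg_genomic if i == 0 else ex.start
        parts.append(
            _founder_feature_seq(
                model, reference, planted, ks, GenomicInterval(ex.contig, start, ex.end)
            )
        )
    return "".join(parts)


def _build_catalogs(model, reference, planted, founder_variants) -> dict[str, AlleleCatalog]:
    """Catalogs hold the first six founders only, leaving the rest to be
    discovered as novel sequences."""
    from .proteins import translate_cds

    iv = model.interval
    full_names = {f: f"HAP-{i + 1:02d}" for i, f in enumerate(CATALOGED_FOUNDERS)}
    cds_names = {
        "F1": "G*01:01:01:01",
        "F2": "G*01:01:02:01",
        "F3": "G*01:03:01:02",
        "F4": "G*01:06:01:01",
        "F5": "G*01:05N",
        "F6": "G*01:01:01:01",  # same CDS as the reference founder
    }
    prot_names = {
        "F1": "G*01:01",
        "F2": "G*01:01",
        "F3": "G*01:03",
        "F4": "G*01:06",
        "F5": "G*01:05N",
        "F6": "G*01:01",
    }
    utr_names = {"F1": "UTR-01", "F2": "UTR-01", "F5": "UTR-02"}
    full = {}
    cds = {}
    prot = {}
    utr = {}
    utr_iv = model.features["utr3"]
    for f in CATALOGED_FOUNDERS:
        ks = founder_variants[f]
        full_seq = _apply(reference, iv.start, [planted[k] for k in ks])
        full[full_names[f]] = full_seq
        cseq = _founder_cds(model, reference, planted, ks)
        cds.setdefault(cds_names[f], cseq)
        p = translate_cds(cseq, SIGNAL_PEPTIDE_LEN, canonical_aa_len=N_CODONS - 1)
        prot.setdefault(prot_names[f], p.precursor)
        useq = _founder_feature_seq(model, reference, planted, ks, utr_iv)
        if f in utr_names:
            utr.setdefault(utr_names[f], useq)
    return {
        "full": AlleleCatalog("full", full, "synthetic founder catalog"),
        "cds": AlleleCatalog("cds", cds, "synthetic founder catalog"),
        "protein": AlleleCatalog("protein", prot, "synthetic founder catalog"),
        "utr3": AlleleCatalog("utr3", utr, "synthetic founder catalog"),
    }


# ----------------------------------------------------------------------
# fixture bundle I/O
# ----------------------------------------------------------------------


def write_fixture_bundle(
    bundle: FixtureBundle, out_dir: str | Path, overwrite: bool = False
) -> dict[str, str]:
    """Write VCF + reference FASTA + manifest + gene model + catalogs + truth
    to ``out_dir``; returns file -> sha256 map (also saved as checksums.json).
    Re-running with the same seed reproduces identical files."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    write_phased_vcf(bundle.cohort, out / "cohort.vcf")
    write_fasta({bundle.model.contig: bundle.reference}, out / "reference.fasta")
    bundle.cohort.manifest.write_tsv(out / "manifest.tsv")
    write_gene_model(bundle.model, out / "gene_model.json")
    for level, cat in bundle.catalogs.items():
        write_catalog(cat, out / f"catalog_{level}.fasta")
    (out / "truth.json").write_text(bundle.truth.to_json() + "\n")
    sums = {}
    for f in sorted(out.iterdir()):
        if f.name == "checksums.json":
            continue
        sums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "checksums.json").write_text(json.dumps(sums, indent=1) + "\n")
    return sums
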