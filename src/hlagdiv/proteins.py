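"""CDS splicing, allotype translation and functional-residue reporting.

HLA-G is remarkable for its low protein diversity: a handful of allotypes
dominate worldwide and the residues behind its receptor interactions — the
dimer-forming Cys42, the KIR2DL4 contacts Met76/Gln79, the ILT-2/ILT-4
contacts at 195/197 and the CD8-binding DQTQDVE motif at 223-229 (mature
numbering) — are expected to be invariant in full-length allotypes.  Null
alleles (frameshifts, e.g. the G*01:05N class) truncate the protein and lose
the membrane-distal motifs entirely; the report distinguishes "altered" from
"absent due to truncation" for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .cohort import PhasedCohort
from .genemodel import GeneModel
from .haplotypes import extract_haplotypes

# canonical receptor-interaction motifs, mature (post-signal-peptide) numbering
MOTIFS: dict[str, dict[int, str]] = {
    "dimer_cys": {42: "C"},
    "kir2dl4": {76: "M", 79: "Q"},
    "ilt2_ilt4": {195: "F", 197: "Y"},
    "cd8": {p: aa for p, aa in zip(range(223, 230), "DQTQDVE")},
}

INTACT, ALTERED, ABSENT = "intact", "altered", "absent-due-to-truncation"


@dataclass
class ProteinAllotype:
    name: str
    precursor: str  # translated sequence incl. signal peptide, no stop char
    mature: str
    truncated: bool
    stop_found_in_cds: bool
    events: list[tuple] = field(default_factory=list)


def splice_cds(cohort: PhasedCohort, reference: str, model: GeneModel,
               ref_offset: int = 0) -> list[str]:
    """Spliced CDS per haplotype copy: per-exon reconstruction concatenated
    in order, starting at the ATG in exon 1, over the coding exons only.

    Reconstructing exon-by-exon keeps exon boundaries anchored in reference
    coordinates, so indels inside an exon shift only that exon's length and a
    deletion spanning an exon/intron boundary is clipped at the boundary.
    """
    pieces: list[list[str]] = []
    for k, ex in enumerate(model.coding_exons):
        iv = ex
        if k == 0:
            if not ex.contains(model.atg_genomic):
                raise ValueError("ATG not inside exon 1")
            iv = type(ex)(ex.contig, model.atg_genomic, ex.end)
        pieces.append(
            extract_haplotypes(cohort, reference, iv, ref_offset=ref_offset)
        )
    strand_flip = model.strand == "-"
    cds = ["".join(parts) for parts in zip(*pieces)]
    if strand_flip:
        from .haplotypes import _revcomp

        cds = [_revcomp(s) for s in cds]
    return cds


def translate_cds(
    cds: str,
    signal_peptide_len: int = 24,
    canonical_aa_len: int | None = None,
    name: str = "",
) -> ProteinAllotype:
    """Translate a spliced CDS into an allotype.

    Standard genetic code; translation stops at the first stop codon, which is
    never emitted.  A frameshifted CDS (length not a multiple of 3) that
    reaches the end without a stop is flagged ``stop_found_in_cds=False`` and
    truncated-at-CDS-end — read-through past the last exon (intron retention)
    is reported as that flag rather than simulated.
    """
    cds = cds.upper()
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")
    events: list[tuple] = []
    if len(cds) % 3:
        events.append(("frameshift_cds_length_mod3", len(cds) % 3))
    n_codons = len(cds) // 3
    aas = []
    stop_found = False
    for k in range(n_codons):
        codon = cds[3 * k : 3 * k + 3]
        aa = str(Seq(codon).translate())
        if aa == "*":
            stop_found = True
            if canonical_aa_len is not None and k < canonical_aa_len:
                events.append(("premature_stop_at_codon", k + 1))
            break
        aas.append(aa)
    precursor = "".join(aas)
    if not stop_found:
        events.append(("no_stop_within_cds",))
    truncated = (not stop_found and bool(len(cds) % 3)) or (
        canonical_aa_len is not None and len(precursor) < canonical_aa_len
    )
    mature = precursor[signal_peptide_len:]
    if not mature and precursor:
        events.append(("mature_sequence_empty",))
    return ProteinAllotype(name, precursor, mature, truncated, stop_found, events)


def residue_report(
    allotype: ProteinAllotype, reference: ProteinAllotype
) -> dict:
    """Status of each functional motif plus the polymorphic residues relative
    to a designated reference allotype (mature numbering)."""
    mat = allotype.mature
    statuses: dict[str, str] = {}
    for motif, spec in MOTIFS.items():
        if any(p > len(mat) for p in spec):
            statuses[motif] = ABSENT
        elif all(mat[p - 1] == aa for p, aa in spec.items()):
            statuses[motif] = INTACT
        else:
            statuses[motif] = ALTERED
    poly = [
        (p + 1, reference.mature[p], mat[p])
        for p in range(min(len(mat), len(reference.mature)))
        if mat[p] != reference.mature[p]
    ]
    return {
        "allotype": allotype.name,
        "motifs": statuses,
        "polymorphic_residues": poly,
        "truncated": allotype.truncated,
    }
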