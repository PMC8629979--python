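"""Phased-cohort container and readers/writers for VCF, manifest and catalogs.

A :class:`PhasedCohort` holds the variant list and the 2N x M haplotype
allele-index matrix ``H`` (two rows per sample: copy A then copy B, in sample
order).  Genotypes must be phased and non-missing — the analyses downstream
(haplotype reconstruction, haplotype-counting LD) are only defined on fully
phased chromosomes, so unphased or missing calls are a hard load error rather
than something to impute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .genemodel import GenomicInterval

MANIFEST_COLUMNS = ["sample", "population", "country", "region"]


def classify_variant(ref: str, alts: list[str]) -> str:
    """SNP / indel / MNP / mixed, judged across all alternates."""
    kinds = set()
    for alt in alts:
        if len(ref) == 1 and len(alt) == 1:
            kinds.add("SNP")
        elif len(ref) != len(alt):
            kinds.add("indel")
        else:
            kinds.add("MNP")
    return kinds.pop() if len(kinds) == 1 else "mixed"


def _trim_normalize(pos: int, ref: str, alts: list[str]) -> tuple[int, str, list[str]]:
    """Right-trim then left-trim shared bases so every indel has one canonical
    (anchored) spelling; assumes input already follows the VCF left-alignment
    convention for placement."""
    ref_l, alts_l = ref, list(alts)
    while len(ref_l) > 1 and all(len(a) > 1 for a in alts_l) and all(
        a[-1] == ref_l[-1] for a in alts_l
    ):
        ref_l = ref_l[:-1]
        alts_l = [a[:-1] for a in alts_l]
    while len(ref_l) > 1 and all(len(a) > 1 for a in alts_l) and all(
        a[0] == ref_l[0] for a in alts_l
    ):
        ref_l = ref_l[1:]
        alts_l = [a[1:] for a in alts_l]
        pos += 1
    return pos, ref_l, alts_l


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    pos: int  # 0-based
    id: str
    ref: str
    alts: tuple[str, ...]
    type: str = ""

    def __post_init__(self) -> None:
        if any(a == self.ref for a in self.alts):
            raise ValueError(f"alt equals ref at {self.contig}:{self.pos}")
        if not self.type:
            object.__setattr__(self, "type", classify_variant(self.ref, list(self.alts)))

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def allele(self, idx: int) -> str:
        return self.ref if idx == 0 else self.alts[idx - 1]


@dataclass
class SampleManifest:
    """sample -> population / country / biogeographic region."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in manifest")
        self.table = self.table[MANIFEST_COLUMNS].reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    def group_of(self, grouping: str) -> dict[str, str]:
        """Map sample id -> group label for grouping in
        {'global','region','country','population'}."""
        if grouping == "global":
            return {s: "GLOBAL" for s in self.samples}
        if grouping not in {"region", "country", "population"}:
            raise ValueError(f"unknown grouping {grouping!r}")
        return dict(zip(self.table["sample"], self.table[grouping]))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleManifest":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class PhasedCohort:
    variants: list[VariantRecord]
    samples: list[str]
    H: np.ndarray  # (2N, M) allele indices
    manifest: SampleManifest

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.int16)
        if self.H.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError(
                f"H shape {self.H.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if (self.H < 0).any():
            raise ValueError("negative allele index (missing genotype?)")
        for j, v in enumerate(self.variants):
            if self.H[:, j].max(initial=0) >= v.n_alleles:
                raise ValueError(f"allele index out of range at variant {j}")
        known = set(self.manifest.samples)
        absent = [s for s in self.samples if s not in known]
        if absent:
            raise ValueError(f"samples absent from manifest: {absent[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_copies(self) -> int:
        return 2 * len(self.samples)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def copy_labels(self) -> list[str]:
        """Haplotype-copy labels, '<sample>_A' / '<sample>_B' in row order."""
        return [f"{s}_{c}" for s in self.samples for c in ("A", "B")]

    def sites_in(self, interval: GenomicInterval) -> np.ndarray:
        pos = self.positions
        return np.nonzero((pos >= interval.start) & (pos < interval.end))[0]

    def genotype_counts(self, site: int, rows: np.ndarray | None = None):
        """(hom-ref, het, hom-alt) diploid counts at a bi-allelic site."""
        col = self.H[:, site] if rows is None else self.H[rows, site]
        a, b = col[0::2], col[1::2]
        return (
            int(((a == 0) & (b == 0)).sum()),
            int((a != b).sum()),
            int(((a != 0) & (b != 0) & (a == b)).sum()),
        )


def read_phased_vcf(
    path: str | Path,
    interval: GenomicInterval | None = None,
    manifest: SampleManifest | None = None,
) -> PhasedCohort:
    """Load a phased diploid VCF into a :class:`PhasedCohort`.

    Multi-allelic records are preserved un-split; indel spellings are
    trim-normalized so each indel has a single canonical representation.
    Unphased ("/") or missing genotypes raise.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if manifest is None:
        manifest = SampleManifest(
            pd.DataFrame(
                {
                    "sample": samples,
                    "population": "NA",
                    "country": "NA",
                    "region": "NA",
                }
            )
        )
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:  # full scan: plain-text VCFs carry no tabix index
        if interval is not None and not (
            rec.CHROM == interval.contig and interval.contains(rec.POS - 1)
        ):
            continue
        gts = rec.genotypes  # [[a, b, phased], ...]
        col = np.empty(2 * len(samples), dtype=np.int16)
        for i, g in enumerate(gts):
            if len(g) < 3:
                raise ValueError(f"non-diploid genotype at {rec.CHROM}:{rec.POS}")
            a, b, phased = g[0], g[1], g[-1]
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}")
            if not phased:
                raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
            col[2 * i] = a
            col[2 * i + 1] = b
        pos0, ref, alts = _trim_normalize(rec.POS - 1, rec.REF, list(rec.ALT))
        variants.append(
            VariantRecord(rec.CHROM, pos0, rec.ID or ".", ref, tuple(alts))
        )
        columns.append(col)
    H = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(samples), 0), dtype=np.int16)
    )
    return PhasedCohort(variants, samples, H, manifest)


def write_phased_vcf(cohort: PhasedCohort, path: str | Path) -> None:
    """Write the cohort back to a plain-text phased VCF 4.2."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    contigs = sorted({v.contig for v in cohort.variants})
    lines += [f"##contig=<ID={c}>" for c in contigs]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + cohort.samples))
    order = np.argsort([v.pos for v in cohort.variants], kind="stable")
    for j in order:
        v = cohort.variants[j]
        col = cohort.H[:, j]
        gts = [f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(cohort.n_samples)]
        lines.append(
            "\t".join(
                [v.contig, str(v.pos + 1), v.id, v.ref, ",".join(v.alts), ".", "PASS", ".", "GT"]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class AlleleCatalog:
    """Known sequences at one resolution level, for exact-match naming."""

    level: str
    entries: dict[str, str] = field(default_factory=dict)  # name -> sequence
    provenance: str = ""

    LEVELS = ("full", "cds", "protein", "utr3")

    def __post_init__(self) -> None:
        if self.level not in self.LEVELS:
            raise ValueError(f"unknown catalog level {self.level!r}")
        self.entries = {n: s.upper() for n, s in self.entries.items()}
        seen: dict[str, str] = {}
        for name, seq in self.entries.items():
            if seq in seen:
                raise ValueError(
                    f"duplicate sequence for {seen[seq]!r} and {name!r} at level {self.level}"
                )
            seen[seq] = name
        self._by_seq = seen

    def __len__(self) -> int:
        return len(self.entries)

    def name_of(self, seq: str) -> str | None:
        return self._by_seq.get(seq.upper())


def load_catalog(path: str | Path, level: str, provenance: str = "") -> AlleleCatalog:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty catalog FASTA: {path}")
    entries: dict[str, str] = {}
    for rec in records:
        name = rec.id
        if name in entries:
            raise ValueError(f"duplicate catalog name {name!r}")
        entries[name] = str(rec.seq).upper()
    return AlleleCatalog(level, entries, provenance or str(path))


def write_catalog(catalog: AlleleCatalog, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in catalog.entries.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()],
        str(path),
        "fasta",
    )
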