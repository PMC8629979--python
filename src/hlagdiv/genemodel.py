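"""Gene model and ATG-anchored coordinate system.

The locus is described in an ATG-relative frame, the convention used for
HLA genes: position +1 is the A of the first translated ATG, position -1 is
the base immediately upstream, and there is no position 0.  Internally all
arithmetic is 0-based half-open genomic; the relative frame is used only at
I/O and reporting boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based, half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """Exon/intron/promoter/UTR structure anchored at the translated ATG.

    Parameters
    ----------
    contig : str
        Contig name shared by all features.
    strand : str
        "+" or "-".  Minus-strand support is limited to reverse-complementing
        at sequence-extraction time; coordinates stay forward-strand.
    atg_genomic : int
        0-based genomic position of the A of the first translated ATG.
    exons : list of GenomicInterval
        Non-overlapping, sorted 5'->3' (i.e. by genomic position on "+").
    promoter_upstream_bp : int
        Promoter length upstream of exon 1 (default 4328).
    downstream_bp : int
        Analysed flank downstream of the last exon (default 100).
    n_coding_exons : int
        Number of leading exons that carry CDS (the stop codon lies in the
        last of these); trailing exons are untranslated.
    """

    contig: str
    strand: str
    atg_genomic: int
    exons: list[GenomicInterval]
    promoter_upstream_bp: int = 4328
    downstream_bp: int = 100
    n_coding_exons: int = 6
    features: dict[str, GenomicInterval] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        exs = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(exs, exs[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping exons: {a} / {b}")
            if a.end == b.start:
                raise ValueError(f"abutting exons leave no intron: {a} / {b}")
        self.exons = exs
        if not exs[0].contains(self.atg_genomic):
            raise ValueError("ATG anchor must lie inside exon 1")
        if not 1 <= self.n_coding_exons <= len(exs):
            raise ValueError("n_coding_exons out of range")
        self._build_features()

    def _build_features(self) -> None:
        f: dict[str, GenomicInterval] = {}
        for i, ex in enumerate(self.exons, start=1):
            f[f"exon{i}"] = ex
        for i, (a, b) in enumerate(zip(self.exons, self.exons[1:]), start=1):
            f[f"intron{i}"] = GenomicInterval(self.contig, a.end, b.start)
        first, last = self.exons[0], self.exons[-1]
        f["promoter"] = GenomicInterval(
            self.contig, first.start - self.promoter_upstream_bp, first.start
        )
        f["utr3"] = last  # the post-stop sequence of earlier exons carries no variation
        self.features = f

    # -- derived bounds ------------------------------------------------

    @property
    def interval(self) -> GenomicInterval:
        """Full analysis interval: promoter through downstream flank."""
        return GenomicInterval(
            self.contig,
            self.features["promoter"].start,
            self.exons[-1].end + self.downstream_bp,
        )

    @property
    def last_exon_end_rel(self) -> int:
        """ATG-relative position of the last transcribed base."""
        return self.to_relative(self.exons[-1].end - 1)

    @property
    def coding_exons(self) -> list[GenomicInterval]:
        return self.exons[: self.n_coding_exons]

    # -- coordinate frame ----------------------------------------------

    def to_relative(self, pos: int) -> int:
        """Genomic 0-based -> ATG-relative (+1 at ATG, no zero)."""
        if not self.interval.contains(pos):
            raise ValueError(f"position {pos} outside analysis interval")
        off = pos - self.atg_genomic
        return off + 1 if off >= 0 else off

    def to_genomic(self, rel: int) -> int:
        """ATG-relative -> genomic 0-based; inverse of :meth:`to_relative`."""
        if rel == 0:
            raise ValueError("ATG-relative coordinates have no position 0")
        pos = self.atg_genomic + (rel - 1 if rel > 0 else rel)
        if not self.interval.contains(pos):
            raise ValueError(f"relative position {rel} outside analysis interval")
        return pos

    def feature_of(self, pos: int) -> str | None:
        """Name of the most specific feature containing ``pos`` (exons/introns
        before promoter), or None for flanking sequence."""
        for name, iv in self.features.items():
            if name != "utr3" and iv.contains(pos):
                return name
        return None


def load_gene_model(path: str | Path) -> GeneModel:
    """Load a gene model from its JSON description.

    The file declares ``contig``, ``strand``, ``atg_genomic``, ``exons`` (list
    of [start, end) pairs) and optionally the promoter/downstream extents and
    the number of coding exons.  Introns, the promoter interval and the 3'UTR
    feature are derived, never stored.
    """
    with open(path) as fh:
        d = json.load(fh)
    try:
        exons = [GenomicInterval(d["contig"], s, e) for s, e in d["exons"]]
        return GeneModel(
            contig=d["contig"],
            strand=d["strand"],
            atg_genomic=int(d["atg_genomic"]),
            exons=exons,
            promoter_upstream_bp=int(d.get("promoter_upstream_bp", 4328)),
            downstream_bp=int(d.get("downstream_bp", 100)),
            n_coding_exons=int(d.get("n_coding_exons", 6)),
        )
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"gene model file missing field {exc}") from exc


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    d = {
        "contig": model.contig,
        "strand": model.strand,
        "atg_genomic": model.atg_genomic,
        "exons": [[iv.start, iv.end] for iv in model.exons],
        "promoter_upstream_bp": model.promoter_upstream_bp,
        "downstream_bp": model.downstream_bp,
        "n_coding_exons": model.n_coding_exons,
    }
    Path(path).write_text(json.dumps(d, indent=1) + "\n")
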