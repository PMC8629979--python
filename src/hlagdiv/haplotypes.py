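"""Per-chromosome sequence reconstruction, naming and frequency tables.

Haplotype copies are rebuilt by substituting each copy's alleles into the
reference over a feature interval, then named against a catalog of known
sequences (exact string identity, the convention used for HLA allele
assignment); sequences absent from the catalog receive deterministic novel
names ordered by descending global count.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AlleleCatalog, PhasedCohort, SampleManifest
from .genemodel import GenomicInterval


@dataclass
class NamedHaplotype:
    level: str
    name: str
    sequence: str
    global_count: int
    carriers: list[int] = field(default_factory=list)  # haplotype-copy row indices

    def __post_init__(self) -> None:
        if self.global_count != len(self.carriers):
            raise ValueError("count does not match carrier list")


def extract_haplotypes(
    cohort: PhasedCohort,
    reference: str,
    feature: GenomicInterval,
    ref_offset: int = 0,
    revcomp: bool = False,
) -> list[str]:
    """Rebuild every haplotype copy's sequence over ``feature``.

    ``reference`` is the forward-strand sequence starting at genomic
    coordinate ``ref_offset``.  Alleles are substituted right-to-left so
    earlier coordinates stay valid through indels.  A variant whose ref
    span crosses the feature end is clipped at the boundary (conservative
    handling of boundary-spanning deletions).

    Returns one uppercase sequence per haplotype copy, in row order.
    """
    s0 = feature.start - ref_offset
    e0 = feature.end - ref_offset
    if s0 < 0 or e0 > len(reference):
        raise ValueError("reference does not cover the feature")
    ref_feat = reference[s0:e0].upper()

    pos = cohort.positions
    idx = np.nonzero((pos >= feature.start) & (pos < feature.end))[0]
    # apply right-to-left
    idx = idx[np.argsort(pos[idx])][::-1]
    for j in idx:  # consistency check: VCF ref alleles must match the FASTA
        v = cohort.variants[j]
        p = v.pos - ref_offset
        if reference[p : p + len(v.ref)].upper() != v.ref.upper():
            raise ValueError(
                f"variant ref {v.ref!r} at {v.contig}:{v.pos} mismatches reference"
            )

    out: list[str] = []
    H = cohort.H
    for row in range(cohort.n_copies):
        seq = ref_feat
        last_start = len(ref_feat) + 1  # leftmost position already rewritten
        for j in idx:
            a = int(H[row, j])
            if a == 0:
                continue
            v = cohort.variants[j]
            off = v.pos - feature.start
            ref_len = min(len(v.ref), len(ref_feat) - off)  # clip at boundary
            if off + len(v.ref) > last_start:
                raise ValueError(
                    f"overlapping ref spans within one copy at {v.contig}:{v.pos}"
                )
            seq = seq[:off] + v.allele(a).upper() + seq[off + ref_len :]
            last_start = off
        out.append(seq if not revcomp else _revcomp(seq))
    return out


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


def name_haplotypes(
    seqs: list[str],
    catalog: AlleleCatalog | None,
    novel_prefix: str = "NOVEL-",
) -> tuple[list[str], list[NamedHaplotype]]:
    """Assign catalog names by exact sequence identity; number novel sequences
    ``prefix1, prefix2, ...`` by decreasing global count, ties broken by
    lexicographic sequence order (deterministic and sample-order invariant).

    Returns (name per copy, inventory sorted by descending count).
    """
    seqs = [s.upper() for s in seqs]
    counts = Counter(seqs)
    level = catalog.level if catalog is not None else "full"
    named: dict[str, str] = {}
    novel = []
    for seq in counts:
        cat_name = catalog.name_of(seq) if catalog is not None else None
        if cat_name is not None:
            named[seq] = cat_name
        else:
            novel.append(seq)
    novel.sort(key=lambda s: (-counts[s], s))
    for k, seq in enumerate(novel, start=1):
        named[seq] = f"{novel_prefix}{k}"

    carriers: dict[str, list[int]] = defaultdict(list)
    for row, seq in enumerate(seqs):
        carriers[seq].append(row)
    inventory = [
        NamedHaplotype(level, named[seq], seq, counts[seq], carriers[seq])
        for seq in sorted(counts, key=lambda s: (-counts[s], s))
    ]
    return [named[s] for s in seqs], inventory


def frequency_table(
    names: list[str],
    manifest: SampleManifest,
    samples: list[str],
    level: str,
    grouping: str = "global",
    min_individuals: int = 10,
) -> pd.DataFrame:
    """Haplotype frequencies per group (over 2N allele copies).

    Columns: group, name, count, two_n, frequency, group_passes_min_n.
    Groups of any size are included; ``group_passes_min_n`` marks groups with
    at least ``min_individuals`` sampled individuals, the usual reporting
    filter for small population samples.
    """
    if len(names) != 2 * len(samples):
        raise ValueError("need one name per haplotype copy (2 per sample)")
    gmap = manifest.group_of(grouping)
    rows = []
    group_per_copy = []
    for s in samples:
        if s not in gmap:
            raise ValueError(f"sample {s} has no group under {grouping!r}")
        group_per_copy += [gmap[s], gmap[s]]
    df = pd.DataFrame({"group": group_per_copy, "name": names})
    sizes = df.groupby("group").size()
    for (group, name), count in df.groupby(["group", "name"]).size().items():
        two_n = int(sizes[group])
        rows.append(
            {
                "group": group,
                "name": name,
                "count": int(count),
                "two_n": two_n,
                "frequency": count / two_n,
                "group_passes_min_n": two_n >= 2 * min_individuals,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["group", "count", "name"], ascending=[True, False, True]
    )
    return out.reset_index(drop=True)


def associate_allele_utr(
    cds_names: list[str],
    utr_names: list[str],
    min_pair_count: int = 2,
) -> pd.DataFrame:
    """Coding-allele <-> 3'UTR-haplotype association table.

    For every (allele, UTR) pair seen on the same chromosome:
    ``global_frequency`` = pair count / total copies, and
    ``internal_frequency`` = pair count / allele count — the fraction of the
    allele's chromosomes that carry that particular 3'UTR.  Internal
    denominators are taken over ALL partners; only then are rows with a pair
    count below ``min_pair_count`` dropped, so printed internal frequencies
    need not sum exactly to 1 across retained rows.
    """
    if len(cds_names) != len(utr_names):
        raise ValueError("allele and UTR namings cover different copy sets")
    total = len(cds_names)
    pair_counts = Counter(zip(cds_names, utr_names))
    allele_counts = Counter(cds_names)
    rows = []
    for (allele, utr), c in pair_counts.items():
        if c < min_pair_count:
            continue
        rows.append(
            {
                "allele": allele,
                "utr": utr,
                "pair_count": c,
                "global_frequency": c / total,
                "internal_frequency": c / allele_counts[allele],
            }
        )
    out = pd.DataFrame(
        rows, columns=["allele", "utr", "pair_count", "global_frequency", "internal_frequency"]
    )
    if len(out):
        out = out.sort_values(
            ["allele", "pair_count", "utr"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return out


def variant_inventory(
    cohort: PhasedCohort,
    feature: GenomicInterval | None = None,
    frequency_threshold: float = 0.01,
) -> tuple[int, int, pd.DataFrame]:
    """Count variants and polymorphisms (minor-allele frequency strictly above
    ``frequency_threshold``) in a feature.

    Returns (total variants, polymorphic variants, per-variant table with
    alt-allele and minor-allele frequencies).
    """
    idx = (
        np.arange(len(cohort.variants))
        if feature is None
        else cohort.sites_in(feature)
    )
    n = cohort.n_copies
    rows = []
    for j in idx:
        v = cohort.variants[j]
        col = cohort.H[:, j]
        alt_freq = float((col != 0).sum()) / n
        counts = np.bincount(col, minlength=v.n_alleles)
        maf = 1.0 - counts.max() / n if n else 0.0
        rows.append(
            {
                "pos": v.pos,
                "id": v.id,
                "type": v.type,
                "alt_frequency": alt_freq,
                "minor_allele_frequency": maf,
                "polymorphic": maf > frequency_threshold,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["pos", "id", "type", "alt_frequency", "minor_allele_frequency", "polymorphic"],
    )
    n_poly = int(table["polymorphic"].sum()) if len(table) else 0
    return len(table), n_poly, table
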