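"""Pairwise linkage disequilibrium, complete-LD groups, tag-SNP selection.

The cohort is fully phased, so two-locus haplotype frequencies are counted
directly (no EM step); this is also why D' = 1 is exact whenever one of the
four haplotype classes is absent.  Only bi-allelic SNPs enter LD analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PhasedCohort
from .diversity import hwe_exact
from .genemodel import GenomicInterval

COMPLETE_LD_EPS = 1e-12


def ld_site_filter(
    cohort: PhasedCohort,
    maf_min: float = 0.01,
    hwe_alpha: float = 0.05,
    hwe_bonferroni: bool = True,
    biallelic_only: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sites eligible for LD analysis: bi-allelic SNPs with minor allele
    frequency strictly above ``maf_min`` that fit Hardy-Weinberg in the
    pooled sample (exact test, Bonferroni across tested sites by default).

    Returns (index array, per-site provenance table)."""
    n = cohort.n_copies
    rows = []
    candidates = []
    for j, v in enumerate(cohort.variants):
        reason = ""
        if biallelic_only and (len(v.alts) != 1 or v.type != "SNP"):
            reason = "not-biallelic-snp"
        else:
            maf = min((cohort.H[:, j] != 0).mean(), (cohort.H[:, j] == 0).mean())
            if not maf > maf_min:
                reason = "maf"
        rows.append({"site": j, "pos": v.pos, "excluded_by": reason})
        if not reason:
            candidates.append(j)
    hwe_p = {j: hwe_exact(*cohort.genotype_counts(j)) for j in candidates}
    thr = hwe_alpha / len(candidates) if (hwe_bonferroni and candidates) else hwe_alpha
    keep = []
    for j in candidates:
        if hwe_p[j] < thr:
            rows[j]["excluded_by"] = "hwe"
        else:
            keep.append(j)
    prov = pd.DataFrame(rows)
    prov["kept"] = prov["excluded_by"] == ""
    return np.array(keep, dtype=int), prov


def pairwise_ld(cohort: PhasedCohort, sites: np.ndarray) -> pd.DataFrame:
    """D, D' and r^2 for every site pair, by direct haplotype counting.

    D = p_AB - p_A p_B; D' = D / D_max with the sign-aware D_max; r^2 =
    D^2 / (p_A q_A p_B q_B).  Raises if any input site is monomorphic.
    """
    sites = np.asarray(sites, dtype=int)
    X = (cohort.H[:, sites] != 0).astype(float)  # alt-carrier indicator
    n = X.shape[0]
    p = X.mean(axis=0)
    if np.any((p == 0) | (p == 1)):
        bad = sites[(p == 0) | (p == 1)]
        raise ValueError(f"monomorphic site(s) in LD input: {bad.tolist()}")
    P = (X.T @ X) / n  # joint alt-alt frequencies
    rows = []
    m = len(sites)
    for a in range(m):
        for b in range(a + 1, m):
            pa, pb = p[a], p[b]
            D = P[a, b] - pa * pb
            if D > 0:
                dmax = min(pa * (1 - pb), (1 - pa) * pb)
            elif D < 0:
                dmax = min(pa * pb, (1 - pa) * (1 - pb))
            else:
                dmax = 1.0  # D' defined as 0 when D = 0
            dprime = D / dmax if dmax > 0 else 0.0
            r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
            rows.append(
                {
                    "i": int(sites[a]),
                    "j": int(sites[b]),
                    "pos_i": int(cohort.variants[sites[a]].pos),
                    "pos_j": int(cohort.variants[sites[b]].pos),
                    "D": D,
                    "Dprime": dprime,
                    "r2": r2,
                }
            )
    return pd.DataFrame(rows, columns=["i", "j", "pos_i", "pos_j", "D", "Dprime", "r2"])


def complete_ld_groups(
    pairs: pd.DataFrame,
    sites: np.ndarray,
    r2_exact: float = 1.0 - COMPLETE_LD_EPS,
) -> list[list[int]]:
    """Partition sites into connected components of the r^2 >= r2_exact graph
    (singletons allowed); groups sorted by first site index."""
    parent = {int(s): int(s) for s in sites}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, row in pairs.iterrows():
        if row["r2"] >= r2_exact:
            ra, rb = find(int(row["i"])), find(int(row["j"]))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[int]] = {}
    for s in sorted(parent):
        groups.setdefault(find(s), []).append(s)
    return [groups[k] for k in sorted(groups)]


@dataclass
class TagSet:
    threshold: float
    tags: list[int]
    cover: dict[int, int]  # site -> its tag
    uncovered: list[int] = field(default_factory=list)

    def verify(self, pairs: pd.DataFrame) -> bool:
        """Independently re-check the cover: every covered non-tag site must
        exceed the threshold with its tag; tags cover themselves."""
        r2 = {}
        for _, row in pairs.iterrows():
            key = frozenset((int(row["i"]), int(row["j"])))
            r2[key] = row["r2"]
        for site, tag in self.cover.items():
            if site == tag:
                continue
            if r2.get(frozenset((site, tag)), 0.0) <= self.threshold:
                return False
        return True


def greedy_tag_selection(
    pairs: pd.DataFrame,
    sites: np.ndarray,
    positions: dict[int, int] | None = None,
    r2_threshold: float = 0.95,
) -> TagSet:
    """Greedy set-cover tag selection: repeatedly pick the site covering the
    most uncovered sites (r^2 strictly above threshold; ties broken by lower
    genomic position, then site index), until all sites are covered."""
    sites = [int(s) for s in sites]
    adj: dict[int, set[int]] = {s: {s} for s in sites}
    for _, row in pairs.iterrows():
        if row["r2"] > r2_threshold:
            a, b = int(row["i"]), int(row["j"])
            adj[a].add(b)
            adj[b].add(a)
    pos = positions or {s: s for s in sites}
    uncovered = set(sites)
    tags: list[int] = []
    cover: dict[int, int] = {}
    while uncovered:
        best = min(
            uncovered | set(sites),
            key=lambda s: (-len(adj[s] & uncovered), pos[s], s),
        )
        newly = adj[best] & uncovered
        if not newly:
            break  # unreachable: every site covers itself
        tags.append(best)
        for s in newly:
            cover[s] = best
        uncovered -= newly
    return TagSet(r2_threshold, tags, cover, sorted(uncovered))


def multiblock_ld(
    cohort: PhasedCohort,
    blocks: list[GenomicInterval],
    mask: set[int] | None = None,
    maf_min: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LD across several disjoint genomic blocks with positions in ``mask``
    removed (e.g. sites coinciding with known structural variants).
    Inter-block pairs are included.  Returns (pair table, site/block table).
    """
    for a, b in zip(blocks, blocks[1:]):
        if a.overlaps(b) or a.start >= b.start:
            raise ValueError("blocks must be disjoint and sorted")
    mask = mask or set()
    sites = []
    meta = []
    for bi, block in enumerate(blocks):
        for j in cohort.sites_in(block):
            v = cohort.variants[j]
            if v.pos in mask or len(v.alts) != 1 or v.type != "SNP":
                continue
            maf = min((cohort.H[:, j] != 0).mean(), (cohort.H[:, j] == 0).mean())
            if maf > maf_min:
                sites.append(int(j))
                meta.append({"site": int(j), "pos": v.pos, "block": bi})
    site_table = pd.DataFrame(meta, columns=["site", "pos", "block"])
    pairs = (
        pairwise_ld(cohort, np.array(sites, dtype=int))
        if len(sites) >= 2
        else pd.DataFrame(columns=["i", "j", "pos_i", "pos_j", "D", "Dprime", "r2"])
    )
    if len(pairs):
        blk = dict(zip(site_table["site"], site_table["block"]))
        pairs["block_i"] = pairs["i"].map(blk)
        pairs["block_j"] = pairs["j"].map(blk)
    return pairs, site_table
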