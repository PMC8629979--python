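"""Nei-Gojobori (1986-style) synonymous/nonsynonymous analysis with
codon-based Z-tests of selection.

Per codon, the potential synonymous sites are the expected fraction of the
nine single-base neighbours that preserve the amino acid (changes to stop
codons count as nonsynonymous, so S + N = 3 per codon exactly).  Observed
differences between codons differing at k positions are averaged over all k!
mutational pathways; pathways passing through a stop codon are excluded, and
a codon pair whose pathways all pass through stops is skipped entirely.

Distances are Jukes-Cantor-corrected proportions; the variance of dN - dS is
estimated by bootstrap over codon columns, and the Z statistic is referred to
a standard normal.  Three alternatives are supported: neutrality (two-tailed),
positive selection dN > dS and purifying selection dN < dS (one-tailed upper;
by convention p = 1 when the test statistic is non-positive).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import norm

BASES = "ACGT"
_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"


def _aa(codon: str) -> str:
    try:
        return _CODON_AA[codon]
    except KeyError as exc:
        raise ValueError(f"ambiguous or invalid codon {codon!r}") from exc


@lru_cache(maxsize=None)
def codon_syn_sites(codon: str) -> float:
    """Potential synonymous sites of a codon (0..3)."""
    aa = _aa(codon)
    if aa == "*":
        raise ValueError(f"internal stop codon {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _aa(mut) == aa:  # stop targets count as nonsynonymous
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def codon_pair_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all orderings of the changes; None if every pathway hits a stop."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return (0.0, 0.0)
    if _aa(c1) == "*" or _aa(c2) == "*":
        raise ValueError("stop codon in sequence")
    sd = nd = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*" and nxt != c2:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if not ok or _aa(cur) == "*":
            continue
        n_paths += 1
        for a, b in steps:
            if _aa(a) == _aa(b):
                sd += 1
            else:
                nd += 1
    if n_paths == 0:
        return None
    return (sd / n_paths, nd / n_paths)


@dataclass
class CodonCounts:
    S_sites: float
    N_sites: float
    S_d: float
    N_d: float
    codons_used: int = 0
    codons_skipped: int = 0

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(
            self.S_sites + other.S_sites,
            self.N_sites + other.N_sites,
            self.S_d + other.S_d,
            self.N_d + other.N_d,
            self.codons_used + other.codons_used,
            self.codons_skipped + other.codons_skipped,
        )


def _split_codons(seq: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def ng86_codon(c1: str, c2: str) -> CodonCounts | None:
    """Counts for one aligned codon pair; None when skipped (gaps, or all
    pathways through stops)."""
    if "-" in c1 or "-" in c2:
        return None
    d = codon_pair_diffs(c1, c2)
    if d is None:
        return None
    s_sites = (codon_syn_sites(c1) + codon_syn_sites(c2)) / 2.0
    return CodonCounts(s_sites, 3.0 - s_sites, d[0], d[1], codons_used=1)


def ng86_pairwise(seq_a: str, seq_b: str) -> CodonCounts:
    """Pathway-averaged synonymous/nonsynonymous sites and differences
    between two equal-length, in-frame coding sequences."""
    ca, cb = _split_codons(seq_a), _split_codons(seq_b)
    if len(ca) != len(cb):
        raise ValueError("sequence length mismatch")
    total = CodonCounts(0.0, 0.0, 0.0, 0.0)
    for c1, c2 in zip(ca, cb):
        cc = ng86_codon(c1, c2)
        if cc is None:
            total.codons_skipped += 1
            continue
        total = total + cc
    return total


def jukes_cantor(p: float) -> float:
    """JC69 distance for a proportion of differences; saturates at p >= 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise ValueError(f"saturated proportion p={p:.4f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _per_codon_pair_totals(seqs: list[str]) -> np.ndarray:
    """(C, 4) array of [S_d, N_d, S_sites, N_sites] summed over all C(n,2)
    pairs, per codon column.  Skipped codon pairs contribute zeros."""
    codon_lists = [_split_codons(s) for s in seqs]
    C = len(codon_lists[0])
    if any(len(cl) != C for cl in codon_lists):
        raise ValueError("sequence length mismatch")
    T = np.zeros((C, 4))
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(C):
                cc = ng86_codon(codon_lists[i][k], codon_lists[j][k])
                if cc is None:
                    continue
                T[k, 0] += cc.S_d
                T[k, 1] += cc.N_d
                T[k, 2] += cc.S_sites
                T[k, 3] += cc.N_sites
    return T


def _d_from_totals(t: np.ndarray) -> tuple[float, float]:
    """(d_N, d_S) from summed [S_d, N_d, S_sites, N_sites]."""
    if t[2] <= 0 or t[3] <= 0:
        raise ValueError("no countable sites")
    return jukes_cantor(t[1] / t[3]), jukes_cantor(t[0] / t[2])


def dnds_estimates(seqs: list[str]) -> tuple[float, float]:
    """(d_N, d_S): proportions pooled over all sequence pairs (ratio of the
    pair-averaged differences to pair-averaged sites), JC-corrected."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    T = _per_codon_pair_totals(seqs)
    return _d_from_totals(T.sum(axis=0))


@dataclass
class DnDsResult:
    alternative: str
    d_N: float
    d_S: float
    z: float
    p_value: float
    variance_method: str
    bootstrap_reps: int
    n_sequences: int
    n_codons: int
    flagged: str = ""


def codon_z_test(
    seqs: list[str],
    alternative: str = "neutral",
    bootstrap_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> DnDsResult:
    """Codon-based Z-test of dN vs dS.

    alternative: 'neutral' (two-tailed), 'positive' (dN > dS, one-tailed) or
    'purifying' (dN < dS, one-tailed).  For the one-tailed tests p = 1.0 when
    the corresponding statistic is non-positive.  SE(dN - dS) comes from
    resampling codon columns with replacement.
    """
    if alternative not in {"neutral", "positive", "purifying"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    C = len(seqs[0]) // 3
    if C < 10:
        raise ValueError("need at least 10 codons")
    rng = np.random.default_rng(rng)
    T = _per_codon_pair_totals(seqs)
    d_N, d_S = _d_from_totals(T.sum(axis=0))

    idx = rng.integers(0, C, size=(bootstrap_reps, C))
    sums = T[idx].sum(axis=1)  # (B, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        pN = np.where(sums[:, 3] > 0, sums[:, 1] / sums[:, 3], np.nan)
        pS = np.where(sums[:, 2] > 0, sums[:, 0] / sums[:, 2], np.nan)
        ok = (pN < 0.75) & (pS < 0.75) & ~np.isnan(pN) & ~np.isnan(pS)
        reps = -0.75 * (np.log1p(-4 * pN[ok] / 3) - np.log1p(-4 * pS[ok] / 3))
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0

    flagged = ""
    if se == 0.0 or not math.isfinite(se):
        flagged = "zero-variance bootstrap; p undefined"
        z = math.nan
        p = math.nan
    else:
        z = (d_N - d_S) / se
        if alternative == "neutral":
            p = 2.0 * float(norm.sf(abs(z)))
        elif alternative == "positive":
            p = 1.0 if z <= 0 else float(norm.sf(z))
        else:  # purifying: statistic is (d_S - d_N)/SE = -z
            z = -z
            p = 1.0 if z <= 0 else float(norm.sf(z))
    return DnDsResult(
        alternative,
        d_N,
        d_S,
        z,
        p,
        "codon-bootstrap",
        bootstrap_reps,
        len(seqs),
        C,
        flagged,
    )
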