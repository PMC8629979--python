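"""Nucleotide diversity, Tajima's D, sliding windows, empirical nulls, HWE.

Statistics follow the classic sample formulas on phased haplotype copies:

* S — count of segregating (polymorphic) columns;
* pi — mean pairwise difference, computed per site as n/(n-1) * (1 - sum p_a^2)
  and summed (identical to averaging Hamming distances over all C(n,2) pairs);
* Tajima's D — (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard
  coefficients; undefined (signalled, never 0) when S = 0 since the variance
  term vanishes.

Indels and multi-allelic sites each count as a single segregating site and
enter pi through the multi-allele frequency formula.

Significance of locus-wide scans is judged against an *empirical* null:
the same statistics in random windows drawn from a large background region,
summarised by nearest-rank quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PhasedCohort, SampleManifest
from .genemodel import GeneModel, GenomicInterval


@dataclass(frozen=True)
class TajimaCoefficients:
    """Constants of the D statistic for a sample of n haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaCoefficients":
        if n < 2:
            raise ValueError("need n >= 2")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        return cls(n, a1, a2, b1, b2, c1, c2, c1 / a1, c2 / (a1**2 + a2))


def segregating_sites(H: np.ndarray) -> int:
    """Number of columns with at least two distinct alleles."""
    H = np.asarray(H)
    if H.size == 0:
        return 0
    return int(np.sum(np.any(H != H[0], axis=0)))


def per_site_pi(H: np.ndarray) -> np.ndarray:
    """Per-column contribution to pi: n/(n-1) * (1 - sum_a p_a^2)."""
    H = np.asarray(H)
    n, m = H.shape
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    out = np.zeros(m)
    for j in range(m):
        counts = np.bincount(H[:, j].astype(np.int64))
        p = counts / n
        out[j] = (n / (n - 1)) * (1.0 - float(np.sum(p**2)))
    return out


def nucleotide_diversity(H: np.ndarray, span_bp: int) -> tuple[float, float]:
    """(pi_total, pi_per_site) over a region of ``span_bp`` bases."""
    pi_total = float(per_site_pi(H).sum()) if np.asarray(H).shape[1] else 0.0
    return pi_total, pi_total / span_bp


def tajimas_d(n: int, S: int, pi_total: float) -> float:
    """Tajima's D; raises for S = 0 (undefined, not zero)."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 1:
        raise ValueError("Tajima's D undefined when S = 0")
    c = TajimaCoefficients.for_n(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (pi_total - S / c.a1) / math.sqrt(var)


def _window_stats(
    positions: np.ndarray,
    site_pi: np.ndarray,
    n: int,
    starts: np.ndarray,
    window: int,
) -> pd.DataFrame:
    """S, pi and D for many windows via prefix sums over sorted sites."""
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    pis = site_pi[order]
    cum_pi = np.concatenate([[0.0], np.cumsum(pis)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    S = (hi - lo).astype(int)
    pi_tot = cum_pi[hi] - cum_pi[lo]
    D = np.full(len(starts), np.nan)
    for i in range(len(starts)):
        if S[i] > 0:
            D[i] = tajimas_d(n, int(S[i]), float(pi_tot[i]))
    return pd.DataFrame(
        {
            "start": starts,
            "center": starts + window / 2.0,
            "S": S,
            "pi_total": pi_tot,
            "pi_per_site": pi_tot / window,
            "tajima_d": D,
        }
    )


def sliding_windows(
    cohort: PhasedCohort,
    interval: GenomicInterval,
    window: int = 500,
    step: int = 1,
) -> pd.DataFrame:
    """Sliding-window S, pi and Tajima's D; one row per start offset, the
    statistic attached to the window midpoint.  D is NaN where S = 0."""
    if len(interval) < window:
        raise ValueError("interval shorter than window")
    starts = interval.start + np.arange(0, len(interval) - window + 1, step)
    idx = cohort.sites_in(interval)
    positions = cohort.positions[idx]
    site_pi = per_site_pi(cohort.H[:, idx]) if len(idx) else np.empty(0)
    return _window_stats(positions, site_pi, cohort.n_copies, starts, window)


@dataclass
class NullDistribution:
    statistic: str
    values: np.ndarray
    mean: float
    q99: float
    q999: float

    def __post_init__(self) -> None:
        if self.q99 > self.q999:
            raise ValueError("nearest-rank quantiles must be monotone")


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    k = max(1, math.ceil(q * len(sorted_vals)))
    return float(sorted_vals[k - 1])


def empirical_null(
    background: PhasedCohort,
    interval: GenomicInterval,
    n_windows: int = 10_000,
    window: int = 500,
    rng: np.random.Generator | int | None = None,
) -> dict[str, NullDistribution]:
    """Null distributions of S, pi and D from random background windows.

    Window starts are drawn uniformly with replacement over valid offsets.
    Windows with S = 0 contribute S = 0 and pi = 0 but are excluded from the
    D null (D is undefined there).  Nearest-rank 99% and 99.9% quantiles.
    """
    if len(interval) < window:
        raise ValueError("background interval shorter than window")
    rng = np.random.default_rng(rng)
    starts = interval.start + rng.integers(0, len(interval) - window + 1, n_windows)
    idx = background.sites_in(interval)
    positions = background.positions[idx]
    site_pi = per_site_pi(background.H[:, idx]) if len(idx) else np.empty(0)
    stats = _window_stats(positions, site_pi, background.n_copies, starts, window)
    out: dict[str, NullDistribution] = {}
    for name, col in [("S", "S"), ("pi_per_site", "pi_per_site"), ("tajima_d", "tajima_d")]:
        vals = stats[col].to_numpy(dtype=float)
        if name == "tajima_d":
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                out[name] = NullDistribution(name, vals, math.nan, math.nan, math.nan)
                continue
        sv = np.sort(vals)
        out[name] = NullDistribution(
            name,
            vals,
            float(vals.mean()),
            _nearest_rank(sv, 0.99),
            _nearest_rank(sv, 0.999),
        )
    return out


def feature_summary(cohort: PhasedCohort, model: GeneModel) -> pd.DataFrame:
    """Per-feature S, pi and Tajima's D (promoter, each exon/intron, 3'UTR)."""
    names = (
        ["promoter"]
        + [f"exon{i}" for i in range(1, len(model.exons) + 1)]
        + [f"intron{i}" for i in range(1, len(model.exons))]
        + ["utr3"]
    )
    rows = []
    n = cohort.n_copies
    for name in names:
        iv = model.features[name]
        idx = cohort.sites_in(iv)
        sub = cohort.H[:, idx]
        S = segregating_sites(sub)
        pi_total, pi_site = nucleotide_diversity(sub, len(iv))
        D = tajimas_d(n, S, pi_total) if S > 0 and n >= 4 else math.nan
        rows.append(
            {
                "feature": name,
                "start": iv.start,
                "end": iv.end,
                "span_bp": len(iv),
                "S": S,
                "pi_per_site": pi_site,
                "tajima_d": D,
            }
        )
    return pd.DataFrame(rows)


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test for a bi-allelic site.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration whose probability does not exceed the
    observed one.  Monomorphic sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    N = n_hom_ref + n_het + n_hom_alt
    if N < 1:
        raise ValueError("empty sample")
    n_a = 2 * n_hom_alt + n_het  # alt allele count
    n_minor = min(n_a, 2 * N - n_a)
    if n_minor == 0:
        return 1.0

    lg = math.lgamma

    def log_prob(het: int) -> float:
        hom_min = (n_minor - het) // 2
        hom_maj = N - het - hom_min
        return (
            lg(N + 1)
            - lg(hom_min + 1)
            - lg(het + 1)
            - lg(hom_maj + 1)
            + het * math.log(2.0)
            + lg(n_minor + 1)
            + lg(2 * N - n_minor + 1)
            - lg(2 * N + 1)
        )

    het_obs = n_het
    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[het_obs]
    total = sum(math.exp(v) for v in logs.values())
    p = sum(math.exp(v) for v in logs.values() if v <= obs + 1e-12) / total
    return min(1.0, p)


def hwe_screen(
    cohort: PhasedCohort,
    min_individuals: int = 10,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Per-population, per-SNP exact HWE screen.

    Only bi-allelic SNPs polymorphic within the population are tested;
    populations with fewer than ``min_individuals`` are skipped.  A
    "deviation" is p below alpha after Bonferroni correction across that
    population's tested SNPs (correction choice recorded in the output).
    """
    gmap = cohort.manifest.group_of("population")
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(cohort.samples):
        pops.setdefault(gmap[s], []).append(i)
    rows = []
    for pop, sample_idx in sorted(pops.items()):
        if len(sample_idx) < min_individuals:
            continue
        rowsel = np.array(
            [r for i in sample_idx for r in (2 * i, 2 * i + 1)], dtype=int
        )
        tested = []
        for j, v in enumerate(cohort.variants):
            if len(v.alts) != 1 or v.type != "SNP":
                continue
            hr, het, ha = cohort.genotype_counts(j, rowsel)
            if het + ha == 0 or hr + het == 0:  # monomorphic in this population
                continue
            tested.append((j, hwe_exact(hr, het, ha)))
        m = len(tested)
        thr = alpha / m if (bonferroni and m) else alpha
        for j, p in tested:
            rows.append(
                {
                    "population": pop,
                    "site": j,
                    "pos": cohort.variants[j].pos,
                    "p_value": p,
                    "n_tested": m,
                    "deviates": p < thr,
                    "correction": "bonferroni" if bonferroni else "none",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["population", "site", "pos", "p_value", "n_tested", "deviates", "correction"],
    )
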