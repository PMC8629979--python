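"""Pairwise population differentiation (FST) and classical MDS.

Two FST flavours mirror the two resolutions of the data:

* SNP level — the Hudson ratio-of-averages estimator on haplotype (allele
  copy) frequencies with the finite-sample correction, combined across sites
  as sum(numerators) / sum(denominators);
* haplotype level — each distinct haplotype name is one allele of a single
  super-locus, differentiated with a G_ST-form estimator using unbiased
  (small-sample corrected) within-population gene diversities.

The FST matrix doubles as a distance matrix for classical (Torgerson) MDS;
negative estimates are clipped to zero only for that purpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PhasedCohort


@dataclass
class FstMatrix:
    populations: list[str]
    matrix: np.ndarray  # raw estimates, symmetric, zero diagonal
    estimator: str
    loci_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.populations),) * 2:
            raise ValueError("matrix shape mismatch")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("FST matrix must be symmetric with zero diagonal")
        self.matrix = m

    def distances(self) -> np.ndarray:
        """Matrix clipped to [0, 1] for use as MDS distances."""
        return np.clip(self.matrix, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.populations, columns=self.populations)


def _pop_rows(cohort: PhasedCohort, min_n: int) -> dict[str, np.ndarray]:
    gmap = cohort.manifest.group_of("population")
    pops: dict[str, list[int]] = {}
    for i, s in enumerate(cohort.samples):
        pops.setdefault(gmap[s], []).append(i)
    return {
        p: np.array([r for i in idx for r in (2 * i, 2 * i + 1)], dtype=int)
        for p, idx in sorted(pops.items())
        if len(idx) >= min_n
    }


def hudson_fst_site(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Per-site (numerator, denominator) of the Hudson estimator on allele
    copies: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1)."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def snp_fst_pairwise(
    cohort: PhasedCohort,
    min_n: int = 10,
    estimator: str = "hudson",
) -> FstMatrix:
    """Pairwise SNP-based FST among populations with >= ``min_n`` individuals.

    Sites monomorphic across a pair are skipped; per-pair values combine
    sites as the ratio of summed numerators to summed denominators.
    """
    if estimator != "hudson":
        raise ValueError(f"unknown estimator {estimator!r}")
    pops = _pop_rows(cohort, min_n)
    if len(pops) < 2:
        raise ValueError("need at least two qualifying populations")
    names = list(pops)
    biallelic = [
        j
        for j, v in enumerate(cohort.variants)
        if len(v.alts) == 1 and v.type == "SNP"
    ]
    freqs = {
        p: (cohort.H[np.ix_(rows, biallelic)] != 0).mean(axis=0)
        for p, rows in pops.items()
    }
    sizes = {p: len(rows) for p, rows in pops.items()}
    K = len(names)
    M = np.zeros((K, K))
    loci = np.zeros((K, K), dtype=int)
    for a in range(K):
        for b in range(a + 1, K):
            p1s, p2s = freqs[names[a]], freqs[names[b]]
            n1, n2 = sizes[names[a]], sizes[names[b]]
            num = den = 0.0
            used = 0
            for p1, p2 in zip(p1s, p2s):
                if (p1 in (0.0, 1.0)) and (p2 in (0.0, 1.0)) and p1 == p2:
                    continue  # monomorphic across the pair
                nn, dd = hudson_fst_site(float(p1), n1, float(p2), n2)
                num += nn
                den += dd
                used += 1
            fst = num / den if den > 0 else 0.0
            M[a, b] = M[b, a] = fst
            loci[a, b] = loci[b, a] = used
    return FstMatrix(names, M, "hudson", loci)


def haplotype_fst_pairwise(
    freq_table: pd.DataFrame,
    min_n: int = 10,
) -> FstMatrix:
    """Pairwise haplotype-level FST from a per-population frequency table
    (columns group/name/count/two_n as produced by ``frequency_table``).

    G_ST form: FST = (H_T - H_S) / H_T with unbiased within-population gene
    diversity H_i = n_i/(n_i - 1) * (1 - sum p_i^2) and H_T from the
    unweighted mean of the two allele-frequency vectors.
    """
    pops = []
    counts: dict[str, pd.Series] = {}
    for group, sub in freq_table.groupby("group"):
        two_n = int(sub["two_n"].iloc[0])
        if two_n < 2 * min_n:
            continue
        if two_n == 0:
            raise ValueError(f"population {group} has zero copies")
        pops.append(group)
        counts[group] = sub.set_index("name")["count"]
    if len(pops) < 2:
        raise ValueError("need at least two qualifying populations")
    K = len(pops)
    M = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            ca, cb = counts[pops[a]], counts[pops[b]]
            names = sorted(set(ca.index) | set(cb.index))
            na, nb = int(ca.sum()), int(cb.sum())
            pa = np.array([ca.get(x, 0) for x in names]) / na
            pb = np.array([cb.get(x, 0) for x in names]) / nb
            Ha = na / (na - 1) * (1.0 - float(np.sum(pa**2)))
            Hb = nb / (nb - 1) * (1.0 - float(np.sum(pb**2)))
            Hs = (Ha + Hb) / 2.0
            pbar = (pa + pb) / 2.0
            n_harm = 2.0 / (1.0 / na + 1.0 / nb)
            # Nei-Chesser-style small-sample correction of the total diversity
            Ht = 1.0 - float(np.sum(pbar**2)) + Hs / (2.0 * n_harm)
            fst = (Ht - Hs) / Ht if Ht > 0 else 0.0
            M[a, b] = M[b, a] = fst
    return FstMatrix(pops, M, "gst-unbiased")


@dataclass
class MdsEmbedding:
    populations: list[str]
    coords: np.ndarray  # (K, k') centered, ordered by descending eigenvalue
    eigenvalues: np.ndarray
    goodness_of_fit: float
    warnings: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim{i + 1}": self.coords[:, i] for i in range(self.coords.shape[1])}
        return pd.DataFrame({"population": self.populations, **cols})


def classical_mds(fst: FstMatrix | np.ndarray, k: int = 2,
                  populations: list[str] | None = None) -> MdsEmbedding:
    """Classical (Torgerson) MDS of a symmetric zero-diagonal distance matrix.

    Double-centers the squared distances, eigendecomposes, and keeps the top
    k positive-eigenvalue axes.  Axis signs are fixed by making each axis's
    largest-magnitude loading positive, so the embedding is deterministic.
    """
    if isinstance(fst, FstMatrix):
        D = fst.distances()
        populations = fst.populations
    else:
        D = np.asarray(fst, dtype=float)
        if populations is None:
            populations = [f"p{i}" for i in range(D.shape[0])]
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    K = D.shape[0]
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    warnings = []
    tol = max(1e-12, 1e-9 * max(abs(evals).max(), 1.0))
    pos = evals > tol
    n_pos = int(pos.sum())
    if (evals < -tol).any():
        warnings.append("negative eigenvalues dropped (non-Euclidean distances)")
    kk = min(k, n_pos)
    if kk < k:
        warnings.append(f"only {kk} positive eigenvalue axes available")
    coords = evecs[:, :kk] * np.sqrt(evals[:kk])
    for ax in range(kk):  # deterministic sign convention
        i = int(np.argmax(np.abs(coords[:, ax])))
        if coords[i, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    coords = coords - coords.mean(axis=0)
    pos_mass = float(evals[pos].sum()) if n_pos else 0.0
    gof = float(evals[:kk].sum() / pos_mass) if pos_mass > 0 else 0.0
    return MdsEmbedding(list(populations), coords, evals[:kk], gof, warnings)
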