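"""Population differentiation and sample relatedness.

Implements the Weir & Cockerham (1984) moment estimator of F_ST from
diploid genotype dosages (variance components a, b, c with observed
heterozygosity), an allele-sharing genetic distance between samples, and a
UPGMA dendrogram with Newick export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average as upgma_linkage
from scipy.spatial.distance import squareform

from .containers import MISSING, GenotypeMatrix


@dataclass
class FstResult:
    """Per-site variance components and their ratio-of-averages summary.

    ``numerator`` holds the among-population component a per site,
    ``denominator`` the total a + b + c. The genome-wide estimate is
    sum(a) / sum(a+b+c) over sites with a non-zero denominator (the
    "weighted" multi-site aggregation); ``mean_of_ratios`` averages the
    per-site ratios instead. Per-site values may legitimately be negative.
    """

    numerator: np.ndarray
    denominator: np.ndarray
    populations: list[str]
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def genomewide_fst(self) -> float:
        ok = self.denominator != 0
        if not ok.any():
            warnings.warn("all sites monomorphic: genome-wide F_ST undefined")
            return float("nan")
        return float(self.numerator[ok].sum() / self.denominator[ok].sum())

    @property
    def mean_of_ratios(self) -> float:
        ok = self.denominator != 0
        if not ok.any():
            return float("nan")
        return float(np.mean(self.numerator[ok] / self.denominator[ok]))

    def per_site(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.numerator / self.denominator


def _wc_components(gt: np.ndarray, pops: np.ndarray, pop_ids: np.ndarray):
    """Vectorized WC84 components a, b, c per site for r populations.

    ``gt`` is (n_sites, n_samples) dosage with MISSING for no-calls.
    Missing genotypes are excluded site-wise from the per-population
    sample sizes. Sites with fewer than 2 called individuals in any
    population, or fewer than 2 populations called, get a = b = c = 0
    (excluded from the ratio by the zero denominator).
    """
    r = len(pop_ids)
    called = gt != MISSING
    # per-population called sample sizes and alt-allele frequencies
    n_i = np.stack([called[:, pops == p].sum(axis=1) for p in pop_ids], axis=1)  # sites x r
    alt_i = np.stack(
        [np.where(called[:, pops == p], gt[:, pops == p], 0).sum(axis=1) for p in pop_ids],
        axis=1,
    )
    het_i = np.stack([((gt[:, pops == p]) == 1).sum(axis=1) for p in pop_ids], axis=1)

    valid = (n_i >= 2).all(axis=1)
    n_i = np.maximum(n_i, 1)  # avoid div-by-zero on invalid rows
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = alt_i / (2.0 * n_i)
        h_i = het_i / n_i

    n_tot = n_i.sum(axis=1).astype(float)
    nbar = n_tot / r
    nc = (n_tot - (n_i**2).sum(axis=1) / n_tot) / (r - 1)
    pbar = (n_i * p_i).sum(axis=1) / n_tot
    s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=1) / n_tot

    inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
    a = nbar / nc * (s2 - inner / (nbar - 1))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    for arr in (a, b, c):
        arr[~valid] = 0.0
    return a, b, c


def wc_fst(gm: GenotypeMatrix, pop_labels: dict[str, str] | "object") -> FstResult:
    """Weir–Cockerham F_ST among populations, plus all pairwise estimates.

    ``pop_labels`` maps sample id -> population name (a mapping or a
    pandas Series indexed by sample id).
    """
    labels = {s: pop_labels[s] for s in gm.samples}
    pops = np.array([labels[s] for s in gm.samples], dtype=object)
    pop_ids = np.array(sorted(set(pops)), dtype=object)
    if len(pop_ids) < 2:
        raise ValueError("F_ST needs at least 2 populations")

    a, b, c = _wc_components(gm.gt, pops, pop_ids)
    result = FstResult(numerator=a, denominator=a + b + c, populations=list(pop_ids))

    for i in range(len(pop_ids)):
        for j in range(i + 1, len(pop_ids)):
            pair = (str(pop_ids[i]), str(pop_ids[j]))
            keep = np.isin(pops, pop_ids[[i, j]])
            aa, bb, cc = _wc_components(gm.gt[:, keep], pops[keep], pop_ids[[i, j]])
            denom = aa + bb + cc
            ok = denom != 0
            result.pairwise[pair] = (
                float(aa[ok].sum() / denom[ok].sum()) if ok.any() else float("nan")
            )
    return result


def allele_sharing_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing distance: mean over co-called sites of |gx-gy|/2.

    Ranges over [0, 1]; 0 for identical genotypes, 1 for opposite
    homozygotes everywhere. Raises if some sample pair shares no
    co-called site.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = gm.gt.astype(float)
    called = g != MISSING
    g = np.where(called, g, 0.0)
    # sum over co-called sites of |gx - gy| via expansion is unreliable for
    # absolute differences; with only 3 dosage levels a direct loop over
    # samples stays cheap (n_samples is tens, sites vectorized).
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        both = called[:, i][:, None] & called[:, i + 1:]
        diff = np.abs(g[:, i][:, None] - g[:, i + 1:]) / 2.0
        overlap = both.sum(axis=0)
        bad = overlap == 0
        if bad.any():
            j = int(np.flatnonzero(bad)[0]) + i + 1
            raise ValueError(
                f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no co-called sites"
            )
        d[i, i + 1:] = np.where(both, diff, 0.0).sum(axis=0) / overlap
    return d + d.T


@dataclass
class DistanceTree:
    """UPGMA dendrogram over a sample distance matrix.

    ``merges`` is the (n-1) x 4 scipy linkage matrix, but heights (column
    2) are node heights (half the cophenetic distance between the merged
    clusters), so an ultrametric tree has every leaf at depth equal to the
    root height.
    """

    labels: list[str]
    distances: np.ndarray
    merges: np.ndarray
    newick: str


def build_dendrogram(distances: np.ndarray, labels: list[str]) -> DistanceTree:
    """UPGMA clustering of a symmetric non-negative distance matrix.

    Merge heights are half the UPGMA cluster distance, so two samples at
    distance d join at height d/2 (branch lengths then read as divergence
    per lineage). Ties break deterministically (scipy's ordering by index).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if len(labels) != d.shape[0]:
        raise ValueError("labels do not match matrix size")
    Z = upgma_linkage(squareform(d, checks=False))
    merges = Z.copy()
    merges[:, 2] = Z[:, 2] / 2.0
    newick = _linkage_to_newick(merges, labels)
    return DistanceTree(labels=list(labels), distances=d, merges=merges, newick=newick)


def _linkage_to_newick(merges: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for k, row in enumerate(merges):
        a, b, h = int(row[0]), int(row[1]), float(row[2])
        left = f"{node[a]}:{h - height[a]:.10g}"
        right = f"{node[b]}:{h - height[b]:.10g}"
        node[n + k] = f"({left},{right})"
        height[n + k] = h
    root = n + len(merges) - 1 if len(merges) else 0
    return node[root] + ";"
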