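"""Enterotype discovery: Jensen-Shannon distance, PAM, CH k-selection, silhouette.

The procedure follows the canonical enterotyping lineage: pairwise
square-root Jensen-Shannon divergence (natural log) between genus-level
relative-abundance profiles, partitioning around medoids for each
candidate k, Calinski-Harabasz index to pick k, and silhouette widths to
judge robustness of the chosen partition.

PAM here is fully deterministic: greedy BUILD seeding followed by
steepest-descent SWAP, with every tie broken toward the lowest sample
index, so repeated runs are bit-identical without any random state.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, to_relative

__all__ = [
    "jsd_distance",
    "jsd_matrix",
    "pam",
    "calinski_harabasz",
    "silhouette_widths",
    "classical_mds",
    "DistanceMatrix",
    "Enterotyper",
    "EnterotypeResults",
    "fit_enterotypes",
]

#: Upper bound of the sqrt-JSD metric under the natural-log convention.
JSD_MAX = float(np.sqrt(np.log(2.0)))

#: Instances with at most this many candidate medoid subsets are solved
#: by exact enumeration instead of BUILD+SWAP local search.
EXACT_PAM_MAX_SUBSETS = 1000


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with ids."""

    d: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return self.d.shape[0]


def _check_prob(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} sums to {p.sum():.12g}, expected 1")
    return p


def _entropy_nat(p: np.ndarray, axis=None) -> np.ndarray:
    """Shannon entropy in nats with the 0*ln(0)=0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -t.sum(axis=axis)


def jsd_distance(p, q) -> float:
    """Square-root Jensen-Shannon divergence between two probability vectors.

    Returns sqrt((KL(P||M) + KL(Q||M))/2) with M = (P+Q)/2, natural log.
    No pseudocounts are needed: the mixture denominator is positive
    wherever either numerator is.  The result is a metric bounded by
    sqrt(ln 2).
    """
    p = _check_prob(p, "P")
    q = _check_prob(q, "Q")
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same length")
    m = 0.5 * (p + q)
    jsd = _entropy_nat(m) - 0.5 * (_entropy_nat(p) + _entropy_nat(q))
    return float(np.sqrt(max(jsd, 0.0)))


def jsd_matrix(table: AbundanceTable) -> DistanceMatrix:
    """All-pairs sqrt-JSD over the samples of a relative-abundance table.

    Uses the identity JSD(P,Q) = H(M) - (H(P)+H(Q))/2 so the n^2 pair
    mixtures are evaluated vectorised in blocks.
    """
    if table.mode != "relative":
        raise ValueError("jsd_matrix requires a relative-abundance table")
    x = table.values.T  # samples x taxa
    n = x.shape[0]
    h = _entropy_nat(x, axis=1)
    d2 = np.zeros((n, n))
    block = max(1, int(2e7 // max(x.size, 1)))
    for i0 in range(0, n, block):
        i1 = min(n, i0 + block)
        m = 0.5 * (x[i0:i1, None, :] + x[None, :, :])
        hm = _entropy_nat(m, axis=2)
        d2[i0:i1] = hm - 0.5 * (h[i0:i1, None] + h[None, :])
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.clip(d2, 0.0, None))
    d = 0.5 * (d + d.T)
    return DistanceMatrix(d, list(table.sample_ids))


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def _assign(d: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid labels (0..k-1 positions into sorted ``medoids``);
    ties go to the lowest medoid index because argmin returns the first."""
    return np.argmin(d[:, medoids], axis=1)


def pam(dist: DistanceMatrix | np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic k-medoids minimising total point-to-medoid distance.

    Tiny instances (at most ``EXACT_PAM_MAX_SUBSETS`` candidate medoid
    sets) are solved exactly by enumeration, because greedy BUILD +
    steepest-descent SWAP is a local search and can stall a few percent
    above the optimum on degenerate small configurations.  Larger
    instances use BUILD seeding followed by SWAP (best single medoid
    exchange until no improvement).  All ties break toward the lowest
    sample index, so the result is seed-free.

    Returns ``(labels, medoid_indices)`` with labels in 0..k-1 referring
    to positions in the ascending-sorted medoid index array.
    """
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    n = d.shape[0]
    if not (2 <= k < n):
        raise ValueError(f"k={k} out of range for n={n} (need 2 <= k < n)")

    if math.comb(n, k) <= EXACT_PAM_MAX_SUBSETS:
        best_cost = math.inf
        best = None
        for comb in itertools.combinations(range(n), k):
            c = d[:, comb].min(axis=1).sum()
            if c < best_cost - 1e-12:  # lex-first subset wins cost ties
                best_cost, best = c, comb
        medoids = np.array(best)
        return _assign(d, medoids), medoids

    # BUILD: first medoid minimises total distance; each next medoid
    # maximises the cost reduction.  np.argmin/argmax tie-break low index.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        nxt = int(np.argmax(gain))
        medoids.append(nxt)
        nearest = np.minimum(nearest, d[:, nxt])
    medoids = np.sort(np.array(medoids))

    # SWAP: evaluate every (medoid, candidate) exchange, take the single
    # best strict improvement, repeat to convergence.
    while True:
        dm = d[:, medoids]                      # n x k
        order = np.argsort(dm, axis=1, kind="stable")
        lab = order[:, 0]
        d1 = dm[np.arange(n), lab]
        d2 = dm[np.arange(n), order[:, 1]]
        cost = d1.sum()

        best = (cost, -1, -1)
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        cand = np.where(~is_medoid)[0]
        for ki in range(len(medoids)):
            mine = lab == ki
            # points losing their medoid fall back to min(second-nearest, new)
            c_lose = np.minimum(d2[mine, None], d[mine][:, cand]).sum(axis=0)
            c_keep = np.minimum(d1[~mine, None], d[~mine][:, cand]).sum(axis=0)
            totals = c_lose + c_keep
            j = int(np.argmin(totals))
            if totals[j] < best[0] - 1e-12:
                best = (float(totals[j]), ki, int(cand[j]))
        if best[1] < 0:
            break
        medoids[best[1]] = best[2]
        medoids = np.sort(medoids)

    labels = _assign(d, medoids)
    return labels, medoids


def total_cost(d: np.ndarray, medoids: np.ndarray) -> float:
    """Sum of distances of all points to their nearest medoid."""
    return float(d[:, medoids].min(axis=1).sum())


# ---------------------------------------------------------------------------
# cluster validity
# ---------------------------------------------------------------------------

def calinski_harabasz(dist: DistanceMatrix | np.ndarray, labels, medoids) -> float:
    """Medoid-based Calinski-Harabasz index on squared distances.

    Distance-matrix analogue of the variance ratio: within-cluster
    dispersion W sums squared distances to cluster medoids, between-cluster
    dispersion B sums cluster sizes times the squared distance of each
    medoid to the overall medoid (the point minimising total squared
    distance).  Degenerate zero-W clusterings return +inf.
    """
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    medoids = np.asarray(medoids)
    n = d.shape[0]
    k = len(medoids)
    if k < 2 or n <= k:
        raise ValueError("need 2 <= k < n for the CH index")
    d2 = d ** 2
    w = 0.0
    for ki, m in enumerate(medoids):
        w += d2[labels == ki, m].sum()
    m0 = int(np.argmin(d2.sum(axis=0)))
    sizes = np.bincount(labels, minlength=k)
    b = float((sizes * d2[medoids, m0]).sum())
    if w <= 0.0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def silhouette_widths(dist: DistanceMatrix | np.ndarray, labels) -> np.ndarray:
    """Per-sample silhouette widths s(i) = (b-a)/max(a,b).

    a is the mean distance to the sample's own cluster (excluding itself),
    b the smallest mean distance to any other cluster.  Members of
    singleton clusters get s = 0 by convention, as do samples where both
    a and b vanish.
    """
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    ks = np.unique(labels)
    if len(ks) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    s = np.zeros(n)
    masks = {c: labels == c for c in ks}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue
        a = d[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(d[i, masks[o]].mean() for o in ks if o != c)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return s


def classical_mds(dist: DistanceMatrix, n_components: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Returns per-sample coordinates for plotting the enterotype landscape;
    negative eigenvalues (non-Euclidean residual of the metric) are
    truncated at zero.
    """
    d2 = dist.d ** 2
    n = dist.n
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(bmat)
    order = np.argsort(vals)[::-1][:n_components]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    return pd.DataFrame(coords, index=dist.sample_ids,
                        columns=[f"MDS{i+1}" for i in range(n_components)])


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class Enterotyper:
    """Enterotype model over a genus-level abundance table.

    Parameters
    ----------
    table : AbundanceTable
        Genus-level table; counts are converted to relative abundances.
    k_range : iterable of int
        Candidate cluster numbers (default 2..10).  Shrunk with a warning
        when the cohort is too small.
    min_mean_abundance : float
        Optional mean-relative-abundance filter applied to genera before
        clustering (default 0 = no filter).
    """

    def __init__(self, table: AbundanceTable, k_range=range(2, 11),
                 min_mean_abundance: float = 0.0):
        table = to_relative(table)
        if min_mean_abundance > 0:
            keep = table.values.mean(axis=1) >= min_mean_abundance
            vals = table.values[keep]
            vals = vals / vals.sum(axis=0)
            table = AbundanceTable(
                vals, [t for t, k in zip(table.taxon_ids, keep) if k],
                list(table.sample_ids), mode="relative", level=table.level)
        if table.n_samples < 12:
            raise ValueError("enterotyping needs at least 12 samples")
        ks = sorted(set(int(k) for k in k_range))
        kmax = table.n_samples - 1
        if any(k > kmax for k in ks):
            warnings.warn(f"k range truncated to < n = {table.n_samples}")
            ks = [k for k in ks if k <= kmax]
        if not ks or min(ks) < 2:
            raise ValueError("k_range must contain integers >= 2")
        self.table = table
        self.k_range = ks

    def fit(self) -> "EnterotypeResults":
        dist = jsd_matrix(self.table)
        ch_by_k: dict[int, float] = {}
        fits: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k in self.k_range:
            labels, medoids = pam(dist, k)
            fits[k] = (labels, medoids)
            ch_by_k[k] = calinski_harabasz(dist, labels, medoids)
        # argmax CH; ties toward smaller k (dict preserves ascending order)
        k_sel = max(ch_by_k, key=lambda k: (ch_by_k[k], -k))
        labels, medoids = fits[k_sel]
        sil = silhouette_widths(dist, labels)

        # relabel clusters 1..k by decreasing size (ties: lower medoid index)
        sizes = np.bincount(labels, minlength=k_sel)
        order = sorted(range(k_sel), key=lambda c: (-sizes[c], medoids[c]))
        remap = {old: new + 1 for new, old in enumerate(order)}
        labels1 = np.array([remap[c] for c in labels])
        medoid_ids = [self.table.sample_ids[medoids[c]] for c in order]

        drivers = []
        for c in range(1, k_sel + 1):
            mean_ab = self.table.values[:, labels1 == c].mean(axis=1)
            drivers.append(self.table.taxon_ids[int(np.argmax(mean_ab))])

        return EnterotypeResults(
            model=self, distance=dist, k_selected=k_sel, labels=labels1,
            medoid_ids=medoid_ids, ch_by_k=ch_by_k,
            silhouette_per_sample=sil,
            silhouette_mean=float(sil.mean()),
            driver_genus_per_cluster=drivers,
        )


@dataclass
class EnterotypeResults:
    """Fitted enterotype partition with validity diagnostics.

    ``labels`` are 1..k with clusters numbered by decreasing size, so
    cluster 1 is always the largest enterotype.
    """

    model: Enterotyper
    distance: DistanceMatrix
    k_selected: int
    labels: np.ndarray
    medoid_ids: list[str]
    ch_by_k: dict[int, float]
    silhouette_per_sample: np.ndarray
    silhouette_mean: float
    driver_genus_per_cluster: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.distance.sample_ids)

    @property
    def cluster_sizes(self) -> list[int]:
        return [int((self.labels == c).sum()) for c in range(1, self.k_selected + 1)]

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({
            "enterotype": self.labels,
            "silhouette": self.silhouette_per_sample,
        }, index=self.sample_ids)

    def mean_abundance(self, genus: str, cluster: int) -> float:
        """Mean relative abundance of ``genus`` within ``cluster`` (1-based)."""
        tab = self.model.table
        row = tab.taxon_ids.index(genus)
        return float(tab.values[row, self.labels == cluster].mean())

    def mds_coordinates(self, n_components: int = 2) -> pd.DataFrame:
        coords = classical_mds(self.distance, n_components)
        coords["enterotype"] = self.labels
        return coords

    def summary(self) -> str:
        lines = [
            "Enterotype clustering (sqrt-JSD + PAM, CH k-selection)",
            f"  samples: {self.distance.n}   genera: {self.model.table.n_taxa}",
            f"  k selected: {self.k_selected} "
            f"(CH by k: {', '.join(f'{k}:{v:.1f}' for k, v in sorted(self.ch_by_k.items()))})",
            f"  mean silhouette width: {self.silhouette_mean:.3f}",
            "  cluster  size  medoid          driver genus        mean abund",
        ]
        for c in range(1, self.k_selected + 1):
            g = self.driver_genus_per_cluster[c - 1]
            ab = self.mean_abundance(g, c)
            lines.append(
                f"  ET{c:<6d} {self.cluster_sizes[c-1]:>4d}  "
                f"{self.medoid_ids[c-1]:<15s} {g:<19s} {ab*100:7.2f}%"
            )
        return "\n".join(lines)


def fit_enterotypes(table: AbundanceTable, k_range=range(2, 11),
                    min_mean_abundance: float = 0.0) -> EnterotypeResults:
    """One-call convenience wrapper: build an :class:`Enterotyper` and fit."""
    return Enterotyper(table, k_range, min_mean_abundance).fit()
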