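"""Community ecology: alpha/beta diversity, ordination and PERMANOVA.

Alpha diversity (Shannon, Simpson, bias-corrected Chao1) is computed on raw
counts — richness estimators need integer singleton/doubleton counts, so the
CSS-normalized table is *not* used here.  Beta diversity uses the
Bray-Curtis dissimilarity; principal coordinate analysis (PCoA) embeds the
distance matrix via Gower double-centering; PERMANOVA tests group location
differences with a permutation null, switching to exhaustive enumeration of
label assignments when that is cheaper than sampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal

ALPHA_METRICS = ("shannon", "simpson", "chao1")


# ---------------------------------------------------------------------------
# distance matrix container
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with a zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != d.shape[0]:
            raise ValueError("ids length does not match matrix size")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix has non-finite entries")
        if np.abs(d - d.T).max() > 1e-12:
            raise ValueError("distance matrix is not symmetric (tol 1e-12)")
        if np.abs(np.diag(d)).max() > 0:
            raise ValueError("distance matrix diagonal must be zero")
        if d.min() < 0:
            raise ValueError("distances must be non-negative")
        self.data = d

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(counts_row, metric: str, base: float = 2.0) -> float:
    """Alpha diversity of one sample.

    Parameters
    ----------
    counts_row:
        Non-negative counts for a single sample; at least one positive.
    metric:
        ``"shannon"`` (−Σ p_i log_base p_i over nonzero proportions, base 2
        by default), ``"simpson"`` (Gini-Simpson, 1 − Σ p_i²) or ``"chao1"``
        (bias-corrected richness, S_obs + F1(F1−1)/(2(F2+1)) with F1/F2 the
        singleton/doubleton counts; requires integer counts).
    """
    x = np.asarray(counts_row, dtype=float)
    if x.ndim != 1:
        raise ValueError("alpha_diversity expects a single sample (1-D)")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample has undefined diversity")
    if metric == "shannon":
        p = x[x > 0] / total
        return float(-(p * (np.log(p) / np.log(base))).sum())
    if metric == "simpson":
        p = x / total
        return float(1.0 - (p ** 2).sum())
    if metric == "chao1":
        if not np.allclose(x, np.round(x)):
            raise ValueError("chao1 requires integer counts")
        xi = np.round(x).astype(int)
        s_obs = int((xi > 0).sum())
        f1 = int((xi == 1).sum())
        f2 = int((xi == 2).sum())
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    raise ValueError(f"unknown metric {metric!r}; choose from {ALPHA_METRICS}")


def alpha_diversity_table(table, metrics=ALPHA_METRICS, base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha diversity for several metrics (samples x metrics)."""
    rows = {m: [alpha_diversity(r, m, base=base) for r in table.values] for m in metrics}
    return pd.DataFrame(rows, index=table.sample_ids)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, d(i,j) = 1 − 2 Σ min(x_i,x_j) / (Σx_i + Σx_j)."""
    X = table.values
    if (X.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis undefined for a sample with zero row sum")
    d = squareform(pdist(X, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates on the retained positive-eigenvalue axes."""

    coordinates: pd.DataFrame   # samples x k
    eigenvalues: np.ndarray     # all eigenvalues, decreasing (negatives kept)
    proportions: np.ndarray     # variance fraction of each retained axis


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering.

    The matrix −½ d² is double-centered and eigendecomposed.  Negative
    eigenvalues (non-Euclidean distances) are reported but their axes are
    dropped; coordinates are scores on the top ``k`` positive axes.
    Variance proportions are relative to the sum of positive eigenvalues.
    """
    n = dm.n
    if k >= n:
        raise ValueError(f"k must be < number of samples ({n})")
    d2 = dm.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    lam = eigvals[:k_eff]
    coords = eigvecs[:, :k_eff] * np.sqrt(lam)
    # deterministic sign: largest-|entry| coordinate positive per axis
    for j in range(k_eff):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    total_pos = eigvals[pos].sum()
    props = lam / total_pos if total_pos > 0 else np.zeros(k_eff)
    cols = [f"PCo{j + 1}" for j in range(k_eff)]
    return OrdinationResult(pd.DataFrame(coords, index=dm.ids, columns=cols),
                            eigvals, props)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in pd.unique(labels)]


def _pseudo_f(d2: np.ndarray, groups: list[np.ndarray], ss_total: float) -> float:
    n = d2.shape[0]
    g = len(groups)
    ss_within = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * len(idx))   # each pair counted twice
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _n_distinct_assignments(sizes: list[int]) -> int:
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    return total


def _enumerate_assignments(n: int, sizes: list[int]):
    """Yield all distinct partitions of range(n) into groups of given sizes."""
    def rec(remaining: tuple, sizes_left: list[int], acc: list):
        if not sizes_left:
            yield list(acc)
            return
        s = sizes_left[0]
        if len(sizes_left) == 1:
            yield acc + [np.array(remaining)]
            return
        # groups are labeled, so every ordered choice of member sets is a
        # distinct assignment
        for combo in itertools.combinations(remaining, s):
            rest = tuple(x for x in remaining if x not in combo)
            yield from rec(rest, sizes_left[1:], acc + [np.array(combo)])
    yield from rec(tuple(range(n)), sizes, [])


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic contrasts between- and within-group sums of
    squared distances.  The p-value is estimated by permuting group labels;
    when the number of distinct label assignments is <= ``n_perm`` the exact
    permutation distribution is enumerated instead (p is then the exact
    fraction of assignments with F >= observed, the identity included).
    Otherwise p uses the add-one estimator (1 + #{F_perm >= F_obs}) /
    (1 + n_perm), which never returns zero.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != dm.n:
        raise ValueError("labels length does not match distance matrix")
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    sizes = [len(g) for g in groups]
    if min(sizes) < 2:
        raise ValueError("every group needs >= 2 samples")
    d2 = dm.data ** 2
    n = dm.n
    ss_total = d2.sum() / (2.0 * n)
    f_obs = _pseudo_f(d2, groups, ss_total)

    n_distinct = _n_distinct_assignments(sizes)
    if n_distinct <= n_perm:
        count = 0
        for assignment in _enumerate_assignments(n, sizes):
            f = _pseudo_f(d2, assignment, ss_total)
            if f >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(float(f_obs), count / n_distinct, n_distinct, True)

    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        perm_groups = [perm[g] for g in groups]
        if _pseudo_f(d2, perm_groups, ss_total) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(float(f_obs), p, n_perm, False)


# ---------------------------------------------------------------------------
# intragroup distances
# ---------------------------------------------------------------------------

@dataclass
class IntragroupResult:
    """Within-group pairwise distances plus a Kruskal-Wallis comparison."""

    distances: dict[str, np.ndarray]
    kw_statistic: float
    kw_p_value: float


def intragroup_distances(dm: DistanceMatrix, labels) -> IntragroupResult:
    """All within-group pairwise distances per group, compared across groups.

    A group of size m contributes m(m−1)/2 distances.  Groups are compared
    with a Kruskal-Wallis test on their distance multisets, quantifying
    whether one group is more dispersed than the others.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != dm.n:
        raise ValueError("labels length does not match distance matrix")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sub = dm.data[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        out[str(g)] = sub[iu]
    vals = list(out.values())
    if np.ptp(np.concatenate(vals)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = kruskal(*vals)
    return IntragroupResult(out, float(h), float(p))
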