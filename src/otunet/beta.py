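"""Bray-Curtis dissimilarity, classical PCoA, and the ANOSIM permutation test.

Between-sample community structure: pairwise Bray-Curtis dissimilarities
``d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``, embedded by principal
coordinates analysis (Gower double-centering of the squared distances and
eigendecomposition), with group separation tested by ANOSIM — Clarke's
rank-based statistic R = (rbar_between - rbar_within) / (n(n-1)/4) under
label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import OtuTable, SampleMetadata

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "AnosimResult",
    "bray_curtis",
    "pcoa",
    "anosim",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric sample-by-sample dissimilarity matrix."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids do not match matrix size")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class PcoaResult:
    """PCoA embedding: coordinates (samples x positive axes), all eigenvalues
    in decreasing order (negatives reported untouched), and the fraction of
    positive-eigenvalue variance each positive axis explains."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    ids: tuple[str, ...]


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities among samples (in [0, 1])."""
    totals = table.sample_sums()
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        raise ValueError(
            f"sample {table.sample_ids[empty[0]]!r} has zero total count; "
            "Bray-Curtis is undefined"
        )
    d = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, table.sample_ids)


def pcoa(d: DistanceMatrix, correction: str | None = None) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower-centers B = -1/2 J D^2 J and eigendecomposes it; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues, so a
    Euclidean-embeddable D is reconstructed exactly.  Negative eigenvalues
    (non-Euclidean input) are reported as-is and excluded from coordinates;
    ``correction="lingoes"`` adds the Lingoes constant to squared
    off-diagonal distances first.
    """
    if d.n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    dv = d.values
    n = d.n
    d2 = dv ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if correction == "lingoes" and eigval[-1] < 0:
        c = -eigval[-1]
        d2c = d2 + 2.0 * c * (1.0 - np.eye(n))
        b = -0.5 * j @ d2c @ j
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
    elif correction is not None and correction != "lingoes":
        raise ValueError(f"unknown correction {correction!r}")

    tol = max(abs(eigval[0]), 1.0) * 1e-12 if eigval.size else 0.0
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total_pos = eigval[pos].sum()
    prop = eigval[pos] / total_pos if total_pos > 0 else eigval[pos]
    return PcoaResult(coords, eigval, prop, d.ids)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n = within.shape[0]
    iu = np.triu_indices(n, k=1)
    w = within[iu]
    r = ranks
    r_within = r[w].mean()
    r_between = r[~w].mean()
    return float((r_between - r_within) / (n * (n - 1) / 4.0))


def anosim(d: DistanceMatrix, groups: SampleMetadata,
           n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """ANOSIM: are between-group distances larger than within-group ones?

    Distances are rank-transformed (average ranks on ties).  The p-value is
    the inclusive permutation estimator
    ``(1 + #{permuted R >= observed R}) / (1 + n_permutations)`` under
    uniform relabeling with the given seed, so p >= 1/(n_permutations + 1).
    """
    labels = groups.group_labels(d.ids)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        bad = uniq[np.argmin(counts)]
        raise ValueError(f"group {bad!r} has fewer than 2 samples")

    ranks = rankdata(d.condensed())
    within = labels[:, None] == labels[None, :]
    r_obs = _anosim_r(ranks, within)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        w = perm[:, None] == perm[None, :]
        if _anosim_r(ranks, w) >= r_obs:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_permutations)
    return AnosimResult(R=r_obs, p_value=p, n_permutations=n_permutations, seed=seed)
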