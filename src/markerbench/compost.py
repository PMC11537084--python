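"""Compositional evaluation: Pearson, CLR/Aitchison, PCoA, ANOSIM.

Compositions live on the simplex, so similarity is judged both by plain
Pearson correlation of proportion vectors and by the Aitchison geometry:
Euclidean distance between centered log-ratio (CLR) transforms.  Zeros
are handled by multiplicative replacement with delta = half the smallest
nonzero proportion, then renormalization — this choice materially affects
distances and is configurable.

PCoA is classical metric scaling (delegated to scikit-bio); ANOSIM is the
rank-based permutation test of whether between-group distances exceed
within-group distances, implemented here with mid-ranks for ties and the
add-one permutation p-value convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

__all__ = ["DistanceMatrix", "pearson", "clr", "aitchison_distance",
           "aitchison_matrix", "pcoa", "anosim"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("matrix not symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValueError("nonzero diagonal")
        if np.any(self.matrix < -1e-12):
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels,
                            columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def pearson(true_profile: np.ndarray, predicted_profile: np.ndarray) -> float:
    """Product-moment correlation between two proportion vectors."""
    a = np.asarray(true_profile, dtype=float)
    b = np.asarray(predicted_profile, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 3:
        raise ValueError("need >= 3 species")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(a, b).statistic)


def _replace_zeros(x: np.ndarray, policy: str, delta: float | None
                   ) -> np.ndarray:
    if not np.any(x == 0):
        return x
    if policy != "multiplicative":
        raise ValueError(f"unknown zero policy {policy!r}")
    if delta is None:
        delta = x[x > 0].min() / 2.0
    out = np.where(x == 0, delta, x)
    return out / out.sum()


def clr(profile: np.ndarray, zero_policy: str = "multiplicative",
        delta: float | None = None) -> np.ndarray:
    """Centered log-ratio transform: ln(x_i / geometric_mean(x)).

    Zeros are multiplicatively replaced (delta defaults to half the
    smallest nonzero part) and the vector renormalized first.  Output
    components sum to 0.
    """
    x = np.asarray(profile, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative parts")
    if not np.any(x > 0):
        raise ValueError("all-zero vector")
    x = _replace_zeros(x, zero_policy, delta)
    logx = np.log(x)
    return logx - logx.mean()


def aitchison_distance(profile_a: np.ndarray, profile_b: np.ndarray,
                       **clr_kw) -> float:
    """Euclidean norm of clr(a) - clr(b); scale-invariant in each input."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched species sets")
    return float(np.linalg.norm(clr(a / a.sum(), **clr_kw)
                                - clr(b / b.sum(), **clr_kw)))


def aitchison_matrix(profiles: Sequence[np.ndarray],
                     labels: Sequence[str], **clr_kw) -> DistanceMatrix:
    clrs = [clr(np.asarray(p, dtype=float) / np.sum(p), **clr_kw)
            for p in profiles]
    n = len(clrs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = np.linalg.norm(clrs[i] - clrs[j])
    return DistanceMatrix(list(labels), m)


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling of a distance matrix.

    Returns (coordinates, eigenvalues), axes ordered by descending
    eigenvalue.  Aitchison distance matrices are Euclidean-embeddable, so
    their eigenvalues are nonnegative up to numerical noise.
    """
    import skbio

    res = skbio.stats.ordination.pcoa(
        skbio.DistanceMatrix(dm.matrix, ids=dm.labels))
    coords = res.samples.copy()
    coords.index = dm.labels
    return coords, res.eigvals.to_numpy()


def anosim(dm: DistanceMatrix, grouping: Sequence[str],
           n_permutations: int = 999,
           seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked with mid-ranks for ties;
    p = (1 + #{permuted R >= observed}) / (1 + n_permutations).
    """
    grouping = np.asarray(grouping)
    n = len(dm.labels)
    if grouping.size != n:
        raise ValueError("grouping length mismatch")
    values, counts = np.unique(grouping, return_counts=True)
    if values.size < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs >= 2 members")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    ranks = stats.rankdata(squareform(dm.matrix, checks=False))
    iu, ju = np.triu_indices(n, k=1)
    denom = (n * (n - 1) / 2) / 2.0

    def r_stat(labels: np.ndarray) -> float:
        within = labels[iu] == labels[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(grouping)
    hits = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(grouping)) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return float(observed), float(p)
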