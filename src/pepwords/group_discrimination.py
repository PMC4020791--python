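"""Group discrimination: MDS ordination, Fisher LDA and permutation tests.

Repeat vectors are compared with a distance metric, embedded in a
low-dimensional space by multidimensional scaling, and the known group
labels are tested by projecting the embedding onto the two-class Fisher
discriminant axis and measuring the separation between group centroids
along it.  Significance comes from a Monte-Carlo permutation test: group
labels are reshuffled (group sizes preserved) and the centroid separation
recomputed, giving the null distribution of separations expected when
labels carry no information.  The add-one estimator

    p = (1 + #{null >= observed}) / (1 + M)

never returns zero.  A multi-group variant runs all pairwise two-group
tests plus an omnibus statistic (mean pairwise centroid separation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS as _SkMDS

from .word_statistics import RepeatVector, vectors_to_matrix


class Metric(str, Enum):
    EUCLIDEAN = "EUCLIDEAN"
    BRAY_CURTIS = "BRAY_CURTIS"


class MdsMethod(str, Enum):
    CLASSICAL = "CLASSICAL"
    NONMETRIC = "NONMETRIC"


class SeparationStatistic(str, Enum):
    """Permutation-test statistic: LDA-axis centroid separation (canonical)
    or MRPP-style weighted within-group mean distance (sign-flipped so that
    larger still means more group structure)."""

    LDA = "LDA"
    MRPP = "MRPP"


def vector_distance_matrix(
    vectors: list[RepeatVector], metric: Metric = Metric.EUCLIDEAN
) -> np.ndarray:
    """Symmetric pairwise distance matrix over genomes' repeat vectors."""
    if len(vectors) < 3:
        raise ValueError("need at least 3 vectors")
    if len({v.mode for v in vectors}) != 1:
        raise ValueError("mixed vector modes")
    if len({v.max_repeat for v in vectors}) != 1:
        raise ValueError("mixed vector lengths")
    x = vectors_to_matrix(vectors)
    metric = Metric(metric)
    name = "euclidean" if metric is Metric.EUCLIDEAN else "braycurtis"
    d = squareform(pdist(x, metric=name))
    return np.nan_to_num(d, nan=0.0)


def classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS by double-centering eigendecomposition.

    Deterministic up to sign; each axis is flipped so its largest-magnitude
    coordinate is positive.  Negative eigenvalues (non-Euclidean input) are
    truncated at zero.
    """
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    for axis in range(coords.shape[1]):  # deterministic sign convention
        imax = np.argmax(np.abs(coords[:, axis]))
        if coords[imax, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    return coords


def mds_embed(
    dist: np.ndarray,
    k: int = 2,
    method: MdsMethod = MdsMethod.CLASSICAL,
    seed: int = 0,
) -> np.ndarray:
    """Embed a distance matrix in k dimensions (classical or non-metric MDS)."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    method = MdsMethod(method)
    if method is MdsMethod.CLASSICAL:
        return classical_mds(dist, k)
    mds = _SkMDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        random_state=seed,
        normalized_stress="auto",
        n_init=4,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # sklearn MDS API migration
        return mds.fit_transform(dist)


def lda_separation(
    coordinates: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Two-class Fisher discriminant axis and centroid separation along it.

    w is proportional to S_w^{-1} (mu_1 - mu_2) with the pooled within-class
    scatter S_w ridge-regularized by 1e-8 * trace(S_w)/k when near-singular;
    w is unit-normalized and the separation is |w . (mu_1 - mu_2)|.
    """
    x = np.asarray(coordinates, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    x1, x2 = x[y == classes[0]], x[y == classes[1]]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each class needs at least 2 members")
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    sw = np.zeros((x.shape[1], x.shape[1]))
    for xi, mui in ((x1, mu1), (x2, mu2)):
        c = xi - mui
        sw += c.T @ c
    k = x.shape[1]
    ridge = 1e-8 * max(np.trace(sw) / k, 1e-300)
    try:
        w = np.linalg.solve(sw + ridge * np.eye(k), mu1 - mu2)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(sw + ridge * np.eye(k), mu1 - mu2, rcond=None)[0]
    norm = np.linalg.norm(w)
    if norm == 0.0:
        return np.zeros(k), 0.0
    w = w / norm
    return w, float(abs(w @ (mu1 - mu2)))


def _mrpp_statistic(coordinates: np.ndarray, labels: np.ndarray) -> float:
    """Negated group-size-weighted mean within-group Euclidean distance."""
    x = np.asarray(coordinates, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    delta = 0.0
    for cls in np.unique(y):
        xi = x[y == cls]
        if len(xi) < 2:
            continue
        delta += (len(xi) / n) * pdist(xi).mean()
    return -delta  # larger = tighter groups = more structure


@dataclass(frozen=True)
class DiscriminationResult:
    genome_ids: tuple[str, ...]
    coordinates: np.ndarray = field(repr=False)
    lda_axis: np.ndarray
    projections: np.ndarray = field(repr=False)
    centroid_separation: float
    null_separations: np.ndarray = field(repr=False)
    p_value: float
    seed: int

    @property
    def n_permutations(self) -> int:
        return len(self.null_separations)


def permutation_test(
    coordinates: np.ndarray,
    labels: np.ndarray,
    m_permutations: int = 10_000,
    seed: int = 0,
    genome_ids: tuple[str, ...] | None = None,
    statistic: SeparationStatistic = SeparationStatistic.LDA,
) -> DiscriminationResult:
    """Monte-Carlo permutation test of the two-group centroid separation.

    For each of ``m_permutations`` label reshuffles (group sizes preserved)
    the separation statistic is recomputed; the add-one p-value and the
    full null distribution are returned.
    """
    if m_permutations < 1:
        raise ValueError("m_permutations must be >= 1")
    x = np.asarray(coordinates, dtype=float)
    y = np.asarray(labels)
    statistic = SeparationStatistic(statistic)

    if statistic is SeparationStatistic.LDA:
        axis, observed = lda_separation(x, y)
        stat = lambda yy: lda_separation(x, yy)[1]  # noqa: E731
    else:
        axis = np.zeros(x.shape[1])
        observed = _mrpp_statistic(x, y)
        stat = lambda yy: _mrpp_statistic(x, yy)  # noqa: E731

    rng = np.random.default_rng(seed)
    null = np.empty(m_permutations)
    for i in range(m_permutations):
        null[i] = stat(rng.permutation(y))
    p = (1 + int(np.count_nonzero(null >= observed))) / (1 + m_permutations)

    projections = x @ axis if statistic is SeparationStatistic.LDA else np.zeros(len(y))
    ids = genome_ids if genome_ids is not None else tuple(str(i) for i in range(len(y)))
    return DiscriminationResult(
        genome_ids=tuple(ids),
        coordinates=x,
        lda_axis=axis,
        projections=projections,
        centroid_separation=float(observed),
        null_separations=null,
        p_value=float(p),
        seed=seed,
    )


@dataclass(frozen=True)
class MultiGroupResult:
    groups: tuple[str, ...]
    pairwise_separation: dict[tuple[str, str], float]
    pairwise_p: dict[tuple[str, str], float]
    omnibus_separation: float
    omnibus_p: float
    m_permutations: int
    seed: int

    def separation(self, g1: str, g2: str) -> float:
        key = (g1, g2) if (g1, g2) in self.pairwise_separation else (g2, g1)
        return self.pairwise_separation[key]

    def p(self, g1: str, g2: str) -> float:
        key = (g1, g2) if (g1, g2) in self.pairwise_p else (g2, g1)
        return self.pairwise_p[key]


def _mean_pairwise_separation(x: np.ndarray, y: np.ndarray) -> float:
    seps = []
    for g1, g2 in itertools.combinations(np.unique(y), 2):
        mask = (y == g1) | (y == g2)
        seps.append(lda_separation(x[mask], y[mask])[1])
    return float(np.mean(seps))


def multigroup_test(
    coordinates: np.ndarray,
    labels: np.ndarray,
    m_permutations: int = 10_000,
    seed: int = 0,
) -> MultiGroupResult:
    """All pairwise two-group permutation tests plus an omnibus statistic.

    The omnibus statistic is the mean pairwise centroid separation; its
    p-value comes from permuting the full label vector.
    """
    x = np.asarray(coordinates, dtype=float)
    y = np.asarray(labels)
    groups = tuple(str(g) for g in np.unique(y))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if np.count_nonzero(y == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    pairwise_sep: dict[tuple[str, str], float] = {}
    pairwise_p: dict[tuple[str, str], float] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(groups) * (len(groups) - 1) // 2 + 1)
    for child, (g1, g2) in zip(children, itertools.combinations(groups, 2)):
        mask = (y == g1) | (y == g2)
        res = permutation_test(
            x[mask],
            y[mask],
            m_permutations=m_permutations,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        pairwise_sep[(g1, g2)] = res.centroid_separation
        pairwise_p[(g1, g2)] = res.p_value

    observed = _mean_pairwise_separation(x, y)
    rng = np.random.default_rng(int(children[-1].generate_state(1)[0] % 2**31))
    null = np.empty(m_permutations)
    for i in range(m_permutations):
        null[i] = _mean_pairwise_separation(x, rng.permutation(y))
    omnibus_p = (1 + int(np.count_nonzero(null >= observed))) / (1 + m_permutations)

    return MultiGroupResult(
        groups=groups,
        pairwise_separation=pairwise_sep,
        pairwise_p=pairwise_p,
        omnibus_separation=observed,
        omnibus_p=float(omnibus_p),
        m_permutations=m_permutations,
        seed=seed,
    )
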