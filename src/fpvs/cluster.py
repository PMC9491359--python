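"""Sensor-space one-sample cluster-based permutation test against a noise level.

The oddball-response SNR of a silent sensor is ~1, so evidence for a tagged
response is tested per sensor as a one-tailed one-sample t-test against 1,
with family-wise error controlled nonparametrically: sensors whose t exceeds
the one-tailed Student quantile at the cluster-forming alpha are grouped into
spatially connected clusters (triangulation-based adjacency, with each member
required to have at least ``min_neighbors`` suprathreshold neighbors), each
cluster is scored by the sum of its member t-values, and the observed scores
are referred to a Monte Carlo null distribution of maximum cluster scores
obtained by randomly sign-flipping each subject's deviation from the noise
level — the exact equivalent of swapping that subject's data with the
all-ones array in a within-subject design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from scipy.stats import t as student_t

from .simulate import SensorLayout

__all__ = [
    "AdjacencyGraph",
    "ClusterTestConfig",
    "Cluster",
    "ClusterTestResult",
    "build_adjacency",
    "one_sample_tmap",
    "form_clusters",
    "cluster_permutation_test",
]


@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive neighbor sets over a full sensor layout."""

    neighbors: list  # list[set[int]]
    method: str = "delaunay"
    positions: np.ndarray | None = None  # (n, 3), used for interpolation weights

    def __post_init__(self) -> None:
        for i, ns in enumerate(self.neighbors):
            if i in ns:
                raise ValueError(f"sensor {i} listed as its own neighbor")
            for j in ns:
                if i not in self.neighbors[j]:
                    raise ValueError(f"asymmetric adjacency between {i} and {j}")

    def __len__(self) -> int:
        return len(self.neighbors)

    def matrix(self) -> np.ndarray:
        """Dense boolean adjacency matrix."""
        n = len(self.neighbors)
        A = np.zeros((n, n), dtype=bool)
        for i, ns in enumerate(self.neighbors):
            A[i, list(ns)] = True
        return A

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(sparse.csr_matrix(self.matrix()))
        return n_comp == 1


def build_adjacency(layout: SensorLayout, method: str = "delaunay") -> AdjacencyGraph:
    """Triangulation-based sensor neighborhoods.

    Delaunay-triangulates the 2D projection of the layout; the edges of the
    triangles define the neighbor pairs (symmetric by construction).
    """
    if method != "delaunay":
        raise ValueError(f"unknown adjacency method {method!r}")
    if len(layout) < 4:
        raise ValueError("need at least 4 sensors to triangulate")
    try:
        tri = Delaunay(layout.projection)
    except QhullError as err:
        raise ValueError(f"layout projection cannot be triangulated: {err}") from err
    if tri.simplices.size == 0:
        raise ValueError("degenerate (collinear) layout projection")
    neighbors = [set() for _ in range(len(layout))]
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    neighbors[a].add(int(b))
    return AdjacencyGraph(neighbors=neighbors, method=method, positions=layout.positions)


@dataclass
class ClusterTestConfig:
    """Parameters of the cluster permutation test (defaults follow the design)."""

    null_value: float = 1.0
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    n_permutations: int = 5000
    tail: str = "greater"
    min_neighbors: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.cluster_alpha < 1 and 0 < self.alpha < 1):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if self.tail != "greater":
            raise ValueError("only the one-sided 'greater' tail is implemented")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Cluster:
    """A connected set of suprathreshold sensors scored by its summed t."""

    members: list
    statistic: float
    p_value: float = float("nan")
    significant: bool = False


@dataclass
class ClusterTestResult:
    tmap: np.ndarray
    df: int
    threshold: float
    clusters: list = field(default_factory=list)
    perm_max: np.ndarray | None = None
    config: ClusterTestConfig | None = None
    zero_variance: list = field(default_factory=list)

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.significant]

    def to_json(self, path, sensor_ids: list | None = None) -> None:
        ids = sensor_ids or [str(i) for i in range(len(self.tmap))]
        report = {
            "df": self.df,
            "threshold_t": self.threshold,
            "config": self.config.to_dict() if self.config else None,
            "zero_variance_sensors": [ids[i] for i in self.zero_variance],
            "clusters": [
                {
                    "members": [ids[i] for i in c.members],
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.clusters
            ],
        }
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)

    def tmap_to_tsv(self, path, sensor_ids: list | None = None) -> None:
        import pandas as pd

        ids = sensor_ids or [str(i) for i in range(len(self.tmap))]
        pd.DataFrame({"sensor": ids, "t": self.tmap}).to_csv(
            path, sep="\t", index=False
        )


def one_sample_tmap(
    responses: np.ndarray, null_value: float = 1.0
) -> tuple[np.ndarray, int]:
    """Per-sensor one-sample t statistic against a constant null value.

    t(s) = (mean(s) - null) / (sd(s) / sqrt(n)) with the n-1 sample sd;
    df = n - 1. A zero-variance sensor gives t = +/-inf (sign of the mean
    deviation) or 0 when the mean equals the null exactly.
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("responses must be a subjects x sensors matrix, n >= 2")
    n = X.shape[0]
    mean = X.mean(axis=0) - null_value
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0  # 0/0: mean exactly at null with zero variance
    return t, n - 1


def _prune(marked: np.ndarray, A: np.ndarray, min_neighbors: int) -> np.ndarray:
    """Iteratively drop marked sensors with < min_neighbors marked neighbors.

    Applied to a fixed point; vectorized over leading batch dimensions.
    """
    if min_neighbors <= 0:
        return marked
    Ai = A.astype(np.int8)
    marked = marked.copy()
    while True:
        counts = marked.astype(np.int8) @ Ai
        keep = marked & (counts >= min_neighbors)
        if np.array_equal(keep, marked):
            return keep
        marked = keep


def _components(mask: np.ndarray, A: np.ndarray, t: np.ndarray) -> list[Cluster]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = sparse.csr_matrix(A[np.ix_(idx, idx)])
    n_comp, labels = connected_components(sub, directed=False)
    clusters = []
    for c in range(n_comp):
        members = idx[labels == c]
        clusters.append(
            Cluster(members=members.tolist(), statistic=float(t[members].sum()))
        )
    clusters.sort(key=lambda c: -c.statistic)
    return clusters


def form_clusters(
    tmap: np.ndarray,
    threshold: float,
    adjacency: AdjacencyGraph,
    min_neighbors: int = 2,
) -> list[Cluster]:
    """Threshold, prune, and group sensors into candidate clusters.

    Sensors with t >= threshold are marked (+inf counts as suprathreshold);
    marked sensors with fewer than ``min_neighbors`` marked neighbors are
    dropped iteratively to a fixed point; connected components of the
    survivors are the clusters, each scored by its summed t, sorted by score.
    """
    t = np.asarray(tmap, dtype=float)
    if len(t) != len(adjacency):
        raise ValueError("t map and adjacency graph cover different sensor sets")
    A = adjacency.matrix()
    marked = _prune(t >= threshold, A, min_neighbors)
    return _components(marked, A, t)


def cluster_permutation_test(
    responses: np.ndarray,
    adjacency: AdjacencyGraph,
    config: ClusterTestConfig | None = None,
) -> ClusterTestResult:
    """One-sample cluster permutation test of responses against a noise level.

    The cluster-forming threshold is the one-tailed Student t quantile at
    1 - cluster_alpha with df = n - 1. The null distribution is built by
    sign-flipping each subject's deviation (response - null_value) with
    probability 1/2, independently per subject and permutation, and recording
    the maximum cluster score (0 when no cluster forms). Each observed
    cluster's Monte Carlo p is (1 + #{perm maxima >= score}) / (1 + n_perm);
    clusters with p <= alpha are flagged significant.
    """
    if config is None:
        config = ClusterTestConfig()
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("responses must be a subjects x sensors matrix, n >= 2")
    if X.shape[1] != len(adjacency):
        raise ValueError(
            f"{X.shape[1]} sensors in responses vs {len(adjacency)} in adjacency"
        )
    n, m = X.shape
    df = n - 1
    threshold = float(student_t.ppf(1.0 - config.cluster_alpha, df))
    tobs, _ = one_sample_tmap(X, config.null_value)
    zero_var = np.flatnonzero(X.std(axis=0, ddof=1) == 0).tolist()
    clusters = form_clusters(tobs, threshold, adjacency, config.min_neighbors)

    dev = X - config.null_value
    ssq = (dev**2).sum(axis=0)
    rng = np.random.default_rng(config.seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(config.n_permutations, n))
    means = signs @ dev / n
    var = np.clip((ssq - n * means**2) / (n - 1), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        tperm = means / np.sqrt(var / n)
    tperm[np.isnan(tperm)] = 0.0

    A = adjacency.matrix()
    marked = _prune(tperm >= threshold, A, config.min_neighbors)
    perm_max = np.zeros(config.n_permutations)
    for i in np.flatnonzero(marked.any(axis=1)):
        comps = _components(marked[i], A, tperm[i])
        if comps:
            perm_max[i] = comps[0].statistic

    for c in clusters:
        # relative epsilon: the identity sign pattern reproduces the observed
        # statistic up to summation order, and must count as >=
        cut = c.statistic - 1e-7 * max(1.0, abs(c.statistic))
        c.p_value = float(
            (1 + np.sum(perm_max >= cut)) / (1 + config.n_permutations)
        )
        c.significant = c.p_value <= config.alpha

    return ClusterTestResult(
        tmap=tobs,
        df=df,
        threshold=threshold,
        clusters=clusters,
        perm_max=perm_max,
        config=config,
        zero_variance=zero_var,
    )
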