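"""Cell-type classification: morphology similarity, Ward clustering, and
partition agreement against reference labels.

Morphology similarity is a simplified point-and-tangent score: each query
point contributes ``exp(-d/sigma) * |u . v|`` where d is the distance to its
nearest neighbour in the target cloud and u, v are the local tangent unit
vectors.  The raw score is normalized by the self-score and symmetrized by
averaging the two directions, so self-similarity is exactly 1.  Any other
pairwise-similarity provider with the same signature can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from lhcoding.datasets import LabeledSkeleton


@dataclass
class Dotprops:
    """Resampled point cloud with unit tangent vectors for one skeleton."""

    points: np.ndarray
    tangents: np.ndarray
    cloud_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, dtype=float))
        if len(self.points) == 0:
            raise ValueError("empty dotprops cloud")
        norms = np.linalg.norm(self.tangents, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self.tangents = self.tangents / norms

    @classmethod
    def from_points(cls, points: np.ndarray, k: int = 5, cloud_id: str = "") -> "Dotprops":
        """Tangents from the first principal direction of each point's k
        nearest neighbours (the published dotprops convention, k = 5)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if len(pts) == 0:
            raise ValueError("empty point cloud")
        k = min(k, len(pts))
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k)
        idx = np.atleast_2d(idx.T).T if k == 1 else idx
        tangents = np.zeros_like(pts)
        for i in range(len(pts)):
            nbrs = pts[np.atleast_1d(idx[i])]
            centered = nbrs - nbrs.mean(axis=0)
            if len(nbrs) < 2 or not np.any(centered):
                tangents[i] = (1.0, 0.0, 0.0)
                continue
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            tangents[i] = vt[0]
        return cls(pts, tangents, cloud_id=cloud_id)

    @classmethod
    def from_skeleton(
        cls,
        skel: LabeledSkeleton,
        spacing: float = 1.0,
        k: int = 5,
        compartment: int | None = None,
    ) -> "Dotprops":
        pts = skel.resample_points(spacing, compartment)
        return cls.from_points(pts, k=k, cloud_id=skel.skeleton_id)


def _raw_score(a: Dotprops, b: Dotprops, sigma: float) -> float:
    tree = cKDTree(b.points)
    d, j = tree.query(a.points, k=1)
    dots = np.abs(np.sum(a.tangents * b.tangents[j], axis=1))
    return float(np.sum(np.exp(-d / sigma) * dots))


def morphology_similarity(a: Dotprops, b: Dotprops, sigma: float = 3.0) -> float:
    """Symmetric normalized similarity in [0, 1]; self-comparison gives 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ab = _raw_score(a, b, sigma) / _raw_score(a, a, sigma)
    ba = _raw_score(b, a, sigma) / _raw_score(b, b, sigma)
    return 0.5 * (ab + ba)


def raw_morphology_score(a: Dotprops, b: Dotprops, sigma: float = 3.0) -> float:
    """Unnormalized directed score S(a, b)."""
    return _raw_score(a, b, sigma)


def similarity_matrix(
    clouds: list[Dotprops], sigma: float = 3.0, score=None
) -> pd.DataFrame:
    """Pairwise symmetric similarity; ``score`` may override the default."""
    score = score or (lambda x, y: morphology_similarity(x, y, sigma))
    n = len(clouds)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = score(clouds[i], clouds[j])
    ids = [c.cloud_id or str(i) for i, c in enumerate(clouds)]
    return pd.DataFrame(mat, index=ids, columns=ids)


# ------------------------------------------------------------------ clustering


def ward_cluster(similarity: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward (minimum-variance) linkage on distance = 1 − similarity.

    Applies the ward.d2-style Lance–Williams update directly to the given
    dissimilarities; ties break toward the lowest index (scipy convention).
    """
    sim = np.asarray(similarity, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if not np.allclose(sim, sim.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method="ward")


def linkage_from_distance(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward linkage directly from a symmetric distance matrix."""
    d = np.asarray(dist, dtype=float)
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    d = d.copy()
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="ward")


@dataclass
class PartitionScore:
    """Agreement between a dendrogram cut and reference labels."""

    ari: float
    percent_correct: float
    n_clusters: int
    cut_height: float
    assignments: np.ndarray


def classification_error(pred: np.ndarray, ref: np.ndarray) -> float:
    """Minimum mislabeling fraction under optimal cluster-to-label matching
    (Hungarian assignment on the confusion matrix)."""
    pred_ids = {c: i for i, c in enumerate(pd.unique(pred))}
    ref_ids = {c: i for i, c in enumerate(pd.unique(ref))}
    conf = np.zeros((len(pred_ids), len(ref_ids)))
    for p, r in zip(pred, ref):
        conf[pred_ids[p], ref_ids[r]] += 1
    rows, cols = linear_sum_assignment(-conf)
    return 1.0 - conf[rows, cols].sum() / len(pred)


def optimize_cut(link: np.ndarray, reference: np.ndarray) -> PartitionScore:
    """Sweep every distinct merge height; return scores at the cut with the
    minimum classification error (ties break toward fewer clusters)."""
    reference = np.asarray(reference)
    n = link.shape[0] + 1
    if n < 2 or len(reference) != n:
        raise ValueError("need one reference label per clustered item (n >= 2)")
    heights = np.concatenate([[0.0], np.sort(np.unique(link[:, 2]))])
    cuts = np.concatenate([(heights[:-1] + heights[1:]) / 2.0, [heights[-1] + 1.0]])
    best: PartitionScore | None = None
    for cut in cuts:
        assign = fcluster(link, t=cut, criterion="distance")
        err = classification_error(assign, reference)
        k = len(np.unique(assign))
        score = PartitionScore(
            ari=adjusted_rand_score(reference, assign),
            percent_correct=100.0 * (1.0 - err),
            n_clusters=k,
            cut_height=float(cut),
            assignments=assign,
        )
        if (
            best is None
            or score.percent_correct > best.percent_correct + 1e-12
            or (
                abs(score.percent_correct - best.percent_correct) <= 1e-12
                and k < best.n_clusters
            )
        ):
            best = score
    assert best is not None
    return best


def pooled_vs_global_classification(
    cells: pd.DataFrame,
    anatomy_similarity: pd.DataFrame,
    physiology_correlation: pd.DataFrame,
) -> pd.DataFrame:
    """Cut-optimized clustering per primary-neurite-tract pool and globally.

    ``cells`` is indexed by cell id with ``tract`` and ``cell_type`` columns;
    the two matrices are square over the same cell ids (similarity in [0, 1]
    for anatomy, Pearson correlation for physiology; distance = 1 − value).
    Pools with a single cell type are skipped with a report row.
    """
    results = []

    def run(ids: list, scope: str) -> None:
        ref = cells.loc[ids, "cell_type"].to_numpy()
        if len(np.unique(ref)) < 2:
            results.append(
                {"scope": scope, "modality": "-", "ari": np.nan,
                 "percent_correct": np.nan, "n_clusters": 0, "skipped": True}
            )
            return
        for modality, mat in (
            ("anatomy", anatomy_similarity),
            ("physiology", physiology_correlation),
        ):
            sub = mat.loc[ids, ids]
            score = optimize_cut(ward_cluster(sub), ref)
            results.append(
                {
                    "scope": scope,
                    "modality": modality,
                    "ari": score.ari,
                    "percent_correct": score.percent_correct,
                    "n_clusters": score.n_clusters,
                    "skipped": False,
                }
            )

    for tract, sub in cells.groupby("tract"):
        run(list(sub.index), f"pool:{tract}")
    run(list(cells.index), "global")
    return pd.DataFrame(results)
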