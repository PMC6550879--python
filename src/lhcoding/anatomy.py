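"""Quantitative neuroanatomy: arbor overlap scores, core output-neuron
selection, cable-by-region tallies, and supervoxel kernel-density maps.

The overlap score between two 1 µm-resampled point clouds i and j is
``sum_s sum_k exp(-d(s,k)^2 / (2 delta^2))`` — a Gaussian potential-synapse
count with length scale delta (default 1 µm).  Neurons scoring below 6000
against the projection-neuron axon reference are treated as merely skimming
the lateral horn.  Supervoxels are weighted Gaussian kernel-density fields
built from Ward-clustered arbor sub-branches (trunk removed by Strahler
order), 25 clusters per space, each point weighted 1/(cluster point count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from lhcoding.config import AnatomyParams
from lhcoding.datasets import SWC_AXON, SWC_DENDRITE, LabeledSkeleton


@dataclass(frozen=True)
class Box:
    """Axis-aligned region mask in µm coordinates."""

    name: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"box {self.name!r}: lo must be < hi per axis")

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo) & (p <= hi), axis=1)

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.lo) + np.asarray(self.hi)) / 2.0


def make_region_layout(boxes: list[Box]) -> dict[str, Box]:
    names = [b.name for b in boxes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate region names: {dupes}")
    return {b.name: b for b in boxes}


# -------------------------------------------------------------- overlap score


def overlap_score(a: np.ndarray, b: np.ndarray, delta: float = 1.0) -> float:
    """Gaussian overlap between two point clouds (symmetric in a, b)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        warnings.warn("overlap_score of an empty cloud is 0", stacklevel=2)
        return 0.0
    total = 0.0
    chunk = 2000  # bound the pairwise-distance workspace
    for start in range(0, len(a), chunk):
        d2 = cdist(a[start : start + chunk], b, "sqeuclidean")
        total += float(np.exp(-d2 / (2.0 * delta**2)).sum())
    return total


def dendrite_fraction_in_region(skel: LabeledSkeleton, region: Box) -> float:
    """Fraction of dendritic cable inside ``region`` (segment-exact)."""
    segs = skel.segments(SWC_DENDRITE)
    if len(segs) == 0:
        return float("nan")
    total = np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1).sum()
    inside = sum(_segment_length_in_box(a, b, region) for a, b in segs)
    return float(inside / total) if total > 0 else float("nan")


def select_core_lhons(
    skeletons: dict[str, LabeledSkeleton],
    pn_axon_cloud: np.ndarray,
    lh_region: Box,
    params: AnatomyParams | None = None,
) -> pd.DataFrame:
    """Flag core output neurons: sufficient PN-axon overlap and >50% of
    dendritic cable inside the lateral horn.

    Returns a DataFrame indexed by skeleton id with ``overlap``,
    ``dendrite_fraction`` and ``core`` columns.  Neurons without a dendritic
    compartment are reported with NaN fraction and excluded from the core set.
    """
    params = params or AnatomyParams()
    rows = []
    for sid, skel in skeletons.items():
        dend = skel.resample_points(1.0, SWC_DENDRITE)
        if len(dend) == 0:
            rows.append((sid, 0.0, float("nan"), False))
            continue
        score = overlap_score(dend, pn_axon_cloud, params.delta)
        frac = dendrite_fraction_in_region(skel, lh_region)
        core = score >= params.overlap_threshold and frac > params.dendrite_fraction
        rows.append((sid, score, frac, bool(core)))
    return pd.DataFrame(
        rows, columns=["skeleton_id", "overlap", "dendrite_fraction", "core"]
    ).set_index("skeleton_id")


# ------------------------------------------------------------ cable by region


def _segment_length_in_box(a: np.ndarray, b: np.ndarray, box: Box) -> float:
    """Length of the part of segment a→b inside an axis-aligned box."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = b - a
    length = float(np.linalg.norm(d))
    if length == 0:
        return 0.0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        lo, hi = box.lo[ax], box.hi[ax]
        if d[ax] == 0:
            if not (lo <= a[ax] <= hi):
                return 0.0
        else:
            ta = (lo - a[ax]) / d[ax]
            tb = (hi - a[ax]) / d[ax]
            ta, tb = min(ta, tb), max(ta, tb)
            t0, t1 = max(t0, ta), min(t1, tb)
            if t0 >= t1:
                return 0.0
    return length * (t1 - t0)


def cable_by_region(
    skeletons: dict[str, LabeledSkeleton],
    type_labels: pd.Series,
    regions: dict[str, Box],
    compartment: int = SWC_AXON,
) -> pd.DataFrame:
    """Per-type mean compartment cable (µm) inside each region.

    Segments crossing a region boundary are split exactly at the boundary.
    The per-region total is the sum of per-type means (so cell types sampled
    at different frequencies contribute equally), following the
    sum-of-type-means convention of the axonal-target tally.
    """
    per_neuron = {}
    for sid, skel in skeletons.items():
        segs = skel.segments(compartment)
        row = {}
        for name, box in regions.items():
            row[name] = sum(_segment_length_in_box(a, b, box) for a, b in segs)
        per_neuron[sid] = row
    df = pd.DataFrame.from_dict(per_neuron, orient="index")
    df["cell_type"] = type_labels.reindex(df.index)
    type_means = df.groupby("cell_type").mean()
    totals = type_means.sum(axis=0).rename("total_cable")
    return pd.DataFrame({"region_total": totals}).join(type_means.T)


# ------------------------------------------------------------- Strahler order


def strahler_order(skel: LabeledSkeleton) -> pd.Series:
    """Strahler order per node (leaf = 1; parent order increments when two or
    more children share the maximum)."""
    nodes = skel.nodes
    children: dict[int, list[int]] = {int(n): [] for n in nodes["node_id"]}
    for nid, pid in zip(nodes["node_id"], nodes["parent_id"]):
        if pid != -1:
            children[int(pid)].append(int(nid))
    order: dict[int, int] = {}

    for root in skel.roots:
        stack = [(int(root), False)]
        while stack:
            nid, processed = stack.pop()
            kids = children[nid]
            if not kids:
                order[nid] = 1
            elif processed:
                ko = [order[k] for k in kids]
                m = max(ko)
                order[nid] = m + 1 if ko.count(m) >= 2 else m
            else:
                stack.append((nid, True))
                stack.extend((k, False) for k in kids)
    return pd.Series(order).reindex(nodes["node_id"]).rename("strahler")


def sub_branches(
    skel: LabeledSkeleton, compartment: int | None = None
) -> list[np.ndarray]:
    """Connected sub-branch point sets after removing the highest-Strahler trunk.

    Returns one (n, 3) coordinate array per remaining connected component,
    resampled at the node level (callers resample at 1 µm as needed).
    """
    import networkx as nx

    order = strahler_order(skel)
    order.index = skel.nodes["node_id"].to_numpy()
    labels = skel.effective_labels()
    labels.index = skel.nodes["node_id"].to_numpy()
    max_order = int(order.max())
    keep = set(order.index[order < max_order])
    if compartment is not None:
        keep &= set(labels.index[labels == compartment])
    g = nx.Graph()
    g.add_nodes_from(keep)
    for nid, pid in zip(skel.nodes["node_id"], skel.nodes["parent_id"]):
        if pid != -1 and int(nid) in keep and int(pid) in keep:
            g.add_edge(int(nid), int(pid))
    pos = skel.nodes.set_index("node_id")[["x", "y", "z"]]
    comps = []
    for comp in nx.connected_components(g):
        comps.append(pos.loc[sorted(comp)].to_numpy(dtype=float))
    return comps


# ------------------------------------------------------------- supervoxels


@dataclass
class DensityField:
    """Weighted isotropic-Gaussian kernel density over 3-D space.

    ``points`` (n, 3) each carry weight 1/n so that fields from clusters of
    different sizes are directly comparable; weights sum to 1 by construction.
    """

    points: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            raise ValueError("density field needs at least one point")

    @property
    def weights(self) -> np.ndarray:
        n = len(self.points)
        return np.full(n, 1.0 / n)

    def evaluate(self, query: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(query, dtype=float))
        bw = self.bandwidth
        norm = (2.0 * np.pi) ** -1.5 * bw**-3
        d2 = cdist(q, self.points, "sqeuclidean")
        return norm * (np.exp(-d2 / (2.0 * bw**2)) @ self.weights)


@dataclass
class SupervoxelSet:
    """Cluster-derived density fields for one space (LH dendritic or target axonal)."""

    fields: list[DensityField]
    space: str = ""

    def inclusion(self, arbor_points: np.ndarray) -> np.ndarray:
        """Mean field density over the arbor's points, per field."""
        pts = np.atleast_2d(np.asarray(arbor_points, dtype=float))
        if pts.size == 0:
            return np.zeros(len(self.fields))
        return np.array([f.evaluate(pts).mean() for f in self.fields])


def build_supervoxels(
    skeletons: dict[str, LabeledSkeleton],
    compartment: int,
    n_clusters: int = 25,
    bandwidth: float = 5.0,
    seed: int = 0,
    sigma: float = 3.0,
    space: str = "",
) -> SupervoxelSet:
    """Cluster arbor sub-branches by morphology similarity and build one
    weighted KDE field per cluster.

    Sub-branches are what remains of each arbor after removing its
    highest-Strahler-order trunk; they are clustered with the same simplified
    morphology similarity used for cell typing (Ward linkage on 1 −
    similarity) into ``n_clusters`` groups.
    """
    from lhcoding.classify import Dotprops, similarity_matrix, ward_cluster
    from scipy.cluster.hierarchy import fcluster

    branches: list[np.ndarray] = []
    for skel in skeletons.values():
        for comp in sub_branches(skel, compartment):
            if len(comp) >= 2:
                branches.append(comp)
    if len(branches) < n_clusters:
        raise ValueError(
            f"only {len(branches)} sub-branches for {n_clusters} clusters"
        )
    dps = [
        Dotprops.from_points(b, k=min(5, len(b)), cloud_id=str(i))
        for i, b in enumerate(branches)
    ]
    sim = similarity_matrix(dps, sigma=sigma)
    link = ward_cluster(sim)
    assign = fcluster(link, t=n_clusters, criterion="maxclust")
    fields = []
    for c in range(1, int(assign.max()) + 1):
        pts = np.concatenate([branches[i] for i in np.where(assign == c)[0]], axis=0)
        fields.append(DensityField(pts, bandwidth))
    return SupervoxelSet(fields, space=space)


def supervoxel_scores(
    lh_set: SupervoxelSet,
    target_set: SupervoxelSet,
    dendrite_arbors: dict[str, np.ndarray],
    axon_arbors: dict[str, np.ndarray],
    category_per_type: dict[str, str] | None = None,
    threshold_percentile: float = 90.0,
) -> dict:
    """Inclusion, projection, and category-voxel score maps.

    * inclusion: per (type, field) mean density over the arbor's 1 µm points;
    * projection: per type, outer product of mean LH and target inclusions;
    * category score: per (field, category), mean inclusion over the types
      whose best-categorized odor category is that category;
    * thresholds: independent display thresholds per space (a score
      percentile, default the 90th).
    """
    types = sorted(dendrite_arbors)
    lh_inc = pd.DataFrame(
        {t: lh_set.inclusion(dendrite_arbors[t]) for t in types}
    ).T
    tgt_inc = pd.DataFrame(
        {t: target_set.inclusion(axon_arbors.get(t, np.zeros((0, 3)))) for t in types}
    ).T
    projection = {
        t: np.outer(lh_inc.loc[t].to_numpy(), tgt_inc.loc[t].to_numpy())
        for t in types
    }
    out = {
        "lh_inclusion": lh_inc,
        "target_inclusion": tgt_inc,
        "projection": projection,
        "lh_threshold": float(np.percentile(lh_inc.to_numpy(), threshold_percentile)),
        "target_threshold": float(
            np.percentile(tgt_inc.to_numpy(), threshold_percentile)
        ),
    }
    if category_per_type:
        cats = sorted(set(category_per_type.values()))
        cat_scores = {}
        for space, inc in (("lh", lh_inc), ("target", tgt_inc)):
            mat = pd.DataFrame(index=inc.columns, columns=cats, dtype=float)
            for cat in cats:
                members = [t for t in types if category_per_type.get(t) == cat]
                if members:
                    mat[cat] = inc.loc[members].mean(axis=0)
            cat_scores[space] = mat
        out["category_scores"] = cat_scores
    return out
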