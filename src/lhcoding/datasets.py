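"""Core in-memory containers: odor panels, trial-structured spike data, skeletons.

All spike times are seconds from trial onset; skeleton coordinates are in
micrometres.  Containers are thin wrappers around pandas DataFrames so that the
analysis modules can use ordinary vectorized operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six chemical-group flags used to categorize odors.
CATEGORIES = ("alcohol", "aldehyde", "amine", "carboxyl", "ester", "phenyl")

GROUPS = ("PN", "LHLN", "LHON")

SPIKE_COLUMNS = ["cell_id", "group", "cell_type", "odor_id", "trial", "spike_time"]

#: SWC structure-type codes used for compartments.
SWC_SOMA, SWC_AXON, SWC_DENDRITE = 1, 2, 3


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass
class OdorPanel:
    """Odor metadata: chemical-category flags and solvent, plus a blank control.

    ``table`` has one row per stimulus with columns ``odor_id``, ``categories``
    (frozenset of flags, possibly empty), ``solvent`` and ``is_blank``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"odor_id", "categories", "solvent", "is_blank"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"odor panel missing columns: {sorted(missing)}")
        if self.table["odor_id"].duplicated().any():
            dups = self.table.loc[self.table["odor_id"].duplicated(), "odor_id"]
            raise ValidationError(f"duplicate odor ids: {sorted(set(dups))}")
        bad = [
            (o, sorted(c - set(CATEGORIES)))
            for o, c in zip(self.table["odor_id"], self.table["categories"])
            if not set(c) <= set(CATEGORIES)
        ]
        if bad:
            raise ValidationError(f"unknown category flags: {bad}")

    @property
    def odor_ids(self) -> list[str]:
        """All stimulus ids including the blank."""
        return list(self.table["odor_id"])

    @property
    def test_odors(self) -> list[str]:
        """Odor ids excluding blank controls."""
        return list(self.table.loc[~self.table["is_blank"], "odor_id"])

    @property
    def blank(self) -> str | None:
        blanks = self.table.loc[self.table["is_blank"], "odor_id"]
        return None if blanks.empty else str(blanks.iloc[0])

    def categories_of(self, odor_id: str) -> frozenset:
        row = self.table.loc[self.table["odor_id"] == odor_id]
        if row.empty:
            raise KeyError(odor_id)
        return frozenset(row["categories"].iloc[0])

    def category_mask(self, category: str) -> pd.Series:
        """Boolean series over test odors: does the odor carry the flag?"""
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        sub = self.table.loc[~self.table["is_blank"]]
        return pd.Series(
            [category in c for c in sub["categories"]],
            index=list(sub["odor_id"]),
            name=category,
        )


@dataclass
class SpikeDataset:
    """Trial-structured spike times for a set of cells.

    ``spikes`` has one row per spike (long format) with columns
    ``cell_id, group, cell_type, odor_id, trial, spike_time``.
    """

    spikes: pd.DataFrame
    panel: OdorPanel
    trial_duration: float = 3.0
    n_trials: int = 4

    def __post_init__(self) -> None:
        missing = set(SPIKE_COLUMNS) - set(self.spikes.columns)
        if missing:
            raise FormatError(f"spike table missing columns: {sorted(missing)}")
        t = self.spikes["spike_time"].to_numpy(dtype=float)
        bad = (t < 0) | (t > self.trial_duration)
        if bad.any():
            rows = self.spikes.index[bad][:10].tolist()
            raise ValidationError(
                f"{int(bad.sum())} spike times outside [0, {self.trial_duration}] s "
                f"(first offending rows: {rows})"
            )
        if (self.spikes["trial"] < 1).any():
            raise ValidationError("trial indices must be >= 1")
        unknown = set(self.spikes["odor_id"]) - set(self.panel.odor_ids)
        if unknown:
            raise ValidationError(f"unknown odor ids in spike table: {sorted(unknown)}")

    @property
    def cells(self) -> list[str]:
        return sorted(self.spikes["cell_id"].unique())

    def cell_meta(self) -> pd.DataFrame:
        """One row per cell: group and cell-type label."""
        meta = (
            self.spikes[["cell_id", "group", "cell_type"]]
            .drop_duplicates("cell_id")
            .set_index("cell_id")
            .sort_index()
        )
        return meta

    def count_in_window(self, window: tuple[float, float]) -> pd.DataFrame:
        """Spike counts per (cell, odor, trial) within ``window`` (half-open).

        Trials with zero spikes anywhere are absent from the spike table, so the
        caller must reindex against the full trial grid where that matters.
        """
        lo, hi = window
        t = self.spikes["spike_time"]
        sub = self.spikes.loc[(t >= lo) & (t < hi)]
        counts = (
            sub.groupby(["cell_id", "odor_id", "trial"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        return counts

    def spike_times(self, cell_id: str, odor_id: str) -> pd.DataFrame:
        sub = self.spikes.loc[
            (self.spikes["cell_id"] == cell_id) & (self.spikes["odor_id"] == odor_id),
            ["trial", "spike_time"],
        ]
        return sub


SWC_COLUMNS = ["node_id", "label", "x", "y", "z", "radius", "parent_id"]


@dataclass
class LabeledSkeleton:
    """A neuron skeleton as an SWC node table with compartment labels.

    ``nodes`` columns follow the 7-column SWC convention (``node_id, label, x,
    y, z, radius, parent_id``); ``parent_id`` is -1 at roots.  Label codes 2 and
    3 mark axonal and dendritic compartments; unlabeled nodes (0/5) inherit the
    nearest labeled ancestor's compartment on request.
    """

    nodes: pd.DataFrame
    skeleton_id: str = ""

    def __post_init__(self) -> None:
        missing = set(SWC_COLUMNS) - set(self.nodes.columns)
        if missing:
            raise FormatError(f"SWC table missing columns: {sorted(missing)}")
        self.nodes = self.nodes[SWC_COLUMNS].reset_index(drop=True)
        ids = self.nodes["node_id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate SWC node ids")
        idset = set(ids.tolist())
        parents = self.nodes["parent_id"].to_numpy()
        for nid, pid in zip(ids, parents):
            if pid != -1 and pid not in idset:
                raise FormatError(f"node {nid} references missing parent {pid}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = dict(zip(self.nodes["node_id"], self.nodes["parent_id"]))
        state: dict[int, int] = {}  # 1 = on stack, 2 = done
        for start in parent:
            if state.get(start):
                continue
            chain = []
            nid = start
            while nid != -1 and not state.get(nid):
                state[nid] = 1
                chain.append(nid)
                nid = parent[nid]
            if nid != -1 and state.get(nid) == 1:
                raise FormatError(f"cyclic parent references involving node {nid}")
            for c in chain:
                state[c] = 2

    @property
    def roots(self) -> list[int]:
        return self.nodes.loc[self.nodes["parent_id"] == -1, "node_id"].tolist()

    def segments(self, compartment: int | None = None) -> np.ndarray:
        """Parent-child segments as an array of shape (n, 2, 3).

        A segment belongs to a compartment if its child node carries (or
        inherits) that label.
        """
        nodes = self.nodes
        if compartment is not None:
            labels = self.effective_labels()
            keep = labels == compartment
        else:
            keep = pd.Series(True, index=nodes.index)
        pos = nodes.set_index("node_id")[["x", "y", "z"]]
        child = nodes.loc[keep & (nodes["parent_id"] != -1)]
        if child.empty:
            return np.zeros((0, 2, 3))
        a = pos.loc[child["parent_id"]].to_numpy(dtype=float)
        b = child[["x", "y", "z"]].to_numpy(dtype=float)
        return np.stack([a, b], axis=1)

    def effective_labels(self) -> pd.Series:
        """Node labels with undefined codes inheriting the nearest labeled ancestor."""
        parent = dict(zip(self.nodes["node_id"], self.nodes["parent_id"]))
        raw = dict(zip(self.nodes["node_id"], self.nodes["label"]))

        cache: dict[int, int] = {}

        def resolve(nid: int) -> int:
            seen = []
            cur = nid
            while cur != -1 and cur not in cache:
                lab = raw[cur]
                if lab in (SWC_SOMA, SWC_AXON, SWC_DENDRITE):
                    cache[cur] = lab
                    break
                seen.append(cur)
                cur = parent[cur]
            base = cache.get(cur, raw[nid]) if cur != -1 else raw[seen[-1]] if seen else raw[nid]
            for s in seen:
                cache[s] = base
            return cache.setdefault(nid, base)

        return pd.Series(
            [resolve(n) for n in self.nodes["node_id"]], index=self.nodes.index
        )

    def cable_length(self, compartment: int | None = None) -> float:
        """Total cable (sum of parent-child segment lengths), micrometres."""
        segs = self.segments(compartment)
        if len(segs) == 0:
            return 0.0
        return float(np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1).sum())

    def resample_points(
        self, spacing: float = 1.0, compartment: int | None = None
    ) -> np.ndarray:
        """Points at ~``spacing`` µm arc-length intervals along each segment.

        Each parent-child segment contributes its endpoints plus evenly spaced
        interior points, de-duplicated; this is the 1 µm "points in the neuron"
        convention used by the overlap and supervoxel scores.
        """
        segs = self.segments(compartment)
        if len(segs) == 0:
            return np.zeros((0, 3))
        pts = []
        for a, b in segs:
            length = float(np.linalg.norm(b - a))
            n = max(1, int(np.ceil(length / spacing)))
            ts = np.linspace(0.0, 1.0, n + 1)
            pts.append(a[None, :] + ts[:, None] * (b - a)[None, :])
        allpts = np.concatenate(pts, axis=0)
        return np.unique(np.round(allpts, 6), axis=0)
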