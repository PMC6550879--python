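"""Readers and writers for the plain-text formats the pipeline exchanges.

Spike data travel as long-format CSV (one row per spike), odor panels and
census samples as CSV, skeletons as standard 7-column SWC.  Every reader
validates domain invariants and every reader/writer pair round-trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from lhcoding.datasets import (
    SPIKE_COLUMNS,
    SWC_COLUMNS,
    FormatError,
    LabeledSkeleton,
    OdorPanel,
    SpikeDataset,
)

# ---------------------------------------------------------------- odor panels


def write_odor_panel(panel: OdorPanel, path: str | Path) -> None:
    out = panel.table.copy()
    out["categories"] = ["|".join(sorted(c)) for c in out["categories"]]
    out.to_csv(path, index=False)


def read_odor_panel(path: str | Path) -> OdorPanel:
    df = pd.read_csv(path, dtype={"odor_id": str, "solvent": str})
    missing = {"odor_id", "categories", "solvent", "is_blank"} - set(df.columns)
    if missing:
        raise FormatError(f"odor panel CSV missing columns: {sorted(missing)}")
    df["categories"] = [
        frozenset() if pd.isna(c) or c == "" else frozenset(str(c).split("|"))
        for c in df["categories"]
    ]
    df["is_blank"] = df["is_blank"].astype(bool)
    return OdorPanel(df)


# ---------------------------------------------------------------- spike tables


def write_spike_table(ds: SpikeDataset, path: str | Path) -> None:
    ds.spikes[SPIKE_COLUMNS].to_csv(path, index=False)


def read_spike_table(
    path: str | Path,
    panel: OdorPanel,
    trial_duration: float = 3.0,
    n_trials: int = 4,
) -> SpikeDataset:
    """Read a long-format spike CSV into a :class:`SpikeDataset`.

    Unknown odor ids and spike times outside the trial raise validation
    errors naming the offending rows; an empty file (header only) yields a
    dataset with zero cells.
    """
    df = pd.read_csv(
        path, dtype={"cell_id": str, "group": str, "cell_type": str, "odor_id": str}
    )
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"spike CSV missing columns: {sorted(missing)}")
    if len(df):
        df["trial"] = df["trial"].astype(int)
        df["spike_time"] = df["spike_time"].astype(float)
    else:
        df = df.astype({"trial": int, "spike_time": float})
    return SpikeDataset(df, panel, trial_duration=trial_duration, n_trials=n_trials)


# ------------------------------------------------------------------ skeletons


def read_swc(path: str | Path, skeleton_id: str | None = None) -> LabeledSkeleton:
    """Parse a standard 7-column SWC file (``#`` comments allowed)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}")
        try:
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    sid = skeleton_id if skeleton_id is not None else Path(path).stem
    return LabeledSkeleton(nodes, skeleton_id=sid)


def write_swc(skel: LabeledSkeleton, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# node_id label x y z radius parent_id\n")
        for row in skel.nodes.itertuples(index=False):
            fh.write(
                f"{int(row.node_id)} {int(row.label)} {row.x:.6f} {row.y:.6f} "
                f"{row.z:.6f} {row.radius:.6f} {int(row.parent_id)}\n"
            )


# -------------------------------------------------------------- census tables


def read_census_table(path: str | Path) -> pd.DataFrame:
    """Census CSV with columns ``tract, N, n, k, cls`` (one row per tract)."""
    df = pd.read_csv(path, dtype={"tract": str, "cls": str})
    missing = {"tract", "N", "n", "k", "cls"} - set(df.columns)
    if missing:
        raise FormatError(f"census CSV missing columns: {sorted(missing)}")
    for col in ("N", "n", "k"):
        df[col] = df[col].astype(int)
    bad = df.loc[(df["k"] < 0) | (df["k"] > df["n"]) | (df["n"] > df["N"])]
    if len(bad):
        raise FormatError(f"census rows violate 0 <= k <= n <= N: {bad['tract'].tolist()}")
    return df


def write_census_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["tract", "N", "n", "k", "cls"]].to_csv(path, index=False)
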