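"""Spike-train response analysis: PSTHs, exact Poisson response test, FDR
control, rate summaries, reliability, and tuning breadth/sparseness.

A cell-odor pair "responds" when the spike count in the 0.7–2.2 s test window,
pooled over trials, significantly exceeds the count for the blank (solvent)
control of the same cell under an exact one-sided two-sample Poisson test,
with Benjamini–Hochberg FDR control over each cell's family of odor p-values
(significant at adjusted p < 0.01; a per-trial variant uses p < 0.04).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lhcoding.config import AnalysisWindows, DetectionParams
from lhcoding.datasets import SpikeDataset


# ---------------------------------------------------------------------- PSTH


def psth_window_starts(w: AnalysisWindows) -> np.ndarray:
    """Sliding-window start times: 0, step, 2·step, … while start+window ≤ span end."""
    lo, hi = w.psth_span
    n = int(np.floor((hi - lo - w.psth_window) / w.psth_step + 1e-9)) + 1
    return lo + w.psth_step * np.arange(n)


def compute_psth(ds: SpikeDataset, w: AnalysisWindows | None = None) -> pd.DataFrame:
    """Trial-averaged firing rate (Hz) per (cell, odor) in sliding windows.

    Returns a DataFrame indexed by (cell_id, odor_id) whose columns are the
    window start times.  rate(t) = spikes in [t, t+window) summed over trials,
    divided by window × n_trials.
    """
    if w is None:
        w = AnalysisWindows()
    starts = psth_window_starts(w)
    edges_lo = starts
    edges_hi = starts + w.psth_window

    groups = ds.spikes.groupby(["cell_id", "odor_id"], observed=True)["spike_time"]
    index = []
    rows = []
    for (cell, odor), times in groups:
        t = np.sort(times.to_numpy(dtype=float))
        counts = np.searchsorted(t, edges_hi, side="left") - np.searchsorted(
            t, edges_lo, side="left"
        )
        index.append((cell, odor))
        rows.append(counts / (w.psth_window * ds.n_trials))
    # (cell, odor) pairs that were presented but fired no spikes at all:
    meta = ds.cell_meta()
    full = pd.MultiIndex.from_product(
        [meta.index, ds.panel.odor_ids], names=["cell_id", "odor_id"]
    )
    psth = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["cell_id", "odor_id"]),
        columns=np.round(starts, 9),
    )
    return psth.reindex(full).fillna(0.0) if len(psth) else pd.DataFrame(
        0.0, index=full, columns=np.round(starts, 9)
    )


# ------------------------------------------------------------- exact test/FDR


def poisson_exact_p(x: int, y: int) -> float:
    """One-sided exact p for H1: rate(x-sample) > rate(y-sample), equal exposure.

    The conditional (binomial) exact test: given x+y events, x ~ Bin(x+y, 1/2)
    under H0, so p = P(Bin(x+y, 1/2) >= x).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    n = x + y
    if n == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, 0.5))


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ResponseTable:
    """Per (cell, odor) response statistics plus detection parameters.

    ``pairs`` is indexed by (cell_id, odor_id) with columns ``x`` (odor spikes
    in the test window over all trials), ``y`` (blank spikes, same window),
    ``p_raw``, ``p_adj``, ``significant``, ``detection_prob`` (fraction of
    single trials significant), ``evoked_rate`` (max PSTH in the evoked
    window, Hz) and ``baseline_rate`` (Hz).
    """

    pairs: pd.DataFrame
    params: DetectionParams
    windows: AnalysisWindows
    n_trials: int = 4

    def cell_breadth(self) -> pd.Series:
        """Fraction of tested odors with a significant response, per cell."""
        return self.pairs.groupby(level="cell_id")["significant"].mean().rename("breadth")


def _counts_grid(ds: SpikeDataset, window, odors) -> pd.DataFrame:
    """Spike counts per (cell, odor, trial) on the full grid (zeros filled)."""
    counts = ds.count_in_window(window)
    grid = pd.MultiIndex.from_product(
        [ds.cells, odors, range(1, ds.n_trials + 1)],
        names=["cell_id", "odor_id", "trial"],
    )
    return (
        counts.set_index(["cell_id", "odor_id", "trial"])["count"]
        .reindex(grid)
        .fillna(0)
        .astype(int)
    )


def detect_responses(
    ds: SpikeDataset,
    w: AnalysisWindows | None = None,
    params: DetectionParams | None = None,
) -> ResponseTable:
    """Run the exact Poisson response test for every (cell, odor) pair.

    Requires the panel to declare a blank odor.  The FDR family is the set of
    odor p-values of one cell; single-trial detection applies the same test
    per trial (FDR over odors within each cell × trial) at the more permissive
    single-trial alpha, yielding a detection probability in {0, 1/T, …, 1}.
    """
    w = w or AnalysisWindows()
    params = params or DetectionParams()
    blank = ds.panel.blank
    if blank is None:
        raise ValueError("dataset panel has no blank/control odor")
    a, b = w.test_window
    if not b > a:
        raise ValueError("zero-length test window")

    odors = ds.panel.odor_ids
    test_odors = [o for o in odors if o != blank]
    cells = ds.cells
    counts = _counts_grid(ds, w.test_window, odors)
    arr = counts.to_numpy().reshape(len(cells), len(odors), ds.n_trials)
    blank_idx = odors.index(blank)
    test_idx = [i for i, o in enumerate(odors) if o != blank]

    per_pair = arr.sum(axis=2)  # (cells, odors)
    x = per_pair[:, test_idx]
    y = per_pair[:, blank_idx][:, None]
    n_tot = x + y
    p_raw = np.where(n_tot > 0, stats.binom.sf(x - 1, np.maximum(n_tot, 1), 0.5), 1.0)
    p_adj = np.vstack([adjust_fdr(row) for row in p_raw])

    # single-trial detection: same test per trial, FDR over odors per cell-trial
    xt = arr[:, test_idx, :]
    yt = arr[:, blank_idx, :][:, None, :]
    nt = xt + yt
    pt = np.where(nt > 0, stats.binom.sf(xt - 1, np.maximum(nt, 1), 0.5), 1.0)
    trial_sig = np.empty_like(pt, dtype=bool)
    for c in range(len(cells)):
        for t in range(ds.n_trials):
            trial_sig[c, :, t] = adjust_fdr(pt[c, :, t]) < params.fdr_alpha_single
    detection_prob = trial_sig.mean(axis=2)

    index = pd.MultiIndex.from_product(
        [cells, test_odors], names=["cell_id", "odor_id"]
    )
    pairs = pd.DataFrame(
        {
            "x": x.ravel(),
            "y": np.broadcast_to(y, x.shape).ravel(),
            "p_raw": p_raw.ravel(),
            "p_adj": p_adj.ravel(),
            "significant": (p_adj < params.fdr_alpha_multi).ravel(),
            "detection_prob": detection_prob.ravel(),
        },
        index=index,
    )

    psth = compute_psth(ds, w)
    starts = np.asarray(psth.columns, dtype=float)
    in_evoked = (starts >= w.evoked_max_window[0]) & (starts <= w.evoked_max_window[1])
    pairs["evoked_rate"] = psth.loc[:, psth.columns[in_evoked]].max(axis=1).reindex(
        pairs.index
    )

    base_lo, base_hi = w.baseline_window
    base_counts = _counts_grid(ds, (base_lo, base_hi), odors)
    base_rate = base_counts.groupby(level=["cell_id", "odor_id"]).sum() / (
        (base_hi - base_lo) * ds.n_trials
    )
    pairs["baseline_rate"] = base_rate.reindex(pairs.index)

    return ResponseTable(pairs, params, w, n_trials=ds.n_trials)


# ------------------------------------------------------------- rate summaries


def summarize_rates(ds: SpikeDataset, responses: ResponseTable) -> pd.DataFrame:
    """Group-mean baseline, all-response and significant-only evoked rates (Hz).

    Baseline is averaged per cell over odors first; evoked rates are the
    per-pair maxima of the PSTH within the evoked window.
    """
    meta = ds.cell_meta()
    pairs = responses.pairs.join(meta["group"], on="cell_id")
    cell_base = pairs.groupby(["cell_id"])["baseline_rate"].mean()
    cell_group = meta["group"]
    out = []
    for group, cells in cell_group.groupby(cell_group):
        sub = pairs.loc[pairs["group"] == group]
        sig = sub.loc[sub["significant"]]
        out.append(
            {
                "group": group,
                "baseline": float(cell_base.loc[cells.index].mean()),
                "all_responses": float(sub["evoked_rate"].mean()),
                "significant_responses": float(sig["evoked_rate"].mean())
                if len(sig)
                else np.nan,
                "n_cells": len(cells),
            }
        )
    return pd.DataFrame(out).set_index("group")


def response_reliability(
    responses: ResponseTable, rate_threshold: float | None = None
) -> pd.Series:
    """Mean single-trial detection probability over each cell's significant pairs.

    With ``rate_threshold`` set, only pairs whose evoked rate reaches the
    threshold (Hz) enter the average.  Cells with no qualifying pair get NaN.
    """
    pairs = responses.pairs
    keep = pairs["significant"]
    if rate_threshold is not None:
        keep = keep & (pairs["evoked_rate"] >= rate_threshold)
    sig = pairs.loc[keep]
    rel = sig.groupby(level="cell_id")["detection_prob"].mean()
    return rel.reindex(pairs.index.get_level_values("cell_id").unique()).rename(
        "reliability"
    )


def lifetime_sparseness(rates: np.ndarray) -> float:
    """Lifetime sparseness S over non-negative response rates.

    S = (1 − (Σr/N)² / (Σr²/N)) / (1 − 1/N); 0 for uniform responses, 1 when a
    single stimulus carries all the response.  Undefined (NaN) for all-zero
    vectors or N < 2.
    """
    r = np.asarray(rates, dtype=float)
    n = r.size
    if n < 2 or not np.any(r > 0):
        return float("nan")
    num = (r.sum() / n) ** 2
    den = (r**2).sum() / n
    return float((1 - num / den) / (1 - 1 / n))


def tuning_measures(responses: ResponseTable) -> pd.DataFrame:
    """Per-cell tuning breadth and lifetime sparseness.

    Breadth is the significant-odor fraction; sparseness uses
    baseline-subtracted evoked rates clipped at zero (the response test is
    excitatory-only, so suppression is not scored).
    """
    pairs = responses.pairs
    breadth = responses.cell_breadth()
    evoked = (pairs["evoked_rate"] - pairs["baseline_rate"]).clip(lower=0.0)
    sparseness = evoked.groupby(level="cell_id").apply(
        lambda r: lifetime_sparseness(r.to_numpy())
    )
    return pd.DataFrame({"breadth": breadth, "sparseness": sparseness})
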