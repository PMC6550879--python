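"""Odor-category coding: ROC/AUC scoring, group comparisons, PCA population
trajectories, and the linear population-decoding harness.

Each cell type is treated as a binary classifier for each of six chemical
categories; its AUC (Mann–Whitney pair counting, half-credit ties) is
normalized as max(AUC, 1 − AUC) so 0.5 always means "no category
information".  A type is category-informative when its best unshuffled score
beats every one of five odor-label-shuffled controls.  Population decoding
trains one-vs-rest linear support-vector classifiers per time bin over a C
grid with stratified cross-validation, picking C on one half of the runs and
reporting accuracy on the other half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import LinearSVC

from lhcoding.config import AnalysisWindows, CodingParams
from lhcoding.datasets import CATEGORIES, OdorPanel, SpikeDataset


# --------------------------------------------------------------- AUC scoring


def auc_score(positives: np.ndarray, negatives: np.ndarray) -> float:
    """Area under the ROC curve by Mann–Whitney pair counting (ties = 1/2)."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def category_response_vectors(
    psth: pd.DataFrame,
    type_labels: pd.Series,
    baseline_rates: pd.Series,
    w: AnalysisWindows | None = None,
    n_bins: int = 6,
    bin_width: float = 0.25,
    onset: float = 0.5,
) -> pd.DataFrame:
    """Scalar response per (cell type, odor): max baseline-subtracted rate in
    the ``n_bins`` non-overlapping ``bin_width``-s bins after odor onset.

    ``psth`` is the (cell, odor) × window-start PSTH frame; ``baseline_rates``
    is per (cell, odor).  Returns a DataFrame types × odors.
    """
    w = w or AnalysisWindows()
    starts = np.asarray(psth.columns, dtype=float)
    rows = {}
    base = baseline_rates.reindex(psth.index).fillna(0.0)
    sub = psth.to_numpy() - base.to_numpy()[:, None]
    bin_max = []
    for b in range(n_bins):
        lo = onset + b * bin_width
        hi = lo + bin_width
        in_bin = (starts >= lo) & (starts < hi)
        if not in_bin.any():
            in_bin = np.argmin(np.abs(starts - lo)) == np.arange(len(starts))
        bin_max.append(sub[:, in_bin].mean(axis=1))
    scalar = np.max(np.stack(bin_max, axis=1), axis=1)
    per_pair = pd.Series(scalar, index=psth.index)
    frame = per_pair.unstack("odor_id")
    labels = type_labels.reindex(frame.index)
    return frame.groupby(labels).mean()


@dataclass
class CategoryScores:
    per_type: pd.DataFrame  # index: cell_type; columns below
    per_category: pd.DataFrame  # normalized AUC per (type, category)
    n_shuffles: int


def auc_category_scores(
    responses: pd.DataFrame,
    panel: OdorPanel,
    n_shuffles: int = 5,
    seed: int = 0,
) -> CategoryScores:
    """Normalized AUC category scores per cell type with shuffled controls.

    For every type and category with at least one positive and one negative
    odor, score = max(AUC, 1 − AUC).  The per-type summary records the
    unshuffled maximum over categories, the average of the shuffle maxima,
    and an ``informative`` flag (unshuffled max strictly above every shuffle
    maximum).
    """
    rng = np.random.default_rng(seed)
    odors = [o for o in responses.columns if o in set(panel.test_odors)]
    masks = {}
    for cat in CATEGORIES:
        mask = panel.category_mask(cat).reindex(odors).fillna(False).to_numpy()
        if mask.any() and (~mask).any():
            masks[cat] = mask
    if not masks:
        raise ValueError("no category with both positive and negative odors")

    def max_norm_auc(values: np.ndarray) -> tuple[float, dict]:
        per_cat = {}
        for cat, mask in masks.items():
            a = auc_score(values[mask], values[~mask])
            per_cat[cat] = max(a, 1.0 - a)
        return max(per_cat.values()), per_cat

    rows, cat_rows = [], []
    for ctype, row in responses[odors].iterrows():
        values = row.to_numpy(dtype=float)
        unshuffled, per_cat = max_norm_auc(values)
        shuffle_maxima = np.array(
            [max_norm_auc(values[rng.permutation(len(values))])[0] for _ in range(n_shuffles)]
        )
        rows.append(
            {
                "cell_type": ctype,
                "max_auc": unshuffled,
                "shuffled_max_auc": float(shuffle_maxima.mean()),
                "informative": bool(np.all(unshuffled > shuffle_maxima)),
                "best_category": max(per_cat, key=per_cat.get),
            }
        )
        cat_rows.append(pd.Series(per_cat, name=ctype))
    return CategoryScores(
        pd.DataFrame(rows).set_index("cell_type"),
        pd.DataFrame(cat_rows),
        n_shuffles,
    )


def group_category_comparison(
    scores: CategoryScores, group_per_type: pd.Series
) -> pd.DataFrame:
    """One-sided Mann–Whitney U tests: LHON > PN and LHLN > PN on the
    distributions of unshuffled per-type maximum AUC scores."""
    groups = {
        g: scores.per_type.loc[
            [t for t in scores.per_type.index if group_per_type.get(t) == g],
            "max_auc",
        ].to_numpy()
        for g in ("PN", "LHLN", "LHON")
    }
    rows = []
    for contrast in ("LHON", "LHLN"):
        a, b = groups[contrast], groups["PN"]
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty group in contrast {contrast} vs PN")
        res = stats.mannwhitneyu(a, b, alternative="greater")
        rows.append(
            {"contrast": f"{contrast} > PN", "U": float(res.statistic),
             "p_value": float(res.pvalue), "n": (a.size, b.size)}
        )
    return pd.DataFrame(rows).set_index("contrast")


# ------------------------------------------------------------------------ PCA


@dataclass
class PCAResult:
    explained_variance_ratio: np.ndarray
    projections: pd.DataFrame  # index (odor, bin), columns PC1..PCk
    components: np.ndarray  # rows = PCs, columns = cells


def pca_population(
    matrix: pd.DataFrame, normalize: bool = False, kappa: float | None = None
) -> PCAResult:
    """PCA of population vectors over odor × time-bin observations.

    ``matrix`` is cells × (odor, bin) as in the concatenated cell-odor
    matrix; observations are the per-(odor, bin) population vectors.  With
    ``normalize``, each odor's trajectory is divided by its peak population
    -vector norm plus a softening constant κ (default: the median of the peak
    norms) before PCA — an adaptive divisive normalization boosting weak
    odors.  Component signs are fixed so the largest-magnitude loading is
    positive.
    """
    obs = matrix.to_numpy().T  # (odor*bin, cells)
    if obs.shape[0] < 3 or obs.shape[1] < 2:
        raise ValueError("need >= 3 observations and >= 2 cells")
    index = matrix.columns
    if normalize:
        odors = index.get_level_values(0)
        norms = np.linalg.norm(obs, axis=1)
        peaks = pd.Series(norms).groupby(odors.to_numpy()).max()
        if kappa is None:
            kappa = float(np.median(peaks))
        scale = peaks.reindex(odors).to_numpy() + kappa
        obs = obs / scale[:, None]
    centered = obs - obs.mean(axis=0)
    if not np.any(centered):
        raise ValueError("constant matrix has no principal components")
    cov = np.cov(centered, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    proj = centered @ evecs
    cols = [f"PC{i + 1}" for i in range(proj.shape[1])]
    return PCAResult(
        explained_variance_ratio=evals / evals.sum(),
        projections=pd.DataFrame(proj, index=index, columns=cols),
        components=evecs.T,
    )


# ----------------------------------------------------------- population decode


@dataclass
class DecodingResult:
    """Per (population size, bin) decoding accuracy with shuffled controls."""

    accuracy: pd.DataFrame  # columns: n_types, bin, mean, sd, shuffled flag
    task: str
    chance: float
    responses_per_cell_per_bin: int
    best_c: pd.DataFrame


def _bin_counts(
    ds: SpikeDataset, odors: list[str], n_bins: int, bin_width: float, onset: float
) -> np.ndarray:
    """Spike counts per (cell, odor, trial, bin) on the full grid."""
    cells = ds.cells
    grid_shape = (len(cells), len(odors), ds.n_trials, n_bins)
    out = np.zeros(grid_shape)
    cell_ix = {c: i for i, c in enumerate(cells)}
    odor_ix = {o: i for i, o in enumerate(odors)}
    sp = ds.spikes
    sel = sp["odor_id"].isin(odor_ix)
    t = sp.loc[sel, "spike_time"].to_numpy()
    b = np.floor((t - onset) / bin_width).astype(int)
    ok = (b >= 0) & (b < n_bins)
    ci = sp.loc[sel, "cell_id"].map(cell_ix).to_numpy()[ok]
    oi = sp.loc[sel, "odor_id"].map(odor_ix).to_numpy()[ok]
    ti = sp.loc[sel, "trial"].to_numpy()[ok] - 1
    np.add.at(out, (ci, oi, ti, b[ok]), 1)
    return out


def population_decode(
    ds: SpikeDataset,
    task: str = "identity",
    params: CodingParams | None = None,
    population_sizes: list[int] | None = None,
    seed: int = 0,
    shuffle: bool = False,
) -> DecodingResult:
    """Linear SVC population decoding of odor identity or chemical category.

    For each run, ``n`` cell types are drawn and one random cell represents
    each; per time bin a one-vs-rest linear SVC is scored at each C on the
    grid with stratified ``folds``-fold cross-validation over the odor ×
    trial responses.  Runs are split in half: the best C per bin comes from
    half 1, reported accuracy (mean ± s.d. over runs) from half 2 only.  With
    ``shuffle``, each cell's responses are permuted independently per bin
    across trials — the chance-level control.
    """
    params = params or CodingParams()
    if task not in ("identity", "category"):
        raise ValueError("task must be 'identity' or 'category'")
    odors = ds.panel.test_odors
    meta = ds.cell_meta()
    by_type = meta.groupby("cell_type").groups
    types = sorted(by_type)
    sizes = population_sizes or list(
        range(1, min(params.max_population, len(types)) + 1)
    )
    if max(sizes) > len(types):
        raise ValueError(f"population size {max(sizes)} exceeds {len(types)} types")

    if task == "identity":
        labels = np.repeat(np.arange(len(odors)), ds.n_trials)
        chance = 1.0 / len(odors)
    else:
        cats = sorted(CATEGORIES)
        cat_of = []
        for o in odors:
            flags = sorted(ds.panel.categories_of(o))
            cat_of.append(cats.index(flags[0]) if flags else len(cats))
        labels = np.repeat(np.asarray(cat_of), ds.n_trials)
        freq = np.bincount(labels) / labels.size
        chance = float(freq.max())

    counts = _bin_counts(
        ds, odors, params.response_bins, params.bin_width, params.onset
    )  # (cells, odors, trials, bins)
    cells = ds.cells
    cell_ix = {c: i for i, c in enumerate(cells)}
    n_resp = len(odors) * ds.n_trials

    rng = np.random.default_rng(seed)
    n_runs = params.runs_per_size
    if n_runs < 2:
        raise ValueError("need at least 2 runs for the half-split C selection")
    acc = np.full(
        (len(sizes), n_runs, params.response_bins, len(params.c_grid)), np.nan
    )
    for si, n in enumerate(sizes):
        for run in range(n_runs):
            chosen_types = rng.choice(types, size=n, replace=False)
            chosen = [
                cell_ix[rng.choice(list(by_type[t]))] for t in chosen_types
            ]
            feats = counts[chosen]  # (n, odors, trials, bins)
            for b in range(params.response_bins):
                X = feats[:, :, :, b].reshape(n, n_resp).T  # (responses, n_cells)
                if shuffle:
                    X = X.copy()
                    for j in range(n):
                        X[:, j] = X[rng.permutation(n_resp), j]
                for ci, c in enumerate(params.c_grid):
                    clf = OneVsRestClassifier(
                        LinearSVC(C=c, dual="auto", max_iter=5000)
                    )
                    cv = StratifiedKFold(
                        n_splits=params.folds, shuffle=True,
                        random_state=int(rng.integers(2**31 - 1)),
                    )
                    try:
                        scores = cross_val_score(clf, X, labels, cv=cv)
                    except ValueError:
                        # a fold missing a class (tiny panels): fall back to
                        # unstratified splitting
                        scores = cross_val_score(clf, X, labels, cv=params.folds)
                    acc[si, run, b, ci] = scores.mean()

    half = n_runs // 2
    rows, c_rows = [], []
    for si, n in enumerate(sizes):
        tune = acc[si, :half].mean(axis=0)  # (bins, C)
        best = tune.argmax(axis=1)
        for b in range(params.response_bins):
            eval_acc = acc[si, half:, b, best[b]]
            rows.append(
                {
                    "n_types": n,
                    "bin": b,
                    "mean_accuracy": float(eval_acc.mean()),
                    "sd_accuracy": float(eval_acc.std()),
                    "shuffled": shuffle,
                }
            )
            c_rows.append(
                {"n_types": n, "bin": b, "best_c": params.c_grid[best[b]]}
            )
    return DecodingResult(
        accuracy=pd.DataFrame(rows),
        task=task,
        chance=chance,
        responses_per_cell_per_bin=n_resp,
        best_c=pd.DataFrame(c_rows),
    )
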