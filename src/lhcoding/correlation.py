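"""Population correlation structure of odor responses.

Each cell's PSTHs over a fixed odor order are concatenated into one long
vector; Pearson correlations across cells (or across cell-type mean profiles)
summarize how similarly the population samples odor space.  A label-shuffle
control permutes whole odor blocks independently per cell type, destroying
across-type tuning alignment while preserving each type's firing rates and
tuning breadth; the mean drop in off-diagonal correlation ("correlation
shift", 1000 replicates) quantifies how much structure the alignment carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class CellOdorMatrix:
    """Rows = cells (or types), columns = concatenated PSTH bins per odor."""

    data: pd.DataFrame  # columns: MultiIndex (odor_id, bin_start)
    odor_order: list[str]

    @property
    def n_bins_per_odor(self) -> int:
        return len(self.data.columns) // len(self.odor_order)

    def odor_block(self, odor: str) -> np.ndarray:
        return self.data[odor].to_numpy()


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame
    excluded: list = field(default_factory=list)
    group_mean_offdiag: pd.Series | None = None


def build_cell_odor_matrix(psth: pd.DataFrame, odor_order: list[str]) -> CellOdorMatrix:
    """Concatenate per-odor PSTH rows into one vector per cell.

    ``psth`` is the (cell, odor) × window-start frame from
    :func:`lhcoding.spikes.compute_psth`.  Cells missing any odor in
    ``odor_order`` are dropped with a logged report.
    """
    if not odor_order:
        raise ValueError("odor_order must be non-empty")
    cells = psth.index.get_level_values("cell_id").unique()
    have = psth.index.to_frame(index=False).groupby("cell_id")["odor_id"].agg(set)
    wanted = set(odor_order)
    keep, dropped = [], []
    for cell in cells:
        (keep if wanted <= have.get(cell, set()) else dropped).append(cell)
    if dropped:
        logger.info("dropping %d cells missing odors: %s", len(dropped), dropped)
    blocks = []
    for odor in odor_order:
        block = psth.xs(odor, level="odor_id").loc[keep]
        block.columns = pd.MultiIndex.from_product([[odor], block.columns])
        blocks.append(block)
    data = pd.concat(blocks, axis=1)
    data.columns.names = ["odor_id", "bin_start"]
    return CellOdorMatrix(data, list(odor_order))


def correlation_matrix(m: CellOdorMatrix) -> CorrelationResult:
    """Pearson correlation between all row pairs; zero-variance rows excluded."""
    data = m.data
    var = data.to_numpy().var(axis=1)
    excluded = list(data.index[var == 0])
    if excluded:
        logger.info("excluding zero-variance rows: %s", excluded)
        data = data.loc[var > 0]
    if len(data) < 2:
        raise ValueError("need at least 2 rows with nonzero variance")
    corr = np.corrcoef(data.to_numpy())
    return CorrelationResult(
        pd.DataFrame(corr, index=data.index, columns=data.index), excluded
    )


def _mean_offdiag(mat: np.ndarray) -> float:
    n = mat.shape[0]
    if n < 2:
        return float("nan")
    mask = ~np.eye(n, dtype=bool)
    return float(mat[mask].mean())


def mean_offdiagonal(corr: pd.DataFrame) -> float:
    """Mean of the off-diagonal entries of a correlation matrix."""
    return _mean_offdiag(np.asarray(corr, dtype=float))


def type_mean_matrix(m: CellOdorMatrix, type_labels: pd.Series) -> CellOdorMatrix:
    """Mean concatenated profile per cell type (rows become types)."""
    labels = type_labels.reindex(m.data.index)
    if labels.isna().any():
        missing = list(m.data.index[labels.isna()])
        raise ValueError(f"cells without type label: {missing}")
    mean = m.data.groupby(labels).mean()
    return CellOdorMatrix(mean, m.odor_order)


def aggregate_type_correlation(
    m: CellOdorMatrix,
    type_labels: pd.Series,
    group_labels: pd.Series | None = None,
) -> CorrelationResult:
    """Type-level Pearson matrix on per-type mean profiles.

    With ``group_labels`` (type → PN/LHLN/LHON), also reports the mean
    off-diagonal correlation within each group.
    """
    tm = type_mean_matrix(m, type_labels)
    res = correlation_matrix(tm)
    if group_labels is not None:
        means = {}
        for group in pd.unique(group_labels):
            types = [
                t for t in res.matrix.index if group_labels.get(t) == group
            ]
            if len(types) >= 2:
                means[group] = _mean_offdiag(res.matrix.loc[types, types].to_numpy())
        res.group_mean_offdiag = pd.Series(means, name="mean_offdiag")
    return res


def _shuffle_odor_blocks(
    data: pd.DataFrame, odor_order: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Permute whole odor blocks independently for each row."""
    n_odors = len(odor_order)
    nbins = len(data.columns) // n_odors
    arr = data.to_numpy().reshape(len(data), n_odors, nbins)
    out = np.empty_like(arr)
    for i in range(len(data)):
        out[i] = arr[i, rng.permutation(n_odors)]
    return pd.DataFrame(
        out.reshape(len(data), n_odors * nbins), index=data.index, columns=data.columns
    )


def shuffle_correlation_shift(
    m: CellOdorMatrix,
    type_labels: pd.Series,
    n_reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Correlation shift distribution under per-type odor-label permutation.

    Per replicate: permute odor blocks independently for each type's mean
    profile, recompute the type-level Pearson matrix, and record
    mean(original − shuffled) over the off-diagonal entries.  The permutation
    reorders whole odor-PSTH blocks, so each type's marginal response
    distribution (tuning breadth) is untouched.
    """
    if len(m.odor_order) < 2:
        raise ValueError("need at least 2 odors to shuffle")
    tm = type_mean_matrix(m, type_labels)
    if len(tm.data) < 2:
        raise ValueError("need at least 2 types")
    rng = np.random.default_rng(seed)
    orig = np.corrcoef(tm.data.to_numpy())
    shifts = np.empty(n_reps)
    for rep in range(n_reps):
        shuf = _shuffle_odor_blocks(tm.data, m.odor_order, rng)
        shifts[rep] = _mean_offdiag(orig) - _mean_offdiag(np.corrcoef(shuf.to_numpy()))
    return shifts


def sparse_subset_correlation(
    response_prob: pd.Series,
    m: CellOdorMatrix,
    type_labels: pd.Series,
    prob_threshold: float = 0.36,
) -> CorrelationResult:
    """Type correlation restricted to sparse types (response prob < threshold).

    ``response_prob`` maps cell type → mean fraction of odors with a
    significant response.  The matrix is recomputed among survivors only, so
    mean cross-correlations are not diluted by broadly tuned types.
    """
    sparse_types = set(response_prob.index[response_prob < prob_threshold])
    keep_cells = [c for c in m.data.index if type_labels.get(c) in sparse_types]
    keep_types = {type_labels[c] for c in keep_cells}
    if len(keep_types) < 2:
        raise ValueError(
            f"fewer than 2 cell types below p(response) < {prob_threshold}"
        )
    sub = CellOdorMatrix(m.data.loc[keep_cells], m.odor_order)
    return aggregate_type_correlation(sub, type_labels.loc[keep_cells])


def breadth_vs_correlation(
    response_prob: pd.Series, corr: CorrelationResult
) -> dict:
    """OLS of per-type mean off-diagonal correlation on response probability.

    Returns slope, intercept, adjusted R² and the two-sided slope p-value.
    """
    types = [t for t in corr.matrix.index if t in response_prob.index]
    if len(types) < 3:
        raise ValueError("need at least 3 types")
    mat = corr.matrix.loc[types, types].to_numpy()
    n = len(types)
    mask = ~np.eye(n, dtype=bool)
    mean_corr = (mat * mask).sum(axis=1) / (n - 1)
    x = response_prob.loc[types].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero-variance predictor")
    model = sm.OLS(mean_corr, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "adj_r_squared": float(model.rsquared_adj),
        "p_value": float(model.pvalues[1]),
        "n_types": n,
    }
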