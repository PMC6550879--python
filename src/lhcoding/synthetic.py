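"""Synthetic spike datasets, skeleton sets and census populations.

The generator emulates the statistical structure of in-vivo patch-clamp
recordings from the fly lateral horn: projection neurons (PNs) fire at ~1.4 Hz
baseline and respond significantly to ~12% of odors with ~21 Hz peaks; LH
output neurons (LHONs) are nearly silent at baseline (~0.1 Hz) but respond to
~35% of odors at ~14 Hz; LH local neurons sit in between (~1 Hz baseline).
Odor trials last 3 s with a 250 ms valve opening at 0.5 s and 4 repeats.
Tuning is stereotyped: which odors a cell type responds to is a fixed function
of the type, the odor panel and the seed, identical for every cell of the
type; per-cell log-normal gain and per-trial jitter add realistic
response-magnitude variability.  Evoked responses are rectangular rate bumps
with Gaussian-smoothed 50 ms edges — an analysis-window-compatible shape, not
a kinetic model — and are excitatory only.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lhcoding.anatomy import Box, make_region_layout
from lhcoding.datasets import CATEGORIES, LabeledSkeleton, OdorPanel, SpikeDataset
from lhcoding.datasets import SWC_AXON, SWC_DENDRITE, SWC_SOMA


@dataclass(frozen=True)
class TuningTemplate:
    """Shared tuning statistics for all cells of one type (tuning stereotypy)."""

    cell_type: str
    group: str  # PN | LHLN | LHON
    baseline_rate: float  # Hz
    response_prob: float  # fraction of odors with an evoked response
    evoked_peak: float  # Hz
    category_bias: dict = field(default_factory=dict)  # category -> multiplier
    response_onset: float = 0.05  # s after valve opening
    response_duration: float = 0.5  # s
    trial_jitter: float = 0.2  # multiplicative s.d. of per-trial gain
    gain_sigma: float = 0.3  # log-normal per-cell gain s.d.
    edge_smoothing: float = 0.05  # s, Gaussian edge of the rate bump

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.evoked_peak < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.response_prob <= 1:
            raise ValueError("response_prob must be in [0, 1]")


def pn_template(**overrides) -> TuningTemplate:
    """Projection-neuron-like template (1.4 Hz baseline, 12% odors, 21 Hz)."""
    kw = dict(
        cell_type="PN1", group="PN", baseline_rate=1.4, response_prob=0.12,
        evoked_peak=21.0,
    )
    kw.update(overrides)
    return TuningTemplate(**kw)


def lhln_template(**overrides) -> TuningTemplate:
    """Local-neuron-like template (1 Hz baseline; breadth/peak between PN and LHON)."""
    kw = dict(
        cell_type="LHLN1", group="LHLN", baseline_rate=1.0, response_prob=0.2,
        evoked_peak=16.0,
    )
    kw.update(overrides)
    return TuningTemplate(**kw)


def lhon_template(**overrides) -> TuningTemplate:
    """Output-neuron-like template (0.1 Hz baseline, 35% odors, 14 Hz)."""
    kw = dict(
        cell_type="LHON1", group="LHON", baseline_rate=0.1, response_prob=0.35,
        evoked_peak=14.0,
    )
    kw.update(overrides)
    return TuningTemplate(**kw)


# ----------------------------------------------------------------- odor panel


def gen_odor_panel(
    n_odors: int = 36, seed: int = 0, multi_flag: bool = False
) -> OdorPanel:
    """Generate an odor panel with balanced category flags plus a blank.

    By default each odor carries exactly one of the six chemical-category
    flags, assigned round-robin so categories are as balanced as possible
    (36 odors → 6 per category).  With ``multi_flag``, each odor may draw
    additional flags with probability 0.15.
    """
    if n_odors < len(CATEGORIES):
        raise ValueError(f"need at least {len(CATEGORIES)} odors")
    rng = np.random.default_rng(seed)
    base = list(CATEGORIES) * (n_odors // len(CATEGORIES) + 1)
    cats = base[:n_odors]
    rng.shuffle(cats)
    rows = []
    for i, cat in enumerate(cats):
        flags = {cat}
        if multi_flag:
            flags |= {c for c in CATEGORIES if c != cat and rng.random() < 0.15}
        rows.append(
            {
                "odor_id": f"odor{i + 1:02d}",
                "categories": frozenset(flags),
                "solvent": "mineral_oil",
                "is_blank": False,
            }
        )
    rows.append(
        {
            "odor_id": "blank",
            "categories": frozenset(),
            "solvent": "mineral_oil",
            "is_blank": True,
        }
    )
    return OdorPanel(pd.DataFrame(rows))


# -------------------------------------------------------------- spike dataset


def _template_stream(template: TuningTemplate, seed: int) -> np.random.Generator:
    """Deterministic per-type RNG so tuning is a fixed function of (type, seed)."""
    key = zlib.crc32(template.cell_type.encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def template_responsive_odors(
    template: TuningTemplate, panel: OdorPanel, seed: int
) -> list[str]:
    """The odor set this cell type responds to — identical for all its cells.

    Each odor is selected with probability response_prob multiplied by the
    product of the template's category-bias factors over the odor's flags
    (clipped to [0, 1]).
    """
    rng = _template_stream(template, seed)
    chosen = []
    for odor in panel.test_odors:
        bias = 1.0
        for cat in panel.categories_of(odor):
            bias *= template.category_bias.get(cat, 1.0)
        if rng.random() < min(1.0, template.response_prob * bias):
            chosen.append(odor)
    return chosen


def gen_spike_dataset(
    templates: list[TuningTemplate],
    cells_per_type: int,
    panel: OdorPanel,
    trials: int = 4,
    seed: int = 0,
    trial_duration: float = 3.0,
    valve_onset: float = 0.5,
) -> SpikeDataset:
    """Draw a trial-structured spike dataset from inhomogeneous Poisson rates.

    Rate = baseline + (for the type's responsive odors) a smoothed
    rectangular bump starting ``response_onset`` after the valve, scaled by
    the per-cell gain and per-trial jitter.  The smoothed bump is sampled
    exactly as U + Z with U uniform over the bump and Z Gaussian edge noise.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not templates:
        raise ValueError("templates must be non-empty")
    rng = np.random.default_rng(seed)
    records: list[pd.DataFrame] = []
    odors = panel.odor_ids

    for template in templates:
        responsive = set(template_responsive_odors(template, panel, seed))
        t0 = valve_onset + template.response_onset
        t1 = t0 + template.response_duration
        for ci in range(cells_per_type):
            cell_id = f"{template.cell_type}_{ci + 1:03d}"
            gain = float(
                rng.lognormal(-0.5 * template.gain_sigma**2, template.gain_sigma)
            ) if template.gain_sigma > 0 else 1.0
            for odor in odors:
                for trial in range(1, trials + 1):
                    times = []
                    if template.baseline_rate > 0:
                        nb = rng.poisson(template.baseline_rate * trial_duration)
                        times.append(rng.uniform(0, trial_duration, nb))
                    if odor in responsive and template.evoked_peak > 0:
                        jitter = (
                            float(
                                rng.lognormal(
                                    -0.5 * template.trial_jitter**2,
                                    template.trial_jitter,
                                )
                            )
                            if template.trial_jitter > 0
                            else 1.0
                        )
                        amp = template.evoked_peak * gain * jitter
                        ne = rng.poisson(amp * (t1 - t0))
                        ev = rng.uniform(t0, t1, ne)
                        if template.edge_smoothing > 0:
                            ev = ev + rng.normal(0, template.edge_smoothing, ne)
                        times.append(ev[(ev >= 0) & (ev <= trial_duration)])
                    t = np.sort(np.concatenate(times)) if times else np.empty(0)
                    if len(t):
                        records.append(
                            pd.DataFrame(
                                {
                                    "cell_id": cell_id,
                                    "group": template.group,
                                    "cell_type": template.cell_type,
                                    "odor_id": odor,
                                    "trial": trial,
                                    "spike_time": t,
                                }
                            )
                        )
    # long format holds one row per spike, so a cell that never fires at all
    # (possible only with zero baseline and no responses) has no rows
    if records:
        spikes = pd.concat(records, ignore_index=True)
    else:
        spikes = pd.DataFrame(
            columns=["cell_id", "group", "cell_type", "odor_id", "trial", "spike_time"]
        ).astype({"trial": int, "spike_time": float})
    return SpikeDataset(spikes, panel, trial_duration=trial_duration, n_trials=trials)


# --------------------------------------------------------------- skeleton sets


def _tree_nodes(
    rng: np.random.Generator,
    start: np.ndarray,
    box: Box,
    depth: int,
    step: float,
    label: int,
    next_id: int,
    parent: int,
) -> tuple[list[tuple], int]:
    """Recursive binary tree of nodes confined to ``box``; returns (rows, next_id)."""
    rows = []

    def clip(p: np.ndarray) -> np.ndarray:
        return np.clip(p, np.asarray(box.lo) + 0.5, np.asarray(box.hi) - 0.5)

    def grow(pos, parent_id, d, nid):
        if d == 0:
            return nid
        for _ in range(2):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            child_pos = clip(pos + direction * step)
            rows.append((nid, label, *child_pos, 0.5, parent_id))
            nid = grow(child_pos, nid, d - 1, nid + 1)
        return nid

    next_id = grow(np.asarray(start, dtype=float), parent, depth, next_id)
    return rows, next_id


def gen_skeleton_set(
    n_types: int,
    cells_per_type: int,
    region_layout: dict[str, Box] | list[Box],
    seed: int = 0,
    jitter: float = 1.0,
) -> dict[str, LabeledSkeleton]:
    """Generate jittered copies of per-type prototype skeletons.

    Each cell type gets a prototype with a soma, a dendritic binary tree
    inside a random sub-region of the "LH" box and an axonal tree inside one
    of the target boxes; cells of the type are node-wise Gaussian-jittered
    copies (``jitter`` = 0 gives identical cells).  Returns a dict keyed by
    skeleton id ``{type}_{copy}``; cell type is recoverable as the id prefix.
    """
    layout = (
        make_region_layout(region_layout)
        if isinstance(region_layout, list)
        else region_layout
    )
    if "LH" not in layout:
        raise ValueError("region layout must contain an 'LH' box")
    targets = [b for name, b in layout.items() if name != "LH"]
    if not targets:
        raise ValueError("region layout needs at least one target box")
    rng = np.random.default_rng(seed)
    lh = layout["LH"]
    skeletons: dict[str, LabeledSkeleton] = {}

    for ti in range(n_types):
        target = targets[ti % len(targets)]
        # anchor the dendrite in a type-specific spot of the LH
        anchor = rng.uniform(np.asarray(lh.lo) + 2, np.asarray(lh.hi) - 2)
        soma = anchor + np.array([0.0, 0.0, (lh.hi[2] - lh.lo[2]) + 10.0])
        rows = [(1, SWC_SOMA, *soma, 1.0, -1), (2, SWC_DENDRITE, *anchor, 0.5, 1)]
        dend_rows, next_id = _tree_nodes(
            rng, anchor, lh, depth=3, step=4.0, label=SWC_DENDRITE, next_id=3, parent=2
        )
        rows.extend(dend_rows)
        # axon: a few segments from the LH anchor to the target box, then a tree
        entry = target.center + rng.normal(0, 2.0, 3)
        path = np.linspace(anchor, entry, 4)[1:]
        parent = 2
        for p in path:
            rows.append((next_id, SWC_AXON, *p, 0.5, parent))
            parent = next_id
            next_id += 1
        axon_rows, next_id = _tree_nodes(
            rng, entry, target, depth=2, step=4.0, label=SWC_AXON,
            next_id=next_id, parent=parent,
        )
        rows.extend(axon_rows)
        proto = pd.DataFrame(
            rows, columns=["node_id", "label", "x", "y", "z", "radius", "parent_id"]
        )
        for ci in range(cells_per_type):
            nodes = proto.copy()
            if jitter > 0:
                nodes[["x", "y", "z"]] += rng.normal(0, jitter, (len(nodes), 3))
            sid = f"type{ti + 1:02d}_{ci + 1:02d}"
            skeletons[sid] = LabeledSkeleton(nodes, skeleton_id=sid)
    return skeletons


def skeleton_type_labels(skeletons: dict[str, LabeledSkeleton]) -> pd.Series:
    """Cell-type label per skeleton id (the ``typeNN`` prefix)."""
    return pd.Series(
        {sid: sid.rsplit("_", 1)[0] for sid in skeletons}, name="cell_type"
    )


# ------------------------------------------------------------------- census


@dataclass
class CensusPopulation:
    """A tract cross-section with known ground truth LHN labels."""

    tract: str
    labels: np.ndarray  # bool per profile: is LHN
    majority_class: str

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def true_K(self) -> int:
        return int(self.labels.sum())


def gen_census_population(
    N: int, true_K: int, majority_class: str = "LHON", seed: int = 0, tract: str = "T1"
) -> CensusPopulation:
    """Randomly assign LHN identity to exactly ``true_K`` of ``N`` profiles."""
    if not 0 <= true_K <= N:
        raise ValueError("need 0 <= true_K <= N")
    rng = np.random.default_rng(seed)
    labels = np.zeros(N, dtype=bool)
    labels[rng.choice(N, size=true_K, replace=False)] = True
    return CensusPopulation(tract=tract, labels=labels, majority_class=majority_class)


def sample_census(pop: CensusPopulation, n: int, seed: int = 0):
    """Trace a random subset of ``n`` profiles; returns a census TractSample."""
    from lhcoding.census import TractSample

    if not 0 <= n <= pop.N:
        raise ValueError("need 0 <= n <= N")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pop.N, size=n, replace=False)
    return TractSample(
        tract=pop.tract, N=pop.N, n=n, k=int(pop.labels[idx].sum()),
        cls=pop.majority_class,
    )
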