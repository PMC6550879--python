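"""Sampling-based census of lateral horn neurons from EM tract cross-sections.

Each primary-neurite tract with N profiles in cross-section is sampled by
tracing n random profiles to the first branch point; k of them prove to be
LHNs.  The number K of LHN profiles in the tract is estimated as round(N·k/n)
with an exact equal-tail confidence interval obtained by inverting the
hypergeometric distribution (sampling without replacement from a finite
population).  Fully traced tracts (n = N) give zero-width intervals.  Tract
classes (local vs output) follow the majority cell class of the tract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TractSample:
    """A census record: N profiles, n traced, k identified as LHNs."""

    tract: str
    N: int
    n: int
    k: int
    cls: str = ""  # majority cell class: "LHON" or "LHLN"

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n <= self.N:
            raise ValueError(f"{self.tract}: need 0 <= k <= n <= N")


@dataclass(frozen=True)
class CensusEstimate:
    tract: str
    estimate: int
    estimate_raw: float
    lo: int
    hi: int
    level: float
    cls: str = ""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def estimate_tract_lhns(s: TractSample, level: float = 0.90) -> CensusEstimate:
    """Point estimate and exact equal-tail CI for the LHN count of one tract.

    K_lo is the smallest K with P(X >= k | N, K, n) >= (1-level)/2 and K_hi
    the largest K with P(X <= k | N, K, n) >= (1-level)/2, clipped to the
    feasible range [k, N - (n - k)].
    """
    if s.n == 0:
        raise ValueError(f"{s.tract}: cannot estimate from an empty sample")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    raw = s.N * s.k / s.n
    k_min, k_max = s.k, s.N - (s.n - s.k)
    ks = np.arange(k_min, k_max + 1)
    # P(X >= k) is non-decreasing in K; P(X <= k) non-increasing in K.
    upper_tail = stats.hypergeom.sf(s.k - 1, s.N, ks, s.n)
    lower_tail = stats.hypergeom.cdf(s.k, s.N, ks, s.n)
    lo_candidates = ks[upper_tail >= alpha]
    hi_candidates = ks[lower_tail >= alpha]
    lo = int(lo_candidates.min()) if lo_candidates.size else k_min
    hi = int(hi_candidates.max()) if hi_candidates.size else k_max
    return CensusEstimate(
        tract=s.tract,
        estimate=_round_half_up(raw),
        estimate_raw=float(raw),
        lo=lo,
        hi=hi,
        level=level,
        cls=s.cls,
    )


def aggregate_census(
    samples: list[TractSample],
    level: float = 0.90,
    n_mc: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class and overall profile sums, estimate sums and combined CIs.

    The combined CI for a sum of tract counts comes from a Monte-Carlo
    convolution of independent per-tract posteriors (uniform prior over the
    feasible K of each tract, likelihood = hypergeometric pmf of the observed
    k); per-tract draws are summed and the equal-tail interval of the summed
    distribution is reported at the same level.
    """
    if not samples:
        raise ValueError("need at least one tract")
    tract_ids = [s.tract for s in samples]
    if len(set(tract_ids)) != len(tract_ids):
        raise ValueError("duplicate tract ids in census samples")
    rng = np.random.default_rng(seed)
    estimates = [estimate_tract_lhns(s, level) for s in samples]

    draws = {}
    for s in samples:
        ks = np.arange(s.k, s.N - (s.n - s.k) + 1)
        post = stats.hypergeom.pmf(s.k, s.N, ks, s.n)
        post = post / post.sum()
        draws[s.tract] = rng.choice(ks, size=n_mc, p=post)

    rows = []
    groups = {"all": samples}
    for cls in sorted({s.cls for s in samples if s.cls}):
        groups[cls] = [s for s in samples if s.cls == cls]
    alpha = (1.0 - level) / 2.0
    for name, members in groups.items():
        ests = [e for e in estimates if e.tract in {s.tract for s in members}]
        total = np.sum([draws[s.tract] for s in members], axis=0)
        raw_sum = sum(e.estimate_raw for e in ests)
        rows.append(
            {
                "group": name,
                "n_tracts": len(members),
                "profiles": sum(s.N for s in members),
                "estimate": _round_half_up(raw_sum),
                "estimate_raw": raw_sum,
                "lo": int(np.quantile(total, alpha)),
                "hi": int(np.quantile(total, 1.0 - alpha)),
                "level": level,
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ------------------------------------------------------- published tract data
#
# The 17 EM-characterized primary-neurite tracts (inputs, not computation):
# tract, majority class, profiles in cross-section, published point estimate,
# published 90% range.  Rows whose range is zero-width were fully traced
# (n = N, k = estimate); for the others the sample size was not published.
EM_TRACT_TABLE = pd.DataFrame(
    [
        ("AV4", "LHLN", 324, 252, 244, 259),
        ("PV4", "LHLN", 158, 155, 152, 158),
        ("PV2", "LHLN", 193, 92, 81, 102),
        ("PD3", "LHLN", 75, 59, 43, 75),
        ("PD4", "LHLN", 88, 22, 10, 33),
        ("AV3", "LHON", 144, 140, 140, 140),
        ("PD2", "LHON", 193, 128, 128, 128),
        ("PV5", "LHON", 127, 119, 119, 119),
        ("AD1", "LHON", 286, 116, 102, 130),
        ("AV6", "LHON", 323, 106, 96, 115),
        ("AV2", "LHON", 98, 63, 49, 77),
        ("AD3", "LHON", 59, 59, 59, 59),
        ("AV7", "LHON", 141, 48, 25, 70),
        ("AV1", "LHON", 33, 25, 25, 25),
        ("AV5", "LHON", 108, 17, 7, 27),
        ("PV3", "LHON", 52, 12, 0, 25),
        ("AD2", "LHON", 52, 0, 0, 0),
    ],
    columns=["tract", "cls", "profiles", "est", "lo", "hi"],
)


def fully_traced_samples() -> list[TractSample]:
    """Census records for the fully traced tracts (zero-width published range)."""
    rows = EM_TRACT_TABLE.loc[EM_TRACT_TABLE["lo"] == EM_TRACT_TABLE["hi"]]
    return [
        TractSample(r.tract, int(r.profiles), int(r.profiles), int(r.est), r.cls)
        for r in rows.itertuples(index=False)
    ]


def profile_sums() -> dict[str, int]:
    """Profile-count sums over the published tract rows, by class and total."""
    by_cls = EM_TRACT_TABLE.groupby("cls")["profiles"].sum()
    return {
        "LHLN": int(by_cls["LHLN"]),
        "LHON": int(by_cls["LHON"]),
        "total": int(EM_TRACT_TABLE["profiles"].sum()),
    }
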