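"""Lineage-through-time statistics, sliding-window rates, and null envelopes.

The LTT function N(t) counts the reconstructed lineages crossing age t
(My before present). At a branching age the post-split count applies, so
N is right-continuous toward the present and a crown tree has N = 2 at
its root age.

The windowed net diversification statistic is

    r(m) = log2( N(m - w/2) / N(m + w/2) )

for a window of width w (default 2 My) centred on age m: r = 1 means
diversity doubled across the window. Summed over adjacent non-overlapping
windows the statistic telescopes to log2(N_final / N_initial) exactly.

Null envelopes are pointwise quantile bands of the windowed statistic
over constant-rate birth-death simulations matched to the observed crown
age and (by default) to the observed richness, mirroring the visual
comparison of an empirical rate curve against simulated grey curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bd_simulator import BDParams, simulate_bd, solve_lambda_for_richness
from .tree_model import Chronogram

__all__ = [
    "LTTSeries",
    "RateSeries",
    "NullEnvelope",
    "ExceedanceRegion",
    "GridMismatchError",
    "compute_ltt",
    "sliding_window_rate",
    "build_envelope",
    "exceedance_regions",
]


class GridMismatchError(ValueError):
    """Observed series and envelope are on different midpoint grids."""


@dataclass(frozen=True)
class LTTSeries:
    """Branching ages (descending, My) and post-split lineage counts.

    ``counts[i]`` is N just after (younger side of) ``ages[i]``; before
    the root age there is a single stem lineage.
    """

    ages: np.ndarray
    counts: np.ndarray

    @property
    def n_tips(self) -> int:
        return int(self.counts[-1])

    @property
    def root_age(self) -> float:
        return float(self.ages[0])

    def n_at(self, age: float) -> int:
        """N(age): number of lineages crossing the given age."""
        if age > self.ages[0]:
            return 1
        # ages are descending; count events at age >= query
        k = int(np.searchsorted(-self.ages, -age, side="right"))
        return int(self.counts[k - 1]) if k > 0 else 1


@dataclass(frozen=True)
class RateSeries:
    """Windowed net diversification rates (doublings per window)."""

    midpoints: np.ndarray   # window centres, My, descending
    rates: np.ndarray
    window: float

    def __len__(self) -> int:
        return len(self.midpoints)


@dataclass(frozen=True)
class NullEnvelope:
    """Pointwise quantile band over simulated constant-rate replicates."""

    midpoints: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    replicates: np.ndarray   # (n_reps, n_midpoints) rate curves
    params: BDParams
    window: float
    quantiles: tuple[float, float]

    @property
    def n_reps(self) -> int:
        return self.replicates.shape[0]


@dataclass(frozen=True)
class ExceedanceRegion:
    """A maximal run of midpoints outside the envelope.

    ``older`` >= ``younger`` in My; direction is "above" or "below".
    """

    older: float
    younger: float
    direction: str


def compute_ltt(chron: Chronogram) -> LTTSeries:
    """Lineage-through-time series of a reconstructed chronogram.

    Polytomies contribute (children - 1) lineages at their age.
    """
    events: list[tuple[float, int]] = []
    for nd in chron.dtree.preorder_node_iter():
        if not nd.is_leaf():
            events.append((nd.age, len(nd.child_nodes()) - 1))
    events.sort(key=lambda e: -e[0])
    ages = np.array([a for a, _ in events])
    increments = np.array([k for _, k in events])
    counts = 1 + np.cumsum(increments)
    return LTTSeries(ages=ages, counts=counts)


def _midpoint_grid(root_age: float, w: float, step: float) -> np.ndarray:
    """Window centres from root_age - w/2 down to w/2, descending."""
    start, stop = root_age - w / 2.0, w / 2.0
    n = int(np.floor((start - stop) / step + 1e-9)) + 1
    return start - step * np.arange(n)


def sliding_window_rate(chron: Chronogram, w: float = 2.0,
                        step: float = 0.1) -> RateSeries:
    """Windowed log2 diversification rate across the chronogram.

    Windows are evaluated wherever both edges lie within [0, root age].
    """
    if w <= 0:
        raise ValueError("window width must be positive")
    root_age = chron.root_age
    if w > root_age:
        raise ValueError(f"window ({w} My) must not exceed the "
                         f"root age ({root_age:.3g} My)")
    ltt = compute_ltt(chron)
    mids = _midpoint_grid(root_age, w, step)
    rates = np.array([
        np.log2(ltt.n_at(m - w / 2.0) / ltt.n_at(m + w / 2.0))
        for m in mids
    ])
    return RateSeries(midpoints=mids, rates=rates, window=w)


def build_envelope(obs: Chronogram,
                   params: BDParams | None = None,
                   *,
                   mu: float = 0.1,
                   rho: float = 1.0,
                   reps: int = 100,
                   quantiles: tuple[float, float] = (0.025, 0.975),
                   seed: int | None = None,
                   w: float = 2.0,
                   step: float = 0.1) -> NullEnvelope:
    """Constant-rate null envelope for the windowed rate statistic.

    If ``params`` is not given, the speciation rate is solved so that
    expected sampled richness at the observed crown age matches the
    observed tip count (given ``mu`` and ``rho``), making the simulated
    curves comparable in scale to the data.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    root_age = obs.root_age
    if params is None:
        lam = solve_lambda_for_richness(obs.n_tips, root_age, mu=mu, rho=rho)
        params = BDParams(birth=lam, death=mu, rho=rho, crown_age=root_age)
    elif params.crown_age is None or not np.isclose(params.crown_age, root_age):
        raise ValueError("params.crown_age must equal the observed root age")
    rng = np.random.default_rng(seed)
    mids = _midpoint_grid(root_age, w, step)
    curves = np.empty((reps, len(mids)))
    for i in range(reps):
        rep_seed = int(rng.integers(2 ** 31))
        rep_params = BDParams(birth=params.birth, death=params.death,
                              rho=params.rho, crown_age=root_age,
                              seed=rep_seed)
        try:
            tree = simulate_bd(rep_params)
        except Exception as exc:
            raise RuntimeError(f"envelope replicate {i} failed: {exc}") from exc
        curves[i] = sliding_window_rate(tree, w=w, step=step).rates
    lo, hi = quantiles
    if not 0 <= lo < hi <= 1:
        raise ValueError("quantiles must satisfy 0 <= lower < upper <= 1")
    lower = np.quantile(curves, lo, axis=0)
    upper = np.quantile(curves, hi, axis=0)
    return NullEnvelope(midpoints=mids, lower=lower, upper=upper,
                        replicates=curves, params=params, window=w,
                        quantiles=quantiles)


def exceedance_regions(obs: RateSeries,
                       env: NullEnvelope) -> list[ExceedanceRegion]:
    """Maximal contiguous runs where the observed rate leaves the band."""
    if len(obs.midpoints) != len(env.midpoints) or \
            not np.allclose(obs.midpoints, env.midpoints):
        raise GridMismatchError(
            "observed rate series and envelope use different midpoint grids")
    state = np.where(obs.rates > env.upper, 1,
                     np.where(obs.rates < env.lower, -1, 0))
    regions: list[ExceedanceRegion] = []
    i = 0
    n = len(state)
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == state[i]:
            j += 1
        regions.append(ExceedanceRegion(
            older=float(obs.midpoints[i]),
            younger=float(obs.midpoints[j]),
            direction="above" if state[i] == 1 else "below",
        ))
        i = j + 1
    return regions
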