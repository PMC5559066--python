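"""Forward-time birth-death tree simulation with shifts and incomplete sampling.

A Gillespie simulation of the constant-rate birth-death process: each of
the current k lineages speciates at rate lambda and goes extinct at rate
mu, so the next event arrives after an Exp(k * (lambda + mu)) wait. The
simulator starts from the crown split (two lineages, root age =
``crown_age``) and runs to the present; extinct lineages are pruned and
each extant species is retained independently with probability rho (the
sampling fraction), yielding the reconstructed chronogram an empiricist
would observe.

Two conditioning modes:

* ``"crown"`` (default): reject-and-retry until both crown children leave
  at least one surviving, sampled descendant, so the reconstructed root
  age equals ``crown_age`` exactly.
* ``"none"``: a single unconditioned draw; returns None when fewer than
  two sampled lineages survive. Under this mode the expected number of
  survivors obeys E[N(t)] = 2 * exp((lambda - mu) * t).

Rate shifts: at a given age a chosen lineage (and all its descendants)
switches to rates (lambda * lm, mu * mm), emulating clade-specific
diversification-rate increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .tree_model import Chronogram, node_ages, parse_newick

__all__ = [
    "BDParams",
    "Shift",
    "ShiftSpec",
    "SimulationFailure",
    "simulate_bd",
    "simulate_with_shifts",
    "apply_incomplete_sampling",
    "sample_extant_counts",
    "solve_lambda_for_richness",
]

_MAX_ATTEMPTS = 100_000
_MAX_SAMPLING_REDRAWS = 10_000


class SimulationFailure(RuntimeError):
    """The rejection budget was exhausted (e.g. mu >= lambda, deep crown)."""

    def __init__(self, message: str, attempts: int):
        super().__init__(f"{message} (after {attempts} attempts)")
        self.attempts = attempts


@dataclass(frozen=True)
class BDParams:
    """Rates per lineage per My; rho is the species sampling fraction."""

    birth: float                      # speciation rate (lambda)
    death: float = 0.0                # extinction rate (mu)
    rho: float = 1.0                  # sampling fraction
    crown_age: float | None = None    # My; root age of the crown clade
    n_tips: int | None = None         # alternative stopping rule
    seed: int | None = None

    def __post_init__(self):
        if self.birth <= 0:
            raise ValueError("speciation rate must be positive")
        if self.death < 0:
            raise ValueError("extinction rate must be non-negative")
        if not 0 < self.rho <= 1:
            raise ValueError("sampling fraction must lie in (0, 1]")
        if (self.crown_age is None) == (self.n_tips is None):
            raise ValueError("specify exactly one of crown_age or n_tips")
        if self.crown_age is not None and self.crown_age <= 0:
            raise ValueError("crown_age must be positive")
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")


@dataclass(frozen=True)
class Shift:
    """A clade rate shift applied at ``age`` My before present.

    ``anchor`` selects what switches rates at the shift time:
    "root:0"/"root:1" shifts the whole subtree of one crown child (every
    lineage of that side alive at the shift time and all their
    descendants), while "random" shifts the subtree of one uniformly
    chosen lineage.
    """

    age: float
    lambda_mult: float = 1.0
    mu_mult: float = 1.0
    anchor: str = "random"

    def __post_init__(self):
        if self.lambda_mult <= 0 or self.mu_mult <= 0:
            raise ValueError("rate multipliers must be positive")
        if self.age <= 0:
            raise ValueError("shift age must be positive")


ShiftSpec = Sequence[Shift]


# ---------------------------------------------------------------------------
# internal forward simulation
# ---------------------------------------------------------------------------

class _Lin:
    __slots__ = ("birth_time", "end_time", "children", "regime", "side", "alive")

    def __init__(self, birth_time: float, regime: int, side: int):
        self.birth_time = birth_time
        self.end_time: float | None = None
        self.children: list["_Lin"] = []
        self.regime = regime
        self.side = side          # 0/1: which crown child this descends from
        self.alive = True


@dataclass
class _SimResult:
    roots: list[_Lin]
    extant: list[_Lin]
    T: float
    shift_lineages: list[list[_Lin]] = field(default_factory=list)


def _forward(params: BDParams, rng: np.random.Generator,
             shifts: ShiftSpec = ()) -> _SimResult | None:
    """One unconditioned forward pass. None if the process dies out."""
    if params.crown_age is not None:
        T = params.crown_age
        pending = sorted(shifts, key=lambda s: -s.age)  # oldest first
        shift_times = [(T - s.age, s) for s in pending]
        for st, s in shift_times:
            if st < 0:
                raise ValueError(f"shift age {s.age} exceeds crown age {T}")
    else:
        T = None
        shift_times = []
        if shifts:
            raise ValueError("shifts require crown_age mode")

    regimes = [(params.birth, params.death)]
    roots = [_Lin(0.0, 0, 0), _Lin(0.0, 0, 1)]
    # alive lineages grouped by regime for weighted sampling
    alive_by_regime: dict[int, list[_Lin]] = {0: list(roots)}
    n_alive = 2
    t = 0.0
    shift_records: list[_Lin] = []

    def pick(regime_filter=None) -> tuple[int, int] | None:
        """Pick (regime, index) weighted by per-lineage total event rate."""
        weights = []
        keys = []
        for r, lins in alive_by_regime.items():
            if not lins:
                continue
            lam, mu = regimes[r]
            weights.append(len(lins) * (lam + mu))
            keys.append(r)
        if not weights:
            return None
        w = np.asarray(weights)
        r = keys[rng.choice(len(keys), p=w / w.sum())]
        i = rng.integers(len(alive_by_regime[r]))
        return r, int(i)

    while True:
        total = sum(len(lins) * sum(regimes[r])
                    for r, lins in alive_by_regime.items())
        if n_alive == 0:
            return None
        wait = rng.exponential(1.0 / total)
        t_next = t + wait
        # apply any shift scheduled before the next event
        while shift_times and shift_times[0][0] <= t_next:
            st, s = shift_times.pop(0)
            candidates = []
            for r, lins in alive_by_regime.items():
                for lin in lins:
                    if s.anchor == "random" or \
                       (s.anchor.startswith("root:") and lin.side == int(s.anchor[5:])):
                        candidates.append(lin)
            if not candidates:
                return None  # anchor side already extinct: reject
            if s.anchor == "random":
                shifted = [candidates[rng.integers(len(candidates))]]
            else:
                shifted = candidates  # the whole crown-child clade switches
            lam, mu = regimes[shifted[0].regime]
            regimes.append((lam * s.lambda_mult, mu * s.mu_mult))
            new_regime = len(regimes) - 1
            for lin in shifted:
                alive_by_regime[lin.regime].remove(lin)
                lin.regime = new_regime
                alive_by_regime.setdefault(new_regime, []).append(lin)
            shift_records.append(shifted)
            t = st
            total = sum(len(lins) * sum(regimes[rr])
                        for rr, lins in alive_by_regime.items())
            wait = rng.exponential(1.0 / total)
            t_next = t + wait
        if T is not None and t_next >= T:
            break
        t = t_next
        picked = pick()
        if picked is None:
            return None
        r, i = picked
        lins = alive_by_regime[r]
        lin = lins[i]
        lam, mu = regimes[r]
        # swap-remove
        lins[i] = lins[-1]
        lins.pop()
        lin.alive = False
        lin.end_time = t
        if rng.random() < lam / (lam + mu):
            c1, c2 = _Lin(t, lin.regime, lin.side), _Lin(t, lin.regime, lin.side)
            lin.children = [c1, c2]
            lins.extend([c1, c2])
            n_alive += 1
        else:
            n_alive -= 1
            if n_alive == 0:
                return None
        if T is None and params.n_tips is not None and n_alive >= params.n_tips:
            T = t  # stop at the moment the target richness is reached
            break

    extant = [lin for lins in alive_by_regime.values() for lin in lins if lin.alive]
    for lin in extant:
        lin.end_time = T
    return _SimResult(roots=roots, extant=extant, T=T,
                      shift_lineages=shift_records)


def _descendant_extant(lin: _Lin) -> list[_Lin]:
    out, stack = [], [lin]
    while stack:
        nd = stack.pop()
        if nd.alive:
            out.append(nd)
        stack.extend(nd.children)
    return out


def _render_newick(sim: _SimResult, retained: set[int],
                   labels: dict[int, str]) -> str:
    """Reconstructed tree over retained extant tips; unifurcations merged."""
    T = sim.T

    # iterative postorder keep-flag computation (trees can be deep)
    keep_flag: dict[int, bool] = {}
    stack: list[tuple[_Lin, bool]] = [(r, False) for r in sim.roots]
    while stack:
        lin, done = stack.pop()
        if lin.alive:
            keep_flag[id(lin)] = id(lin) in retained
        elif done:
            keep_flag[id(lin)] = any(keep_flag[id(c)] for c in lin.children)
        else:
            stack.append((lin, True))
            stack.extend((c, False) for c in lin.children)

    def keep(lin: _Lin) -> bool:
        return keep_flag[id(lin)]

    def render(lin: _Lin, origin: float) -> str:
        if lin.alive:
            return f"{labels[id(lin)]}:{T - origin!r}"
        kept = [c for c in lin.children if keep(c)]
        if len(kept) == 1:
            return render(kept[0], origin)
        inner = ",".join(render(c, lin.end_time) for c in kept)
        return f"({inner}):{lin.end_time - origin!r}"

    kept_roots = [r for r in sim.roots if keep(r)]
    if len(kept_roots) == 2:
        return "(" + ",".join(render(r, 0.0) for r in kept_roots) + ");"
    # root degenerates to one side: strip the top branch length
    s = render(kept_roots[0], 0.0)
    top = s.rsplit(":", 1)[0] if not s.endswith(")") else s
    if top.startswith("("):
        return top + ";"
    return f"({top});"  # single-tip degenerate case


def _retain(extant: list[_Lin], rho: float, rng: np.random.Generator) -> set[int]:
    if rho >= 1.0:
        return {id(lin) for lin in extant}
    mask = rng.random(len(extant)) < rho
    return {id(lin) for lin, m in zip(extant, mask) if m}


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_bd(params: BDParams,
                condition: Literal["crown", "none"] = "crown",
                label_prefix: str = "t") -> Chronogram | None:
    """Simulate a reconstructed (extant, sampled) birth-death chronogram.

    Under ``condition="crown"`` the draw is repeated until both crown
    children leave sampled survivors, so the result always has root age
    ``crown_age``; :class:`SimulationFailure` is raised when the
    rejection budget runs out. Under ``condition="none"`` a single draw
    is made and None is returned if fewer than two sampled lineages
    survive. Reproducible given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    attempts = 0
    while attempts < _MAX_ATTEMPTS:
        attempts += 1
        sim = _forward(params, rng)
        if sim is None:
            if condition == "none":
                return None
            continue
        retained = _retain(sim.extant, params.rho, rng)
        if len(retained) < 2:
            if condition == "none":
                return None
            continue
        if condition == "crown":
            sides = {lin.side for lin in sim.extant if id(lin) in retained}
            if sides != {0, 1}:
                continue
        labels = {id(lin): f"{label_prefix}{i + 1}"
                  for i, lin in enumerate(sim.extant) if id(lin) in retained}
        nwk = _render_newick(sim, retained, labels)
        return node_ages(parse_newick(nwk), tol=1e-6 * sim.T)
    raise SimulationFailure(
        "could not condition on crown survival; consider lower mu or "
        "shallower crown age", attempts)


def simulate_with_shifts(params: BDParams, shifts: ShiftSpec,
                         label_prefix: str = "t",
                         require_shift_survival: bool = True,
                         ) -> tuple[Chronogram, dict]:
    """Simulate under clade rate shifts; crown-conditioned.

    Returns the chronogram and a ground-truth manifest with, per shift,
    the shift age, multipliers, and the labels of sampled extant tips
    descending from the shifted lineage.
    """
    rng = np.random.default_rng(params.seed)
    attempts = 0
    while attempts < _MAX_ATTEMPTS:
        attempts += 1
        sim = _forward(params, rng, shifts=shifts)
        if sim is None:
            continue
        retained = _retain(sim.extant, params.rho, rng)
        if len(retained) < 2:
            continue
        sides = {lin.side for lin in sim.extant if id(lin) in retained}
        if sides != {0, 1}:
            continue
        if len(sim.shift_lineages) != len(shifts):
            continue
        labels = {id(lin): f"{label_prefix}{i + 1}"
                  for i, lin in enumerate(sim.extant) if id(lin) in retained}
        shift_manifest = []
        ok = True
        for s, lins in zip(sorted(shifts, key=lambda x: -x.age), sim.shift_lineages):
            tips = [labels[id(d)] for lin in lins for d in _descendant_extant(lin)
                    if id(d) in retained]
            if require_shift_survival and not tips:
                ok = False
                break
            shift_manifest.append({
                "age": s.age,
                "lambda_mult": s.lambda_mult,
                "mu_mult": s.mu_mult,
                "tips": sorted(tips),
            })
        if not ok:
            continue
        nwk = _render_newick(sim, retained, labels)
        chron = node_ages(parse_newick(nwk), tol=1e-6 * sim.T)
        return chron, {"shifts": shift_manifest, "params": params}
    raise SimulationFailure("could not satisfy shift/crown conditioning", attempts)


def apply_incomplete_sampling(tree: Chronogram, rho: float,
                              seed: int | None = None) -> Chronogram:
    """Retain each tip independently with probability rho.

    Redraws until at least two tips remain; retained branch structure is
    preserved with suppressed unifurcations merged (lengths summed).
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    labels = sorted(tree.tip_labels)
    if rho == 1.0:
        return tree
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_SAMPLING_REDRAWS):
        mask = rng.random(len(labels)) < rho
        kept = [lb for lb, m in zip(labels, mask) if m]
        if len(kept) >= 2:
            dt2 = tree.dtree.extract_tree_with_taxa_labels(kept)
            sub = parse_newick(
                dt2.as_string(schema="newick", unquoted_underscores=True).strip())
            return node_ages(sub, tol=1e-6 * max(tree.root_age, 1.0))
    raise SimulationFailure("sampling kept < 2 tips in every redraw",
                            _MAX_SAMPLING_REDRAWS)


def sample_extant_counts(params: BDParams, reps: int,
                         seed: int | None = None) -> np.ndarray:
    """Numbers of sampled surviving lineages over unconditioned draws.

    Fast path for Monte-Carlo checks of E[N(t)] = 2 exp((lambda-mu) t):
    no trees are built, extinction counts as 0.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    counts = np.zeros(reps, dtype=int)
    for i in range(reps):
        sim = _forward(params, rng)
        if sim is None:
            continue
        counts[i] = len(_retain(sim.extant, params.rho, rng))
    return counts


def solve_lambda_for_richness(n_observed: int, crown_age: float,
                              mu: float = 0.0, rho: float = 1.0) -> float:
    """Speciation rate whose expected sampled richness at the crown age
    matches the observed tip count: 2 rho exp((lambda-mu) T) = n."""
    if n_observed < 2:
        raise ValueError("observed richness must be at least 2")
    target = n_observed / (2.0 * rho)
    lam = mu + np.log(target) / crown_age
    if lam <= 0:
        raise ValueError("implied speciation rate is non-positive")
    return float(lam)
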