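"""Synthetic respondents for health-state valuation surveys.

Generates answers to the four elicitation instruments used in
general-population disability-weight studies -- paired comparison (PC),
visual analogue scale (VAS), standard gamble (SG) and population health
equivalence (PHE) -- from a known latent disability scale, so that every
downstream estimator can be tested against ground truth.

The respondent model is Thurstonian: a pair (a, b) is judged with state *a*
healthier with probability ``Phi((d_b - d_a) / sigma_pc)`` where ``d`` is the
latent disability weight (0 = full health, 1 = dead) and ``Phi`` the standard
normal CDF.  VAS, SG and PHE answers are produced by perturbing the latent
weight with instrument-specific Gaussian noise and pushing it through a
deterministic responder mechanic (a 5 %-grid gamble staircase, a
person-trade-off ladder over fixed rung values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "ANCHOR_FULL_HEALTH",
    "ANCHOR_DEAD",
    "ANCHOR_NONE",
    "PHE_LADDER",
    "PHE_DEATHS_AVERTED",
    "SG_GRID_STEP",
    "SG_GRID_START",
    "HealthState",
    "StateRegistry",
    "TrueWeights",
    "SimConfig",
    "PCResponse",
    "VASResponse",
    "SGRecord",
    "PHERecord",
    "make_state_registry",
    "simulate_pc_responses",
    "simulate_vas_responses",
    "sg_staircase",
    "simulate_sg_responses",
    "phe_ladder",
    "simulate_phe_responses",
    "simulate_all",
]

ANCHOR_NONE = "none"
ANCHOR_FULL_HEALTH = "full_health"
ANCHOR_DEAD = "dead"

#: Rung values offered for programme B in the person-trade-off ladder.
PHE_LADDER: tuple[int, ...] = (1500, 2000, 3000, 5000, 10000)
#: Deaths averted by programme A; one averted death == one unit of full health.
PHE_DEATHS_AVERTED = 1000

SG_GRID_STEP = 0.05
SG_GRID_START = 0.50


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HealthState:
    """A health state in the valuation universe.

    ``anchor`` marks the two pseudo-states that pin the disability-weight
    scale: ``"full_health"`` (weight 0) and ``"dead"`` (weight 1); every
    substantive state carries ``"none"``.
    """

    state_id: str
    label: str = ""
    anchor: str = ANCHOR_NONE

    def __post_init__(self) -> None:
        if self.anchor not in (ANCHOR_NONE, ANCHOR_FULL_HEALTH, ANCHOR_DEAD):
            raise ValueError(f"unknown anchor kind: {self.anchor!r}")


class StateRegistry:
    """Ordered collection of health states with exactly one of each anchor."""

    def __init__(self, states: Sequence[HealthState]):
        states = tuple(states)
        ids = [s.state_id for s in states]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate state_id(s): {dup}")
        fh = [s for s in states if s.anchor == ANCHOR_FULL_HEALTH]
        dead = [s for s in states if s.anchor == ANCHOR_DEAD]
        if len(fh) != 1 or len(dead) != 1:
            raise ValueError(
                "registry needs exactly one full-health and one dead anchor "
                f"(got {len(fh)} and {len(dead)})"
            )
        if len(states) < 3:
            raise ValueError("registry needs at least one substantive state")
        self.states = states
        self._by_id = {s.state_id: s for s in states}
        self.full_health_id = fh[0].state_id
        self.dead_id = dead[0].state_id

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, state_id: str) -> bool:
        return state_id in self._by_id

    def __getitem__(self, state_id: str) -> HealthState:
        return self._by_id[state_id]

    @property
    def state_ids(self) -> list[str]:
        return [s.state_id for s in self.states]

    @property
    def substantive_ids(self) -> list[str]:
        return [s.state_id for s in self.states if s.anchor == ANCHOR_NONE]


class TrueWeights(Mapping[str, float]):
    """Latent disability weights: the simulator's ground truth.

    A mapping ``state_id -> d`` with ``d`` in [0, 1]; the registry anchors
    must be present at exactly 0 (full health) and 1 (dead).
    """

    def __init__(self, weights: Mapping[str, float], registry: StateRegistry):
        w = dict(weights)
        if w.get(registry.full_health_id) != 0.0:
            raise ValueError("d(full_health) must be exactly 0")
        if w.get(registry.dead_id) != 1.0:
            raise ValueError("d(dead) must be exactly 1")
        missing = set(registry.state_ids) - set(w)
        if missing:
            raise ValueError(f"weights missing for states: {sorted(missing)}")
        bad = {k: v for k, v in w.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"weights outside [0, 1]: {bad}")
        self._w = w
        self.registry = registry

    def __getitem__(self, state_id: str) -> float:
        return self._w[state_id]

    def __iter__(self):
        return iter(self._w)

    def __len__(self) -> int:
        return len(self._w)

    def as_series(self):
        import pandas as pd

        return pd.Series(self._w, name="true_dw")


@dataclass(frozen=True)
class SimConfig:
    """Survey design and noise parameters.

    Defaults mirror the field designs these simulators emulate: 15 paired
    comparisons per respondent, 3 VAS ratings (the third always 'being
    dead'), 3 SG staircases, 3 PHE ladders.  Noise scales are on the latent
    scale except ``sigma_vas`` (VAS points out of 100).
    """

    n_respondents: int = 500
    k_pairs: int = 15
    sigma_pc: float = 0.25
    sigma_vas: float = 10.0
    sigma_sg: float = 0.10
    sigma_phe: float = 0.10
    n_vas_substantive: int = 2
    n_sg: int = 3
    n_phe: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.k_pairs < 1:
            raise ValueError("k_pairs must be >= 1")
        for name in ("sigma_pc", "sigma_vas", "sigma_sg", "sigma_phe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PCResponse:
    respondent_id: str
    state_a: str
    state_b: str
    chose_a_healthier: bool

    def __post_init__(self) -> None:
        if self.state_a == self.state_b:
            raise ValueError("paired comparison needs two distinct states")


@dataclass(frozen=True)
class VASResponse:
    respondent_id: str
    state_id: str
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError(f"VAS value outside [0, 100]: {self.value}")


@dataclass(frozen=True)
class SGRecord:
    respondent_id: str
    state_id: str
    worse_than_dead: bool
    endpoint_p: float | None = None

    def __post_init__(self) -> None:
        if self.worse_than_dead:
            if self.endpoint_p is not None:
                raise ValueError("worse-than-dead record carries no endpoint")
        else:
            if self.endpoint_p is None:
                raise ValueError("endpoint_p required when not worse than dead")
            k = round(self.endpoint_p / SG_GRID_STEP)
            if not (1 <= k <= 19) or abs(self.endpoint_p - k * SG_GRID_STEP) > 1e-9:
                raise ValueError(
                    f"endpoint_p not on the 5% grid in [0.05, 0.95]: {self.endpoint_p}"
                )


@dataclass(frozen=True)
class PHERecord:
    """One person-trade-off ladder walk.

    ``trace`` lists (rung value, chose programme B) in the order asked.
    ``final_bracket`` is ``(X_low, X_high)``; ``None`` at one end marks an
    open-ended outcome (B preferred even at the lowest rung, or A preferred
    even at the highest).
    """

    respondent_id: str
    state_id: str
    trace: tuple[tuple[int, bool], ...]
    final_bracket: tuple[int | None, int | None]

    def __post_init__(self) -> None:
        for x, _ in self.trace:
            if x not in PHE_LADDER:
                raise ValueError(f"rung {x} not in ladder {PHE_LADDER}")
        lo, hi = self.final_bracket
        if lo is None and hi != PHE_LADDER[0]:
            raise ValueError("open-below bracket must be (None, lowest rung)")
        if hi is None and lo != PHE_LADDER[-1]:
            raise ValueError("open-above bracket must be (highest rung, None)")
        if lo is not None and hi is not None:
            i, j = PHE_LADDER.index(lo), PHE_LADDER.index(hi)
            if j != i + 1:
                raise ValueError(f"bracket {self.final_bracket} is not adjacent rungs")


# ---------------------------------------------------------------------------
# Registry / truth construction
# ---------------------------------------------------------------------------

def make_state_registry(
    n_substantive: int,
    seed: int | np.random.Generator = 0,
    low: float = 0.02,
    high: float = 0.95,
) -> tuple[StateRegistry, TrueWeights]:
    """Build a registry of ``n_substantive + 2`` states with latent weights.

    Substantive weights are drawn i.i.d. uniform on ``[low, high]``; the two
    anchors are fixed at exactly 0 and 1.  The default support keeps
    substantive states away from the anchor values so parameter-recovery
    checks are not confounded by boundary coincidences.
    """
    if n_substantive < 1:
        raise ValueError("n_substantive must be >= 1")
    rng = np.random.default_rng(seed)
    states = [HealthState("FH", "full health", ANCHOR_FULL_HEALTH)]
    width = len(str(n_substantive))
    for i in range(n_substantive):
        states.append(HealthState(f"S{i + 1:0{width}d}", f"state {i + 1}"))
    states.append(HealthState("DEAD", "being dead", ANCHOR_DEAD))
    registry = StateRegistry(states)
    d = rng.uniform(low, high, size=n_substantive)
    weights = {registry.full_health_id: 0.0, registry.dead_id: 1.0}
    weights.update(zip(registry.substantive_ids, d))
    return registry, TrueWeights(weights, registry)


def _respondent_ids(n: int, prefix: str) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Paired comparison
# ---------------------------------------------------------------------------

def simulate_pc_responses(
    registry: StateRegistry,
    truth: TrueWeights,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[PCResponse]:
    """Simulate forced choices of the healthier of two states.

    Each respondent answers ``k_pairs`` comparisons; both members of a pair
    are drawn uniformly without replacement from the full registry, anchors
    included.  With ``sigma_pc == 0`` the choice is deterministic by latent
    weight; an exact tie is resolved by a fair coin.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ids = np.asarray(registry.state_ids)
    d = np.array([truth[s] for s in ids])
    n_total = config.n_respondents * config.k_pairs

    # sample index pairs without replacement within a comparison
    a_idx = rng.integers(0, len(ids), size=n_total)
    b_idx = rng.integers(0, len(ids) - 1, size=n_total)
    b_idx = np.where(b_idx >= a_idx, b_idx + 1, b_idx)

    diff = d[b_idx] - d[a_idx]
    if config.sigma_pc > 0:
        p_a = norm.cdf(diff / config.sigma_pc)
    else:
        p_a = np.where(diff > 0, 1.0, np.where(diff < 0, 0.0, 0.5))
    chose_a = rng.random(n_total) < p_a

    out: list[PCResponse] = []
    rids = _respondent_ids(config.n_respondents, "R")
    for i in range(n_total):
        out.append(
            PCResponse(
                respondent_id=rids[i // config.k_pairs],
                state_a=str(ids[a_idx[i]]),
                state_b=str(ids[b_idx[i]]),
                chose_a_healthier=bool(chose_a[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Visual analogue scale
# ---------------------------------------------------------------------------

def simulate_vas_responses(
    registry: StateRegistry,
    truth: TrueWeights,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[VASResponse]:
    """Simulate 0-100 ratings: two substantive states plus 'being dead'.

    The noiseless rating of a state with weight ``d`` is ``100 * (1 - d)``;
    Gaussian noise (``sigma_vas`` VAS points) is added and the mark clamped
    to the instrument's [0, 100] range.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sub = registry.substantive_ids
    out: list[VASResponse] = []
    for rid in _respondent_ids(config.n_respondents, "R"):
        picks = list(rng.choice(sub, size=min(config.n_vas_substantive, len(sub)), replace=False))
        for sid in picks + [registry.dead_id]:
            raw = 100.0 * (1.0 - truth[sid]) + rng.normal(0.0, config.sigma_vas)
            out.append(VASResponse(rid, str(sid), float(np.clip(raw, 0.0, 100.0))))
    return out


# ---------------------------------------------------------------------------
# Standard gamble
# ---------------------------------------------------------------------------

def sg_staircase(
    u: float,
    grid_step: float = SG_GRID_STEP,
    start: float = SG_GRID_START,
) -> tuple[bool, float | None]:
    """Deterministic gamble-staircase responder for internal utility ``u``.

    A respondent who values the state below dead (``u < 0``) says so at the
    first question and the staircase stops: ``(True, None)``.  Otherwise the
    titration converges on the grid probability nearest ``u`` (ties break
    toward the lower probability) and the endpoint is capped to the grid's
    reachable range [0.05, 0.95], since a 5 % staircase from 50 % can state
    indifference only at interior rungs.
    """
    if u < 0:
        return True, None
    # nearest grid multiple; ties toward lower p
    lo = int(np.floor(u / grid_step + 1e-12))
    hi = lo + 1
    if abs(u - lo * grid_step) <= abs(hi * grid_step - u):
        k = lo
    else:
        k = hi
    n_rungs = int(round(1.0 / grid_step))  # 20 for a 5% grid
    k = min(max(k, 1), n_rungs - 1)
    return False, round(k * grid_step, 10)


def simulate_sg_responses(
    registry: StateRegistry,
    truth: TrueWeights,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SGRecord]:
    """Simulate SG staircases: internal utility ``(1 - d) + noise``."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sub = registry.substantive_ids
    out: list[SGRecord] = []
    for rid in _respondent_ids(config.n_respondents, "R"):
        picks = rng.choice(sub, size=min(config.n_sg, len(sub)), replace=False)
        for sid in picks:
            u = (1.0 - truth[sid]) + rng.normal(0.0, config.sigma_sg)
            worse, p = sg_staircase(u)
            out.append(SGRecord(rid, str(sid), worse, p))
    return out


# ---------------------------------------------------------------------------
# Population health equivalence (person trade-off ladder)
# ---------------------------------------------------------------------------

def _prefers_b(x: int, w: float) -> bool:
    # programme B prevents x cases of a state with weight w; programme A
    # averts PHE_DEATHS_AVERTED deaths.  Exact equivalence counts as B.
    return x * w >= PHE_DEATHS_AVERTED


def phe_ladder(
    w: float,
    start_x: int,
    ladder: Sequence[int] = PHE_LADDER,
) -> tuple[tuple[tuple[int, bool], ...], tuple[int | None, int | None]]:
    """Deterministic ladder walk for internal disability weight ``w``.

    The respondent prefers the disease-prevention programme B at rung ``X``
    iff ``X * w >= 1000`` (benefit equivalence; a tie counts as B).  The walk
    moves up the ladder while A is preferred and down while B is preferred,
    stopping when the preference flips or an extreme rung is reached.
    Returns (trace, final_bracket).
    """
    if not 0.0 < w <= 1.0:
        raise ValueError(f"internal weight must be in (0, 1]: {w}")
    ladder = tuple(ladder)
    if start_x not in ladder:
        raise ValueError(f"start rung {start_x} not on ladder {ladder}")
    i = ladder.index(start_x)
    trace: list[tuple[int, bool]] = []
    first = _prefers_b(ladder[i], w)
    trace.append((ladder[i], first))
    step = -1 if first else +1
    while True:
        j = i + step
        if j < 0:
            return tuple(trace), (None, ladder[0])
        if j >= len(ladder):
            return tuple(trace), (ladder[-1], None)
        b = _prefers_b(ladder[j], w)
        trace.append((ladder[j], b))
        if b != first:
            lo, hi = sorted((ladder[i], ladder[j]))
            return tuple(trace), (lo, hi)
        i = j


def simulate_phe_responses(
    registry: StateRegistry,
    truth: TrueWeights,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[PHERecord]:
    """Simulate PHE ladders: internal weight ``d + noise`` clamped to (0, 1]."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sub = registry.substantive_ids
    eps = 1e-6
    out: list[PHERecord] = []
    for rid in _respondent_ids(config.n_respondents, "W"):
        picks = rng.choice(sub, size=min(config.n_phe, len(sub)), replace=False)
        for sid in picks:
            w = float(np.clip(truth[sid] + rng.normal(0.0, config.sigma_phe), eps, 1.0))
            start = int(rng.choice(PHE_LADDER))
            trace, bracket = phe_ladder(w, start)
            out.append(PHERecord(rid, str(sid), trace, bracket))
    return out


def simulate_all(
    registry: StateRegistry,
    truth: TrueWeights,
    config: SimConfig,
) -> dict[str, list]:
    """Run all four instruments from a single seed.

    Each instrument gets an independent child stream of the configured seed,
    so adding respondents to one instrument does not perturb another.
    """
    root = np.random.default_rng(config.seed)
    pc_rng, vas_rng, sg_rng, phe_rng = root.spawn(4)
    return {
        "pc": simulate_pc_responses(registry, truth, config, pc_rng),
        "vas": simulate_vas_responses(registry, truth, config, vas_rng),
        "sg": simulate_sg_responses(registry, truth, config, sg_rng),
        "phe": simulate_phe_responses(registry, truth, config, phe_rng),
    }
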