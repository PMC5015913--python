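"""Direct valuation models: VAS (Model 3) and standard gamble (Model 4).

Both models equate the disability weight with the disutility ``1 - utility``.

VAS utilities rescale each 0-100 rating against the respondent's own rating
of 'being dead': ``u = v / 100`` when dead was rated 0, otherwise
``u = (v - v_dead) / (100 - v_dead)``.  A respondent who rated dead at 100
leaves the denominator zero and the whole VAS block is excluded (logged).
States a respondent rated below their dead rating come out with negative
utility, i.e. disutility above 1; those are flagged but never clipped, since
clipping would bias the state means.

SG utilities are the staircase's indifference probability of restoration to
full health; a state judged worse than dead is censored at utility 0
(disutility 1) rather than measured.

Per-state disability weights are the coefficients of a linear regression of
disutility on state dummies without intercept -- algebraically the per-state
arithmetic means -- with 95% CIs from the pooled residual variance of that
single regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pc_model import DWEstimate
from .survey_sim import SGRecord, StateRegistry, VASResponse

__all__ = [
    "DisutilityRecord",
    "VASExclusion",
    "vas_utility",
    "sg_utility",
    "disutilities_from_vas",
    "disutilities_from_sg",
    "estimate_state_dws",
]


@dataclass(frozen=True)
class DisutilityRecord:
    """One elicitation event reduced to a disutility (= 1 - utility)."""

    respondent_id: str
    state_id: str
    disutility: float
    source: str  # "vas" or "sg"

    def __post_init__(self) -> None:
        if self.source not in ("vas", "sg"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "sg" and not 0.05 - 1e-9 <= self.disutility <= 1.0 + 1e-9:
            raise ValueError(f"SG disutility outside [0.05, 1]: {self.disutility}")


@dataclass(frozen=True)
class VASExclusion:
    """A respondent's VAS block dropped because 'being dead' was rated 100."""

    respondent_id: str
    reason: str


def vas_utility(v: float, v_dead: float) -> float:
    """Utility of a state rated ``v`` by a respondent who rated dead ``v_dead``."""
    if not (0.0 <= v <= 100.0 and 0.0 <= v_dead <= 100.0):
        raise ValueError(f"VAS values must lie in [0, 100]: v={v}, v_dead={v_dead}")
    if v_dead == 100.0:
        raise ZeroDivisionError("dead rated 100: rescaling denominator is zero")
    if v_dead == 0.0:
        return v / 100.0
    return (v - v_dead) / (100.0 - v_dead)


def sg_utility(rec: SGRecord) -> float:
    """Indifference probability, censored at 0 for worse-than-dead states."""
    if rec.worse_than_dead:
        return 0.0
    if rec.endpoint_p is None:
        raise ValueError(f"record for {rec.state_id} lacks an endpoint")
    return float(rec.endpoint_p)


def disutilities_from_vas(
    vas: Sequence[VASResponse],
    registry: StateRegistry,
) -> tuple[list[DisutilityRecord], list[VASExclusion]]:
    """Convert VAS blocks to disutilities using each respondent's dead rating.

    Returns the usable records plus an exclusion log: blocks whose dead
    rating is 100 (denominator zero) or missing entirely.  Disutilities
    above 1 (state rated below dead) trigger a warning but are retained.
    """
    by_resp: dict[str, list[VASResponse]] = {}
    for r in vas:
        by_resp.setdefault(r.respondent_id, []).append(r)

    records: list[DisutilityRecord] = []
    exclusions: list[VASExclusion] = []
    n_over = 0
    for rid, rows in by_resp.items():
        dead_rows = [r for r in rows if r.state_id == registry.dead_id]
        if not dead_rows:
            exclusions.append(VASExclusion(rid, "no rating of 'being dead'"))
            continue
        v_dead = dead_rows[0].value
        if v_dead == 100.0:
            exclusions.append(VASExclusion(rid, "rated 'being dead' at 100"))
            continue
        for r in rows:
            if r.state_id in (registry.dead_id, registry.full_health_id):
                continue
            d = 1.0 - vas_utility(r.value, v_dead)
            if d > 1.0:
                n_over += 1
            records.append(DisutilityRecord(rid, r.state_id, d, "vas"))
    if n_over:
        warnings.warn(
            f"{n_over} VAS disutilities exceed 1 (state rated below dead); "
            "retained unclipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return records, exclusions


def disutilities_from_sg(sg: Sequence[SGRecord]) -> list[DisutilityRecord]:
    return [
        DisutilityRecord(r.respondent_id, r.state_id, 1.0 - sg_utility(r), "sg")
        for r in sg
    ]


def estimate_state_dws(
    records: Sequence[DisutilityRecord],
    model_tag: str,
) -> list[DWEstimate]:
    """Per-state disability weights as dummy-regression coefficients.

    A no-intercept regression of disutility on the full set of state dummies
    has coefficients equal to the per-state means; the CI uses the pooled
    residual variance s^2 = RSS / (n - k) of that single fit, so
    ``se_h = s / sqrt(n_h)`` with a t(n - k) critical value.  A state with a
    single record gets an undefined (NaN) interval; zero residual variance
    yields zero-width intervals.
    """
    if model_tag not in ("model3", "model4"):
        raise ValueError("model_tag must be 'model3' or 'model4'")
    if not records:
        raise ValueError("no disutility records")
    df = pd.DataFrame(
        [(r.state_id, r.disutility) for r in records], columns=["state_id", "d"]
    )
    g = df.groupby("state_id")["d"]
    means, counts = g.mean(), g.size()
    n, k = len(df), len(means)
    rss = float(((df["d"] - df["state_id"].map(means)) ** 2).sum())
    dof = n - k
    if dof > 0:
        s2 = rss / dof
        tcrit = stats.t.ppf(0.975, dof)
    else:
        s2, tcrit = np.nan, np.nan

    out = []
    for sid in means.index:
        m = float(means[sid])
        if counts[sid] == 1 or dof <= 0:
            # single observation: no within-state replication to anchor a CI
            lo = hi = np.nan
        else:
            half = tcrit * np.sqrt(s2 / counts[sid])
            lo, hi = m - half, m + half
        out.append(DWEstimate(str(sid), m, float(lo), float(hi), model_tag))
    return out
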