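"""Hybrid person-trade-off / paired-comparison model (Model 2).

The population-health-equivalence (PHE) ladder asks whether averting 1,000
deaths or preventing X cases of a health state produces more population
health; indifference at X implies a disability weight of about 1000/X.  A
completed ladder therefore brackets the respondent's weight between the two
rungs where the preference flipped.

The per-state PHE weight is estimated by interval regression: an
interval-censored normal likelihood on the log-weight scale with one mean
per state and a common scale.  Per-state estimates are linked to the
paired-comparison predicted probabilities by ordinary least squares, and the
fitted line converts every state's probability into a hybrid disability
weight -- including states that never appeared in a PHE ladder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .pc_model import DWEstimate, Z95
from .survey_sim import PHE_DEATHS_AVERTED, PHE_LADDER, PHERecord

__all__ = [
    "IntervalObs",
    "IntervalRegressionFit",
    "LinkageFit",
    "OPEN_ABOVE_FLOOR",
    "phe_record_to_interval",
    "fit_interval_regression",
    "link_hybrid",
]

#: Lower bound substituted for an open-ended "above the top rung" outcome:
#: below the ladder's resolution the data carry no information, and the
#: log-scale likelihood needs a finite positive bound.
OPEN_ABOVE_FLOOR = 0.001


@dataclass(frozen=True)
class IntervalObs:
    """One respondent's bracketed disability weight, ``0 < lo <= hi <= 1``."""

    state_id: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lo <= self.hi <= 1.0:
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}] for {self.state_id}")


def phe_record_to_interval(rec: PHERecord) -> IntervalObs:
    """Invert the ladder walk into a disability-weight interval.

    A flip between rungs (X_low, X_high) brackets the weight in
    [1000/X_high, 1000/X_low].  Open-ended outcomes map to
    [2/3, 1] (programme B preferred even at the lowest rung) and
    [``OPEN_ABOVE_FLOOR``, 0.1] (programme A preferred even at 10,000).
    """
    _check_trace(rec)
    lo_x, hi_x = rec.final_bracket
    if lo_x is None:  # B preferred at the bottom rung: weight above 1000/1500
        return IntervalObs(rec.state_id, PHE_DEATHS_AVERTED / PHE_LADDER[0], 1.0)
    if hi_x is None:  # A preferred at the top rung: weight below 1000/10000
        return IntervalObs(rec.state_id, OPEN_ABOVE_FLOOR, PHE_DEATHS_AVERTED / PHE_LADDER[-1])
    return IntervalObs(rec.state_id, PHE_DEATHS_AVERTED / hi_x, PHE_DEATHS_AVERTED / lo_x)


def _check_trace(rec: PHERecord) -> None:
    """A valid walk moves monotonically and flips preference at most once."""
    xs = [x for x, _ in rec.trace]
    bs = [b for _, b in rec.trace]
    if len(xs) >= 2:
        steps = np.diff([PHE_LADDER.index(x) for x in xs])
        if not (np.all(steps == 1) or np.all(steps == -1)):
            raise ValueError(f"non-monotone ladder trace for {rec.state_id}: {xs}")
        if len(set(bs[:-1])) > 1:
            raise ValueError(f"preference flipped mid-walk for {rec.state_id}: {rec.trace}")


# ---------------------------------------------------------------------------
# Interval regression
# ---------------------------------------------------------------------------

@dataclass
class IntervalRegressionFit:
    """Interval-censored normal MLE with state-dummy means, common scale.

    ``estimates`` holds per-state weight (back-transformed from the model
    scale), delta-method 95% CI, and a flag for point-degenerate states
    (all intervals identical with zero width -- fitted exactly, zero-width
    CI).  ``sigma`` is the common latent scale.
    """

    estimates: pd.DataFrame  # index state_id; columns phe_dw, ci_lo, ci_hi, n, degenerate
    sigma: float
    loglik: float
    log_scale: bool

    def as_mapping(self) -> dict[str, float]:
        return self.estimates["phe_dw"].to_dict()


def _interval_nll_grad(theta: np.ndarray, lo, hi, idx, n_states, exact_mask):
    """Negative loglik and gradient; theta = (mu_1..mu_S, log sigma)."""
    mu = theta[:n_states][idx]
    sigma = np.exp(theta[-1])
    zl = (lo - mu) / sigma
    zh = (hi - mu) / sigma
    nll = 0.0
    grad_mu = np.zeros_like(mu)
    grad_ls = 0.0

    iv = ~exact_mask
    if iv.any():
        # log(Phi(zh) - Phi(zl)) computed stably via the wider tail
        a, b = zl[iv], zh[iv]
        log_p = np.maximum(_log_ndtr_diff(a, b), -700.0)  # floor keeps grads finite
        nll -= float(np.sum(log_p))
        # density-to-mass ratios phi/P in log space to avoid underflow
        ra = np.exp(norm.logpdf(a) - log_p)
        rb = np.exp(norm.logpdf(b) - log_p)
        grad_mu[iv] = (rb - ra) / sigma  # d nll / d mu
        grad_ls += float(np.sum(b * rb - a * ra))  # d nll / d log sigma
    if exact_mask.any():
        z = zl[exact_mask]
        nll -= float(np.sum(norm.logpdf(z) - np.log(sigma)))
        grad_mu[exact_mask] = -z / sigma
        grad_ls += float(np.sum(1.0 - z**2))

    grad = np.zeros_like(theta)
    np.add.at(grad, idx, grad_mu)
    grad[-1] = grad_ls
    return nll, grad


def _log_ndtr_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) for a < b, stable in both tails."""
    flip = a + b > 0  # reflect to the left tail where log_ndtr is accurate
    aa = np.where(flip, -b, a)
    bb = np.where(flip, -a, b)
    lb = log_ndtr(bb)
    la = log_ndtr(aa)
    return lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-300)))


def fit_interval_regression(
    obs: Sequence[IntervalObs],
    log_scale: bool = True,
    gtol: float = 1e-8,
) -> IntervalRegressionFit:
    """MLE of per-state weights from interval-censored observations.

    The default model places the censored normal on log(DW) -- keeping
    estimates positive and matching the multiplicative spacing of the ladder
    rungs -- with the per-state estimate ``exp(mu_s)`` and delta-method CI
    ``exp(mu_s +/- 1.96 se)``.  ``log_scale=False`` fits on the natural
    scale for sensitivity analysis.
    """
    if not obs:
        raise ValueError("no interval observations")
    state_ids = sorted({o.state_id for o in obs})
    sidx = {s: i for i, s in enumerate(state_ids)}
    lo = np.array([o.lo for o in obs])
    hi = np.array([o.hi for o in obs])
    idx = np.array([sidx[o.state_id] for o in obs])
    if log_scale:
        lo, hi = np.log(lo), np.log(hi)
    exact_mask = hi - lo < 1e-12

    # states whose every observation is the same zero-width point need no fit
    degenerate: dict[str, float] = {}
    for s, i in sidx.items():
        rows = idx == i
        if exact_mask[rows].all() and np.ptp(lo[rows]) < 1e-12:
            degenerate[s] = float(lo[rows][0])

    n_states = len(state_ids)
    mid = (lo + hi) / 2
    x0 = np.zeros(n_states + 1)
    for s, i in sidx.items():
        x0[i] = float(np.mean(mid[idx == i]))
    spread = float(np.std(mid)) if len(obs) > 1 else 0.5
    x0[-1] = np.log(max(spread, 0.25))

    free = np.array([s not in degenerate for s in state_ids])
    if free.any() or not degenerate:
        bounds = [(-30.0, 30.0)] * n_states + [(np.log(1e-4), np.log(50.0))]
        res = minimize(
            _interval_nll_grad,
            x0,
            args=(lo, hi, idx, n_states, exact_mask),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-15, "gtol": gtol},
        )
        theta = res.x
        nll, grad = _interval_nll_grad(theta, lo, hi, idx, n_states, exact_mask)
        # projected gradient: a parameter resting on its bound is converged
        # when the gradient points out of the feasible region
        lb = np.array([b[0] for b in bounds])
        ub = np.array([b[1] for b in bounds])
        grad = np.where(theta <= lb + 1e-9, np.minimum(grad, 0.0), grad)
        grad = np.where(theta >= ub - 1e-9, np.maximum(grad, 0.0), grad)
        free_grad = np.abs(np.concatenate([grad[:-1][free], grad[-1:]]))
        if free_grad.size and np.max(free_grad) > max(gtol * 100, 1e-5 * max(1.0, abs(nll))):
            raise RuntimeError(
                f"interval regression did not converge: |grad|_inf = {np.max(free_grad):.2e}"
            )
    else:
        theta = x0
        nll = _interval_nll_grad(theta, lo, hi, idx, n_states, exact_mask)[0]

    sigma = float(np.exp(theta[-1]))
    se = _delta_se(theta, lo, hi, idx, n_states, exact_mask, free)

    rows = []
    for s, i in sidx.items():
        n_s = int(np.sum(idx == i))
        if s in degenerate:
            point = np.exp(degenerate[s]) if log_scale else degenerate[s]
            rows.append((s, point, point, point, n_s, True))
            continue
        mu, e = theta[i], se[i]
        if not np.isfinite(e):
            e = np.nan
        if log_scale:
            rows.append((s, np.exp(mu), np.exp(mu - Z95 * e), np.exp(mu + Z95 * e), n_s, False))
        else:
            rows.append((s, mu, mu - Z95 * e, mu + Z95 * e, n_s, False))
    est = pd.DataFrame(
        rows, columns=["state_id", "phe_dw", "ci_lo", "ci_hi", "n", "degenerate"]
    ).set_index("state_id")
    return IntervalRegressionFit(estimates=est, sigma=sigma, loglik=-nll, log_scale=log_scale)


def _delta_se(theta, lo, hi, idx, n_states, exact_mask, free) -> np.ndarray:
    """Standard errors from a finite-difference observed information.

    Central differences of the analytic gradient; the information matrix is
    restricted to free (non-degenerate) parameters.
    """
    free_idx = np.concatenate([np.flatnonzero(free), [n_states]])
    k = len(free_idx)
    h = 1e-5
    info = np.zeros((k, k))
    for col, j in enumerate(free_idx):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = _interval_nll_grad(tp, lo, hi, idx, n_states, exact_mask)[1]
        gm = _interval_nll_grad(tm, lo, hi, idx, n_states, exact_mask)[1]
        info[:, col] = (gp - gm)[free_idx] / (2 * h)
    info = (info + info.T) / 2
    se = np.full(n_states, np.nan)
    try:
        cov = np.linalg.inv(info)
        d = np.sqrt(np.clip(np.diag(cov), 0, None))
        for col, j in enumerate(free_idx[:-1]):
            se[j] = d[col]
    except np.linalg.LinAlgError:
        pass
    return se


# ---------------------------------------------------------------------------
# Linkage to the paired-comparison probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageFit:
    intercept: float
    slope: float
    r_squared: float
    n_states: int

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("linkage regression needs >= 2 states")


def link_hybrid(
    pc_probs: pd.DataFrame | Mapping[str, float],
    phe_dws: Mapping[str, float],
    model_tag: str = "model2",
) -> tuple[list[DWEstimate], LinkageFit]:
    """Regress PHE weights on paired-comparison probabilities; predict all.

    OLS with intercept over the states common to both inputs; the hybrid
    disability weight of *every* state with a paired-comparison probability
    (PHE-observed or not) is the fitted value ``a + b * p_h``, with 95% CI
    from the prediction interval for the mean response.
    """
    if isinstance(pc_probs, pd.DataFrame):
        p_map = pc_probs["p"].to_dict()
    else:
        p_map = dict(pc_probs)
    common = sorted(set(p_map) & set(phe_dws))
    if len(common) < 2:
        raise ValueError(f"need >= 2 states common to both maps, got {len(common)}")
    x = np.array([p_map[s] for s in common])
    y = np.array([phe_dws[s] for s in common])
    if np.ptp(x) < 1e-12:
        raise np.linalg.LinAlgError(
            "all paired-comparison probabilities equal: linkage design is rank-deficient"
        )
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    a, b = float(ols.params[0]), float(ols.params[1])

    all_states = sorted(p_map)
    Xnew = sm.add_constant(np.array([p_map[s] for s in all_states]), has_constant="add")
    pred = ols.get_prediction(Xnew).summary_frame(alpha=0.05)
    out = [
        DWEstimate(
            s,
            float(pred["mean"].iloc[i]),
            float(pred["mean_ci_lower"].iloc[i]),
            float(pred["mean_ci_upper"].iloc[i]),
            model_tag,
        )
        for i, s in enumerate(all_states)
    ]
    link = LinkageFit(a, b, float(ols.rsquared), len(common))
    return out, link
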