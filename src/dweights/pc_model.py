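"""Paired-comparison probit model with dead/full-health anchoring (Model 1).

Choices of the healthier of two health states are modelled Thurstone-style:
``P(a judged healthier than b) = Phi(beta_a - beta_b)`` with one latent scale
value per state and 'being dead' as the reference category (``beta_dead = 0``).
The fitted scale values are turned into predicted probabilities
``p_h = Phi(beta_h)`` -- the probability state *h* is judged healthier than
'being dead' -- and anchored onto the disability-weight scale by the affine
map of the latent index ``z = Phi^{-1}(p)`` that sends the full-health
anchor to 0 and the dead anchor to 1:

    dw_h = (z_FH - z_h) / (z_FH - z_dead)

Confidence intervals are Wald intervals on beta pushed through the same
monotone maps, with the anchors treated as fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .survey_sim import PCResponse, StateRegistry

__all__ = [
    "DesignSpec",
    "ProbitFit",
    "DWEstimate",
    "HoldoutReport",
    "SeparationError",
    "AnchoringError",
    "UnidentifiedStateError",
    "build_design",
    "fit_probit",
    "predicted_probabilities",
    "anchor_to_dw",
    "estimate_model1",
    "split_and_validate",
]

Z95 = norm.ppf(0.975)


class SeparationError(RuntimeError):
    """A state is perfectly separated (always or never chosen healthier)."""


class AnchoringError(RuntimeError):
    """The anchor probabilities cannot orient the disability-weight scale."""


class UnidentifiedStateError(RuntimeError):
    """A requested state carries no information in the comparison data."""


@dataclass(frozen=True)
class DWEstimate:
    state_id: str
    dw: float
    ci_lo: float
    ci_hi: float
    model_tag: str

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.dw <= self.ci_hi or np.isnan(self.ci_lo)):
            raise ValueError(
                f"CI does not bracket the estimate for {self.state_id}: "
                f"{self.ci_lo}, {self.dw}, {self.ci_hi}"
            )


def estimates_to_frame(estimates: Iterable[DWEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.state_id, e.dw, e.ci_lo, e.ci_hi, e.model_tag) for e in estimates],
        columns=["state_id", "dw", "ci_lo", "ci_hi", "model_tag"],
    )


@dataclass
class DesignSpec:
    """Difference-coded design for the paired-comparison probit.

    Each response contributes a row with +1 on the column of the state shown
    first and -1 on the state shown second; the 'being dead' column is
    dropped (reference).  Rows are stored in aggregated form: ``a_idx``,
    ``b_idx`` index into ``columns`` (-1 = reference), ``y`` is the outcome
    and ``counts`` the multiplicity of identical (a, b, y) triples.
    """

    columns: list[str]
    a_idx: np.ndarray
    b_idx: np.ndarray
    y: np.ndarray
    counts: np.ndarray
    reference: str
    unidentifiable: list[str]
    n_obs: int

    @property
    def n_params(self) -> int:
        return len(self.columns)


def build_design(pc: Sequence[PCResponse], registry: StateRegistry) -> DesignSpec:
    """Difference-code paired choices against the 'being dead' reference.

    States never seen in any comparison are listed in ``unidentifiable`` and
    excluded from the parameter vector; the fit refuses to emit a weight for
    them downstream.
    """
    if not pc:
        raise ValueError("no paired-comparison responses")
    for r in pc:
        for s in (r.state_a, r.state_b):
            if s not in registry:
                raise KeyError(f"response references unknown state {s!r}")

    seen = {r.state_a for r in pc} | {r.state_b for r in pc}
    reference = registry.dead_id
    columns = [s for s in registry.state_ids if s != reference and s in seen]
    unidentifiable = [s for s in registry.state_ids if s != reference and s not in seen]
    col_of = {s: i for i, s in enumerate(columns)}
    col_of[reference] = -1

    a = np.array([col_of[r.state_a] for r in pc], dtype=np.int64)
    b = np.array([col_of[r.state_b] for r in pc], dtype=np.int64)
    y = np.array([r.chose_a_healthier for r in pc], dtype=np.int64)
    triples, counts = np.unique(np.column_stack([a, b, y]), axis=0, return_counts=True)
    return DesignSpec(
        columns=columns,
        a_idx=triples[:, 0],
        b_idx=triples[:, 1],
        y=triples[:, 2],
        counts=counts.astype(float),
        reference=reference,
        unidentifiable=unidentifiable,
        n_obs=len(pc),
    )


@dataclass
class ProbitFit:
    """Maximum-likelihood fit of the paired-comparison probit.

    ``beta`` maps state_id to its latent scale value (reference 'being dead'
    fixed at 0); ``cov`` is the observed-information covariance over the
    non-reference parameters in ``columns`` order.
    """

    beta: dict[str, float]
    cov: np.ndarray
    loglik: float
    n_obs: int
    columns: list[str]
    reference: str
    unidentifiable: list[str] = field(default_factory=list)
    n_iter: int = 0

    def se(self, state_id: str) -> float:
        if state_id == self.reference:
            return 0.0
        return float(np.sqrt(self.cov[self.columns.index(state_id), self.columns.index(state_id)]))


def _signed_diff(design: DesignSpec, beta: np.ndarray) -> np.ndarray:
    ba = np.where(design.a_idx >= 0, beta[design.a_idx], 0.0)
    bb = np.where(design.b_idx >= 0, beta[design.b_idx], 0.0)
    s = 2 * design.y - 1  # +1 if a chosen healthier
    return s * (ba - bb)


def _neg_loglik_grad(beta: np.ndarray, design: DesignSpec, ridge: float):
    s = 2 * design.y - 1
    z = _signed_diff(design, beta)
    nll = -float(np.sum(design.counts * log_ndtr(z)))
    lam = np.exp(norm.logpdf(z) - log_ndtr(z))  # inverse Mills ratio at z
    w = design.counts * s * lam
    grad = np.zeros_like(beta)
    np.add.at(grad, design.a_idx[design.a_idx >= 0], -w[design.a_idx >= 0])
    np.add.at(grad, design.b_idx[design.b_idx >= 0], w[design.b_idx >= 0])
    if ridge > 0:
        nll += 0.5 * ridge * float(beta @ beta)
        grad += ridge * beta
    return nll, grad


def _observed_information(beta: np.ndarray, design: DesignSpec, ridge: float) -> np.ndarray:
    z = _signed_diff(design, beta)
    lam = np.exp(norm.logpdf(z) - log_ndtr(z))
    w = design.counts * lam * (z + lam)  # -d2 logPhi / deta2, always > 0
    k = len(beta)
    info = np.zeros((k, k))
    for ai, bi, wi in zip(design.a_idx, design.b_idx, w):
        if ai >= 0:
            info[ai, ai] += wi
        if bi >= 0:
            info[bi, bi] += wi
        if ai >= 0 and bi >= 0:
            info[ai, bi] -= wi
            info[bi, ai] -= wi
    if ridge > 0:
        info += ridge * np.eye(k)
    return info


def _check_separation(design: DesignSpec) -> None:
    wins: dict[int, list[int]] = {}
    for ai, bi, yi, ci in zip(design.a_idx, design.b_idx, design.y, design.counts):
        for idx, won in ((ai, yi), (bi, 1 - yi)):
            if idx >= 0:
                wins.setdefault(int(idx), []).extend([int(won)] * int(ci))
    for idx, outcomes in wins.items():
        if all(outcomes) or not any(outcomes):
            kind = "always" if all(outcomes) else "never"
            raise SeparationError(
                f"state {design.columns[idx]!r} is {kind} chosen healthier in "
                "every comparison; its scale value is not finite "
                "(perfect separation -- consider a ridge penalty)"
            )


def fit_probit(
    design: DesignSpec,
    ridge: float = 0.0,
    gtol: float = 1e-8,
    maxiter: int = 500,
) -> ProbitFit:
    """Maximise the paired-comparison probit likelihood.

    Newton-type optimisation with analytic gradient; convergence is declared
    at gradient sup-norm ``gtol``.  Perfect separation of any state raises
    :class:`SeparationError` before optimisation unless a ridge penalty
    (``ridge > 0``) regularises the likelihood.  Covariance is the inverse
    observed information at the optimum.
    """
    if design.counts.size == 0:
        raise ValueError("empty design")
    if ridge == 0.0:
        _check_separation(design)
    k = design.n_params
    x0 = np.zeros(k)
    res = minimize(
        _neg_loglik_grad,
        x0,
        args=(design, ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol * 1e-2, "ftol": 1e-14},
    )
    beta = res.x
    # polish with Newton steps to the stated gradient tolerance
    for _ in range(50):
        nll, grad = _neg_loglik_grad(beta, design, ridge)
        if np.max(np.abs(grad)) < gtol:
            break
        info = _observed_information(beta, design, ridge)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        new = beta - step
        if _neg_loglik_grad(new, design, ridge)[0] > nll + 1e-9:
            # halve until improvement
            t = 0.5
            while t > 1e-6 and _neg_loglik_grad(beta - t * step, design, ridge)[0] > nll:
                t *= 0.5
            new = beta - t * step
        beta = new
    nll, grad = _neg_loglik_grad(beta, design, ridge)
    if np.max(np.abs(grad)) > max(gtol, 1e-6 * max(1.0, abs(nll))):
        raise RuntimeError(
            f"probit fit did not converge: |grad|_inf = {np.max(np.abs(grad)):.3e} "
            f"after {res.nit} L-BFGS iterations + Newton polish"
        )
    info = _observed_information(beta, design, ridge)
    cov = np.linalg.inv(info)
    beta_map = {design.reference: 0.0}
    beta_map.update({s: float(b) for s, b in zip(design.columns, beta)})
    return ProbitFit(
        beta=beta_map,
        cov=cov,
        loglik=-nll if ridge == 0 else -_neg_loglik_grad(beta, design, 0.0)[0],
        n_obs=design.n_obs,
        columns=design.columns,
        reference=design.reference,
        unidentifiable=list(design.unidentifiable),
        n_iter=int(res.nit),
    )


def predicted_probabilities(fit: ProbitFit) -> pd.DataFrame:
    """Per-state probability of being judged healthier than 'being dead'.

    ``p_h = Phi(beta_h)``; the 95% CI transforms the Wald interval of beta
    through Phi (monotone, so endpoints stay ordered).  The reference state
    appears with p = 0.5 and a degenerate interval.
    """
    rows = []
    for s, b in fit.beta.items():
        se = fit.se(s)
        rows.append(
            (s, float(ndtr(b)), float(ndtr(b - Z95 * se)), float(ndtr(b + Z95 * se)))
        )
    return pd.DataFrame(rows, columns=["state_id", "p", "p_lo", "p_hi"]).set_index("state_id")


def anchor_to_dw(
    probs: pd.DataFrame,
    registry: StateRegistry,
    model_tag: str = "model1",
) -> list[DWEstimate]:
    """Anchor predicted probabilities onto the 0-1 disability-weight scale.

    The probabilities are transformed back to the latent probit index
    ``z = Phi^{-1}(p)`` (equal to the fitted scale value beta) and anchored
    by the affine map on that scale fixing full health at 0 and dead at 1:

        dw_h = (z_FH - z_h) / (z_FH - z_dead)

    Anchoring on the latent scale rather than on the probability scale keeps
    the map affine in the Thurstone index, so a responder population whose
    choices follow ``Phi((d_b - d_a)/sigma)`` is recovered with dw equal to
    the latent weight in expectation for any discrimination ``sigma``; the
    probability scale would compress severe states whenever ``Phi``
    saturates.  The map is strictly decreasing in ``p``, so the CI endpoints
    swap roles.  Anchor states are emitted at exactly 0 and 1 with
    degenerate intervals; anchor uncertainty is not propagated.
    """
    for anchor in (registry.full_health_id, registry.dead_id):
        if anchor not in probs.index:
            raise AnchoringError(f"anchor state {anchor!r} missing from probabilities")
    z = probs[["p", "p_lo", "p_hi"]].apply(
        lambda col: norm.ppf(np.clip(col, 1e-12, 1 - 1e-12))
    )
    z_fh = float(z.loc[registry.full_health_id, "p"])
    z_dead = float(z.loc[registry.dead_id, "p"])
    if z_fh <= z_dead:
        raise AnchoringError(
            f"p(full health) = {float(probs.loc[registry.full_health_id, 'p']):.4f} <= "
            f"p(dead) = {float(probs.loc[registry.dead_id, 'p']):.4f}: "
            "the data cannot orient the disability-weight scale"
        )
    span = z_fh - z_dead

    out = []
    for sid, row in z.iterrows():
        if sid == registry.full_health_id:
            out.append(DWEstimate(str(sid), 0.0, 0.0, 0.0, model_tag))
            continue
        if sid == registry.dead_id:
            out.append(DWEstimate(str(sid), 1.0, 1.0, 1.0, model_tag))
            continue
        dw = (z_fh - row["p"]) / span
        lo = (z_fh - row["p_hi"]) / span  # decreasing map: upper p -> lower dw
        hi = (z_fh - row["p_lo"]) / span
        if not 0.0 <= dw <= 1.0:
            warnings.warn(
                f"disability weight for {sid} outside [0, 1]: {dw:.4f} "
                "(emitted unclipped)",
                RuntimeWarning,
                stacklevel=2,
            )
        out.append(DWEstimate(str(sid), float(dw), float(lo), float(hi), model_tag))
    return out


def estimate_model1(
    pc: Sequence[PCResponse],
    registry: StateRegistry,
    ridge: float = 0.0,
) -> tuple[list[DWEstimate], ProbitFit]:
    """Full paired-comparison-only pipeline: design, fit, predict, anchor."""
    design = build_design(pc, registry)
    fit = fit_probit(design, ridge=ridge)
    probs = predicted_probabilities(fit)
    return anchor_to_dw(probs, registry), fit


# ---------------------------------------------------------------------------
# Holdout fit assessment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoldoutReport:
    n_fit: int
    n_holdout: int
    mad: float
    n_pairs_compared: int
    n_pairs_excluded: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mad <= 1.0:
            raise ValueError(f"mean absolute difference outside [0, 1]: {self.mad}")


def split_and_validate(
    pc: Sequence[PCResponse],
    registry: StateRegistry,
    frac: float = 0.8,
    seed: int = 0,
    ridge: float = 0.0,
) -> HoldoutReport:
    """Fit on a random fraction of comparisons, score the rest.

    The split is at the individual-comparison level.  For every unordered
    pair present in the holdout, the observed frequency with which the
    lower-ordered state was chosen healthier is compared with the model's
    ``Phi(beta_a - beta_b)``; ``mad`` is the mean absolute difference over
    those pairs.  Holdout pairs touching a state unidentified in the fit
    fraction are excluded and counted.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be strictly between 0 and 1 (need a holdout)")
    rng = np.random.default_rng(seed)
    n = len(pc)
    n_fit = int(round(frac * n))
    if n_fit < 1 or n_fit >= n:
        raise ValueError(f"split of {n} responses at frac={frac} leaves no data on one side")
    perm = rng.permutation(n)
    fit_rows = [pc[i] for i in perm[:n_fit]]
    holdout = [pc[i] for i in perm[n_fit:]]

    fit = fit_probit(build_design(fit_rows, registry), ridge=ridge)
    known = set(fit.beta)

    tallies: dict[tuple[str, str], list[int]] = {}
    excluded = set()
    for r in holdout:
        key = tuple(sorted((r.state_a, r.state_b)))
        if r.state_a not in known or r.state_b not in known:
            excluded.add(key)
            continue
        first_chosen = r.chose_a_healthier if r.state_a == key[0] else not r.chose_a_healthier
        tallies.setdefault(key, []).append(int(first_chosen))

    diffs = []
    for (sa, sb), outcomes in tallies.items():
        obs = float(np.mean(outcomes))
        pred = float(ndtr(fit.beta[sa] - fit.beta[sb]))
        diffs.append(abs(obs - pred))
    if not diffs:
        raise ValueError("no scorable holdout pairs")
    return HoldoutReport(
        n_fit=len(fit_rows),
        n_holdout=len(holdout),
        mad=float(np.mean(diffs)),
        n_pairs_compared=len(diffs),
        n_pairs_excluded=len(excluded),
    )
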