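"""Empirical Bayesian LASSO solver for sparse high-dimensional regression.

The model is ``y = mu 1 + X beta + e`` with ``e ~ N(0, sigma0^2 I)``.  Each
coefficient carries a zero-mean Gaussian prior with its own variance
``sigma_i^2``; the variances carry independent exponential priors whose common
rate is itself Gamma(a, b) distributed.  Marginalizing the rate analytically
yields the component-wise variance prior

    p(sigma_i^2) = a b^a (b + sigma_i^2)^(-(a+1)),

so the only hyperparameters at run time are ``a`` (any value > -1.5; the
range (-1.5, 0] corresponds to an improper prior, and a = -1 recovers the
uniform-prior limit used by the relevance vector machine) and ``b > 0``.

Working with precisions ``alpha_i = 1 / sigma_i^2``, the log marginal
posterior L(theta) of (mu, sigma0^2, alpha) separates, for each component,
into a part that depends on alpha_i only through the *sparsity factor* s_i
and *quality factor* q_i (leave-one-out statistics of the candidate column
against the current model):

    l(alpha_i) = 0.5 [ log alpha_i - log(alpha_i + s_i) + q_i^2/(alpha_i + s_i) ]
                 - (a + 1) log(1 + 1/(alpha_i b)),

measured relative to the excluded state alpha_i = infinity.  For a > -1.5,
b > 0, l has a unique global maximum over (0, inf]; stationary points solve
the quadratic

    A t^2 + B t + C = 0,   A = b (s - q^2) + 2(a + 1),
                           B = b s^2 + s - q^2 + 4(a + 1) s,
                           C = (2a + 3) s^2,

and at a = -1 the maximizer collapses to the closed form s^2/(q^2 - s)
when q^2 > s (else infinity).

The greedy active-set algorithm maintains only the reduced model of columns
with finite precision.  All candidate statistics are computed through the
Woodbury identity, so only k_r x k_r systems are ever factorized, and are
updated by rank-one formulas after each add / delete / re-estimate action,
with periodic full recomputation to bound floating-point drift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .design import DesignMatrix

__all__ = [
    "Hyperparams",
    "FitConfig",
    "ModelState",
    "CandidateStats",
    "EBLassoResult",
    "alpha_star",
    "candidate_stats",
    "cinv_woodbury",
    "posterior_update",
    "log_marginal",
    "greedy_inner_loop",
    "update_nuisance",
    "fit",
]

logger = logging.getLogger(__name__)

ALPHA_CAP = 1e12  # precisions above this are treated as exclusion


@dataclass(frozen=True)
class Hyperparams:
    """Prior parameters of the Gamma level: shape-like ``a`` and inverse
    scale ``b``.  ``a = -1`` selects the uniform-prior (RVM) limit, where
    ``b`` drops out of the objective."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a > -1.5:
            raise ValueError(f"hyperparameter a must exceed -1.5 (got {self.a})")
        if not self.b > 0:
            raise ValueError(f"hyperparameter b must be positive (got {self.b})")


@dataclass
class FitConfig:
    """Convergence and bookkeeping knobs for the solver.

    tol_logl: relative change of L(theta) regarded as converged.
    tol_param: relative parameter-change tolerance (alpha, mu, sigma0^2).
    sigma0_init_frac: initial sigma0^2 as a fraction of var(y).
    recompute_every: full Sigma/S/Q recomputation every this many greedy
        actions, bounding drift of the rank-one fast path.
    max_cycles: add/delete oscillation guard per column.
    """

    tol_logl: float = 1e-6
    tol_param: float = 1e-4
    max_inner: int = 1000
    max_outer: int = 50
    standardize: bool = True  # fit on unit-norm columns so the prior acts on a common scale
    sigma0_init_frac: float = 0.1
    alpha_max: float = ALPHA_CAP
    recompute_every: int = 100
    max_cycles: int = 10
    max_active_frac: float = 0.9  # cap k_r at this fraction of n (reduced model needs k_r < n)
    nuisance_max_iter: int = 100
    nuisance_tol: float = 1e-10
    significance_level: float = 0.05


@dataclass
class CandidateStats:
    """Sparsity/quality factors for all k candidates.

    ``S``/``Q`` include the candidate's own contribution to the model
    covariance; ``s``/``q`` are the leave-one-out versions that drive the
    precision update (equal to S/Q for columns outside the active set).
    """

    S: np.ndarray
    Q: np.ndarray
    s: np.ndarray
    q: np.ndarray


@dataclass
class ModelState:
    """Reduced model: active columns, their precisions and posterior."""

    active: list[int]
    alpha: np.ndarray  # (k_r,)
    mu: float
    sigma0_sq: float
    Sigma: np.ndarray  # (k_r, k_r) posterior covariance
    u: np.ndarray  # (k_r,) posterior means
    S: np.ndarray  # (k,) cached sparsity factors
    Q: np.ndarray  # (k,) cached quality factors
    Xr: np.ndarray  # (n, k_r) cached active columns
    logL: float = -np.inf

    @property
    def k_r(self) -> int:
        return len(self.active)

    def active_mask(self, k: int) -> np.ndarray:
        m = np.zeros(k, dtype=bool)
        m[self.active] = True
        return m


def _delta_l(alpha, s, q2, hyper: Hyperparams):
    """Gain in L from keeping a component at precision ``alpha`` instead of
    excluding it, given its leave-one-out factors."""
    alpha = np.asarray(alpha, dtype=float)
    r = alpha + s
    with np.errstate(divide="ignore", invalid="ignore"):
        val = 0.5 * (np.log(alpha) - np.log(r) + q2 / r)
        if hyper.a != -1.0:
            val = val - (hyper.a + 1.0) * np.log1p(1.0 / (alpha * hyper.b))
    return np.where(np.isinf(alpha), 0.0, val)


def alpha_star(s, q, hyper: Hyperparams, alpha_max: float = ALPHA_CAP):
    """Optimal precision per candidate: the unique global maximizer of the
    component objective over (0, inf].  ``inf`` signals exclusion.

    Vectorized over ``s`` (sparsity factors, must be > 0 for live columns)
    and ``q`` (quality factors).  Non-positive ``s`` (zero-variance columns)
    maps to ``inf``.
    """
    s = np.asarray(s, dtype=float)
    q = np.asarray(q, dtype=float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    q2 = np.atleast_1d(q).astype(float) ** 2
    out = np.full(s.shape, np.inf)
    live = (s > 0) & np.isfinite(s) & np.isfinite(q2)

    if hyper.a == -1.0:
        m = live & (q2 > s)
        out[m] = s[m] ** 2 / (q2[m] - s[m])
    else:
        a1 = hyper.a + 1.0
        b = hyper.b
        A = b * (s - q2) + 2.0 * a1
        B = b * s * s + s - q2 + 4.0 * a1 * s
        C = (2.0 * hyper.a + 3.0) * s * s
        best_dl = np.zeros(s.shape)  # exclusion baseline
        with np.errstate(divide="ignore", invalid="ignore"):
            disc = B * B - 4.0 * A * C
            sq = np.sqrt(np.maximum(disc, 0.0))
            quad = live & (np.abs(A) > 1e-300) & (disc >= 0)
            lin = live & ~ (np.abs(A) > 1e-300)
            for root in ((-B + sq) / (2.0 * A), (-B - sq) / (2.0 * A)):
                cand = quad & (root > 0) & np.isfinite(root)
                if cand.any():
                    dl = _delta_l(root[cand], s[cand], q2[cand], hyper)
                    take = dl > best_dl[cand]
                    idx = np.flatnonzero(cand)[take]
                    out[idx] = root[cand][take]
                    best_dl[idx] = dl[take]
            root = -C / B
            cand = lin & (root > 0) & np.isfinite(root)
            if cand.any():
                dl = _delta_l(root[cand], s[cand], q2[cand], hyper)
                take = dl > best_dl[cand]
                idx = np.flatnonzero(cand)[take]
                out[idx] = root[cand][take]
    out[out > alpha_max] = np.inf
    return float(out[0]) if scalar else out


def _posterior_factors(Xr: np.ndarray, alpha: np.ndarray, sigma0_sq: float):
    """Cholesky of P = diag(alpha) + Xr^T Xr / sigma0^2 (the posterior
    precision of the active effects)."""
    P = (Xr.T @ Xr) / sigma0_sq
    P[np.diag_indices_from(P)] += alpha
    try:
        return cho_factor(P, lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"posterior precision factorization failed (k_r={len(alpha)}); "
            f"the active-set system is numerically singular"
        ) from err


def posterior_update(state: ModelState, design: DesignMatrix, y: np.ndarray) -> ModelState:
    """Recompute the Gaussian posterior (Sigma, u) of the active effects.

    Sigma = (diag(alpha) + Xr^T Xr / sigma0^2)^-1 and
    u = Sigma Xr^T (y - mu 1) / sigma0^2 — the ridge-type generalized
    least-squares solution with per-coordinate penalties alpha.
    """
    k_r = state.k_r
    if k_r == 0:
        state.Sigma = np.empty((0, 0))
        state.u = np.empty(0)
        return state
    c = _posterior_factors(state.Xr, state.alpha, state.sigma0_sq)
    state.Sigma = cho_solve(c, np.eye(k_r))
    yh = y - state.mu
    state.u = cho_solve(c, state.Xr.T @ yh / state.sigma0_sq)
    return state


def cinv_woodbury(state: ModelState, design: DesignMatrix | None = None):
    """Operator applying C^-1 to a vector, where
    C = sigma0^2 I + Xr diag(1/alpha) Xr^T is the marginal covariance of y.

    Uses the Woodbury identity: C^-1 v = (v - Xr Sigma Xr^T v / sigma0^2)
    / sigma0^2, so only the k_r x k_r posterior system is ever involved.
    """
    sig = state.sigma0_sq
    if sig <= 0:
        raise ValueError(f"sigma0_sq must be positive (got {sig})")
    if state.k_r == 0:
        return lambda v: np.asarray(v, dtype=float) / sig
    Xr, Sigma = state.Xr, state.Sigma

    def apply(v):
        v = np.asarray(v, dtype=float)
        return (v - Xr @ (Sigma @ (Xr.T @ v)) / sig) / sig

    return apply


def candidate_stats(design: DesignMatrix, y: np.ndarray, state: ModelState) -> CandidateStats:
    """Full refresh of the sparsity/quality factors for all k candidates.

    S_i = x_i^T C^-1 x_i and Q_i = x_i^T C^-1 (y - mu 1), computed through
    the Woodbury form (cost O(n k k_r); the n x n matrix C is never formed).
    Leave-one-out versions for active columns: s_i = alpha_i S_i /
    (alpha_i - S_i), q_i = alpha_i Q_i / (alpha_i - S_i).
    """
    if state.sigma0_sq <= 0:
        raise ValueError(f"sigma0_sq must be positive (got {state.sigma0_sq})")
    sig = state.sigma0_sq
    yh = y - state.mu
    xty = design.matvec_T(yh)
    norms = design.norms_sq
    if state.k_r == 0:
        S = norms / sig
        Q = xty / sig
    else:
        Xr = state.Xr
        G = np.column_stack([design.matvec_T(Xr[:, t]) for t in range(state.k_r)])  # X^T Xr
        S = norms / sig - np.einsum("ij,ij->i", G @ state.Sigma, G) / sig**2
        Q = xty / sig - (G @ (state.Sigma @ (Xr.T @ yh))) / sig**2
    s, q = _loo_stats(S, Q, state, design.k)
    return CandidateStats(S=S, Q=Q, s=s, q=q)


def _loo_stats(S, Q, state: ModelState, k: int):
    """Leave-one-out factors from the full ones (identity off the active set)."""
    s = S.copy()
    q = Q.copy()
    if state.k_r:
        idx = np.asarray(state.active)
        denom = state.alpha - S[idx]
        # denom <= 0 indicates numerical drift; clip to keep the column's
        # statistics finite (a full recompute follows on the next refresh)
        denom = np.maximum(denom, 1e-12)
        s[idx] = state.alpha * S[idx] / denom
        q[idx] = state.alpha * Q[idx] / denom
    return s, q


def log_marginal(state: ModelState, design: DesignMatrix, y: np.ndarray, hyper: Hyperparams) -> float:
    """L(theta): Gaussian log-density of y under N(mu 1, C) plus the active
    components' prior terms (normalized so an excluded component contributes
    zero; additive constants from the improper priors are dropped).

    Evaluated through the determinant lemma / Woodbury route, never forming C.
    """
    n = len(y)
    yh = y - state.mu
    sig = state.sigma0_sq
    if state.k_r == 0:
        logdet = n * np.log(sig)
        quad = yh @ yh / sig
    else:
        c = _posterior_factors(state.Xr, state.alpha, sig)
        logdet = n * np.log(sig) - np.sum(np.log(state.alpha)) + 2.0 * np.sum(np.log(np.diag(c[0])))
        u = cho_solve(c, state.Xr.T @ yh / sig)
        quad = (yh @ yh - yh @ (state.Xr @ u)) / sig
    L = -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)
    if hyper.a != -1.0 and state.k_r:
        L -= (hyper.a + 1.0) * np.sum(np.log1p(1.0 / (state.alpha * hyper.b)))
    return float(L)


# ---------------------------------------------------------------------------
# greedy active-set machinery


def _action_deltas(state: ModelState, stats_s, stats_q, astar, hyper, k):
    """Predicted L-gain of the best action available for each candidate."""
    q2 = stats_q**2
    act = state.active_mask(k)
    finite = np.isfinite(astar)
    dl = np.full(k, -np.inf)
    # additions
    m = ~act & finite
    if m.any():
        dl[m] = _delta_l(astar[m], stats_s[m], q2[m], hyper)
    if state.k_r:
        idx = np.asarray(state.active)
        a_old = state.alpha
        dl_old = _delta_l(a_old, stats_s[idx], q2[idx], hyper)
        a_new = astar[idx]
        fin = np.isfinite(a_new)
        dl_new = np.where(fin, _delta_l(np.where(fin, a_new, 1.0), stats_s[idx], q2[idx], hyper), 0.0)
        dl[idx] = dl_new - dl_old  # re-estimate if finite, delete if inf
    return dl


def _apply_action(state: ModelState, design: DesignMatrix, j: int, alpha_new: float) -> str:
    """Add / delete / re-estimate column j, with rank-one updates of
    Sigma, u and the cached S/Q of every candidate."""
    sig = state.sigma0_sq
    act = j in state.active
    x_j = state.Xr[:, state.active.index(j)] if act else design.columns([j])[:, 0]
    # c_i = x_i^T C^-1 x_j for all i (one lazy matvec)
    w = cinv_woodbury(state)(x_j)
    c = design.matvec_T(w)
    S_j, Q_j = state.S[j], state.Q[j]
    alpha_old = state.alpha[state.active.index(j)] if act else np.inf
    d_prec = (0.0 if np.isinf(alpha_new) else 1.0 / alpha_new) - (0.0 if np.isinf(alpha_old) else 1.0 / alpha_old)
    rho = d_prec / (1.0 + d_prec * S_j)
    state.S = state.S - rho * c * c
    state.Q = state.Q - rho * Q_j * c

    if not act:  # addition
        sjj = 1.0 / (alpha_new + S_j)
        v = state.Sigma @ (state.Xr.T @ x_j) / sig if state.k_r else np.empty(0)
        u_j = sjj * Q_j
        k_r = state.k_r
        Sigma = np.empty((k_r + 1, k_r + 1))
        Sigma[:k_r, :k_r] = state.Sigma + sjj * np.outer(v, v)
        Sigma[:k_r, k_r] = -sjj * v
        Sigma[k_r, :k_r] = -sjj * v
        Sigma[k_r, k_r] = sjj
        state.Sigma = Sigma
        state.u = np.append(state.u - u_j * v, u_j)
        state.Xr = np.column_stack([state.Xr, x_j]) if k_r else x_j[:, None]
        state.active.append(j)
        state.alpha = np.append(state.alpha, alpha_new)
        return "add"

    l = state.active.index(j)
    Sig_l = state.Sigma[:, l]
    if np.isinf(alpha_new):  # deletion
        Sig_ll = state.Sigma[l, l]
        state.Sigma = state.Sigma - np.outer(Sig_l, Sig_l) / Sig_ll
        state.u = state.u - state.u[l] * Sig_l / Sig_ll
        keep = [t for t in range(state.k_r) if t != l]
        state.Sigma = state.Sigma[np.ix_(keep, keep)]
        state.u = state.u[keep]
        state.Xr = state.Xr[:, keep]
        state.alpha = state.alpha[keep]
        state.active.pop(l)
        return "delete"

    d_alpha = alpha_new - state.alpha[l]  # re-estimate
    kap = d_alpha / (1.0 + d_alpha * state.Sigma[l, l])
    state.Sigma = state.Sigma - kap * np.outer(Sig_l, Sig_l)
    state.u = state.u - kap * state.u[l] * Sig_l
    state.alpha = state.alpha.copy()
    state.alpha[l] = alpha_new
    return "reestimate"


def _full_refresh(state: ModelState, design: DesignMatrix, y: np.ndarray, hyper: Hyperparams) -> None:
    posterior_update(state, design, y)
    st = candidate_stats(design, y, state)
    state.S, state.Q = st.S, st.Q
    state.logL = log_marginal(state, design, y, hyper)


def greedy_inner_loop(
    state: ModelState,
    design: DesignMatrix,
    y: np.ndarray,
    hyper: Hyperparams,
    config: FitConfig | None = None,
    log: list | None = None,
) -> ModelState:
    """One inner loop of the greedy algorithm with mu and sigma0^2 fixed.

    Repeatedly computes the optimal precision of every candidate, picks the
    action (add / delete / re-estimate) with the largest predicted gain in
    L(theta), and applies it with rank-one updates.  Terminates when no add
    or delete is available, the best gain is below tolerance, and precision
    changes are below tolerance (all three simultaneously).
    """
    config = config or FitConfig()
    k = design.k
    const = design.constant_mask
    cycle_count: dict[int, int] = {}
    barred: set[int] = set()
    since_refresh = 0
    max_active = max(1, int(config.max_active_frac * design.n))

    for _ in range(config.max_inner):
        s, q = _loo_stats(state.S, state.Q, state, k)
        astar = alpha_star(s, q, hyper, config.alpha_max)
        astar[const] = np.inf
        if barred:
            bar = np.fromiter(barred, dtype=int)
            inact = ~state.active_mask(k)
            astar[bar[inact[bar]]] = np.inf  # bar re-addition only
        act_mask = state.active_mask(k)
        if state.k_r >= max_active:
            astar[~act_mask] = np.inf  # saturation guard: no further additions
        dl = _action_deltas(state, s, q, astar, hyper, k)
        j = int(np.argmax(dl))
        best = dl[j]

        adds_avail = bool((~act_mask & np.isfinite(astar)).any())
        dels_avail = bool((act_mask & ~np.isfinite(astar)).any())
        if state.k_r:
            idx = np.asarray(state.active)
            fin = np.isfinite(astar[idx])
            rel_da = np.abs(astar[idx][fin] - state.alpha[fin]) / np.maximum(state.alpha[fin], 1e-300)
            max_da = float(rel_da.max()) if fin.any() else 0.0
        else:
            max_da = 0.0
        tolL = config.tol_logl * max(1.0, abs(state.logL))
        if (not adds_avail) and (not dels_avail) and best <= tolL and max_da <= config.tol_param:
            break
        if not np.isfinite(best) or best <= 0:
            break

        was_active = j in state.active
        action = _apply_action(state, design, j, astar[j])
        state.logL += best
        if log is not None:
            log.append(
                {
                    "action": action,
                    "column": j,
                    "delta_logL": float(best),
                    "logL": float(state.logL),
                    "sigma0_sq": float(state.sigma0_sq),
                    "k_r": state.k_r,
                }
            )
        if action in ("add", "delete"):
            cycle_count[j] = cycle_count.get(j, 0) + 1
            if cycle_count[j] > 2 * config.max_cycles:
                warnings.warn(
                    f"column {j} oscillated between add and delete more than "
                    f"{config.max_cycles} times; barring it for this inner loop",
                    RuntimeWarning,
                )
                barred.add(j)
        since_refresh += 1
        if since_refresh >= config.recompute_every:
            _full_refresh(state, design, y, hyper)
            since_refresh = 0
    return state


def update_nuisance(
    state: ModelState,
    design: DesignMatrix,
    y: np.ndarray,
    hyper: Hyperparams,
    config: FitConfig | None = None,
) -> ModelState:
    """Update the population mean and residual variance at fixed alpha.

    mu solves 1^T (y - mu 1 - Xr u(mu)) = 0 exactly (u is affine in mu), and
    sigma0^2 iterates its stationary-point form
    ||y - mu 1 - Xr u||^2 / (n - k_r + sum_i alpha_i Sigma_ii) with the
    posterior refreshed, until self-consistency — so both returned values are
    stationary points of L in their coordinate.  A safeguard falls back to
    bounded 1-D maximization of L over sigma0^2 if a pass decreases L.
    """
    config = config or FitConfig()
    n = len(y)
    if state.k_r == 0:
        state.mu = float(np.mean(y))
        state.sigma0_sq = float(np.mean((y - state.mu) ** 2))
        posterior_update(state, design, y)
        return state

    L_before = log_marginal(state, design, y, hyper)
    mu0, sig0, Sigma0, u0 = state.mu, state.sigma0_sq, state.Sigma, state.u
    Xr = state.Xr
    for _ in range(config.nuisance_max_iter):
        mu_prev, sig_prev = state.mu, state.sigma0_sq
        # residual variance (denominator n - sum_i gamma_i must stay positive)
        resid = y - state.mu - Xr @ state.u
        denom = n - state.k_r + float(np.sum(state.alpha * np.diag(state.Sigma)))
        if denom <= 0:
            raise FloatingPointError(
                f"residual-variance denominator {denom:.3g} <= 0 (n={n}, k_r={state.k_r}); inconsistent model state"
            )
        state.sigma0_sq = float(resid @ resid / denom)
        posterior_update(state, design, y)
        # exact coordinate maximizer for mu: mu = mean(y - Xr u(mu))
        c = _posterior_factors(Xr, state.alpha, state.sigma0_sq)
        u_y = cho_solve(c, Xr.T @ y / state.sigma0_sq)
        h = cho_solve(c, Xr.sum(axis=0) / state.sigma0_sq)
        g = float(np.mean(Xr @ h))
        state.mu = float((np.mean(y) - np.mean(Xr @ u_y)) / (1.0 - g))
        state.u = u_y - state.mu * h
        if abs(state.mu - mu_prev) <= config.nuisance_tol * (1 + abs(mu_prev)) and abs(
            state.sigma0_sq - sig_prev
        ) <= config.nuisance_tol * (1 + sig_prev):
            break

    if log_marginal(state, design, y, hyper) < L_before - 1e-9 * max(1.0, abs(L_before)):
        # fixed point overshot: maximize L over sigma0^2 directly (monotone
        # by construction), keeping the exact mu solve
        state.mu, state.sigma0_sq, state.Sigma, state.u = mu0, sig0, Sigma0, u0

        def neg_l(log_sig):
            state.sigma0_sq = float(np.exp(log_sig))
            posterior_update(state, design, y)
            return -log_marginal(state, design, y, hyper)

        res = minimize_scalar(neg_l, bounds=(np.log(sig0) - 5, np.log(sig0) + 5), method="bounded")
        state.sigma0_sq = float(np.exp(res.x))
        posterior_update(state, design, y)
    return state


@dataclass
class EBLassoResult:
    """Outcome of a fit: final reduced model plus the iteration log."""

    state: ModelState
    design: DesignMatrix
    y: np.ndarray
    hyper: Hyperparams
    config: FitConfig
    log: list = field(default_factory=list)
    n_outer: int = 0
    converged: bool = False

    @property
    def active(self) -> list[int]:
        return self.state.active

    @property
    def mu(self) -> float:
        return self.state.mu

    @property
    def sigma0_sq(self) -> float:
        return self.state.sigma0_sq

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """(active column ids, posterior-mean effects), in descriptor order."""
        order = np.argsort(self.state.active)
        return np.asarray(self.state.active)[order], self.state.u[order]

    def predict(self, design: DesignMatrix | None = None) -> np.ndarray:
        design = design or self.design
        if not self.state.k_r:
            return np.full(design.n, self.state.mu)
        X = design.columns(np.asarray(self.state.active))
        return self.state.mu + X @ self.state.u


def _to_raw_units(state: ModelState, raw_design: DesignMatrix, work_design) -> None:
    """Map a state fitted on a unit-norm view back to original column units."""
    scales = getattr(work_design, "scales", None)
    if scales is None:
        return
    state.S = state.S * scales**2
    state.Q = state.Q * scales
    if state.k_r:
        c = scales[np.asarray(state.active)]
        state.u = state.u / c
        state.Sigma = state.Sigma / np.outer(c, c)
        state.alpha = state.alpha * c**2
        state.Xr = raw_design.columns(np.asarray(state.active))


def _init_state(y: np.ndarray, design: DesignMatrix, config: FitConfig) -> ModelState:
    mu = float(np.mean(y))
    var_y = float(np.var(y))
    sig = config.sigma0_init_frac * var_y if var_y > 0 else 1e-6
    state = ModelState(
        active=[],
        alpha=np.empty(0),
        mu=mu,
        sigma0_sq=sig,
        Sigma=np.empty((0, 0)),
        u=np.empty(0),
        S=np.empty(0),
        Q=np.empty(0),
        Xr=np.empty((len(y), 0)),
    )
    st = candidate_stats(design, y, state)
    state.S, state.Q = st.S, st.Q
    return state


def fit(
    y: np.ndarray,
    design: DesignMatrix,
    hyper: Hyperparams,
    config: FitConfig | None = None,
) -> EBLassoResult:
    """Run the full greedy empirical-Bayes fit.

    Initialization: mu = mean(y); sigma0^2 a small fraction of var(y); the
    initial model holds the single candidate maximizing the component
    objective in its uniform-prior (a = -1) form.  Outer iterations then
    alternate the greedy inner loop with nuisance updates until both the
    change of L and the total parameter change fall below tolerance.

    By default columns are standardized to unit Euclidean norm internally,
    so that ``b`` refers to effect variances on a common column scale;
    estimates and the returned state are in the original column units.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n,):
        raise ValueError(f"response length {y.shape} does not match design rows ({design.n})")
    config = config or FitConfig()
    raw_design = design
    if config.standardize:
        design = design.unit_norm_view() if hasattr(design, "unit_norm_view") else design
    log: list = []
    state = _init_state(y, design, config)
    rvm = Hyperparams(a=-1.0, b=1.0)

    # initial single-effect model, chosen at a = -1
    a0 = alpha_star(state.S, state.Q, rvm, config.alpha_max)
    a0[design.constant_mask] = np.inf
    finite = np.isfinite(a0)
    if not finite.any():
        # no candidate carries signal: intercept-only model
        update_nuisance(state, design, y, hyper, config)
        state.logL = log_marginal(state, design, y, hyper)
        _to_raw_units(state, raw_design, design)
        return EBLassoResult(state, raw_design, y, hyper, config, log, n_outer=0, converged=True)
    dl0 = np.full(design.k, -np.inf)
    dl0[finite] = _delta_l(a0[finite], state.S[finite], state.Q[finite] ** 2, rvm)
    j0 = int(np.argmax(dl0))
    state.logL = log_marginal(state, design, y, hyper)
    _apply_action(state, design, j0, float(a0[j0]))
    _full_refresh(state, design, y, hyper)
    log.append(
        {
            "action": "add",
            "column": j0,
            "delta_logL": np.nan,
            "logL": float(state.logL),
            "sigma0_sq": float(state.sigma0_sq),
            "k_r": 1,
        }
    )

    converged = False
    outer = 0
    for outer in range(1, config.max_outer + 1):
        state = greedy_inner_loop(state, design, y, hyper, config, log)
        prev_L = state.logL
        prev = (state.mu, state.sigma0_sq, state.alpha.copy(), list(state.active))
        update_nuisance(state, design, y, hyper, config)
        _full_refresh(state, design, y, hyper)
        log.append(
            {
                "action": "nuisance",
                "column": -1,
                "delta_logL": float(state.logL - prev_L),
                "logL": float(state.logL),
                "sigma0_sq": float(state.sigma0_sq),
                "k_r": state.k_r,
            }
        )
        dL = abs(state.logL - prev_L)
        mu0, sig0, alpha0, active0 = prev
        same_active = active0 == state.active
        d_param = abs(state.mu - mu0) / (1 + abs(mu0)) + abs(state.sigma0_sq - sig0) / (1 + sig0)
        if same_active and state.k_r:
            d_param += float(np.sum(np.abs(state.alpha - alpha0) / (1 + alpha0)))
        if same_active and dL <= config.tol_logl * max(1.0, abs(state.logL)) and d_param <= config.tol_param:
            converged = True
            break
    if not converged:
        logger.warning("fit reached max_outer=%d without meeting the global criterion", config.max_outer)
    _to_raw_units(state, raw_design, design)
    return EBLassoResult(state, raw_design, y, hyper, config, log, n_outer=outer, converged=converged)
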