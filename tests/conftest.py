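import numpy as np
import pytest

from eblasso.core import Hyperparams, ModelState, _delta_l
from eblasso.design import DesignMatrix, EffectDescriptor, _DenseBlock


def dense_design(cols: np.ndarray, kinds: str = "env") -> DesignMatrix:
    """Wrap a plain array as a DesignMatrix with generic descriptors."""
    cols = np.asarray(cols, dtype=float)
    descr = [EffectDescriptor(kinds, i) for i in range(cols.shape[1])]
    return DesignMatrix([_DenseBlock(cols, descr)], n=cols.shape[0])


def empty_state(y: np.ndarray, mu: float, sigma0_sq: float) -> ModelState:
    n = len(y)
    return ModelState(
        active=[],
        alpha=np.empty(0),
        mu=mu,
        sigma0_sq=sigma0_sq,
        Sigma=np.empty((0, 0)),
        u=np.empty(0),
        S=np.empty(0),
        Q=np.empty(0),
        Xr=np.empty((n, 0)),
    )


def explicit_C(Xr: np.ndarray, alpha: np.ndarray, sigma0_sq: float, n: int) -> np.ndarray:
    """Dense marginal covariance C = sigma0^2 I + Xr diag(1/alpha) Xr^T."""
    C = sigma0_sq * np.eye(n)
    for t in range(Xr.shape[1]):
        C += np.outer(Xr[:, t], Xr[:, t]) / alpha[t]
    return C


def numeric_alpha_star(s: float, q: float, hyper: Hyperparams) -> float:
    """Independent bounded 1-D maximizer of the component objective."""
    from scipy.optimize import minimize_scalar

    q2 = q * q
    grid = np.logspace(-10, 13, 4000)
    vals = _delta_l(grid, s, q2, hyper)
    i = int(np.argmax(vals))
    if vals[i] <= 0:
        return np.inf
    lo = np.log(grid[max(i - 1, 0)])
    hi = np.log(grid[min(i + 1, len(grid) - 1)])
    res = minimize_scalar(lambda t: -_delta_l(np.exp(t), s, q2, hyper), bounds=(lo, hi), method="bounded", options={"xatol": 1e-14})
    a = float(np.exp(res.x))
    return a if _delta_l(a, s, q2, hyper) > 0 else np.inf


def assert_monotone_log(result, rel_tol: float = 1e-8) -> None:
    """L(theta) must be non-decreasing along the whole iteration log."""
    Ls = np.array([rec["logL"] for rec in result.log])
    if len(Ls) < 2:
        return
    drops = np.diff(Ls)
    floor = -rel_tol * np.maximum(1.0, np.abs(Ls[:-1]))
    assert (drops >= floor).all(), f"L decreased by {drops.min()} at step {int(np.argmin(drops))}"


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
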