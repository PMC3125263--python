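"""Significance tests, variance decomposition and heritability summaries.

Each retained effect is reported with its posterior mean (the empirical
Bayes estimate beta_hat_j), posterior standard deviation (used as the
standard error), a t statistic t_j = beta_hat_j / se_j with n - k_r degrees
of freedom, and a two-sided p value.  No multiple-testing correction is
applied by default (a Bonferroni option exists).

The total phenotypic variance decomposes as

    V_P = sum_j sum_j' beta_j beta_j' cov(x_j, x_j') + sigma0^2,

with covariances estimated from the realized design columns; the double sum
alone is the genetic variance, and the per-effect heritability is
h2_j = beta_j^2 var(x_j) / V_P (covariance terms ignored, as is standard for
this approximation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import DesignMatrix, EffectDescriptor
from .core import EBLassoResult

__all__ = [
    "effect_tests",
    "effect_report",
    "variance_decomposition",
    "heritability",
    "score_detections",
]


def effect_tests(
    result: EBLassoResult,
    alpha_level: float = 0.05,
    df: int | None = None,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Posterior t tests of the retained effects.

    Rows are sorted by descriptor (design-column) order.  ``df`` defaults to
    n - k_r; Bonferroni correction is off by default.
    """
    state = result.state
    n = len(result.y)
    k_r = state.k_r
    if df is None:
        df = max(n - k_r, 1)
    rows = []
    for loc in np.argsort(state.active):
        col = state.active[loc]
        var = state.Sigma[loc, loc]
        if var <= 0:
            raise ValueError(f"non-positive posterior variance for column {col}")
        se = float(np.sqrt(var))
        est = float(state.u[loc])
        t = est / se
        p = float(2.0 * sps.t.sf(abs(t), df))
        d = result.design.descriptor(col)
        rows.append(
            {
                "column": int(col),
                "kind": d.kind,
                "i": -1 if d.i is None else d.i + 1,
                "j": -1 if d.j is None else d.j + 1,
                "label": d.label(),
                "estimate": est,
                "se": se,
                "t": t,
                "p": p,
            }
        )
    df_out = pd.DataFrame(
        rows, columns=["column", "kind", "i", "j", "label", "estimate", "se", "t", "p"]
    )
    thr = alpha_level / max(len(rows), 1) if bonferroni else alpha_level
    df_out["significant"] = df_out["p"] < thr if len(rows) else pd.Series(dtype=bool)
    return df_out


def variance_decomposition(
    beta: np.ndarray,
    design: DesignMatrix,
    col_ids: np.ndarray,
    sigma0_sq: float,
) -> tuple[float, float]:
    """(V_P, genetic variance) from realized column covariances.

    V_G = beta^T Cov_hat beta over the referenced columns; V_P = V_G +
    sigma0^2.
    """
    beta = np.asarray(beta, dtype=float)
    col_ids = np.asarray(col_ids, dtype=int)
    if beta.size == 0:
        return float(sigma0_sq), 0.0
    X = design.columns(col_ids)
    C = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    v_g = float(beta @ C @ beta)
    return v_g + float(sigma0_sq), v_g


def heritability(
    beta: np.ndarray,
    design: DesignMatrix,
    col_ids: np.ndarray,
    V_P: float,
) -> np.ndarray:
    """Per-effect h2_j = beta_j^2 var(x_j) / V_P with realized variances."""
    if V_P <= 0:
        raise ValueError("V_P must be positive")
    beta = np.asarray(beta, dtype=float)
    col_ids = np.asarray(col_ids, dtype=int)
    if beta.size == 0:
        return np.empty(0)
    X = design.columns(col_ids)
    var = X.var(axis=0, ddof=1)
    return beta**2 * var / V_P


def effect_report(result: EBLassoResult, alpha_level: float = 0.05, **kwargs) -> pd.DataFrame:
    """Effect table with t tests plus per-effect heritability; the global
    decomposition is attached in ``DataFrame.attrs``."""
    tab = effect_tests(result, alpha_level=alpha_level, **kwargs)
    if len(tab):
        cols = tab["column"].to_numpy()
        beta = tab["estimate"].to_numpy()
        v_p, v_g = variance_decomposition(beta, result.design, cols, result.sigma0_sq)
        tab["h2"] = heritability(beta, result.design, cols, v_p)
    else:
        v_p, v_g = float(result.sigma0_sq), 0.0
        tab["h2"] = pd.Series(dtype=float)
    tab.attrs.update(
        mu=float(result.mu),
        sigma0_sq=float(result.sigma0_sq),
        V_P=float(v_p),
        V_G=float(v_g),
        n=len(result.y),
        k_r=result.state.k_r,
    )
    return tab


def _true_keys(true_effects) -> set[tuple]:
    keys = set()
    for d, _ in true_effects:
        if d.kind == "epistatic":
            keys.add(("epistatic", min(d.i, d.j), max(d.i, d.j)))
        else:
            keys.add((d.kind, d.i))
    return keys


def score_detections(report: pd.DataFrame, true_effects, window: int = 0) -> tuple[int, int]:
    """(true positives, false positives) among significant effects.

    With ``window=0`` a detection is a true positive iff its descriptor
    exactly matches a simulated nonzero effect — the same marker for a main
    effect, the same unordered marker pair for an epistatic effect.  With
    ``window=w`` a detection within w markers of a true QTL (per coordinate,
    pairs unordered) is credited to it, reflecting the positional
    uncertainty of mapped QTL on a dense map; each true effect can absorb at
    most one detection.
    """
    truth = _true_keys(true_effects)
    sig = report[report["significant"]] if "significant" in report else report
    keys = []
    for _, row in sig.iterrows():
        if row["kind"] == "epistatic":
            keys.append(("epistatic", int(row["i"]) - 1, int(row["j"]) - 1))
        else:
            keys.append((row["kind"], int(row["i"]) - 1))
    tp = fp = 0
    used = {k for k in keys if k in truth}  # exact matches claim their QTL first
    tp += len(used)
    for key in keys:
        if key in truth:
            continue
        match = None
        if window:
            for t in sorted(truth - used):
                if t[0] == key[0] and all(abs(a - b) <= window for a, b in zip(key[1:], t[1:])):
                    match = t
                    break
        if match is not None:
            tp += 1
            used.add(match)
        else:
            fp += 1
    return tp, fp
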