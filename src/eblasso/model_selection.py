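"""Cross-validated prediction error and the two-step (a, b) search.

Hyperparameters are chosen by the prediction error (PE): individuals are
partitioned into k near-equal folds by a seeded shuffle, the model is fitted
on the remainder and the mean squared prediction error of the held-out fold
is recorded.  The reported PE is the mean over folds and its standard error
is SD(fold PEs)/sqrt(k).

The two-step search first evaluates the diagonal grid
a = b in {0.001, 0.01, 0.05, 0.1, 0.5, 1} (the degree of shrinkage
generally decreases along this path), then fixes b at the step-1 winner and
scans a configurable set of a values — including negative a down to -0.95,
which weakens shrinkage further — returning the global PE minimizer over
everything evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EBLassoResult, FitConfig, Hyperparams, fit
from .design import DesignMatrix
from .inference import effect_tests

__all__ = ["CVResult", "kfold_pe", "cv_grid", "two_step_search"]

STEP1_GRID = (0.001, 0.01, 0.05, 0.1, 0.5, 1.0)
STEP2_A_DEFAULT = (-0.95, -0.75, -0.5, -0.01, 0.5)


@dataclass
class CVResult:
    """Grid of evaluated (a, b) points with the chosen minimizer."""

    table: pd.DataFrame  # a, b, pe, ste, n_effects, sigma0_sq
    best_a: float
    best_b: float

    @property
    def best_pe(self) -> float:
        row = self.table[(self.table.a == self.best_a) & (self.table.b == self.best_b)]
        return float(row.pe.iloc[0])


def _fold_indices(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, n_folds)
    if any(len(f) == 0 for f in folds):
        raise ValueError(f"{n_folds} folds leave an empty test fold for n={n}")
    return folds


def kfold_pe(
    y: np.ndarray,
    design: DesignMatrix,
    hyper: Hyperparams,
    n_folds: int = 10,
    seed: int = 0,
    config: FitConfig | None = None,
) -> tuple[float, float, list[EBLassoResult]]:
    """Mean squared prediction error under k-fold cross-validation.

    Returns (mean PE, standard error over folds, per-fold fit results).
    Fold assignment is reproducible from the seed.
    """
    y = np.asarray(y, dtype=float)
    n = design.n
    folds = _fold_indices(n, n_folds, seed)
    pes = []
    fits = []
    for test in folds:
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        train_idx = np.flatnonzero(mask)
        res = fit(y[train_idx], design.subset_rows(train_idx), hyper, config)
        pred = res.predict(design.subset_rows(test))
        pes.append(float(np.mean((y[test] - pred) ** 2)))
        fits.append(res)
    pes = np.asarray(pes)
    return float(pes.mean()), float(pes.std(ddof=1) / np.sqrt(n_folds)), fits


def cv_grid(
    y: np.ndarray,
    design: DesignMatrix,
    grid,
    n_folds: int = 10,
    seed: int = 0,
    config: FitConfig | None = None,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Evaluate PE on a list of (a, b) points; one row per point."""
    rows = []
    for a, b in grid:
        hyper = Hyperparams(a, b)
        pe, ste, fits = kfold_pe(y, design, hyper, n_folds, seed, config)
        n_eff = float(np.mean([int(effect_tests(r, alpha_level).significant.sum()) for r in fits]))
        sig = float(np.mean([r.sigma0_sq for r in fits]))
        rows.append({"a": a, "b": b, "pe": pe, "ste": ste, "n_effects": n_eff, "sigma0_sq": sig})
    return pd.DataFrame(rows)


def two_step_search(
    y: np.ndarray,
    design: DesignMatrix,
    n_folds: int = 10,
    seed: int = 0,
    step1_grid=STEP1_GRID,
    step2_a=STEP2_A_DEFAULT,
    config: FitConfig | None = None,
) -> CVResult:
    """Two-step hyperparameter search: diagonal grid, then scan a at b = b*."""
    tab1 = cv_grid(y, design, [(v, v) for v in step1_grid], n_folds, seed, config)
    b_star = float(tab1.loc[tab1.pe.idxmin(), "b"])
    extra = [(float(a), b_star) for a in step2_a if not any(np.isclose(a, r.a) and np.isclose(b_star, r.b) for r in tab1.itertuples())]
    if extra:
        tab2 = cv_grid(y, design, extra, n_folds, seed, config)
        table = pd.concat([tab1, tab2], ignore_index=True)
    else:
        table = tab1
    best = table.loc[table.pe.idxmin()]
    result = CVResult(table=table, best_a=float(best.a), best_b=float(best.b))
    assert result.best_pe <= table.pe.min() + 1e-12
    return result
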