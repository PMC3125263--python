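"""Cockerham-coded design matrices for multiple-QTL regression.

The regression model for a quantitative trait is

    y = mu 1 + X_E b_E + X_G b_G + X_GG b_GG + X_GE b_GE + e,

where ``X_E`` holds environmental covariates, ``X_G`` the coded main effects
of the markers, ``X_GG`` the pairwise epistatic effects (element-wise products
of two different main-effect columns) and ``X_GE`` the gene-environment
interactions (products of a covariate column with a main-effect column).
Under the Cockerham model an F2 additive effect is coded -1/0/1 for the three
genotypes, a dominance effect -0.5/+0.5 for homozygote/heterozygote, and a
backcross (or doubled-haploid) main effect -0.5/+0.5 for the two genotypes.

With ``p`` covariates and ``q`` additively coded markers the full design has
``k = p + q(q+1)/2 + pq`` effect columns, typically far more than the sample
size.  The epistatic block is therefore available in a *lazy* representation
that never materializes the n x q(q-1)/2 product columns: matrix-vector
products against the full design and extraction of individual columns are
computed on the fly from the n x q main-effect block, and are bit-identical
to the eager (materialized) representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "EffectDescriptor",
    "DesignMatrix",
    "encode_main",
    "build_interaction_columns",
    "assemble_design",
    "effect_count",
]

DESIGNS = ("F2", "backcross", "DH")

# genotype codes accepted per cross design (0 also appears for imputed
# missing calls in backcross/DH data)
_VALID_CODES = {
    "F2": (-1.0, 0.0, 1.0),
    "backcross": (-0.5, 0.0, 0.5),
    "DH": (-1.0, 0.0, 1.0),
}


@dataclass
class GenotypeMatrix:
    """Genotype codes for ``n`` individuals at ``q`` markers.

    ``values`` holds raw codes: F2 additive -1/0/1; backcross -0.5/+0.5;
    DH -1/+1 (rescaled to -0.5/+0.5 during encoding).  Missing entries must
    be imputed (to 0) before encoding.
    """

    values: np.ndarray
    design: str = "F2"
    marker_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D (individuals x markers) array")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown cross design {self.design!r}; expected one of {DESIGNS}")
        if self.marker_names is None:
            self.marker_names = [f"m{j + 1}" for j in range(self.values.shape[1])]
        if len(self.marker_names) != self.values.shape[1]:
            raise ValueError("marker_names length does not match the number of marker columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def validate_codes(self) -> None:
        """Reject genotype codes that are invalid for the declared design."""
        valid = _VALID_CODES[self.design]
        ok = np.isin(self.values, valid)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid {self.design} genotype code {self.values[i, j]!r} at "
                f"individual {i}, marker {self.marker_names[j]!r} (column {j})"
            )


@dataclass(frozen=True)
class EffectDescriptor:
    """What a design column encodes.

    ``kind`` is one of env / main_additive / main_dominance / epistatic /
    gxe / const.  ``i``/``j`` are 0-based source indices: marker indices for
    genetic effects (epistatic pairs ordered i < j), covariate index first
    for gxe.
    """

    kind: str
    i: int | None = None
    j: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "epistatic" and not (self.i is not None and self.j is not None and self.i < self.j):
            raise ValueError("epistatic descriptor needs two distinct markers with i < j")

    def label(self, offset: int = 1) -> str:
        """Human-readable label; marker/covariate indices printed ``offset``-based."""
        if self.kind == "const":
            return "const"
        if self.kind in ("main_additive", "main_dominance"):
            tag = "a" if self.kind == "main_additive" else "d"
            return f"{tag}({self.i + offset})"
        if self.kind == "env":
            return f"env({self.i + offset})"
        if self.kind == "epistatic":
            return f"epi({self.i + offset},{self.j + offset})"
        return f"gxe(e{self.i + offset},m{self.j + offset})"


class _Block:
    """Interface for a contiguous block of design columns."""

    k: int

    def matvec_T(self, v: np.ndarray) -> np.ndarray:  # X_block^T v
        raise NotImplementedError

    def columns(self, idx: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def norms_sq(self) -> np.ndarray:
        raise NotImplementedError

    def sums(self) -> np.ndarray:
        raise NotImplementedError

    def descriptor(self, i: int) -> EffectDescriptor:
        raise NotImplementedError

    def subset_rows(self, rows: np.ndarray) -> "_Block":
        raise NotImplementedError


class _DenseBlock(_Block):
    def __init__(self, cols: np.ndarray, descriptors: Sequence[EffectDescriptor]):
        self.cols = np.ascontiguousarray(cols, dtype=float)
        self.descriptors = list(descriptors)
        self.k = self.cols.shape[1]
        if len(self.descriptors) != self.k:
            raise ValueError("one descriptor per column required")

    def matvec_T(self, v):
        return self.cols.T @ v

    def columns(self, idx):
        return self.cols[:, idx]

    def norms_sq(self):
        return np.einsum("ij,ij->j", self.cols, self.cols)

    def sums(self):
        return self.cols.sum(axis=0)

    def descriptor(self, i):
        return self.descriptors[i]

    def subset_rows(self, rows):
        return _DenseBlock(self.cols[rows], self.descriptors)


class _PairProductBlock(_Block):
    """Lazy epistatic block: column (i,j) = base[:, i] * base[:, j], i < j."""

    def __init__(self, base: np.ndarray, marker_idx: np.ndarray | None = None):
        self.base = np.ascontiguousarray(base, dtype=float)
        q = self.base.shape[1]
        self.ii, self.jj = np.triu_indices(q, k=1)
        # marker indices the base columns refer to (identity unless the base
        # is itself a subset of markers)
        self.marker_idx = np.arange(q) if marker_idx is None else np.asarray(marker_idx)
        self.k = self.ii.size

    def matvec_T(self, v):
        w = self.base.T @ (self.base * v[:, None])
        return w[self.ii, self.jj]

    def columns(self, idx):
        idx = np.atleast_1d(idx)
        return self.base[:, self.ii[idx]] * self.base[:, self.jj[idx]]

    def norms_sq(self):
        sq = self.base**2
        return (sq.T @ sq)[self.ii, self.jj]

    def sums(self):
        return (self.base.T @ self.base)[self.ii, self.jj]

    def descriptor(self, i):
        return EffectDescriptor("epistatic", int(self.marker_idx[self.ii[i]]), int(self.marker_idx[self.jj[i]]))

    def subset_rows(self, rows):
        return _PairProductBlock(self.base[rows], self.marker_idx)


class _CrossProductBlock(_Block):
    """Lazy gxe block: ordered pairs (covariate e, marker m), e outer, m inner."""

    def __init__(self, env: np.ndarray, main: np.ndarray):
        self.env = np.ascontiguousarray(env, dtype=float)
        self.main = np.ascontiguousarray(main, dtype=float)
        self.p = self.env.shape[1]
        self.m = self.main.shape[1]
        self.k = self.p * self.m

    def matvec_T(self, v):
        return np.concatenate([self.main.T @ (self.env[:, e] * v) for e in range(self.p)])

    def columns(self, idx):
        idx = np.atleast_1d(idx)
        return self.env[:, idx // self.m] * self.main[:, idx % self.m]

    def norms_sq(self):
        return np.concatenate(
            [np.einsum("ij,ij->j", (self.env[:, e : e + 1] * self.main), (self.env[:, e : e + 1] * self.main)) for e in range(self.p)]
        )

    def sums(self):
        return np.concatenate([(self.env[:, e : e + 1] * self.main).sum(axis=0) for e in range(self.p)])

    def descriptor(self, i):
        return EffectDescriptor("gxe", int(i // self.m), int(i % self.m))

    def subset_rows(self, rows):
        return _CrossProductBlock(self.env[rows], self.main[rows])


@dataclass
class DesignMatrix:
    """Coded effect columns with per-column descriptors.

    Column order is deterministic: env block, main block (all additive, then
    all dominance), epistatic block in lexicographic (i, j) order, gxe block,
    optional trailing constant column.
    """

    blocks: list[_Block]
    n: int
    p: int = 0
    q: int = 0

    @property
    def k(self) -> int:
        return sum(b.k for b in self.blocks)

    @cached_property
    def _offsets(self) -> np.ndarray:
        return np.cumsum([0] + [b.k for b in self.blocks])

    def _locate(self, i: int) -> tuple[int, int]:
        bi = int(np.searchsorted(self._offsets, i, side="right") - 1)
        return bi, i - int(self._offsets[bi])

    def matvec_T(self, v: np.ndarray) -> np.ndarray:
        """``X^T v`` over all k columns, computed blockwise (lazy-safe)."""
        v = np.asarray(v, dtype=float)
        if v.shape != (self.n,):
            raise ValueError(f"expected a length-{self.n} vector")
        return np.concatenate([b.matvec_T(v) for b in self.blocks]) if self.blocks else np.empty(0)

    def columns(self, idx) -> np.ndarray:
        """Materialize the requested columns as an n x len(idx) array."""
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        out = np.empty((self.n, idx.size))
        offs = self._offsets
        for t, i in enumerate(idx):
            if not 0 <= i < self.k:
                raise IndexError(f"column {i} out of range [0, {self.k})")
            bi, loc = self._locate(int(i))
            out[:, t] = self.blocks[bi].columns(np.array([loc]))[:, 0]
        return out

    @cached_property
    def norms_sq(self) -> np.ndarray:
        return np.concatenate([b.norms_sq() for b in self.blocks]) if self.blocks else np.empty(0)

    @cached_property
    def col_sums(self) -> np.ndarray:
        return np.concatenate([b.sums() for b in self.blocks]) if self.blocks else np.empty(0)

    @cached_property
    def constant_mask(self) -> np.ndarray:
        """True for zero-variance (constant) columns; flagged, never selected."""
        var = self.norms_sq / self.n - (self.col_sums / self.n) ** 2
        return var <= 1e-12

    def descriptor(self, i: int) -> EffectDescriptor:
        bi, loc = self._locate(int(i))
        return self.blocks[bi].descriptor(loc)

    def descriptors(self) -> list[EffectDescriptor]:
        return [self.descriptor(i) for i in range(self.k)]

    def subset_rows(self, rows) -> "DesignMatrix":
        rows = np.asarray(rows)
        new = DesignMatrix([b.subset_rows(rows) for b in self.blocks], n=len(np.arange(self.n)[rows]), p=self.p, q=self.q)
        return new

    def to_dense(self, max_entries: int = 50_000_000) -> np.ndarray:
        if self.n * self.k > max_entries:
            raise MemoryError(f"refusing to materialize {self.n} x {self.k} design")
        return self.columns(np.arange(self.k))

    def unit_norm_view(self) -> "UnitNormDesign":
        """View with every column scaled to unit Euclidean norm (zero
        columns are left untouched)."""
        return UnitNormDesign(self)


class UnitNormDesign:
    """Column-normalized view of a :class:`DesignMatrix`.

    Shrinkage priors act on the scale of the coefficients, so the solver
    standardizes columns to unit norm internally; estimates are mapped back
    to the original column units via ``scales``.
    """

    def __init__(self, base: DesignMatrix):
        self.base = base
        norms = np.sqrt(base.norms_sq)
        self.scales = np.where(norms > 0, norms, 1.0)

    @property
    def n(self) -> int:
        return self.base.n

    @property
    def k(self) -> int:
        return self.base.k

    @property
    def p(self) -> int:
        return self.base.p

    @property
    def q(self) -> int:
        return self.base.q

    def matvec_T(self, v: np.ndarray) -> np.ndarray:
        return self.base.matvec_T(v) / self.scales

    def columns(self, idx) -> np.ndarray:
        idx = np.atleast_1d(np.asarray(idx, dtype=int))
        return self.base.columns(idx) / self.scales[idx]

    @cached_property
    def norms_sq(self) -> np.ndarray:
        return self.base.norms_sq / self.scales**2

    @cached_property
    def col_sums(self) -> np.ndarray:
        return self.base.col_sums / self.scales

    @property
    def constant_mask(self) -> np.ndarray:
        return self.base.constant_mask

    def descriptor(self, i: int) -> EffectDescriptor:
        return self.base.descriptor(i)

    def descriptors(self) -> list[EffectDescriptor]:
        return self.base.descriptors()

    def subset_rows(self, rows) -> "UnitNormDesign":
        return UnitNormDesign(self.base.subset_rows(rows))


def encode_main(genotypes: GenotypeMatrix, include_dominance: bool = False) -> tuple[np.ndarray, list[EffectDescriptor]]:
    """Code the main-effect columns under the Cockerham model.

    F2: additive column -1/0/1 per marker, plus a dominance column
    (-0.5 homozygote, +0.5 heterozygote) per marker when requested.
    Backcross: one -0.5/+0.5 column per marker.  DH: raw -1/+1 calls are
    rescaled to -0.5/+0.5 (imputed 0 stays 0).
    """
    genotypes.validate_codes()
    g = genotypes.values
    if genotypes.design == "F2":
        cols = [g]
        descr = [EffectDescriptor("main_additive", j) for j in range(genotypes.q)]
        if include_dominance:
            dom = np.where(g == 0.0, 0.5, -0.5)
            cols.append(dom)
            descr += [EffectDescriptor("main_dominance", j) for j in range(genotypes.q)]
        return np.hstack(cols), descr
    if include_dominance:
        raise ValueError(f"dominance effects are undefined for a {genotypes.design} design")
    scale = 0.5 if genotypes.design == "DH" else 1.0
    return g * scale, [EffectDescriptor("main_additive", j) for j in range(genotypes.q)]


def build_interaction_columns(
    left_block: np.ndarray,
    right_block: np.ndarray | None = None,
    mode: str = "epistatic",
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Element-wise product columns.

    ``epistatic``: unordered pairs of distinct columns within ``left_block``
    (strict upper triangle, lexicographic order).  ``gxe``: ordered
    (covariate, marker) pairs across ``left_block`` x ``right_block``.
    Returns the materialized columns and the source-index pairs.
    """
    left = np.asarray(left_block, dtype=float)
    if mode == "epistatic":
        ii, jj = np.triu_indices(left.shape[1], k=1)
        return left[:, ii] * left[:, jj], list(zip(ii.tolist(), jj.tolist()))
    if mode == "gxe":
        right = np.asarray(right_block, dtype=float)
        if right.shape[0] != left.shape[0]:
            raise ValueError(f"row mismatch: {left.shape[0]} vs {right.shape[0]}")
        p, m = left.shape[1], right.shape[1]
        cols = np.empty((left.shape[0], p * m))
        pairs = []
        for e in range(p):
            cols[:, e * m : (e + 1) * m] = left[:, e : e + 1] * right
            pairs += [(e, g) for g in range(m)]
        return cols, pairs
    raise ValueError(f"unknown interaction mode {mode!r}")


def effect_count(
    p: int,
    q: int,
    include_dominance: bool = False,
    include_epistasis: bool = True,
    include_gxe: bool = True,
) -> int:
    """Closed-form column count of the assembled design (constant excluded).

    With all interaction blocks and additive coding only this is
    ``p + q(q+1)/2 + pq``.
    """
    if p < 0 or q < 1:
        raise ValueError("need p >= 0 and q >= 1")
    k = p + q
    if include_dominance:
        k += q
    if include_epistasis:
        k += q * (q - 1) // 2
    if include_gxe:
        k += p * q
    return k


def assemble_design(
    genotypes: GenotypeMatrix,
    env: np.ndarray | None = None,
    include_dominance: bool = False,
    include_epistasis: bool = True,
    include_gxe: bool | None = None,
    include_constant: bool = False,
    lazy: bool | str = "auto",
) -> DesignMatrix:
    """Assemble X = [X_E, X_G, X_GG, X_GE] with column metadata.

    Epistatic columns are products of *additive* main columns (dominance
    columns, when present, enter only the main block).  ``lazy`` keeps the
    epistatic and gxe blocks implicit; "auto" switches to lazy once the full
    matrix would exceed ~2e7 entries.  Lazy and eager designs produce
    bit-identical columns; blocked matrix-vector products agree to
    floating-point roundoff.
    """
    if genotypes.q < 1 or genotypes.n < 1:
        raise ValueError("empty genotype input")
    n = genotypes.n
    env_arr = None
    if env is not None:
        env_arr = np.asarray(env, dtype=float)
        if env_arr.ndim == 1:
            env_arr = env_arr[:, None]
        if env_arr.shape[0] != n:
            raise ValueError(f"covariate rows ({env_arr.shape[0]}) do not match individuals ({n})")
    p = 0 if env_arr is None else env_arr.shape[1]
    if include_gxe is None:
        include_gxe = p > 0
    if include_gxe and p == 0:
        raise ValueError("gxe block requested without environmental covariates")

    main_cols, main_descr = encode_main(genotypes, include_dominance)
    additive = main_cols[:, : genotypes.q]

    k_total = effect_count(p, genotypes.q, include_dominance, include_epistasis, include_gxe)
    if lazy == "auto":
        lazy = n * k_total > 20_000_000

    blocks: list[_Block] = []
    if p:
        blocks.append(_DenseBlock(env_arr, [EffectDescriptor("env", e) for e in range(p)]))
    blocks.append(_DenseBlock(main_cols, main_descr))
    if include_epistasis and genotypes.q >= 2:
        if lazy:
            blocks.append(_PairProductBlock(additive))
        else:
            cols, pairs = build_interaction_columns(additive, mode="epistatic")
            blocks.append(_DenseBlock(cols, [EffectDescriptor("epistatic", i, j) for i, j in pairs]))
    if include_gxe:
        if lazy:
            blocks.append(_CrossProductBlock(env_arr, additive))
        else:
            cols, pairs = build_interaction_columns(env_arr, additive, mode="gxe")
            blocks.append(_DenseBlock(cols, [EffectDescriptor("gxe", e, g) for e, g in pairs]))
    if include_constant:
        blocks.append(_DenseBlock(np.ones((n, 1)), [EffectDescriptor("const")]))
    return DesignMatrix(blocks, n=n, p=p, q=genotypes.q)
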