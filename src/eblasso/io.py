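"""Plain-text file I/O and run configuration.

All formats are delimited text: genotypes as individuals x markers with a
header of marker names and an id column; phenotypes as (id, value); genetic
maps as (marker, chrom, pos_cM); effect reports and cross-validation tables
as TSV.  Missing genotype calls (empty or NA) are imputed as 0 with a
logged count.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .design import GenotypeMatrix
from .simulate import ChromosomeMap

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_map",
    "write_map",
    "read_effect_report",
    "write_effect_report",
    "read_cv_table",
    "write_cv_table",
]

logger = logging.getLogger(__name__)

# call-string -> raw code, per cross design
_CALL_CODES = {
    "F2": {"A": 1.0, "H": 0.0, "B": -1.0},
    "backcross": {"A": 0.5, "H": -0.5, "B": -0.5},
    "DH": {"A": 1.0, "B": -1.0},
}
_MISSING = {"", "NA", "N", "-", "NAN"}


@dataclass
class RunConfig:
    """Serializable run configuration (hyperparameters, tolerances, CV and
    design options); validated against the same bounds as the solver."""

    a: float = 0.1
    b: float = 0.1
    tol_logl: float = 1e-6
    tol_param: float = 1e-4
    max_inner: int = 1000
    max_outer: int = 50
    n_folds: int = 10
    seed: int = 0
    include_dominance: bool = False
    include_epistasis: bool = True
    include_gxe: bool = False
    significance_level: float = 0.05
    design: str = "F2"

    def __post_init__(self) -> None:
        if not self.a > -1.5:
            raise ValueError(f"hyperparameter a must exceed -1.5 (got {self.a})")
        if not self.b > 0:
            raise ValueError(f"hyperparameter b must be positive (got {self.b})")
        if not 0 < self.significance_level < 1:
            raise ValueError("significance_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_genotypes(path, fmt: str = "coded_csv", design: str = "F2", sep: str = ",") -> GenotypeMatrix:
    """Read a genotype table (rows = individuals, columns = markers, first
    column = individual id).

    ``coded_csv`` expects numeric codes; ``call_csv`` expects A/B/H call
    strings.  Missing entries (empty/NA) are imputed as 0 and counted in the
    log.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no marker columns found")
    vals = df.to_numpy()
    out = np.empty(vals.shape, dtype=float)
    n_missing = 0
    if fmt == "coded_csv":
        for r in range(vals.shape[0]):
            for c in range(vals.shape[1]):
                cell = vals[r, c].strip()
                if cell.upper() in _MISSING:
                    out[r, c] = 0.0
                    n_missing += 1
                else:
                    try:
                        out[r, c] = float(cell)
                    except ValueError:
                        raise ValueError(f"{path}: invalid genotype code {cell!r} at line {r + 2}, column {df.columns[c]!r}") from None
    elif fmt == "call_csv":
        codes = _CALL_CODES[design]
        for r in range(vals.shape[0]):
            for c in range(vals.shape[1]):
                cell = vals[r, c].strip().upper()
                if cell in _MISSING:
                    out[r, c] = 0.0
                    n_missing += 1
                elif cell in codes:
                    out[r, c] = codes[cell]
                else:
                    raise ValueError(f"{path}: unknown genotype call {vals[r, c]!r} at line {r + 2}, column {df.columns[c]!r}")
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if n_missing:
        logger.info("%s: imputed %d missing genotype cells as 0", path, n_missing)
    g = GenotypeMatrix(out, design=design, marker_names=list(df.columns))
    g.individual_ids = list(df.index)  # type: ignore[attr-defined]
    g.n_imputed = n_missing  # type: ignore[attr-defined]
    return g


def write_genotypes(genotypes: GenotypeMatrix, path, ids=None, sep: str = ",") -> None:
    ids = ids if ids is not None else getattr(genotypes, "individual_ids", None)
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(genotypes.n)]
    df = pd.DataFrame(genotypes.values, index=pd.Index(ids, name="id"), columns=genotypes.marker_names)
    df.to_csv(path, sep=sep, float_format="%g")


def read_phenotypes(path, ids=None, sep: str = ",") -> np.ndarray:
    """Read an (id, value) table; if ``ids`` is given, rows are aligned to
    that order and mismatches rejected."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected (id, value) columns")
    df = df.set_index(df.columns[0])
    series = df[df.columns[0]].astype(float)
    if ids is not None:
        missing = [i for i in ids if i not in series.index]
        if missing:
            raise ValueError(f"{path}: phenotype ids not found: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        series = series.loc[list(ids)]
    return series.to_numpy()


def write_phenotypes(y: np.ndarray, path, ids=None, sep: str = ",") -> None:
    ids = ids if ids is not None else [f"ind{i + 1}" for i in range(len(y))]
    pd.DataFrame({"id": ids, "value": y}).to_csv(path, sep=sep, index=False)


def read_map(path, sep: str = ",") -> ChromosomeMap:
    """Read (marker, chrom, pos_cM) rows; positions must be strictly
    increasing within each chromosome."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected (marker, chrom, pos) columns")
    marker, chrom, pos = df.columns[:3]
    positions, names, chroms = [], [], []
    for c, grp in df.groupby(chrom, sort=False):
        positions.append(grp[pos].to_numpy(dtype=float))
        names.extend(grp[marker].astype(str))
        chroms.append(str(c))
    return ChromosomeMap(positions, names=names, chromosomes=chroms)


def write_map(cmap: ChromosomeMap, path, sep: str = ",") -> None:
    rows = []
    t = 0
    for c, pos in enumerate(cmap.positions):
        for p in pos:
            rows.append({"marker": cmap.names[t], "chrom": cmap.chromosomes[c], "pos": p})
            t += 1
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_effect_report(report: pd.DataFrame, path) -> None:
    """Effect table as TSV; the global summary travels as '# key: value'
    header comments."""
    with open(path, "w") as fh:
        for key, val in report.attrs.items():
            fh.write(f"# {key}: {val}\n")
        report.to_csv(fh, sep="\t", index=False)


def read_effect_report(path) -> pd.DataFrame:
    attrs = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            try:
                attrs[key.strip()] = float(val)
            except ValueError:
                attrs[key.strip()] = val.strip()
        else:
            body.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    df.attrs.update(attrs)
    return df


def write_cv_table(table: pd.DataFrame, path, best: tuple[float, float] | None = None) -> None:
    with open(path, "w") as fh:
        if best is not None:
            fh.write(f"# best_a: {best[0]}\n# best_b: {best[1]}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_cv_table(path) -> pd.DataFrame:
    return read_effect_report(path)
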