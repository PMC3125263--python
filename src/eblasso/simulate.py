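"""Simulation of experimental-cross genotypes and quantitative traits.

Gametes are simulated as a Markov chain along each chromosome: the allele at
the first marker is a fair coin flip, and between adjacent markers the chain
switches parental origin with the recombination fraction given by the map
function (Haldane by default, r = (1 - exp(-2d/100))/2 for a distance of
d cM; Kosambi optional).  There is no crossover interference.  F2 genotypes
are sums of two independent gametes (additive code -1/0/1), a backcross
carries one segregating gamete (-0.5/+0.5), and a doubled haploid is one
gamete doubled (-1/+1).  Chromosomes and individuals are independent.

The built-in scenario factories reproduce the reference simulation design:
a single 2400 cM chromosome covered by 481 evenly spaced markers (5 cM
interval), n = 1000 F2 individuals, 20 main-effect QTLs and 20 epistatic
marker pairs, population mean 100 and residual variance 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import EffectDescriptor, GenotypeMatrix, encode_main

__all__ = [
    "ChromosomeMap",
    "SimScenario",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_scenario",
    "scenario_main_epistatic",
    "scenario_main_only",
    "TRUE_MAIN_EFFECTS",
    "TRUE_EPISTATIC_EFFECTS",
]


def haldane(d_cm: np.ndarray) -> np.ndarray:
    """Map distance (cM) -> recombination fraction, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))


def kosambi(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * np.tanh(2.0 * np.asarray(d_cm, float) / 100.0)


_MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}


@dataclass
class ChromosomeMap:
    """Marker positions in cM, grouped by chromosome."""

    positions: list[np.ndarray]
    names: list[str] | None = None
    chromosomes: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = [np.asarray(p, dtype=float) for p in self.positions]
        for c, pos in enumerate(self.positions):
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions on chromosome {c + 1} must be strictly increasing")
        if self.chromosomes is None:
            self.chromosomes = [f"{c + 1}" for c in range(len(self.positions))]
        if self.names is None:
            self.names = [f"c{self.chromosomes[c]}_m{j + 1}" for c, pos in enumerate(self.positions) for j in range(len(pos))]
        if len(self.names) != self.q:
            raise ValueError("marker name count does not match map size")

    @property
    def q(self) -> int:
        return sum(len(p) for p in self.positions)

    @classmethod
    def uniform(cls, length_cm: float, spacing_cm: float, n_chrom: int = 1) -> "ChromosomeMap":
        """Evenly spaced markers covering [0, length_cm] on each chromosome
        (a 2400 cM chromosome at 5 cM spacing yields 481 markers)."""
        pos = np.arange(0.0, length_cm + 0.5 * spacing_cm, spacing_cm)
        return cls([pos.copy() for _ in range(n_chrom)])


@dataclass
class SimScenario:
    """A full simulation configuration: map, cross design, true effects
    (descriptor, beta), population mean, residual variance and sample size."""

    map: ChromosomeMap
    design: str = "F2"
    true_effects: list[tuple[EffectDescriptor, float]] = field(default_factory=list)
    mu: float = 0.0
    sigma0_sq: float = 1.0
    n: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be positive")
        q = self.map.q
        for d, _ in self.true_effects:
            for m in (d.i, d.j):
                if m is not None and not 0 <= m < q:
                    raise ValueError(f"effect descriptor references unmapped marker {m}")


def _simulate_gametes(cmap: ChromosomeMap, n: int, rng: np.random.Generator, map_function: str) -> np.ndarray:
    mf = _MAP_FUNCTIONS[map_function]
    out = []
    for pos in cmap.positions:
        q = len(pos)
        g = np.empty((n, q), dtype=np.int8)
        g[:, 0] = rng.integers(0, 2, size=n)
        if q > 1:
            r = mf(np.diff(pos))
            switches = rng.random((n, q - 1)) < r[None, :]
            g[:, 1:] = g[:, :1] ^ (np.cumsum(switches, axis=1) % 2).astype(np.int8)
        out.append(g)
    return np.hstack(out)


def simulate_genotypes(
    cmap: ChromosomeMap,
    design: str = "F2",
    n: int = 100,
    seed: int | np.random.Generator | None = None,
    map_function: str = "haldane",
) -> GenotypeMatrix:
    """Simulate genotype codes for ``n`` individuals along the map."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if design == "F2":
        values = (_simulate_gametes(cmap, n, rng, map_function).astype(np.int16) + _simulate_gametes(cmap, n, rng, map_function) - 1).astype(float)
    elif design == "backcross":
        values = _simulate_gametes(cmap, n, rng, map_function).astype(float) - 0.5
    elif design == "DH":
        values = 2.0 * _simulate_gametes(cmap, n, rng, map_function).astype(float) - 1.0
    else:
        raise ValueError(f"unknown cross design {design!r}")
    return GenotypeMatrix(values, design=design, marker_names=list(cmap.names))


def _effect_columns(genotypes: GenotypeMatrix, effects: list[tuple[EffectDescriptor, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Coded columns and beta values for the scenario's effects (epistatic
    value = product of the two markers' additive codes)."""
    main, _ = encode_main(genotypes, include_dominance=False)
    cols = []
    betas = []
    for d, beta in effects:
        if d.kind == "main_additive":
            cols.append(main[:, d.i])
        elif d.kind == "epistatic":
            cols.append(main[:, d.i] * main[:, d.j])
        else:
            raise ValueError(f"cannot simulate effect kind {d.kind!r}")
        betas.append(beta)
    if not cols:
        return np.empty((genotypes.n, 0)), np.empty(0)
    return np.column_stack(cols), np.asarray(betas)


def simulate_trait(
    genotypes: GenotypeMatrix,
    scenario: SimScenario,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """y = mu + sum_j beta_j x_j + e with iid Gaussian residuals."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X, beta = _effect_columns(genotypes, scenario.true_effects)
    e = rng.normal(0.0, np.sqrt(scenario.sigma0_sq), size=genotypes.n)
    return scenario.mu + X @ beta + e


def simulate_scenario(scenario: SimScenario, seed: int | None = None) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw one realization (genotypes + trait) of a scenario."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    g = simulate_genotypes(scenario.map, scenario.design, scenario.n, rng)
    y = simulate_trait(g, scenario, rng)
    return g, y


# Reference simulation: 20 main-effect QTLs (1-based marker, beta) and 20
# epistatic pairs on the 481-marker / 2400 cM map, mu = 100, sigma0^2 = 10.
TRUE_MAIN_EFFECTS: list[tuple[int, float]] = [
    (11, 4.47), (26, 3.16), (42, -2.24), (48, -1.58), (72, 2.24),
    (73, 3.16), (123, 1.10), (127, -1.10), (161, 0.77), (181, 1.73),
    (182, 3.81), (185, 2.25), (221, -1.30), (243, -1.00), (262, -2.24),
    (268, 1.58), (270, 1.00), (274, -1.73), (361, 0.71), (461, 0.89),
]

TRUE_EPISTATIC_EFFECTS: list[tuple[int, int, float]] = [
    (5, 6, 2.24), (6, 39, 2.25), (42, 220, 4.47), (75, 431, 0.77),
    (81, 200, -2.24), (82, 193, 1.58), (87, 164, 3.16), (87, 322, 3.81),
    (92, 395, 1.73), (104, 328, 1.00), (118, 278, -2.24), (150, 269, 1.10),
    (237, 313, 0.71), (246, 470, -1.10), (323, 464, 0.89), (328, 404, -1.73),
    (342, 420, -1.30), (344, 407, -1.00), (373, 400, -1.58), (431, 439, 3.16),
]


def scenario_main_epistatic(n: int = 1000, seed: int | None = None) -> SimScenario:
    """The full reference scenario: 20 main + 20 epistatic QTL effects."""
    cmap = ChromosomeMap.uniform(2400.0, 5.0)
    effects: list[tuple[EffectDescriptor, float]] = [
        (EffectDescriptor("main_additive", m - 1), b) for m, b in TRUE_MAIN_EFFECTS
    ] + [(EffectDescriptor("epistatic", i - 1, j - 1), b) for i, j, b in TRUE_EPISTATIC_EFFECTS]
    return SimScenario(map=cmap, design="F2", true_effects=effects, mu=100.0, sigma0_sq=10.0, n=n, seed=seed)


def scenario_main_only(n: int = 1000, seed: int | None = None) -> SimScenario:
    """The reference scenario with the 20 epistatic effects removed."""
    sc = scenario_main_epistatic(n=n, seed=seed)
    sc.true_effects = [(d, b) for d, b in sc.true_effects if d.kind == "main_additive"]
    return sc
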