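"""Simulation of marker genotypes along a genetic map and epistatic traits.

Genotypes are generated for an F2-like population: each individual is the
sum of two independent gametes from fully heterozygous parents with known
phase, so allele frequencies are 0.5 and the dosage correlation between two
markers at map distance d cM is exp(-2d/100) (Haldane map function,
r = (1 - exp(-2d/100)) / 2).

Traits are built from additive terms (centered dosages) and epistatic terms
(products of centered dosages at two loci).  Each term's coefficient is
calibrated so its empirical variance equals a target fraction of the total
phenotypic variance; the residual takes up the remaining fraction.

The bundled preset emulates a classic epistatic benchmark genome: one
chromosome of 1,800 cM, 121 markers at 15 cM spacing, 600 individuals,
9 additive QTL and 13 QTL-by-QTL interactions, each contributing between
0.5% and 20% of the phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CovariateMatrix, GenotypeMatrix

__all__ = [
    "TraitSimulationSpec",
    "SimulatedDataset",
    "haldane_recombination",
    "simulate_genotypes",
    "calibrate_effects",
    "simulate_dataset",
    "expand_interactions",
    "epistatic_benchmark_spec",
]


def haldane_recombination(d_cm: np.ndarray) -> np.ndarray:
    """Recombination probability for a map distance in cM: (1 - e^{-2d/100})/2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass
class TraitSimulationSpec:
    """Architecture of a simulated quantitative trait.

    ``additive_qtl`` holds (marker index, target variance fraction) pairs and
    ``epistatic_pairs`` holds (i, j, target fraction) triples.  Fractions are
    of total phenotypic variance; together with the residual fraction they
    sum to one.
    """

    n_individuals: int
    chromosome_length: float  # cM
    marker_spacing: float  # cM
    additive_qtl: list = field(default_factory=list)
    epistatic_pairs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        total = self.genetic_fraction
        if total >= 1.0:
            raise ValueError(f"variance fractions sum to {total:.3f} >= 1")
        for f in self._fractions():
            if f <= 0:
                raise ValueError("variance fractions must be positive")

    def _fractions(self):
        return [f for _, f in self.additive_qtl] + [f for _, _, f in self.epistatic_pairs]

    @property
    def genetic_fraction(self) -> float:
        """Sum of all QTL target fractions."""
        return float(sum(self._fractions()))

    @property
    def residual_fraction(self) -> float:
        return 1.0 - self.genetic_fraction

    @property
    def marker_positions(self) -> np.ndarray:
        """Evenly spaced positions 0, spacing, ..., chromosome_length (cM)."""
        n_markers = int(round(self.chromosome_length / self.marker_spacing)) + 1
        return np.arange(n_markers) * self.marker_spacing


@dataclass
class SimulatedDataset:
    """Genotypes, phenotypes and ground truth from one simulation run."""

    genotypes: GenotypeMatrix
    phenotypes: np.ndarray
    genetic_values: np.ndarray
    spec: TraitSimulationSpec
    effects: dict  # term label -> coefficient
    realized_fractions: dict  # term label -> realized variance fraction

    @property
    def heritability(self) -> float:
        """Realized fraction of phenotypic variance that is genetic."""
        return float(np.var(self.genetic_values) / np.var(self.phenotypes))


def simulate_genotypes(n: int, positions, seed=None, line_prefix: str = "L") -> GenotypeMatrix:
    """Draw n individuals as sums of two independent gametes along a map.

    Within a gamete, the allele at the first marker is Bernoulli(1/2) and
    switches between parental haplotypes across each interval with the
    Haldane probability for that interval's length.
    """
    positions = np.asarray(positions, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    if positions.ndim != 1 or positions.size < 1:
        raise ValueError("positions must be a non-empty 1-D array")
    if np.any(np.diff(positions) < 0):
        raise ValueError("marker positions must be non-decreasing")
    rng = np.random.default_rng(seed)
    p = positions.size
    r = haldane_recombination(np.diff(positions))
    n_gam = 2 * n
    start = rng.integers(0, 2, size=(n_gam, 1))
    if p > 1:
        switches = rng.random((n_gam, p - 1)) < r[None, :]
        parity = np.cumsum(switches, axis=1) & 1
        alleles = np.concatenate([start, start ^ parity], axis=1)
    else:
        alleles = start
    dosages = alleles[0::2] + alleles[1::2]
    line_ids = [f"{line_prefix}{i + 1:04d}" for i in range(n)]
    marker_ids = [f"m{j + 1}" for j in range(p)]
    return GenotypeMatrix(line_ids, marker_ids, dosages)


def _term_matrix(spec: TraitSimulationSpec, dosages: np.ndarray):
    """Centered additive columns and centered-product epistatic columns."""
    Xc = dosages - dosages.mean(axis=0, keepdims=True)
    cols, labels, targets = [], [], []
    for j, f in spec.additive_qtl:
        cols.append(Xc[:, j])
        labels.append(f"add:m{j + 1}")
        targets.append(f)
    for i, j, f in spec.epistatic_pairs:
        cols.append(Xc[:, i] * Xc[:, j])
        labels.append(f"epi:m{i + 1}:m{j + 1}")
        targets.append(f)
    return np.column_stack(cols), labels, np.asarray(targets, dtype=float)


def calibrate_effects(
    spec: TraitSimulationSpec,
    genotypes: GenotypeMatrix,
    rel_tol: float = 0.10,
    max_iter: int = 100,
):
    """Scale each QTL coefficient so its term realizes its target fraction.

    The phenotypic variance is taken as var(sum of terms)/(1 - residual
    fraction), which is self-consistent with drawing the residual at the
    residual fraction.  Because terms can covary (linked loci), coefficients
    are rescaled iteratively until every realized fraction is within
    ``rel_tol`` relative error of its target.

    Returns (coefficients, term matrix, labels, realized fractions, Vy).
    """
    for j, _ in spec.additive_qtl:
        if not 0 <= j < genotypes.n_markers:
            raise IndexError(f"additive QTL marker index {j} out of range")
    for i, j, _ in spec.epistatic_pairs:
        if not (0 <= i < genotypes.n_markers and 0 <= j < genotypes.n_markers):
            raise IndexError(f"epistatic pair ({i},{j}) out of range")
    T, labels, targets = _term_matrix(spec, genotypes.dosages.astype(float))
    term_var = T.var(axis=0)
    if np.any(term_var <= 0):
        bad = labels[int(np.argmin(term_var))]
        raise ValueError(f"QTL term {bad} has zero variance (monomorphic locus?)")

    f_res = spec.residual_fraction
    beta = np.sqrt(targets / term_var)  # start as if terms were orthogonal, Vy = 1
    realized = np.full_like(targets, np.nan)
    for _ in range(max_iter):
        g = T @ beta
        vy = g.var() / (1.0 - f_res)
        realized = beta**2 * term_var / vy
        if np.all(np.abs(realized / targets - 1.0) <= rel_tol):
            break
        beta = np.sqrt(targets * vy / term_var)
    return beta, T, labels, realized, vy


def simulate_dataset(spec: TraitSimulationSpec, seed=None) -> SimulatedDataset:
    """Genotypes + calibrated epistatic trait in one call.

    ``seed`` overrides ``spec.seed`` when given.  Alternate coefficient signs
    are applied after calibration (signs do not change variances).
    """
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    geno_seed, noise_seed = ss.spawn(2)
    geno = simulate_genotypes(spec.n_individuals, spec.marker_positions, seed=geno_seed)
    f_res = spec.residual_fraction
    if spec.additive_qtl or spec.epistatic_pairs:
        beta, T, labels, realized, _ = calibrate_effects(spec, geno)
        signs = np.where(np.arange(beta.size) % 2 == 0, 1.0, -1.0)
        beta = beta * signs
        g = T @ beta
        # residual drawn at the residual fraction of the signed-term variance
        vy = g.var() / (1.0 - f_res)
        realized = beta**2 * T.var(axis=0) / vy
    else:
        beta = np.array([])
        labels, realized = [], np.array([])
        vy = 1.0
        g = np.zeros(spec.n_individuals)
    rng = np.random.default_rng(noise_seed)
    eps = rng.standard_normal(spec.n_individuals) * np.sqrt(f_res * vy)
    y = g + eps
    return SimulatedDataset(
        genotypes=geno,
        phenotypes=y,
        genetic_values=g,
        spec=spec,
        effects=dict(zip(labels, np.atleast_1d(beta))),
        realized_fractions=dict(zip(labels, np.atleast_1d(realized))),
    )


def expand_interactions(
    genotypes, include_main: bool = False, coding: str = "raw"
) -> CovariateMatrix:
    """All p(p+1)/2 unordered marker-by-marker products x_j * x_j' (j <= j').

    With the default ``coding="raw"`` the products are taken on the dosage
    codes themselves; diagonal pairs (j = j') give squared dosages, so
    values lie in {0,1,2,4}.  ``coding="centered"`` multiplies mean-centered
    dosages instead, which makes the interaction covariates (nearly)
    orthogonal to the marker main effects — raw products carry a large
    main-effect component because cov(x_i x_j, x_i) != 0.  Column ids are
    "mJ:mJ'".  With ``include_main`` the original p columns (always raw)
    are prepended, giving p + p(p+1)/2 columns in total.
    """
    if coding not in ("raw", "centered"):
        raise ValueError("coding must be 'raw' or 'centered'")
    X = np.asarray(genotypes.values, dtype=np.int16 if coding == "raw" else float)
    ids = genotypes.column_ids
    n, p = X.shape
    if p < 1:
        raise ValueError("need at least one marker")
    blocks, labels = [], []
    if include_main:
        blocks.append(X)
        labels.extend(ids)
    P = X if coding == "raw" else X - X.mean(axis=0, keepdims=True)
    for j in range(p):
        blocks.append(P[:, j : j + 1] * P[:, j:])
        labels.extend(f"{ids[j]}:{ids[k]}" for k in range(j, p))
    return CovariateMatrix(list(genotypes.line_ids), labels, np.concatenate(blocks, axis=1))


def epistatic_benchmark_spec(n_individuals: int = 600, seed: int = 0) -> TraitSimulationSpec:
    """Preset emulating the epistatic benchmark trait.

    One 1,800 cM chromosome, 121 markers at 15 cM, 600 individuals.  Nine
    additive QTL sit on evenly spread markers with variance fractions
    log-spaced from 0.75% to 17% (sum ~0.51); the 13 QTL-by-QTL interactions
    pair loci among those same nine QTL, with fractions log-spaced from 0.5%
    to 10% (sum ~0.44), leaving a residual fraction of ~0.05.  Every per-QTL
    fraction respects the 0.5-20% range.  The high heritability and the
    placement of interactions on loci that also carry main effects are what
    let distance-based kernel methods pick up the epistatic signal: the
    non-additive part of the genetic value is then a function of a few
    coordinates that already dominate genetic distance, and the residual
    noise is small enough for local basis functions to generalize.
    """
    additive_idx = [4, 18, 32, 46, 60, 74, 88, 102, 116]
    pairs = [
        (4, 18), (4, 60), (4, 116), (18, 46), (18, 88), (32, 60), (32, 102),
        (46, 74), (46, 116), (60, 88), (74, 102), (88, 116), (32, 74),
    ]
    add_frac = np.geomspace(0.0075, 0.17, 9)
    epi_frac = np.geomspace(0.005, 0.10, 13)
    return TraitSimulationSpec(
        n_individuals=n_individuals,
        chromosome_length=1800.0,
        marker_spacing=15.0,
        additive_qtl=[(int(j), float(f)) for j, f in zip(additive_idx, add_frac)],
        epistatic_pairs=[(i, j, float(f)) for (i, j), f in zip(pairs, epi_frac)],
        seed=seed,
    )
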