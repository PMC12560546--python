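"""Seeded F2 simulator with Haldane (no-interference) crossovers.

Each F2 individual is the union of two independent gametes from a fully
heterozygous F1: per chromosome, the crossover count is Poisson with mean
length/100 cM (one expected crossover per Morgan), crossover positions are
uniform, and the starting parental origin is a or b with probability 1/2.
Adjacent-marker recombinant fractions therefore follow the Haldane map
function r = (1 - exp(-2d))/2, and per-marker genotypes segregate 1:2:1
(A:H:B).  Markers are equidistant at positions (i + 0.5)/m * L, keeping
them off the chromosome ends.

Phase is exact by construction, so simulated data can validate
recombination counting against the known crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import GenotypeMatrix, MarkerMap
from .scoring import A, B, H, MISSING


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome: name, genetic length (cM), marker count."""

    name: str
    length_cm: float
    n_markers: int

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ValueError("chromosome length must be > 0 cM")
        if self.n_markers < 1:
            raise ValueError("marker count must be >= 1")

    def marker_positions(self) -> np.ndarray:
        """Equidistant positions (i + 0.5)/m * L, i = 0..m-1, in cM."""
        m = self.n_markers
        return (np.arange(m) + 0.5) / m * self.length_cm


@dataclass(frozen=True)
class SimConfig:
    """Genetic map and population parameters for one F2 simulation."""

    chromosomes: tuple[ChromosomeSpec, ...]
    n_individuals: int
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")


def default_config(
    n_individuals: int,
    n_chromosomes: int = 10,
    length_cm: float = 100.0,
    markers_per_chromosome: int = 50,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimConfig:
    """Uniform-genome convenience constructor (chr01..chrNN)."""
    chroms = tuple(
        ChromosomeSpec(f"chr{i + 1:02d}", length_cm, markers_per_chromosome)
        for i in range(n_chromosomes)
    )
    return SimConfig(chroms, n_individuals, missing_rate, seed)


def simulate_gamete(
    chrom_length_cm: float,
    marker_positions_cm: Sequence[float] | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete's parental-origin sequence (0 = a, 1 = b) at the markers.

    Crossovers: Poisson(length/100), positions uniform, starting origin
    Bernoulli(1/2); the origin flips at every crossover.
    """
    return _simulate_gametes(chrom_length_cm,
                             np.asarray(marker_positions_cm, dtype=float),
                             1, rng)[0]


def _simulate_gametes(
    length_cm: float, positions: np.ndarray, n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised gamete origins, shape (n_gametes, n_markers), values {0,1}."""
    if positions.size and (positions.min() < 0 or positions.max() > length_cm):
        raise ValueError("marker positions must lie within [0, length]")
    n_xo = rng.poisson(length_cm / 100.0, size=n_gametes)
    start = rng.integers(0, 2, size=n_gametes, dtype=np.uint8)
    k_max = int(n_xo.max()) if n_gametes else 0
    if k_max == 0:
        return np.repeat(start[:, None], positions.size, axis=1)
    # Crossover positions as a padded matrix; padding sits beyond the
    # chromosome end so it never flips any marker.
    xo = rng.uniform(0.0, length_cm, size=(n_gametes, k_max))
    pad = np.arange(k_max)[None, :] >= n_xo[:, None]
    xo[pad] = length_cm + 1.0
    out = np.empty((n_gametes, positions.size), dtype=np.uint8)
    for j, pos in enumerate(positions):
        flips = (xo < pos).sum(axis=1)
        out[:, j] = (start + flips) % 2
    return out


def simulate_f2(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, MarkerMap, tuple[np.ndarray, np.ndarray]]:
    """Simulate an F2 population from a fully heterozygous F1.

    Returns the ABH genotype matrix, the marker map (chromosomes
    contiguous, in config order) and the two phased haplotype matrices
    (parental origins, 0 = a / 1 = b).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    hap1_parts: list[np.ndarray] = []
    hap2_parts: list[np.ndarray] = []
    entries: list[tuple[str, str]] = []
    for chrom in cfg.chromosomes:
        pos = chrom.marker_positions()
        hap1_parts.append(_simulate_gametes(chrom.length_cm, pos, n, rng))
        hap2_parts.append(_simulate_gametes(chrom.length_cm, pos, n, rng))
        entries.extend(
            (chrom.name, f"{chrom.name}_m{i + 1:03d}")
            for i in range(chrom.n_markers)
        )
    hap1 = np.concatenate(hap1_parts, axis=1)
    hap2 = np.concatenate(hap2_parts, axis=1)
    dosage = hap1.astype(np.int16) + hap2  # 0, 1, 2 copies of allele b
    codes = np.full(dosage.shape, H, dtype=np.uint8)
    codes[dosage == 0] = A
    codes[dosage == 2] = B
    ids = [f"sim{i + 1:05d}" for i in range(n)]
    gm = GenotypeMatrix(ids, [m for _, m in entries], codes)
    if cfg.missing_rate > 0:
        gm = inject_missing(gm, cfg.missing_rate, rng)
    return gm, MarkerMap(entries), (hap1, hap2)


def inject_missing(
    gm: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    """Independently blank each cell to '-' with probability *rate*."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    codes = gm.codes.copy()
    if rate > 0:
        mask = rng.random(codes.shape) < rate
        codes[mask] = MISSING
    return GenotypeMatrix(list(gm.individual_ids), list(gm.marker_ids), codes)
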