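"""Synthetic spatial transcriptomics generator.

Produces hexagonal-offset spot lattices with planted laminar domains,
domain-specific marker programs, ubiquitous high-expression housekeeping
genes, and negative-binomial counts with log-normal library-size
variation — the test substrate for the rest of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .core_io import SpatialDataset

HOUSEKEEPING_FACTOR = 10.0  # housekeeping mean relative to baseline


@dataclass
class SimConfig:
    n_rows: int = 30
    n_cols: int = 30
    n_domains: int = 4
    n_genes: int = 200
    n_markers_per_domain: int = 20
    n_housekeeping: int = 20
    marker_log2_fc: float = 2.0
    baseline_mean: float = 5.0
    dispersion: float = 10.0  # negative-binomial shape (larger = less noise)
    libsize_sigma: float = 0.2
    curvature: float = 0.0  # sine amplitude warping domain boundaries
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.marker_log2_fc < 0:
            raise ValueError("effect size must be non-negative")
        if self.n_markers_per_domain * self.n_domains + self.n_housekeeping > self.n_genes:
            raise ValueError("marker + housekeeping genes exceed n_genes")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be positive")


def hex_lattice(n_rows: int, n_cols: int) -> np.ndarray:
    """Hexagonal offset lattice: odd rows shifted by 0.5, rows sqrt(3)/2 apart."""
    coords = np.empty((n_rows * n_cols, 2))
    i = 0
    for row in range(n_rows):
        for col in range(n_cols):
            coords[i] = (col + 0.5 * (row % 2), row * math.sqrt(3.0) / 2.0)
            i += 1
    return coords


def _domain_of(coords: np.ndarray, config: SimConfig) -> np.ndarray:
    y = coords[:, 1].copy()
    if config.curvature:
        width = coords[:, 0].max() - coords[:, 0].min() + 1e-12
        y = y + config.curvature * np.sin(2 * np.pi * coords[:, 0] / width)
    lo, hi = y.min(), y.max()
    frac = (y - lo) / (hi - lo + 1e-12)
    return np.minimum((frac * config.n_domains).astype(int), config.n_domains - 1)


def simulate_tissue(config: SimConfig) -> SpatialDataset:
    """Simulate a laminar tissue section; truth labels are the planted bands.

    Counts are negative binomial with mean
    baseline * 2^(log2_fc if marker-in-domain) * library factor; the
    designated housekeeping genes have mean 10x baseline in every domain.
    Gene roles are encoded in gene_ids prefixes (marker{d}_, hk_, noise_).
    """
    rng = np.random.default_rng(config.seed)
    coords = hex_lattice(config.n_rows, config.n_cols)
    n = coords.shape[0]
    domains = _domain_of(coords, config)

    p = config.n_genes
    gene_ids = []
    mean = np.full((n, p), config.baseline_mean)
    g = 0
    for d in range(config.n_domains):
        for j in range(config.n_markers_per_domain):
            gene_ids.append(f"marker{d}_{j}")
            mean[domains == d, g] *= 2.0**config.marker_log2_fc
            g += 1
    for j in range(config.n_housekeeping):
        gene_ids.append(f"hk_{j}")
        mean[:, g] *= HOUSEKEEPING_FACTOR
        g += 1
    for j in range(p - g):
        gene_ids.append(f"noise_{j}")

    lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=n))
    mu = mean * lib[:, None]
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    spot_ids = [f"s{i:04d}" for i in range(n)]
    return SpatialDataset(
        counts=counts,
        coords=coords,
        spot_ids=spot_ids,
        gene_ids=gene_ids,
        truth_labels=domains,
    )


def gene_roles(dataset: SpatialDataset) -> Dict[str, np.ndarray]:
    """Index arrays for marker / housekeeping / noise genes of a simulation."""
    ids = dataset.gene_ids
    return {
        "marker": np.array([i for i, g in enumerate(ids) if g.startswith("marker")]),
        "housekeeping": np.array([i for i, g in enumerate(ids) if g.startswith("hk_")]),
        "noise": np.array([i for i, g in enumerate(ids) if g.startswith("noise_")]),
    }


def make_candidate_labelings(
    dataset: SpatialDataset, qualities: Sequence[float], seed: int = 0
) -> Dict[str, np.ndarray]:
    """Corrupt the truth labels at the given rates for ensemble tests.

    For each rate rho, a fraction rho of spots is relabeled uniformly at
    random over the observed label set.
    """
    if dataset.truth_labels is None:
        raise ValueError("dataset has no truth labels")
    truth = np.asarray(dataset.truth_labels)
    classes = np.unique(truth)
    rng = np.random.default_rng(seed)
    out = {}
    for rho in qualities:
        if not (0.0 <= rho <= 1.0):
            raise ValueError(f"corruption rate {rho} outside [0, 1]")
        labels = truth.copy()
        n_flip = int(round(rho * len(truth)))
        idx = rng.choice(len(truth), size=n_flip, replace=False)
        labels[idx] = rng.choice(classes, size=n_flip)
        out[f"corrupt_{rho:g}"] = labels
    return out
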