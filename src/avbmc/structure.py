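"""Structural diagnostics for cluster and bulk configurations.

Coordination-number histograms (surface particles = coordination < 9),
the global Steinhardt Q6 bond-orientational order parameter, and the
distribution of particle displacements from their assigned lattice sites.
The neighbor definition everywhere is a plain distance cutoff (default
1.5 sigma, around the first minimum of the LJ pair correlation); reports
carry the cutoff used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .lattice import FccLattice, SiteOccupancy
from .model_core import ParticleConfig

DEFAULT_NEIGHBOR_CUTOFF = 1.5
SURFACE_COORDINATION = 9
DISPLACEMENT_BIN_WIDTH = 0.005


@dataclass
class StructureReport:
    coordination: np.ndarray        # fraction of particles per coordination
    surface_count: int
    q6: float
    neighbor_cutoff: float
    displacement_bins: np.ndarray | None = None
    displacement_density: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.q6 <= 1.0 + 1e-9:
            raise ValueError("q6 out of [0, 1]")


def _pair_displacements(config: ParticleConfig) -> np.ndarray:
    pos = config.positions
    d = pos[:, None, :] - pos[None, :, :]
    if config.mode == "bulk":
        box = config.box_length
        d -= box * np.rint(d / box)
    return d


def coordination_numbers(config: ParticleConfig,
                         neighbor_cutoff: float = DEFAULT_NEIGHBOR_CUTOFF
                         ) -> np.ndarray:
    if neighbor_cutoff <= 0:
        raise ValueError("neighbor_cutoff must be > 0")
    d = _pair_displacements(config)
    r2 = np.sum(d * d, axis=-1)
    np.fill_diagonal(r2, np.inf)
    return (r2 < neighbor_cutoff ** 2).sum(axis=1)


def coordination_histogram(config: ParticleConfig,
                           neighbor_cutoff: float = DEFAULT_NEIGHBOR_CUTOFF
                           ) -> tuple[np.ndarray, int]:
    """Fractions per integer coordination, and the surface-particle count.

    Surface particles are those with fewer than 9 neighbors.
    """
    cn = coordination_numbers(config, neighbor_cutoff)
    hist = np.bincount(cn) / config.n
    surface = int(np.sum(cn < SURFACE_COORDINATION))
    return hist, surface


def q6_global(config: ParticleConfig,
              neighbor_cutoff: float = DEFAULT_NEIGHBOR_CUTOFF) -> float:
    """Global Steinhardt Q6 averaged over all neighbor bonds.

        Q6 = sqrt( (4 pi / 13) sum_m | <Y_6m> |^2 ),

    the average running over every neighbor pair (bond) in the
    configuration, both bond directions included (|Y_6m| is insensitive
    to the choice since l is even).
    """
    d = _pair_displacements(config)
    r2 = np.sum(d * d, axis=-1)
    iu = np.triu_indices(config.n, k=1)
    mask = r2[iu] < neighbor_cutoff ** 2
    bonds = d[iu[0][mask], iu[1][mask]]
    if len(bonds) == 0:
        raise ValueError("no neighbor bonds: Q6 undefined")
    r = np.linalg.norm(bonds, axis=1)
    theta = np.arccos(np.clip(bonds[:, 2] / r, -1.0, 1.0))  # polar
    phi = np.arctan2(bonds[:, 1], bonds[:, 0])              # azimuth
    acc = 0.0
    for m in range(-6, 7):
        ylm = sph_harm_y(6, m, theta, phi)
        acc += np.abs(ylm.mean()) ** 2
    return float(np.sqrt(4.0 * np.pi / 13.0 * acc))


def site_displacement_histogram(config: ParticleConfig, occ: SiteOccupancy,
                                lattice: FccLattice,
                                bin_width: float = DISPLACEMENT_BIN_WIDTH
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Unit-area histogram of |x_i - site_i|; returns (bin_edges, density)."""
    if occ.n != config.n:
        raise ValueError("every particle needs an assigned site")
    dists = np.array([
        np.linalg.norm(config.positions[p]
                       - lattice.site_position(occ.site_of(p)))
        for p in occ.particles()])
    top = max(dists.max(), bin_width)
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    density, edges = np.histogram(dists, bins=edges, density=True)
    return edges, density


def structure_report(config: ParticleConfig,
                     neighbor_cutoff: float = DEFAULT_NEIGHBOR_CUTOFF,
                     occ: SiteOccupancy | None = None,
                     lattice: FccLattice | None = None) -> StructureReport:
    hist, surface = coordination_histogram(config, neighbor_cutoff)
    q6 = q6_global(config, neighbor_cutoff)
    edges = density = None
    if occ is not None and lattice is not None:
        edges, density = site_displacement_histogram(config, occ, lattice)
    return StructureReport(hist, surface, q6, neighbor_cutoff, edges, density)
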