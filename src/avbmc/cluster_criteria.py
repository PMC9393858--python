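"""Cluster membership criteria.

Liquid clusters use the Stillinger definition: the graph on particles with
edges at pair distance < R must be connected.  Solid clusters require (a)
every particle within r of its assigned lattice site (<= r, boundary
included) and (b) the occupied-site graph, with edges between FCC
nearest-neighbor sites, connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .lattice import NEIGHBOR_DELTAS, FccLattice, SiteOccupancy
from .model_core import ParticleConfig


@dataclass(frozen=True)
class LiquidClusterParams:
    """Stillinger radius; also the insertion radius of the original AVBMC."""

    R: float

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError("R must be > 0")


@dataclass(frozen=True)
class SolidClusterParams:
    r: float

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("r must be > 0")

    def warn_if_large(self, spacing: float) -> None:
        if self.r > spacing / 2:
            warnings.warn(
                f"site radius r={self.r} exceeds spacing/2={spacing / 2:.4f}; "
                "insertion spheres of adjacent sites overlap", stacklevel=2)


def liquid_cluster_ok(config: ParticleConfig,
                      params: LiquidClusterParams) -> bool:
    """True iff all particles form a single Stillinger cluster (N<=1: True)."""
    if config.mode != "cluster":
        raise ValueError("liquid cluster criterion needs a cluster-mode config")
    n = config.n
    if n <= 1:
        return True
    return bool(K.liquid_connected(config.positions, n, -1, params.R ** 2))


def liquid_cluster_ok_without(positions: np.ndarray, n: int, skip: int,
                              R: float) -> bool:
    """Connectivity of the cluster with particle `skip` removed."""
    return bool(K.liquid_connected(positions, n, skip, R ** 2))


def solid_sites_connected(occ: SiteOccupancy, skip_site: int | None = None) -> bool:
    keys = occ.occupied_sites()
    if skip_site is not None:
        keys = keys[keys != skip_site]
    return bool(K.solid_connected(keys, NEIGHBOR_DELTAS))


def solid_cluster_ok(config: ParticleConfig, occ: SiteOccupancy,
                     lattice: FccLattice, params: SolidClusterParams) -> bool:
    """Both solid conditions: site binding (<= r) and site-graph connectivity."""
    if occ.n != config.n:
        raise ValueError("every particle needs an assigned site")
    for p in occ.particles():
        site_pos = lattice.site_position(occ.site_of(p))
        d = np.linalg.norm(config.positions[p] - site_pos)
        if d > params.r:
            return False
    return solid_sites_connected(occ)
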