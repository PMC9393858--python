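"""Lennard-Jones energetics for open clusters and periodic bulk systems.

Reduced units throughout: lengths in sigma, energies in epsilon, k_B = 1.
Cluster configurations include all pair interactions (no cutoff, no box);
bulk configurations use a spherical cutoff with the minimum-image
convention and optional analytical mean-field tail corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels as K

logger = logging.getLogger("avbmc")

#: squared-distance threshold below which two particles count as overlapping
OVERLAP_R2 = 1e-12


@dataclass(frozen=True)
class PairPotentialSpec:
    """12-6 Lennard-Jones parameters and truncation scheme.

    ``cutoff`` must be absent for cluster-mode energies and present for
    bulk-mode energies; ``tail_corrections`` only applies with a cutoff.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    cutoff: float | None = None
    tail_corrections: bool = False

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.cutoff is not None and self.cutoff <= self.sigma:
            raise ValueError("cutoff must exceed sigma")
        if self.tail_corrections and self.cutoff is None:
            raise ValueError("tail corrections require a cutoff")


@dataclass
class ParticleConfig:
    """N particle coordinates, either an open-space cluster or a periodic box."""

    positions: np.ndarray
    box_length: float | None = None
    mode: str = "cluster"

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.mode == "bulk":
            if self.box_length is None or self.box_length <= 0:
                raise ValueError("bulk mode requires a positive box_length")
            self.positions %= self.box_length
        elif self.mode == "cluster":
            if self.box_length is not None:
                raise ValueError("cluster mode forbids box_length")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def density(self) -> float:
        if self.mode != "bulk":
            raise ValueError("density defined only for bulk configurations")
        return self.n / self.box_length ** 3


@dataclass
class MoveProposal:
    """Outcome record of one attempted Monte Carlo move."""

    kind: str
    delta_E: float
    accepted: bool


# -- proposed configuration changes -----------------------------------------

@dataclass(frozen=True)
class Insertion:
    position: np.ndarray


@dataclass(frozen=True)
class Deletion:
    index: int


@dataclass(frozen=True)
class Displacement:
    index: int
    new_position: np.ndarray


def pair_energy(r: float, spec: PairPotentialSpec) -> float:
    """u(r) = 4 eps [(sig/r)^12 - (sig/r)^6]; zero beyond the cutoff."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if spec.cutoff is not None and r > spec.cutoff:
        return 0.0
    sr6 = (spec.sigma / r) ** 6
    return 4.0 * spec.epsilon * (sr6 * sr6 - sr6)


def _check_mode(config: ParticleConfig, spec: PairPotentialSpec) -> None:
    if config.mode == "cluster" and spec.cutoff is not None:
        raise ValueError("cluster-mode energies use no cutoff")
    if config.mode == "bulk":
        if spec.cutoff is None:
            raise ValueError("bulk mode requires a cutoff")
        if config.box_length < 2.0 * spec.cutoff:
            raise ValueError(
                f"box_length {config.box_length:.4f} violates the "
                f"minimum-image requirement box >= 2*cutoff = {2 * spec.cutoff:.4f}"
            )


def total_energy(config: ParticleConfig, spec: PairPotentialSpec) -> float:
    """Sum of pair energies over all unordered pairs (plus bulk tail term)."""
    _check_mode(config, spec)
    n = config.n
    if n < 2:
        return 0.0
    sig2 = spec.sigma ** 2
    if config.mode == "cluster":
        e, mr2 = K.total_energy_cluster(config.positions, n, spec.epsilon, sig2)
    else:
        e, mr2 = K.total_energy_bulk(config.positions, n, config.box_length,
                                     spec.cutoff ** 2, spec.epsilon, sig2)
        if spec.tail_corrections:
            e += K.tail_energy_total(n, config.box_length ** 3, spec.cutoff,
                                     spec.epsilon, spec.sigma)
    if mr2 < OVERLAP_R2:
        raise ValueError("overlapping particle coordinates")
    return e


def particle_energy(config: ParticleConfig, position: np.ndarray,
                    spec: PairPotentialSpec, skip: int = -1) -> float:
    """Interaction energy of one test position with all particles but `skip`."""
    _check_mode(config, spec)
    x, y, z = (float(v) for v in position)
    sig2 = spec.sigma ** 2
    if config.mode == "cluster":
        return K.particle_energy_cluster(config.positions, config.n, skip,
                                         x, y, z, spec.epsilon, sig2)
    return K.particle_energy_bulk(config.positions, config.n, skip, x, y, z,
                                  config.box_length, spec.cutoff ** 2,
                                  spec.epsilon, sig2)


def delta_energy(config: ParticleConfig,
                 change: Insertion | Deletion | Displacement,
                 spec: PairPotentialSpec) -> float:
    """Incremental energy change of one insertion/deletion/displacement.

    Only pairs involving the changed particle are evaluated, so the cost is
    O(N); equals total_energy(after) - total_energy(before) up to roundoff.
    Tail corrections (fixed N, V) cancel for displacements; insertions and
    deletions into bulk boxes are not supported here.
    """
    if isinstance(change, Insertion):
        if config.mode == "bulk":
            raise ValueError("grand-canonical changes are cluster-mode only")
        return particle_energy(config, change.position, spec)
    if isinstance(change, Deletion):
        if not 0 <= change.index < config.n:
            raise IndexError("deletion index out of range")
        if config.mode == "bulk":
            raise ValueError("grand-canonical changes are cluster-mode only")
        xi = config.positions[change.index]
        return -particle_energy(config, xi, spec, skip=change.index)
    if isinstance(change, Displacement):
        if not 0 <= change.index < config.n:
            raise IndexError("displacement index out of range")
        old = particle_energy(config, config.positions[change.index], spec,
                              skip=change.index)
        new = particle_energy(config, change.new_position, spec,
                              skip=change.index)
        return new - old
    raise TypeError(f"unsupported change {change!r}")


def tail_correction(density: float, cutoff: float,
                    spec: PairPotentialSpec) -> tuple[float, float]:
    """Mean-field long-range corrections beyond the cutoff.

    Returns (energy per particle, pressure correction) assuming g(r)=1 for
    r > cutoff:

        u_tail = (8/3) pi rho eps sig^3 [ (1/3)(sig/rc)^9 - (sig/rc)^3 ]
        p_tail = (16/3) pi rho^2 eps sig^3 [ (2/3)(sig/rc)^9 - (sig/rc)^3 ]
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    sr3 = (spec.sigma / cutoff) ** 3
    sr9 = sr3 ** 3
    pref = np.pi * spec.epsilon * spec.sigma ** 3
    u = (8.0 / 3.0) * pref * density * (sr9 / 3.0 - sr3)
    p = (16.0 / 3.0) * pref * density ** 2 * ((2.0 / 3.0) * sr9 - sr3)
    return u, p


# ---------------------------------------------------------------------------
# XYZ serialization
# ---------------------------------------------------------------------------

_ELEMENT = "LJ"


def write_xyz(path: str | Path, config: ParticleConfig, append: bool = False) -> None:
    """Plain XYZ with mode/box recorded on the comment line."""
    comment = f"mode={config.mode}"
    if config.box_length is not None:
        comment += f" box_length={config.box_length:.12g}"
    lines = [str(config.n), comment]
    for p in config.positions:
        lines.append(f"{_ELEMENT} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
    with open(path, "a" if append else "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> ParticleConfig:
    with open(path) as fh:
        n = int(fh.readline())
        comment = fh.readline().split()
        meta = dict(tok.split("=", 1) for tok in comment if "=" in tok)
        pos = np.empty((n, 3))
        for i in range(n):
            parts = fh.readline().split()
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
    mode = meta.get("mode", "cluster")
    box = float(meta["box_length"]) if "box_length" in meta else None
    return ParticleConfig(pos, box_length=box, mode=mode)
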