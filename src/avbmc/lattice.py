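"""FCC lattice geometry and particle<->site occupancy bookkeeping.

Sites live on the even sublattice of a half-cell cubic grid: integer
triples (i, j, k) with i + j + k even, at coordinates origin + (a/2)(i,j,k)
where a = spacing * sqrt(2) is the conventional cubic cell edge.  Each site
id is the triple packed into one int64, so ids are intrinsic to the
geometry: generating more of the lattice can never renumber a site, and
addition of a packed neighbor offset yields the packed neighbor id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_SHIFT = 21
_BIAS = 1 << 20
_MASK = (1 << _SHIFT) - 1

# the 12 FCC nearest-neighbor offsets in half-cell units
NEIGHBOR_TRIPLES = np.array(
    [(di, dj, dk)
     for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
     if abs(di) + abs(dj) + abs(dk) == 2],
    dtype=np.int64,
)


def pack_site(i: int, j: int, k: int) -> int:
    """Pack a half-cell triple into one int64 site id."""
    return (((int(i) + _BIAS) << (2 * _SHIFT))
            | ((int(j) + _BIAS) << _SHIFT)
            | (int(k) + _BIAS))


def unpack_site(key: int) -> tuple[int, int, int]:
    return ((int(key) >> (2 * _SHIFT)) - _BIAS,
            ((int(key) >> _SHIFT) & _MASK) - _BIAS,
            (int(key) & _MASK) - _BIAS)


#: packed neighbor offsets; adding one to a packed id gives the neighbor id
#: (arithmetic, not bitwise: components may be negative)
NEIGHBOR_DELTAS = np.array(
    [int(di) * (1 << (2 * _SHIFT)) + int(dj) * (1 << _SHIFT) + int(dk)
     for di, dj, dk in NEIGHBOR_TRIPLES],
    dtype=np.int64,
)


@dataclass
class FccLattice:
    """Face-centered cubic site geometry with on-demand replication."""

    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    generated_extent: float = 0.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        self.origin = np.asarray(self.origin, dtype=np.float64)

    @property
    def cell_edge(self) -> float:
        """Conventional 4-atom cubic cell edge a = spacing * sqrt(2)."""
        return self.spacing * math.sqrt(2.0)

    def site_position(self, key: int) -> np.ndarray:
        i, j, k = unpack_site(key)
        return self.origin + 0.5 * self.cell_edge * np.array([i, j, k], float)

    def site_positions(self, keys: np.ndarray) -> np.ndarray:
        keys = np.asarray(keys, dtype=np.int64)
        ijk = np.stack([(keys >> (2 * _SHIFT)) - _BIAS,
                        ((keys >> _SHIFT) & _MASK) - _BIAS,
                        (keys & _MASK) - _BIAS], axis=1).astype(np.float64)
        return self.origin + 0.5 * self.cell_edge * ijk

    def generate_sites(self, required_extent: float) -> np.ndarray:
        """All site ids within `required_extent` of the origin.

        Deterministic (sorted by packed id, i.e. lexicographic in the
        triple) and stable: a later call with a larger extent returns a
        superset in which earlier ids are unchanged.
        """
        if required_extent < 0:
            raise ValueError("required_extent must be >= 0")
        half = 0.5 * self.cell_edge
        m = int(math.floor(required_extent / half)) + 1
        rng = np.arange(-m, m + 1)
        ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
        mask = (ii + jj + kk) % 2 == 0
        ii, jj, kk = ii[mask], jj[mask], kk[mask]
        r2 = (ii * ii + jj * jj + kk * kk) * half * half
        keep = r2 <= required_extent ** 2 + 1e-12
        keys = ((ii[keep] + _BIAS).astype(np.int64) << (2 * _SHIFT)) \
            | ((jj[keep] + _BIAS).astype(np.int64) << _SHIFT) \
            | (kk[keep] + _BIAS).astype(np.int64)
        self.generated_extent = max(self.generated_extent, required_extent)
        return np.sort(keys)

    def site_neighbors(self, key: int) -> np.ndarray:
        """The 12 nearest-neighbor site ids (distance = spacing)."""
        return np.int64(key) + NEIGHBOR_DELTAS

    def nearest_site(self, position: np.ndarray) -> int:
        """Packed id of the site closest to `position` (lowest id on ties)."""
        x = (np.asarray(position, float) - self.origin) / (0.5 * self.cell_edge)
        base = np.floor(x).astype(np.int64)
        best, best_d2 = None, np.inf
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    t = base + (di, dj, dk)
                    if (t[0] + t[1] + t[2]) % 2:
                        continue
                    d2 = float(np.sum((x - t) ** 2))
                    k = pack_site(*t)
                    if d2 < best_d2 - 1e-12 or (abs(d2 - best_d2) <= 1e-12
                                                and (best is None or k < best)):
                        best, best_d2 = k, d2
        # the 2x2x2 corner block always contains >= 4 even-parity sites
        return int(best)


class SiteOccupancy:
    """Bidirectional particle <-> site assignment ("one particle per site")."""

    def __init__(self):
        self._site_of: dict[int, int] = {}
        self._particle_of: dict[int, int] = {}

    @property
    def n(self) -> int:
        return len(self._site_of)

    def assign(self, particle: int, site: int) -> None:
        if site in self._particle_of:
            raise ValueError(f"site {site} already occupied")
        if particle in self._site_of:
            raise ValueError(f"particle {particle} already assigned")
        self._site_of[particle] = site
        self._particle_of[site] = particle

    def release(self, particle: int) -> int:
        site = self._site_of.pop(particle)
        del self._particle_of[site]
        return site

    def relabel(self, old: int, new: int) -> None:
        """Rename a particle index (used when deletions compact storage)."""
        site = self._site_of.pop(old)
        self._site_of[new] = site
        self._particle_of[site] = new

    def site_of(self, particle: int) -> int:
        try:
            return self._site_of[particle]
        except KeyError:
            raise KeyError(f"particle {particle} has no assigned site") from None

    def particle_at(self, site: int) -> int | None:
        return self._particle_of.get(site)

    def is_vacant(self, site: int) -> bool:
        return site not in self._particle_of

    def occupied_sites(self) -> np.ndarray:
        return np.sort(np.fromiter(self._particle_of.keys(), dtype=np.int64,
                                   count=len(self._particle_of)))

    def particles(self):
        return self._site_of.keys()

    def audit(self) -> None:
        """Verify the two maps are mutual inverses."""
        if len(self._site_of) != len(self._particle_of):
            raise AssertionError("occupancy maps differ in size")
        for p, s in self._site_of.items():
            if self._particle_of.get(s) != p:
                raise AssertionError(f"maps disagree on particle {p} / site {s}")


def vacant_neighbor_sites(j: int, occ: SiteOccupancy,
                          lattice: FccLattice) -> np.ndarray:
    """Vacant sites among the 12 neighbors of particle j's site (N_vac)."""
    nbrs = lattice.site_neighbors(occ.site_of(j))
    return np.array([s for s in nbrs if occ.is_vacant(int(s))], dtype=np.int64)


def occupied_neighbor_particles(j: int, occ: SiteOccupancy,
                                lattice: FccLattice) -> np.ndarray:
    """Particles on sites adjacent to particle j's site (N_in)."""
    nbrs = lattice.site_neighbors(occ.site_of(j))
    out = [occ.particle_at(int(s)) for s in nbrs]
    return np.array([p for p in out if p is not None], dtype=np.int64)


def write_occupancy_tsv(path, occ: SiteOccupancy) -> None:
    """Sidecar table (particle_index, site_id) alongside an XYZ snapshot."""
    with open(path, "w") as fh:
        fh.write("particle_index\tsite_id\n")
        for p in sorted(occ.particles()):
            fh.write(f"{p}\t{occ.site_of(p)}\n")


def read_occupancy_tsv(path) -> SiteOccupancy:
    occ = SiteOccupancy()
    with open(path) as fh:
        next(fh)
        for line in fh:
            p, s = line.split()
            occ.assign(int(p), int(s))
    return occ
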