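"""Grand-canonical cluster Monte Carlo engine.

Two swap-move families equilibrate a cluster with an implicit ideal-gas
reservoir of density n_v at temperature T:

* original AVBMC — the insertion volume is a sphere of radius R around a
  target particle; cluster membership follows the Stillinger criterion;
* lattice-based AVBMC — the insertion volume is a sphere of radius r
  around a vacant FCC site adjacent to the target particle's site; the
  solid cluster criterion applies.

Both use per-path (super-detailed-balance) acceptance rules validated
against exact enumeration on tiny models (see validation_oracle).  The
stationary weight is pi(x, N) proportional to n_v^N exp(-beta [U + eta(N)])
restricted to a size window.  Chemical-potential convention:
beta mu_gas = ln(n_v sigma^3), so n_v = 1 means mu_gas = 0 with the kinetic
term excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .cluster_criteria import solid_sites_connected
from .lattice import (FccLattice, SiteOccupancy, occupied_neighbor_particles,
                      vacant_neighbor_sites)
from .model_core import MoveProposal
from .umbrella import BiasPotential, SizeHistogram, N_BLOCKS

logger = logging.getLogger("avbmc")

RESYNC_INTERVAL = 100_000  # moves between full-energy resyncs
RESYNC_TOL = 1e-7


@dataclass(frozen=True)
class ReservoirSpec:
    """Ideal-gas reservoir: temperature and number density (reduced units)."""

    T: float
    n_v: float

    def __post_init__(self):
        if self.T <= 0 or self.n_v <= 0:
            raise ValueError("T and n_v must be > 0")

    @property
    def beta(self) -> float:
        return 1.0 / self.T

    @property
    def mu_gas(self) -> float:
        return self.T * math.log(self.n_v)


@dataclass(frozen=True)
class MoveParams:
    """Insertion radii and translation cap.

    R -- original-AVBMC sphere radius (doubles as the Stillinger radius);
    r -- lattice-AVBMC site radius; V_in = (4/3) pi radius^3 in each mode.
    """

    R: float | None = None
    r: float | None = None
    max_displacement: float = 0.2

    def __post_init__(self):
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")

    def insertion_volume(self, mode: str) -> float:
        radius = self.R if mode == "liquid" else self.r
        if radius is None:
            raise ValueError(f"no radius configured for mode {mode!r}")
        return (4.0 / 3.0) * math.pi * radius ** 3


@dataclass(frozen=True)
class SizeWindow:
    n_min: int
    n_max: int

    def __post_init__(self):
        if not 1 <= self.n_min <= self.n_max:
            raise ValueError("need 1 <= n_min <= n_max")

    def contains(self, n: int) -> bool:
        return self.n_min <= n <= self.n_max


class MoveStats:
    """Per-move-type attempt/acceptance counters."""

    def __init__(self):
        self.attempts: dict[str, int] = {}
        self.accepts: dict[str, int] = {}

    def record(self, kind: str, accepted: bool) -> None:
        self.attempts[kind] = self.attempts.get(kind, 0) + 1
        if accepted:
            self.accepts[kind] = self.accepts.get(kind, 0) + 1

    def rate(self, *kinds: str) -> float:
        att = sum(self.attempts.get(k, 0) for k in kinds)
        acc = sum(self.accepts.get(k, 0) for k in kinds)
        return acc / att if att else math.nan

    def as_dict(self) -> dict:
        return {k: {"attempts": self.attempts.get(k, 0),
                    "accepts": self.accepts.get(k, 0)}
                for k in sorted(self.attempts)}


class ClusterState:
    """Mutable cluster configuration with cached energy.

    Solid states carry the lattice, the particle<->site occupancy and the
    per-particle site coordinates.  `frozen_energy` evaluates all energies
    at site centers (used by the validation oracles to separate entropic
    from energetic factors); `allowed_sites`, when set, restricts insertions
    to a finite sub-lattice (enumeration harness).
    """

    def __init__(self, mode: str, positions: np.ndarray, *,
                 lattice: FccLattice | None = None,
                 site_keys: np.ndarray | None = None,
                 epsilon: float = 1.0,
                 frozen_energy: bool = False,
                 allowed_sites: frozenset | None = None):
        if mode not in ("liquid", "solid"):
            raise ValueError("mode must be 'liquid' or 'solid'")
        if mode == "solid" and (lattice is None or site_keys is None):
            raise ValueError("solid state needs lattice and site_keys")
        positions = np.ascontiguousarray(positions, dtype=np.float64)
        n = positions.shape[0]
        if n < 1:
            raise ValueError("cluster must hold at least one particle")
        cap = max(2 * n, n + 64)
        self.mode = mode
        self.n = n
        self.pos = np.zeros((cap, 3))
        self.pos[:n] = positions
        self.epsilon = float(epsilon)
        self.frozen_energy = frozen_energy
        self.lattice = lattice
        self.allowed_sites = allowed_sites
        self.occ = SiteOccupancy()
        if mode == "solid":
            self.site_keys = np.zeros(cap, dtype=np.int64)
            self.site_keys[:n] = np.asarray(site_keys, dtype=np.int64)
            self.site_pos = np.zeros((cap, 3))
            self.site_pos[:n] = lattice.site_positions(self.site_keys[:n])
            for p in range(n):
                self.occ.assign(p, int(self.site_keys[p]))
        else:
            self.site_keys = None
            self.site_pos = None
        self.energy = self.full_energy()
        self._moves_since_resync = 0

    # -- energy ------------------------------------------------------------

    def _epos(self) -> np.ndarray:
        return self.site_pos if self.frozen_energy else self.pos

    def full_energy(self) -> float:
        e, mr2 = K.total_energy_cluster(self._epos(), self.n, self.epsilon, 1.0)
        return e

    def point_energy(self, x: float, y: float, z: float, skip: int = -1) -> float:
        return K.particle_energy_cluster(self._epos(), self.n, skip,
                                         x, y, z, self.epsilon, 1.0)

    def maybe_resync(self) -> None:
        self._moves_since_resync += 1
        if self._moves_since_resync >= RESYNC_INTERVAL:
            self._moves_since_resync = 0
            fresh = self.full_energy()
            if abs(fresh - self.energy) > RESYNC_TOL:
                logger.warning("energy cache drift %.3e exceeds %.1e",
                               abs(fresh - self.energy), RESYNC_TOL)
            self.energy = fresh

    # -- structural edits ----------------------------------------------------

    def _grow(self) -> None:
        cap = self.pos.shape[0]
        new = np.zeros((2 * cap, 3))
        new[:cap] = self.pos
        self.pos = new
        if self.mode == "solid":
            sk = np.zeros(2 * cap, dtype=np.int64)
            sk[:cap] = self.site_keys
            self.site_keys = sk
            sp = np.zeros((2 * cap, 3))
            sp[:cap] = self.site_pos
            self.site_pos = sp

    def insert(self, position: np.ndarray, site: int | None = None) -> None:
        if self.n == self.pos.shape[0]:
            self._grow()
        i = self.n
        self.pos[i] = position
        if self.mode == "solid":
            self.site_keys[i] = site
            self.site_pos[i] = self.lattice.site_position(site)
            self.occ.assign(i, int(site))
        self.n += 1

    def delete(self, i: int) -> None:
        last = self.n - 1
        if self.mode == "solid":
            self.occ.release(i)
        if i != last:
            self.pos[i] = self.pos[last]
            if self.mode == "solid":
                self.site_keys[i] = self.site_keys[last]
                self.site_pos[i] = self.site_pos[last]
                self.occ.relabel(last, i)
        self.n = last

    def snapshot_positions(self) -> np.ndarray:
        return self.pos[:self.n].copy()

    def occupied_pattern(self) -> frozenset:
        return frozenset(int(k) for k in self.site_keys[:self.n])


# ---------------------------------------------------------------------------
# factories
# ---------------------------------------------------------------------------

def initial_solid_cluster(lattice: FccLattice, n: int, *,
                          epsilon: float = 1.0,
                          frozen_energy: bool = False,
                          allowed_sites: frozenset | None = None) -> ClusterState:
    """Filled FCC ball: the n sites nearest the origin, particles at centers."""
    extent = lattice.spacing * (2.0 + (n / 2.0) ** (1.0 / 3.0))
    keys = lattice.generate_sites(extent)
    while len(keys) < n:
        extent *= 1.4
        keys = lattice.generate_sites(extent)
    if allowed_sites is not None:
        keys = np.array([k for k in keys if int(k) in allowed_sites],
                        dtype=np.int64)
        if len(keys) < n:
            raise ValueError("not enough allowed sites")
    coords = lattice.site_positions(keys)
    d2 = np.sum((coords - lattice.origin) ** 2, axis=1)
    order = np.lexsort((keys, np.round(d2, 9)))
    chosen = keys[order[:n]]
    return ClusterState("solid", lattice.site_positions(chosen),
                        lattice=lattice, site_keys=chosen, epsilon=epsilon,
                        frozen_energy=frozen_energy, allowed_sites=allowed_sites)


def initial_liquid_cluster(n: int, reservoir: ReservoirSpec, params: MoveParams,
                           seed: int, relax_sweeps: int = 1000,
                           epsilon: float = 1.0) -> ClusterState:
    """Excised FCC ball relaxed by pure translation sweeps."""
    lat = FccLattice(spacing=2.0 ** (1.0 / 6.0))
    solid = initial_solid_cluster(lat, n)
    state = ClusterState("liquid", solid.snapshot_positions(), epsilon=epsilon)
    rng = np.random.default_rng(seed)
    for _ in range(relax_sweeps):
        for _ in range(n):
            translate(state, reservoir, params, rng)
    return state


# ---------------------------------------------------------------------------
# move primitives
# ---------------------------------------------------------------------------

def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return radius * rng.random() ** (1.0 / 3.0) * v


def _metropolis(rng: np.random.Generator, q: float) -> bool:
    return q >= 1.0 or rng.random() < q


def _bias_delta(bias: BiasPotential | None, n_old: int, n_new: int) -> float:
    if bias is None:
        return 0.0
    return bias.value(n_new) - bias.value(n_old)


def lattice_avbmc_swap(state: ClusterState, reservoir: ReservoirSpec,
                       params: MoveParams, window: SizeWindow,
                       rng: np.random.Generator,
                       bias: BiasPotential | None = None,
                       _drop_nvac_factor: bool = False) -> MoveProposal:
    """One lattice-based AVBMC insertion/deletion attempt.

    Per-path acceptance (counts evaluated in the pre-move state):

      insert: min{1, n_v V_in e^{-beta dE'} N N_vac(j) / [(N+1)(N_in(j)+1)]}
      delete: min{1, e^{-beta dE'} / (n_v V_in) N N_in(j) / [(N-1)(N_vac(j)+1)]}

    with dE' = dE + d(eta).  `_drop_nvac_factor` deliberately corrupts the
    insertion rule (negative control for the enumeration oracle).
    """
    if state.mode != "solid":
        raise ValueError("lattice swap needs a solid-mode state")
    n = state.n
    if n == 0:
        raise ValueError("empty cluster")
    beta = reservoir.beta
    v_in = params.insertion_volume("solid")
    do_insert = rng.random() < 0.5
    j = int(rng.integers(n))

    if do_insert:
        kind = "lattice_insert"
        if not window.contains(n + 1):
            return MoveProposal(kind, 0.0, False)
        vac = vacant_neighbor_sites(j, state.occ, state.lattice)
        if state.allowed_sites is not None:
            vac = np.array([s for s in vac if int(s) in state.allowed_sites],
                           dtype=np.int64)
        n_vac = len(vac)
        if n_vac == 0:
            return MoveProposal(kind, 0.0, False)
        n_in_j = len(occupied_neighbor_particles(j, state.occ, state.lattice))
        site = int(vac[rng.integers(n_vac)])
        center = state.lattice.site_position(site)
        x = center + _uniform_in_sphere(rng, params.r)
        if state.frozen_energy:
            de = K.particle_energy_cluster(state.site_pos, n, -1,
                                           center[0], center[1], center[2],
                                           state.epsilon, 1.0)
        else:
            de = state.point_energy(x[0], x[1], x[2])
        de_eff = de + _bias_delta(bias, n, n + 1)
        q = (reservoir.n_v * v_in * math.exp(-beta * de_eff)
             * n / ((n + 1) * (n_in_j + 1)))
        if not _drop_nvac_factor:
            q *= n_vac
        accepted = _metropolis(rng, q)
        if accepted:
            state.insert(x, site)
            state.energy += de
        state.maybe_resync()
        return MoveProposal(kind, de, accepted)

    kind = "lattice_delete"
    if not window.contains(n - 1):
        return MoveProposal(kind, 0.0, False)
    nbrs = occupied_neighbor_particles(j, state.occ, state.lattice)
    n_in = len(nbrs)
    if n_in == 0:
        return MoveProposal(kind, 0.0, False)
    k = int(nbrs[rng.integers(n_in)])
    site_k = state.occ.site_of(k)
    if not solid_sites_connected(state.occ, skip_site=site_k):
        return MoveProposal(kind, 0.0, False)
    vac_j = vacant_neighbor_sites(j, state.occ, state.lattice)
    if state.allowed_sites is not None:
        vac_j = np.array([s for s in vac_j if int(s) in state.allowed_sites],
                         dtype=np.int64)
    n_vac_j = len(vac_j)
    if state.frozen_energy:
        ck = state.site_pos[k]
        de = -K.particle_energy_cluster(state.site_pos, n, k,
                                        ck[0], ck[1], ck[2], state.epsilon, 1.0)
    else:
        pk = state.pos[k]
        de = -state.point_energy(pk[0], pk[1], pk[2], skip=k)
    de_eff = de + _bias_delta(bias, n, n - 1)
    q = (math.exp(-beta * de_eff) / (reservoir.n_v * v_in)
         * n * n_in / ((n - 1) * (n_vac_j + 1)))
    accepted = _metropolis(rng, q)
    if accepted:
        state.delete(k)
        state.energy += de
    state.maybe_resync()
    return MoveProposal(kind, de, accepted)


def original_avbmc_swap(state: ClusterState, reservoir: ReservoirSpec,
                        params: MoveParams, window: SizeWindow,
                        rng: np.random.Generator,
                        bias: BiasPotential | None = None) -> MoveProposal:
    """One original-AVBMC insertion/deletion attempt (liquid clusters).

    Per-path acceptance (counts in the pre-move state):

      insert: min{1, n_v V_in e^{-beta dE'} N / [(N+1)(N_in(j)+1)]}
      delete: min{1, e^{-beta dE'} N N_in(j) / [n_v V_in (N-1)]}

    The deletion form follows from the reverse insertion targeting j among
    the N-1 survivors; the forward/reverse arguments multiply to one.
    """
    if state.mode != "liquid":
        raise ValueError("original swap needs a liquid-mode state")
    n = state.n
    if n == 0:
        raise ValueError("empty cluster")
    beta = reservoir.beta
    v_in = params.insertion_volume("liquid")
    r2 = params.R ** 2
    do_insert = rng.random() < 0.5
    j = int(rng.integers(n))
    pj = state.pos[j]

    if do_insert:
        kind = "avbmc_insert"
        if not window.contains(n + 1):
            return MoveProposal(kind, 0.0, False)
        x = pj + _uniform_in_sphere(rng, params.R)
        n_in_j = K.count_within(state.pos, n, j, pj[0], pj[1], pj[2], r2)
        de = state.point_energy(x[0], x[1], x[2])
        de_eff = de + _bias_delta(bias, n, n + 1)
        q = (reservoir.n_v * v_in * math.exp(-beta * de_eff)
             * n / ((n + 1) * (n_in_j + 1)))
        accepted = _metropolis(rng, q)
        if accepted:
            state.insert(x)
            state.energy += de
        state.maybe_resync()
        return MoveProposal(kind, de, accepted)

    kind = "avbmc_delete"
    if not window.contains(n - 1):
        return MoveProposal(kind, 0.0, False)
    d2 = np.sum((state.pos[:n] - pj) ** 2, axis=1)
    d2[j] = np.inf
    nbr = np.flatnonzero(d2 < r2)
    n_in = len(nbr)
    if n_in == 0:
        return MoveProposal(kind, 0.0, False)
    k = int(nbr[rng.integers(n_in)])
    if not K.liquid_connected(state.pos, n, k, r2):
        return MoveProposal(kind, 0.0, False)
    pk = state.pos[k]
    de = -state.point_energy(pk[0], pk[1], pk[2], skip=k)
    de_eff = de + _bias_delta(bias, n, n - 1)
    q = (math.exp(-beta * de_eff) * n * n_in
         / (reservoir.n_v * v_in * (n - 1)))
    accepted = _metropolis(rng, q)
    if accepted:
        state.delete(k)
        state.energy += de
    state.maybe_resync()
    return MoveProposal(kind, de, accepted)


def intrasite_jump(state: ClusterState, reservoir: ReservoirSpec,
                   params: MoveParams,
                   rng: np.random.Generator) -> MoveProposal:
    """Jump a particle to a uniform point in the sphere around its own site.

    Plain Boltzmann acceptance; the solid binding condition holds by
    construction since the proposal never leaves the site sphere.
    """
    if state.mode != "solid":
        raise ValueError("intrasite jumps need a solid-mode state")
    i = int(rng.integers(state.n))
    new = state.site_pos[i] + _uniform_in_sphere(rng, params.r)
    if state.frozen_energy:
        de = 0.0
    else:
        old = state.pos[i]
        e_old = state.point_energy(old[0], old[1], old[2], skip=i)
        e_new = state.point_energy(new[0], new[1], new[2], skip=i)
        de = e_new - e_old
    q = 1.0 if de <= 0 else math.exp(-reservoir.beta * de)
    accepted = _metropolis(rng, q)
    if accepted:
        state.pos[i] = new
        state.energy += de
    state.maybe_resync()
    return MoveProposal("intrasite", de, accepted)


def translate(state: ClusterState, reservoir: ReservoirSpec,
              params: MoveParams, rng: np.random.Generator) -> MoveProposal:
    """Cubic-cap single-particle translation with Stillinger-criterion veto."""
    if state.mode != "liquid":
        raise ValueError("translations apply to liquid-mode states")
    n = state.n
    i = int(rng.integers(n))
    disp = (rng.random(3) - 0.5) * 2.0 * params.max_displacement
    old = state.pos[i].copy()
    new = old + disp
    e_old = state.point_energy(old[0], old[1], old[2], skip=i)
    e_new = state.point_energy(new[0], new[1], new[2], skip=i)
    de = e_new - e_old
    state.pos[i] = new
    if n > 1 and not K.liquid_connected(state.pos, n, -1, params.R ** 2):
        state.pos[i] = old
        state.maybe_resync()
        return MoveProposal("translate", de, False)
    q = 1.0 if de <= 0 else math.exp(-reservoir.beta * de)
    accepted = _metropolis(rng, q)
    if accepted:
        state.energy += de
    else:
        state.pos[i] = old
    state.maybe_resync()
    return MoveProposal("translate", de, accepted)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_gc_cluster(state: ClusterState, reservoir: ReservoirSpec,
                   params: MoveParams, window: SizeWindow,
                   bias: BiasPotential | None, n_moves: int, seed: int,
                   traj_stride: int = 0,
                   observer=None, observer_stride: int = 0):
    """Biased grand-canonical run; 50/50 swaps vs. local moves.

    Local moves are intrasite jumps (solid) or translations (liquid).  The
    visited size is tallied after every attempted move into 5 equal blocks.
    Returns (SizeHistogram, MoveStats, trajectory) where trajectory is a
    list of (move_index, positions) when traj_stride > 0.
    """
    if not window.contains(state.n):
        raise ValueError("initial state outside the size window")
    if n_moves < 0:
        raise ValueError("n_moves must be >= 0")
    rng = np.random.default_rng(seed)
    k_sizes = window.n_max - window.n_min + 1
    block_counts = np.zeros((N_BLOCKS, k_sizes))
    stats = MoveStats()
    traj = []
    swap = lattice_avbmc_swap if state.mode == "solid" else original_avbmc_swap
    local = intrasite_jump if state.mode == "solid" else translate
    for m in range(n_moves):
        if rng.random() < 0.5:
            prop = swap(state, reservoir, params, window, rng, bias)
        else:
            prop = local(state, reservoir, params, rng)
        stats.record(prop.kind, prop.accepted)
        b = m * N_BLOCKS // n_moves
        block_counts[b, state.n - window.n_min] += 1
        if traj_stride and (m + 1) % traj_stride == 0:
            traj.append((m + 1, state.snapshot_positions()))
        if observer_stride and (m + 1) % observer_stride == 0:
            observer(state)
    return SizeHistogram(window.n_min, block_counts), stats, traj


# ---------------------------------------------------------------------------
# self-adaptive flattening
# ---------------------------------------------------------------------------

def _tolerant_dg(hist: SizeHistogram, bias: BiasPotential, T: float) -> np.ndarray:
    """Free-energy estimate that tolerates unvisited sizes.

    Visited sizes use -T ln H - eta; gaps are filled by continuing the last
    observed per-size increment so the next bias still steers the walk into
    unexplored sizes.
    """
    counts = hist.counts
    sizes = hist.sizes
    beta_eta = np.array([bias.value(n) for n in sizes]) / T
    g = np.full(len(sizes), np.nan)
    vis = counts > 0
    g[vis] = T * (-np.log(counts[vis]) - beta_eta[vis])
    vis_idx = np.flatnonzero(vis)
    if len(vis_idx) == 0:
        raise RuntimeError("no sizes visited")
    if len(vis_idx) >= 2:
        slope = (g[vis_idx[-1]] - g[vis_idx[0]]) / (vis_idx[-1] - vis_idx[0])
    else:
        slope = 0.0
    # interior gaps: linear interpolation between bracketing visits
    nan = np.isnan(g)
    g[nan] = np.interp(np.flatnonzero(nan), vis_idx, g[vis_idx])
    # edges: continue the mean visited slope outward
    for i in range(vis_idx[0] - 1, -1, -1):
        g[i] = g[i + 1] - slope
    for i in range(vis_idx[-1] + 1, len(sizes)):
        g[i] = g[i - 1] + slope
    return g


def adaptive_flattening(state: ClusterState, reservoir: ReservoirSpec,
                        params: MoveParams, window: SizeWindow, seed: int,
                        moves_per_iter: int, max_iter: int = 20,
                        ratio_target: float = 10.0,
                        initial_bias: BiasPotential | None = None):
    """Iterate bias <- -dG_est until the window histogram is even.

    Termination: max/min visited-size count ratio < `ratio_target` (default
    10) or `max_iter` iterations.  Returns (bias, last_histogram, n_iter).
    """
    bias = initial_bias or BiasPotential.zero(window.n_min, window.n_max)
    hist = None
    for it in range(max_iter):
        hist, _, _ = run_gc_cluster(state, reservoir, params, window, bias,
                                    moves_per_iter, seed + 7919 * it)
        if hist.flatness_ratio() < ratio_target:
            return bias, hist, it + 1
        g = _tolerant_dg(hist, bias, reservoir.T)
        eta = -(g - g[0])
        bias = BiasPotential(window.n_min, eta)
    return bias, hist, max_iter
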