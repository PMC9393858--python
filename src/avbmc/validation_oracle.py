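"""Exact references that certify the swap acceptance rules on tiny models.

For a lattice model restricted to an enumerable site set (<= 12 sites) the
grand-canonical size distribution is summed exactly over all connected
occupancy patterns: each occupied site contributes an activity factor
n_v * V_in (positions integrate analytically over the insertion sphere)
times, in frozen-energy mode, the Boltzmann factor of the site-center
pair energies.  The Monte Carlo engine run on the same model must
reproduce this distribution; `mc_vs_oracle` reports the chi-square
p-value of thinned visited-pattern frequencies, and a deliberately
corrupted acceptance rule serves as the negative control.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cluster_mc import (MoveParams, ReservoirSpec, SizeWindow,
                         initial_solid_cluster)
from .lattice import NEIGHBOR_TRIPLES, FccLattice, pack_site
from .model_core import PairPotentialSpec, pair_energy

MAX_ORACLE_SITES = 12


@dataclass
class TinyModel:
    """Enumerable solid-cluster model on an explicit FCC sub-lattice."""

    lattice: FccLattice
    sites: tuple[int, ...]            # packed site ids, <= 12 of them
    r: float                          # insertion-sphere radius
    reservoir: ReservoirSpec
    energy_rule: str = "ideal"        # "ideal" (E=0) or "frozen" (site centers)

    def __post_init__(self):
        if len(self.sites) > MAX_ORACLE_SITES:
            raise ValueError(f"enumeration limited to {MAX_ORACLE_SITES} sites")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate sites")
        if self.energy_rule not in ("ideal", "frozen"):
            raise ValueError("energy_rule must be 'ideal' or 'frozen'")

    @property
    def v_in(self) -> float:
        return (4.0 / 3.0) * math.pi * self.r ** 3

    def adjacency(self) -> dict[int, set[int]]:
        out = {s: set() for s in self.sites}
        site_set = set(self.sites)
        for s in self.sites:
            for t in (int(x) for x in self.lattice.site_neighbors(s)):
                if t in site_set:
                    out[s].add(t)
        return out

    def pattern_energy(self, pattern: frozenset) -> float:
        if self.energy_rule == "ideal":
            return 0.0
        spec = PairPotentialSpec()
        coords = [self.lattice.site_position(s) for s in pattern]
        e = 0.0
        for a, b in itertools.combinations(coords, 2):
            e += pair_energy(float(np.linalg.norm(a - b)), spec)
        return e


def chain_sites(lattice: FccLattice, length: int) -> tuple[int, ...]:
    """A linear chain of `length` mutually adjacent-in-sequence sites."""
    sites = [pack_site(0, 0, 0)]
    step = NEIGHBOR_TRIPLES[0]
    cur = np.zeros(3, dtype=np.int64)
    for _ in range(length - 1):
        cur = cur + step
        sites.append(pack_site(*cur))
    return tuple(sites)


def _connected(pattern: frozenset, adj: dict[int, set[int]]) -> bool:
    if len(pattern) <= 1:
        return True
    start = next(iter(pattern))
    seen = {start}
    stack = [start]
    while stack:
        s = stack.pop()
        for t in adj[s]:
            if t in pattern and t not in seen:
                seen.add(t)
                stack.append(t)
    return len(seen) == len(pattern)


def enumerate_lattice_gc(model: TinyModel):
    """Exact P(n) and per-pattern weights of the tiny grand-canonical model.

    Returns (size_probs, pattern_probs): dictionaries keyed by cluster size
    and by frozenset of occupied sites, both normalized over all nonempty
    connected patterns (the empty cluster is excluded, matching the
    engine's minimum size of one).
    """
    adj = model.adjacency()
    z = model.reservoir.n_v * model.v_in
    beta = model.reservoir.beta
    pattern_w: dict[frozenset, float] = {}
    for k in range(1, len(model.sites) + 1):
        for combo in itertools.combinations(model.sites, k):
            pat = frozenset(combo)
            if not _connected(pat, adj):
                continue
            e = model.pattern_energy(pat)
            pattern_w[pat] = z ** k * math.exp(-beta * e)
    total = sum(pattern_w.values())
    pattern_p = {p: w / total for p, w in pattern_w.items()}
    size_p: dict[int, float] = {}
    for p, w in pattern_p.items():
        size_p[len(p)] = size_p.get(len(p), 0.0) + w
    return size_p, pattern_p


def run_engine_on_model(model: TinyModel, n_moves: int, seed: int,
                        thin: int = 50, corrupt: bool = False):
    """Run the real engine on the tiny model; tally thinned pattern visits."""
    from . import cluster_mc

    window = SizeWindow(1, len(model.sites))
    params = MoveParams(r=model.r)
    allowed = frozenset(model.sites)
    state = initial_solid_cluster(model.lattice, 1, frozen_energy=True,
                                  allowed_sites=allowed,
                                  epsilon=0.0 if model.energy_rule == "ideal"
                                  else 1.0)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for m in range(1, n_moves + 1):
        cluster_mc.lattice_avbmc_swap(state, model.reservoir, params, window,
                                      rng, _drop_nvac_factor=corrupt)
        if m % thin == 0:
            pat = state.occupied_pattern()
            counts[pat] = counts.get(pat, 0) + 1
    return counts


def mc_vs_oracle(model: TinyModel, n_moves: int, seed: int,
                 thin: int = 50, corrupt: bool = False):
    """Chi-square comparison of engine pattern frequencies vs. enumeration.

    Thinning decorrelates successive samples so the chi-square reference
    distribution applies.  Returns a dict with the statistic, p-value,
    sample size, and the two frequency tables.
    """
    _, pattern_p = enumerate_lattice_gc(model)
    counts = run_engine_on_model(model, n_moves, seed, thin, corrupt)
    n_tot = sum(counts.values())
    patterns = sorted(pattern_p, key=lambda p: (len(p), sorted(p)))
    observed = np.array([counts.get(p, 0) for p in patterns], dtype=float)
    expected = np.array([pattern_p[p] * n_tot for p in patterns])
    # pool bins with tiny expectation to keep the chi-square valid
    keep = expected >= 5.0
    if (~keep).any():
        observed = np.append(observed[keep], observed[~keep].sum())
        expected = np.append(expected[keep], expected[~keep].sum())
    chi2, p = stats.chisquare(observed, expected)
    return {"chi2": float(chi2), "p_value": float(p), "n_samples": int(n_tot),
            "observed": observed, "expected": expected,
            "patterns": patterns}


# -- liquid-cluster references ---------------------------------------------

def liquid_dimer_ratio(reservoir: ReservoirSpec, R: float,
                       epsilon: float = 1.0, n_quad: int = 4096) -> float:
    """Exact P(2)/P(1) for the original-AVBMC liquid model.

    Standard cluster statistics, P(n) proportional to n_v^n Z_n / n! with
    Z_n the labeled configuration integral in relative coordinates, gives

        P(2)/P(1) = (n_v / 2) int_{r<R} e^{-beta u(r)} 4 pi r^2 dr,

    i.e. n_v V_in / 2 for an ideal dimer.  The 1/n! indistinguishability
    factor is what makes the CNT intercept extrapolate to the bulk
    chemical potential.
    """
    r = np.linspace(1e-8, R, n_quad)
    if epsilon == 0.0:
        integrand = 4.0 * np.pi * r ** 2
    else:
        sr6 = (1.0 / r) ** 6
        u = 4.0 * epsilon * (sr6 ** 2 - sr6)
        integrand = np.exp(-np.clip(reservoir.beta * u, -700, 700)) \
            * 4.0 * np.pi * r ** 2
    return 0.5 * reservoir.n_v * float(np.trapezoid(integrand, r))


def liquid_trimer_ratio_ideal(reservoir: ReservoirSpec, R: float,
                              n_samples: int = 400_000,
                              seed: int = 0) -> tuple[float, float]:
    """P(3)/P(2) for the ideal liquid model by brute-force MC integration.

    P(3)/P(2) = (n_v / 3) Z_3 / Z_2 with Z_n the connectivity-constrained
    labeled configuration integral in relative coordinates (Z_2 = V_in);
    returns (ratio, standard error).
    """
    rng = np.random.default_rng(seed)
    box = 2.0 * R
    x2 = rng.uniform(-box, box, size=(n_samples, 3))
    x3 = rng.uniform(-box, box, size=(n_samples, 3))
    d12 = np.linalg.norm(x2, axis=1) < R
    d13 = np.linalg.norm(x3, axis=1) < R
    d23 = np.linalg.norm(x3 - x2, axis=1) < R
    connected = (d12 & d13) | (d12 & d23) | (d13 & d23)
    vol6 = (2 * box) ** 6
    z3 = connected.mean() * vol6
    z3_err = connected.std(ddof=1) / math.sqrt(n_samples) * vol6
    z2 = (4.0 / 3.0) * math.pi * R ** 3
    return (reservoir.n_v / 3.0) * z3 / z2, (reservoir.n_v / 3.0) * z3_err / z2
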