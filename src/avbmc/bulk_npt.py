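"""Isobaric-isothermal Monte Carlo of bulk Lennard-Jones liquid and solid.

Used to obtain the bulk number density (hence the FCC lattice spacing for
the solid-cluster simulations), the enthalpy per particle that feeds the
Gibbs-Helmholtz propagation, and the virial pressure as a consistency
check.  Single-particle translations plus volume moves uniform in ln V
(acceptance carries the (N+1) ln V Jacobian term); energies use a
spherical cutoff with analytical tail corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .model_core import PairPotentialSpec, tail_correction

N_BLOCKS = 5


@dataclass
class ThermoState:
    """Bulk state point: density and enthalpy per particle with errors."""

    T: float
    P: float
    rho: float
    rho_err: float
    h: float
    h_err: float
    phase: str = ""
    u: float = math.nan          # potential energy per particle
    p_virial: float = math.nan
    p_virial_err: float = math.nan
    meta: dict | None = None

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.rho_err < 0 or self.h_err < 0:
            raise ValueError("errors must be >= 0")


def fcc_positions(cells: int, box: float) -> np.ndarray:
    """4*cells^3 particles on a perfect FCC lattice in a cubic box."""
    a = box / cells
    basis = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    pts = []
    for i in range(cells):
        for j in range(cells):
            for k in range(cells):
                pts.append((np.array([i, j, k]) + basis) * a)
    return np.concatenate(pts)


def _block_stats(samples: np.ndarray) -> tuple[float, float]:
    blocks = np.array_split(samples, N_BLOCKS)
    means = np.array([b.mean() for b in blocks])
    return float(samples.mean()), float(means.std(ddof=1) / math.sqrt(N_BLOCKS))


def lattice_spacing_from_density(rho: float) -> float:
    """FCC nearest-neighbor distance a_nn = (4/rho)^(1/3) / sqrt(2)."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    return (4.0 / rho) ** (1.0 / 3.0) / math.sqrt(2.0)


def density_from_lattice_spacing(a_nn: float) -> float:
    return 4.0 / (a_nn * math.sqrt(2.0)) ** 3


def run_npt(phase: str, N: int, T: float, P: float, cutoff: float,
            sweeps: int, seed: int, *, equilibration: int | None = None,
            max_displacement: float = 0.12, max_dlnv: float = 0.008,
            vol_moves_per_sweep: int = 4, sample_every: int = 1,
            initial_density: float | None = None,
            epsilon: float = 1.0) -> ThermoState:
    """NPT run returning averaged density and enthalpy with 5-block errors.

    `phase` picks the starting structure: 'fcc_solid' needs N = 4 k^3 and
    starts on a perfect lattice; 'liquid' starts from a random
    non-overlapping packing.  `sweeps` counts production sweeps (one sweep
    = N translation attempts + `vol_moves_per_sweep` volume attempts);
    equilibration defaults to half the production length.
    """
    if phase not in ("liquid", "fcc_solid"):
        raise ValueError("phase must be 'liquid' or 'fcc_solid'")
    if T <= 0 or P < 0 or cutoff <= 0:
        raise ValueError("invalid state point")
    if equilibration is None:
        equilibration = max(200, sweeps // 2)

    if phase == "fcc_solid":
        cells = round((N / 4.0) ** (1.0 / 3.0))
        if 4 * cells ** 3 != N:
            raise ValueError(f"N={N} is not 4k^3 (FCC-commensurate)")
        rho0 = initial_density or 0.985
        box = (N / rho0) ** (1.0 / 3.0)
        pos = fcc_positions(cells, box)
    else:
        rho0 = initial_density or 0.80
        box = (N / rho0) ** (1.0 / 3.0)
        pos, placed = K.rsa_fill(N, box, 0.85, seed % 2 ** 31, 400 * N)
        if placed < N:
            raise RuntimeError("could not place initial liquid configuration")
    if box < 2.0 * cutoff:
        raise ValueError(
            f"box {box:.3f} < 2*cutoff {2 * cutoff:.3f}: reduce cutoff or N")

    # constant-volume warm-up so thermal pressure builds before the box moves
    warm = max(50, int(equilibration) // 10)
    out = K.run_npt(pos, box, T, P, cutoff, True, warm,
                    max_displacement, max_dlnv, 0,
                    (seed + 3) % 2 ** 31, max(1, sample_every), epsilon)
    # equilibration
    out = K.run_npt(pos, box, T, P, cutoff, True, int(equilibration),
                    max_displacement, max_dlnv, vol_moves_per_sweep,
                    (seed + 1) % 2 ** 31, max(1, sample_every), epsilon)
    box = out[8]
    if out[9] != 0:
        raise RuntimeError("box shrank below 2*cutoff during equilibration")
    # production
    (rho_s, u_s, v_s, w_s, acc_tr, att_tr, acc_v, att_v, box, status) = K.run_npt(
        pos, box, T, P, cutoff, True, int(sweeps),
        max_displacement, max_dlnv, vol_moves_per_sweep,
        (seed + 2) % 2 ** 31, max(1, sample_every), epsilon)
    if status != 0:
        raise RuntimeError("box shrank below 2*cutoff during production")

    rho, rho_err = _block_stats(rho_s)
    h_s = (u_s + P * v_s) / N
    h, h_err = _block_stats(h_s)

    # per-sample virial pressure with tail correction
    spec = PairPotentialSpec(epsilon=epsilon, cutoff=cutoff,
                             tail_corrections=True)
    p_tail_s = np.array([tail_correction(r, cutoff, spec)[1] for r in rho_s])
    p_vir_s = rho_s * T + w_s / (3.0 * v_s) + p_tail_s
    p_vir, p_vir_err = _block_stats(p_vir_s)

    return ThermoState(
        T=T, P=P, rho=rho, rho_err=rho_err, h=h, h_err=h_err, phase=phase,
        u=float(u_s.mean() / N), p_virial=p_vir, p_virial_err=p_vir_err,
        meta={
            "N": N, "cutoff": cutoff, "sweeps": int(sweeps),
            "equilibration": int(equilibration), "seed": seed,
            "max_displacement": max_displacement, "max_dlnv": max_dlnv,
            "vol_moves_per_sweep": vol_moves_per_sweep,
            "acc_translation": acc_tr / max(att_tr, 1),
            "acc_volume": acc_v / max(att_v, 1),
            "final_box": float(box),
            "mean_volume": float(v_s.mean()),
        })


def virial_pressure_series(phase: str, N: int, T: float, P: float,
                           cutoff: float, sweeps: int, seed: int,
                           n_checks: int = 20, **kw) -> tuple[float, float]:
    """Mean virial pressure with error, via independent short segments."""
    ps = []
    for c in range(n_checks):
        st = run_npt(phase, N, T, P, cutoff, sweeps, seed + 1013 * c, **kw)
        ps.append(st.p_virial)
    ps = np.array(ps)
    return float(ps.mean()), float(ps.std(ddof=1) / math.sqrt(len(ps)))
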