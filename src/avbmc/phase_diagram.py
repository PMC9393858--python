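"""Melting point, solid-liquid coexistence, and the triple point.

Chemical potentials of the bulk liquid and solid at a reference
temperature (from the CNT intercepts) are propagated in temperature with
the Gibbs-Helmholtz relation

    d(beta mu)/d(beta) = h(beta)   at fixed P,

using enthalpy-per-particle tables from the NPT simulations.  The melting
point is the root of the chemical-potential difference; the solid-liquid
coexistence line follows from the Clapeyron equation dP/dT = dh/(T dv),
and the triple point is its intersection with the liquid-vapor curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

GH_BETA_STEP = 0.001
CLAPEYRON_T_STEP = 0.0005


@dataclass
class PhasePoint:
    T: float
    P: float
    T_err: float = 0.0
    P_err: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be > 0")


@dataclass
class CoexistenceCurve:
    """(T, P) locus of two-phase coexistence; T strictly increasing."""

    T: np.ndarray
    P: np.ndarray
    phases: str = ""  # "SL" or "LV"

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=np.float64)
        self.P = np.asarray(self.P, dtype=np.float64)
        if len(self.T) != len(self.P) or len(self.T) < 2:
            raise ValueError("need matching T/P arrays of length >= 2")
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("T must be strictly increasing")

    def pressure_at(self, T: float) -> float:
        if not (self.T[0] <= T <= self.T[-1]):
            raise ValueError(f"T={T} outside curve range")
        return float(np.interp(T, self.T, self.P))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"T": self.T, "P": self.P}).to_csv(path, sep="\t",
                                                        index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, phases: str = "") -> "CoexistenceCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(df["T"].to_numpy(), df["P"].to_numpy(), phases)


@dataclass
class EnthalpyTable:
    """h(T) at fixed pressure, interpolated linearly in beta = 1/T."""

    T: np.ndarray
    h: np.ndarray

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=np.float64)
        self.h = np.asarray(self.h, dtype=np.float64)
        if len(self.T) == 0 or len(self.T) != len(self.h):
            raise ValueError("empty or mismatched enthalpy table")
        order = np.argsort(1.0 / self.T)
        self._beta = (1.0 / self.T)[order]
        self._hb = self.h[order]

    def at_beta(self, beta) -> np.ndarray:
        # linear in beta, constant extrapolation beyond the table ends
        return np.interp(beta, self._beta, self._hb)

    @classmethod
    def constant(cls, h: float, T_lo: float = 0.1, T_hi: float = 10.0):
        return cls(np.array([T_lo, T_hi]), np.array([h, h]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnthalpyTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df["T"].to_numpy(), df["h"].to_numpy())


def gibbs_helmholtz_mu(mu0: float, T0: float, h_of_T: EnthalpyTable,
                       T: float, beta_step: float = GH_BETA_STEP) -> float:
    """mu(T) at fixed P from beta*mu(T) = beta0*mu0 + int_beta0^beta h dbeta'.

    Trapezoidal quadrature on a beta grid with step <= `beta_step`;
    exactly reversible in T -> T0 -> T round trips up to roundoff.
    """
    if T <= 0 or T0 <= 0:
        raise ValueError("temperatures must be > 0")
    b0, b1 = 1.0 / T0, 1.0 / T
    if b0 == b1:
        return mu0
    nstep = max(2, int(math.ceil(abs(b1 - b0) / beta_step)) + 1)
    grid = np.linspace(b0, b1, nstep)
    integral = np.trapezoid(h_of_T.at_beta(grid), grid)
    return (b0 * mu0 + integral) / b1


def melting_point(mu_liq0: float, mu_sol0: float, T0: float,
                  h_liq: EnthalpyTable, h_sol: EnthalpyTable, *,
                  bracket: tuple[float, float] | None = None,
                  mu_liq0_err: float = 0.0, mu_sol0_err: float = 0.0,
                  h_err: float = 0.0, n_resample: int = 1000,
                  seed: int = 0, pressure: float = 0.0) -> PhasePoint:
    """Temperature at which the solid and liquid chemical potentials cross.

    Bisection (via brentq) on Delta(beta mu)(T) to |dT| < 1e-6; the quoted
    uncertainty resamples the input chemical potentials (and optionally a
    common enthalpy offset per phase) from their stated errors.
    """
    if bracket is None:
        bracket = (max(0.3 * T0, 0.05), 3.0 * T0)

    def d_beta_mu(T, dml=0.0, dms=0.0, dhl=0.0, dhs=0.0):
        hl = EnthalpyTable(h_liq.T, h_liq.h + dhl) if dhl else h_liq
        hs = EnthalpyTable(h_sol.T, h_sol.h + dhs) if dhs else h_sol
        ml = gibbs_helmholtz_mu(mu_liq0 + dml, T0, hl, T)
        ms = gibbs_helmholtz_mu(mu_sol0 + dms, T0, hs, T)
        return (ms - ml) / T

    if mu_sol0 == mu_liq0:
        return PhasePoint(T0, pressure, label="melting")
    f_lo, f_hi = d_beta_mu(bracket[0]), d_beta_mu(bracket[1])
    if f_lo * f_hi > 0:
        raise ValueError("no sign change of Delta(beta mu) in bracket")
    t_m = brentq(d_beta_mu, bracket[0], bracket[1], xtol=1e-6)

    t_err = 0.0
    if any(e > 0 for e in (mu_liq0_err, mu_sol0_err, h_err)) and n_resample:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_resample):
            args = (rng.normal(0, mu_liq0_err), rng.normal(0, mu_sol0_err),
                    rng.normal(0, h_err), rng.normal(0, h_err))
            try:
                draws.append(brentq(d_beta_mu, bracket[0], bracket[1],
                                    xtol=1e-6, args=args))
            except ValueError:
                continue
        if len(draws) > 10:
            t_err = float(np.std(draws, ddof=1))
    return PhasePoint(float(t_m), pressure, T_err=t_err, label="melting")


def clapeyron_curve(start: PhasePoint, delta_h, delta_v,
                    T_range: tuple[float, float],
                    step: float = CLAPEYRON_T_STEP,
                    phases: str = "SL") -> CoexistenceCurve:
    """Integrate dP/dT = dh / (T dv) from `start` with classic RK4.

    `delta_h` and `delta_v` are callables (T, P) -> value for the phase
    pair (second minus first phase, consistently).  Aborts when dv
    approaches zero.
    """
    def rhs(T, P):
        dv = delta_v(T, P)
        if abs(dv) < 1e-12:
            raise ZeroDivisionError(f"Delta v vanished at T={T:.6f}")
        return delta_h(T, P) / (T * dv)

    def integrate(T_from, P_from, T_to):
        n = max(1, int(math.ceil(abs(T_to - T_from) / step)))
        h = (T_to - T_from) / n
        Ts = [T_from]
        Ps = [P_from]
        T, P = T_from, P_from
        for _ in range(n):
            k1 = rhs(T, P)
            k2 = rhs(T + h / 2, P + h * k1 / 2)
            k3 = rhs(T + h / 2, P + h * k2 / 2)
            k4 = rhs(T + h, P + h * k3)
            P += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
            T += h
            Ts.append(T)
            Ps.append(P)
        return Ts, Ps

    lo, hi = T_range
    if not lo <= start.T <= hi:
        raise ValueError("start temperature outside requested range")
    T_dn, P_dn = integrate(start.T, start.P, lo)
    T_up, P_up = integrate(start.T, start.P, hi)
    T_all = np.array(T_dn[::-1] + T_up[1:])
    P_all = np.array(P_dn[::-1] + P_up[1:])
    keep = np.concatenate([[True], np.diff(T_all) > 1e-15])
    return CoexistenceCurve(T_all[keep], P_all[keep], phases)


def triple_point(sl: CoexistenceCurve, lv: CoexistenceCurve, *,
                 T_err: float = 0.0) -> PhasePoint:
    """Intersection of the solid-liquid and liquid-vapor curves."""
    lo = max(sl.T[0], lv.T[0])
    hi = min(sl.T[-1], lv.T[-1])
    if lo >= hi:
        raise ValueError("curves do not overlap in temperature")

    def diff(T):
        return sl.pressure_at(T) - lv.pressure_at(T)

    grid = np.linspace(lo, hi, 512)
    d = np.array([diff(t) for t in grid])
    if np.all(np.abs(d) < 1e-14):
        raise ValueError("degenerate: curves coincide over the overlap")
    sign = np.sign(d)
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if len(crossings) == 0:
        if np.any(d == 0):
            i = int(np.flatnonzero(d == 0)[0])
            t_t = float(grid[i])
        else:
            raise ValueError("no crossing of SL and LV curves in overlap")
    else:
        i = int(crossings[0])
        t_t = brentq(diff, grid[i], grid[i + 1], xtol=1e-10)
    return PhasePoint(float(t_t), float(lv.pressure_at(t_t)),
                      T_err=T_err, label="triple")


# ---------------------------------------------------------------------------
# liquid-vapor saturation input
# ---------------------------------------------------------------------------

# Clausius-type correlation ln p = A + B/T + C/T^2 fit to reduced-LJ
# vapor-liquid coexistence simulation data for the full (tail-corrected)
# potential; used only to set the (small) pressure of the saturated vapor.
_PSAT_COEFFS = (4.3104149, -8.8819238, 0.8853146)


def lj_saturation_pressure(T: float) -> float:
    """Saturated vapor pressure of the reduced LJ fluid (correlation)."""
    if T <= 0:
        raise ValueError("T must be > 0")
    a, b, c = _PSAT_COEFFS
    return math.exp(a + b / T + c / T ** 2)


def lv_curve(T_lo: float, T_hi: float, n: int = 64) -> CoexistenceCurve:
    """Liquid-vapor coexistence curve from the saturation correlation."""
    T = np.linspace(T_lo, T_hi, n)
    P = np.array([lj_saturation_pressure(t) for t in T])
    return CoexistenceCurve(T, P, "LV")
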