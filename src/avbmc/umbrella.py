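"""Umbrella sampling over cluster size.

A bias eta(n) is added to the configurational energy so that all sizes in
a window are visited; formation free energies are recovered from the
visited-size histogram by

    beta dG(n) = -ln H(n) - beta eta(n) + C,

with the additive constant fixed by an anchor size.  Errors come from five
equal simulation blocks.  Downstream analysis works on the increments
dG(n) - dG(n-1), which are independent of the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

N_BLOCKS = 5


class InsufficientSamplingError(RuntimeError):
    pass


@dataclass
class BiasPotential:
    """eta(n) on a contiguous size range; sizes outside are excluded (+inf)."""

    n_min: int
    eta: np.ndarray

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=np.float64)
        if not np.all(np.isfinite(self.eta)):
            raise ValueError("bias values must be finite")

    @classmethod
    def zero(cls, n_min: int, n_max: int) -> "BiasPotential":
        return cls(n_min, np.zeros(n_max - n_min + 1))

    @property
    def n_max(self) -> int:
        return self.n_min + len(self.eta) - 1

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1)

    def value(self, n: int) -> float:
        if self.n_min <= n <= self.n_max:
            return float(self.eta[n - self.n_min])
        return np.inf

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"n": self.sizes, "eta": self.eta}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BiasPotential":
        df = pd.read_csv(path, sep="\t")
        n = df["n"].to_numpy(dtype=int)
        if not np.all(np.diff(n) == 1):
            raise ValueError("bias table must cover a contiguous size range")
        return cls(int(n[0]), df["eta"].to_numpy(dtype=float))


@dataclass
class SizeHistogram:
    """Visited-size counts over a window, partitioned into 5 blocks."""

    n_min: int
    block_counts: np.ndarray  # (N_BLOCKS, n_sizes)

    def __post_init__(self):
        self.block_counts = np.asarray(self.block_counts, dtype=np.float64)
        if self.block_counts.ndim != 2 or self.block_counts.shape[0] != N_BLOCKS:
            raise ValueError(f"expected {N_BLOCKS} blocks")
        if np.any(self.block_counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def counts(self) -> np.ndarray:
        return self.block_counts.sum(axis=0)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_min + self.block_counts.shape[1])

    @property
    def total(self) -> float:
        return float(self.block_counts.sum())

    def flatness_ratio(self) -> float:
        """max/min of total counts; inf when some size is unvisited."""
        c = self.counts
        if c.min() <= 0:
            return np.inf
        return float(c.max() / c.min())

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for b in range(N_BLOCKS):
            for i, n in enumerate(self.sizes):
                rows.append((n, self.block_counts[b, i], b))
        pd.DataFrame(rows, columns=["n", "counts", "block_id"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SizeHistogram":
        df = pd.read_csv(path, sep="\t")
        sizes = np.sort(df["n"].unique())
        bc = np.zeros((N_BLOCKS, len(sizes)))
        for _, row in df.iterrows():
            bc[int(row.block_id), int(row.n - sizes[0])] = row.counts
        return cls(int(sizes[0]), bc)


@dataclass
class FreeEnergyProfile:
    """dG(n) with an explicit anchor and per-block profiles for errors."""

    n: np.ndarray
    delta_G: np.ndarray
    se: np.ndarray
    block_delta_G: np.ndarray  # (N_BLOCKS, n_sizes)
    anchor: tuple[int, float]

    def value(self, size: int) -> float:
        idx = int(size - self.n[0])
        if not 0 <= idx < len(self.n):
            raise KeyError(f"size {size} outside profile")
        return float(self.delta_G[idx])

    def shifted(self, offset: float) -> "FreeEnergyProfile":
        return FreeEnergyProfile(self.n, self.delta_G + offset, self.se,
                                 self.block_delta_G + offset,
                                 (self.anchor[0], self.anchor[1] + offset))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"n": self.n, "delta_G": self.delta_G,
                      "se": self.se}).to_csv(path, sep="\t", index=False)


@dataclass
class DeltaGSeries:
    """Rows (n, x = n^{2/3} - (n-1)^{2/3}, dG(n) - dG(n-1), standard error)."""

    n: np.ndarray
    x: np.ndarray
    delta: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        for name in ("n", "x", "delta", "se"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(self.n < 2):
            raise ValueError("series starts at n = 2")
        if np.any(np.diff(self.x[np.argsort(self.n)]) >= 0):
            raise ValueError("x must decrease with n")

    def restrict(self, n_lo: int, n_hi: int) -> "DeltaGSeries":
        m = (self.n >= n_lo) & (self.n <= n_hi)
        return DeltaGSeries(self.n[m], self.x[m], self.delta[m], self.se[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n.astype(int), "x": self.x,
                             "dG": self.delta, "err": self.se})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DeltaGSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df["n"].to_numpy(), df["x"].to_numpy(),
                   df["dG"].to_numpy(), df["err"].to_numpy())

    @classmethod
    def concat(cls, parts: list["DeltaGSeries"]) -> "DeltaGSeries":
        n = np.concatenate([p.n for p in parts])
        order = np.argsort(n)
        return cls(n[order],
                   np.concatenate([p.x for p in parts])[order],
                   np.concatenate([p.delta for p in parts])[order],
                   np.concatenate([p.se for p in parts])[order])


def shape_x(n) -> np.ndarray:
    """CNT surface-area increment n^{2/3} - (n-1)^{2/3}."""
    n = np.asarray(n, dtype=np.float64)
    return n ** (2.0 / 3.0) - (n - 1.0) ** (2.0 / 3.0)


def unbias(hist: SizeHistogram, bias: BiasPotential, T: float,
           anchor: tuple[int, float] | None = None) -> FreeEnergyProfile:
    """Histogram -> formation free energies, with 5-block standard errors.

    Every size in the window must be visited in every block; otherwise the
    block free energies are undefined and an InsufficientSamplingError
    names the offending size.
    """
    sizes = hist.sizes
    beta_eta = np.array([bias.value(n) for n in sizes]) / T
    for b in range(N_BLOCKS):
        for i, n in enumerate(sizes):
            if hist.block_counts[b, i] <= 0:
                raise InsufficientSamplingError(
                    f"insufficient sampling: size {n} unvisited in block {b}")
    if anchor is None:
        anchor = (int(sizes[0]), 0.0)
    n0, g0 = anchor
    i0 = int(n0 - sizes[0])
    if not 0 <= i0 < len(sizes):
        raise ValueError("anchor outside histogram window")

    def profile(counts):
        bg = -np.log(counts) - beta_eta
        g = T * bg
        return g - g[i0] + g0

    block_g = np.stack([profile(hist.block_counts[b]) for b in range(N_BLOCKS)])
    g_tot = profile(hist.counts)
    se = block_g.std(axis=0, ddof=1) / np.sqrt(N_BLOCKS)
    return FreeEnergyProfile(sizes, g_tot, se, block_g, (n0, g0))


def adapt_bias(profile: FreeEnergyProfile) -> BiasPotential:
    """Next-iteration bias: the negative of the current free-energy estimate."""
    if not np.all(np.isfinite(profile.delta_G)):
        raise ValueError("profile must be finite")
    eta = -profile.delta_G
    return BiasPotential(int(profile.n[0]), eta - eta[0])


def delta_g_series(profile: FreeEnergyProfile) -> DeltaGSeries:
    """Adjacent-size free-energy increments; anchor-independent by construction.

    Standard errors are the block scatter of the per-block increments (the
    increments, not the two endpoint errors, since adjacent dG values from
    the same run are strongly correlated).
    """
    ns = profile.n.astype(int)
    keep = np.isin(ns - 1, ns) & (ns >= 2)
    rows_n = ns[keep]
    idx = {int(n): i for i, n in enumerate(ns)}
    i_hi = np.array([idx[int(n)] for n in rows_n])
    i_lo = np.array([idx[int(n) - 1] for n in rows_n])
    delta = profile.delta_G[i_hi] - profile.delta_G[i_lo]
    block_delta = profile.block_delta_G[:, i_hi] - profile.block_delta_G[:, i_lo]
    se = block_delta.std(axis=0, ddof=1) / np.sqrt(N_BLOCKS)
    return DeltaGSeries(rows_n, shape_x(rows_n), delta, se)


def cnt_extend_bias(fit, anchor: tuple[int, float],
                    target_sizes) -> BiasPotential:
    """Extend a bias to larger sizes along the fitted CNT line.

    dG is continued from the anchor (n_ref, dG(n_ref)) by adding
    b + s*(m^{2/3} - (m-1)^{2/3}) per particle; the bias is its negative.
    `fit` needs .slope and .intercept.
    """
    n_ref, g_ref = int(anchor[0]), float(anchor[1])
    target_sizes = np.asarray(target_sizes, dtype=int)
    if target_sizes.min() <= n_ref:
        raise ValueError("extrapolation targets must exceed the anchor size")
    n_hi = int(target_sizes.max())
    ms = np.arange(n_ref + 1, n_hi + 1)
    increments = fit.intercept + fit.slope * shape_x(ms)
    g = g_ref + np.cumsum(increments)
    eta_all = -g  # indexed by n_ref+1 .. n_hi
    n_lo = int(target_sizes.min())
    return BiasPotential(n_lo, eta_all[n_lo - (n_ref + 1):])


def stitch_profiles(profiles: list[FreeEnergyProfile]) -> pd.DataFrame:
    """Align overlapping window profiles by least squares on shared sizes.

    Requires >= 2 shared sizes between consecutive windows (sorted by
    starting size).  Returns a table (n, delta_G, se) on the union grid;
    overlap rows keep the earlier window's value.
    """
    profiles = sorted(profiles, key=lambda p: p.n[0])
    out_n = list(profiles[0].n.astype(int))
    out_g = list(profiles[0].delta_G)
    out_se = list(profiles[0].se)
    for p in profiles[1:]:
        shared = np.intersect1d(np.array(out_n), p.n.astype(int))
        if len(shared) < 2:
            raise ValueError("windows must overlap in at least 2 sizes")
        have = {n: g for n, g in zip(out_n, out_g)}
        offset = float(np.mean([have[int(n)] - p.value(int(n)) for n in shared]))
        for n, g, s in zip(p.n.astype(int), p.delta_G + offset, p.se):
            if n not in have:
                out_n.append(int(n))
                out_g.append(float(g))
                out_se.append(float(s))
    order = np.argsort(out_n)
    return pd.DataFrame({"n": np.array(out_n)[order],
                         "delta_G": np.array(out_g)[order],
                         "se": np.array(out_se)[order]})
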