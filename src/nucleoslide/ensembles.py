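"""Residence distributions, free-energy surfaces and hydrogen-bond
strength reweighting.

Frames are records of (trajectory id, sliding coordinate in bp,
rotation coordinate in deg, per-frame hydrogen-bond energy ``v_hb`` at
the reference bond strength eps).  Free energies are reported as
F = -ln P in kBT with the minimum shifted to zero; empty bins are
masked rather than pseudocounted.

Because the hydrogen-bond potential is exactly linear in its strength
eps, an ensemble sampled at eps can be reweighted to a different
strength eps' with per-frame weights

    w  proportional to  exp(-(eps'/eps - 1) * v_hb)

(all other energy terms cancel).  The effective sample size
(sum w)^2 / sum w^2 quantifies the reliability of the reweighted
estimate; it equals the frame count only at eps' = eps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["traj_id", "bp_shift", "eta_deg", "v_hb"]

DEFAULT_BP_BIN = 0.25   # bp
DEFAULT_ETA_BIN = 9.0   # deg


def as_records(data) -> pd.DataFrame:
    """Coerce input to a record table with the canonical columns."""
    df = pd.DataFrame(data)
    if "traj_id" not in df.columns:
        df["traj_id"] = 0
    if "v_hb" not in df.columns:
        df["v_hb"] = 0.0
    if "eta_deg" not in df.columns:
        df["eta_deg"] = np.nan
    missing = {"bp_shift"} - set(df.columns)
    if missing:
        raise ValueError(f"records lack columns {sorted(missing)}")
    return df[RECORD_COLUMNS]


def burn_in(records, n_discard: int) -> pd.DataFrame:
    """Drop the first ``n_discard`` frames of every trajectory.

    Trajectories left empty are dropped entirely with a warning.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    df = as_records(records)
    if n_discard == 0:
        return df.copy()
    kept = []
    for tid, grp in df.groupby("traj_id", sort=False):
        if len(grp) <= n_discard:
            warnings.warn(f"trajectory {tid!r} fully discarded by burn-in",
                          stacklevel=2)
            continue
        kept.append(grp.iloc[n_discard:])
    if not kept:
        return df.iloc[0:0].copy()
    return pd.concat(kept, ignore_index=True)


def residence_distribution(records, bin_width: float = 1.0):
    """Normalized histogram of the sliding coordinate.

    Bins are centred on integer multiples of ``bin_width`` so that a
    lattice of discrete shifts maps one state per bin.  Returns
    (bin_centers, probabilities).
    """
    df = as_records(records)
    if df.empty:
        raise ValueError("no records")
    x = df["bp_shift"].to_numpy(dtype=float)
    lo = np.floor(x.min() / bin_width) - 0.5
    hi = np.ceil(x.max() / bin_width) + 0.5
    edges = np.arange(lo, hi + 1) * bin_width
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum()


@dataclass
class FreeEnergySurface:
    """Binned -ln P over (bp_shift [, eta]) in kBT.

    ``f`` is NaN on empty bins; over occupied bins the underlying
    probabilities sum to one and min(f) = 0.
    """

    bin_edges: tuple            # one or two arrays of edges
    counts: np.ndarray          # histogram weights
    f: np.ndarray               # -ln P, min-shifted, NaN-masked
    epsilon: float              # hydrogen-bond strength of this surface
    effective_samples: float
    axes: tuple = ("bp_shift",)

    @property
    def bin_centers(self):
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.bin_edges)

    def delta_f(self, x_a, x_b) -> float:
        """F(b) - F(a) between the bins containing two coordinates
        (1D surfaces only)."""
        if len(self.bin_edges) != 1:
            raise ValueError("delta_f is defined for 1D surfaces")
        e = self.bin_edges[0]
        ia = np.clip(np.searchsorted(e, x_a, side="right") - 1, 0, len(e) - 2)
        ib = np.clip(np.searchsorted(e, x_b, side="right") - 1, 0, len(e) - 2)
        return float(self.f[ib] - self.f[ia])


def _make_edges(x, width):
    lo = np.floor(x.min() / width) - 0.5
    hi = np.ceil(x.max() / width) + 0.5
    return np.arange(lo, hi + 1) * width


def free_energy_surface(records, bp_bin: float = DEFAULT_BP_BIN,
                        eta_bin: float | None = None,
                        weights=None, epsilon: float = 1.2) -> FreeEnergySurface:
    """Histogram free energy F = -ln P (kBT) over the sliding coordinate,
    optionally 2D over (sliding, rotation).

    ``weights`` are optional per-frame statistical weights (used by the
    reweighting estimator); by default every frame counts once.
    """
    df = as_records(records)
    if df.empty:
        raise ValueError("no records")
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)
    x = df["bp_shift"].to_numpy(dtype=float)
    if eta_bin is None:
        edges = (_make_edges(x, bp_bin),)
        counts, _ = np.histogram(x, bins=edges[0], weights=w)
        axes = ("bp_shift",)
    else:
        y = df["eta_deg"].to_numpy(dtype=float)
        edges = (_make_edges(x, bp_bin), _make_edges(y, eta_bin))
        counts, _, _ = np.histogram2d(x, y, bins=edges, weights=w)
        axes = ("bp_shift", "eta_deg")
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        f = -np.log(np.where(p > 0, p, np.nan))
    f = f - np.nanmin(f)
    ess = float(w.sum() ** 2 / np.sum(w**2))
    return FreeEnergySurface(bin_edges=edges, counts=counts, f=f,
                             epsilon=epsilon, effective_samples=ess, axes=axes)


def reweight_surface(records, eps_prime: float, eps_ref: float = 1.2,
                     bp_bin: float = DEFAULT_BP_BIN,
                     eta_bin: float | None = None) -> FreeEnergySurface:
    """Free-energy surface at bond strength ``eps_prime`` estimated from
    an ensemble sampled at ``eps_ref``.

    Uses the exact linearity of the hydrogen-bond energy in its
    strength: each frame is weighted by exp(-(eps'/eps - 1) * v_hb)
    with ``v_hb`` the frame's hydrogen-bond energy at ``eps_ref``.
    """
    if eps_ref == 0:
        raise ValueError("reference epsilon must be non-zero")
    df = as_records(records)
    if df.empty:
        raise ValueError("no records")
    dv = (eps_prime / eps_ref - 1.0) * df["v_hb"].to_numpy(dtype=float)
    w = np.exp(-(dv - dv.min()))   # shift for numerical stability
    w /= w.sum()
    out = free_energy_surface(df, bp_bin=bp_bin, eta_bin=eta_bin,
                              weights=w, epsilon=eps_prime)
    return out


def block_bootstrap_delta_f(records, x_a, x_b, eps_prime: float,
                            eps_ref: float = 1.2, bp_bin: float = DEFAULT_BP_BIN,
                            n_boot: int = 200, seed: int = 0):
    """Standard error of a reweighted free-energy difference by
    bootstrap over independent trajectories (blocks)."""
    df = as_records(records)
    tids = df["traj_id"].unique()
    rng = np.random.default_rng(seed)
    groups = {t: g for t, g in df.groupby("traj_id", sort=False)}
    vals = []
    for _ in range(n_boot):
        pick = rng.choice(tids, size=len(tids), replace=True)
        boot = pd.concat([groups[t] for t in pick], ignore_index=True)
        try:
            s = reweight_surface(boot, eps_prime, eps_ref, bp_bin=bp_bin)
            vals.append(s.delta_f(x_a, x_b))
        except (ValueError, FloatingPointError):
            continue
    vals = np.asarray(vals, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        return np.nan
    return float(vals.std(ddof=1))


@dataclass
class FrameRecord:
    """One analysed frame (convenience constructor for record tables)."""

    bp_shift: float
    eta_deg: float = np.nan
    v_hb: float = 0.0
    traj_id: int = 0


def read_records_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return as_records(df)


def write_records_tsv(records, path) -> None:
    as_records(records).to_csv(path, sep="\t", index=False)
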