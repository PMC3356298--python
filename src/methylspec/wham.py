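"""Potential of mean force from umbrella windows via WHAM.

Umbrella sampling restrains the SN2 reaction coordinate
R = r(CM…Sδ) − r(CM…Nζ) in overlapping windows with harmonic biases
w_i(R) = k_i·(R − c_i)² (no ½ prefactor — the CHARMM umbrella
convention; pass ``half_k=True`` for the ½k convention).  The Weighted
Histogram Analysis Method recombines the biased histograms into one
unbiased profile by iterating the self-consistency equations

    P(b) = [Σ_i n_i(b)] / [Σ_i N_i exp((f_i − w_i(b)) / k_B T)]
    f_i  = −k_B T · ln Σ_b P(b) exp(−w_i(b) / k_B T)

to a fixed point of the window free-energy constants f_i (gauge
f_1 = 0), then F(b) = −k_B T ln P(b), anchored so the reactant-region
minimum is zero.  All exponentials are evaluated in log space, so
arbitrarily stiff biases are safe.

Barrier extraction reads the profile directly — no smoothing — and the
empirical correction step adds an externally supplied ΔE(R) curve
through monotone cubic interpolation (the curve is derived elsewhere by
comparing the semi-empirical QM Hamiltonian against a higher-level
reference on a small model system; this module only applies it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import logsumexp

from .constants import kt
from .errors import (
    EmptyDataError,
    ExtrapolationError,
    NoBarrierError,
    ParameterError,
)
from .io import UmbrellaWindow

__all__ = [
    "PMFProfile",
    "BarrierResult",
    "CorrectionCurve",
    "wham_solve",
    "extract_barrier",
    "apply_correction",
    "bootstrap_pmf",
    "DEFAULT_GRID",
]

#: default reaction-coordinate grid: R ∈ [−2.5, 2.5] Å, 0.05 Å bins
DEFAULT_GRID = (-2.5, 2.5, 0.05)


class CoverageWarning(UserWarning):
    """Window overlap or interior-gap data-quality warning."""


@dataclass(frozen=True)
class PMFProfile:
    """Free energy vs R on a uniform grid; NaN where bins hold no samples."""

    grid: np.ndarray  # bin centers, Å
    free_energy: np.ndarray  # kcal/mol, NaN-masked
    temperature: float  # K
    window_shifts: np.ndarray  # f_i, kcal/mol, gauge f_1 = 0
    converged: bool
    iterations: int
    n_samples_per_bin: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.free_energy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "R": self.grid,
                "free_energy": self.free_energy,
                "defined": self.defined.astype(int),
                "n_samples": self.n_samples_per_bin.astype(int),
            }
        )


@dataclass(frozen=True)
class BarrierResult:
    """Forward barrier of a PMF: ΔF‡ = F(R_TS) − F(R_reactant)."""

    barrier: float  # kcal/mol
    R_reactant: float  # Å
    R_TS: float  # Å
    F_TS: float  # kcal/mol


@dataclass(frozen=True)
class CorrectionCurve:
    """Knots (R, ΔE) of an empirical free-energy correction."""

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self):
        k = tuple((float(r), float(e)) for r, e in self.knots)
        if len(k) < 2:
            raise ParameterError("a correction curve needs at least 2 knots")
        rs = np.array([r for r, _ in k])
        if np.any(np.diff(rs) <= 0):
            raise ParameterError("correction-curve R knots must be strictly increasing")
        object.__setattr__(self, "knots", k)

    @classmethod
    def zero(cls, r_min: float = -3.0, r_max: float = 3.0) -> "CorrectionCurve":
        """The identity correction (ΔE ≡ 0) spanning [r_min, r_max]."""
        return cls(knots=((r_min, 0.0), (r_max, 0.0)))

    @classmethod
    def from_file(cls, path: str | Path) -> "CorrectionCurve":
        """Read a 2-column (R, ΔE) text/CSV file."""
        arr = np.loadtxt(path, delimiter=None if str(path).endswith(".dat") else ",", ndmin=2)
        return cls(knots=tuple((float(r), float(e)) for r, e in arr[:, :2]))

    def interpolator(self) -> PchipInterpolator:
        rs = np.array([r for r, _ in self.knots])
        es = np.array([e for _, e in self.knots])
        return PchipInterpolator(rs, es, extrapolate=False)


def _grid_edges(grid: tuple[float, float, float]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi, width = grid
    if width <= 0 or hi <= lo:
        raise ParameterError(f"bad grid spec {grid}")
    n = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return edges, centers


def _check_overlap(windows: Sequence[UmbrellaWindow]) -> None:
    ordered = sorted(windows, key=lambda w: w.center)
    for a, b in zip(ordered, ordered[1:]):
        if a.samples.max() < b.samples.min() or b.samples.max() < a.samples.min():
            warnings.warn(
                f"umbrella windows at centers {a.center:g} and {b.center:g} have "
                "disjoint sample ranges; the PMF may be unreliable between them",
                CoverageWarning,
                stacklevel=3,
            )


def _anchor(free_energy: np.ndarray, reactant_side: str) -> np.ndarray:
    """Shift F so the reactant-region minimum is 0.

    With a detectable interior maximum the reactant-side minimum is
    used; for single-basin profiles the global minimum.
    """
    f = free_energy.copy()
    defined = ~np.isnan(f)
    if not defined.any():
        return f
    try:
        i_ts, i_react, _ = _barrier_indices(f, reactant_side)
        ref = f[i_react]
    except NoBarrierError:
        ref = np.nanmin(f)
    return f - ref


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    temperature: float = 283.15,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    tolerance: float = 1e-6,
    max_iterations: int = 100_000,
    half_k: bool = False,
    reactant_side: str = "negative",
) -> PMFProfile:
    """Self-consistent WHAM estimate of the PMF along R.

    Parameters
    ----------
    windows
        Umbrella windows (center, force constant, sampled R series).
    temperature
        Simulation temperature in K.
    grid
        (low, high, bin width) of the uniform R grid in Å.
    tolerance
        Convergence threshold on max|Δf_i| in kcal/mol.
    max_iterations
        Fixed-point iteration cap; non-convergence is reported in the
        returned profile (``converged=False``) with a warning, never
        silently.
    half_k
        Interpret force constants under the ½k(R−c)² convention.
    reactant_side
        'negative' (methyl on the sulfur donor; default) or 'positive';
        fixes which side's minimum anchors F = 0.
    """
    if not windows:
        raise ParameterError("at least one umbrella window is required")
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    kbt = kt(temperature)
    edges, centers = _grid_edges(grid)
    _check_overlap(windows)

    n_win = len(windows)
    counts = np.zeros((n_win, centers.size))
    for i, w in enumerate(windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
    n_tot = counts.sum(axis=0)
    occupied = n_tot > 0
    if not occupied.any():
        raise EmptyDataError("no window samples fall on the WHAM grid")

    n_i = counts.sum(axis=1)  # samples per window that landed on the grid
    bias = np.stack([w.bias_energy(centers, half_k=half_k) for w in windows])  # (W, B)
    log_ni = np.log(np.where(n_i > 0, n_i, 1.0))
    log_ntot = np.where(occupied, np.log(np.where(occupied, n_tot, 1.0)), -np.inf)

    f = np.zeros(n_win)  # window free-energy constants, kcal/mol
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        # log denominator(b) = logsumexp_i [ ln N_i + (f_i − w_i(b))/kBT ]
        log_denom = logsumexp(
            log_ni[:, None] + (f[:, None] - bias) / kbt, axis=0,
            b=(n_i > 0)[:, None].astype(float),
        )
        log_p = log_ntot - log_denom  # unnormalized; -inf off-grid
        # f_i = −kBT ln Σ_b P(b) exp(−w_i(b)/kBT)
        f_new = -kbt * logsumexp(log_p[None, :] - bias / kbt, axis=1)
        f_new -= f_new[0]  # gauge: f_1 = 0
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iterations} iterations "
            f"(last max|Δf| = {delta:.3g} kcal/mol)",
            CoverageWarning,
            stacklevel=2,
        )

    log_denom = logsumexp(
        log_ni[:, None] + (f[:, None] - bias) / kbt, axis=0,
        b=(n_i > 0)[:, None].astype(float),
    )
    log_p = log_ntot - log_denom
    free_energy = np.where(occupied, -kbt * log_p, np.nan)
    free_energy = _anchor(free_energy, reactant_side)

    return PMFProfile(
        grid=centers,
        free_energy=free_energy,
        temperature=temperature,
        window_shifts=f,
        converged=converged,
        iterations=it,
        n_samples_per_bin=n_tot,
    )


def _barrier_indices(
    free_energy: np.ndarray, reactant_side: str
) -> tuple[int, int, int]:
    """Locate (TS, reactant-min, product-min) indices on a masked profile.

    The TS is the highest interior-maximum bin: a defined bin with at
    least one strictly lower defined bin on each side.  Raises
    :class:`NoBarrierError` for monotone profiles.
    """
    if reactant_side not in ("negative", "positive"):
        raise ParameterError(f"reactant_side must be 'negative' or 'positive'")
    defined = np.flatnonzero(~np.isnan(free_energy))
    if defined.size < 3:
        raise NoBarrierError("profile has fewer than 3 defined bins")
    f = free_energy[defined]
    # running minima over defined bins only
    left_min = np.minimum.accumulate(f)
    right_min = np.minimum.accumulate(f[::-1])[::-1]
    interior = np.flatnonzero(
        (np.roll(left_min, 1) < f) & (np.roll(right_min, -1) < f)
    )
    interior = interior[(interior > 0) & (interior < f.size - 1)]
    if interior.size == 0:
        raise NoBarrierError("profile is monotone: no interior maximum")
    k_ts = interior[np.argmax(f[interior])]
    if reactant_side == "negative":
        k_react = int(np.argmin(f[: k_ts + 1]))
        k_prod = k_ts + int(np.argmin(f[k_ts:]))
    else:
        k_react = k_ts + int(np.argmin(f[k_ts:]))
        k_prod = int(np.argmin(f[: k_ts + 1]))
    return int(defined[k_ts]), int(defined[k_react]), int(defined[k_prod])


def extract_barrier(profile: PMFProfile, reactant_side: str = "negative") -> BarrierResult:
    """Forward barrier read directly off the profile (no smoothing).

    R_reactant is the lowest defined bin on the reactant side, R_TS the
    highest defined bin between the two minima.  An interior gap wider
    than 3 masked bins between reactant minimum and TS triggers a
    data-quality warning.
    """
    i_ts, i_react, _ = _barrier_indices(profile.free_energy, reactant_side)
    lo, hi = sorted((i_react, i_ts))
    gap = 0
    worst_gap = 0
    for i in range(lo, hi + 1):
        if np.isnan(profile.free_energy[i]):
            gap += 1
            worst_gap = max(worst_gap, gap)
        else:
            gap = 0
    if worst_gap > 3:
        warnings.warn(
            f"{worst_gap} consecutive empty bins between reactant minimum and TS; "
            "barrier may be unreliable",
            CoverageWarning,
            stacklevel=2,
        )
    f_ts = float(profile.free_energy[i_ts])
    f_react = float(profile.free_energy[i_react])
    return BarrierResult(
        barrier=f_ts - f_react,
        R_reactant=float(profile.grid[i_react]),
        R_TS=float(profile.grid[i_ts]),
        F_TS=f_ts,
    )


def apply_correction(
    profile: PMFProfile, curve: CorrectionCurve, reactant_side: str = "negative"
) -> PMFProfile:
    """Add ΔE(R) (monotone cubic through the knots) to the profile.

    The curve must span the profile's defined grid range — extrapolation
    is forbidden.  The corrected profile is re-anchored so the reactant
    minimum is 0.
    """
    defined = profile.defined
    if not defined.any():
        raise EmptyDataError("profile has no defined bins")
    r_def = profile.grid[defined]
    r_knots = np.array([r for r, _ in curve.knots])
    if r_def.min() < r_knots[0] or r_def.max() > r_knots[-1]:
        raise ExtrapolationError(
            f"correction curve spans [{r_knots[0]:g}, {r_knots[-1]:g}] Å but the "
            f"profile is defined on [{r_def.min():g}, {r_def.max():g}] Å"
        )
    delta = curve.interpolator()(profile.grid)
    corrected = np.where(defined, profile.free_energy + delta, np.nan)
    corrected = _anchor(corrected, reactant_side)
    return PMFProfile(
        grid=profile.grid,
        free_energy=corrected,
        temperature=profile.temperature,
        window_shifts=profile.window_shifts,
        converged=profile.converged,
        iterations=profile.iterations,
        n_samples_per_bin=profile.n_samples_per_bin,
    )


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_resamples: int = 50,
    seed: int = 0,
    **wham_kwargs,
) -> pd.DataFrame:
    """Bootstrap PMF uncertainty: resample within windows, re-solve WHAM.

    Returns a DataFrame (R, mean, std, n_defined) over the resamples.
    Purely diagnostic; the point estimate remains :func:`wham_solve` on
    the full samples.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    grid = None
    for _ in range(n_resamples):
        resampled = [
            UmbrellaWindow(
                center=w.center,
                force_constant=w.force_constant,
                samples=rng.choice(w.samples, size=w.samples.size, replace=True),
            )
            for w in windows
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CoverageWarning)
            prof = wham_solve(resampled, **wham_kwargs)
        grid = prof.grid
        profiles.append(prof.free_energy)
    stack = np.stack(profiles)
    return pd.DataFrame(
        {
            "R": grid,
            "mean": np.nanmean(stack, axis=0),
            "std": np.nanstd(stack, axis=0),
            "n_defined": np.sum(~np.isnan(stack), axis=0),
        }
    )
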