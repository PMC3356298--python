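"""Reactive-configuration statistics of the SN2 methyl transfer.

For every trajectory frame we measure the geometry that governs how
easily the methyl group hops from the AdoMet sulfur (Sδ) to the lysine
ε-amino nitrogen (Nζ):

* ``r_CN`` — distance from the transferable methyl carbon CM to Nζ (Å),
* ``r_CS`` — distance from CM to Sδ (Å),
* ``R = r_CS − r_CN`` — the SN2 reaction coordinate (negative in the
  reactant, where the methyl is bonded to sulfur),
* ``theta`` — the angle between the lone-pair direction on Nζ and the
  CM→Sδ vector; 0° is perfect in-line SN2 alignment.

The lone-pair direction is constructed geometrically as the negative
normalized sum of the three unit bond vectors at Nζ — exact for an
ideal sp³ nitrogen and robust to moderate distortion.

Ensembles of these records become 2D (r, θ) histograms, Boltzmann-
inverted free-energy surfaces F = −k_B·T·ln(p/p_max), 1D marginal
free-energy profiles, and geometric hydrogen-bond occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import kt
from .errors import (
    DegenerateGeometryError,
    EmptyDataError,
    ParameterError,
    RoleResolutionError,
)
from .io import Frame, FrameSeries, RoleMap

__all__ = [
    "GeometryRecord",
    "Histogram2D",
    "FreeEnergySurface",
    "HBondSpec",
    "lone_pair_direction",
    "compute_geometry",
    "geometry_table",
    "build_histogram2d",
    "boltzmann_invert",
    "marginal_free_energy",
    "hbond_occupancy",
    "DEFAULT_R_EDGES",
    "DEFAULT_THETA_EDGES",
]

#: default bins: r ∈ [2, 6] Å in 0.05 Å steps, θ ∈ [0°, 180°] in 5° steps
DEFAULT_R_EDGES = np.round(np.arange(2.0, 6.0 + 1e-9, 0.05), 10)
DEFAULT_THETA_EDGES = np.arange(0.0, 180.0 + 1e-9, 5.0)


@dataclass(frozen=True)
class GeometryRecord:
    """Per-frame SN2 geometry; R = r_CS − r_CN holds exactly."""

    frame_index: int
    r_CN: float  # Å
    r_CS: float  # Å
    R: float  # Å
    theta: float  # degrees

    def __post_init__(self):
        if self.r_CN <= 0 or self.r_CS <= 0:
            raise ParameterError("distances must be positive")
        if not (0.0 <= self.theta <= 180.0):
            raise ParameterError(f"theta must lie in [0, 180], got {self.theta}")


@dataclass(frozen=True)
class Histogram2D:
    """2D (r, θ) occupancy histogram on strictly increasing bin edges.

    Binning is half-open [low, high) with the last bin closed; records
    exactly on an interior edge go to the higher bin.  Out-of-range
    records are counted in ``n_out_of_range``, never binned.
    """

    r_edges: np.ndarray
    theta_edges: np.ndarray
    counts: np.ndarray  # shape (len(r_edges)-1, len(theta_edges)-1), ints
    n_total: int
    n_out_of_range: int = 0

    def __post_init__(self):
        r = np.asarray(self.r_edges, float)
        t = np.asarray(self.theta_edges, float)
        c = np.asarray(self.counts)
        if np.any(np.diff(r) <= 0) or np.any(np.diff(t) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if c.shape != (r.size - 1, t.size - 1):
            raise ParameterError("counts shape does not match edges")
        if np.any(c < 0):
            raise ParameterError("counts must be non-negative")
        if int(c.sum()) != self.n_total:
            raise ParameterError("sum of counts must equal n_total")
        object.__setattr__(self, "r_edges", r)
        object.__setattr__(self, "theta_edges", t)
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])


@dataclass(frozen=True)
class FreeEnergySurface:
    """Boltzmann-inverted F(r, θ) in kcal/mol; NaN where counts = 0.

    The minimum over defined cells is exactly 0.
    """

    r_edges: np.ndarray
    theta_edges: np.ndarray
    free_energy: np.ndarray  # kcal/mol, NaN-masked
    counts: np.ndarray
    temperature: float  # K

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        rr, tt = np.meshgrid(self.r_centers, self.theta_centers, indexing="ij")
        return pd.DataFrame(
            {
                "r": rr.ravel(),
                "theta": tt.ravel(),
                "free_energy": self.free_energy.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass(frozen=True)
class HBondSpec:
    """Geometric hydrogen-bond criterion over role-map selections.

    A frame satisfies the bond when the donor-heavy-atom…acceptor
    distance is ≤ ``distance_cutoff`` and, if a hydrogen selector is
    given, the D–H…A angle is ≥ ``angle_cutoff``.
    """

    donor: str
    acceptor: str
    hydrogen: str | None = None
    distance_cutoff: float = 3.5  # Å
    angle_cutoff: float = 120.0  # degrees

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ParameterError("H-bond cutoffs must be positive")


def lone_pair_direction(frame: Frame, roles: RoleMap) -> np.ndarray:
    """Unit vector along the Nζ lone pair.

    u = −normalize(Σᵢ normalize(pᵢ − p_N)) over the three substituents;
    invariant under rigid rotation and translation.  A planar nitrogen
    (substituent unit vectors summing to ~0) is degenerate.
    """
    p_n = roles.resolve(frame, "n_zeta").position
    total = np.zeros(3)
    for i in range(1, 4):
        p_i = roles.resolve(frame, f"n_substituent_{i}").position
        bond = p_i - p_n
        norm = np.linalg.norm(bond)
        if norm < 1e-12:
            raise DegenerateGeometryError(
                f"substituent {i} coincides with N_zeta in frame {frame.index}"
            )
        total += bond / norm
    n = np.linalg.norm(total)
    if n < 1e-8:
        raise DegenerateGeometryError(
            f"planar/degenerate nitrogen geometry in frame {frame.index}: "
            f"substituent sum vector norm {n:.2e} < 1e-8"
        )
    return -total / n


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compute_geometry(frames: FrameSeries) -> list[GeometryRecord]:
    """Measure (r_CN, r_CS, R, θ) for every frame, in frame order."""
    records = []
    roles = frames.role_map
    for frame in frames.frames:
        p_s = roles.resolve(frame, "s_delta").position
        p_c = roles.resolve(frame, "c_methyl").position
        p_n = roles.resolve(frame, "n_zeta").position
        try:
            u = lone_pair_direction(frame, roles)
        except DegenerateGeometryError as exc:
            raise DegenerateGeometryError(f"frame {frame.index}: {exc}") from exc
        r_cn = float(np.linalg.norm(p_c - p_n))
        r_cs = float(np.linalg.norm(p_c - p_s))
        theta = _angle_deg(u, p_s - p_c)
        records.append(
            GeometryRecord(
                frame_index=frame.index,
                r_CN=r_cn,
                r_CS=r_cs,
                R=r_cs - r_cn,
                theta=theta,
            )
        )
    return records


def geometry_table(records: list[GeometryRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame (one row per frame)."""
    return pd.DataFrame(
        {
            "frame_index": [r.frame_index for r in records],
            "r_CN": [r.r_CN for r in records],
            "r_CS": [r.r_CS for r in records],
            "R": [r.R for r in records],
            "theta": [r.theta for r in records],
        }
    )


def build_histogram2d(
    records: list[GeometryRecord],
    r_edges: np.ndarray | None = None,
    theta_edges: np.ndarray | None = None,
) -> Histogram2D:
    """Bin (r_CN, θ) records on the given edges.

    Half-open bins [low, high), last bin closed; a value exactly on an
    interior edge goes to the higher bin (numpy's histogram convention).
    """
    if not records:
        raise EmptyDataError("no geometry records to histogram")
    r_edges = DEFAULT_R_EDGES if r_edges is None else np.asarray(r_edges, float)
    theta_edges = DEFAULT_THETA_EDGES if theta_edges is None else np.asarray(theta_edges, float)
    if np.any(np.diff(r_edges) <= 0) or np.any(np.diff(theta_edges) <= 0):
        raise ParameterError("bin edges must be strictly increasing")
    r = np.array([rec.r_CN for rec in records])
    t = np.array([rec.theta for rec in records])
    in_range = (
        (r >= r_edges[0]) & (r <= r_edges[-1]) & (t >= theta_edges[0]) & (t <= theta_edges[-1])
    )
    n_out = int((~in_range).sum())
    if n_out == len(records):
        raise EmptyDataError("all records fall outside the histogram range")
    counts, _, _ = np.histogram2d(r[in_range], t[in_range], bins=[r_edges, theta_edges])
    return Histogram2D(
        r_edges=r_edges,
        theta_edges=theta_edges,
        counts=counts.astype(np.int64),
        n_total=int(counts.sum()),
        n_out_of_range=n_out,
    )


def boltzmann_invert(hist: Histogram2D, temperature: float) -> FreeEnergySurface:
    """F_cell = −k_B·T·ln(count/count_max); zero-count cells are masked.

    The most-populated cell sits at F = 0 exactly, so the minimum over
    defined cells is 0.
    """
    kbt = kt(temperature)
    if hist.n_total <= 0:
        raise EmptyDataError("histogram is empty")
    counts = hist.counts.astype(float)
    cmax = counts.max()
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(counts / cmax)
    f[hist.counts == 0] = np.nan
    return FreeEnergySurface(
        r_edges=hist.r_edges,
        theta_edges=hist.theta_edges,
        free_energy=f,
        counts=hist.counts,
        temperature=temperature,
    )


def marginal_free_energy(
    hist: Histogram2D, axis: str, temperature: float
) -> pd.DataFrame:
    """1D free-energy profile along ``axis`` ('r' or 'theta').

    Counts are summed over the other axis, then Boltzmann-inverted; the
    minimum over defined bins is 0.  Returns columns (center, free_energy,
    count); empty bins carry NaN free energy.
    """
    kbt = kt(temperature)
    if axis == "r":
        c = hist.counts.sum(axis=1).astype(float)
        centers = hist.r_centers
    elif axis == "theta":
        c = hist.counts.sum(axis=0).astype(float)
        centers = hist.theta_centers
    else:
        raise ParameterError(f"axis must be 'r' or 'theta', got {axis!r}")
    if c.sum() <= 0:
        raise EmptyDataError("histogram is empty")
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(c / c.max())
    f[c == 0] = np.nan
    return pd.DataFrame({"center": centers, "free_energy": f, "count": c.astype(np.int64)})


def hbond_occupancy(frames: FrameSeries, spec: HBondSpec) -> float:
    """Fraction of frames (in [0, 1]) satisfying the H-bond criterion."""
    roles = frames.role_map
    n_ok = 0
    for frame in frames.frames:
        try:
            p_d = roles.resolve(frame, "hbond_donor", spec.donor).position
            p_a = roles.resolve(frame, "hbond_acceptor", spec.acceptor).position
        except RoleResolutionError:
            raise
        if np.linalg.norm(p_d - p_a) > spec.distance_cutoff:
            continue
        if spec.hydrogen is not None:
            p_h = roles.resolve(frame, "hbond_hydrogen", spec.hydrogen).position
            # D–H…A angle at the hydrogen
            if _angle_deg(p_d - p_h, p_a - p_h) < spec.angle_cutoff:
                continue
        n_ok += 1
    return n_ok / len(frames)
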