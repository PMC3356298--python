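"""Synthetic study inputs: model potentials, umbrella windows, frames.

The QM/MM MD engine that produced the original trajectories is outside
this package's scope; this module generates statistically controlled
stand-ins for everything downstream analysis needs:

* analytic model potentials along the reaction coordinate R with
  *exactly* known stationary points and barrier heights,
* umbrella-window samples drawn i.i.d. from the harmonically biased
  Boltzmann density over such a potential (inverse-CDF sampling on a
  dense grid — the target distribution is hit exactly, with no
  integrator artifacts, and every draw is reproducible from the seed),
* active-site frame ensembles with prescribed (r, θ) statistics,
  constructed so that :func:`methylspec.geometry.compute_geometry`
  returns each frame's drawn values to 1e-6 (the module's master
  invariant).

Default study conditions follow the simulated system: 283.15 K, 20
umbrella windows per transfer, harmonic force constants between 50 and
400 kcal mol⁻¹ Å⁻², reactive reactant ensembles centered at
r(CM…Nζ) ≈ 3.0 Å / θ ≈ 30°, and a non-reactive third-transfer ensemble
at r ≈ 4.5 Å with a broad θ distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicHermiteSpline
from scipy.optimize import brentq
from scipy.stats import norm

from .constants import kt
from .errors import GeneratorError, ParameterError
from .io import AtomRecord, Frame, FrameSeries, RoleMap, UmbrellaWindow

__all__ = [
    "ModelPotential",
    "FrameEnsembleSpec",
    "make_potential",
    "gen_umbrella_windows",
    "gen_frames",
    "default_window_layout",
    "truncated_normal_mean",
    "PRESETS",
    "SYNTHETIC_ROLE_MAP",
]

#: ideal tetrahedral angle, degrees
_TET = 109.47122063449069


@dataclass(frozen=True)
class ModelPotential:
    """Closed-form U(R) with analytically known stationary points.

    ``barrier`` is U(R_t) − U(R_a) exactly; U(R_a) = 0.  ``r_range`` is
    the declared sampling range used by the umbrella generator.
    """

    form: str
    fn: Callable[[np.ndarray], np.ndarray]
    R_a: float | None  # reactant minimum, Å
    R_t: float | None  # transition state, Å
    R_b: float | None  # product minimum, Å
    barrier: float | None  # kcal/mol
    delta_rp: float | None  # U(R_b) − U(R_a), kcal/mol
    r_range: tuple[float, float]

    def __call__(self, r: np.ndarray | float) -> np.ndarray | float:
        return self.fn(np.asarray(r, dtype=float))


def _quartic_double_well(
    barrier: float, R_a: float, R_b: float, delta_rp: float
) -> tuple[Callable, float]:
    """Quartic with minima at R_a/R_b, U(R_a)=0, programmed barrier.

    U'(R) = c·(R − R_a)(R − R_t)(R − R_b); R_t and c are fixed by the
    barrier height and reactant–product offset (root-find on the ratio
    of the two antiderivative differences, then scale).
    """

    def antiderivative(t):
        # ∫ (R−a)(R−t)(R−b) dR as polynomial coefficients
        poly = np.polynomial.polynomial.polyfromroots([R_a, t, R_b])
        return np.polynomial.polynomial.polyint(poly)

    ev = np.polynomial.polynomial.polyval
    target = delta_rp / barrier

    def mismatch(t):
        # num → c·ΔF_rp, den → c·B (den > 0 for t in (a, b)); the root of
        # num − target·den is the TS location.  Division-free for stability
        # at the interval endpoints.
        v = antiderivative(t)
        num = ev(R_b, v) - ev(R_a, v)
        den = ev(t, v) - ev(R_a, v)
        return num - target * den

    R_t = brentq(mismatch, R_a, R_b, xtol=1e-14)
    v = antiderivative(R_t)
    ev = np.polynomial.polynomial.polyval
    c = barrier / (ev(R_t, v) - ev(R_a, v))
    v0 = ev(R_a, v)

    def u(r):
        return c * (ev(r, v) - v0)

    return u, float(R_t)


def make_potential(
    form: str,
    barrier: float | None = None,
    R_a: float = -1.4,
    R_b: float = 1.2,
    R_t: float | None = None,
    delta_rp: float = 0.0,
    kappa: float | None = None,
    r_range: tuple[float, float] | None = None,
) -> ModelPotential:
    """Build an evaluable model potential.

    Forms
    -----
    ``harmonic``
        U(R) = (κ/2)·R²; pass ``kappa`` (kcal mol⁻¹ Å⁻²).
    ``quartic_double_well``
        Minima at R_a < R_b with U(R_a) = 0, U(R_b) = ``delta_rp`` and
        barrier U(R_t) − U(R_a) = ``barrier`` exactly; the TS location
        falls out of the construction.
    ``piecewise_cubic``
        Monotone-stationary cubic Hermite through (R_a, 0), (R_t,
        barrier), (R_b, delta_rp) with zero slope at each, plus high
        guard knots outside so sampling stays confined.
    """
    if form == "harmonic":
        if kappa is None or kappa <= 0:
            raise ParameterError("harmonic form requires kappa > 0")
        k = float(kappa)
        rng = r_range or (-2.5, 2.5)
        return ModelPotential(
            form=form,
            fn=lambda r: 0.5 * k * np.asarray(r, float) ** 2,
            R_a=0.0,
            R_t=None,
            R_b=None,
            barrier=None,
            delta_rp=None,
            r_range=rng,
        )
    if barrier is None or barrier <= 0:
        raise ParameterError(
            "double-well forms require barrier > 0 (stationary-point ordering "
            "degenerates at barrier = 0)"
        )
    if not R_a < R_b:
        raise ParameterError(f"need R_a < R_b, got {R_a} >= {R_b}")
    if delta_rp >= barrier:
        raise ParameterError(
            f"reactant–product offset ({delta_rp}) must lie below the barrier ({barrier})"
        )
    span = R_b - R_a
    rng = r_range or (R_a - 0.55 * span / 2, R_b + 0.55 * span / 2)
    if form == "quartic_double_well":
        u, r_t = _quartic_double_well(barrier, R_a, R_b, delta_rp)
        return ModelPotential(
            form=form, fn=u, R_a=R_a, R_t=r_t, R_b=R_b,
            barrier=barrier, delta_rp=delta_rp, r_range=rng,
        )
    if form == "piecewise_cubic":
        r_t = R_t if R_t is not None else 0.5 * (R_a + R_b)
        if not R_a < r_t < R_b:
            raise ParameterError(f"need R_a < R_t < R_b, got {R_a}, {r_t}, {R_b}")
        guard = max(barrier, delta_rp) + 25.0
        xs = [R_a - span, R_a, r_t, R_b, R_b + span]
        ys = [guard, 0.0, barrier, delta_rp, guard]
        spline = CubicHermiteSpline(xs, ys, np.zeros(5), extrapolate=True)
        return ModelPotential(
            form=form, fn=spline, R_a=R_a, R_t=r_t, R_b=R_b,
            barrier=barrier, delta_rp=delta_rp, r_range=rng,
        )
    raise ParameterError(f"unknown potential form {form!r}")


def default_window_layout(
    potential: ModelPotential, n_windows: int = 20,
    k_min: float = 50.0, k_max: float = 400.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced bias centers spanning the wells, stiffer uphill.

    Centers run from R_a to R_b.  Force constants follow the practice of
    restraining hardest where the mean force is largest (so the biased
    distribution stays near its window center): k = k_min + 2·|U'|,
    clipped to [k_min, k_max].  Near the wells and the TS the force
    vanishes and the softest restraint suffices, which also maximizes
    overlap between neighbouring windows.
    """
    if potential.R_a is None or potential.R_b is None:
        raise ParameterError("window layout requires a double-well potential")
    centers = np.linspace(potential.R_a, potential.R_b, n_windows)
    slope = np.abs(np.gradient(np.asarray(potential(centers), float), centers))
    ks = np.clip(k_min + 2.0 * slope, k_min, k_max)
    return centers, ks


def gen_umbrella_windows(
    potential: ModelPotential,
    centers: Sequence[float],
    force_constants: Sequence[float],
    n_per_window: int,
    temperature: float = 283.15,
    seed: int = 0,
    half_k: bool = False,
    grid_points: int = 4096,
) -> list[UmbrellaWindow]:
    """Draw i.i.d. samples from each biased Boltzmann density.

    Window i samples R with density ∝ exp(−[U(R) + kᵢ(R − cᵢ)²]/k_BT)
    (or with the ½kᵢ prefactor when ``half_k``), by inverse-CDF lookup
    on a ``grid_points`` grid over the potential's declared range.
    Bitwise reproducible for a given seed.
    """
    centers = np.asarray(centers, float)
    force_constants = np.asarray(force_constants, float)
    if centers.shape != force_constants.shape:
        raise ParameterError("centers and force_constants must have the same length")
    if n_per_window <= 0:
        raise ParameterError("n_per_window must be positive")
    kbt = kt(temperature)
    lo, hi = potential.r_range
    grid = np.linspace(lo, hi, grid_points)
    u_grid = np.asarray(potential(grid), float)
    pref = 0.5 if half_k else 1.0
    rng = np.random.default_rng(seed)
    windows = []
    for c, k in zip(centers, force_constants):
        energy = u_grid + pref * k * (grid - c) ** 2
        logp = -(energy - energy.min()) / kbt
        pdf = np.exp(logp)
        cdf = np.concatenate(([0.0], cumulative_trapezoid(pdf, grid)))
        cdf /= cdf[-1]
        # strictly increasing CDF for the inverse lookup
        cdf = np.maximum.accumulate(cdf + np.arange(grid_points) * 1e-15)
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        samples = np.interp(u, cdf, grid)
        windows.append(UmbrellaWindow(center=float(c), force_constant=float(k), samples=samples))
    return windows


# ---------------------------------------------------------------------------
# frame ensembles
# ---------------------------------------------------------------------------

#: substituent naming per methylation state of Nζ (Cε plus H / methyl C)
_SUBSTITUENTS = {
    0: (("CE", "C"), ("HZ1", "H"), ("HZ2", "H")),
    1: (("CE", "C"), ("MZ1", "C"), ("HZ1", "H")),
    2: (("CE", "C"), ("MZ1", "C"), ("MZ2", "C")),
}
_BOND_LENGTH = {"C": 1.47, "H": 1.01}  # N–X distances, Å

SYNTHETIC_ROLE_MAP = {
    state: RoleMap(
        s_delta="SD",
        c_methyl="CM",
        n_zeta="NZ",
        n_substituents=tuple(name for name, _ in subs),
    )
    for state, subs in _SUBSTITUENTS.items()
}


@dataclass(frozen=True)
class FrameEnsembleSpec:
    """Target statistics of a synthetic reactant-complex ensemble.

    r and θ are drawn from truncated normals (r > 1.5 Å, θ ∈ [0°, 180°]);
    an sd of zero pins the value exactly.
    """

    n_frames: int
    mean_r: float  # Å, r(CM…Nζ)
    sd_r: float
    mean_theta: float  # degrees
    sd_theta: float
    mean_r_cs: float = 1.81  # Å, CM–Sδ bond in the reactant
    sd_r_cs: float = 0.03
    methylation_state: int = 0
    seed: int = 0
    temperature: float = 283.15

    def __post_init__(self):
        if self.n_frames <= 0:
            raise ParameterError("n_frames must be positive")
        if min(self.sd_r, self.sd_theta, self.sd_r_cs) < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.mean_r <= 0 or self.mean_r_cs <= 0:
            raise ParameterError("mean distances must be positive")
        if not (0.0 <= self.mean_theta <= 180.0):
            raise ParameterError("mean_theta must lie in [0, 180] degrees")
        if self.methylation_state not in (0, 1, 2):
            raise ParameterError("methylation_state must be 0, 1 or 2")


#: named emulation presets for the simulated reactant ensembles
PRESETS = {
    "reactive_wt_like": dict(mean_r=3.0, sd_r=0.15, mean_theta=30.0, sd_theta=12.0),
    "nonreactive_wt3_like": dict(mean_r=4.5, sd_r=0.25, mean_theta=70.0, sd_theta=35.0),
}


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of a normal(mean, sd) truncated to [lo, hi]."""
    if sd == 0:
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    z = norm.cdf(b) - norm.cdf(a)
    return mean + sd * (norm.pdf(a) - norm.pdf(b)) / z


def _draw_truncated(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float,
    what: str,
) -> np.ndarray:
    if sd == 0:
        if not (lo <= mean <= hi):
            raise GeneratorError(f"{what}: fixed value {mean} outside [{lo}, {hi}]")
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    mass = norm.cdf(b) - norm.cdf(a)
    if mass < 0.01:
        raise GeneratorError(
            f"{what}: truncation to [{lo}, {hi}] keeps only {mass:.2e} of the "
            f"normal({mean}, {sd}) mass — spec is infeasible"
        )
    # inverse-CDF draw: exact truncated normal, reproducible from rng
    u = rng.random(n)
    return norm.ppf(norm.cdf(a) + u * mass) * sd + mean


def _orthonormal_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def gen_frames(spec: FrameEnsembleSpec) -> FrameSeries:
    """Build an active-site frame ensemble with the drawn (r, θ) values.

    Geometry per frame: CM at the origin, Sδ on +z at the drawn r_CS,
    Nζ on −z at the drawn r_CN (collinear S–C–N attack axis).  The
    three Nζ substituents sit in an ideal tetrahedral arrangement whose
    missing-vertex direction — which is exactly the constructed lone
    pair — makes the drawn θ with the CM→Sδ vector, at a uniformly
    random azimuth about that axis.  Running
    :func:`methylspec.geometry.compute_geometry` on the result returns
    each frame's drawn (r_CN, r_CS, θ) to 1e-6.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    r_cn = _draw_truncated(rng, n, spec.mean_r, spec.sd_r, 1.5, np.inf, "r_CN")
    r_cs = _draw_truncated(rng, n, spec.mean_r_cs, spec.sd_r_cs, 1.0, np.inf, "r_CS")
    theta = _draw_truncated(rng, n, spec.mean_theta, spec.sd_theta, 0.0, 180.0, "theta")
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    subs = _SUBSTITUENTS[spec.methylation_state]

    cos_tet, sin_tet = np.cos(np.radians(_TET)), np.sin(np.radians(_TET))
    frames = []
    z = np.array([0.0, 0.0, 1.0])
    for i in range(n):
        th = np.radians(theta[i])
        # lone-pair direction: angle θ from +z (= CM→Sδ), azimuth φ
        u = np.array(
            [np.sin(th) * np.cos(phi[i]), np.sin(th) * np.sin(phi[i]), np.cos(th)]
        )
        p_c = np.zeros(3)
        p_s = r_cs[i] * z
        p_n = -r_cn[i] * z
        e1, e2 = _orthonormal_basis(u)
        atoms = [
            AtomRecord("SD", "S", p_s),
            AtomRecord("CM", "C", p_c),
            AtomRecord("NZ", "N", p_n),
        ]
        for j, (name, element) in enumerate(subs):
            alpha = 2.0 * np.pi * j / 3.0
            d = cos_tet * u + sin_tet * (np.cos(alpha) * e1 + np.sin(alpha) * e2)
            atoms.append(
                AtomRecord(name, element, p_n + _BOND_LENGTH[element] * d)
            )
        frames.append(Frame(index=i, atoms=tuple(atoms), time=0.05 * i))
    return FrameSeries(
        frames=tuple(frames),
        role_map=SYNTHETIC_ROLE_MAP[spec.methylation_state],
        temperature=spec.temperature,
    )


def preset_spec(name: str, n_frames: int, seed: int, **overrides) -> FrameEnsembleSpec:
    """Instantiate a named ensemble preset as a FrameEnsembleSpec."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return FrameEnsembleSpec(n_frames=n_frames, seed=seed, **params)
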