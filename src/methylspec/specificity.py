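"""Free-energy triplets and the mono/di/tri product-specificity call.

A protein lysine methyltransferase can add up to three methyl groups to
its target lysine; how far it goes (product specificity) tracks how the
free-energy barrier grows across the successive transfers.  The
formalism summarizes an enzyme's per-step barriers ΔF‡₁..ΔF‡₃ as a
*triplet* referenced to the wild-type first-transfer barrier:

    element j = ΔF‡_j(enzyme) − ΔF‡₁(WT)

so the WT triplet always starts with exactly 0.  A second, within-enzyme
set of deltas (ΔF‡_j − ΔF‡₁ of the *same* enzyme) measures how much
harder each further transfer is for that enzyme, and drives the
classification: the first step whose within-enzyme delta reaches the
blocking threshold stops the methylation ladder — a block at step 2
makes a mono-methyltransferase, at step 3 a di-methyltransferase, and
no block across three steps a tri-methyltransferase.

Missing steps (an enzyme simulated for fewer than three transfers) are
carried explicitly as the marker ``x`` and never silently block or
pass; a call derived from an incomplete ladder carries an
``undetermined_beyond`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ParameterError

__all__ = [
    "MISSING",
    "BarrierSet",
    "TripletResult",
    "SpecificityCall",
    "compute_triplet",
    "classify_specificity",
    "threshold_consistency_band",
    "DEFAULT_THRESHOLD",
]

#: printed marker for a missing methyl-transfer step
MISSING = "x"

#: default blocking threshold, kcal/mol (midpoint of the band over which
#: the known GLP enzymes keep their experimental calls)
DEFAULT_THRESHOLD = 3.0


@dataclass(frozen=True)
class BarrierSet:
    """Per-step forward barriers ΔF‡ (kcal/mol) for one enzyme.

    ``barriers`` lists steps 1..k in order; ``None`` marks a step that
    was not characterized.
    """

    enzyme: str
    barriers: tuple[float | None, ...]

    def __post_init__(self):
        b = tuple(None if v is None else float(v) for v in self.barriers)
        if len(b) < 1 or len(b) > 3:
            raise ParameterError("a barrier set holds 1 to 3 steps")
        for v in b:
            if v is not None and not math.isfinite(v):
                raise ParameterError(f"non-finite barrier in {self.enzyme!r}")
        object.__setattr__(self, "barriers", b)

    def step(self, j: int) -> float | None:
        """Barrier of step j (1-based); None if absent."""
        return self.barriers[j - 1] if j <= len(self.barriers) else None


@dataclass(frozen=True)
class TripletResult:
    """WT-referenced triplet plus within-enzyme deltas.

    Both sequences use ``None`` for missing steps (printed as ``x``).
    """

    enzyme: str
    triplet: tuple[float | None, float | None, float | None]
    within_enzyme_deltas: tuple[float | None, float | None, float | None]
    wt_reference: float  # ΔF‡₁(WT), kcal/mol

    def formatted(self, decimals: int = 1) -> str:
        """Render like the printed form, e.g. ``(0.4, 4.0, x)``."""

        def fmt(v):
            return MISSING if v is None else f"{v:.{decimals}f}".replace("-0.0", "0.0")

        return "(" + ", ".join(fmt(v) for v in self.triplet) + ")"


@dataclass(frozen=True)
class SpecificityCall:
    """Mono/di/tri call with the blocking step and threshold used."""

    enzyme: str
    call: str  # 'mono' | 'di' | 'tri'
    threshold: float  # kcal/mol
    blocking_step: int | None  # 2, 3 or None
    undetermined_beyond: int | None = None  # last present step, if incomplete

    def __post_init__(self):
        expected = {2: "mono", 3: "di", None: self.call}
        if self.call not in ("mono", "di", "tri"):
            raise ParameterError(f"unknown call {self.call!r}")
        if expected[self.blocking_step] != self.call:
            raise ParameterError(
                f"call {self.call!r} inconsistent with blocking step {self.blocking_step}"
            )


def compute_triplet(wt: BarrierSet, enzyme: BarrierSet) -> TripletResult:
    """WT-referenced triplet and within-enzyme deltas for one enzyme.

    Element j of the triplet is ΔF‡_j(enzyme) − ΔF‡₁(WT); the
    within-enzyme delta j is ΔF‡_j − ΔF‡₁ of the enzyme itself.
    Missing steps propagate as ``None``.
    """
    ref = wt.step(1)
    if ref is None:
        raise ParameterError(f"WT set {wt.enzyme!r} lacks a step-1 barrier")
    own_ref = enzyme.step(1)
    if own_ref is None:
        raise ParameterError(f"enzyme set {enzyme.enzyme!r} lacks a step-1 barrier")
    triplet = tuple(
        None if enzyme.step(j) is None else enzyme.step(j) - ref for j in (1, 2, 3)
    )
    within = tuple(
        None if enzyme.step(j) is None else enzyme.step(j) - own_ref for j in (1, 2, 3)
    )
    return TripletResult(
        enzyme=enzyme.enzyme,
        triplet=triplet,  # type: ignore[arg-type]
        within_enzyme_deltas=within,  # type: ignore[arg-type]
        wt_reference=ref,
    )


def classify_specificity(
    enzyme: BarrierSet, threshold: float = DEFAULT_THRESHOLD
) -> SpecificityCall:
    """Call mono/di/tri from within-enzyme barrier deltas.

    Scanning steps 2 then 3, the first step whose delta
    (ΔF‡_j − ΔF‡₁) ≥ threshold blocks the ladder.  Steps absent from
    the set stop the scan and are reported via ``undetermined_beyond``
    — the call then reflects the methylation depth attainable from the
    present steps.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be > 0, got {threshold}")
    b1 = enzyme.step(1)
    if b1 is None:
        raise ParameterError(f"enzyme set {enzyme.enzyme!r} lacks a step-1 barrier")
    calls = {2: "mono", 3: "di"}
    last_present = 1
    for j in (2, 3):
        bj = enzyme.step(j)
        if bj is None:
            # no block so far: depth attainable is the last present step
            return SpecificityCall(
                enzyme=enzyme.enzyme,
                call={1: "mono", 2: "di", 3: "tri"}[last_present],
                threshold=threshold,
                blocking_step=None,
                undetermined_beyond=last_present,
            )
        if bj - b1 >= threshold:
            return SpecificityCall(
                enzyme=enzyme.enzyme,
                call=calls[j],
                threshold=threshold,
                blocking_step=j,
            )
        last_present = j
    return SpecificityCall(
        enzyme=enzyme.enzyme, call="tri", threshold=threshold, blocking_step=None
    )


def _call_interval(enzyme: BarrierSet, call: str) -> tuple[float, float]:
    """Threshold interval (low, high] over which ``enzyme`` yields ``call``.

    Open at the low end, closed at the high end; ±inf for unbounded
    sides.  Intervals follow directly from the within-enzyme deltas d2,
    d3: mono ⇔ t ≤ d2; di ⇔ d2 < t ≤ d3 (d3 present) or d2 < t (step 3
    missing); tri ⇔ t > max(d2, d3).
    """
    b1 = enzyme.step(1)
    d2 = None if enzyme.step(2) is None else enzyme.step(2) - b1
    d3 = None if enzyme.step(3) is None else enzyme.step(3) - b1
    inf = math.inf
    if call == "mono":
        if d2 is None:
            return (0.0, inf)  # only step 1 present: mono at any threshold
        return (0.0, d2)
    if call == "di":
        if d2 is None:
            return (inf, inf)  # empty
        lo = d2
        hi = inf if d3 is None else d3
        return (lo, hi)
    if call == "tri":
        if d2 is None or d3 is None:
            return (inf, inf)  # cannot certify tri with missing steps
        return (max(d2, d3), inf)
    raise ParameterError(f"unknown call {call!r}")


def threshold_consistency_band(
    barrier_sets: Mapping[str, BarrierSet], expected_calls: Mapping[str, str]
) -> tuple[float, float]:
    """Threshold interval (low, high] over which every enzyme keeps its call.

    Returns the intersection of the per-enzyme intervals; the low end is
    open (a threshold exactly equal to a delta blocks, by the ≥ rule)
    and the high end closed.  Raises :class:`ParameterError` when no
    threshold satisfies all calls simultaneously.
    """
    lo, hi = 0.0, math.inf
    for label, bset in barrier_sets.items():
        a, b = _call_interval(bset, expected_calls[label])
        lo, hi = max(lo, a), min(hi, b)
    if lo >= hi:
        raise ParameterError(
            f"no blocking threshold reproduces all expected calls (band ({lo:g}, {hi:g}])"
        )
    return lo, hi


def triplet_table(
    wt: BarrierSet, enzymes: Sequence[BarrierSet], threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Summary table: barriers, triplet, within-enzyme deltas, call."""
    rows = []
    for e in enzymes:
        t = compute_triplet(wt, e)
        c = classify_specificity(e, threshold)
        rows.append(
            {
                "enzyme": e.enzyme,
                "barrier_1": e.step(1),
                "barrier_2": e.step(2),
                "barrier_3": e.step(3),
                "triplet": t.formatted(),
                "delta_2_1": t.within_enzyme_deltas[1],
                "delta_3_1": t.within_enzyme_deltas[2],
                "call": c.call,
                "blocking_step": c.blocking_step,
                "undetermined_beyond": c.undetermined_beyond,
            }
        )
    return pd.DataFrame(rows)
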