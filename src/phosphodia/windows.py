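"""DIA isolation-window scheme design with phosphopeptide forbidden zones.

Peptide precursor masses cluster around a near-linear function of nominal
(integer) mass because amino acids share an almost uniform mass defect.  The
narrow m/z bands in which no peptide precursor can fall -- the *forbidden
zones* -- are therefore the natural places to put isolation-window edges:
an edge in a forbidden zone never bisects a precursor isotope cluster and
avoids quadrupole transmission edge effects.  Phospho-enrichment shifts the
cluster, which is absorbed by an additive constant.

This module computes forbidden-zone boundaries, snaps arbitrary m/z values
to the nearest boundary, and builds staggered window schemes (two grids
offset by half a window width) and gas-phase-fractionation (GPF) plans in
which the precursor range is split across several narrow-range injections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_MZ_INCREMENT",
    "DEFAULT_MZ_CONSTANT",
    "ForbiddenZoneParams",
    "IsolationWindow",
    "WindowScheme",
    "GPFInjection",
    "GPFPlan",
    "forbidden_zone_boundary",
    "snap_to_forbidden_zone",
    "build_staggered_scheme",
    "build_gpf_plan",
    "scheme_summary",
]

logger = logging.getLogger(__name__)

#: Optimal m/z spacing of forbidden-zone boundaries per nominal-mass unit.
DEFAULT_MZ_INCREMENT = 1.00045475
#: Additive offset of the boundaries for phospho-enriched samples.
DEFAULT_MZ_CONSTANT = 0.18


@dataclass(frozen=True)
class ForbiddenZoneParams:
    """Parameters of the forbidden-zone boundary lattice.

    Parameters
    ----------
    mz_increment : float
        m/z advance of the boundary per nominal-mass unit.  Slightly above
        1 because the average residue mass defect is positive.
    mz_constant : float
        Constant m/z offset of the lattice; for phospho-enriched peptides
        the cluster is shifted by the phosphate mass defect.
    """

    mz_increment: float = DEFAULT_MZ_INCREMENT
    mz_constant: float = DEFAULT_MZ_CONSTANT

    def __post_init__(self) -> None:
        if not 1.0 < self.mz_increment < 1.001:
            raise ValueError(
                f"mz_increment must lie in (1.0, 1.001), got {self.mz_increment!r}"
            )
        if not 0.0 <= self.mz_constant < 1.0:
            raise ValueError(
                f"mz_constant must lie in [0, 1), got {self.mz_constant!r}"
            )


@dataclass(frozen=True)
class IsolationWindow:
    """Half-open m/z interval [lower, upper) selected by the quadrupole."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(
                f"window upper bound must exceed lower bound "
                f"({self.lower!r} >= {self.upper!r})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def center(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, mz: float) -> bool:
        """Membership in the half-open interval [lower, upper)."""
        return self.lower <= mz < self.upper


@dataclass(frozen=True)
class WindowScheme:
    """A staggered DIA isolation-window scheme.

    ``phase_a`` is a contiguous grid of ``window_width`` windows starting at
    ``span_lower``; ``phase_b`` is the same grid shifted by half a window
    width, so that computational demultiplexing can resolve signal to
    half-width *effective* windows.  Edges may additionally be snapped to
    forbidden-zone boundaries (``aligned_to_forbidden_zones``), in which
    case individual window widths deviate slightly from nominal.
    """

    span_lower: float
    span_upper: float
    window_width: float
    phase_a: tuple[IsolationWindow, ...]
    phase_b: tuple[IsolationWindow, ...]
    aligned_to_forbidden_zones: bool = False
    forbidden_zone_params: ForbiddenZoneParams = field(
        default_factory=ForbiddenZoneParams
    )

    @property
    def n_windows_per_phase(self) -> int:
        return len(self.phase_a)

    @property
    def is_staggered(self) -> bool:
        return len(self.phase_b) > 0


@dataclass(frozen=True)
class GPFInjection:
    """One narrow-range injection of a gas-phase-fractionation plan."""

    lower: float
    upper: float
    scheme: WindowScheme


@dataclass(frozen=True)
class GPFPlan:
    """Gas-phase fractionation plan: overlapping narrow-range injections.

    Consecutive injections advance by ``injection_step`` but span
    ``injection_span``, overlapping by the difference (10 m/z at defaults)
    so no precursor falls on an injection edge; each injection carries its
    own staggered scheme of narrow (``ms2_width``) MS2 windows.
    """

    injections: tuple[GPFInjection, ...]
    injection_span: float = 110.0
    injection_step: float = 100.0
    ms2_width: float = 4.0

    @property
    def n_injections(self) -> int:
        return len(self.injections)


def forbidden_zone_boundary(
    nominal_mass: float, params: ForbiddenZoneParams | None = None
) -> float:
    """Forbidden-zone boundary m/z for an integer nominal mass.

    Computes ``ceil(nominal_mass / mz_increment) * mz_increment +
    mz_constant`` in double precision.

    Parameters
    ----------
    nominal_mass : int
        Nominal (integer) mass in Da; must be nonnegative.
    params : ForbiddenZoneParams, optional
        Lattice parameters; defaults to the phospho-enrichment values.
    """
    if params is None:
        params = ForbiddenZoneParams()
    if nominal_mass < 0:
        raise ValueError(f"nominal_mass must be >= 0, got {nominal_mass!r}")
    return (
        math.ceil(nominal_mass / params.mz_increment) * params.mz_increment
        + params.mz_constant
    )


def snap_to_forbidden_zone(
    target: float, params: ForbiddenZoneParams | None = None
) -> float:
    """Nearest forbidden-zone boundary to ``target``.

    Scans integer nominal masses around the target and returns the boundary
    at minimal distance; exact ties are broken toward the lower boundary.
    """
    if params is None:
        params = ForbiddenZoneParams()
    if not target > 0:
        raise ValueError(f"target m/z must be > 0, got {target!r}")
    guess = int((target - params.mz_constant) / params.mz_increment)
    best_dist = math.inf
    best_boundary = math.nan
    # Candidates in ascending order: ties keep the first (lower) boundary.
    for m in range(max(guess - 3, 0), guess + 5):
        boundary = forbidden_zone_boundary(m, params)
        dist = abs(boundary - target)
        if dist < best_dist:
            best_dist = dist
            best_boundary = boundary
    return best_boundary


def _grid(edges: list[float]) -> tuple[IsolationWindow, ...]:
    return tuple(
        IsolationWindow(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])
    )


def build_staggered_scheme(
    span_lower: float,
    span_upper: float,
    window_width: float,
    align: bool = False,
    params: ForbiddenZoneParams | None = None,
) -> WindowScheme:
    """Build a staggered isolation-window scheme over a precursor span.

    ``phase_a`` holds ``ceil(span / window_width)`` contiguous windows
    starting at ``span_lower``; ``phase_b`` is the same grid shifted by
    ``+window_width/2`` (its last window overhangs the span top by half a
    width, preserving the exact half-width stagger).  With ``align`` every
    edge is replaced by its nearest forbidden-zone boundary; shared edges
    snap identically so contiguity is preserved.
    """
    if params is None:
        params = ForbiddenZoneParams()
    if not span_upper > span_lower:
        raise ValueError(
            f"span_upper must exceed span_lower ({span_lower!r} >= {span_upper!r})"
        )
    if not window_width > 0:
        raise ValueError(f"window_width must be > 0, got {window_width!r}")

    span = span_upper - span_lower
    if window_width >= span:
        logger.warning(
            "window_width %.3f >= span %.3f: scheme degenerates to one "
            "window per phase",
            window_width,
            span,
        )
    n = max(1, math.ceil(span / window_width - 1e-9))
    half = window_width / 2.0
    edges_a = [span_lower + i * window_width for i in range(n + 1)]
    edges_b = [e + half for e in edges_a]
    if align:
        edges_a = [snap_to_forbidden_zone(e, params) for e in edges_a]
        edges_b = [snap_to_forbidden_zone(e, params) for e in edges_b]
        for edges in (edges_a, edges_b):
            if any(hi <= lo for lo, hi in zip(edges[:-1], edges[1:])):
                raise ValueError(
                    "forbidden-zone snapping collapsed a window; "
                    "window_width is too small relative to the boundary spacing"
                )
    return WindowScheme(
        span_lower=span_lower,
        span_upper=span_upper,
        window_width=window_width,
        phase_a=_grid(edges_a),
        phase_b=_grid(edges_b),
        aligned_to_forbidden_zones=align,
        forbidden_zone_params=params,
    )


def build_gpf_plan(
    full_lower: float = 394.8,
    full_upper: float = 1104.8,
    injection_span: float = 110.0,
    injection_step: float = 100.0,
    ms2_width: float = 4.0,
    align: bool = False,
    params: ForbiddenZoneParams | None = None,
) -> GPFPlan:
    """Plan gas-phase-fractionation injections covering a full precursor range.

    Injection ``k`` spans ``[full_lower + k*injection_step,
    full_lower + k*injection_step + injection_span]`` for
    ``k = 0 .. ceil((full_upper - full_lower - injection_span) /
    injection_step)``, so consecutive injections overlap by
    ``injection_span - injection_step`` and the union covers
    ``full_upper``.  Each injection carries a staggered scheme of
    ``ms2_width`` windows.
    """
    if not injection_step > 0:
        raise ValueError(f"injection_step must be > 0, got {injection_step!r}")
    if injection_step > injection_span:
        raise ValueError(
            "injection_step must not exceed injection_span "
            f"({injection_step!r} > {injection_span!r})"
        )
    if full_upper - full_lower < injection_span - 1e-9:
        raise ValueError(
            "full range must be at least one injection_span wide "
            f"({full_lower!r}..{full_upper!r} vs {injection_span!r})"
        )
    k_max = max(
        0,
        math.ceil((full_upper - full_lower - injection_span) / injection_step - 1e-9),
    )
    injections = []
    for k in range(k_max + 1):
        lo = full_lower + k * injection_step
        hi = lo + injection_span
        injections.append(
            GPFInjection(
                lower=lo,
                upper=hi,
                scheme=build_staggered_scheme(lo, hi, ms2_width, align, params),
            )
        )
    return GPFPlan(
        injections=tuple(injections),
        injection_span=injection_span,
        injection_step=injection_step,
        ms2_width=ms2_width,
    )


def scheme_summary(scheme: WindowScheme) -> dict:
    """Summary record of a scheme.

    The effective window width after staggered-window demultiplexing is
    exactly half the nominal window width.
    """
    return {
        "n_windows_phase_a": len(scheme.phase_a),
        "n_windows_phase_b": len(scheme.phase_b),
        "span_lower": scheme.span_lower,
        "span_upper": scheme.span_upper,
        "window_width": scheme.window_width,
        "effective_window_width": scheme.window_width / 2.0,
        "aligned_to_forbidden_zones": scheme.aligned_to_forbidden_zones,
    }
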