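"""Computational demultiplexing of staggered DIA scans.

Staggered acquisition interleaves two isolation-window grids offset by half
a window width.  Every half-width *effective* window inside the span is
covered by one window of each phase (except at the span edges), so each
scan's observation is the sum of the two effective windows it straddles.
Solving the resulting nonnegative linear system per fragment channel and
scan cycle resolves signal to effective windows of half the nominal width
-- the "factor of two" selectivity gain of staggered DIA.

The in-span system for a scheme with ``n`` windows per phase has ``2n``
scans and ``2n`` effective-window unknowns and is full rank (a terminating
chain), so noiseless point sources are recovered exactly; with noise the
nonnegative least-squares solution is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .windows import IsolationWindow, WindowScheme

__all__ = [
    "AnalyteSignal",
    "Scan",
    "ScanCycle",
    "effective_windows",
    "effective_window_index",
    "demultiplex",
]


@dataclass(frozen=True)
class AnalyteSignal:
    """Ground-truth analyte used to synthesize and validate scan cycles."""

    precursor_mz: float
    fragment_channel: str
    intensity_trace: tuple[float, ...]
    true_effective_window: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.intensity_trace):
            raise ValueError("intensity_trace must be nonnegative")


@dataclass(frozen=True)
class Scan:
    """One MS2 scan: an isolation window, its phase, and summed intensities
    per fragment channel."""

    window: IsolationWindow
    phase: str  # "a" | "b"
    observed: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.phase not in ("a", "b"):
            raise ValueError(f"phase must be 'a' or 'b', got {self.phase!r}")


@dataclass(frozen=True)
class ScanCycle:
    """One duty cycle: the full ordered set of scans of both phases."""

    cycle_index: int
    scans: tuple[Scan, ...]


def effective_windows(scheme: WindowScheme) -> list[IsolationWindow]:
    """Half-width effective-window grid of a staggered scheme.

    The grid starts at ``span_lower`` with spacing ``window_width / 2`` and
    covers the scheme span; each staggered window covers exactly two
    consecutive effective windows.
    """
    if not scheme.is_staggered:
        raise ValueError("scheme is not staggered: no phase_b windows")
    half = scheme.window_width / 2.0
    span = scheme.span_upper - scheme.span_lower
    n_eff = max(1, math.ceil(span / half - 1e-9))
    return [
        IsolationWindow(
            scheme.span_lower + k * half, scheme.span_lower + (k + 1) * half
        )
        for k in range(n_eff)
    ]


def effective_window_index(scheme: WindowScheme, mz: float) -> int:
    """Index of the effective window containing ``mz`` (nominal grid)."""
    half = scheme.window_width / 2.0
    if not scheme.span_lower <= mz < scheme.span_upper:
        raise ValueError(
            f"m/z {mz!r} outside scheme span "
            f"[{scheme.span_lower!r}, {scheme.span_upper!r})"
        )
    return int((mz - scheme.span_lower) // half)


def _design_matrix(scheme: WindowScheme, n_eff: int) -> np.ndarray:
    """Scan x effective-window incidence matrix, scans ordered phase-a grid
    then phase-b grid."""
    n = scheme.n_windows_per_phase
    rows = []
    for i in range(n):  # phase a window i covers effective 2i, 2i+1
        row = np.zeros(n_eff)
        for k in (2 * i, 2 * i + 1):
            if k < n_eff:
                row[k] = 1.0
        rows.append(row)
    for j in range(n):  # phase b window j covers effective 2j+1, 2j+2
        row = np.zeros(n_eff)
        for k in (2 * j + 1, 2 * j + 2):
            if k < n_eff:
                row[k] = 1.0
        rows.append(row)
    return np.array(rows)


def _ordered_scans(cycle: ScanCycle, scheme: WindowScheme) -> list[Scan]:
    """Order a cycle's scans phase-a then phase-b, each by window position,
    and check they conform to the scheme geometry."""
    by_phase: dict[str, list[Scan]] = {"a": [], "b": []}
    for scan in cycle.scans:
        by_phase[scan.phase].append(scan)
    n = scheme.n_windows_per_phase
    for phase, expected in (("a", scheme.phase_a), ("b", scheme.phase_b)):
        scans = sorted(by_phase[phase], key=lambda s: s.window.lower)
        if len(scans) != n:
            raise ValueError(
                f"cycle {cycle.cycle_index}: expected {n} phase-{phase} "
                f"scans, got {len(scans)}"
            )
        for scan, win in zip(scans, expected):
            if not (
                math.isclose(scan.window.lower, win.lower, abs_tol=1e-6)
                and math.isclose(scan.window.upper, win.upper, abs_tol=1e-6)
            ):
                raise ValueError(
                    f"cycle {cycle.cycle_index}: scan window "
                    f"[{scan.window.lower}, {scan.window.upper}) does not "
                    f"match scheme window [{win.lower}, {win.upper})"
                )
        by_phase[phase] = scans
    return by_phase["a"] + by_phase["b"]


def demultiplex(
    cycles: Iterable[ScanCycle], scheme: WindowScheme
) -> pd.DataFrame:
    """Demultiplex staggered scan cycles into effective-window traces.

    For every cycle and fragment channel the full in-span nonnegative
    linear system (each scan = sum of its two constituent effective
    windows) is solved by nonnegative least squares.

    Returns
    -------
    pandas.DataFrame
        Columns ``cycle``, ``fragment_channel``, ``effective_index``,
        ``eff_lower``, ``eff_upper``, ``intensity``, ``single_phase``
        (True for edge windows covered by scans of only one phase, whose
        estimate is a pass-through rather than a demultiplexed split).
    """
    cycles = list(cycles)
    if len(cycles) < 2:
        raise ValueError("demultiplexing requires at least 2 scan cycles")
    eff = effective_windows(scheme)
    n_eff = len(eff)
    A = _design_matrix(scheme, n_eff)
    single_phase = np.asarray(
        (A[: scheme.n_windows_per_phase].sum(axis=0) == 0)
        | (A[scheme.n_windows_per_phase :].sum(axis=0) == 0)
    )

    out: dict[str, list] = {
        "cycle": [],
        "fragment_channel": [],
        "effective_index": [],
        "eff_lower": [],
        "eff_upper": [],
        "intensity": [],
        "single_phase": [],
    }
    for cycle in cycles:
        scans = _ordered_scans(cycle, scheme)
        channels = sorted({ch for s in scans for ch in s.observed})
        for channel in channels:
            y = np.array([float(s.observed.get(channel, 0.0)) for s in scans])
            if np.any(y < 0):
                raise ValueError(
                    f"cycle {cycle.cycle_index}, channel {channel!r}: "
                    "negative observed intensity"
                )
            x = lsq_linear(A, y, bounds=(0.0, np.inf), method="bvls", tol=1e-14).x
            for k in range(n_eff):
                out["cycle"].append(cycle.cycle_index)
                out["fragment_channel"].append(channel)
                out["effective_index"].append(k)
                out["eff_lower"].append(eff[k].lower)
                out["eff_upper"].append(eff[k].upper)
                out["intensity"].append(x[k])
                out["single_phase"].append(bool(single_phase[k]))
    return pd.DataFrame(out)
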