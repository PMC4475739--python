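"""Tortuosity of a tracked vessel segment.

Three indices are computed on every segment:

``ti_composite``
    The package's primary index. The segment is rotated into its chord frame
    (both operator-selected endpoints at y = 0), a smoothing spline
    y = f(x) with continuous derivative is fitted, and two normalized
    features are combined linearly::

        ti_composite = K_dc * N_dc / L_chord  +  K_area * area / L_chord**2

    where ``N_dc`` is the number of interior zeros of f' (directional
    changes — the points where the vessel path changes slope) and ``area``
    is the integral of |f| between curve and chord. Both terms are
    dimensionless after the normalization; the default weights
    (K_dc = 1000, K_area = 100) deliberately make the directional-change
    term dominant, since change counts — not curve area — carry the
    discriminative signal between normal and abnormal vessels.

``ti_integral``
    Comparator: area / chord length (curvature-integral family).

``ti_arc_chord``
    Comparator: curve length / chord length; 1 for a straight segment.

A vessel that doubles back past vertical has no single-valued chord-frame
representation; such paths fall back to arc-length parameterization
(x := cumulative arc length, y := signed perpendicular deviation from the
chord) with the same downstream definitions, and the result is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import UnivariateSpline
from scipy.optimize import brentq

from .errors import ContractError
from .tracking import SegmentPath, path_length

__all__ = [
    "FittedCurve",
    "TortuosityResult",
    "fit_curve",
    "directional_changes",
    "curve_area",
    "compute_ti",
    "average_ti",
]

#: Merge window for derivative roots and endpoint exclusion zone (pixels).
ROOT_MERGE_PX = 2.0
#: Dense sampling step for locating derivative sign changes (pixels).
SAMPLE_STEP_PX = 0.1


@dataclass
class FittedCurve:
    """Chord-frame analytic description y = f(x) of a vessel path."""

    spline: UnivariateSpline
    domain: tuple[float, float]          # x-range of f (0 .. chord or arc length)
    chord_length: float                  # Euclidean start-end distance
    arc_length: float                    # polyline length of the input points
    fallback: bool = False               # arc-length parameterization used
    _ramp: tuple[float, float] = (0.0, 0.0)  # linear correction g(0), g(L)

    def __call__(self, x):
        g0, gL = self._ramp
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        span = hi - lo
        lin = g0 + (gL - g0) * (x - lo) / span
        return self.spline(x) - lin

    def derivative(self, x):
        g0, gL = self._ramp
        lo, hi = self.domain
        return self.spline.derivative()(np.asarray(x, float)) - (gL - g0) / (hi - lo)


def _chord_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotate/translate so the start-end chord lies on the +x axis.

    Returns (u, v, chord_length): along-chord and perpendicular coordinates.
    """
    pts = np.asarray(points, dtype=float)
    start, end = pts[0], pts[-1]
    chord_vec = end - start
    chord = float(np.hypot(*chord_vec))
    if chord == 0:
        raise ContractError("path start and end coincide")
    # treat (row, col) as a plane; u along chord, v perpendicular
    c, s = chord_vec / chord
    rel = pts - start
    u = rel[:, 0] * c + rel[:, 1] * s
    v = -rel[:, 0] * s + rel[:, 1] * c
    return u, v, chord


def _monotone_subsequence(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedily keep points with strictly increasing u; return kept fraction."""
    keep = [0]
    last = u[0]
    for i in range(1, len(u)):
        if u[i] > last + 1e-9:
            keep.append(i)
            last = u[i]
    idx = np.array(keep)
    return u[idx], v[idx], len(idx) / len(u)


def fit_curve(
    path: SegmentPath | np.ndarray,
    smoothing: float = 0.25,
) -> FittedCurve:
    """Fit the chord-frame smoothing spline y = f(x) to a vessel path.

    ``smoothing`` scales the spline residual budget proportionally to the
    number of path points (s = smoothing * n); 0 interpolates exactly, which
    is appropriate for noise-free analytic point samples. f(0) = f(L) = 0 is
    enforced by subtracting the residual linear ramp between the fitted
    endpoint values, pinning the operator-selected endpoints to y = 0.

    Paths that are not single-valued in the chord frame (hairpins) fall back
    to arc-length parameterization and are flagged on the returned curve.
    """
    pts = path.points if isinstance(path, SegmentPath) else np.asarray(path, float)
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 4:
        raise ContractError(f"fit_curve needs >= 4 path points, got {len(pts)}")
    u, v, chord = _chord_frame(pts)
    arc = path_length(pts)

    uk, vk, kept = _monotone_subsequence(u, v)
    fallback = kept < 0.8 or len(uk) < 4
    if fallback:
        # arc-length parameterization: x = cumulative arc length, y = perp dev
        steps = np.hypot(*np.diff(pts, axis=0).T)
        x = np.concatenate([[0.0], np.cumsum(steps)])
        # drop exact duplicates (repeated pixels should not occur, but be safe)
        keep = np.concatenate([[True], np.diff(x) > 1e-9])
        x, y = x[keep], v[keep]
    else:
        x, y = uk, vk

    s = smoothing * len(x)
    k = 3 if len(x) > 3 else len(x) - 1
    spline = UnivariateSpline(x, y, k=k, s=s)
    curve = FittedCurve(
        spline=spline,
        domain=(float(x[0]), float(x[-1])),
        chord_length=chord,
        arc_length=arc,
        fallback=fallback,
    )
    curve._ramp = (float(spline(x[0])), float(spline(x[-1])))
    return curve


def directional_changes(curve: FittedCurve) -> int:
    """Count interior points where f'(x) = 0 (the vessel changes slope).

    f' is sampled densely (0.1-px step); each sign change is refined by
    bracketed root finding; roots closer than 2 px are merged and roots
    within 2 px of either endpoint are excluded (spline edge effects).
    """
    lo, hi = curve.domain
    n = max(int((hi - lo) / SAMPLE_STEP_PX), 10)
    xs = np.linspace(lo, hi, n + 1)
    ds = curve.derivative(xs)
    sign = np.sign(ds)
    # a directional change is a sign *flip* of f'; zero-runs (flat stretches,
    # including the identically-straight case) count once only when the sign
    # differs on their two sides
    nz = np.nonzero(sign != 0)[0]
    roots: list[float] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] * sign[b] < 0:
            if b == a + 1:
                try:
                    r = brentq(lambda x: float(curve.derivative(x)),
                               xs[a], xs[b])
                except ValueError:
                    r = 0.5 * (xs[a] + xs[b])
            else:
                r = 0.5 * (xs[a] + xs[b])  # center of the flat zero-run
            roots.append(float(r))
    roots.sort()
    merged: list[float] = []
    for r in roots:
        if lo + ROOT_MERGE_PX < r < hi - ROOT_MERGE_PX:
            if not merged or r - merged[-1] > ROOT_MERGE_PX:
                merged.append(r)
    return len(merged)


def curve_area(curve: FittedCurve) -> float:
    """Area between curve and chord: integral of |f(x)| over the domain.

    The integral is split at the sign changes of f so each piece is smooth
    for the adaptive quadrature.
    """
    lo, hi = curve.domain
    n = max(int((hi - lo) / SAMPLE_STEP_PX), 10)
    xs = np.linspace(lo, hi, n + 1)
    fs = curve(xs)
    cuts = [lo]
    sign = np.sign(fs)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        try:
            cuts.append(float(brentq(lambda x: float(curve(x)), xs[i], xs[i + 1])))
        except ValueError:
            cuts.append(0.5 * (xs[i] + xs[i + 1]))
    cuts.append(hi)
    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a < 1e-12:
            continue
        piece, _ = quad(lambda x: float(curve(x)), a, b, limit=200)
        total += abs(piece)
    return total


@dataclass(frozen=True)
class TortuosityResult:
    """All tortuosity measurements for one tracked segment."""

    n_dc: int                 # directional-change count
    area: float               # |curve - chord| area, px^2
    chord_length: float       # px
    curve_length: float       # polyline arc length, px
    ti_composite: float       # primary composite index
    ti_integral: float        # comparator: area / chord
    ti_arc_chord: float       # comparator: arc / chord
    fallback: bool = False    # arc-length fallback parameterization used
    vessel_class: str | None = None


def compute_ti(
    path: SegmentPath | np.ndarray,
    smoothing: float = 0.25,
    k_dc: float = 1000.0,
    k_area: float = 100.0,
    vessel_class: str | None = None,
) -> TortuosityResult:
    """Composite tortuosity index plus both comparator indices for one path."""
    if vessel_class is None and isinstance(path, SegmentPath):
        vessel_class = path.vessel_class
    curve = fit_curve(path, smoothing=smoothing)
    n_dc = directional_changes(curve)
    area = curve_area(curve)
    chord = curve.chord_length
    arc = curve.arc_length
    return TortuosityResult(
        n_dc=n_dc,
        area=area,
        chord_length=chord,
        curve_length=arc,
        ti_composite=k_dc * n_dc / chord + k_area * area / chord**2,
        ti_integral=area / chord,
        ti_arc_chord=arc / chord,
        fallback=curve.fallback,
        vessel_class=vessel_class,
    )


def average_ti(results: list[TortuosityResult]) -> float:
    """Per-subject TI: arithmetic mean of the segment composite indices
    (the 2 arterioles and 2 venules)."""
    if not results:
        raise ContractError("average_ti needs at least one segment result")
    return float(np.mean([r.ti_composite for r in results]))
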