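"""2D geometric primitives for layout modification.

Cartesian coordinates, y increasing upward.  The central primitive is
the equal-arc placement of n points on a circle through two anchors,
with the circle radius chosen so consecutive chord lengths approach the
backbone step.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "unit",
    "perp",
    "rotate_about",
    "distribute_on_circle",
    "arc_circle",
]

_EPS = 1e-12


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n < _EPS:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def perp(v: np.ndarray) -> np.ndarray:
    """Counter-clockwise perpendicular (rotate +90 degrees)."""
    return np.array([-v[1], v[0]], dtype=float)


def rotate_about(p: np.ndarray, center: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    d = p - center
    return center + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def _solve_arc_angle(d: float, n: int, step: float) -> float:
    """Central angle of the a->b arc carrying n interior points.

    Solves d*sin(t/(2(n+1))) = step*sin(t/2) for t in (0, 2*pi): the
    n+1 equal arc gaps then have chord length `step`.  When the anchors
    are too far apart for any circle with that spacing (no root), fall
    back to a semicircular arc.
    """

    def f(t: float) -> float:
        return d * math.sin(t / (2.0 * (n + 1))) - step * math.sin(t / 2.0)

    lo, hi = None, None
    prev_t, prev_f = 1e-9, f(1e-9)
    for k in range(1, 257):
        t = 1e-9 + (2.0 * math.pi - 2e-6 - 1e-9) * k / 256.0
        ft = f(t)
        if prev_f <= 0.0 < ft or prev_f < 0.0 <= ft:
            lo, hi = prev_t, t
            break
        prev_t, prev_f = t, ft
    if lo is None:
        return math.pi  # semicircular fallback
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def arc_circle(
    a: np.ndarray, b: np.ndarray, n: int, side: np.ndarray, step: float
) -> tuple[np.ndarray, float, list[np.ndarray]]:
    """Circle (center, radius) and the n equally spaced interior points
    of the arc from a to b passing through the `side` half-plane."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = float(np.hypot(*(b - a)))
    if d < _EPS:
        raise ValueError("anchors coincide")
    theta = _solve_arc_angle(d, n, step)
    nhat = unit(np.asarray(side, dtype=float))
    # keep only the component of `side` normal to the chord
    chord = unit(b - a)
    nperp = nhat - chord * float(np.dot(nhat, chord))
    if np.hypot(*nperp) < 1e-9:
        nperp = perp(chord)
    nperp = unit(nperp)
    mid = 0.5 * (a + b)
    r = d / (2.0 * math.sin(theta / 2.0))
    center = mid - nperp * (r * math.cos(theta / 2.0))
    # sweep direction: rotating a about center by +/- theta must land
    # on b with the arc midpoint on the requested side
    pts: list[np.ndarray] = []
    for sgn in (1.0, -1.0):
        endp = rotate_about(a, center, sgn * theta)
        if np.hypot(*(endp - b)) > 1e-6 * max(1.0, d):
            continue
        arcmid = rotate_about(a, center, sgn * theta / 2.0)
        if float(np.dot(arcmid - mid, nperp)) > 0.0:
            pts = [
                rotate_about(a, center, sgn * theta * k / (n + 1))
                for k in range(1, n + 1)
            ]
            break
    if not pts and n > 0:  # pragma: no cover - numerical safety net
        sgn = 1.0 if np.hypot(*(rotate_about(a, center, theta) - b)) <= np.hypot(
            *(rotate_about(a, center, -theta) - b)
        ) else -1.0
        pts = [
            rotate_about(a, center, sgn * theta * k / (n + 1))
            for k in range(1, n + 1)
        ]
    return center, r, pts


def distribute_on_circle(
    anchor_a: np.ndarray,
    anchor_b: np.ndarray,
    n: int,
    side: np.ndarray,
    step: float = 8.0,
) -> list[np.ndarray]:
    """Place n points between two anchors on a common circle.

    The n+1 consecutive arc gaps (a->p1, ..., pn->b) are equal; the
    radius is solved numerically so each gap's chord length is as close
    as possible to `step`.  `side` selects the half-plane of the chord
    that receives the arc.  n = 0 returns an empty list; coincident
    anchors raise ``ValueError``.
    """
    if n == 0:
        return []
    if n < 0:
        raise ValueError("n must be non-negative")
    _, _, pts = arc_circle(anchor_a, anchor_b, n, side, step)
    return pts
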