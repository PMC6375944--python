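"""Shared elliptic-geometry helpers (arc-length parametrization, rotations)."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["arc_table", "arc_fraction", "rotation_about", "ellipse_radius"]


def arc_table(sa: float, sb: float, m: int = 8192) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative normalized arc length s(E) of the ellipse with semi-axes
    (sa, sb), tabulated on the parametric angle E in [0, 2π].

    Returns (E grid, normalized cumulative arc length, perimeter).
    """
    E = np.linspace(0.0, 2.0 * np.pi, m + 1)
    ds = np.hypot(sa * np.sin(E), sb * np.cos(E))
    s = np.concatenate([[0.0], np.cumsum((ds[1:] + ds[:-1]) * 0.5 * np.diff(E))])
    perim = s[-1]
    return E, s / perim, perim


def arc_fraction(E: np.ndarray, table: tuple[np.ndarray, np.ndarray, float]) -> np.ndarray:
    """Normalized arc-length position s in [0,1) for parametric angles E."""
    Et, st, _ = table
    return np.interp(np.mod(E, 2.0 * np.pi), Et, st)


def uniform_arc_angles(sa: float, sb: float, n: int, m: int = 8192) -> np.ndarray:
    """Parametric angles E of n points equally spaced in arc length."""
    Et, st, _ = arc_table(sa, sb, m)
    s_targets = (np.arange(n) + 0.5) / n
    return np.interp(s_targets, st, Et)


def ellipse_radius(psi: np.ndarray, sa: float, sb: float) -> np.ndarray:
    """Central radius of the ellipse along polar direction psi (axis frame)."""
    return sa * sb / np.hypot(sb * np.cos(psi), sa * np.sin(psi))


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)
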