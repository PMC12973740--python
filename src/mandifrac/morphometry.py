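"""Radiomorphometric indices from landmark coordinates.

Mandibular cortical width (MCW, the measurement ``a``) is the cortical
bone thickness measured along a line perpendicular to the inferior
mandibular border, passing through the lower edge of the mental
foramen. The panoramic mandibular index (PMI) is the ratio ``a / b``
where ``b`` is the distance from the foramen's lower edge to the
inferior border along the same perpendicular axis; dividing by the
local mandibular height makes the index independent of panoramic
magnification.

The module takes operator-supplied landmark polylines (the inferior
border and the endosteal / inner cortical margin) and a foramen point,
all in pixel units. The local border tangent is estimated by a
least-squares line through the k nearest border vertices (default 7),
which is robust to digitization jitter; the measurement axis is the
normal to that tangent oriented toward the foramen. Whether ``b``
should instead be a point-to-curve minimum distance is not settled in
the field; the along-axis convention is used here (for a locally
straight border the two coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InvalidParameterError, MeasurementError

__all__ = [
    "LandmarkSet",
    "MorphometricResult",
    "perpendicular_axis",
    "mcw",
    "pmi",
]


@dataclass
class LandmarkSet:
    """Pixel landmarks for one hemimandible."""

    inferior_border: np.ndarray  # (N, 2) of (row, col)
    foramen_lower_edge: np.ndarray  # (2,)
    cortical_inner_margin: np.ndarray  # (M, 2)
    side: str = "right"

    def __post_init__(self) -> None:
        self.inferior_border = np.atleast_2d(
            np.asarray(self.inferior_border, dtype=float)
        )
        self.cortical_inner_margin = np.atleast_2d(
            np.asarray(self.cortical_inner_margin, dtype=float)
        )
        self.foramen_lower_edge = np.asarray(
            self.foramen_lower_edge, dtype=float
        ).reshape(2)
        if self.inferior_border.shape[0] < 2:
            raise InvalidParameterError(
                "inferior_border needs at least 2 points"
            )
        if self.side not in ("right", "left"):
            raise InvalidParameterError(f"side must be right/left, got {self.side!r}")


@dataclass(frozen=True)
class MorphometricResult:
    """MCW (a), foramen-to-border distance (b) and PMI = a / b."""

    mcw: float
    foramen_border_distance: float
    pmi: float
    side: str


def _project_to_polyline(
    polyline: np.ndarray, point: np.ndarray
) -> np.ndarray:
    """Closest point on the polyline (per-segment projection)."""
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    degenerate = denom == 0
    denom[degenerate] = 1.0
    t = np.clip(((point - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    t[degenerate] = 0.0
    feet = a + t[:, None] * ab
    d2 = ((feet - point) ** 2).sum(axis=1)
    return feet[int(np.argmin(d2))]


def perpendicular_axis(
    border: np.ndarray, through: np.ndarray, k: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Measurement axis: foot point on the border + unit normal.

    The foot is the projection of ``through`` onto the border polyline;
    the tangent is the principal direction of the ``k`` border vertices
    nearest the foot (total-least-squares line, so vertical borders are
    handled); the returned normal is the tangent's perpendicular,
    oriented toward ``through``. When ``through`` lies exactly on the
    border the orientation is arbitrary and the caller sees b = 0.
    """
    border = np.atleast_2d(np.asarray(border, dtype=float))
    through = np.asarray(through, dtype=float).reshape(2)
    if border.shape[0] < 2:
        raise GeometryError("border polyline needs at least 2 points")
    foot = _project_to_polyline(border, through)
    d2 = ((border - foot) ** 2).sum(axis=1)
    nearest = border[np.argsort(d2)[: max(2, min(k, border.shape[0]))]]
    centred = nearest - nearest.mean(axis=0)
    cov = centred.T @ centred
    if np.allclose(cov, 0.0):
        raise GeometryError("degenerate tangent: repeated border points")
    eigvals, eigvecs = np.linalg.eigh(cov)
    tangent = eigvecs[:, int(np.argmax(eigvals))]
    normal = np.array([-tangent[1], tangent[0]])
    if normal @ (through - foot) < 0:
        normal = -normal
    return foot, normal


def mcw(landmarks: LandmarkSet, k: int = 7) -> float:
    """Cortical width: axis distance from border to inner margin.

    Casts a ray from the border foot point along the normal toward the
    foramen and returns the distance to its first intersection with the
    endosteal margin polyline. Raises :class:`MeasurementError` when
    the ray never meets the margin.
    """
    foot, normal = perpendicular_axis(
        landmarks.inferior_border, landmarks.foramen_lower_edge, k=k
    )
    margin = landmarks.cortical_inner_margin
    best = None
    for p1, p2 in zip(margin[:-1], margin[1:]):
        seg = p2 - p1
        mat = np.column_stack([normal, -seg])
        det = np.linalg.det(mat)
        if abs(det) < 1e-12:
            continue
        t, s = np.linalg.solve(mat, p1 - foot)
        if -1e-9 <= s <= 1 + 1e-9 and t >= -1e-9:
            t = max(t, 0.0)
            if best is None or t < best:
                best = t
    if best is None:
        raise MeasurementError(
            "perpendicular axis does not intersect the cortical inner margin"
        )
    return float(best)


def pmi(landmarks: LandmarkSet, k: int = 7) -> MorphometricResult:
    """PMI = MCW / (foramen-to-border distance along the axis).

    Invariant under rigid motions of all landmarks and under uniform
    scaling (magnification independence, the index's purpose). A
    foramen at zero height above the border is degenerate geometry.
    """
    foot, normal = perpendicular_axis(
        landmarks.inferior_border, landmarks.foramen_lower_edge, k=k
    )
    b = float(normal @ (landmarks.foramen_lower_edge - foot))
    if b <= 0:
        raise GeometryError(
            f"foramen-to-border distance must be > 0, got {b:.3g}"
        )
    a = mcw(landmarks, k=k)
    return MorphometricResult(
        mcw=a, foramen_border_distance=b, pmi=a / b, side=landmarks.side
    )
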