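"""Doublet mechanics: separation force, contact angle, tension balance.

A cell doublet held in a dual-pipette aspiration (DPA) assay is pulled
apart under stepwise increasing probe pressures; the separation force is
computed from the separating pressure P_n and the last failed pressure
P_{n−1} as

    F_s = π R² (P_{n−1} + P_n) / 2,

with R the pipette internal radius.  A doublet's contact strength is also
visible in its geometry: modelling the two cells as intersecting circles
of radii ρ₁, ρ₂ whose contact is the common chord, each cell's contact
angle is the angle between its surface tangent at a contact vertex and
the contact line, θᵢ = arccos(dᵢ/ρᵢ) with dᵢ the centre-to-chord
distance — 0° at vanishing contact, 90° at full merge.  Finally the
tissue surface tension of an aggregate follows the balance
TST = Tcm − Tcc + Acc/2 of cell–medium cortical tension, cell–cell
cortical tension, and adhesion tension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

Circle = tuple[tuple[float, float], float]  # ((cx, cy) µm, radius µm)


@dataclass
class DPARecord:
    """One dual-pipette aspiration run: pressure steps and the outcome.

    ``pressures_pa`` are the probe pressures of successive pull attempts
    (strictly increasing); ``separated_at`` is the 0-based index of the
    separating step, or None if the doublet never separated.
    """

    pipette_radius_um: float
    pressures_pa: np.ndarray
    separated_at: int | None

    def __post_init__(self) -> None:
        self.pressures_pa = np.asarray(self.pressures_pa, dtype=float)
        if self.pipette_radius_um <= 0:
            raise ValueError("pipette radius must be positive")
        if self.pressures_pa.ndim != 1 or len(self.pressures_pa) == 0:
            raise ValueError("pressures must be a non-empty 1D sequence")
        if np.any(np.diff(self.pressures_pa) <= 0):
            raise ValueError("pressures must be strictly increasing")
        if self.separated_at is not None and not (
            0 <= self.separated_at < len(self.pressures_pa)
        ):
            raise ValueError("separated_at outside the step range")


@dataclass
class SeparationForce:
    F_s: float  # newtons
    lower_bound_flag: bool = False


@dataclass
class DoubletGeometry:
    """Two-circle doublet with its contact chord and contact angles."""

    circle1: Circle
    circle2: Circle
    chord: tuple[tuple[float, float], tuple[float, float]]
    d1: float
    d2: float
    theta1: float  # degrees
    theta2: float
    theta_mean: float
    fit_residual: float = 0.0

    @property
    def theta_vertex(self) -> float:
        """Full opening angle at a contact vertex (θ1 + θ2), degrees."""
        return self.theta1 + self.theta2


@dataclass
class TensionBalance:
    Tcm: float
    Tcc: float
    Acc: float
    TST: float = field(init=False)

    def __post_init__(self) -> None:
        if self.Tcm < 0 or self.Tcc < 0:
            warnings.warn("negative cortical tension supplied", stacklevel=2)
        self.TST = self.Tcm - self.Tcc + self.Acc / 2.0


def separation_force(record: DPARecord) -> SeparationForce:
    """Separation force F_s = πR²(P_{n−1} + P_n)/2 in SI units (newtons).

    When separation happened at the very first step there is no failed
    step, so P_{n−1} = 0 is used and the value flagged as a lower bound.
    """
    if record.separated_at is None:
        raise ValueError("doublet not separated: F_s undefined")
    n = record.separated_at
    P_n = record.pressures_pa[n]
    lower_bound = n == 0
    P_prev = 0.0 if lower_bound else record.pressures_pa[n - 1]
    R_m = record.pipette_radius_um * 1e-6
    F = np.pi * R_m**2 * (P_prev + P_n) / 2.0
    return SeparationForce(F_s=float(F), lower_bound_flag=lower_bound)


def contact_angle_from_circles(circle1: Circle, circle2: Circle) -> DoubletGeometry:
    """Contact geometry of two intersecting circles.

    The contact line is the common chord.  For each circle the distance d
    from its centre to the chord gives the per-cell contact angle
    θ = arccos(d/ρ) (degrees); ``theta_mean`` averages the two cells.
    Externally tangent circles return the analytic limit θ = 0; disjoint
    or nested circles raise (no contact chord).
    """
    (c1, r1), (c2, r2) = circle1, circle2
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    D = float(np.linalg.norm(c2 - c1))
    if D == 0.0:
        # Concentric equal circles: the chord through the centres is the
        # analytic limit, θ = 90° for both cells.
        if not np.isclose(r1, r2):
            raise ValueError("no contact chord: nested circles")
        u = np.array([0.0, 1.0])
        p1, p2 = c1 + r1 * u, c1 - r1 * u
        return DoubletGeometry(
            circle1=circle1,
            circle2=circle2,
            chord=(tuple(p1), tuple(p2)),
            d1=0.0,
            d2=0.0,
            theta1=90.0,
            theta2=90.0,
            theta_mean=90.0,
        )
    if D == r1 + r2:
        # Externally tangent: the contact has shrunk to a single point and
        # the angle reaches its analytic limit θ = 0 for both cells.
        p = tuple(c1 + r1 * (c2 - c1) / D)
        return DoubletGeometry(
            circle1=circle1,
            circle2=circle2,
            chord=(p, p),
            d1=r1,
            d2=r2,
            theta1=0.0,
            theta2=0.0,
            theta_mean=0.0,
        )
    if D > r1 + r2 or D <= abs(r1 - r2):
        raise ValueError("no contact chord: circles disjoint or nested")
    # Signed distance from centre 1 to the chord along the centre line.
    a = (D**2 + r1**2 - r2**2) / (2.0 * D)
    h = float(np.sqrt(max(r1**2 - a**2, 0.0)))
    axis = (c2 - c1) / D
    perp = np.array([-axis[1], axis[0]])
    mid = c1 + a * axis
    p1, p2 = mid + h * perp, mid - h * perp
    d1, d2 = abs(a), abs(D - a)
    th1 = float(np.degrees(np.arccos(np.clip(d1 / r1, -1.0, 1.0))))
    th2 = float(np.degrees(np.arccos(np.clip(d2 / r2, -1.0, 1.0))))
    return DoubletGeometry(
        circle1=circle1,
        circle2=circle2,
        chord=(tuple(p1), tuple(p2)),
        d1=d1,
        d2=d2,
        theta1=th1,
        theta2=th2,
        theta_mean=(th1 + th2) / 2.0,
    )


def tst_balance(Tcm: float, Tcc: float, Acc: float) -> TensionBalance:
    """Tissue-surface-tension balance TST = Tcm − Tcc + Acc/2."""
    return TensionBalance(Tcm=Tcm, Tcc=Tcc, Acc=Acc)


# --------------------------------------------------------------------------
# Image-side contact-angle estimation
# --------------------------------------------------------------------------


def _kasa_circle_fit(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) least-squares circle through 2D points."""
    x, y = points[:, 0], points[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = float(np.sqrt(sol[2] + cx**2 + cy**2))
    return np.array([cx, cy]), r


def _refine_circle(points: np.ndarray, center: np.ndarray, r: float):
    """Geometric refinement minimising radial residuals."""

    def resid(p):
        return np.sqrt((points[:, 0] - p[0]) ** 2 + (points[:, 1] - p[1]) ** 2) - p[2]

    res = optimize.least_squares(resid, x0=[center[0], center[1], r])
    c = res.x[:2]
    rr = float(res.x[2])
    return c, rr, float(np.sqrt(np.mean(resid(res.x) ** 2)))


def _smooth_closed(contour: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of a closed contour (first point dropped
    if duplicated)."""
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    n = len(contour)
    window = max(3, min(window, n // 4 * 2 + 1))
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.vstack([contour[-pad:], contour, contour[:pad]])
    sm = np.column_stack(
        [np.convolve(ext[:, k], kernel, mode="valid") for k in range(2)]
    )
    return sm


def fit_doublet_geometry(
    mask: np.ndarray,
    pixel_size: float,
    smooth_window: int | None = None,
    concavity_min_deg: float = 8.0,
) -> DoubletGeometry:
    """Estimate doublet contact geometry from a segmented binary mask.

    The outer contour is traced at sub-pixel resolution and smoothed; the
    two contact vertices are located as the two strongest concavities
    (most negative turning angles) of the closed contour; the contour is
    split there and a circle fitted to each arc (Kåsa initialisation,
    geometric refinement).  The contact angles then follow from
    :func:`contact_angle_from_circles`.  Raises ``ValueError("not a
    doublet")`` when fewer than two sufficiently concave vertices exist
    (e.g. a single circle).
    """
    from skimage import measure as skmeasure

    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    f = ndimage.gaussian_filter(np.pad(mask.astype(float), 2), 1.0)
    contours = skmeasure.find_contours(f, 0.5)
    if not contours:
        raise ValueError("no contour found")
    contour = max(contours, key=len)  # (row, col) order
    if smooth_window is None:
        smooth_window = max(5, len(contour) // 40)
    c = _smooth_closed(contour, smooth_window)
    n = len(c)

    # Turning angle at each vertex over a small arc stride (robust to
    # residual pixel noise); concave vertices have negative turning for a
    # consistently oriented contour.
    stride = max(2, n // 100)
    prev = np.roll(c, stride, axis=0)
    nxt = np.roll(c, -stride, axis=0)
    v1 = c - prev
    v2 = nxt - c
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    turning = np.arctan2(cross, dot)
    if turning.sum() < 0:  # orient so that convex turning is positive
        turning = -turning
    turning_deg = np.degrees(turning)

    concave = np.flatnonzero(turning_deg < -concavity_min_deg)
    if concave.size == 0:
        raise ValueError("not a doublet: no concave contact vertices")
    # Group contiguous concave runs (circular) and keep each run's minimum.
    breaks = np.flatnonzero(np.diff(concave) > stride)
    groups = np.split(concave, breaks + 1)
    if len(groups) > 1 and (concave[0] == 0 and concave[-1] == n - 1):
        groups[0] = np.concatenate([groups[-1], groups[0]])
        groups = groups[:-1]
    minima = sorted(
        (int(g[np.argmin(turning_deg[g])]) for g in groups),
        key=lambda i: turning_deg[i],
    )
    if len(minima) < 2:
        raise ValueError("not a doublet: fewer than two concave vertices")
    i1, i2 = sorted(minima[:2])

    arc_a = c[i1:i2]
    arc_b = np.vstack([c[i2:], c[:i1]])
    # Trim the immediate vertex neighbourhood, which belongs to neither circle.
    trim = max(2, stride)
    arcs = []
    for arc in (arc_a, arc_b):
        if len(arc) <= 4 * trim:
            raise ValueError("not a doublet: degenerate contact arcs")
        arcs.append(arc[trim:-trim])
    fits = []
    resids = []
    for arc in arcs:
        pts = arc[:, ::-1]  # (x, y) in pixel units
        center, r = _kasa_circle_fit(pts)
        center, r, rms = _refine_circle(pts, center, r)
        fits.append((tuple(center * pixel_size), r * pixel_size))
        resids.append(rms * pixel_size)
    geom = contact_angle_from_circles(fits[0], fits[1])
    geom.fit_residual = float(np.hypot(*resids))
    return geom
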