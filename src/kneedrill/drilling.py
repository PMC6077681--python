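"""Virtual femoral-tunnel drilling through the far anteromedial portal.

The drill is an 8-mm cylinder through the portal centre and the femoral
footprint centre. The portal lies on a line 10 mm above the posed tibial
plateau, parallel to its ML axis, a fixed offset anterior to the plateau's
anterior-most point. The maximum transverse drill angle (MTA) is the most
medial portal whose cylinder still clears the articular surface of the
medial femoral condyle; MTA-10 deg and MTA-20 deg portals are found by
moving laterally. Tunnel length runs from the intra-articular footprint
centre to the external-cortex exit; a tunnel under 25 mm is "short"; wall
breakage within the first 25 mm is classified as entrance (no intact rim at
the aperture) or mid-tunnel (intact aperture, wall lost further in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .kinematics import PosedModel
from .mesh import Ray, SurfaceMesh, cast_ray
from .mesh import _point_segment_distance

__all__ = [
    "DRILL_DIAMETER_MM",
    "PORTAL_HEIGHT_MM",
    "PORTAL_ANTERIOR_OFFSET_MM",
    "SHORT_TUNNEL_MM",
    "BREAKAGE_WINDOW_MM",
    "DrillError",
    "PortalLine",
    "PortalSolution",
    "TunnelResult",
    "portal_line",
    "transverse_angle",
    "find_mta",
    "portal_at_angle",
    "drill_tunnel",
    "classify_breakage",
]

DRILL_DIAMETER_MM = 8.0        # drill-bit diameter
PORTAL_HEIGHT_MM = 10.0        # portal centre height above the tibial plateau
PORTAL_ANTERIOR_OFFSET_MM = 15.0  # portal AP offset anterior to the plateau edge
SHORT_TUNNEL_MM = 25.0         # tunnels shorter than this are "short"
BREAKAGE_WINDOW_MM = 25.0      # wall inspected within this distance of the entrance

# operationalisation of the verbal breakage definition
APERTURE_ALLOWANCE_MM = 8.0    # oblique-aperture allowance before "entrance breakage"
WALL_STEP_MM = 0.25            # axial sampling step along wall generators
N_WALL_GENERATORS = 72         # angular sampling of the cylinder wall
END_MARGIN_MM = 0.5            # margins excluded around aperture/window ends


class DrillError(RuntimeError):
    pass


@dataclass(frozen=True)
class PortalLine:
    """Parametric portal line: ``point(s) = base + s * medial_dir``.

    ``s`` is the signed ML position, increasing medially; the line is
    parallel to the posed plateau ML axis at the portal height and AP offset.
    """

    base: np.ndarray
    medial_dir: np.ndarray

    def point(self, s: float) -> np.ndarray:
        return self.base + s * self.medial_dir


@dataclass
class PortalSolution:
    portal_point: np.ndarray
    transverse_angle_deg: float
    offset_from_mta: float      # 0, -10 or -20
    s: float                    # ML parameter on the portal line
    clearance_mm: float | None = None
    constraint_active: bool = True


@dataclass
class TunnelResult:
    """One drilled tunnel: axis from the femoral footprint centre F into bone."""

    axis: Ray                   # origin F, direction away from the portal
    exit_point: np.ndarray      # centre of the external-cortex exit
    length_mm: float
    diameter_mm: float
    breakage: str               # "none" | "entrance" | "mid_tunnel"
    short: bool

    def __post_init__(self):
        assert abs(self.length_mm - np.linalg.norm(self.exit_point - self.axis.origin)) < 1e-6
        assert self.short == (self.length_mm < SHORT_TUNNEL_MM)


# ---------------------------------------------------------------------------


def portal_line(posed: PosedModel,
                anterior_offset_mm: float = PORTAL_ANTERIOR_OFFSET_MM,
                height_mm: float = PORTAL_HEIGHT_MM) -> PortalLine:
    """Portal line 10 mm above the posed plateau, offset anterior to its edge."""
    f = posed.plateau_frame_posed
    plateau = posed.tibia_posed.region_centroids("plateau")
    if not len(plateau):
        plateau = posed.tibia_posed.vertices
    v_ant = float(((plateau - f.origin) @ f.v).max())
    base = f.origin + (v_ant + anterior_offset_mm) * f.v + height_mm * f.w
    return PortalLine(base=base, medial_dir=-f.u)


def transverse_angle(portal: np.ndarray, F: np.ndarray, frame) -> float:
    """Angle (deg, in [0, 90]) between the drill direction projected into the
    posed plateau plane and the plateau AP axis. 0 = sagittal drill,
    90 = fully transverse."""
    d = np.asarray(F, float) - np.asarray(portal, float)
    if np.linalg.norm(d) < 1e-9:
        raise DrillError("portal coincides with the femoral footprint")
    du = float(d @ frame.u)
    dv = float(d @ frame.v)
    if abs(du) < 1e-12 and abs(dv) < 1e-12:
        raise DrillError("drill direction perpendicular to the plateau plane")
    return float(np.degrees(np.arctan2(abs(du), abs(dv))))


def _tunnel_exit(femur: SurfaceMesh, F: np.ndarray, direction: np.ndarray):
    """Last inside->outside crossing of the drill axis with the femur."""
    crossings = cast_ray(femur, Ray(F, direction))
    exits = [c for c in crossings if c.kind == "exiting" and c.t > 1e-6]
    if not exits:
        if not crossings or max(c.t for c in crossings) <= 1e-6:
            return 0.0  # grazing axis from an on-surface F: degenerate chord
        raise DrillError("drill axis never exits the femur")
    return exits[-1].t


def _cylinder_clearance(femur: SurfaceMesh, obstacle: np.ndarray, P: np.ndarray,
                        F: np.ndarray, radius: float) -> float:
    """Min distance from the obstacle region to the drill cylinder axis
    (portal -> tunnel exit), minus the radius. Negative = contact."""
    d = F - P
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise DrillError("degenerate drill segment")
    direction = d / n
    t_exit = _tunnel_exit(femur, F, direction)
    end = F + t_exit * direction
    a = np.broadcast_to(P, obstacle.shape)
    b = np.broadcast_to(end, obstacle.shape)
    dist = _point_segment_distance(obstacle, a, b)
    return float(dist.min() - radius)


def _sagittal_s(line: PortalLine, F: np.ndarray, frame) -> float:
    """Portal parameter at which the drill direction lies in the sagittal
    plane ((F - P) . u = 0); portals medial of this drill laterally."""
    return -float((np.asarray(F, float) - line.base) @ frame.u)


def _obstacle_points(femur: SurfaceMesh, max_points: int = 4000) -> np.ndarray:
    pts = femur.region_centroids("medial_condyle_articular")
    if not len(pts):
        # unlabelled mesh: heuristic stand-in for the medial-condyle articular
        # surface — distal-half faces on the medial quarter (canonical frame)
        c = femur.face_centroids
        lo, hi = femur.bounds
        z_mid = 0.5 * (lo[2] + hi[2])
        x_cut = lo[0] + 0.25 * (hi[0] - lo[0])
        pts = c[(c[:, 2] < z_mid) & (c[:, 0] < x_cut)]
    if not len(pts):
        raise DrillError("no medial-condyle articular region available")
    if len(pts) > max_points:
        step = int(np.ceil(len(pts) / max_points))
        pts = pts[::step]
    return pts


def find_mta(posed: PosedModel, F: np.ndarray,
             diameter_mm: float = DRILL_DIAMETER_MM,
             anterior_offset_mm: float = PORTAL_ANTERIOR_OFFSET_MM,
             s_tol: float = 0.02,
             n_validate: int = 17,
             obstacle: np.ndarray | None = None,
             height_mm: float = PORTAL_HEIGHT_MM) -> PortalSolution:
    """Most medial feasible portal: bisection on the portal ML parameter for
    the position where the full drill cylinder just clears the medial-condyle
    articular surface.

    Feasibility must be monotone over the bracket (validated on a coarse
    sample); if the constraint never binds the medial end of the portal line
    is returned with ``constraint_active=False``.
    """
    femur = posed.base.femur
    line = portal_line(posed, anterior_offset_mm, height_mm)
    if obstacle is None:
        obstacle = _obstacle_points(femur)
    r = diameter_mm / 2.0
    f = posed.plateau_frame_posed
    plateau = posed.tibia_posed.region_centroids("plateau")
    if not len(plateau):
        plateau = posed.tibia_posed.vertices
    u_rel = (plateau - line.base) @ (-f.u)
    # lateral end: plateau extent, but never so lateral that the drill points
    # medially (the transportal construction needs a laterally-directed drill;
    # angle monotonicity in s holds only on that branch)
    s_lo = max(float(u_rel.min()) - 20.0, _sagittal_s(line, F, f) + 1.0)
    s_hi = float(u_rel.max()) + 20.0   # medial end

    def clearance(s: float) -> float:
        return _cylinder_clearance(femur, obstacle, line.point(s), F, r)

    samples = np.linspace(s_lo, s_hi, n_validate)
    feas = np.array([clearance(s) >= 0.0 for s in samples])
    if not feas[0]:
        raise DrillError("drill corridor blocked: no feasible portal on the line")
    if feas.all():
        s = s_hi
        sol_clear = clearance(s)
        ang = transverse_angle(line.point(s), F, f)
        return PortalSolution(line.point(s), ang, 0.0, s, sol_clear, constraint_active=False)
    first_bad = int(np.argmin(feas))
    if feas[first_bad:].any():
        trace = ", ".join(f"s={s:.1f}:{'ok' if ok else 'hit'}"
                          for s, ok in zip(samples, feas))
        raise DrillError(f"non-monotone portal feasibility over the bracket: {trace}")
    lo, hi = samples[first_bad - 1], samples[first_bad]
    while hi - lo > s_tol:
        mid = 0.5 * (lo + hi)
        if clearance(mid) >= 0.0:
            lo = mid
        else:
            hi = mid
    s = float(lo)
    ang = transverse_angle(line.point(s), F, f)
    return PortalSolution(line.point(s), ang, 0.0, s, clearance(s), constraint_active=True)


def portal_at_angle(posed: PosedModel, F: np.ndarray, target_deg: float,
                    mta: PortalSolution,
                    anterior_offset_mm: float = PORTAL_ANTERIOR_OFFSET_MM,
                    angle_tol: float = 0.01,
                    height_mm: float = PORTAL_HEIGHT_MM) -> PortalSolution:
    """Portal lateral to the MTA achieving the target transverse angle."""
    if target_deg > mta.transverse_angle_deg + 1e-9:
        raise DrillError(
            f"target angle {target_deg:.2f} exceeds MTA {mta.transverse_angle_deg:.2f}"
        )
    line = portal_line(posed, anterior_offset_mm, height_mm)
    frame = posed.plateau_frame_posed

    def g(s: float) -> float:
        return transverse_angle(line.point(s), F, frame) - target_deg

    s_hi = mta.s
    if abs(g(s_hi)) <= angle_tol:
        return PortalSolution(line.point(s_hi), target_deg + g(s_hi),
                              target_deg - mta.transverse_angle_deg, s_hi,
                              mta.clearance_mm, mta.constraint_active)
    # bracket laterally: the transverse angle decreases as the portal moves
    # laterally, reaching 0 where the drill crosses the sagittal direction
    s_min = _sagittal_s(line, F, frame)
    s_lo = s_hi
    step = 5.0
    while s_lo > s_min:
        s_lo = max(s_lo - step, s_min)
        if g(s_lo) <= 0.0:
            break
    else:
        raise DrillError(f"target angle {target_deg:.2f} deg unreachable on the portal line")
    s = brentq(g, s_lo, s_hi, xtol=1e-6)
    ang = transverse_angle(line.point(s), F, frame)
    if abs(ang - target_deg) > angle_tol:
        raise DrillError(f"root finding failed: angle {ang:.4f} vs target {target_deg:.4f}")
    return PortalSolution(line.point(s), ang, target_deg - mta.transverse_angle_deg,
                          float(s))


def drill_axis(femur: SurfaceMesh, portal_point: np.ndarray, F: np.ndarray,
               diameter_mm: float = DRILL_DIAMETER_MM,
               **breakage_kwargs) -> TunnelResult:
    """Drill along portal -> F through ``femur``: length to the external
    cortex, short flag and wall-breakage class."""
    F = np.asarray(F, float)
    d = F - np.asarray(portal_point, float)
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise DrillError("portal coincides with footprint")
    direction = d / n
    t_exit = _tunnel_exit(femur, F, direction)
    exit_point = F + t_exit * direction
    breakage = classify_breakage(femur, F, direction, t_exit, diameter_mm,
                                 **breakage_kwargs)
    return TunnelResult(
        axis=Ray(F, direction),
        exit_point=exit_point,
        length_mm=float(t_exit),
        diameter_mm=diameter_mm,
        breakage=breakage,
        short=bool(t_exit < SHORT_TUNNEL_MM),
    )


def drill_tunnel(posed: PosedModel, portal: PortalSolution, F: np.ndarray,
                 diameter_mm: float = DRILL_DIAMETER_MM,
                 **breakage_kwargs) -> TunnelResult:
    """Drill along portal -> F, measure length to the external-cortex exit and
    classify wall breakage."""
    return drill_axis(posed.base.femur, portal.portal_point, F, diameter_mm,
                      **breakage_kwargs)


def classify_breakage(femur: SurfaceMesh, F: np.ndarray, direction: np.ndarray,
                      length_mm: float,
                      diameter_mm: float = DRILL_DIAMETER_MM,
                      a_cap: float = APERTURE_ALLOWANCE_MM,
                      step: float = WALL_STEP_MM,
                      n_theta: int = N_WALL_GENERATORS,
                      margin: float = END_MARGIN_MM) -> str:
    """Classify tunnel-wall breakage within the first 25 mm.

    Wall generators ``W_theta(t) = F + t*axis + r*n_theta`` are sampled every
    ``step`` mm over ``t in [0, min(length, 25)]``. A generator with no
    in-bone sample within the first ``a_cap`` mm (the oblique-aperture
    allowance) signals *entrance* breakage. Otherwise a generator that leaves
    bone again between its first in-bone sample (+margin) and the end of the
    window (-margin) signals *mid-tunnel* breakage. The two classes are
    mutually exclusive by definition.
    """
    F = np.asarray(F, float)
    direction = np.asarray(direction, float)
    r = diameter_mm / 2.0
    helper = np.array([0.0, 0.0, 1.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    t_max = min(length_mm, BREAKAGE_WINDOW_MM)
    ts = np.arange(0.0, t_max + 1e-9, step)
    thetas = 2.0 * np.pi * np.arange(n_theta) / n_theta
    ring = r * (np.cos(thetas)[:, None] * e1 + np.sin(thetas)[:, None] * e2)  # (n,3)
    pts = (F + ring[:, None, :] + ts[None, :, None] * direction)  # (n, nt, 3)
    inside = femur.contains(pts.reshape(-1, 3)).reshape(n_theta, len(ts))

    within_cap = ts <= a_cap + 1e-9
    entrance = ~(inside[:, within_cap].any(axis=1))
    if entrance.any():
        return "entrance"

    first_in = np.argmax(inside, axis=1)  # every generator has an inside sample
    a = ts[first_in]
    lo = a[:, None] + margin
    hi = t_max - margin
    broken = (~inside) & (ts[None, :] > lo) & (ts[None, :] < hi)
    if broken.any():
        return "mid_tunnel"
    return "none"
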