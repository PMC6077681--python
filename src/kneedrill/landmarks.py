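"""Anatomical landmark detection and quadrant-method footprint localisation.

The femoral ACL footprint centre is placed on the medial wall of the lateral
femoral condyle by the Bernard quadrant convention: in the true-lateral
projection (viewing along the transepicondylar axis, condyles superimposed)
a grid is aligned to the notch-roof line (the Blumensaat-line proxy on a 3D
model) and the footprint sits at fixed fractional coordinates of the
condyle's projected silhouette — by default 28.4% along the roof line from
the posterior border and 35.7% perpendicular to it, toward distal.

The tibial footprint centre lies at 35.7% of the plateau's AP depth from the
anterior border and 51.5% of its ML width from the medial border, on a true
proximal-to-distal view.

All operations assume the canonical right-knee frame (+X lateral, +Y
anterior, +Z proximal) unless an explicit body ``frame`` is supplied; use
``KneeModel.canonical()`` for left knees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Frame, Ray, SurfaceMesh, _triangle_hits, cast_ray

__all__ = [
    "FEMORAL_FRAC_ALONG",
    "FEMORAL_FRAC_PERP",
    "TIBIAL_FRAC_AP",
    "TIBIAL_FRAC_ML",
    "Landmarks",
    "QuadrantGrid",
    "LandmarkError",
    "epicondylar_axis",
    "notch_reference_line",
    "quadrant_grid",
    "grid_point_2d",
    "femoral_footprint_center",
    "plateau_frame",
    "tibial_footprint_center",
    "compute_landmarks",
]

# quadrant-method footprint coordinates for single-bundle reconstruction
FEMORAL_FRAC_ALONG = 0.284  # along the Blumensaat proxy, from the posterior border
FEMORAL_FRAC_PERP = 0.357   # perpendicular to it, from the proxy line toward distal
TIBIAL_FRAC_AP = 0.357      # AP depth fraction from the anterior border
TIBIAL_FRAC_ML = 0.515      # ML width fraction from the medial border


class LandmarkError(RuntimeError):
    pass


def _canonical_frame() -> Frame:
    return Frame((0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


@dataclass
class QuadrantGrid:
    """The quadrant grid in the true-lateral projection.

    ``origin2d`` is the grid corner at (posterior border, Blumensaat proxy);
    ``e_along`` points posterior->anterior along the proxy line, ``e_perp``
    perpendicular toward distal. Extents are the silhouette spans (mm).
    """

    origin2d: np.ndarray
    e_along: np.ndarray
    e_perp: np.ndarray
    extent_along: float
    extent_perp: float

    def __post_init__(self):
        if not (self.extent_along > 0 and self.extent_perp > 0):
            raise ValueError("grid extents must be positive")
        if abs(float(np.dot(self.e_along, self.e_perp))) > 1e-9:
            raise ValueError("grid axes must be orthonormal")


@dataclass
class Landmarks:
    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    tea: Ray
    lateral_frame: Frame
    notch_apex: np.ndarray          # 3D, on the mid-sagittal projection plane
    blumensaat_dir_2d: np.ndarray   # unit 2D vector in the lateral projection
    grid: QuadrantGrid
    plateau_frame: Frame
    femoral_fp: np.ndarray
    tibial_fp: np.ndarray


# ---------------------------------------------------------------------------
# epicondyles and the transepicondylar axis
# ---------------------------------------------------------------------------


def epicondylar_axis(femur: SurfaceMesh, frame: Frame | None = None):
    """Extreme medial/lateral surface points within the distal condylar half.

    Returns ``(medial_epicondyle, lateral_epicondyle, tea)`` with the TEA ray
    through the midpoint, directed medial -> lateral (+u of the body frame).
    """
    frame = frame or _canonical_frame()
    v = femur.vertices
    z = (v - frame.origin) @ frame.w
    zmid = 0.5 * (z.min() + z.max())
    distal = v[z < zmid]
    if len(distal) < 3:
        raise LandmarkError("no distal vertices below the bounding-box midplane")
    x = (distal - frame.origin) @ frame.u
    if x.max() - x.min() < 1.0:
        raise LandmarkError(
            f"degenerate mesh: medio-lateral extent {x.max() - x.min():.3f} mm is ambiguous"
        )
    med = distal[np.argmin(x)]
    lat = distal[np.argmax(x)]
    mid = 0.5 * (med + lat)
    direction = (lat - med) / np.linalg.norm(lat - med)
    return med, lat, Ray(mid, direction)


def lateral_projection_frame(tea: Ray, frame: Frame | None = None) -> Frame:
    """True-lateral view: w along the TEA, u anterior, v proximal."""
    frame = frame or _canonical_frame()
    return Frame.from_w(tea.origin, tea.direction, u_hint=frame.v)


# ---------------------------------------------------------------------------
# notch roof tracing (Blumensaat-line proxy)
# ---------------------------------------------------------------------------


def notch_reference_line(femur: SurfaceMesh, tea: Ray, frame: Frame | None = None,
                         n_ap: int = 121, n_height: int = 101):
    """Trace the intercondylar notch roof and fit the Blumensaat-line proxy.

    A lateral-projection location (u=anterior, v=proximal) lies in the
    intercondylar corridor when a ray along the TEA passes bone on both sides
    of the mid-epicondylar plane without being inside bone at that plane. The
    roof is, per anterior station, the most proximal corridor location; the
    notch apex is the most anterior roof point and the proxy direction is the
    principal axis of the traced roof, oriented posterior -> anterior.

    Returns ``(notch_apex_3d, blumensaat_dir_2d, roof_points_2d)``.
    """
    frame = frame or _canonical_frame()
    lat = lateral_projection_frame(tea, frame)
    # sample the lateral-projection plane over the distal half of the femur;
    # ranges come from the projected vertices so the trace is equivariant
    # under rigid transforms applied jointly to mesh and frame
    uv = lat.project(femur.vertices)
    us = np.linspace(uv[:, 0].min(), uv[:, 0].max(), n_ap)
    v_lo, v_hi = uv[:, 1].min(), uv[:, 1].max()
    vs = np.linspace(v_lo, v_lo + 0.5 * (v_hi - v_lo), n_height)
    U, V = np.meshgrid(us, vs, indexing="ij")
    uv_grid = np.stack([U.ravel(), V.ravel()], axis=1)
    # ray origins behind the mesh on the medial side, cast along +w (= TEA dir)
    w_lo = float(((femur.vertices - lat.origin) @ lat.w).min()) - 5.0
    origins = lat.lift(uv_grid, w_coord=w_lo)
    axis = int(np.argmax(np.abs(lat.w)))
    if abs(lat.w[axis] - 1.0) > 1e-6:
        # generic direction: fall back to per-ray casting (canonical TEA is +X,
        # where the bucketed axis caster applies)
        open_mask = np.array([_corridor_open(femur, Ray(o, lat.w), -w_lo)
                              for o in origins])
    else:
        caster = femur._caster(axis)
        pi, t = caster.hits(origins)
        open_mask = np.zeros(len(origins), dtype=bool)
        t_mid = -w_lo  # parameter of the mid-epicondylar plane
        uniq, starts = np.unique(pi, return_index=True)
        ends = np.append(starts[1:], len(pi))
        for i, s, e in zip(uniq, starts, ends):
            ts = t[s:e]
            if len(ts) < 2:
                continue
            parity_at_mid = int(np.searchsorted(ts, t_mid) % 2)
            open_mask[i] = (parity_at_mid == 0) and (ts[0] < t_mid) and (ts[-1] > t_mid)
    open_grid = open_mask.reshape(n_ap, n_height)
    # per anterior station: top of the lowest contiguous open run (>= 2 cells),
    # kept only distal to the epicondylar level (v < 0) — the notch roof sits
    # below the TEA; isolated sliver openings are noise.
    roof_pts = []
    for iu in range(n_ap):
        col = np.flatnonzero(open_grid[iu])
        if len(col) < 2:
            continue
        breaks = np.flatnonzero(np.diff(col) > 1)
        top = col[breaks[0]] if len(breaks) else col[-1]
        run_lo = col[0]
        if top - run_lo < 1:
            continue
        if vs[top] < 0.0:
            roof_pts.append((us[iu], vs[top]))
    if not roof_pts:
        raise LandmarkError("no intercondylar notch detected")
    roof = np.asarray(roof_pts)
    apex2d = roof[np.argmax(roof[:, 0])]
    centred = roof - roof.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if direction[0] < 0:
        direction = -direction  # orient posterior -> anterior
    apex3d = lat.lift(apex2d)
    return apex3d, direction, roof


def _corridor_open(femur: SurfaceMesh, ray: Ray, t_mid: float) -> bool:
    cr = cast_ray(femur, ray)
    ts = np.array([c.t for c in cr])
    if len(ts) < 2:
        return False
    parity = int(np.searchsorted(ts, t_mid) % 2)
    return parity == 0 and ts[0] < t_mid and ts[-1] > t_mid


# ---------------------------------------------------------------------------
# femoral footprint (quadrant method)
# ---------------------------------------------------------------------------


def _wall_faces(femur: SurfaceMesh, frame: Frame) -> np.ndarray:
    idx = femur.region_faces("lateral_condyle_medial_wall")
    if len(idx):
        return idx
    # heuristic: medially-facing faces on the lateral side, distal half
    n = femur.face_normals @ frame.u
    c = femur.face_centroids
    x = (c - frame.origin) @ frame.u
    z = (c - frame.origin) @ frame.w
    zmid = 0.5 * (z.min() + z.max())
    idx = np.flatnonzero((n < -0.5) & (x > 0) & (z < zmid))
    if not len(idx):
        raise LandmarkError("no medial-wall faces found (no labels, heuristic empty)")
    return idx


def quadrant_grid(femur: SurfaceMesh, tea: Ray, notch_apex: np.ndarray,
                  blumensaat_dir_2d: np.ndarray, frame: Frame | None = None) -> QuadrantGrid:
    """Quadrant grid spanning the medial-wall silhouette in the lateral view."""
    frame = frame or _canonical_frame()
    lat = lateral_projection_frame(tea, frame)
    faces = _wall_faces(femur, frame)
    verts = femur.vertices[np.unique(femur.faces[faces])]
    pts2d = lat.project(verts)
    e_a = np.asarray(blumensaat_dir_2d, float)
    e_a = e_a / np.linalg.norm(e_a)
    e_p = np.array([e_a[1], -e_a[0]])  # rotate -90 deg: distal for e_a anterior
    a = pts2d @ e_a
    p = pts2d @ e_p
    apex2d = lat.project(notch_apex.reshape(1, 3))[0]
    a0 = float(a.min())                      # posterior border
    p0 = float(apex2d @ e_p)                 # Blumensaat proxy line
    extent_along = float(a.max() - a0)
    extent_perp = float(p.max() - p0)        # toward distal (articular margin)
    return QuadrantGrid(a0 * e_a + p0 * e_p, e_a, e_p, extent_along, extent_perp)


def grid_point_2d(grid: QuadrantGrid, frac_along: float, frac_perp: float) -> np.ndarray:
    """Exact 2D grid coordinates: fractions 0/1 map to the grid borders."""
    return (grid.origin2d
            + frac_along * grid.extent_along * grid.e_along
            + frac_perp * grid.extent_perp * grid.e_perp)


def femoral_footprint_center(femur: SurfaceMesh, tea: Ray, grid: QuadrantGrid,
                             frac_along: float = FEMORAL_FRAC_ALONG,
                             frac_perp: float = FEMORAL_FRAC_PERP,
                             frame: Frame | None = None) -> np.ndarray:
    """Lift the 2D grid point onto the lateral condyle's medial wall.

    The lift ray runs along the viewing axis from the medial side; the first
    hit on the medial-wall submesh is returned.
    """
    frame = frame or _canonical_frame()
    lat = lateral_projection_frame(tea, frame)
    q = grid_point_2d(grid, frac_along, frac_perp)
    w_lo = float(((femur.vertices - lat.origin) @ lat.w).min()) - 5.0
    origin = lat.lift(q, w_coord=w_lo)
    faces = _wall_faces(femur, frame)
    tri = femur.vertices[femur.faces[faces]]
    t, _ = _triangle_hits(
        np.ascontiguousarray(tri[:, 0]),
        np.ascontiguousarray(tri[:, 1] - tri[:, 0]),
        np.ascontiguousarray(tri[:, 2] - tri[:, 0]),
        origin, lat.w,
    )
    t = t[t > 0]
    if not len(t):
        raise LandmarkError(f"footprint lift ray missed the medial wall at 2D {q}")
    return origin + float(t.min()) * lat.w


# ---------------------------------------------------------------------------
# tibial plateau frame and footprint
# ---------------------------------------------------------------------------


def plateau_frame(tibia: SurfaceMesh, frame: Frame | None = None) -> Frame:
    """Least-squares plane through the plateau region: origin on the plateau,
    u = medio-lateral, v = antero-posterior, w = proximal normal."""
    frame = frame or _canonical_frame()
    idx = tibia.region_faces("plateau")
    if len(idx):
        pts = tibia.face_centroids[idx]
    else:
        # heuristic: near-vertical normals in the top 15 mm
        c = tibia.face_centroids
        z = (c - frame.origin) @ frame.w
        near_top = z > z.max() - 15.0
        vertical = (tibia.face_normals @ frame.w) > 0.7
        pts = c[near_top & vertical]
        if len(pts) < 3:
            raise LandmarkError("no plateau faces found (no labels, heuristic empty)")
    origin = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - origin, full_matrices=False)
    w = vt[2]
    if np.dot(w, frame.w) < 0:
        w = -w
    return Frame.from_w(origin, w, u_hint=frame.u)


def tibial_footprint_center(tibia: SurfaceMesh, pframe: Frame,
                            frac_ap: float = TIBIAL_FRAC_AP,
                            frac_ml: float = TIBIAL_FRAC_ML) -> np.ndarray:
    """Fractional point of the plateau outline's bounding box, lifted onto the
    plateau surface by a proximal -> distal ray."""
    idx = tibia.region_faces("plateau")
    pts = tibia.face_centroids[idx] if len(idx) else tibia.vertices
    uv = pframe.project(pts)
    u_min, u_max = uv[:, 0].min(), uv[:, 0].max()   # u_min = medial border
    v_min, v_max = uv[:, 1].min(), uv[:, 1].max()   # v_max = anterior border
    u_star = u_min + frac_ml * (u_max - u_min)
    v_star = v_max - frac_ap * (v_max - v_min)
    high = float(((tibia.vertices - pframe.origin) @ pframe.w).max()) + 5.0
    origin = pframe.lift(np.array([u_star, v_star]), w_coord=high)
    crossings = cast_ray(tibia, Ray(origin, -pframe.w))
    if not crossings:
        raise LandmarkError("tibial footprint lift ray missed the tibia")
    return origin - crossings[0].t * pframe.w


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def compute_landmarks(femur: SurfaceMesh, tibia: SurfaceMesh,
                      frame: Frame | None = None,
                      femoral_frac_along: float = FEMORAL_FRAC_ALONG,
                      femoral_frac_perp: float = FEMORAL_FRAC_PERP,
                      tibial_frac_ap: float = TIBIAL_FRAC_AP,
                      tibial_frac_ml: float = TIBIAL_FRAC_ML) -> Landmarks:
    """Full landmark set for one canonical-frame knee."""
    frame = frame or _canonical_frame()
    med, lat_e, tea = epicondylar_axis(femur, frame)
    apex, bdir, _ = notch_reference_line(femur, tea, frame)
    grid = quadrant_grid(femur, tea, apex, bdir, frame)
    fem_fp = femoral_footprint_center(femur, tea, grid, femoral_frac_along,
                                      femoral_frac_perp, frame)
    pframe = plateau_frame(tibia, frame)
    tib_fp = tibial_footprint_center(tibia, pframe, tibial_frac_ap, tibial_frac_ml)
    return Landmarks(
        medial_epicondyle=med,
        lateral_epicondyle=lat_e,
        tea=tea,
        lateral_frame=lateral_projection_frame(tea, frame),
        notch_apex=apex,
        blumensaat_dir_2d=bdir,
        grid=grid,
        plateau_frame=pframe,
        femoral_fp=fem_fp,
        tibial_fp=tib_fp,
    )
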