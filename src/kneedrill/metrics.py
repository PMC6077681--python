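"""Graft bending angle at the femoral tunnel aperture.

Measured with the knee in full extension: the intra-articular graft runs
from the tibial footprint centre A to the femoral footprint centre B; its
extension beyond B defines the straight-graft direction. The bending angle
is the angle at B between that extension and the tunnel axis toward the
external-cortex exit D. 0 deg means the tunnel prolongs the graft line;
larger values mean a sharper bend at the aperture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BendingResult", "graft_bending_angle"]


@dataclass
class BendingResult:
    angle_deg: float
    A: np.ndarray  # tibial footprint centre (extension pose)
    B: np.ndarray  # femoral footprint centre
    D: np.ndarray  # tunnel exit point


def graft_bending_angle(A, B, D) -> float:
    """Angle (deg, in [0, 180]) at B between the A->B direction continued
    beyond B and the direction B->D."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    D = np.asarray(D, float)
    g = B - A
    t = D - B
    ng = np.linalg.norm(g)
    nt = np.linalg.norm(t)
    if ng < 1e-12 or nt < 1e-12:
        raise ValueError("coincident points: bending angle undefined")
    c = float(np.dot(g, t) / (ng * nt))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
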