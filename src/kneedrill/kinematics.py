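"""Knee flexion posing: a pure hinge about the transepicondylar axis.

The femur (and hence the drilled tunnel) stays fixed in the world frame; the
tibia, its plateau frame and its footprint centre rotate about the TEA by the
flexion angle, in the direction that carries the tibial shaft posteriorly.
Roll-back and screw-home motion are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .landmarks import Landmarks
from .mesh import Frame, SurfaceMesh, rotation_about_axis
from .synthetic import KneeModel

__all__ = ["PosedModel", "flex_knee", "flexion_rotation"]


@dataclass
class PosedModel:
    """A knee posed at a given flexion angle (femur world-fixed)."""

    base: KneeModel
    landmarks: Landmarks
    flexion_deg: float
    tibia_posed: SurfaceMesh
    plateau_frame_posed: Frame
    tibial_fp_posed: np.ndarray
    rotation: Rotation
    pivot: np.ndarray


def flexion_rotation(model: KneeModel, landmarks: Landmarks,
                     flexion_deg: float) -> tuple[Rotation, np.ndarray]:
    """Rotation carrying the extension-pose tibia to ``flexion_deg``.

    The hinge is the TEA; the sign is chosen so the tibial shaft's distal end
    moves posteriorly (toward -v of the body frame, -Y canonically).
    """
    tea = landmarks.tea
    # distal end of the tibia = lowest point along the proximal axis
    w = landmarks.plateau_frame.w
    distal = model.tibia.vertices[np.argmin(model.tibia.vertices @ w)]
    probe_angle = min(max(flexion_deg, 1.0), 90.0)
    best = None
    for sign in (+1.0, -1.0):
        rot, pivot = rotation_about_axis(tea.origin, tea.direction, sign * probe_angle)
        moved = pivot + rot.apply(distal - pivot)
        dy = float((moved - distal) @ landmarks.lateral_frame.u)  # anterior component
        if best is None or dy < best[0]:
            best = (dy, sign)
    sign = best[1]
    return rotation_about_axis(tea.origin, tea.direction, sign * flexion_deg)


def flex_knee(model: KneeModel, landmarks: Landmarks, flexion_deg: float) -> PosedModel:
    """Pose the tibia at ``flexion_deg`` about the TEA (femur untouched)."""
    if not (0.0 <= flexion_deg <= 160.0):
        raise ValueError(f"flexion {flexion_deg} deg outside [0, 160]")
    rot, pivot = flexion_rotation(model, landmarks, flexion_deg)
    tibia_posed = model.tibia.transformed(rot=rot, about=pivot)
    pframe = landmarks.plateau_frame.transformed(rot, pivot)
    tib_fp = pivot + rot.apply(landmarks.tibial_fp - pivot)
    return PosedModel(
        base=model,
        landmarks=landmarks,
        flexion_deg=flexion_deg,
        tibia_posed=tibia_posed,
        plateau_frame_posed=pframe,
        tibial_fp_posed=tib_fp,
        rotation=rot,
        pivot=pivot,
    )
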