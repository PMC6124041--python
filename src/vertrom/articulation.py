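"""Articulated-chain kinematics: neutral pose, pivots, spacing, rotations.

The chain convention: world +x is anterior, +y left-lateral, +z dorsal.  A
neutral pose straightens the column along x with each vertebra's local frame
axis-aligned, reproducing the requested inter-centrum spacing.  Every joint
carries a pivot at the midpoint between the facing centrum-face centroids --
the operational "center of the intervertebral disc" -- and two rotation axes:
rotation about the dorsoventral (z) axis is lateral flexion in the frontal
plane, rotation about the mediolateral (y) axis is dorsal/ventral flexion in
the median plane.  Dorsal is positive about +y, ventral negative, and lateral
rotation moves the posterior vertebra toward the animal's right.

Vertebra motion is rigid throughout; there are no translational (shear) or
axial-torsion degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._proximity import PartSurface, pair_min_distance
from .errors import ParameterError, PoseError, ReductionError
from .mesh_io import LabeledVertebraMesh

__all__ = [
    "JointFrame",
    "ColumnPose",
    "PROFILES",
    "neutral_pose",
    "compute_pivot",
    "reduce_spacing",
    "apply_rotation",
]

#: profile name -> (axis attribute, sign) for a positive commanded angle
PROFILES = {
    "lateral": ("lateral_axis", +1.0),
    "lateral_left": ("lateral_axis", -1.0),
    "dorsal": ("dorsoventral_axis", +1.0),
    "ventral": ("dorsoventral_axis", -1.0),
}


@dataclass
class JointFrame:
    """Rotation frame of the joint between vertebra ``index`` and ``index+1``.

    ``lateral_axis`` (the dorsoventral direction) is the axis of lateral
    flexion; ``dorsoventral_axis`` (the mediolateral direction) is the axis of
    dorsal/ventral flexion.  ``gap`` is the distance between the facing
    centrum-face centroids.
    """

    index: int
    pivot: np.ndarray
    lateral_axis: np.ndarray
    dorsoventral_axis: np.ndarray
    gap: float

    def validate(self) -> None:
        for axis in (self.lateral_axis, self.dorsoventral_axis):
            if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-9):
                raise PoseError("joint axes must be unit length")
        if not np.isclose(self.lateral_axis @ self.dorsoventral_axis, 0.0, atol=1e-9):
            raise PoseError("joint axes must be orthogonal")


@dataclass
class ColumnPose:
    """Rigid transforms of every vertebra plus per-joint frames."""

    column: list[LabeledVertebraMesh]
    transforms: list[np.ndarray]
    joints: list[JointFrame]
    mode: str = "preserved"
    applied: dict[tuple[int, str], float] = field(default_factory=dict)
    reduction_translations: list[float] | None = None

    def world_landmark(self, index: int, key: str) -> np.ndarray:
        t = self.transforms[index]
        return t[:3, :3] @ self.column[index].landmarks[key] + t[:3, 3]

    def copy(self) -> "ColumnPose":
        return ColumnPose(
            column=self.column,
            transforms=[t.copy() for t in self.transforms],
            joints=[replace(j, pivot=j.pivot.copy()) for j in self.joints],
            mode=self.mode,
            applied=dict(self.applied),
            reduction_translations=None
            if self.reduction_translations is None
            else list(self.reduction_translations),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "vertebrae": [
                {"id": v.id, "transform": t.tolist()}
                for v, t in zip(self.column, self.transforms)
            ],
            "joints": [
                {
                    "index": j.index,
                    "pivot": j.pivot.tolist(),
                    "lateral_axis": j.lateral_axis.tolist(),
                    "dorsoventral_axis": j.dorsoventral_axis.tolist(),
                    "gap": j.gap,
                }
                for j in self.joints
            ],
            "applied": [
                {"joint": k[0], "profile": k[1], "angle_deg": v}
                for k, v in sorted(self.applied.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _frame_rotation(vert: LabeledVertebraMesh) -> np.ndarray:
    """World rotation aligning the vertebra's local frame with the chain axes."""
    frame = np.asarray(vert.frame, dtype=float)
    if not np.allclose(frame @ frame.T, np.eye(3), atol=1e-9):
        raise PoseError(f"{vert.id}: local frame is not orthonormal")
    return frame


def compute_pivot(pose: ColumnPose, joint: int) -> JointFrame:
    """Joint frame between vertebrae ``joint`` and ``joint+1`` in a pose.

    The pivot is the midpoint of the segment joining the anterior vertebra's
    posterior-face centroid and the posterior vertebra's anterior-face
    centroid (world coordinates); axes come from the anterior vertebra's
    frame in the current pose.
    """
    if not 0 <= joint < len(pose.column) - 1:
        raise ParameterError(f"joint index {joint} out of range")
    p_post = pose.world_landmark(joint, "posterior")
    p_ant = pose.world_landmark(joint + 1, "anterior")
    rot = pose.transforms[joint][:3, :3]
    frame = _frame_rotation(pose.column[joint])
    # world directions of the anterior vertebra's local axes
    left = rot @ frame[1]
    dorsal = rot @ frame[2]
    jf = JointFrame(
        index=joint,
        pivot=(p_post + p_ant) / 2.0,
        lateral_axis=dorsal,
        dorsoventral_axis=left,
        gap=float(np.linalg.norm(p_post - p_ant)),
    )
    jf.validate()
    return jf


def neutral_pose(
    column: list[LabeledVertebraMesh],
    gaps: list[float] | None = None,
    mode: str = "preserved",
) -> ColumnPose:
    """Straighten a column along the chain axis at the requested spacing.

    ``gaps`` gives the inter-centrum spacing per joint (distance between the
    facing face centroids, mm).  When omitted it is measured from the source
    coordinates, i.e. the preserved spacing of an in-situ scan.  All applied
    joint angles are zero in the result.
    """
    if len(column) < 2:
        raise PoseError("a chain needs at least two vertebrae")
    if gaps is None:
        gaps = [
            float(
                np.linalg.norm(
                    column[i + 1].landmarks["anterior"] - column[i].landmarks["posterior"]
                )
            )
            for i in range(len(column) - 1)
        ]
    if len(gaps) != len(column) - 1:
        raise PoseError("need one gap per joint")
    for vert in column:
        if np.allclose(vert.landmarks["anterior"], vert.landmarks["posterior"]):
            raise PoseError(f"{vert.id}: coincident face landmarks")

    ex = np.array([1.0, 0.0, 0.0])
    transforms = []
    cursor = np.zeros(3)  # world position of the next anterior-face centroid
    for i, vert in enumerate(column):
        rot = _frame_rotation(vert)
        t = np.eye(4)
        t[:3, :3] = rot
        t[:3, 3] = cursor - rot @ vert.landmarks["anterior"]
        transforms.append(t)
        if i < len(column) - 1:
            post = rot @ vert.landmarks["posterior"] + t[:3, 3]
            cursor = post - gaps[i] * ex

    pose = ColumnPose(column=column, transforms=transforms, joints=[], mode=mode)
    pose.joints = [compute_pivot(pose, j) for j in range(len(column) - 1)]
    return pose


def apply_rotation(
    pose: ColumnPose,
    joint: int,
    profile: str,
    angle_deg: float,
    chain: bool = False,
) -> ColumnPose:
    """Rotate the joint's posterior vertebra rigidly about the joint pivot.

    ``profile`` selects the axis and sign convention (see :data:`PROFILES`).
    In pairwise mode (default, replicating two-vertebrae-at-a-time
    manipulation) only the vertebra directly behind the joint moves; with
    ``chain=True`` every vertebra behind it moves too, for whole-neck sweeps.
    """
    if profile not in PROFILES:
        raise ParameterError(f"unknown profile {profile!r}")
    if not 0 <= joint < len(pose.column) - 1:
        raise ParameterError(f"joint index {joint} out of range")
    if abs(angle_deg) > 180:
        raise ParameterError("|angle| must be <= 180 degrees")
    attr, sign = PROFILES[profile]
    jf = pose.joints[joint]
    axis = getattr(jf, attr)
    theta = np.deg2rad(sign * angle_deg)

    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)
    a4 = np.eye(4)
    a4[:3, :3] = rot
    a4[:3, 3] = jf.pivot - rot @ jf.pivot

    out = pose.copy()
    movers = range(joint + 1, len(pose.column)) if chain else (joint + 1,)
    for j in movers:
        out.transforms[j] = a4 @ out.transforms[j]
    key = (joint, profile)
    out.applied[key] = out.applied.get(key, 0.0) + angle_deg
    return out


def _centrum_surfaces(pose: ColumnPose, cache: dict) -> None:
    for vert in pose.column:
        if vert.id not in cache:
            mesh = vert.parts["centrum"]
            cache[vert.id] = PartSurface(mesh.vertices, mesh.faces)


def reduce_spacing(pose: ColumnPose, eps: float = 1e-3) -> ColumnPose:
    """Collapse every intervertebral gap until the centra touch.

    Each posterior vertebra (with everything behind it) is translated along
    the chain axis toward its anterior neighbour until the centrum-centrum
    surface distance lies in ``[0, eps]`` mm, with no interpenetration.  The
    result is the minimum-spacing pose; joint frames are recomputed at the
    collapsed-gap midpoints and the applied per-joint translations are
    recorded so the preserved pose can be recovered.
    """
    if any(abs(a) > 0 for a in pose.applied.values()):
        raise PoseError("reduce_spacing expects a neutral starting pose")
    out = pose.copy()
    ex = np.array([1.0, 0.0, 0.0])
    cache: dict[str, PartSurface] = {}
    _centrum_surfaces(out, cache)
    translations = []

    for j in range(len(out.column) - 1):
        a = cache[out.column[j].id]
        b = cache[out.column[j + 1].id]
        ta = out.transforms[j]

        def dist(t: float) -> float:
            tb = out.transforms[j + 1].copy()
            tb[:3, 3] += t * ex
            d, _, _ = pair_min_distance(a, ta, b, tb)
            return d

        d0 = dist(0.0)
        if d0 <= eps:
            translations.append(0.0)
            continue
        # expand the bracket until the surfaces meet or the search exceeds
        # the available gap (plus a small margin for concave faces)
        hi = d0
        limit = d0 + 2 * (a.radius + b.radius)
        while dist(hi) > eps / 2:
            hi *= 1.5
            if hi > limit:
                raise ReductionError(
                    f"joint {j}: spacing reduction did not converge within the gap"
                )
        lo = 0.0
        while hi - lo > eps / 4:
            mid = (lo + hi) / 2
            if dist(mid) > eps / 2:
                lo = mid
            else:
                hi = mid
        t_star = hi
        d_final = dist(t_star)
        if not 0.0 <= d_final <= eps:
            raise ReductionError(f"joint {j}: final centrum distance {d_final:.4g} outside [0, eps]")
        for k in range(j + 1, len(out.column)):
            out.transforms[k][:3, 3] += t_star * ex
        translations.append(float(t_star))

    out.mode = "minimum"
    out.reduction_translations = translations
    out.joints = [compute_pivot(out, j) for j in range(len(out.column) - 1)]
    return out
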