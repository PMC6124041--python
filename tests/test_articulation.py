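"""Chain kinematics: neutral spacing, pivots, spacing reduction, rotations."""

import numpy as np
import pytest

from vertrom._proximity import per_point_min_dist
from vertrom.articulation import (
    apply_rotation,
    compute_pivot,
    neutral_pose,
    reduce_spacing,
)
from vertrom.errors import ParameterError, PoseError
from vertrom.synthetic import ColumnSpec, VertebraParams, make_column, make_sphere_pair


def test_neutral_pose_sphere_pair(sphere_pose):
    jf = sphere_pose.joints[0]
    centers = [t[:3, 3] for t in sphere_pose.transforms]
    assert np.linalg.norm(centers[0] - centers[1]) == pytest.approx(2.2, abs=1e-12)
    # pivot at the gap midpoint, 1.1 mm from either center
    assert np.linalg.norm(jf.pivot - centers[0]) == pytest.approx(1.1, abs=1e-12)
    assert jf.gap == pytest.approx(0.2, abs=1e-12)
    assert sphere_pose.applied == {}


def test_neutral_pose_reproduces_requested_gaps():
    column, _ = make_column(ColumnSpec(n_vertebrae=5, base=VertebraParams(mesh_resolution=8)))
    pose = neutral_pose(column, gaps=[1.0, 2.0, 3.0, 4.0])
    for j, expected in enumerate([1.0, 2.0, 3.0, 4.0]):
        d = np.linalg.norm(
            pose.world_landmark(j, "posterior") - pose.world_landmark(j + 1, "anterior")
        )
        assert d == pytest.approx(expected, abs=1e-6)


def test_pivot_on_median_plane(small_column):
    column, gaps = small_column
    pose = neutral_pose(column, gaps=gaps)
    for jf in pose.joints:
        assert abs(jf.pivot[1]) < 1e-9
        jf.validate()


def test_rotation_inverse_and_rigidity(small_column):
    column, gaps = small_column
    pose = neutral_pose(column, gaps=gaps)
    out = apply_rotation(apply_rotation(pose, 0, "dorsal", 17.3), 0, "dorsal", -17.3)
    for t0, t1 in zip(pose.transforms, out.transforms):
        assert np.max(np.abs(t0 - t1)) < 1e-9

    rot = apply_rotation(pose, 1, "lateral", 33.0)
    verts = column[2].parts["centrum"].vertices[::7]
    t = rot.transforms[2]
    posed = verts @ t[:3, :3].T + t[:3, 3]
    d_before = np.linalg.norm(verts[:, None] - verts[None], axis=-1)
    d_after = np.linalg.norm(posed[:, None] - posed[None], axis=-1)
    assert np.max(np.abs(d_before - d_after)) < 1e-9


def test_rotation_closed_form_circle(sphere_pose):
    """The rotated sphere center stays on a circle of radius r + g/2 about the pivot."""
    jf = sphere_pose.joints[0]
    c0 = sphere_pose.transforms[0][:3, 3]
    for profile in ("lateral", "dorsal", "ventral"):
        for phi in (5.0, 20.0, 60.0):
            posed = apply_rotation(sphere_pose, 0, profile, phi)
            cb = posed.transforms[1][:3, 3]
            assert np.linalg.norm(cb - jf.pivot) == pytest.approx(1.1, abs=1e-9)
            expected = 1.1 * np.sqrt(2 + 2 * np.cos(np.deg2rad(phi)))
            assert np.linalg.norm(cb - c0) == pytest.approx(expected, abs=1e-9)


def test_rotation_sign_conventions(small_column):
    column, gaps = small_column
    pose = neutral_pose(column, gaps=gaps)
    assert apply_rotation(pose, 0, "dorsal", 15).world_landmark(1, "posterior")[2] > 1.0
    assert apply_rotation(pose, 0, "ventral", 15).world_landmark(1, "posterior")[2] < -1.0
    # lateral convention: posterior vertebra swings toward the right (-y)
    assert apply_rotation(pose, 0, "lateral", 15).world_landmark(1, "posterior")[1] < -1.0


def test_whole_chain_mode_propagates(small_column):
    column, gaps = small_column
    pose = neutral_pose(column, gaps=gaps)
    chained = apply_rotation(pose, 0, "dorsal", 10, chain=True)
    pairwise = apply_rotation(pose, 0, "dorsal", 10, chain=False)
    assert np.allclose(chained.transforms[1], pairwise.transforms[1])
    # the grandchild carries the same world rotation, the pairwise one does not
    assert not np.allclose(chained.transforms[2], pose.transforms[2])
    assert np.allclose(pairwise.transforms[2], pose.transforms[2])
    rel = np.linalg.inv(chained.transforms[1]) @ chained.transforms[2]
    rel0 = np.linalg.inv(pose.transforms[1]) @ pose.transforms[2]
    assert np.allclose(rel, rel0, atol=1e-9)


def test_reduce_spacing_sphere_pair(sphere_pose):
    reduced = reduce_spacing(sphere_pose, eps=1e-3)
    t = reduced.reduction_translations[0]
    assert 0.199 <= t <= 0.2
    assert reduced.mode == "minimum"
    # pivot recomputed at the collapsed-gap midpoint
    assert reduced.joints[0].gap < 2e-3


def test_reduce_spacing_touching_pair_is_fixed_point():
    pair, gap = make_sphere_pair(1.0, 0.0)
    pose = neutral_pose(pair, gaps=[gap])
    reduced = reduce_spacing(pose, eps=1e-2)
    assert reduced.reduction_translations == [0.0]


def test_reduce_spacing_proximity_oracle(small_column):
    """Post-reduction centrum gaps verified by exhaustive brute-force proximity."""
    column, gaps = small_column
    eps = 1e-2
    reduced = reduce_spacing(neutral_pose(column, gaps=gaps), eps=eps)
    for j in range(len(column) - 1):
        a = column[j].parts["centrum"]
        b = column[j + 1].parts["centrum"]
        ta, tb = reduced.transforms[j], reduced.transforms[j + 1]
        va = a.vertices @ ta[:3, :3].T + ta[:3, 3]
        vb = b.vertices @ tb[:3, :3].T + tb[:3, 3]
        d = min(
            per_point_min_dist(va, vb[b.faces]).min(),
            per_point_min_dist(vb, va[a.faces]).min(),
        )
        assert 0.0 <= d <= eps


def test_reduction_reexpansion_recovers_preserved_pose(small_column):
    column, gaps = small_column
    pose = neutral_pose(column, gaps=gaps)
    reduced = reduce_spacing(pose, eps=1e-2)
    ex = np.array([1.0, 0.0, 0.0])
    restored = [t.copy() for t in reduced.transforms]
    for j, tr in enumerate(reduced.reduction_translations):
        for k in range(j + 1, len(column)):
            restored[k][:3, 3] -= tr * ex
    for t0, t1 in zip(pose.transforms, restored):
        assert np.max(np.abs(t0 - t1)) < 1e-9


def test_reduce_spacing_requires_neutral(sphere_pose):
    rotated = apply_rotation(sphere_pose, 0, "dorsal", 5.0)
    with pytest.raises(PoseError):
        reduce_spacing(rotated)


def test_pose_errors(small_column):
    column, gaps = small_column
    with pytest.raises(PoseError):
        neutral_pose(column[:1])
    pose = neutral_pose(column, gaps=gaps)
    with pytest.raises(ParameterError):
        apply_rotation(pose, 5, "dorsal", 1.0)
    with pytest.raises(ParameterError):
        apply_rotation(pose, 0, "sideways", 1.0)
    with pytest.raises(ParameterError):
        apply_rotation(pose, 0, "dorsal", 181.0)
    with pytest.raises(ParameterError):
        compute_pivot(pose, 2)


def test_pose_serialization(tmp_path, sphere_pose):
    path = tmp_path / "pose.json"
    apply_rotation(sphere_pose, 0, "dorsal", 10).to_json(path)
    import json

    payload = json.loads(path.read_text())
    assert len(payload["vertebrae"]) == 2
    assert payload["applied"] == [{"joint": 0, "profile": "dorsal", "angle_deg": 10.0}]
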