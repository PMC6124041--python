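"""Generator invariants: symmetry, determinism, analytic extents, fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertrom.errors import ParameterError
from vertrom.mesh_io import MIRROR_PAIRS
from vertrom.synthetic import (
    ColumnSpec,
    GradientSpec,
    VertebraParams,
    make_column,
    make_sphere_pair,
    make_vertebra,
    sphere_discretization_bound,
    standin_angle_table,
    PLESIOSAUR_TRIAL_SUMMARY,
    VARANID_TRIAL_SUMMARY,
)


def _vertex_set(mesh):
    return np.array(sorted(map(tuple, np.round(mesh.vertices, 9))))


def test_part_toggles():
    params = VertebraParams(
        include_cervical_ribs=False, include_neural_spine=False, include_zygapophyses=False
    )
    vert = make_vertebra(params)
    assert vert.part_names == {"centrum"}
    vert = make_vertebra(VertebraParams(rib_length=0.0))
    assert "cervical_rib_L" not in vert.part_names


def test_bilateral_symmetry():
    vert = make_vertebra(VertebraParams(mesh_resolution=12))
    for name, mesh in vert.parts.items():
        partner = vert.parts[MIRROR_PAIRS.get(name, name)]
        reflected = mesh.vertices * np.array([1.0, -1.0, 1.0])
        a = np.array(sorted(map(tuple, np.round(reflected, 9))))
        b = _vertex_set(partner)
        assert a.shape == b.shape
        assert np.max(np.abs(a - b)) <= 1e-6, name


@pytest.mark.parametrize("height", [15.0, 25.0, 40.0])
def test_spine_height_sets_dorsal_extent(height):
    vert = make_vertebra(VertebraParams(spine_height=height))
    top = vert.parts["neural_spine"].vertices[:, 2].max()
    assert top == pytest.approx(height, abs=1e-9)


def test_determinism_bitwise():
    a = make_vertebra(VertebraParams(surface_jitter=0.05, seed=3))
    b = make_vertebra(VertebraParams(surface_jitter=0.05, seed=3))
    for name in a.parts:
        assert a.parts[name].export(file_type="obj") == b.parts[name].export(file_type="obj")
    c = make_vertebra(VertebraParams(surface_jitter=0.05, seed=4))
    assert not np.array_equal(a.parts["centrum"].vertices, c.parts["centrum"].vertices)


def test_column_counts_and_gaps():
    column, gaps = make_column(ColumnSpec(n_vertebrae=24, gap=1.5,
                                          base=VertebraParams(mesh_resolution=8)))
    assert len(column) == 24
    assert len(gaps) == 23
    assert all(g == 1.5 for g in gaps)


def test_damage_mask_removes_parts():
    spec = ColumnSpec(
        n_vertebrae=10,
        base=VertebraParams(mesh_resolution=8),
        damage={6: ("neural_spine",), 7: ("neural_spine",), 8: ("neural_spine", "cervical_rib_L")},
    )
    column, _ = make_column(spec)
    for i in (6, 7, 8):
        assert "neural_spine" not in column[i].part_names
    assert "cervical_rib_L" not in column[8].part_names
    assert "neural_spine" in column[0].part_names


def test_zero_gradient_gives_identical_vertebrae():
    column, _ = make_column(ColumnSpec(n_vertebrae=3, base=VertebraParams(mesh_resolution=8)))
    ref = column[0]
    for other in column[1:]:
        for name in ref.parts:
            assert np.array_equal(ref.parts[name].vertices, other.parts[name].vertices)


def test_gradient_changes_geometry():
    column, _ = make_column(
        ColumnSpec(
            n_vertebrae=3,
            base=VertebraParams(mesh_resolution=8),
            gradient=GradientSpec(spine_height=2.0),
        )
    )
    tops = [v.parts["neural_spine"].vertices[:, 2].max() for v in column]
    assert tops == pytest.approx([25.0, 27.0, 29.0])


def test_sphere_pair_construction(sphere_pose):
    centers = [t[:3, 3] for t in sphere_pose.transforms]
    assert np.linalg.norm(centers[0] - centers[1]) == pytest.approx(2.2, abs=1e-12)


def test_sphere_pair_touching_at_zero_gap():
    from vertrom._proximity import PartSurface, pair_min_distance
    from vertrom.articulation import neutral_pose

    pair, gap = make_sphere_pair(1.0, 0.0)
    pose = neutral_pose(pair, gaps=[gap])
    a = PartSurface(pair[0].parts["centrum"].vertices, pair[0].parts["centrum"].faces)
    b = PartSurface(pair[1].parts["centrum"].vertices, pair[1].parts["centrum"].faces)
    d, _, _ = pair_min_distance(a, pose.transforms[0], b, pose.transforms[1])
    bound = sphere_discretization_bound(pair[0], 1.0)
    assert abs(d) <= 2 * bound + 1e-9


def test_sphere_mesh_deviation_bound():
    pair, _ = make_sphere_pair(2.0, 0.1)
    mesh = pair[0].parts["centrum"]
    bound = sphere_discretization_bound(pair[0], 2.0)
    radii = np.linalg.norm(mesh.vertices - mesh.vertices.mean(0), axis=1)
    assert np.max(np.abs(radii - 2.0)) <= 1e-9  # vertices exactly on the sphere
    assert 0 < bound < 0.02 * 2.0  # faces sag inward by less than 2% of r


@pytest.mark.parametrize(
    "kwargs",
    [
        {"concavity_depth": 10.0},
        {"mesh_resolution": 4},
        {"centrum_radius": 0.0},
        {"spine_height": 5.0},
        {"surface_jitter": -1.0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ParameterError):
        make_vertebra(VertebraParams(**kwargs))


def test_invalid_column_specs_rejected():
    with pytest.raises(ParameterError):
        make_column(ColumnSpec(n_vertebrae=1))
    with pytest.raises(ParameterError):
        make_column(ColumnSpec(n_vertebrae=3, gap=(1.0,)))
    with pytest.raises(ParameterError):
        make_sphere_pair(-1.0, 0.1)


@given(
    r=st.sampled_from([0.5, 1.0, 2.0]),
    g=st.floats(min_value=0.0, max_value=1.0),
)
@settings(max_examples=10, deadline=None)
def test_sphere_pair_center_distance_property(r, g):
    from vertrom.articulation import neutral_pose

    pair, gap = make_sphere_pair(r, g, subdivisions=1)
    pose = neutral_pose(pair, gaps=[gap])
    d = np.linalg.norm(pose.transforms[0][:3, 3] - pose.transforms[1][:3, 3])
    assert d == pytest.approx(2 * r + g, abs=1e-9)


def test_standin_angle_table_matches_published_moments():
    for summary in (PLESIOSAUR_TRIAL_SUMMARY, VARANID_TRIAL_SUMMARY):
        df = standin_angle_table(summary)
        assert (df["angle_deg"] >= 0).all()
        for (trial, profile), (n, mean, sd) in summary.items():
            sub = df[(df["trial"] == trial) & (df["profile"] == profile)]["angle_deg"]
            assert len(sub) == n
            assert sub.mean() == pytest.approx(mean, abs=1e-9)
            assert sub.std(ddof=1) == pytest.approx(sd, abs=1e-9)
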