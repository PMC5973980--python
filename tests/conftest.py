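"""Shared fixtures: analytic micro-phantoms and the reference phantom.

Everything is generated at test time; session scope keeps the expensive
reference-phantom pipeline (volume -> anatomy -> candidate planes -> scored
planes) to a single run shared by the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import eusplan as e
from eusplan.phantom import OrganSpec, PhantomSpec, TubeSpec


# ---------------------------------------------------------------------------
# analytic micro-phantoms

@pytest.fixture(scope="session")
def cube_volume():
    vox = np.zeros((30, 30, 30), dtype=np.int32)
    vox[5:25, 5:25, 5:25] = 1  # 20 mm cube at 1 mm spacing
    return e.LabeledVolume(vox, (1, 1, 1), (0, 0, 0),
                           {1: e.LabelInfo("cube", "organ")})


@pytest.fixture(scope="session")
def sphere_volume():
    x, y, z = np.mgrid[:60, :60, :60]
    vox = (((x - 30) ** 2 + (y - 30) ** 2 + (z - 30) ** 2) <= 15 ** 2
           ).astype(np.int32)
    return e.LabeledVolume(vox, (1, 1, 1), (0, 0, 0),
                           {1: e.LabelInfo("sphere", "organ")})


@pytest.fixture(scope="session")
def cylinder_volume():
    """Straight cylinder, radius 3 mm, length 60 mm along z, axis at
    (10.0, 10.0)."""
    x, y, z = np.mgrid[:21, :21, :80]
    vox = ((((x - 10) ** 2 + (y - 10) ** 2) <= 3 ** 2)
           & (z >= 10) & (z < 70)).astype(np.int32)
    return e.LabeledVolume(vox, (1, 1, 1), (0, 0, 0),
                           {1: e.LabelInfo("cyl", "tube")})


@pytest.fixture(scope="session")
def l_tube_volume():
    """L-shaped tube: radius 2.5 mm arms along z then x."""
    x, y, z = np.mgrid[:60, :21, :60]
    arm1 = (((x - 10) ** 2 + (y - 10) ** 2) <= 2.5 ** 2) & (z >= 8) & (z <= 45)
    arm2 = (((z - 45) ** 2 + (y - 10) ** 2) <= 2.5 ** 2) & (x >= 10) & (x <= 50)
    return e.LabeledVolume((arm1 | arm2).astype(np.int32), (1, 1, 1), (0, 0, 0),
                           {1: e.LabelInfo("ltube", "tube")})


# ---------------------------------------------------------------------------
# reference phantom pipeline (session-shared)

@pytest.fixture(scope="session")
def ref_spec():
    return e.reference_phantom()


@pytest.fixture(scope="session")
def ref_volume(ref_spec):
    volume, _ = e.generate_phantom(ref_spec)
    return volume


@pytest.fixture(scope="session")
def ref_ground_truth(ref_spec):
    _, gt = e.generate_phantom(ref_spec)
    return gt


@pytest.fixture(scope="session")
def ref_anatomy(ref_volume, ref_spec):
    return e.build_anatomy(ref_volume, target_label=ref_spec.target_label)


@pytest.fixture(scope="session")
def contact_vertex_normals(ref_anatomy):
    cs = ref_anatomy.contact_surfaces[0]
    mesh = trimesh.Trimesh(cs.points, cs.faces, process=False)
    return cs.points, np.asarray(mesh.vertex_normals)


@pytest.fixture(scope="session")
def candidate_planes(ref_volume, ref_anatomy, contact_vertex_normals):
    """Usable candidate planes from a fixed subset of contact vertices."""
    points, normals = contact_vertex_normals
    rng = np.random.default_rng(12345)
    vids = rng.choice(len(points), 12, replace=False)
    cands = []
    for vid in vids:
        planes = e.sample_planes_at_vertex(points[vid], normals[vid],
                                           e.RotationGrid(), vertex_id=int(vid))
        for pl in planes:
            feats = e.plane_features(pl, ref_anatomy, ref_volume)
            if e.plane_is_usable(feats):
                cands.append((pl, feats))
    assert len(cands) >= 30
    if len(cands) > 100:  # bound the session's simulation budget
        keep = np.sort(rng.choice(len(cands), 100, replace=False))
        cands = [cands[i] for i in keep]
    return cands


@pytest.fixture(scope="session")
def scored_planes(candidate_planes, ref_anatomy):
    """Every candidate plane scored with a modest optimisation budget."""
    noise = e.NoiseModel()
    out = []
    for i, (pl, feats) in enumerate(candidate_planes):
        res = e.simulate_plane(pl, ref_anatomy, noise, features=feats,
                               n_sims=100, seed=20_000 + i)
        out.append((pl, feats, res, 20_000 + i))
    return out
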