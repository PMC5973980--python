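"""Ultrasound sector-view planes and in-plane anatomical features.

A sector plane models the fan-shaped field of view of an endoscopic
ultrasound transducer: an apex (the transducer position, a vertex of the
contact-organ surface), an in-plane beam axis pointing into the tissue, a
plane normal, a fan angle (default 120 deg) and a scanning depth (default
50 mm) — the geometry of standard clinical EUS transducers.

Candidate views are sampled per contact vertex by rotating a base plane
(aligned with the inward surface normal) about the three axes of the
vertex's local frame on a uniform angular grid.  Each structure crossing a
plane contributes "features": connected cross-section components with an
area, a bounding box, and an automatically extracted landmark — the
centroid for vessels/ducts, the boundary point nearest the visible-boundary
mean for organs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .anatomy import LabeledVolume, Structure

EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RotationGrid:
    """Symmetric angular grid about the three local-frame axes."""

    range_deg: float = 60.0
    step_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.range_deg < 0 or self.step_deg <= 0:
            raise ValueError("angles must be non-negative, step positive")
        if self.range_deg > 0:
            k = 2 * self.range_deg / self.step_deg
            if abs(k - round(k)) > 1e-9:
                raise ValueError("step_deg must divide 2*range_deg")

    @property
    def angles(self) -> np.ndarray:
        if self.range_deg == 0:
            return np.array([0.0])
        n = int(round(2 * self.range_deg / self.step_deg)) + 1
        return np.linspace(-self.range_deg, self.range_deg, n)


@dataclass
class SectorPlane:
    """A posed 2D ultrasound sector view in 3D world coordinates.

    ``axis`` is the unit in-plane beam direction from the apex into the
    tissue; ``normal`` the unit plane normal.  In-plane coordinates are
    (u, v) with u along the axis and v along ``lateral = normal x axis``.
    """

    apex: np.ndarray
    normal: np.ndarray
    axis: np.ndarray
    fan_angle: float = 120.0
    depth: float = 50.0
    pixel_pitch: float = 0.5
    plane_id: int = -1
    vertex_id: int = -1

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        for v in (self.normal, self.axis):
            if abs(np.linalg.norm(v) - 1) > 1e-8:
                raise ValueError("normal and axis must be unit vectors")
        if abs(self.normal @ self.axis) > 1e-8:
            raise ValueError("normal must be orthogonal to axis")
        if not (0 < self.fan_angle < 180) or self.depth <= 0:
            raise ValueError("need 0 < fan_angle < 180 and depth > 0")

    @property
    def lateral(self) -> np.ndarray:
        return np.cross(self.normal, self.axis)

    def to_world(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)[..., None]
        v = np.asarray(v, dtype=float)[..., None]
        return self.apex + u * self.axis + v * self.lateral

    def grid(self, pitch: float | None = None) -> np.ndarray:
        """World coordinates of the sector's pixel centres at ``pitch``."""
        u, v, inside = self._raster_coords(pitch)
        return self.to_world(u[inside], v[inside])

    def _raster_coords(self, pitch: float | None = None):
        """Full rectangular raster (u, v in mm) plus the in-sector mask.

        Cached per (fan, depth, pitch) since every plane of a run shares
        the same sector geometry.
        """
        p = self.pixel_pitch if pitch is None else pitch
        return _sector_raster(self.fan_angle, self.depth, p)

    def to_dict(self) -> dict:
        frame = np.column_stack([self.axis, self.lateral, self.normal])
        quat = Rotation.from_matrix(frame).as_quat()
        return {"apex": self.apex.tolist(), "quaternion_xyzw": quat.tolist(),
                "fan_angle_deg": self.fan_angle, "depth_mm": self.depth,
                "pixel_pitch_mm": self.pixel_pitch,
                "plane_id": self.plane_id, "vertex_id": self.vertex_id}


@dataclass
class PlaneFeature:
    """One structure's visible cross-section in a sector plane."""

    structure_label: int
    kind: str  # organ | tube
    area_mm2: float
    bbox_w: float
    bbox_h: float
    landmark: np.ndarray = field(default=None)  # type: ignore[assignment]
    boundary_points: np.ndarray | None = None
    region_points: np.ndarray | None = None


class GeometryError(ValueError):
    pass


_RASTER_CACHE: dict[tuple[float, float, float], tuple] = {}


def _sector_raster(fan_angle: float, depth: float, pitch: float):
    key = (fan_angle, depth, pitch)
    if key not in _RASTER_CACHE:
        half = np.deg2rad(fan_angle / 2)
        vmax = depth * np.sin(min(half, np.pi / 2))
        us = np.arange(pitch / 2, depth, pitch)
        vs = np.arange(-vmax + pitch / 2, vmax, pitch)
        U, V = np.meshgrid(us, vs, indexing="ij")
        R = np.hypot(U, V)
        ang = np.arctan2(np.abs(V), U)
        inside = (R <= depth) & (ang <= half)
        _RASTER_CACHE[key] = (U, V, inside)
    return _RASTER_CACHE[key]


def _tangent_frame(inward: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal tangents for a unit inward normal."""
    ref = np.eye(3)[np.argmin(np.abs(inward))]
    t1 = np.cross(inward, ref)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(inward, t1)


def sample_planes_at_vertex(vertex: np.ndarray, outward_normal: np.ndarray,
                            grid: RotationGrid = RotationGrid(), *,
                            fan_angle: float = 120.0, depth: float = 50.0,
                            pixel_pitch: float = 0.5,
                            vertex_id: int = -1) -> list[SectorPlane]:
    """All candidate sector planes at one contact-surface vertex.

    The base plane's beam axis is the inward surface normal; the grid's
    angle triples are applied as intrinsic rotations about the local frame
    axes (tangent1, tangent2, inward) in that fixed order, giving
    ``len(grid.angles)**3`` planes (125 at the default 60 deg range /
    30 deg step).
    """
    n = np.asarray(outward_normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise GeometryError("zero outward normal")
    inward = -n / nn
    t1, t2 = _tangent_frame(inward)
    frame = np.column_stack([t1, t2, inward])  # local -> world
    planes = []
    pid = 0
    for a in grid.angles:
        for b in grid.angles:
            for c in grid.angles:
                rot = Rotation.from_euler("XYZ", [a, b, c], degrees=True)
                local = rot.as_matrix()
                axis = frame @ local[:, 2]      # rotated inward normal
                normal = frame @ local[:, 0]    # rotated first tangent
                planes.append(SectorPlane(
                    apex=vertex, normal=normal, axis=axis,
                    fan_angle=fan_angle, depth=depth, pixel_pitch=pixel_pitch,
                    plane_id=pid, vertex_id=vertex_id))
                pid += 1
    return planes


def point_in_sector(p: np.ndarray, plane: SectorPlane) -> bool:
    """True iff ``p`` lies in the plane (within half a pixel), within the
    scanning depth of the apex, and within half the fan angle of the axis."""
    r = np.asarray(p, dtype=float) - plane.apex
    if abs(r @ plane.normal) > plane.pixel_pitch / 2:
        return False
    u = r @ plane.axis
    v = r @ plane.lateral
    if np.hypot(u, v) > plane.depth:
        return False
    return np.arctan2(abs(v), u) <= np.deg2rad(plane.fan_angle / 2) + 1e-12


def _sample_labels(plane: SectorPlane, volume: LabeledVolume,
                   U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Nearest-neighbour labels of the volume at the plane's pixel centres."""
    world = plane.to_world(U, V)
    idx = np.rint(volume.world_to_index(world)).astype(int)
    shape = np.array(volume.voxels.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=-1)
    idx = np.clip(idx, 0, shape - 1)
    lab = volume.voxels[idx[..., 0], idx[..., 1], idx[..., 2]]
    return np.where(ok, lab, 0)


def intersect_structure(plane: SectorPlane, s: Structure,
                        volume: LabeledVolume) -> list[PlaneFeature]:
    """Cross-section features of one structure visible in a sector plane.

    The labelled volume is resampled on the plane's pixel grid
    (nearest-neighbour at ``pixel_pitch``); 8-connected components of the
    structure's in-sector mask become features.  Organ boundaries are taken
    from the unclipped in-plane contour so that sector-edge clipping lines
    are not mistaken for anatomy.
    """
    U, V, in_sector = plane._raster_coords()
    labels = _sample_labels(plane, volume, U, V)
    return _features_from_label_image(plane, s, labels, U, V, in_sector)


def _features_from_label_image(plane: SectorPlane, s: Structure,
                               labels: np.ndarray, U: np.ndarray,
                               V: np.ndarray, in_sector: np.ndarray
                               ) -> list[PlaneFeature]:
    mask_full = labels == s.label
    mask = mask_full & in_sector
    if not mask.any():
        return []
    # contour of the full cross-section (8-connectivity erosion residue)
    eroded = ndimage.binary_erosion(mask_full, structure=EIGHT_CONN,
                                    border_value=0)
    contour_full = mask_full & ~eroded
    comp, ncomp = ndimage.label(mask, structure=EIGHT_CONN)
    pitch = plane.pixel_pitch
    feats: list[PlaneFeature] = []
    for ci in range(1, ncomp + 1):
        m = comp == ci
        area = float(m.sum()) * pitch * pitch
        uu, vv = U[m], V[m]
        bbox_h = float(uu.max() - uu.min()) + pitch   # along the beam axis
        bbox_w = float(vv.max() - vv.min()) + pitch   # lateral
        region = plane.to_world(uu, vv)
        bmask = m & contour_full & in_sector
        boundary = plane.to_world(U[bmask], V[bmask]) if bmask.any() else None
        f = PlaneFeature(structure_label=s.label, kind=s.kind,
                         area_mm2=area, bbox_w=bbox_w, bbox_h=bbox_h,
                         boundary_points=boundary, region_points=region)
        if s.kind == "organ" and boundary is None:
            continue  # no identifiable contour inside the sector
        f.landmark = extract_landmark(f)
        feats.append(f)
    return feats


def extract_landmark(f: PlaneFeature) -> np.ndarray:
    """The automatically extracted landmark of one feature.

    Tubes (vessels/ducts): the cross-section centroid (centre of mass of
    the region pixels).  Organs: the visible-boundary point closest to the
    mean of all visible-boundary points.
    """
    if f.kind == "tube":
        if f.region_points is None or len(f.region_points) == 0:
            raise ValueError("empty feature")
        return f.region_points.mean(axis=0)
    if f.boundary_points is None or len(f.boundary_points) == 0:
        raise ValueError("empty feature")
    mean = f.boundary_points.mean(axis=0)
    d = np.linalg.norm(f.boundary_points - mean, axis=1)
    return f.boundary_points[int(np.argmin(d))]


def filter_features(features: list[PlaneFeature],
                    min_area_mm2: float = 5.0) -> list[PlaneFeature]:
    """Discard features with cross-sectional area below ``min_area_mm2``
    (too small to identify confidently on EUS); order preserved."""
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be non-negative")
    return [f for f in features if f.area_mm2 >= min_area_mm2]


def plane_is_usable(features: list[PlaneFeature]) -> bool:
    """A plane supports six-degree-of-freedom registration only with three
    or more (area-filtered) features."""
    return len(features) >= 3


def plane_features(plane: SectorPlane, anatomy, volume: LabeledVolume, *,
                   min_area_mm2: float = 5.0,
                   exclude_labels: set[int] | None = None) -> list[PlaneFeature]:
    """All filtered features of a plane across every structure.

    The volume is resampled onto the plane once and shared by all
    structures, so this is much cheaper than calling
    :func:`intersect_structure` per structure.
    """
    U, V, in_sector = plane._raster_coords()
    labels = _sample_labels(plane, volume, U, V)
    present = set(np.unique(labels[in_sector]).tolist())
    feats: list[PlaneFeature] = []
    for lab, s in anatomy.structures.items():
        if lab not in present or (exclude_labels and lab in exclude_labels):
            continue
        feats.extend(_features_from_label_image(plane, s, labels, U, V,
                                                in_sector))
    return filter_features(feats, min_area_mm2)
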