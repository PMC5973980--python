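"""Synthetic labelled abdominal phantoms with known analytic geometry.

Every stage of the planning pipeline (surface/centreline extraction, plane
sampling, registration, TRE simulation) is testable against these phantoms
because each voxelised structure is generated from an analytic primitive —
(super)ellipsoids for organs, tubes of constant radius around polylines for
vessels and ducts — whose parameters are returned alongside the volume.

The reference phantom mimics an upper-abdominal segmentation inventory
(stomach shell as the transducer contact surface, pancreas target, liver,
gallbladder, left kidney, aorta, inferior vena cava, portal and splenic
veins) at clinically realistic sizes, and is deliberately asymmetric so
that rigid registration has a unique global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import LabeledVolume, LabelInfo


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class OrganSpec:
    """A (super)ellipsoid, optionally hollow (shell) and rotated about z.

    ``exponent`` = 2 gives an ordinary ellipsoid; larger exponents flatten
    towards a box.  ``shell_mm`` > 0 keeps only the outer shell of that
    thickness (used for the stomach wall).
    """

    label: int
    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    rotation_z_deg: float = 0.0
    exponent: float = 2.0
    shell_mm: float = 0.0
    kind: str = "organ"  # or "contact_surface_organ"


@dataclass(frozen=True)
class TubeSpec:
    """Constant-radius tube around a polyline path (world mm)."""

    label: int
    name: str
    path: tuple[tuple[float, float, float], ...]
    radius_mm: float


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organs: tuple[OrganSpec, ...] = ()
    tubes: tuple[TubeSpec, ...] = ()
    contact_labels: tuple[int, ...] = ()
    target_label: int | None = None
    seed: int = 0


@dataclass
class GroundTruth:
    """Analytic parameters of every generated structure, for oracle tests."""

    organs: dict[int, OrganSpec] = field(default_factory=dict)
    tubes: dict[int, TubeSpec] = field(default_factory=dict)


class PhantomSpecError(ValueError):
    pass


def _superellipsoid_inside(p: np.ndarray, org: OrganSpec) -> np.ndarray:
    rel = (p - np.array(org.center)) @ _rot_z(org.rotation_z_deg)
    q = np.abs(rel / np.array(org.radii)) ** org.exponent
    return q.sum(axis=-1) <= 1.0


def _dist_to_polyline(p: np.ndarray, path: np.ndarray) -> np.ndarray:
    d = np.full(len(p), np.inf)
    for a, b in zip(path[:-1], path[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((p - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, p.shape)
        d = np.minimum(d, np.linalg.norm(p - proj, axis=1))
    return d


def _axis_worlds(spec: PhantomSpec) -> list[np.ndarray]:
    return [spec.origin[ax] + np.arange(spec.shape[ax]) * spec.spacing[ax]
            for ax in range(3)]


def _check_bounds(spec: PhantomSpec) -> None:
    lo = np.array(spec.origin)
    hi = lo + (np.array(spec.shape) - 1) * np.array(spec.spacing)
    for org in spec.organs:
        c, r = np.array(org.center), max(org.radii)
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise PhantomSpecError(f"organ {org.name!r} exceeds volume bounds")
    for tube in spec.tubes:
        path = np.array(tube.path)
        if (np.any(path - tube.radius_mm < lo)
                or np.any(path + tube.radius_mm > hi)):
            raise PhantomSpecError(f"tube {tube.name!r} exceeds volume bounds")


def generate_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, GroundTruth]:
    """Voxelise a phantom spec; later-listed structures overwrite earlier ones.

    Organs are filled where the implicit superellipsoid function is <= 1
    (minus the hollow interior for shells); tubes where the distance to the
    polyline is <= the radius.  Deterministic for a given spec.
    """
    labels = [o.label for o in spec.organs] + [t.label for t in spec.tubes]
    if len(set(labels)) != len(labels):
        raise PhantomSpecError("duplicate labels in phantom spec")
    _check_bounds(spec)

    ax = _axis_worlds(spec)
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    vox = np.zeros(spec.shape, dtype=np.int32)
    gt = GroundTruth()
    table: dict[int, LabelInfo] = {}

    for org in spec.organs:
        inside = _superellipsoid_inside(pts, org)
        if org.shell_mm > 0:
            inner = OrganSpec(org.label, org.name, org.center,
                              tuple(max(r - org.shell_mm, 0.1) for r in org.radii),
                              org.rotation_z_deg, org.exponent)
            inside &= ~_superellipsoid_inside(pts, inner)
        vox[inside] = org.label
        gt.organs[org.label] = org
        kind = "contact_surface_organ" if (org.label in spec.contact_labels
                                           or org.kind == "contact_surface_organ") \
            else "organ"
        table[org.label] = LabelInfo(org.name, kind)

    flat = pts.reshape(-1, 3)
    for tube in spec.tubes:
        path = np.array(tube.path, dtype=float)
        # restrict the distance computation to the tube's bounding box
        lo = path.min(axis=0) - tube.radius_mm - 1.0
        hi = path.max(axis=0) + tube.radius_mm + 1.0
        sel = np.all((flat >= lo) & (flat <= hi), axis=1)
        d = _dist_to_polyline(flat[sel], path)
        mask = np.zeros(len(flat), dtype=bool)
        mask[np.flatnonzero(sel)[d <= tube.radius_mm]] = True
        vox[mask.reshape(spec.shape)] = tube.label
        gt.tubes[tube.label] = tube
        table[tube.label] = LabelInfo(tube.name, "tube")

    volume = LabeledVolume(vox, np.array(spec.spacing), np.array(spec.origin),
                           table)
    return volume, gt


def reference_phantom() -> PhantomSpec:
    """The fixed reference phantom used throughout the test suite.

    150 x 150 x 130 mm at 1 mm isotropic spacing.  The hollow, rotated
    stomach shell is the transducer contact surface; the pancreas (an
    elongated ellipsoid behind it, flanked by the splenic vein) is the
    clinical target.  Organ radii, wall thickness and vessel calibres are at
    adult-abdominal scale; rotations and offsets remove all rigid
    self-symmetry.
    """
    organs = (
        OrganSpec(1, "stomach", center=(62, 58, 72), radii=(33, 27, 41),
                  rotation_z_deg=25.0, shell_mm=4.0,
                  kind="contact_surface_organ"),
        OrganSpec(2, "liver", center=(100, 52, 92), radii=(36, 28, 26),
                  rotation_z_deg=-15.0),
        OrganSpec(3, "pancreas", center=(82, 97, 70), radii=(37, 12, 10),
                  rotation_z_deg=-18.0),
        OrganSpec(4, "gallbladder", center=(104, 78, 70), radii=(9, 7, 13)),
        OrganSpec(5, "left_kidney", center=(38, 104, 50), radii=(13, 11, 21),
                  rotation_z_deg=10.0),
    )
    tubes = (
        TubeSpec(6, "aorta",
                 path=((70, 114, 10), (71, 112, 60), (73, 110, 120)),
                 radius_mm=6.0),
        TubeSpec(7, "inferior_vena_cava",
                 path=((92, 110, 10), (91, 108, 120)), radius_mm=5.0),
        TubeSpec(8, "splenic_vein",
                 path=((34, 86, 74), (52, 90, 72), (70, 96, 70),
                       (84, 102, 71)),
                 radius_mm=3.2),
        TubeSpec(9, "portal_vein",
                 path=((84, 102, 71), (92, 88, 80), (98, 74, 88)),
                 radius_mm=4.0),
    )
    return PhantomSpec(shape=(150, 150, 130), spacing=(1.0, 1.0, 1.0),
                       organs=organs, tubes=tubes,
                       contact_labels=(1,), target_label=3, seed=0)
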