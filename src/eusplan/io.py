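"""Serialisation of structures, planes, distributions and maps.

Meshes go to PLY (with an optional per-vertex ``quality`` scalar so TRE
maps open directly in standard mesh viewers), centrelines to CSV point
lists, planes to JSON, TRE distributions to CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import Structure
from .planes import SectorPlane
from .selection import PlaneScore, TreMap
from .simulation import TreDistribution


def write_ply(path: str | Path, points: np.ndarray, faces: np.ndarray,
              quality: np.ndarray | None = None) -> None:
    """ASCII PLY writer with an optional per-vertex scalar ``quality``
    property (unusable vertices may carry NaN)."""
    path = Path(path)
    lines = ["ply", "format ascii 1.0",
             f"element vertex {len(points)}",
             "property float x", "property float y", "property float z"]
    if quality is not None:
        lines.append("property float quality")
    lines += [f"element face {len(faces)}",
              "property list uchar int vertex_indices", "end_header"]
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i, p in enumerate(points):
            row = f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}"
            if quality is not None:
                row += f" {quality[i]:.4f}"
            fh.write(row + "\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_structure(path: str | Path, s: Structure) -> None:
    """Organ meshes as PLY; tube centrelines as CSV point lists."""
    path = Path(path)
    if s.kind == "organ":
        write_ply(path.with_suffix(".ply"), s.points, s.faces)
    else:
        pd.DataFrame(s.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            path.with_suffix(".csv"), index=False)


def write_tre_map(path: str | Path, tmap: TreMap) -> None:
    write_ply(path, tmap.mesh.points, tmap.mesh.faces, quality=tmap.values)


def write_planes_json(path: str | Path, planes: list[SectorPlane]) -> None:
    Path(path).write_text(json.dumps([p.to_dict() for p in planes], indent=1))


def write_distribution_csv(path: str | Path, dist: TreDistribution) -> None:
    pd.DataFrame({"tre_mm": dist.samples_mm}).to_csv(path, index=False)


def write_scores_csv(path: str | Path, scores: list[PlaneScore]) -> None:
    rows = [{"plane_id": "/".join(map(str, s.plane_id)), "p90_mm": s.p90_mm,
             "mean_mm": s.mean_mm, "sd_mm": s.sd_mm, "n_sims": s.n_sims,
             "n_tubes": s.n_tubes, "n_organs": s.n_organs} for s in scores]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")
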