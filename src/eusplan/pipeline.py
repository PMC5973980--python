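"""End-to-end planning pipeline.

From a labelled volume to a ranked list of EUS initialisation planes:

1. extract structures (surfaces / centrelines), decimate the contact mesh;
2. sample candidate sector planes at contact-surface vertices;
3. keep planes with >= 3 area-filtered features;
4. Monte-Carlo simulate each plane's TRE distribution and rank by p90;
5. optionally sample plane pairs (Latin hypercube) and rank those;
6. re-estimate the winners on independent simulations;
7. assemble the per-vertex TRE map and persist everything with a manifest.

Every random draw descends from the single run seed, so a run is
reproducible bit for bit from its manifest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import io as eio
from .anatomy import AnatomyModel, LabeledVolume, build_anatomy
from .config import RunConfig
from .planes import (PlaneFeature, RotationGrid, SectorPlane, plane_features,
                     plane_is_usable, sample_planes_at_vertex)
from .selection import (PlaneScore, TreMap, build_tre_map, reestimate,
                        sample_pairs_lhs, score_from_result, select_optimal)
from .simulation import NoiseModel, simulate_pair, simulate_plane

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class CandidatePlane:
    plane: SectorPlane
    features: list[PlaneFeature]

    @property
    def key(self) -> tuple[int, int]:
        return (self.plane.vertex_id, self.plane.plane_id)


@dataclass
class PipelineResult:
    anatomy: AnatomyModel
    candidates: list[CandidatePlane]
    single_scores: list[PlaneScore]
    pair_scores: list[PlaneScore]
    best_single: PlaneScore | None
    best_pair: PlaneScore | None
    best_single_reest: PlaneScore | None
    best_pair_reest: PlaneScore | None
    tre_map: TreMap | None
    manifest: dict = field(default_factory=dict)


def _contact_vertices(anatomy: AnatomyModel, max_vertices: int | None,
                      rng: np.random.Generator):
    mesh_s = anatomy.contact_surfaces[0]
    mesh = trimesh.Trimesh(mesh_s.points, mesh_s.faces, process=False)
    normals = np.asarray(mesh.vertex_normals)
    ids = np.arange(len(mesh_s.points))
    if max_vertices is not None and max_vertices < len(ids):
        ids = np.sort(rng.choice(ids, size=max_vertices, replace=False))
    return [(int(i), mesh_s.points[i], normals[i]) for i in ids]


def find_usable_planes(volume: LabeledVolume, anatomy: AnatomyModel,
                       cfg: RunConfig, rng: np.random.Generator
                       ) -> list[CandidatePlane]:
    """Sample planes at contact vertices and keep the usable ones."""
    grid = RotationGrid(cfg.grid_range_deg, cfg.grid_step_deg)
    out: list[CandidatePlane] = []
    for vid, vtx, nrm in _contact_vertices(anatomy, cfg.max_vertices, rng):
        planes = sample_planes_at_vertex(
            vtx, nrm, grid, fan_angle=cfg.fan_angle_deg, depth=cfg.depth_mm,
            pixel_pitch=cfg.pixel_pitch_mm, vertex_id=vid)
        for pl in planes:
            feats = plane_features(pl, anatomy, volume,
                                   min_area_mm2=cfg.min_area_mm2)
            if plane_is_usable(feats):
                out.append(CandidatePlane(pl, feats))
    return out


def run_pipeline(volume: LabeledVolume | str | Path, cfg: RunConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full planning pipeline; write a result bundle if ``out_dir``
    is given."""
    t0 = time.time()
    if not isinstance(volume, LabeledVolume):
        volume = LabeledVolume.from_nifti(str(volume))
    if cfg.labels:
        volume.label_table = dict(cfg.labels)
    if not volume.label_table:
        raise ConfigError("no label roles configured")
    present = volume.labels_present()
    absent = [f"{info.name} ({lab})" for lab, info in volume.label_table.items()
              if lab not in present]
    if absent:
        raise ConfigError("labels named in the configuration are absent from "
                          "the volume: " + ", ".join(absent))

    anatomy = build_anatomy(volume, target_label=cfg.target_label,
                            contact_decimation_mm=cfg.decimation_edge_mm,
                            smoothing_sigma=cfg.smoothing_sigma_voxels)
    log.info("anatomy: %d structures, contact mesh %d vertices (%.1fs)",
             len(anatomy.structures), len(anatomy.contact_surfaces[0].points),
             time.time() - t0)

    rng = np.random.default_rng(cfg.seed)
    candidates = find_usable_planes(volume, anatomy, cfg, rng)
    log.info("usable planes: %d (%.1fs)", len(candidates), time.time() - t0)

    noise = NoiseModel(organ_sigma_mm=cfg.organ_sigma_mm,
                       tracking_sigma_pos_mm=cfg.tracking_sigma_pos_mm,
                       tracking_sigma_rot_deg=cfg.tracking_sigma_rot_deg)

    plane_seeds = {c.key: int(rng.integers(2 ** 31)) for c in candidates}
    single_scores = []
    results = {}
    for c in candidates:
        res = simulate_plane(c.plane, anatomy, noise, features=c.features,
                             n_sims=cfg.n_sims_single,
                             seed=plane_seeds[c.key], n_starts=cfg.n_starts,
                             tre_pitch=cfg.tre_pitch_mm)
        results[c.key] = res
        single_scores.append(score_from_result(c.key, res, c.features))
    best_single = select_optimal(single_scores)[0] if single_scores else None
    log.info("single-plane simulation done (%.1fs)", time.time() - t0)

    pair_scores: list[PlaneScore] = []
    best_pair = None
    pair_lookup = {}
    if cfg.pairs and len(candidates) >= 2:
        n_vert = len({c.plane.vertex_id for c in candidates})
        n_pairs = max(1, int(cfg.pair_budget_factor * n_vert))
        pair_seed = int(rng.integers(2 ** 31))
        pairs = sample_pairs_lhs(candidates, n_pairs, pair_seed)
        for ca, cb in pairs:
            key = ca.key + cb.key
            res = simulate_pair((ca.plane, cb.plane), anatomy, noise,
                                features=(ca.features, cb.features),
                                n_sims=cfg.n_sims_pair,
                                seed=int(rng.integers(2 ** 31)),
                                n_starts=cfg.n_starts,
                                tre_pitch=cfg.tre_pitch_mm)
            pair_lookup[key] = (ca, cb)
            pair_scores.append(
                score_from_result(key, res, ca.features + cb.features))
        if pair_scores:
            best_pair = select_optimal(pair_scores)[0]
        log.info("pair simulation done: %d pairs (%.1fs)", len(pair_scores),
                 time.time() - t0)

    # unbiased re-estimation of the winners on fresh seeds
    by_key = {c.key: c for c in candidates}
    best_single_reest = best_pair_reest = None
    if best_single is not None:
        fresh = int(rng.integers(2 ** 31))
        while fresh == plane_seeds[best_single.plane_id]:
            fresh = int(rng.integers(2 ** 31))
        cbest = by_key[best_single.plane_id]
        best_single_reest = reestimate(
            best_single, anatomy, noise, planes=cbest.plane,
            features=cbest.features, n=cfg.n_sims_reestimate,
            fresh_seed=fresh, opt_seed=plane_seeds[best_single.plane_id],
            n_starts=cfg.n_starts)
    if best_pair is not None:
        ca, cb = pair_lookup[best_pair.plane_id]
        best_pair_reest = reestimate(
            best_pair, anatomy, noise, planes=(ca.plane, cb.plane),
            features=(ca.features, cb.features), n=cfg.n_sims_reestimate,
            fresh_seed=int(rng.integers(2 ** 31)), opt_seed=cfg.seed,
            n_starts=cfg.n_starts)

    tre_map = build_tre_map(anatomy, single_scores) if single_scores else None

    manifest = {"config": cfg.to_manifest(),
                "n_candidate_planes": len(candidates),
                "plane_seeds": {"/".join(map(str, k)): v
                                for k, v in plane_seeds.items()},
                "elapsed_s": time.time() - t0}
    result = PipelineResult(anatomy, candidates, single_scores, pair_scores,
                            best_single, best_pair, best_single_reest,
                            best_pair_reest, tre_map, manifest)
    if out_dir is not None:
        _write_bundle(Path(out_dir), volume, result, results)
    return result


def _write_bundle(out: Path, volume: LabeledVolume, res: PipelineResult,
                  sims: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "structures").mkdir(exist_ok=True)
    for lab, s in res.anatomy.structures.items():
        eio.write_structure(out / "structures" / f"{s.name or lab}", s)
    eio.write_planes_json(out / "planes.json",
                          [c.plane for c in res.candidates])
    eio.write_scores_csv(out / "ranking_single.csv",
                         select_optimal(res.single_scores,
                                        len(res.single_scores))
                         if res.single_scores else [])
    if res.pair_scores:
        eio.write_scores_csv(out / "ranking_pairs.csv",
                             select_optimal(res.pair_scores,
                                            len(res.pair_scores)))
    if res.best_single is not None:
        eio.write_distribution_csv(
            out / "best_single_tre.csv",
            sims[res.best_single.plane_id].plane_tre)
    if res.tre_map is not None:
        eio.write_tre_map(out / "tre_map.ply", res.tre_map)
    summary = {}
    for name in ("best_single", "best_pair", "best_single_reest",
                 "best_pair_reest"):
        sc = getattr(res, name)
        if sc is not None:
            summary[name] = {"plane_id": list(sc.plane_id),
                             "p90_mm": sc.p90_mm, "mean_mm": sc.mean_mm,
                             "sd_mm": sc.sd_mm, "n_sims": sc.n_sims}
    eio.write_json(out / "summary.json", summary)
    eio.write_json(out / "manifest.json", res.manifest)
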